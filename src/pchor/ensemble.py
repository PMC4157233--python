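"""Protein electrostatic corrections averaged over protonation microstates.

The electrostatic influence of the protein environment on an active-site
reaction step is Δ_prot = E_elec(total system) − E_elec(active site), a
plain fixed-charge Coulomb difference (ε = 1, no cutoffs). Because each
titratable residue's contribution to a step energy is additive, the step
energy under any protonation microstate is a fixed part plus the sum of the
contributions of the protonated sites. The phenomenological ensemble
correction is the Boltzmann average over all 2^N protonation microstates,

    exp(−ΔE_avg/RT) = Σ_i p_i · exp(−ΔE_i/RT),

evaluated in log-sum-exp form. When the microstate distribution factorizes
over groups of sites (exact for independent groups, a good approximation
when groups collect the mutually correlated sites), the average decomposes
as ΔE_avg = Σ_groups ΔE_group, which reduces the 2^N enumeration to a sum
of 2^(N_g) enumerations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.special import logsumexp

from .thermo import CONSTANTS

__all__ = [
    "COULOMB_CONSTANT",
    "ChargeSet",
    "SiteContributionTable",
    "MicrostatePopulation",
    "read_pqr",
    "coulomb_energy",
    "delta_prot",
    "microstate_step_energy",
    "boltzmann_average_correction",
    "group_sites",
    "screen_by_effective_dielectric",
    "population_from_samples",
]

#: kcal·Å·mol⁻¹·e⁻²; Coulomb's law prefactor for charges in elementary units
COULOMB_CONSTANT = 332.0636

ACTIVE = "ACTIVE"
ENVIRONMENT = "ENVIRONMENT"


@dataclass
class ChargeSet:
    """Point charges with coordinates (Å) and ACTIVE/ENVIRONMENT region tags."""

    coordinates: np.ndarray  # (N, 3)
    charges: np.ndarray  # (N,)
    regions: np.ndarray  # (N,) of {"ACTIVE", "ENVIRONMENT"}
    residues: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.charges = np.asarray(self.charges, dtype=float)
        self.regions = np.asarray(self.regions, dtype=object)
        n = len(self.charges)
        if self.coordinates.shape != (n, 3):
            raise ValueError("coordinates must be (N, 3)")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")
        bad = set(self.regions) - {ACTIVE, ENVIRONMENT}
        if bad:
            raise ValueError(f"unknown region tags {bad}")
        if self.residues is None:
            self.residues = np.array([""] * n, dtype=object)

    @property
    def n_atoms(self) -> int:
        return len(self.charges)

    def mask(self, region: str) -> np.ndarray:
        return self.regions == region


def read_pqr(
    source: str | Path | IO[str],
    active_residues: Iterable[str] = (),
) -> ChargeSet:
    """Read a whitespace-separated PQR file into a :class:`ChargeSet`.

    Tolerant of the common dialect variations (optional chain id, insertion
    codes): the last five numeric fields of each ATOM/HETATM record are
    taken as x, y, z, charge, radius. Atoms whose ``resname_resseq`` (or
    chain-qualified ``resname_chain_resseq``) tag is listed in
    ``active_residues`` are tagged ACTIVE; all others ENVIRONMENT.
    """
    if isinstance(source, (str, Path)):
        lines = Path(source).read_text(encoding="utf-8").splitlines()
    else:
        lines = source.read().splitlines()
    active = set(active_residues)
    coords, charges, regions, residues = [], [], [], []
    for line in lines:
        if not line.startswith(("ATOM", "HETATM")):
            continue
        fields = line.split()
        if len(fields) < 8:
            raise ValueError(f"malformed PQR record: {line!r}")
        x, y, z, q = (float(v) for v in fields[-5:-1])
        # fields: record serial name resname [chain] resseq x y z q r
        resname = fields[3]
        resseq_idx = len(fields) - 6
        resseq = fields[resseq_idx]
        chain = fields[4] if resseq_idx == 5 else ""
        tag = f"{resname}_{resseq}"
        qualified = f"{resname}_{chain}_{resseq}" if chain else tag
        coords.append((x, y, z))
        charges.append(q)
        residues.append(qualified if chain else tag)
        regions.append(
            ACTIVE if (tag in active or qualified in active) else ENVIRONMENT
        )
    if not coords:
        raise ValueError("no ATOM/HETATM records found")
    return ChargeSet(
        np.array(coords), np.array(charges), np.array(regions, dtype=object),
        np.array(residues, dtype=object),
    )


def _pair_energy_matrix(charges: ChargeSet) -> np.ndarray:
    d = squareform(pdist(charges.coordinates))
    np.fill_diagonal(d, np.inf)
    if np.any(d == 0.0):
        raise ValueError("coincident atoms: zero interatomic distance")
    q = charges.charges
    return COULOMB_CONSTANT * np.outer(q, q) / d


def coulomb_energy(charges: ChargeSet, pair_filter: str = "all") -> float:
    """Pairwise Coulomb energy (kcal/mol) at ε = 1 over selected pairs.

    ``pair_filter``: ``"all"`` (every pair), ``"active"`` / ``"environment"``
    (pairs internal to one region), or ``"cross"`` (one atom in each).
    """
    if charges.n_atoms < 2:
        return 0.0
    e = _pair_energy_matrix(charges)
    a = charges.mask(ACTIVE)
    if pair_filter == "all":
        m = np.ones(charges.n_atoms, dtype=bool)
        sel = np.outer(m, m)
    elif pair_filter == "active":
        sel = np.outer(a, a)
    elif pair_filter == "environment":
        sel = np.outer(~a, ~a)
    elif pair_filter == "cross":
        sel = np.outer(a, ~a) | np.outer(~a, a)
    else:
        raise ValueError(f"unknown pair filter {pair_filter!r}")
    sel &= ~np.eye(charges.n_atoms, dtype=bool)
    return float(0.5 * e[sel].sum())


def delta_prot(charges: ChargeSet, cross_only: bool = False) -> float:
    """Protein electrostatic contribution Δ_prot (kcal/mol).

    Total electrostatic energy minus the ACTIVE-region internal energy;
    equals the cross-region interaction plus the ENVIRONMENT self-energy.
    The self-energy term is constant across intermediates sharing a frozen
    environment and cancels in step differences; ``cross_only=True`` drops
    it for diagnostics.
    """
    if not charges.mask(ENVIRONMENT).any():
        return 0.0
    cross = coulomb_energy(charges, "cross")
    if cross_only:
        return cross
    return cross + coulomb_energy(charges, "environment")


# -- per-site contributions and the ensemble average ----------------------


@dataclass
class SiteContributionTable:
    """Additive per-site contributions (kcal/mol) to each reaction step's
    electrostatic energy, paid when the site is protonated."""

    table: pd.DataFrame  # index = site ids, columns = step names

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.table.to_numpy(dtype=float))):
            raise ValueError("contributions must be finite")

    @property
    def site_ids(self) -> tuple[str, ...]:
        return tuple(self.table.index)

    @property
    def steps(self) -> tuple[str, ...]:
        return tuple(self.table.columns)

    def contribution(self, site_id: str, step: str) -> float:
        try:
            return float(self.table.at[site_id, step])
        except KeyError:
            raise KeyError(f"unknown site {site_id!r} or step {step!r}") from None

    @classmethod
    def from_tsv(cls, source: str | Path | IO[str]) -> "SiteContributionTable":
        return cls(pd.read_csv(source, sep="\t", index_col=0))

    def to_tsv(self, target: str | Path | IO[str]) -> None:
        self.table.to_csv(target, sep="\t")


@dataclass
class MicrostatePopulation:
    """Protonation-microstate distribution factorized over site groups.

    Each group is a list of site ids plus a list of (occupancy sub-vector,
    probability) pairs; within every group the probabilities sum to 1.
    """

    groups: list[tuple[tuple[str, ...], list[tuple[tuple[int, ...], float]]]]

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("empty population")
        seen: set[str] = set()
        for ids, states in self.groups:
            if not states:
                raise ValueError(f"group {ids} has no states")
            total = sum(p for _, p in states)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"group {ids} probabilities sum to {total}, expected 1"
                )
            for s, p in states:
                if len(s) != len(ids):
                    raise ValueError("sub-state length mismatch")
                if p < 0:
                    raise ValueError("negative probability")
            dup = seen & set(ids)
            if dup:
                raise ValueError(f"sites {dup} appear in more than one group")
            seen |= set(ids)

    @property
    def site_ids(self) -> tuple[str, ...]:
        return tuple(i for ids, _ in self.groups for i in ids)


def microstate_step_energy(
    table: SiteContributionTable,
    step: str,
    state: Mapping[str, int] | Sequence[int],
    fixed_part: float = 0.0,
) -> float:
    """Step energy under one protonation microstate: fixed part plus the
    contributions of the protonated sites."""
    if isinstance(state, Mapping):
        items = state.items()
    else:
        if len(state) != len(table.site_ids):
            raise ValueError("state vector length must match table sites")
        items = zip(table.site_ids, state)
    total = fixed_part
    for site_id, s in items:
        if s:
            total += table.contribution(site_id, step)
    return total


def boltzmann_average_correction(
    table: SiteContributionTable,
    step: str,
    population: MicrostatePopulation,
    temperature: float = CONSTANTS.temperature_titration,
    fixed_part: float = 0.0,
) -> float:
    """Boltzmann-averaged electrostatic correction ΔE_avg (kcal/mol).

    Per group g: ΔE_g = −RT·ln Σ_i p_i·exp(−ΔE_i/RT) over the group's
    sub-states, evaluated with log-sum-exp; the total is Σ_g ΔE_g plus the
    state-independent fixed part.
    """
    missing = set(table.site_ids) - set(population.site_ids)
    if missing:
        raise ValueError(f"population does not cover sites {missing}")
    rt = CONSTANTS.rt(temperature)
    total = fixed_part
    for ids, states in population.groups:
        contribs = np.array(
            [table.contribution(i, step) if i in table.site_ids else 0.0 for i in ids]
        )
        energies = np.array([np.dot(s, contribs) for s, _ in states])
        probs = np.array([p for _, p in states])
        keep = probs > 0
        total += -rt * logsumexp(-energies[keep] / rt, b=probs[keep])
    return float(total)


def population_from_samples(
    samples: np.ndarray,
    site_ids: Sequence[str],
    groups: Sequence[Sequence[str]],
) -> MicrostatePopulation:
    """Estimate a factorized population by frequency-counting trajectory
    samples (rows = samples, columns = sites in ``site_ids`` order)."""
    samples = np.asarray(samples)
    idx = {s: k for k, s in enumerate(site_ids)}
    out = []
    for ids in groups:
        cols = [idx[i] for i in ids]
        sub = samples[:, cols]
        uniq, counts = np.unique(sub, axis=0, return_counts=True)
        states = [
            (tuple(int(v) for v in u), c / len(sub))
            for u, c in zip(uniq, counts)
        ]
        out.append((tuple(ids), states))
    return MicrostatePopulation(out)


def group_sites(
    correlation: pd.DataFrame, max_group_size: int = 10
) -> tuple[list[list[str]], float]:
    """Partition sites into groups of mutually correlated sites.

    Greedy agglomeration: repeatedly merge the two groups linked by the
    strongest remaining inter-group |correlation|, subject to the size cap.
    Returns the partition and the maximum |correlation| neglected between
    groups (0 for a perfectly separable matrix).
    """
    if max_group_size < 1:
        raise ValueError("max_group_size must be >= 1")
    ids = list(correlation.index)
    c = np.abs(np.nan_to_num(correlation.to_numpy(dtype=float)))
    if not np.allclose(c, c.T, atol=1e-9):
        raise ValueError("correlation matrix must be symmetric")
    groups: list[list[int]] = [[i] for i in range(len(ids))]
    while True:
        best, bi, bj = 0.0, -1, -1
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                if len(groups[i]) + len(groups[j]) > max_group_size:
                    continue
                link = max(c[a, b] for a in groups[i] for b in groups[j])
                if link > best:
                    best, bi, bj = link, i, j
        if bi < 0 or best == 0.0:
            break
        groups[bi] = groups[bi] + groups[bj]
        del groups[bj]
    neglected = 0.0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            neglected = max(
                neglected, max(c[a, b] for a in groups[i] for b in groups[j])
            )
    return [[ids[k] for k in g] for g in groups], neglected


def screen_by_effective_dielectric(correction: float, epsilon_eff: float) -> float:
    """Scale an ε = 1 electrostatic correction by an effective dielectric.

    Fixed-charge corrections neglect the relaxation of the protein and
    solvent; dividing by a site-dependent effective dielectric constant
    (≥ 1) recovers realistic stabilization energies.
    """
    if epsilon_eff < 1.0:
        raise ValueError(f"effective dielectric must be >= 1, got {epsilon_eff}")
    return correction / epsilon_eff
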