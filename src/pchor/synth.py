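"""Seeded generators for every input the analysis pipeline consumes.

Each generator is a pure function of a :class:`GeneratorSpec` (which
includes the seed): identical specs give bit-identical outputs, via numpy's
PCG64 generator. Alongside each synthetic input the generators return the
planted ground truth — midpoints, couplings, rate-limiting barriers — so
recovery tests can close the loop without consulting the code under test.

Default ranges straddle the titration grid windows (pH 5–9, −750 to
−200 mV) so that planted midpoints are observable, and energy-table values
live on a 0.1 kcal/mol grid so CSV round trips are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .energy_model import EnergyTable, MechanismState, ProtonPosition
from .ensemble import ChargeSet, MicrostatePopulation
from .titration import SiteKind, TitratableSite, TitrationSystem

__all__ = [
    "GeneratorSpec",
    "gen_titration_system",
    "gen_energy_table",
    "gen_charge_fixture",
    "gen_correlated_population",
]

_P = ProtonPosition


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the synthetic-data generators.

    ``coupling_density`` is the probability that a site pair interacts;
    ``coupling_scale`` sets the interaction magnitude (kcal/mol).
    ``correlation_strength`` injects inter-group coupling into generated
    microstate populations (0 = exactly product-form).
    """

    seed: int = 0
    n_sites: int = 10
    n_electron_sites: int = 1
    pka_range: tuple[float, float] = (3.0, 10.0)
    midpoint_range: tuple[float, float] = (-0.6, -0.2)
    coupling_density: float = 0.3
    coupling_scale: float = 1.5
    barrier_range: tuple[float, float] = (3.0, 20.0)
    pathway_a_barriers: tuple[float, float] | None = None
    pathway_b_barriers: tuple[float, float] | None = None
    correlation_strength: float = 0.0
    n_atoms: int = 50
    n_active_atoms: int = 10
    box_size: float = 12.0
    min_separation: float = 1.0

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


def gen_titration_system(
    spec: GeneratorSpec,
) -> tuple[TitrationSystem, dict]:
    """Random coupled proton/electron system with planted intrinsic values."""
    if spec.n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if not (0 <= spec.n_electron_sites <= spec.n_sites):
        raise ValueError("n_electron_sites must be within n_sites")
    lo, hi = spec.pka_range
    if lo >= hi:
        raise ValueError("invalid pKa range")
    mlo, mhi = spec.midpoint_range
    if mlo >= mhi:
        raise ValueError("invalid midpoint range")
    rng = spec.rng(stream=1)
    sites = []
    for i in range(spec.n_sites):
        if i < spec.n_electron_sites:
            sites.append(
                TitratableSite(f"e{i}", SiteKind.ELECTRON, float(rng.uniform(mlo, mhi)))
            )
        else:
            sites.append(
                TitratableSite(f"h{i}", SiteKind.PROTON, float(rng.uniform(lo, hi)))
            )
    n = spec.n_sites
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < spec.coupling_density:
                w[i, j] = w[j, i] = rng.choice([-1.0, 1.0]) * rng.uniform(
                    0.2, spec.coupling_scale
                )
    system = TitrationSystem(sites, w)
    truth = {
        "intrinsic": {s.id: s.intrinsic_value for s in sites},
        "coupling": w.copy(),
    }
    return system, truth


def _r1(x: float) -> float:
    return round(float(x), 1)


def gen_energy_table(spec: GeneratorSpec) -> tuple[EnergyTable, dict]:
    """A 25-state mechanism energy table with planted step barriers.

    Minima descend along each protonation sequence and reduction surfaces
    are well separated, so every planted transition-state height equals the
    forward barrier measured from the preceding minimum. The truth record
    carries the proton-chemistry barriers of the two canonical pathways and
    the index of the planted rate-limiting step (ties break to the first).
    """
    rng = spec.rng(stream=2)
    blo, bhi = spec.barrier_range
    if blo <= 0 or bhi <= blo:
        raise ValueError("barrier_range must be positive and increasing")

    def bar() -> float:
        return _r1(rng.uniform(blo, bhi))

    b_a1 = _r1(spec.pathway_a_barriers[0]) if spec.pathway_a_barriers else bar()
    b_a2 = _r1(spec.pathway_a_barriers[1]) if spec.pathway_a_barriers else bar()
    b_b1 = _r1(spec.pathway_b_barriers[0]) if spec.pathway_b_barriers else bar()
    b_b2 = _r1(spec.pathway_b_barriers[1]) if spec.pathway_b_barriers else bar()

    e: dict[tuple[int, _P, _P], float] = {}
    on = _P.ON_DONOR
    # unreduced surface: protonation uphill
    e[(0, on, on)] = 0.0
    e[(0, on, _P.C18_CORRECT)] = _r1(rng.uniform(10, 25))
    e[(0, _P.C17_CORRECT, on)] = _r1(rng.uniform(10, 25))
    e[(0, on, _P.IN_FLIGHT_C18)] = _r1(e[(0, on, _P.C18_CORRECT)] + bar())
    e[(0, _P.IN_FLIGHT_C17, on)] = _r1(e[(0, _P.C17_CORRECT, on)] + bar())

    def surface(base_lo: float, base_hi: float, n_e: int, b17: float, b18: float,
                b_c18_then_17: float) -> None:
        m_ap = _r1(rng.uniform(base_lo, base_hi))
        m_c17 = _r1(m_ap - rng.uniform(1, 8))
        m_c18 = _r1(m_ap - rng.uniform(1, 8))
        m_both = _r1(min(m_c17, m_c18) - rng.uniform(1, 8))
        e[(n_e, on, on)] = m_ap
        e[(n_e, _P.C17_CORRECT, on)] = m_c17
        e[(n_e, on, _P.C18_CORRECT)] = m_c18
        e[(n_e, _P.C17_CORRECT, _P.C18_CORRECT)] = m_both
        e[(n_e, _P.C18_WRONG, on)] = _r1(m_c18 + rng.uniform(2, 12))
        e[(n_e, on, _P.C17_WRONG)] = _r1(m_c17 + rng.uniform(2, 12))
        e[(n_e, _P.IN_FLIGHT_C17, on)] = _r1(m_ap + b17)
        e[(n_e, on, _P.IN_FLIGHT_C18)] = _r1(m_ap + b18)
        e[(n_e, _P.C17_CORRECT, _P.IN_FLIGHT_C18)] = _r1(m_c17 + bar())
        e[(n_e, _P.IN_FLIGHT_C17, _P.C18_CORRECT)] = _r1(m_c18 + b_c18_then_17)

    surface(-75.0, -60.0, 1, b_a1, b_b1, bar())
    # pathway A's second proton step rides the (C17,·) minimum at 1 e-
    e[(1, _P.C17_CORRECT, _P.IN_FLIGHT_C18)] = _r1(
        e[(1, _P.C17_CORRECT, on)] + b_a2
    )
    surface(-135.0, -120.0, 2, bar(), bar(), b_b2)

    conditions = ("eps4", "eps10", "eps20", "eps78")
    shifts = {0: (0.0, 0.0, 0.0, 0.0)}
    for n_e in (1, 2):
        s = rng.uniform(0, 5)
        shifts[n_e] = (_r1(s), 0.0, _r1(-s / 2), _r1(-s))
    entries = {}
    for (n_e, asp, prop), val in e.items():
        state = MechanismState(n_e, asp, prop)
        for cond, shift in zip(conditions, shifts[n_e]):
            entries[(state, cond)] = _r1(val + shift)
    table = EnergyTable(entries, conditions)

    a_barriers = (b_a1, b_a2)
    b_barriers = (b_b1, b_b2)
    truth = {
        "pathway_a_step_barriers": a_barriers,
        "pathway_b_step_barriers": b_barriers,
        "pathway_a_overall": max(a_barriers),
        "pathway_b_overall": max(b_barriers),
        # indices into the canonical 4-step pathways (0: e-, 1/2 or 1/3: H+)
        "pathway_a_rls": 1 if b_a1 >= b_a2 else 2,
        "pathway_b_rls": 1 if b_b1 >= b_b2 else 3,
    }
    return table, truth


def gen_charge_fixture(spec: GeneratorSpec) -> ChargeSet:
    """Random non-overlapping point charges in a box with region tags."""
    rng = spec.rng(stream=3)
    coords: list[np.ndarray] = []
    attempts = 0
    while len(coords) < spec.n_atoms:
        p = rng.uniform(0, spec.box_size, size=3)
        if all(np.linalg.norm(p - q) >= spec.min_separation for q in coords):
            coords.append(p)
        attempts += 1
        if attempts > 100_000:
            raise RuntimeError("could not place atoms; box too small")
    charges = np.round(rng.uniform(-1.0, 1.0, size=spec.n_atoms), 4)
    regions = np.array(
        ["ACTIVE"] * spec.n_active_atoms
        + ["ENVIRONMENT"] * (spec.n_atoms - spec.n_active_atoms),
        dtype=object,
    )
    return ChargeSet(np.array(coords), charges, regions)


def gen_correlated_population(
    spec: GeneratorSpec,
    group_sizes: Sequence[int] = (4, 4),
) -> tuple[np.ndarray, np.ndarray, MicrostatePopulation, list[list[str]]]:
    """Joint microstate distribution with tunable inter-group correlation.

    Builds a joint distribution over ``sum(group_sizes)`` sites: independent
    per-site occupation probabilities tilted by
    exp(α · n_group1 · n_group2 / size), where α is
    ``spec.correlation_strength``. Returns the full enumeration (states
    matrix, joint probabilities), the group-factorized marginal population,
    and the group id lists. At α = 0 the joint is exactly the product of
    the group marginals.
    """
    rng = spec.rng(stream=4)
    n = int(sum(group_sizes))
    if n > 16:
        raise ValueError("population enumeration limited to 16 sites")
    theta = rng.uniform(0.2, 0.8, size=n)
    bits = np.arange(2**n, dtype=np.uint32)
    states = ((bits[:, None] >> np.arange(n)) & 1).astype(np.float64)
    logp = states @ np.log(theta) + (1 - states) @ np.log1p(-theta)
    ids: list[list[str]] = []
    start = 0
    masks = []
    for k, size in enumerate(group_sizes):
        ids.append([f"s{start + i}" for i in range(size)])
        m = np.zeros(n)
        m[start : start + size] = 1.0
        masks.append(m)
        start += size
    if len(masks) >= 2 and spec.correlation_strength != 0.0:
        tilt = (states @ masks[0]) * (states @ masks[1]) / max(group_sizes)
        logp = logp + spec.correlation_strength * tilt
    p = np.exp(logp - logp.max())
    p /= p.sum()

    groups = []
    start = 0
    for k, size in enumerate(group_sizes):
        cols = slice(start, start + size)
        sub = states[:, cols]
        uniq, inv = np.unique(sub, axis=0, return_inverse=True)
        marg = np.zeros(len(uniq))
        np.add.at(marg, inv, p)
        marg /= marg.sum()
        groups.append(
            (
                tuple(ids[k]),
                [
                    (tuple(int(v) for v in u), float(q))
                    for u, q in zip(uniq, marg)
                ],
            )
        )
        start += size
    return states, p, MicrostatePopulation(groups), ids
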