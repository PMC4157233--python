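"""Coupled protonation/reduction titration by Metropolis Monte Carlo.

A :class:`TitrationSystem` is a set of interacting binding sites — proton
sites with intrinsic pKa values and electron sites with intrinsic midpoint
potentials — plus a symmetric pairwise interaction matrix W (kcal/mol, paid
when both sites are occupied). A microstate assigns occupied/empty to every
site; its energy at a given pH and solution potential is

    E(s) = Σ_i s_i·g_i + Σ_{i<j} W_ij·s_i·s_j

with g_i = RT·ln10·(pH − pKa_i) for proton sites and g_i = F·(E − E°_i)
for electron sites, so that occupancy (protonated / reduced) is penalized
above the site's midpoint. For one isolated site this reproduces the
Henderson–Hasselbalch and Nernst curves exactly.

Sampling follows the scan/production protocol of the Monte Carlo
reduction-and-protonation method: a short scan over the whole pH × potential
grid identifies sites that stay ≥ 90% occupied (or empty) everywhere; those
are clamped and excluded from the long production runs. Strongly coupled
pairs additionally get double-flip moves, which fix mixing for locked pairs.
:func:`exact_titration` enumerates all 2^N microstates and serves as the
sampler's oracle for systems of up to 20 sites.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Sequence

import numpy as np
import pandas as pd
from numba import njit

from .thermo import CONSTANTS

__all__ = [
    "SiteKind",
    "TitratableSite",
    "TitrationSystem",
    "GridSpec",
    "OccupancyMap",
    "MidpointReport",
    "MidpointOutOfWindowError",
    "PAIR_FLIP_THRESHOLD",
    "microstate_energy",
    "exact_titration",
    "mc_titration",
    "midpoint_and_slope",
    "site_correlation",
    "correlation_matrix",
    "read_sites_tsv",
    "read_coupling_tsv",
    "write_occupancy_tsv",
]

_LN10 = math.log(10.0)

#: |W| (kcal/mol) above which a site pair gets joint double-flip moves;
#: equals a 2-pKa-unit coupling at 300 K.
PAIR_FLIP_THRESHOLD = 2.73


class SiteKind(enum.Enum):
    PROTON = "proton"
    ELECTRON = "electron"


@dataclass(frozen=True)
class TitratableSite:
    """A titratable site: pKa units for protons, volts for electrons."""

    id: str
    kind: SiteKind
    intrinsic_value: float


class TitrationSystem:
    """Sites plus a symmetric pairwise interaction matrix (kcal/mol)."""

    def __init__(
        self,
        sites: Sequence[TitratableSite],
        coupling: np.ndarray | None = None,
        temperature: float = CONSTANTS.temperature_titration,
    ) -> None:
        self.sites = tuple(sites)
        ids = [s.id for s in self.sites]
        if len(set(ids)) != len(ids):
            raise ValueError("site ids must be unique")
        n = len(self.sites)
        if coupling is None:
            coupling = np.zeros((n, n))
        coupling = np.asarray(coupling, dtype=float)
        if coupling.shape != (n, n):
            raise ValueError(f"coupling must be {n}x{n}, got {coupling.shape}")
        if not np.allclose(coupling, coupling.T, atol=1e-12):
            raise ValueError("coupling matrix must be symmetric")
        if np.any(np.diagonal(coupling) != 0.0):
            raise ValueError("coupling diagonal must be zero")
        self.coupling = coupling
        self.temperature = float(temperature)
        self._index = {s.id: i for i, s in enumerate(self.sites)}

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def site_ids(self) -> tuple[str, ...]:
        return tuple(s.id for s in self.sites)

    def index(self, site_id: str) -> int:
        return self._index[site_id]

    @property
    def rt(self) -> float:
        return CONSTANTS.rt(self.temperature)

    def site_energies(self, ph: float, potential: float) -> np.ndarray:
        """Per-site occupation energies g_i (kcal/mol); potential in volts."""
        g = np.empty(self.n_sites)
        for i, s in enumerate(self.sites):
            if s.kind is SiteKind.PROTON:
                g[i] = self.rt * _LN10 * (ph - s.intrinsic_value)
            else:
                g[i] = CONSTANTS.faraday * (potential - s.intrinsic_value)
        return g


def microstate_energy(
    system: TitrationSystem,
    state: Sequence[int] | np.ndarray,
    ph: float,
    potential: float,
) -> float:
    """Energy (kcal/mol) of one occupancy vector at (pH, potential in V)."""
    s = np.asarray(state, dtype=float)
    if s.shape != (system.n_sites,) or not np.all(np.isin(s, (0.0, 1.0))):
        raise ValueError(
            f"state must be a 0/1 vector of length {system.n_sites}"
        )
    g = system.site_energies(ph, potential)
    return float(s @ g + 0.5 * s @ system.coupling @ s)


@dataclass(frozen=True)
class GridSpec:
    """pH × potential grid and sampling protocol parameters.

    Defaults follow the standard protocol: pH 5–9 in 0.1 steps, −750 to
    −200 mV in 20 mV steps, 2 × 10⁵ scan steps, 10⁶ production steps, and a
    90% grid-wide occupancy threshold for clamping.
    """

    ph_values: tuple[float, ...] = tuple(
        np.round(np.arange(5.0, 9.0 + 1e-9, 0.1), 6)
    )
    potential_mv: tuple[float, ...] = tuple(
        np.arange(-750.0, -200.0 + 1e-9, 20.0)
    )
    steps_scan: int = 200_000
    steps_production: int = 1_000_000
    clamp_threshold: float = 0.9
    seed: int = 0
    #: production-trajectory recording stride (samples kept for correlations)
    thin: int = 100

    def __post_init__(self) -> None:
        if self.steps_scan <= 0 or self.steps_production <= 0:
            raise ValueError("step counts must be positive")
        if not 0.5 < self.clamp_threshold <= 1.0:
            raise ValueError("clamp_threshold must be in (0.5, 1]")

    def with_(self, **kw) -> "GridSpec":
        return replace(self, **kw)


@dataclass
class OccupancyMap:
    """Mean occupancies θ ∈ [0,1] on the grid, with sampling standard errors.

    ``clamped[i]`` is 0/1 for sites frozen during production and −1 for
    freely titrating sites. ``trajectory`` (present for Monte Carlo runs
    when requested) holds thinned production samples per grid point, shape
    (n_ph, n_potential, n_samples, n_sites).
    """

    site_ids: tuple[str, ...]
    ph_values: np.ndarray
    potential_mv: np.ndarray
    occupancy: np.ndarray  # (n_sites, n_ph, n_pot)
    stderr: np.ndarray
    clamped: np.ndarray = field(default=None)  # type: ignore[assignment]
    trajectory: np.ndarray | None = None
    temperature: float = CONSTANTS.temperature_titration

    def __post_init__(self) -> None:
        if self.clamped is None:
            self.clamped = np.full(len(self.site_ids), -1, dtype=np.int8)

    def site(self, site_id: str) -> int:
        return self.site_ids.index(site_id)


# -- exact enumeration ----------------------------------------------------


def _all_states(n: int) -> np.ndarray:
    bits = np.arange(2**n, dtype=np.uint32)
    return ((bits[:, None] >> np.arange(n)) & 1).astype(np.float64)


def exact_titration(system: TitrationSystem, grid: GridSpec) -> OccupancyMap:
    """Boltzmann-exact occupancies from the full 2^N partition function."""
    n = system.n_sites
    if n > 20:
        raise ValueError(f"exact enumeration limited to 20 sites, got {n}")
    states = _all_states(n)
    pair_e = 0.5 * np.einsum("si,ij,sj->s", states, system.coupling, states)

    # g is affine in pH and potential: precompute the three projections
    kinds = np.array([s.kind is SiteKind.PROTON for s in system.sites])
    intrinsic = np.array([s.intrinsic_value for s in system.sites])
    rt = system.rt
    g0 = np.where(
        kinds, -rt * _LN10 * intrinsic, -CONSTANTS.faraday * intrinsic
    )
    u = np.where(kinds, rt * _LN10, 0.0)  # ∂g/∂pH
    v = np.where(kinds, 0.0, CONSTANTS.faraday)  # ∂g/∂E (per volt)
    base = pair_e + states @ g0
    dph = states @ u
    dpot = states @ v

    phs = np.asarray(grid.ph_values, dtype=float)
    pots = np.asarray(grid.potential_mv, dtype=float)
    occ = np.empty((n, phs.size, pots.size))
    for i, ph in enumerate(phs):
        for j, pot_mv in enumerate(pots):
            e = base + ph * dph + (pot_mv / 1000.0) * dpot
            w = np.exp(-(e - e.min()) / rt)
            p = w / w.sum()
            occ[:, i, j] = p @ states
    return OccupancyMap(
        site_ids=system.site_ids,
        ph_values=phs,
        potential_mv=pots,
        occupancy=occ,
        stderr=np.zeros_like(occ),
        temperature=system.temperature,
    )


# -- Metropolis sampling --------------------------------------------------


@njit(cache=True)
def _mc_kernel(
    g, W, state, free, pairs, rt, n_steps, n_burn, seed, n_batches, record_every, traj
):  # pragma: no cover - exercised via mc_titration
    np.random.seed(seed)
    n = state.size
    n_free = free.size
    n_pairs = pairs.shape[0]
    n_moves = n_free + n_pairs
    batch_len = n_steps // n_batches
    batch_occ = np.zeros((n_batches, n))
    occ_sum = np.zeros(n)
    n_rec = traj.shape[0]
    rec = 0
    for step in range(-n_burn, n_steps):
        m = int(np.random.random() * n_moves)
        if m < n_free:
            i = free[m]
            h = g[i]
            for k in range(n):
                h += W[i, k] * state[k]
            d_e = (1.0 - 2.0 * state[i]) * h
            if d_e <= 0.0 or np.random.random() < np.exp(-d_e / rt):
                state[i] = 1 - state[i]
        else:
            i = pairs[m - n_free, 0]
            j = pairs[m - n_free, 1]
            h_i = g[i]
            for k in range(n):
                h_i += W[i, k] * state[k]
            d1 = (1.0 - 2.0 * state[i]) * h_i
            state[i] = 1 - state[i]
            h_j = g[j]
            for k in range(n):
                h_j += W[j, k] * state[k]
            d2 = (1.0 - 2.0 * state[j]) * h_j
            d_e = d1 + d2
            if d_e <= 0.0 or np.random.random() < np.exp(-d_e / rt):
                state[j] = 1 - state[j]
            else:
                state[i] = 1 - state[i]
        if step < 0:
            continue
        b = step // batch_len
        if b >= n_batches:
            b = n_batches - 1
        for k in range(n):
            occ_sum[k] += state[k]
            batch_occ[b, k] += state[k]
        if n_rec > 0 and step % record_every == 0 and rec < n_rec:
            for k in range(n):
                traj[rec, k] = state[k]
            rec += 1
    for b in range(n_batches):
        length = batch_len
        if b == n_batches - 1:
            length = n_steps - batch_len * (n_batches - 1)
        for k in range(n):
            batch_occ[b, k] /= length
    return occ_sum / n_steps, batch_occ


def _point_seed(base_seed: int, phase: int, i: int, j: int) -> int:
    ss = np.random.SeedSequence([base_seed, phase, i, j])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _run_grid(
    system: TitrationSystem,
    grid: GridSpec,
    n_steps: int,
    phase: int,
    free: np.ndarray,
    fixed_state: np.ndarray,
    record_every: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    n = system.n_sites
    phs = np.asarray(grid.ph_values, dtype=float)
    pots = np.asarray(grid.potential_mv, dtype=float)
    W = system.coupling
    rt = system.rt
    n_batches = max(1, min(20, n_steps))

    free_set = set(int(i) for i in free)
    pair_list = [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if abs(W[i, j]) > PAIR_FLIP_THRESHOLD and i in free_set and j in free_set
    ]
    pairs = (
        np.array(pair_list, dtype=np.int64)
        if pair_list
        else np.empty((0, 2), dtype=np.int64)
    )

    occ = np.empty((n, phs.size, pots.size))
    se = np.empty_like(occ)
    n_rec = (n_steps + record_every - 1) // record_every if record_every else 0
    traj = (
        np.empty((phs.size, pots.size, n_rec, n), dtype=np.uint8)
        if record_every
        else None
    )
    if free.size == 0 and pairs.shape[0] == 0:
        # fully clamped system: nothing to sample
        occ[:] = fixed_state[:, None, None]
        se[:] = 0.0
        if traj is not None:
            traj[:] = fixed_state.astype(np.uint8)
        return occ, se, traj
    for i, ph in enumerate(phs):
        for j, pot_mv in enumerate(pots):
            g = system.site_energies(ph, pot_mv / 1000.0)
            state = fixed_state.astype(np.int64).copy()
            point_traj = (
                traj[i, j]
                if traj is not None
                else np.empty((0, n), dtype=np.uint8)
            )
            mean, batches = _mc_kernel(
                g,
                W,
                state,
                free.astype(np.int64),
                pairs,
                rt,
                n_steps,
                max(1000, n_steps // 10),  # equilibration before averaging
                _point_seed(grid.seed, phase, i, j),
                n_batches,
                record_every if record_every else n_steps,
                point_traj,
            )
            occ[:, i, j] = mean
            se[:, i, j] = batches.std(axis=0, ddof=1) / math.sqrt(n_batches)
    return occ, se, traj


def mc_titration(
    system: TitrationSystem,
    grid: GridSpec,
    store_trajectory: bool = True,
) -> OccupancyMap:
    """Metropolis-sampled occupancies over the pH × potential grid.

    Runs the scan phase on every grid point, clamps sites that stay within
    ``clamp_threshold`` of full (or zero) occupancy across the *entire*
    grid, then runs the production phase with the remaining free sites.
    Identical system/grid/seed inputs give bit-identical results.
    """
    n = system.n_sites
    all_free = np.arange(n, dtype=np.int64)
    start = np.zeros(n, dtype=np.int64)
    scan_occ, _, _ = _run_grid(
        system, grid, grid.steps_scan, phase=0, free=all_free, fixed_state=start
    )

    clamped = np.full(n, -1, dtype=np.int8)
    min_occ = scan_occ.min(axis=(1, 2))
    max_occ = scan_occ.max(axis=(1, 2))
    clamped[min_occ >= grid.clamp_threshold] = 1
    clamped[max_occ <= 1.0 - grid.clamp_threshold] = 0

    free = np.where(clamped < 0)[0].astype(np.int64)
    fixed_state = np.where(clamped == 1, 1, 0).astype(np.int64)
    occ, se, traj = _run_grid(
        system,
        grid,
        grid.steps_production,
        phase=1,
        free=free,
        fixed_state=fixed_state,
        record_every=grid.thin if store_trajectory else 0,
    )
    # clamped sites hold their frozen occupancy with zero sampling error
    for k in range(n):
        if clamped[k] >= 0:
            occ[k] = float(clamped[k])
            se[k] = 0.0
    return OccupancyMap(
        site_ids=system.site_ids,
        ph_values=np.asarray(grid.ph_values, dtype=float),
        potential_mv=np.asarray(grid.potential_mv, dtype=float),
        occupancy=occ,
        stderr=se,
        clamped=clamped,
        trajectory=traj,
        temperature=system.temperature,
    )


# -- analysis -------------------------------------------------------------


class MidpointOutOfWindowError(ValueError):
    """The θ = 0.5 crossing lies outside the evaluated potential window."""


@dataclass
class MidpointReport:
    """Midpoint potentials per pH, their pH slope, and the implied proton
    uptake per electron."""

    site_id: str
    e_half_mv: dict[float, float]
    slope_mv_per_ph: float
    protons_per_electron: float


def _interp_midpoint(theta: np.ndarray, pots: np.ndarray) -> float:
    """Linear interpolation of the θ(E) = 0.5 crossing; θ decreasing in E."""
    above = theta >= 0.5
    if above.all() or (~above).all():
        raise MidpointOutOfWindowError("midpoint out of window")
    # last index where θ >= 0.5 (reduced side), crossing to the next point
    k = int(np.nonzero(above)[0].max())
    if k == len(pots) - 1:
        raise MidpointOutOfWindowError("midpoint out of window")
    t0, t1 = theta[k], theta[k + 1]
    return float(pots[k] + (0.5 - t0) / (t1 - t0) * (pots[k + 1] - pots[k]))


def midpoint_and_slope(
    occ: OccupancyMap,
    site_id: str,
    ph_subset: Sequence[float] | None = None,
) -> MidpointReport:
    """Midpoint potential vs. pH for an electron site, and its Nernst slope.

    The slope (mV per pH unit) divided by the ideal one-proton slope
    RT·ln10/F gives the number of protons taken up per electron.
    """
    k = occ.site(site_id)
    phs = occ.ph_values if ph_subset is None else np.asarray(ph_subset, float)
    e_half: dict[float, float] = {}
    for ph in phs:
        i = int(np.argmin(np.abs(occ.ph_values - ph)))
        if abs(occ.ph_values[i] - ph) > 1e-6:
            raise ValueError(f"pH {ph} not on the evaluated grid")
        e_half[float(ph)] = _interp_midpoint(occ.occupancy[k, i, :], occ.potential_mv)
    xs = np.array(sorted(e_half))
    ys = np.array([e_half[x] for x in xs])
    slope = float(np.polyfit(xs, ys, 1)[0]) if xs.size > 1 else 0.0
    nernst = 1000.0 * CONSTANTS.rt(occ.temperature) * _LN10 / CONSTANTS.faraday
    return MidpointReport(
        site_id=site_id,
        e_half_mv=e_half,
        slope_mv_per_ph=slope,
        protons_per_electron=-slope / nernst,
    )


def site_correlation(
    occ: OccupancyMap,
    pair: tuple[str, str],
    ph: float,
    potential_mv: float,
) -> float:
    """Pearson correlation of two sites' occupancies at one grid point."""
    if occ.trajectory is None:
        raise ValueError("occupancy map carries no trajectory samples")
    a, b = occ.site(pair[0]), occ.site(pair[1])
    for k, sid in ((a, pair[0]), (b, pair[1])):
        if occ.clamped[k] >= 0:
            raise ValueError(f"correlation undefined for clamped site {sid!r}")
    i = int(np.argmin(np.abs(occ.ph_values - ph)))
    j = int(np.argmin(np.abs(occ.potential_mv - potential_mv)))
    x = occ.trajectory[i, j, :, a].astype(float)
    y = occ.trajectory[i, j, :, b].astype(float)
    if a == b:
        return 1.0
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


def correlation_matrix(
    occ: OccupancyMap, ph: float, potential_mv: float
) -> pd.DataFrame:
    """Pairwise occupancy correlations of all free sites at one grid point."""
    if occ.trajectory is None:
        raise ValueError("occupancy map carries no trajectory samples")
    i = int(np.argmin(np.abs(occ.ph_values - ph)))
    j = int(np.argmin(np.abs(occ.potential_mv - potential_mv)))
    free = [k for k in range(len(occ.site_ids)) if occ.clamped[k] < 0]
    ids = [occ.site_ids[k] for k in free]
    x = occ.trajectory[i, j][:, free].astype(float)
    with np.errstate(invalid="ignore"):
        c = np.corrcoef(x, rowvar=False)
    c = np.atleast_2d(c)
    np.fill_diagonal(c, 1.0)
    return pd.DataFrame(c, index=ids, columns=ids)


# -- I/O ------------------------------------------------------------------


def read_sites_tsv(source: str | Path | IO[str]) -> list[TitratableSite]:
    """Read sites from TSV columns ``site_id, kind, intrinsic_value``."""
    df = pd.read_csv(source, sep="\t")
    sites = []
    for _, row in df.iterrows():
        sites.append(
            TitratableSite(
                str(row["site_id"]),
                SiteKind(str(row["kind"]).strip().lower()),
                float(row["intrinsic_value"]),
            )
        )
    return sites


def read_coupling_tsv(
    source: str | Path | IO[str], site_ids: Sequence[str]
) -> np.ndarray:
    """Read a square interaction matrix TSV (header row/index = site ids)."""
    df = pd.read_csv(source, sep="\t", index_col=0)
    df = df.loc[list(site_ids), list(site_ids)]
    return df.to_numpy(dtype=float)


def write_occupancy_tsv(occ: OccupancyMap, target: str | Path | IO[str]) -> None:
    rows = []
    for k, sid in enumerate(occ.site_ids):
        for i, ph in enumerate(occ.ph_values):
            for j, pot in enumerate(occ.potential_mv):
                rows.append(
                    {
                        "site_id": sid,
                        "ph": ph,
                        "potential_mv": pot,
                        "occupancy": occ.occupancy[k, i, j],
                        "stderr": occ.stderr[k, i, j],
                    }
                )
    pd.DataFrame(rows).to_csv(target, sep="\t", index=False)
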