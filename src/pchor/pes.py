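"""Potential-energy-surface bookkeeping over mechanism energy tables.

Builds reaction pathways from proton-transfer steps (reactant, transition
state, product on one reduction surface) and electron-transfer steps
(hopping between reduction surfaces with an externally supplied activation
energy), and reports step barriers, overall barriers and redox potentials.

The overall barrier of a pathway follows the energetic-span convention
within each reduction state: the highest transition-state energy minus the
lowest *preceding* resting-state energy. Electron-transfer steps reset the
energy reference, because relative enthalpies on different reduction
surfaces are not commensurate (their offset is the redox energy itself).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence, Union

from .energy_model import EnergyTable, MechanismState, ProtonPosition
from .thermo import potential_from_delta_g

__all__ = [
    "ProtonStep",
    "ElectronStep",
    "BarrierReport",
    "MechanismComparison",
    "InconsistentTableWarning",
    "step_barrier",
    "pathway_overall_barrier",
    "redox_potential",
    "stereochemistry_penalty",
    "compare_mechanisms",
    "pathway_a",
    "pathway_b",
]


class InconsistentTableWarning(UserWarning):
    """A transition state lies below its reactant in the table."""


@dataclass(frozen=True)
class ProtonStep:
    reactant: MechanismState
    ts: MechanismState
    product: MechanismState

    def __post_init__(self) -> None:
        if not self.ts.is_transition_state:
            raise ValueError(f"{self.ts} is not a transition state")
        if self.reactant.is_transition_state or self.product.is_transition_state:
            raise ValueError("reactant and product must be minima")
        if not (
            self.reactant.electrons_added
            == self.ts.electrons_added
            == self.product.electrons_added
        ):
            raise ValueError("proton step must stay on one reduction surface")


@dataclass(frozen=True)
class ElectronStep:
    """One-electron uptake at a fixed protonation pattern.

    ``activation`` is supplied externally (e.g. from the Marcus module);
    ``"fast"`` marks a step treated as activationless.
    """

    from_state: MechanismState
    activation: Union[float, Literal["fast"]] = "fast"

    def __post_init__(self) -> None:
        if self.from_state.is_transition_state:
            raise ValueError("electron step endpoints must be minima")
        if self.from_state.electrons_added >= 2:
            raise ValueError("cannot add a third electron")
        if self.activation != "fast" and self.activation < 0:
            raise ValueError("activation energy must be non-negative")

    @property
    def to_state(self) -> MechanismState:
        return MechanismState(
            self.from_state.electrons_added + 1,
            self.from_state.asp_proton,
            self.from_state.prop_proton,
        )

    @property
    def activation_value(self) -> float:
        return 0.0 if self.activation == "fast" else float(self.activation)


Step = Union[ProtonStep, ElectronStep]


def _check_chaining(steps: Sequence[Step]) -> None:
    current: MechanismState | None = None
    for i, step in enumerate(steps):
        start = step.reactant if isinstance(step, ProtonStep) else step.from_state
        if current is not None and start != current:
            raise ValueError(
                f"pathway broken at step {i}: expected reactant {current}, got {start}"
            )
        current = step.product if isinstance(step, ProtonStep) else step.to_state


@dataclass
class BarrierReport:
    """Forward barriers of each step and the pathway's overall barrier."""

    step_barriers: list[float]
    overall_barrier: float
    rate_limiting_index: int
    resting_state: MechanismState
    proton_chemistry_barrier: float = field(default=float("nan"))


def step_barrier(
    table: EnergyTable,
    eps: float | str,
    reactant: MechanismState,
    ts: MechanismState,
) -> float:
    """Forward barrier E(ts) − E(reactant), kcal/mol.

    A negative value is returned but flagged with
    :class:`InconsistentTableWarning` — a transition state below its
    reactant indicates an internally inconsistent table.
    """
    if not ts.is_transition_state:
        raise ValueError(f"{ts} is not a transition state")
    if reactant.is_transition_state:
        raise ValueError("reactant must be a minimum")
    if reactant.electrons_added != ts.electrons_added:
        raise ValueError("reactant and TS must share the reduction state")
    barrier = table.energy(ts, eps) - table.energy(reactant, eps)
    if barrier < 0:
        warnings.warn(
            f"transition state {ts} lies {-barrier:.2f} kcal/mol below "
            f"reactant {reactant}",
            InconsistentTableWarning,
            stacklevel=2,
        )
    return barrier


def pathway_overall_barrier(
    table: EnergyTable, eps: float | str, steps: Sequence[Step]
) -> BarrierReport:
    """Per-step and overall barriers of a chained pathway.

    Within one reduction surface the effective barrier of each
    proton-transfer step is its TS energy minus the lowest resting-state
    energy reached so far on that surface; the overall barrier is the
    maximum. Electron steps contribute their supplied activation and reset
    the reference.
    """
    if not steps:
        raise ValueError("empty pathway")
    _check_chaining(steps)
    first = steps[0]
    start = first.reactant if isinstance(first, ProtonStep) else first.from_state
    ref_energy = table.energy(start, eps)
    ref_state = start

    barriers: list[float] = []
    proton_barriers: list[float] = []
    best = -float("inf")
    best_idx = 0
    best_ref = ref_state
    for i, step in enumerate(steps):
        if isinstance(step, ProtonStep):
            e_ts = table.energy(step.ts, eps)
            eff = e_ts - ref_energy
            barriers.append(eff)
            proton_barriers.append(eff)
            e_prod = table.energy(step.product, eps)
            if eff > best:
                best, best_idx, best_ref = eff, i, ref_state
            if e_prod < ref_energy:
                ref_energy, ref_state = e_prod, step.product
        else:
            eff = step.activation_value
            barriers.append(eff)
            if eff > best:
                best, best_idx, best_ref = eff, i, step.from_state
            # new reduction surface: reset the resting-state reference
            ref_energy = table.energy(step.to_state, eps)
            ref_state = step.to_state
    return BarrierReport(
        step_barriers=barriers,
        overall_barrier=best,
        rate_limiting_index=best_idx,
        resting_state=best_ref,
        proton_chemistry_barrier=max(proton_barriers) if proton_barriers else 0.0,
    )


def redox_potential(
    table: EnergyTable,
    eps: float | str,
    pattern: tuple[ProtonPosition, ProtonPosition],
    from_electrons: int,
) -> float:
    """Absolute one-electron reduction potential (V) of a protonation pattern.

    Differences the (n+1)-electron and n-electron energies of the same
    protonation pattern and converts with ΔG = −nFΔE (n = 1).
    """
    asp, prop = pattern
    if asp.in_flight or prop.in_flight:
        raise ValueError("redox potentials are defined for minima, not TSs")
    lo = MechanismState(from_electrons, asp, prop)
    hi = MechanismState(from_electrons + 1, asp, prop)
    delta_g = table.energy(hi, eps) - table.energy(lo, eps)
    return potential_from_delta_g(delta_g, 1)


def stereochemistry_penalty(
    table: EnergyTable, eps: float | str, electrons: int
) -> dict[str, float]:
    """Energy cost (kcal/mol) of protonating each ring carbon with the wrong
    stereochemistry, relative to the correct singly protonated isomer.

    Wrong C17 protonation comes from the propionic acid; wrong C18
    protonation from Asp274.
    """
    on, c17, c18 = (
        ProtonPosition.ON_DONOR,
        ProtonPosition.C17_CORRECT,
        ProtonPosition.C18_CORRECT,
    )
    wrong_c17 = MechanismState(electrons, on, ProtonPosition.C17_WRONG)
    right_c17 = MechanismState(electrons, c17, on)
    wrong_c18 = MechanismState(electrons, ProtonPosition.C18_WRONG, on)
    right_c18 = MechanismState(electrons, on, c18)
    return {
        "C17": table.energy(wrong_c17, eps) - table.energy(right_c17, eps),
        "C18": table.energy(wrong_c18, eps) - table.energy(right_c18, eps),
    }


# -- canonical pathways ---------------------------------------------------

_ON = ProtonPosition.ON_DONOR


def _state(electrons: int, asp: ProtonPosition, prop: ProtonPosition) -> MechanismState:
    return MechanismState(electrons, asp, prop)


def pathway_a(et_activation: Union[float, Literal["fast"]] = "fast") -> list[Step]:
    """Slow cluster re-reduction: e⁻, H⁺ to C17, H⁺ to C18, e⁻."""
    p = ProtonPosition
    return [
        ElectronStep(_state(0, _ON, _ON), et_activation),
        ProtonStep(
            _state(1, _ON, _ON),
            _state(1, p.IN_FLIGHT_C17, _ON),
            _state(1, p.C17_CORRECT, _ON),
        ),
        ProtonStep(
            _state(1, p.C17_CORRECT, _ON),
            _state(1, p.C17_CORRECT, p.IN_FLIGHT_C18),
            _state(1, p.C17_CORRECT, p.C18_CORRECT),
        ),
        ElectronStep(_state(1, p.C17_CORRECT, p.C18_CORRECT), et_activation),
    ]


def pathway_b(et_activation: Union[float, Literal["fast"]] = "fast") -> list[Step]:
    """Fast cluster re-reduction: e⁻, H⁺ to C18, e⁻, H⁺ to C17."""
    p = ProtonPosition
    return [
        ElectronStep(_state(0, _ON, _ON), et_activation),
        ProtonStep(
            _state(1, _ON, _ON),
            _state(1, _ON, p.IN_FLIGHT_C18),
            _state(1, _ON, p.C18_CORRECT),
        ),
        ElectronStep(_state(1, _ON, p.C18_CORRECT), et_activation),
        ProtonStep(
            _state(2, _ON, p.C18_CORRECT),
            _state(2, p.IN_FLIGHT_C17, p.C18_CORRECT),
            _state(2, p.C17_CORRECT, p.C18_CORRECT),
        ),
    ]


@dataclass
class MechanismComparison:
    pathway_a_report: BarrierReport
    pathway_b_report: BarrierReport
    eyring_limit: float
    rate_limiting: Literal["substrate_chemistry", "cluster_re_reduction"]

    @property
    def best_overall_barrier(self) -> float:
        return min(
            self.pathway_a_report.overall_barrier,
            self.pathway_b_report.overall_barrier,
        )


def compare_mechanisms(
    table: EnergyTable,
    eps: float | str,
    et_activation: float = 4.0,
    eyring_limit: float = 19.3,
) -> MechanismComparison:
    """Compare the two canonical mechanisms and classify the rate limit.

    ``et_activation`` is the ceiling assumed for every electron-transfer
    step (kcal/mol). If the faster pathway's overall barrier sits below the
    Eyring bound implied by the measured turnover, the substrate chemistry
    cannot be rate-limiting and re-reduction of the Fe-S cluster by its
    external ATP-dependent partner is implicated instead.
    """
    if et_activation < 0:
        raise ValueError("et_activation must be non-negative")
    rep_a = pathway_overall_barrier(table, eps, pathway_a(et_activation))
    rep_b = pathway_overall_barrier(table, eps, pathway_b(et_activation))
    best = min(rep_a.overall_barrier, rep_b.overall_barrier)
    verdict = "cluster_re_reduction" if best < eyring_limit else "substrate_chemistry"
    return MechanismComparison(rep_a, rep_b, eyring_limit, verdict)
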