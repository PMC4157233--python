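"""Marcus-theory electron-transfer activation energies.

Two diabatic parabolas are drawn along a dimensionless reaction coordinate:
the reactant state E_R(x) = λ_R·x² with its minimum at x = 0, and the
product state E_P(x) = ΔG + λ_P·(1−x)² with its minimum at x = 1 and
vertical offset ΔG (product minus reactant, both at their own equilibrium
geometries). Each state carries its own reorganization energy, so the two
curvatures may differ. The activation energy is the height of the
lowest-energy real intersection above the reactant minimum; when the
parabolas do not intersect the result is reported as ``NO_CROSSING`` — a
physically meaningful outcome, not an error.

For equal reorganization energies this reduces to the classical closed form
ΔG‡ = (λ + ΔG)²/(4λ).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

__all__ = [
    "MarcusStatus",
    "MarcusInput",
    "MarcusResult",
    "reorganization_energy",
    "activation_energy",
]


class MarcusStatus(enum.Enum):
    CROSSING = "crossing"
    NO_CROSSING = "no_crossing"


@dataclass(frozen=True)
class MarcusInput:
    """Driving force and the two reorganization energies, kcal/mol."""

    delta_g: float
    lambda_reactant: float
    lambda_product: float

    def __post_init__(self) -> None:
        if self.lambda_reactant < 0 or self.lambda_product < 0:
            raise ValueError("reorganization energies must be non-negative")
        for v in (self.delta_g, self.lambda_reactant, self.lambda_product):
            if not math.isfinite(v):
                raise ValueError("Marcus inputs must be finite")


@dataclass(frozen=True)
class MarcusResult:
    status: MarcusStatus
    activation_energy: float | None = None
    crossing_coordinate: float | None = None


def reorganization_energy(
    e_state_at_other_geometry: float, e_state_at_own_geometry: float
) -> float:
    """λ = E(state @ other state's geometry) − E(state @ its own geometry).

    The energy needed to distort a state to the other state's equilibrium
    geometry; a negative difference means the claimed minimum is not a
    minimum and is rejected.
    """
    lam = e_state_at_other_geometry - e_state_at_own_geometry
    if lam < 0:
        raise ValueError(
            f"negative reorganization energy ({lam:.4g} kcal/mol): "
            "a state cannot be stabler away from its own minimum"
        )
    return lam


def activation_energy(inp: MarcusInput) -> MarcusResult:
    """Lowest-crossing activation energy of the two Marcus parabolas."""
    dg, lr, lp = inp.delta_g, inp.lambda_reactant, inp.lambda_product

    a = lr - lp
    if a == 0.0:
        if lr == 0.0:
            # two horizontal lines: they coincide only for ΔG = 0
            if dg == 0.0:
                return MarcusResult(MarcusStatus.CROSSING, 0.0, 0.0)
            return MarcusResult(MarcusStatus.NO_CROSSING)
        # equal curvatures: single crossing, classical closed form
        x = (lr + dg) / (2.0 * lr)
        return MarcusResult(MarcusStatus.CROSSING, lr * x * x, x)

    # (λ_R − λ_P)x² + 2λ_P·x − (λ_P + ΔG) = 0
    disc = lp * lp + a * (lp + dg)
    if disc < 0.0:
        return MarcusResult(MarcusStatus.NO_CROSSING)
    sq = math.sqrt(disc)
    roots = [(-lp + sq) / a, (-lp - sq) / a]
    # both roots are genuine crossings; the reaction traverses the lower one
    x_star = min(roots, key=lambda x: lr * x * x)
    return MarcusResult(MarcusStatus.CROSSING, lr * x_star * x_star, x_star)
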