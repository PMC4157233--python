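"""Mechanism states and relative-enthalpy tables.

The reduction of the protochlorophyllide C17=C18 double bond involves up to
two added electrons and two protons: one originating on the active-site
Asp274 carboxylic acid and one on the substrate's own C17-propionic acid
side chain. A :class:`MechanismState` records where each proton sits (still
on its donor, delivered to a ring carbon with correct or wrong
stereochemistry, or in flight at a proton-transfer transition state) plus
the number of added electrons. An :class:`EnergyTable` maps states to
relative enthalpies (kcal/mol) under one or more conditions — dielectric
constants for the quantum-cluster tables, or e.g. reduced/oxidized Fe-S
cluster environments.

Tables are stored as plain CSV with the proton-position labels used in the
field ("Asp274", "C17", "C18*", "Asp274...C17", ...) so fixtures stay
human-diffable; the typographic "•••" separator and Unicode minus signs are
normalized on load.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Mapping

import pandas as pd

__all__ = [
    "ProtonPosition",
    "MechanismState",
    "EnergyTable",
    "EnergyTableError",
    "REFERENCE_STATE",
    "DIELECTRIC_COLUMNS",
    "load_energy_table",
    "write_energy_table",
    "load_table1",
    "load_table2",
    "load_table5",
    "parse_state",
]


class EnergyTableError(ValueError):
    """Raised for malformed or inconsistent energy tables."""


class ProtonPosition(enum.Enum):
    ON_DONOR = "on_donor"
    C17_CORRECT = "c17_correct"
    C18_CORRECT = "c18_correct"
    C17_WRONG = "c17_wrong"
    C18_WRONG = "c18_wrong"
    IN_FLIGHT_C17 = "in_flight_c17"
    IN_FLIGHT_C18 = "in_flight_c18"

    @property
    def in_flight(self) -> bool:
        return self in (ProtonPosition.IN_FLIGHT_C17, ProtonPosition.IN_FLIGHT_C18)

    @property
    def delivered_carbon(self) -> str | None:
        """Ring carbon this proton occupies, if delivered (not in flight)."""
        return {
            ProtonPosition.C17_CORRECT: "C17",
            ProtonPosition.C17_WRONG: "C17",
            ProtonPosition.C18_CORRECT: "C18",
            ProtonPosition.C18_WRONG: "C18",
        }.get(self)


# Positions each proton origin may legally take. The Asp274 proton reaches
# C17 with the correct stereochemistry and C18 with the wrong one; the
# propionate proton is the mirror image.
_ASP_ALLOWED = frozenset(
    {
        ProtonPosition.ON_DONOR,
        ProtonPosition.C17_CORRECT,
        ProtonPosition.C18_WRONG,
        ProtonPosition.IN_FLIGHT_C17,
        ProtonPosition.IN_FLIGHT_C18,
    }
)
_PROP_ALLOWED = frozenset(
    {
        ProtonPosition.ON_DONOR,
        ProtonPosition.C18_CORRECT,
        ProtonPosition.C17_WRONG,
        ProtonPosition.IN_FLIGHT_C18,
        ProtonPosition.IN_FLIGHT_C17,
    }
)

_ASP_LABELS = {
    "Asp274": ProtonPosition.ON_DONOR,
    "C17": ProtonPosition.C17_CORRECT,
    "C18*": ProtonPosition.C18_WRONG,
    "Asp274...C17": ProtonPosition.IN_FLIGHT_C17,
    "Asp274...C18": ProtonPosition.IN_FLIGHT_C18,
}
_PROP_LABELS = {
    "Propionate": ProtonPosition.ON_DONOR,
    "C18": ProtonPosition.C18_CORRECT,
    "C17*": ProtonPosition.C17_WRONG,
    "Propionate...C18": ProtonPosition.IN_FLIGHT_C18,
    "Propionate...C17": ProtonPosition.IN_FLIGHT_C17,
}
_ASP_LABELS_INV = {v: k for k, v in _ASP_LABELS.items()}
_PROP_LABELS_INV = {v: k for k, v in _PROP_LABELS.items()}

#: CSV condition columns that denote a dielectric constant.
DIELECTRIC_COLUMNS: Mapping[str, float] = {
    "eps4": 4.0,
    "eps10": 10.0,
    "eps20": 20.0,
    "eps78": 78.36,
}
_DIELECTRIC_TO_COLUMN = {v: k for k, v in DIELECTRIC_COLUMNS.items()}


def _normalize(text: str) -> str:
    """Map typographic minus/bullets to their ASCII equivalents."""
    return (
        text.replace("−", "-")  # minus sign
        .replace("–", "-")  # en dash occasionally used as minus
        .replace("•••", "...")
        .replace("⋯", "...")
        .strip()
    )


@dataclass(frozen=True, order=True)
class MechanismState:
    """One protonation/reduction pattern of the substrate-Asp274 system."""

    electrons_added: int
    asp_proton: ProtonPosition
    prop_proton: ProtonPosition

    def __post_init__(self) -> None:
        if not 0 <= self.electrons_added <= 2:
            raise ValueError(
                f"electrons_added must be 0-2, got {self.electrons_added}"
            )
        if self.asp_proton not in _ASP_ALLOWED:
            raise ValueError(
                f"Asp274 proton cannot occupy {self.asp_proton.name}"
            )
        if self.prop_proton not in _PROP_ALLOWED:
            raise ValueError(
                f"propionate proton cannot occupy {self.prop_proton.name}"
            )
        if self.asp_proton.in_flight and self.prop_proton.in_flight:
            raise ValueError("at most one proton may be in flight")
        c1, c2 = self.asp_proton.delivered_carbon, self.prop_proton.delivered_carbon
        if c1 is not None and c1 == c2:
            raise ValueError(f"both protons delivered to {c1}")

    @property
    def is_transition_state(self) -> bool:
        """True iff exactly one proton is in flight."""
        return self.asp_proton.in_flight or self.prop_proton.in_flight

    @property
    def protonation_pattern(self) -> tuple[ProtonPosition, ProtonPosition]:
        return (self.asp_proton, self.prop_proton)

    @property
    def asp_label(self) -> str:
        return _ASP_LABELS_INV[self.asp_proton]

    @property
    def prop_label(self) -> str:
        return _PROP_LABELS_INV[self.prop_proton]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        ts = " (TS)" if self.is_transition_state else ""
        return f"{self.electrons_added}e-/{self.asp_label}/{self.prop_label}{ts}"


def parse_state(
    electrons: int, asp_label: str, prop_label: str
) -> MechanismState:
    """Build a state from the field's textual proton-position labels."""
    asp_label = _normalize(asp_label)
    prop_label = _normalize(prop_label)
    try:
        asp = _ASP_LABELS[asp_label]
    except KeyError:
        raise EnergyTableError(f"unknown Asp274-proton label {asp_label!r}") from None
    try:
        prop = _PROP_LABELS[prop_label]
    except KeyError:
        raise EnergyTableError(
            f"unknown propionate-proton label {prop_label!r}"
        ) from None
    return MechanismState(int(electrons), asp, prop)


REFERENCE_STATE = MechanismState(
    0, ProtonPosition.ON_DONOR, ProtonPosition.ON_DONOR
)

_META_COLUMNS = ("electrons", "asp_proton", "prop_proton", "is_ts")


class EnergyTable:
    """Relative enthalpies of mechanism states under one or more conditions.

    Parameters
    ----------
    entries
        Mapping ``(state, condition key)`` -> energy in kcal/mol.
    conditions
        Ordered condition keys (CSV column names such as ``eps10``).
    decimals
        Printing precision per condition column, preserved on round trips.
    """

    def __init__(
        self,
        entries: Mapping[tuple[MechanismState, str], float],
        conditions: Iterable[str],
        decimals: Mapping[str, int] | None = None,
    ) -> None:
        self.conditions: tuple[str, ...] = tuple(conditions)
        self._entries: dict[tuple[MechanismState, str], float] = dict(entries)
        self.decimals = dict(decimals or {c: 1 for c in self.conditions})
        self.states: tuple[MechanismState, ...] = tuple(
            dict.fromkeys(s for s, _ in self._entries)
        )
        self._validate()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_csv(cls, source: str | Path | IO[str]) -> "EnergyTable":
        if isinstance(source, (str, Path)):
            text = Path(source).read_text(encoding="utf-8")
        else:
            text = source.read()
        text = _normalize(text)
        if not text:
            raise EnergyTableError("empty table: no reference state")
        df = pd.read_csv(io.StringIO(text), dtype=str, skipinitialspace=True)
        missing = [c for c in _META_COLUMNS if c not in df.columns]
        if missing:
            raise EnergyTableError(f"missing columns {missing}")
        conditions = [c for c in df.columns if c not in _META_COLUMNS]
        if not conditions:
            raise EnergyTableError("no energy columns found")
        entries: dict[tuple[MechanismState, str], float] = {}
        decimals = {c: 0 for c in conditions}
        seen: set[MechanismState] = set()
        for _, row in df.iterrows():
            state = parse_state(
                int(row["electrons"]), row["asp_proton"], row["prop_proton"]
            )
            is_ts = str(row["is_ts"]).strip().lower() in ("1", "true", "yes")
            if is_ts != state.is_transition_state:
                raise EnergyTableError(
                    f"is_ts flag inconsistent with proton labels for {state}"
                )
            if state in seen:
                raise EnergyTableError(f"duplicate state {state}")
            seen.add(state)
            for cond in conditions:
                cell = str(row[cond]).strip()
                try:
                    value = float(cell)
                except ValueError:
                    raise EnergyTableError(
                        f"non-numeric energy {cell!r} for {state}/{cond}"
                    ) from None
                entries[(state, cond)] = value
                if "." in cell:
                    decimals[cond] = max(decimals[cond], len(cell.split(".")[1]))
        return cls(entries, conditions, decimals)

    def _validate(self) -> None:
        for state in self.states:
            for cond in self.conditions:
                if (state, cond) not in self._entries:
                    raise EnergyTableError(
                        f"state {state} missing under condition {cond!r}"
                    )
        if REFERENCE_STATE not in self.states:
            raise EnergyTableError("no reference state (0 e-, both protons on donors)")
        for cond in self.conditions:
            if self._entries[(REFERENCE_STATE, cond)] != 0.0:
                raise EnergyTableError(
                    f"reference state energy must be 0.0 under {cond!r}"
                )

    # -- access -----------------------------------------------------------

    @property
    def reference_state(self) -> MechanismState:
        return REFERENCE_STATE

    @property
    def dielectrics(self) -> tuple[float, ...]:
        return tuple(
            DIELECTRIC_COLUMNS[c] for c in self.conditions if c in DIELECTRIC_COLUMNS
        )

    def _condition_key(self, eps: float | str) -> str:
        if isinstance(eps, str):
            key = eps
        else:
            key = _DIELECTRIC_TO_COLUMN.get(float(eps))
            if key is None:
                raise KeyError(f"unknown dielectric constant {eps}")
        if key not in self.conditions:
            raise KeyError(f"condition {key!r} not in table")
        return key

    def __contains__(self, state: MechanismState) -> bool:
        return state in set(self.states)

    def energy(self, state: MechanismState, eps: float | str) -> float:
        """Stored relative enthalpy of ``state`` under condition ``eps``.

        A lookup miss raises ``KeyError`` ("state not tabulated"); there is
        deliberately no silent default.
        """
        cond = self._condition_key(eps)
        try:
            return self._entries[(state, cond)]
        except KeyError:
            raise KeyError(f"state not tabulated: {state} at {cond!r}") from None

    def states_at(self, electrons: int) -> tuple[MechanismState, ...]:
        return tuple(s for s in self.states if s.electrons_added == electrons)

    # -- output -----------------------------------------------------------

    def to_csv(self, target: str | Path | IO[str] | None = None) -> str | None:
        rows = []
        for state in self.states:
            row = {
                "electrons": state.electrons_added,
                "asp_proton": state.asp_label,
                "prop_proton": state.prop_label,
                "is_ts": int(state.is_transition_state),
            }
            for cond in self.conditions:
                row[cond] = format(
                    self._entries[(state, cond)], f".{self.decimals.get(cond, 1)}f"
                )
            rows.append(row)
        df = pd.DataFrame(rows, columns=list(_META_COLUMNS) + list(self.conditions))
        csv = df.to_csv(index=False)
        if target is None:
            return csv
        if isinstance(target, (str, Path)):
            Path(target).write_text(csv, encoding="utf-8")
        else:
            target.write(csv)
        return None


def load_energy_table(source: str | Path | IO[str]) -> EnergyTable:
    """Load and validate a CSV energy table (see module docstring for schema)."""
    return EnergyTable.from_csv(source)


def write_energy_table(table: EnergyTable, target: str | Path | IO[str]) -> None:
    table.to_csv(target)


def _load_fixture(name: str) -> EnergyTable:
    with resources.files("pchor.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return EnergyTable.from_csv(fh)


def load_table1() -> EnergyTable:
    """Quantum-cluster relative enthalpies of all 25 mechanism states at
    dielectric constants 4, 10, 20 and 78.36."""
    return _load_fixture("table1.csv")


def load_table2() -> EnergyTable:
    """Relative enthalpies of the non-TS intermediates in the presence of the
    separately optimized [4Fe-4S] cluster (reduced / oxidized), at ε = 10."""
    return _load_fixture("table2.csv")


def load_table5() -> EnergyTable:
    """Relative energies of the intermediates with the electrostatic
    protonation-ensemble correction applied (single condition column)."""
    return _load_fixture("table5.csv")
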