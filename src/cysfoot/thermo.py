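"""Binding thermodynamics: ΔG from K_D and the ΔG = ΔH − TΔS decomposition.

For a binding reaction characterized by isothermal titration calorimetry,
the dissociation constant and enthalpy determine the remaining columns of a
standard binding table:

    ΔG = R·T·ln(K_D)        (kcal/mol, negative for K_D < 1 M)
    TΔS = ΔH − ΔG

with R = 1.987e-3 kcal/(mol·K) and T defaulting to 298.15 K (25 °C).

``REFERENCE_BINDING_TABLE`` carries the measured ITC values for αE-catenin
R551A binding to vinculin and β-catenin constructs (with published wild-type
comparators); ``derive_table`` recomputes the derived columns for any such
table from K_D and ΔH alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "R_KCAL",
    "STANDARD_TEMPERATURE",
    "BindingMeasurement",
    "ThermoDerived",
    "delta_g_from_kd",
    "t_delta_s",
    "derive",
    "derive_table",
    "kd_ratio",
    "REFERENCE_BINDING_TABLE",
]

#: Gas constant in kcal/(mol·K).
R_KCAL = 1.987e-3

#: Default temperature: 25 °C.
STANDARD_TEMPERATURE = 298.15


@dataclass(frozen=True)
class BindingMeasurement:
    """Measured binding parameters for one cell/titrant pair."""

    label_cell: str
    label_titrant: str
    kd: float  # molar
    dh: float  # kcal/mol
    temperature: float = STANDARD_TEMPERATURE

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError("K_D must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")


@dataclass(frozen=True)
class ThermoDerived:
    """Derived free energy and entropic term, kcal/mol."""

    dg: float
    tds: float


def delta_g_from_kd(kd: float, temperature: float = STANDARD_TEMPERATURE) -> float:
    """Binding free energy ΔG = R·T·ln(K_D), kcal/mol."""
    if kd <= 0:
        raise ValueError("K_D must be positive")
    if temperature <= 0:
        raise ValueError("temperature must be positive (kelvin)")
    return R_KCAL * temperature * math.log(kd)


def t_delta_s(dh: float, dg: float) -> float:
    """Entropic term TΔS = ΔH − ΔG, kcal/mol."""
    return dh - dg


def derive(m: BindingMeasurement) -> ThermoDerived:
    dg = delta_g_from_kd(m.kd, m.temperature)
    return ThermoDerived(dg=dg, tds=t_delta_s(m.dh, dg))


def kd_ratio(kd_weak: float, kd_tight: float) -> float:
    """Fold difference in affinity between two dissociation constants."""
    if kd_tight <= 0:
        raise ValueError("K_D must be positive")
    return kd_weak / kd_tight


# Measured ITC binding table: (cell, titrant, K_D [M], ΔH, TΔS, ΔG [kcal/mol]).
# Rows without detectable binding carry None. Printed to one decimal; the
# derived columns reconstruct from K_D and ΔH to within 0.2 kcal/mol.
REFERENCE_BINDING_TABLE: tuple[tuple[str, str, float | None, float | None,
                                     float | None, float | None], ...] = (
    ("alphaE-catenin R551A", "vinculin D1", 4.1e-9, 7.7, 19.0, -11.4),
    ("alphaE-catenin R551A + beta-catenin + Ecyto", "vinculin D1",
     2.6e-8, 6.7, 17.0, -10.3),
    ("alphaE-catenin R551A", "vinculin full length", None, None, None, None),
    ("alphaE-catenin R551A", "beta-catenin", 7.8e-8, -33.3, -23.6, -9.7),
    ("alphaE-catenin R551A", "beta-catenin + Ecyto", 1.4e-8, -32.3, -21.6, -10.7),
    ("alphaE-catenin wt", "vinculin D1", 1.8e-6, 12.6, 20.4, -7.8),
    ("alphaE-catenin MI-MII", "vinculin D1", 5.2e-9, 9.9, 21.2, -11.3),
    ("alphaE-catenin + beta-catenin + Ecyto", "vinculin D1", 1.9e-6, 1.4, 9.2, -7.8),
    ("alphaE-catenin wt", "beta-catenin", 2.3e-8, -16.1, -5.7, -10.4),
    ("alphaE-catenin wt", "beta-catenin + Ecyto", 0.9e-9, -10.1, 2.2, -12.3),
)


def derive_table(
    table: "pd.DataFrame | None" = None,
    temperature: float = STANDARD_TEMPERATURE,
) -> pd.DataFrame:
    """Recompute ΔG and TΔS from K_D and ΔH for a binding table.

    ``table`` needs columns cell, titrant, kd, dh (and may carry printed
    tds/dg columns for comparison); None uses the reference table. Output
    adds ``dg_calc`` and ``tds_calc`` rounded to one decimal; rows without
    binding (kd NaN) pass through with NaN derived values.
    """
    if table is None:
        table = pd.DataFrame(
            REFERENCE_BINDING_TABLE,
            columns=["cell", "titrant", "kd", "dh", "tds", "dg"],
        )
    out = table.copy()
    dg = [
        delta_g_from_kd(kd, temperature) if pd.notna(kd) else math.nan
        for kd in out["kd"]
    ]
    out["dg_calc"] = [round(g, 1) if not math.isnan(g) else g for g in dg]
    out["tds_calc"] = [
        round(t_delta_s(dh, g), 1) if pd.notna(dh) and not math.isnan(g) else math.nan
        for dh, g in zip(out["dh"], dg)
    ]
    return out


def read_measurements(path: str | Path) -> pd.DataFrame:
    """Read a TSV of binding measurements (columns cell, titrant, kd, dh)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in ("cell", "titrant", "kd", "dh") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return df
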