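"""Peptide-spectrum-match (PSM) tables with cysteine-modification localization.

One row of a PSM table is one identified spectrum — one spectral count. The
tables emulate a search-engine export already filtered at a given false
discovery rate; quantification downstream is purely count-based, so charge
state, scan number and mass error columns are carried through but ignored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "PSMRecord",
    "PSMTable",
    "read_psm_table",
    "write_psm_table",
    "filter_psms",
    "DEFAULT_FDR_MAX",
]

logger = logging.getLogger(__name__)

#: Default FDR ceiling, matching a 1% search-engine filter.
DEFAULT_FDR_MAX = 0.01

_REQUIRED_COLUMNS = ("condition", "replicate", "protein_id", "peptide", "mod_offsets")


@dataclass(frozen=True)
class PSMRecord:
    """One peptide-spectrum match.

    ``mod_offsets`` are 1-based positions *within the peptide* carrying the
    thiol label (monobromobimane); each must point at a cysteine.
    ``localized`` is False when the search engine could not confidently
    assign the modified site among multiple cysteines in the peptide.
    """

    condition: str
    replicate: str
    protein_id: str
    peptide: str
    mod_offsets: tuple[int, ...] = ()
    localized: bool = True
    score_fdr: float | None = None

    def __post_init__(self) -> None:
        if not self.condition or not self.replicate:
            raise ValueError("condition and replicate labels must be non-empty")
        offs = tuple(sorted(set(int(o) for o in self.mod_offsets)))
        if offs != tuple(self.mod_offsets):
            object.__setattr__(self, "mod_offsets", offs)
        for o in offs:
            if not (1 <= o <= len(self.peptide)):
                raise ValueError(
                    f"mod offset {o} outside peptide {self.peptide!r}"
                )
            if self.peptide[o - 1] != "C":
                raise ValueError(
                    f"mod offset {o} of peptide {self.peptide!r} is "
                    f"{self.peptide[o - 1]!r}, not a cysteine"
                )

    @property
    def modified(self) -> bool:
        return len(self.mod_offsets) > 0


@dataclass
class PSMTable:
    """A list of PSM records plus free-text provenance."""

    records: list[PSMRecord]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "condition": [r.condition for r in self.records],
                "replicate": [r.replicate for r in self.records],
                "protein_id": [r.protein_id for r in self.records],
                "peptide": [r.peptide for r in self.records],
                "mod_offsets": [
                    ";".join(str(o) for o in r.mod_offsets) for r in self.records
                ],
                "localized": [int(r.localized) for r in self.records],
                "fdr": [
                    "" if r.score_fdr is None else repr(r.score_fdr)
                    for r in self.records
                ],
            }
        )


def _parse_offsets(cell: object) -> tuple[int, ...]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return ()
    s = str(cell).strip()
    if not s:
        return ()
    return tuple(int(tok) for tok in s.split(";") if tok.strip())


def read_psm_table(path: str | Path) -> PSMTable:
    """Read a TSV PSM table.

    Required columns: condition, replicate, protein_id, peptide,
    mod_offsets (semicolon-separated 1-based peptide offsets, empty for
    unmodified). Optional: localized (0/1, default 1), fdr (fraction).
    ``#`` comment lines are skipped; extra columns pass through unread.

    Raises
    ------
    ValueError
        On missing required columns, or on a row whose modification offset
        does not point at a cysteine (message carries the line number).
    """
    path = Path(path)
    df = pd.read_csv(
        path, sep="\t", comment="#", dtype=str, keep_default_na=False
    )
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    has_loc = "localized" in df.columns
    has_fdr = "fdr" in df.columns
    records: list[PSMRecord] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        row_d = dict(zip(df.columns, row))
        try:
            fdr_cell = row_d.get("fdr", "") if has_fdr else ""
            records.append(
                PSMRecord(
                    condition=row_d["condition"],
                    replicate=row_d["replicate"],
                    protein_id=row_d["protein_id"],
                    peptide=row_d["peptide"].upper(),
                    mod_offsets=_parse_offsets(row_d["mod_offsets"]),
                    localized=(
                        str(row_d["localized"]).strip() not in ("0", "false", "False")
                        if has_loc
                        else True
                    ),
                    score_fdr=float(fdr_cell) if str(fdr_cell).strip() else None,
                )
            )
        except ValueError as exc:
            # +2: one for header, one for 1-based numbering
            raise ValueError(f"{path}, line {idx + 2}: {exc}") from exc
    return PSMTable(records=records, provenance=f"read from {path}")


def write_psm_table(table: PSMTable, path: str | Path) -> None:
    """Write a PSM table as TSV (lossless round-trip with read_psm_table)."""
    table.to_frame().to_csv(path, sep="\t", index=False)


def filter_psms(table: PSMTable, fdr_max: float = DEFAULT_FDR_MAX) -> PSMTable:
    """Drop records whose FDR exceeds ``fdr_max``; records without an FDR
    estimate are retained. Idempotent."""
    if not (0 < fdr_max <= 1):
        raise ValueError("fdr_max must be in (0, 1]")
    if all(r.score_fdr is None for r in table.records):
        logger.warning("no fdr column present; table returned unchanged")
        return PSMTable(records=list(table.records), provenance=table.provenance)
    kept = [
        r for r in table.records if r.score_fdr is None or r.score_fdr <= fdr_max
    ]
    n_removed = len(table.records) - len(kept)
    logger.info("filter_psms: removed %d of %d records at fdr<=%g",
                n_removed, len(table.records), fdr_max)
    return PSMTable(
        records=kept,
        provenance=f"{table.provenance} | fdr<={fdr_max} ({n_removed} removed)",
    )
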