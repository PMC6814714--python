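"""Protein sequence handling: FASTA input, in-silico proteolysis, peptide mapping.

Coordinates are 1-based and inclusive throughout, matching the residue
numbering conventions used for cysteine sites (e.g. C116 is the cysteine at
``sequence[115]`` in Python terms).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

__all__ = [
    "ProteinRecord",
    "PeptideMatch",
    "DigestParams",
    "UnmappedPeptideError",
    "AmbiguousPeptideError",
    "read_fasta",
    "tryptic_digest",
    "map_peptide_to_protein",
    "cys_sites_in_peptide",
    "write_peptide_table",
]

_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
# Non-standard but occasionally seen in databases; accepted only with
# permissive=True and treated as non-cleavage sites.
_EXTENDED_AA = _STANDARD_AA | set("XUBZJO")


class UnmappedPeptideError(ValueError):
    """Peptide has no exact-substring occurrence in the protein."""


class AmbiguousPeptideError(ValueError):
    """Peptide occurs more than once in the protein; site assignment undefined."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with its cysteine positions pre-indexed.

    Attributes
    ----------
    id : str
        Sequence identifier (FASTA header up to first whitespace).
    sequence : str
        Upper-case amino-acid sequence.
    cys_positions : tuple of int
        1-based indices of every ``C`` in ``sequence``.
    """

    id: str
    sequence: str
    cys_positions: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        if any(c.isspace() for c in self.sequence):
            raise ValueError(f"protein {self.id!r}: whitespace in sequence")
        expected = tuple(
            i + 1 for i, aa in enumerate(self.sequence) if aa == "C"
        )
        if self.cys_positions != expected:
            object.__setattr__(self, "cys_positions", expected)

    @classmethod
    def from_sequence(
        cls, id: str, sequence: str, *, permissive: bool = False
    ) -> "ProteinRecord":
        seq = sequence.upper()
        alphabet = _EXTENDED_AA if permissive else _STANDARD_AA
        bad = {aa for aa in seq if aa not in alphabet}
        if bad:
            raise ValueError(
                f"protein {id!r}: non-amino-acid characters {sorted(bad)}"
            )
        return cls(id=id, sequence=seq)


@dataclass(frozen=True)
class PeptideMatch:
    """A peptide located within a protein (1-based inclusive coordinates)."""

    peptide: str
    protein_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid coordinates {self.start}..{self.end}")
        if len(self.peptide) != self.end - self.start + 1:
            raise ValueError(
                f"peptide length {len(self.peptide)} does not match span "
                f"{self.start}..{self.end}"
            )


@dataclass(frozen=True)
class DigestParams:
    """Trypsin/LysC digestion parameters.

    Defaults target the typical LC-MS detectability window: up to two missed
    cleavages, peptide lengths 5-50.
    """

    missed_cleavages: int = 2
    min_length: int = 5
    max_length: int = 50

    def __post_init__(self) -> None:
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be non-negative")
        if not (0 < self.min_length <= self.max_length):
            raise ValueError("require 0 < min_length <= max_length")


def read_fasta(path: str | Path, *, permissive: bool = False) -> list[ProteinRecord]:
    """Read a (possibly multi-record, line-wrapped) FASTA file.

    Sequences are upper-cased and validated against the standard 20-letter
    alphabet; ``permissive=True`` additionally tolerates X/U/B/Z/J/O.

    Raises
    ------
    ValueError
        On an empty file or non-amino-acid characters (message names the
        offending record).
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            ProteinRecord.from_sequence(rec.id, str(rec.seq), permissive=permissive)
        )
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def _cleavage_sites(sequence: str) -> list[int]:
    """0-based indices i such that cleavage occurs between i and i+1.

    Trypsin rule: cleave C-terminal to K or R unless the next residue is P.
    LysC (cleaves after K) adds no sites beyond this rule.
    """
    n = len(sequence)
    return [
        i
        for i in range(n - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def tryptic_digest(
    protein: ProteinRecord, params: DigestParams | None = None
) -> list[PeptideMatch]:
    """Digest a protein with trypsin/LysC specificity.

    Emits all peptides with up to ``params.missed_cleavages`` internal
    uncleaved sites, filtered to ``[min_length, max_length]``. Peptides are
    ordered by start position, then by span length.
    """
    if params is None:
        params = DigestParams()
    seq = protein.sequence
    # Fragment boundaries: 0-based half-open [b[i], b[i+1]) fully cleaved runs
    bounds = [0] + [i + 1 for i in _cleavage_sites(seq)] + [len(seq)]
    out: list[PeptideMatch] = []
    nfrag = len(bounds) - 1
    for i in range(nfrag):
        for j in range(i, min(i + params.missed_cleavages + 1, nfrag)):
            start, end = bounds[i], bounds[j + 1]
            length = end - start
            if params.min_length <= length <= params.max_length:
                out.append(
                    PeptideMatch(
                        peptide=seq[start:end],
                        protein_id=protein.id,
                        start=start + 1,
                        end=end,
                    )
                )
    out.sort(key=lambda m: (m.start, m.end))
    return out


def map_peptide_to_protein(peptide: str, protein: ProteinRecord) -> PeptideMatch:
    """Locate a peptide in a protein by exact substring match (I/L distinct).

    Raises
    ------
    UnmappedPeptideError
        If the peptide does not occur.
    AmbiguousPeptideError
        If it occurs at more than one position.
    """
    if not peptide:
        raise ValueError("empty peptide")
    pep = peptide.upper()
    first = protein.sequence.find(pep)
    if first < 0:
        raise UnmappedPeptideError(
            f"unmapped peptide {pep!r} in protein {protein.id!r}"
        )
    second = protein.sequence.find(pep, first + 1)
    if second >= 0:
        raise AmbiguousPeptideError(
            f"ambiguous peptide {pep!r}: occurs at positions "
            f"{first + 1} and {second + 1} of protein {protein.id!r}"
        )
    return PeptideMatch(
        peptide=pep, protein_id=protein.id, start=first + 1, end=first + len(pep)
    )


def cys_sites_in_peptide(match: PeptideMatch, protein: ProteinRecord) -> list[int]:
    """1-based protein coordinates of every cysteine within a peptide span."""
    return [p for p in protein.cys_positions if match.start <= p <= match.end]


def write_peptide_table(matches: Iterable[PeptideMatch], path: str | Path) -> None:
    """Write peptides as TSV: protein_id, start, end, peptide."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("protein_id\tstart\tend\tpeptide\n")
        for m in matches:
            fh.write(f"{m.protein_id}\t{m.start}\t{m.end}\t{m.peptide}\n")
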