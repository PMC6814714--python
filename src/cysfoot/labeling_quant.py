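"""Per-cysteine labeling ratios from spectral counts, with replicate aggregation.

The quantification model
------------------------
For a given cysteine, the labeling ratio (labeling efficiency) is the
fraction of spectral counts of peptides containing that cysteine that carry
the thiol modification:

    r = SC_mod / SC_total

Replicates are combined as a weighted mean, each replicate weighted by the
total number of peptides it contributed:

    r_bar = sum_i w_i r_i,   w_i = n_i / N,   N = sum_i n_i

which is algebraically identical to pooling all counts first. Three error
terms accompany each estimate:

* weighted standard error: SE = sqrt( sum_i w_i (r_i - r_bar)^2 / (m - 1) )
  over the m replicates with data (0 when m = 1);
* measurement (counting) error from the signal-to-noise of N spectral
  counts: ME = sqrt(N)/N = 1/sqrt(N);
* total error: quadrature combination sqrt(SE^2 + ME^2) by default, or the
  RMS variant sqrt((SE^2 + ME^2)/2) when ``rms=True``.

Peptides containing several cysteines cannot always be localized; the
``AmbiguityPolicy`` decides whether such PSMs are dropped (``localized_only``,
the default) or spread fractionally across their cysteines (``fractional``).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .psm_io import PSMTable
from .sequence_io import ProteinRecord, cys_sites_in_peptide, map_peptide_to_protein

__all__ = [
    "SiteCounts",
    "SiteEstimate",
    "AmbiguityPolicy",
    "SiteNotDetectedError",
    "tally_site_counts",
    "labeling_ratio",
    "aggregate_replicates",
    "quantify",
    "estimates_to_frame",
    "write_estimates",
    "replicate_ratio_series",
]


class SiteNotDetectedError(ValueError):
    """No spectral counts cover this site; no ratio can be estimated."""


class AmbiguityPolicy(str, enum.Enum):
    """How to tally unlocalized modifications on multi-cysteine peptides."""

    localized_only = "localized_only"
    fractional = "fractional"


@dataclass(frozen=True)
class SiteCounts:
    """Spectral counts for one site in one condition/replicate.

    ``sc_mod`` may be fractional under the ``fractional`` ambiguity policy.
    """

    protein_id: str
    residue_index: int
    condition: str
    replicate: str
    sc_mod: float
    sc_total: int
    n_ambiguous: int = 0  # covering PSMs excluded/split for ambiguity

    def __post_init__(self) -> None:
        if self.sc_mod < 0 or self.sc_total < 0:
            raise ValueError("negative spectral count")
        if self.sc_mod > self.sc_total + 1e-9:
            raise ValueError(
                f"sc_mod={self.sc_mod} exceeds sc_total={self.sc_total}"
            )


@dataclass(frozen=True)
class SiteEstimate:
    """Aggregated labeling ratio for one site in one condition."""

    protein_id: str
    residue_index: int
    condition: str
    ratio: float
    weighted_se: float
    measurement_error: float
    total_error: float
    n_total: int
    n_replicates: int
    ambiguous_fraction: float = 0.0


def labeling_ratio(sc_mod: float, sc_total: int) -> float:
    """SC_mod / SC_total. Raises SiteNotDetectedError when SC_total is 0."""
    if sc_total <= 0:
        raise SiteNotDetectedError("site not detected: zero spectral counts")
    r = sc_mod / sc_total
    if not (0.0 <= r <= 1.0 + 1e-12):
        raise ValueError(f"labeling ratio {r} outside [0, 1]")
    return min(r, 1.0)


def tally_site_counts(
    psms: PSMTable,
    protein: ProteinRecord,
    policy: AmbiguityPolicy = AmbiguityPolicy.localized_only,
) -> list[SiteCounts]:
    """Tally modified and total spectral counts per (site, condition, replicate).

    Every PSM whose peptide contains a cysteine contributes one total count
    to that site. A localized modification contributes one modified count to
    its site. Multi-cysteine PSMs flagged unlocalized are handled per
    ``policy``: excluded entirely (``localized_only``) or, for an unlocalized
    modification on a k-cysteine peptide, 1/k modified count to each
    contained site (``fractional``); either way they are tallied as
    ambiguous for reporting.

    PSMs for other proteins are ignored; peptides that fail to map raise
    the sequence-mapping errors.
    """
    policy = AmbiguityPolicy(policy)
    mod: dict[tuple[int, str, str], float] = {}
    tot: dict[tuple[int, str, str], int] = {}
    amb: dict[tuple[int, str, str], int] = {}
    pep_cache: dict[str, tuple[int, list[int]]] = {}

    for rec in psms:
        if rec.protein_id != protein.id:
            continue
        if rec.peptide not in pep_cache:
            match = map_peptide_to_protein(rec.peptide, protein)
            pep_cache[rec.peptide] = (match.start, cys_sites_in_peptide(match, protein))
        start, sites = pep_cache[rec.peptide]
        if not sites:
            continue
        k = len(sites)
        keys = [(s, rec.condition, rec.replicate) for s in sites]
        ambiguous = k > 1 and not rec.localized
        if ambiguous:
            for key in keys:
                amb[key] = amb.get(key, 0) + 1
            if policy is AmbiguityPolicy.localized_only:
                continue
        for key in keys:
            tot[key] = tot.get(key, 0) + 1
        if rec.modified:
            if ambiguous:
                # fractional policy: spread each unlocalized label over the
                # k cysteines of the peptide
                for key in keys:
                    mod[key] = mod.get(key, 0.0) + len(rec.mod_offsets) / k
            else:
                for off in rec.mod_offsets:
                    site = start + off - 1
                    key = (site, rec.condition, rec.replicate)
                    mod[key] = mod.get(key, 0.0) + 1.0

    out = [
        SiteCounts(
            protein_id=protein.id,
            residue_index=site,
            condition=cond,
            replicate=repl,
            sc_mod=mod.get((site, cond, repl), 0.0),
            sc_total=n,
            n_ambiguous=amb.get((site, cond, repl), 0),
        )
        for (site, cond, repl), n in tot.items()
    ]
    # ambiguous-only keys (every covering PSM excluded) still reported, with
    # zero totals, so the ambiguity is visible downstream
    for key, n_amb in amb.items():
        if key not in tot:
            site, cond, repl = key
            out.append(
                SiteCounts(
                    protein_id=protein.id,
                    residue_index=site,
                    condition=cond,
                    replicate=repl,
                    sc_mod=0.0,
                    sc_total=0,
                    n_ambiguous=n_amb,
                )
            )
    out.sort(key=lambda c: (c.residue_index, c.condition, str(c.replicate)))
    return out


def aggregate_replicates(
    counts: Sequence[SiteCounts], *, rms: bool = False
) -> SiteEstimate:
    """Combine one site+condition's replicate counts into a SiteEstimate.

    Weights are proportional to each replicate's total spectral count, so the
    weighted mean equals the pooled ratio sum(SC_mod)/sum(SC_total) exactly.
    """
    if not counts:
        raise SiteNotDetectedError("site not detected: no replicate counts")
    keys = {(c.protein_id, c.residue_index, c.condition) for c in counts}
    if len(keys) != 1:
        raise ValueError(f"counts span multiple sites/conditions: {sorted(keys)}")
    protein_id, residue_index, condition = keys.pop()

    with_data = [c for c in counts if c.sc_total > 0]
    if not with_data:
        raise SiteNotDetectedError(
            f"site {residue_index} not detected in condition {condition!r}"
        )
    n_total = sum(c.sc_total for c in with_data)
    weights = [c.sc_total / n_total for c in with_data]
    ratios = [labeling_ratio(c.sc_mod, c.sc_total) for c in with_data]
    r_bar = sum(w * r for w, r in zip(weights, ratios))

    m = len(with_data)
    if m > 1:
        se = math.sqrt(
            sum(w * (r - r_bar) ** 2 for w, r in zip(weights, ratios)) / (m - 1)
        )
    else:
        se = 0.0
    me = math.sqrt(n_total) / n_total  # = 1/sqrt(N)
    if rms:
        total = math.sqrt((se**2 + me**2) / 2.0)
    else:
        total = math.sqrt(se**2 + me**2)

    n_amb = sum(c.n_ambiguous for c in counts)
    # ambiguous_fraction: ambiguous covering PSMs over all covering PSMs.
    # Under localized_only ambiguous PSMs are not in sc_total, so the
    # denominator adds them back; under fractional they are already counted.
    denom = n_total + n_amb if _ambiguous_excluded(counts) else n_total
    amb_frac = (n_amb / denom) if denom > 0 else 0.0

    return SiteEstimate(
        protein_id=protein_id,
        residue_index=residue_index,
        condition=condition,
        ratio=r_bar,
        weighted_se=se,
        measurement_error=me,
        total_error=total,
        n_total=n_total,
        n_replicates=m,
        ambiguous_fraction=amb_frac,
    )


def _ambiguous_excluded(counts: Sequence[SiteCounts]) -> bool:
    # Heuristic only for the reporting denominator: if any replicate carries
    # ambiguous PSMs but fractional sc_mod never appears, they were excluded.
    any_amb = any(c.n_ambiguous > 0 for c in counts)
    any_frac = any(abs(c.sc_mod - round(c.sc_mod)) > 1e-9 for c in counts)
    return any_amb and not any_frac


def quantify(
    psms: PSMTable,
    protein: ProteinRecord,
    policy: AmbiguityPolicy = AmbiguityPolicy.localized_only,
    *,
    rms: bool = False,
) -> list[SiteEstimate]:
    """Full quantification: tally counts, then aggregate per site+condition."""
    counts = tally_site_counts(psms, protein, policy)
    grouped: dict[tuple[int, str], list[SiteCounts]] = {}
    for c in counts:
        grouped.setdefault((c.residue_index, c.condition), []).append(c)
    estimates = []
    for key in sorted(grouped, key=lambda k: (k[0], k[1])):
        try:
            estimates.append(aggregate_replicates(grouped[key], rms=rms))
        except SiteNotDetectedError:
            continue  # site flagged by absence from the output
    return estimates


def replicate_ratio_series(
    counts: Iterable[SiteCounts],
) -> dict[tuple[int, str], list[float]]:
    """Per-(site, condition) lists of replicate-level ratios, replicate-sorted.

    This is the granularity at which the two-condition Welch test operates.
    Replicates with zero coverage are omitted.
    """
    grouped: dict[tuple[int, str], list[tuple[str, float]]] = {}
    for c in counts:
        if c.sc_total > 0:
            grouped.setdefault((c.residue_index, c.condition), []).append(
                (str(c.replicate), labeling_ratio(c.sc_mod, c.sc_total))
            )
    return {
        key: [r for _, r in sorted(vals)] for key, vals in grouped.items()
    }


def estimates_to_frame(estimates: Iterable[SiteEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "protein_id": e.protein_id,
                "residue": e.residue_index,
                "condition": e.condition,
                "ratio": e.ratio,
                "weighted_se": e.weighted_se,
                "measurement_error": e.measurement_error,
                "total_error": e.total_error,
                "n_total": e.n_total,
                "n_replicates": e.n_replicates,
                "ambiguous_fraction": e.ambiguous_fraction,
            }
            for e in estimates
        ]
    )


def write_estimates(estimates: Iterable[SiteEstimate], path: str | Path) -> None:
    estimates_to_frame(estimates).to_csv(path, sep="\t", index=False)
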