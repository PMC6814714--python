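"""Differential labeling between two conditions: Welch's t-test and star flags.

The test operates on replicate-level ratios (one number per replicate) —
the only granularity at which a two-sample t-test is defined for this data.
Significance flags follow the conventional star thresholds with inclusive
comparisons: * for p <= 0.05, ** for p <= 0.01, *** for p <= 0.001.
No multiple-testing correction is applied by default; Benjamini-Hochberg
q-values are available on request.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .labeling_quant import SiteEstimate

__all__ = [
    "DifferentialResult",
    "InsufficientReplicatesError",
    "welch_test",
    "star_level",
    "compare_conditions",
    "results_to_frame",
    "write_results",
]


class InsufficientReplicatesError(ValueError):
    """Fewer than two replicate observations on one side of the test."""


@dataclass(frozen=True)
class DifferentialResult:
    """Per-site two-condition comparison.

    ``delta`` is ratio_b - ratio_a. ``stars`` encodes the significance flag
    (0-3). ``p_value``/``t_stat``/``df`` are None for presence/absence rows
    (site detected in only one condition) or when replicates are
    insufficient.
    """

    residue_index: int
    condition_a: str
    condition_b: str
    ratio_a: float | None
    ratio_b: float | None
    delta: float | None
    t_stat: float | None
    df: float | None
    p_value: float | None
    stars: int
    q_value: float | None = None
    note: str = ""


def welch_test(
    a: Sequence[float], b: Sequence[float]
) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test on two replicate series.

    Returns ``(t, df, p)`` with t = (mean_a - mean_b)/sqrt(s_a^2/n_a +
    s_b^2/n_b), Welch-Satterthwaite degrees of freedom, and a two-sided p
    from Student's t distribution.

    Degenerate input with both sample variances zero and equal means returns
    ``(0.0, n_a + n_b - 2, 1.0)``; zero variances with unequal means return
    ``(±inf, ..., 0.0)``.

    Raises
    ------
    InsufficientReplicatesError
        If either series has fewer than two values.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientReplicatesError(
            f"need >=2 replicates per side, got {a.size} and {b.size}"
        )
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        t = math.inf if a.mean() > b.mean() else -math.inf
        return t, float(a.size + b.size - 2), 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def star_level(p: float) -> int:
    """Map a p-value to 0-3 stars (inclusive thresholds 0.05/0.01/0.001)."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p <= 0.001:
        return 3
    if p <= 0.01:
        return 2
    if p <= 0.05:
        return 1
    return 0


def compare_conditions(
    estimates_a: Iterable[SiteEstimate],
    estimates_b: Iterable[SiteEstimate],
    replicate_ratios_a: Mapping[int, Sequence[float]],
    replicate_ratios_b: Mapping[int, Sequence[float]],
    *,
    bh: bool = False,
) -> list[DifferentialResult]:
    """Site-by-site Welch comparison of two conditions.

    ``replicate_ratios_*`` map residue index to that site's replicate-level
    ratios in the respective condition. Sites present on only one side are
    emitted as presence/absence rows without a p-value. With ``bh=True``,
    Benjamini-Hochberg q-values are attached to the tested rows.

    Raises
    ------
    ValueError
        If the two conditions share no site at all.
    """
    est_a = {e.residue_index: e for e in estimates_a}
    est_b = {e.residue_index: e for e in estimates_b}
    if not est_a or not est_b:
        raise ValueError("empty estimate list")
    cond_a = next(iter(est_a.values())).condition
    cond_b = next(iter(est_b.values())).condition
    shared = sorted(set(est_a) & set(est_b))
    if not shared:
        raise ValueError(
            f"conditions {cond_a!r} and {cond_b!r} share no detected site"
        )

    results: list[DifferentialResult] = []
    tested_idx: list[int] = []
    pvals: list[float] = []
    for site in shared:
        ra, rb = est_a[site].ratio, est_b[site].ratio
        reps_a = list(replicate_ratios_a.get(site, ()))
        reps_b = list(replicate_ratios_b.get(site, ()))
        try:
            t, df, p = welch_test(reps_a, reps_b)
            # welch_test is mean_a - mean_b; keep t's sign consistent with
            # delta = ratio_b - ratio_a by reporting the a-vs-b statistic as-is
            tested_idx.append(len(results))
            pvals.append(p)
            results.append(
                DifferentialResult(
                    residue_index=site,
                    condition_a=cond_a,
                    condition_b=cond_b,
                    ratio_a=ra,
                    ratio_b=rb,
                    delta=rb - ra,
                    t_stat=t,
                    df=df,
                    p_value=p,
                    stars=star_level(p),
                )
            )
        except InsufficientReplicatesError as exc:
            results.append(
                DifferentialResult(
                    residue_index=site,
                    condition_a=cond_a,
                    condition_b=cond_b,
                    ratio_a=ra,
                    ratio_b=rb,
                    delta=rb - ra,
                    t_stat=None,
                    df=None,
                    p_value=None,
                    stars=0,
                    note=str(exc),
                )
            )
    for site in sorted(set(est_a) ^ set(est_b)):
        on_a = site in est_a
        results.append(
            DifferentialResult(
                residue_index=site,
                condition_a=cond_a,
                condition_b=cond_b,
                ratio_a=est_a[site].ratio if on_a else None,
                ratio_b=est_b[site].ratio if not on_a else None,
                delta=None,
                t_stat=None,
                df=None,
                p_value=None,
                stars=0,
                note=f"detected only in {cond_a if on_a else cond_b!r}",
            )
        )

    if bh and pvals:
        qvals = stats.false_discovery_control(np.asarray(pvals), method="bh")
        for i, q in zip(tested_idx, qvals):
            r = results[i]
            results[i] = DifferentialResult(
                **{**r.__dict__, "q_value": float(q)}
            )
    results.sort(key=lambda r: r.residue_index)
    return results


def results_to_frame(results: Iterable[DifferentialResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def write_results(results: Iterable[DifferentialResult], path: str | Path) -> None:
    results_to_frame(results).to_csv(path, sep="\t", index=False)
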