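"""Distributional checks and nonparametric group comparisons.

Percentage-of-pixel data are compared between temperature ranges and
between study subsets with the Kruskal-Wallis rank test followed by Dunn's
multiple-comparison z tests (tie-corrected, Bonferroni-adjusted by
default). Normality is screened per sample with Shapiro-Wilk, and
distributions are summarised box-plot style with median, quartiles and
min/max whiskers (no outlier trimming).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps


def normality_check(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk test: returns (W, p). Requires 3 <= n <= 5000."""
    x = np.asarray(values, dtype=float)
    if not 3 <= len(x) <= 5000:
        raise ValueError(f"Shapiro-Wilk needs 3 <= n <= 5000, got n={len(x)}")
    if np.ptp(x) == 0.0:
        raise ValueError("constant sample: normality test undefined")
    w, p = _sps.shapiro(x)
    return float(w), float(p)


@dataclass
class BoxSummary:
    """Five-number box-plot summary (whiskers at min/max, no trimming)."""

    median: float
    lower_quartile: float
    upper_quartile: float
    minimum: float
    maximum: float


def describe_box(values: Sequence[float]) -> BoxSummary:
    """Median and quartiles (linear interpolation between order statistics)
    with whiskers at the sample extremes."""
    x = np.asarray(values, dtype=float)
    if len(x) == 0:
        raise ValueError("empty sample")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return BoxSummary(
        median=float(med),
        lower_quartile=float(q1),
        upper_quartile=float(q3),
        minimum=float(x.min()),
        maximum=float(x.max()),
    )


@dataclass
class KWResult:
    """Kruskal-Wallis H with Dunn pairwise follow-up."""

    H: float
    df: int
    p: float
    pairwise: list[tuple] = field(default_factory=list)
    adjustment: str = "bonferroni"

    def pairwise_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.pairwise, columns=["group_i", "group_j", "z", "p_raw", "p_adjusted"]
        )


def dunn_posthoc(
    groups: Sequence[Sequence[float]],
    adjustment: str = "bonferroni",
    labels: Sequence | None = None,
) -> list[tuple]:
    """Dunn's multiple-comparison z tests after a Kruskal-Wallis test.

    Pools all observations, ranks with midranks for ties, and for each pair
    computes z = (Rbar_i - Rbar_j) / sqrt(V (1/n_i + 1/n_j)) with the
    tie-corrected variance V = N(N+1)/12 - sum(t^3 - t)/(12(N-1)). Raw
    p-values are two-sided normal tails; ``bonferroni`` multiplies by the
    number of pairs (capped at 1), ``none`` leaves them raw.
    """
    if adjustment not in {"bonferroni", "none"}:
        raise ValueError(f"adjustment must be 'bonferroni' or 'none', got {adjustment!r}")
    samples = [np.asarray(g, dtype=float) for g in groups]
    if len(samples) < 2 or any(len(g) < 1 for g in samples):
        raise ValueError("need at least two non-empty groups")
    if labels is None:
        labels = list(range(len(samples)))
    pooled = np.concatenate(samples)
    n_total = len(pooled)
    if np.ptp(pooled) == 0.0:
        raise ValueError("all observations identical: ranks are degenerate")
    ranks = _sps.rankdata(pooled)
    mean_ranks = []
    start = 0
    for g in samples:
        mean_ranks.append(ranks[start : start + len(g)].mean())
        start += len(g)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    variance = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    n_pairs = len(samples) * (len(samples) - 1) // 2
    rows = []
    for i, j in combinations(range(len(samples)), 2):
        se = np.sqrt(variance * (1.0 / len(samples[i]) + 1.0 / len(samples[j])))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p_raw = 2.0 * _sps.norm.sf(abs(z))
        p_adj = min(1.0, p_raw * n_pairs) if adjustment == "bonferroni" else p_raw
        rows.append((labels[i], labels[j], float(z), float(p_raw), float(p_adj)))
    return rows


def kruskal_wallis(
    groups: Sequence[Sequence[float]],
    adjustment: str = "bonferroni",
    labels: Sequence | None = None,
) -> KWResult:
    """Tie-corrected Kruskal-Wallis H with chi-square p and Dunn follow-up."""
    samples = [np.asarray(g, dtype=float) for g in groups]
    if len(samples) < 2 or any(len(g) < 1 for g in samples):
        raise ValueError("need at least two non-empty groups")
    if sum(len(g) for g in samples) < 3:
        raise ValueError("need at least three observations in total")
    pooled = np.concatenate(samples)
    if np.ptp(pooled) == 0.0:
        raise ValueError("all observations identical: H undefined under total ties")
    h, p = _sps.kruskal(*samples)
    pairwise = dunn_posthoc(samples, adjustment=adjustment, labels=labels)
    return KWResult(
        H=float(h), df=len(samples) - 1, p=float(p), pairwise=pairwise, adjustment=adjustment
    )


def descriptive_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and sample SD (n-1 denominator) of age, height and body
    condition score over a cohort demographics table.

    Expects columns ``age_years``, ``height_cm`` and ``bcs``.
    """
    if len(table) == 0:
        raise ValueError("empty demographics table")
    cols = {"age_years": "age (years)", "height_cm": "height (cm)", "bcs": "BCS"}
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"demographics table lacks columns: {missing}")
    rows = []
    for col, label in cols.items():
        x = table[col].astype(float)
        rows.append({"variable": label, "mean": x.mean(), "sd": x.std(ddof=1)})
    return pd.DataFrame(rows)


def compact_letter_display(
    labels: Sequence, pairwise: Sequence[tuple], alpha: float = 0.05
) -> dict:
    """Assign lowercase letters so groups sharing a letter do not differ.

    Deterministic insert-and-absorb: groups are processed in the given
    order; each significant pair (adjusted p < alpha) must end up with no
    letter in common.
    """
    labels = list(labels)
    differ = {
        frozenset((a, b)) for a, b, _z, _p, p_adj in pairwise if p_adj < alpha
    }
    letter_sets: list[set] = [set(labels)]
    for pair in sorted(differ, key=lambda s: tuple(sorted(map(str, s)))):
        a, b = sorted(pair, key=str)
        for s in list(letter_sets):
            if a in s and b in s:
                letter_sets.remove(s)
                letter_sets.append(s - {a})
                letter_sets.append(s - {b})
    # absorb subsets, keep deterministic order
    letter_sets = [s for s in letter_sets if s and not any(
        s < t for t in letter_sets
    )]
    seen = []
    for s in letter_sets:
        fs = frozenset(s)
        if fs not in seen:
            seen.append(fs)
    letters = {}
    for label in labels:
        letters[label] = "".join(
            chr(ord("a") + i) for i, s in enumerate(seen) if label in s
        )
    return letters
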