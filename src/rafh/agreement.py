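"""Two-grader reliability of RAFH measurements.

Bland-Altman limits of agreement (mean difference +/- 1.96 x SD of the
per-image differences), the two-way random-effects absolute-agreement
single-rater intraclass correlation ICC(A,1) with its F-based confidence
interval, strict flagging of images whose intergrader difference falls
outside the limits of agreement, and grader averaging for downstream
analyses.

The consensus procedure runs once: flag discordant images, substitute
re-graded values, recompute the summary.  It is not iterated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

LOA_MULTIPLIER = 1.96


@dataclass
class GraderPairSet:
    """Per-image RAFH readings from two independent graders."""

    ids: list
    g1: np.ndarray
    g2: np.ndarray

    def __post_init__(self) -> None:
        self.g1 = np.asarray(self.g1, dtype=float)
        self.g2 = np.asarray(self.g2, dtype=float)
        if not (len(self.ids) == len(self.g1) == len(self.g2)):
            raise ValueError("ids, g1 and g2 must have equal length")
        for name, vals in (("g1", self.g1), ("g2", self.g2)):
            if np.any((vals < 0) | (vals > 1)):
                raise ValueError(f"{name} contains RAFH values outside [0, 1]")

    @property
    def n(self) -> int:
        return len(self.ids)

    def with_consensus(self, consensus: dict) -> "GraderPairSet":
        """Return a copy where flagged images carry re-graded values.

        ``consensus`` maps image id -> agreed RAFH; both graders' entries are
        replaced by it.
        """
        g1, g2 = self.g1.copy(), self.g2.copy()
        index = {im_id: i for i, im_id in enumerate(self.ids)}
        for im_id, value in consensus.items():
            i = index[im_id]
            g1[i] = g2[i] = float(value)
        return GraderPairSet(list(self.ids), g1, g2)


@dataclass
class AgreementSummary:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int
    icc: float | None = None
    icc_ci_low: float | None = None
    icc_ci_high: float | None = None
    n_flagged: int | None = None
    flagged_ids: list = field(default_factory=list)


def bland_altman(pairs: GraderPairSet) -> AgreementSummary:
    """Mean difference (g1 - g2), sample SD (n-1), and 95% limits of agreement."""
    if pairs.n < 2:
        raise ValueError("need at least 2 pairs")
    d = pairs.g1 - pairs.g2
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return AgreementSummary(
        mean_diff=mean,
        sd_diff=sd,
        loa_low=mean - LOA_MULTIPLIER * sd,
        loa_high=mean + LOA_MULTIPLIER * sd,
        n=pairs.n,
    )


def icc_absolute_agreement(
    pairs: GraderPairSet, alpha: float = 0.05
) -> tuple[float, float, float]:
    """ICC(A,1): two-way random effects, absolute agreement, single rater.

    Computed from the two-way ANOVA mean squares (rows = images, columns =
    graders) with the F-distribution confidence interval of McGraw & Wong.
    Returns (icc, ci_low, ci_high); a degenerate zero-variance input yields
    NaNs.
    """
    if pairs.n < 5:
        raise ValueError("need at least 5 pairs for a meaningful ICC")
    data = np.column_stack([pairs.g1, pairs.g2])
    if np.ptp(data) == 0:  # zero total variance: ICC undefined
        return float("nan"), float("nan"), float("nan")
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom <= 0 or ss_total == 0:
        return float("nan"), float("nan"), float("nan")
    icc = (msr - mse) / denom

    # McGraw & Wong (1996) CI for case 2A single-measurement
    if icc >= 1.0 or not np.isfinite(icc):
        return float(icc), float("nan"), float("nan")
    a = (k * icc) / (n * (1 - icc))
    b = 1 + (k * icc * (n - 1)) / (n * (1 - icc))
    v_num = (a * msc + b * mse) ** 2
    v_den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    v = v_num / v_den
    f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f1 * mse) / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f2 * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
    return float(icc), float(lower), float(upper)


def flag_discordant(pairs: GraderPairSet, summary: AgreementSummary) -> list:
    """Image ids whose difference lies STRICTLY outside the limits of agreement."""
    d = pairs.g1 - pairs.g2
    outside = (d < summary.loa_low) | (d > summary.loa_high)
    return [im_id for im_id, out in zip(pairs.ids, outside) if out]


def mean_grader_rafh(pairs: GraderPairSet) -> np.ndarray:
    """Per-image consensus value: the plain mean of the two graders."""
    if np.any(np.isnan(pairs.g1)) or np.any(np.isnan(pairs.g2)):
        raise ValueError("grader pair set has missing readings")
    return 0.5 * (pairs.g1 + pairs.g2)


def grade_agreement(
    pairs: GraderPairSet, consensus: dict | None = None, alpha: float = 0.05
) -> tuple[AgreementSummary, GraderPairSet]:
    """Full single-round agreement workflow.

    Flags discordant images on the initial limits of agreement, substitutes
    consensus values where provided (by default the pair mean stands in for
    the joint re-grade), recomputes the summary once, and attaches the ICC.
    Returns the final summary and the post-consensus pair set.
    """
    initial = bland_altman(pairs)
    flagged = flag_discordant(pairs, initial)
    if consensus is None:
        consensus = {}
        idx = {im_id: i for i, im_id in enumerate(pairs.ids)}
        for im_id in flagged:
            i = idx[im_id]
            consensus[im_id] = 0.5 * (pairs.g1[i] + pairs.g2[i])
    resolved = pairs.with_consensus({k: v for k, v in consensus.items() if k in set(flagged)})
    summary = bland_altman(resolved)
    icc, lo, hi = icc_absolute_agreement(resolved, alpha=alpha)
    summary.icc, summary.icc_ci_low, summary.icc_ci_high = icc, lo, hi
    summary.n_flagged = len(flagged)
    summary.flagged_ids = flagged
    return summary, resolved


def bland_altman_plot(pairs: GraderPairSet, summary: AgreementSummary | None = None, ax=None):
    """Bland-Altman scatter with mean-difference and limits-of-agreement lines."""
    import matplotlib.pyplot as plt

    if summary is None:
        summary = bland_altman(pairs)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    means = 0.5 * (pairs.g1 + pairs.g2)
    diffs = pairs.g1 - pairs.g2
    ax.scatter(means, diffs, s=14, alpha=0.6, edgecolor="none")
    ax.axhline(summary.mean_diff, color="k", lw=1.2)
    for y in (summary.loa_low, summary.loa_high):
        ax.axhline(y, color="k", lw=1.0, ls="--")
    ax.set_xlabel("Mean RAFH of graders")
    ax.set_ylabel("Grader 1 $-$ Grader 2")
    ax.set_title(f"Intergrader agreement (n={summary.n})")
    return ax
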