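"""Group comparisons and repeatability metrics for cohort biomarkers.

Normality is assessed per group (Shapiro-Wilk at alpha = 0.05); normally
distributed pairs are compared with an unpaired two-sided t-test, otherwise
an unpaired rank test is used.  The nonparametric branch is the
Mann-Whitney rank-sum test: a signed-rank test is a paired procedure and
is not applicable to independent groups (recorded in the result notes).

Repeatability between aligned repeated profiles is summarized by pairwise
Pearson correlation coefficients and root-mean-square deviations (RMSD).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = ["GroupComparison", "RepeatabilityResult", "compare_groups",
           "repeatability"]


@dataclass
class GroupComparison:
    """Two-group comparison with the test choice recorded for reproducibility."""

    labels: tuple[str, str]
    mean_sd: dict[str, tuple[float, float]]
    test: str  # "t-test (parametric)" or "rank-sum (nonparametric)"
    statistic: float
    p_value: float
    alpha: float
    significant: bool
    shapiro_p: tuple[float, float]
    notes: str = ""

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "mean_sd": {k: list(v) for k, v in self.mean_sd.items()},
            "test": self.test,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "alpha": self.alpha,
            "significant": self.significant,
            "shapiro_p": list(self.shapiro_p),
            "notes": self.notes,
        }


@dataclass
class RepeatabilityResult:
    """Pairwise Pearson r and RMSD between repeated aligned measurements."""

    pearson: dict[tuple[int, int], float]
    rmsd: dict[tuple[int, int], float]
    pearson_mean_sd: tuple[float, float] = field(init=False)
    rmsd_mean_sd: tuple[float, float] = field(init=False)

    def __post_init__(self) -> None:
        r = np.array(list(self.pearson.values()))
        d = np.array(list(self.rmsd.values()))
        self.pearson_mean_sd = (float(r.mean()), float(r.std(ddof=1)) if r.size > 1 else 0.0)
        self.rmsd_mean_sd = (float(d.mean()), float(d.std(ddof=1)) if d.size > 1 else 0.0)


def compare_groups(a, b, alpha: float = 0.05,
                   labels: tuple[str, str] = ("a", "b")) -> GroupComparison:
    """Compare two independent samples with a normality-gated test choice.

    Both groups normal by Shapiro-Wilk (p > 0.05) -> unpaired two-sided
    t-test; otherwise -> two-sided Mann-Whitney rank-sum.  Means and SDs are
    always reported.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each sample must have at least 3 observations")
    sp_a = sps.shapiro(a).pvalue if np.ptp(a) > 0 else 1.0
    sp_b = sps.shapiro(b).pvalue if np.ptp(b) > 0 else 1.0
    notes = ""
    if sp_a > 0.05 and sp_b > 0.05:
        test = "t-test (parametric)"
        if np.ptp(np.concatenate([a, b])) == 0:
            stat, p = 0.0, 1.0  # identical constant samples
        else:
            stat, p = sps.ttest_ind(a, b, equal_var=True)
    else:
        test = "rank-sum (nonparametric)"
        notes = ("unpaired Mann-Whitney rank-sum used for independent groups "
                 "(signed-rank is a paired procedure)")
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
    return GroupComparison(
        labels=labels,
        mean_sd={labels[0]: (float(a.mean()), float(a.std(ddof=1))),
                 labels[1]: (float(b.mean()), float(b.std(ddof=1)))},
        test=test, statistic=float(stat), p_value=float(p), alpha=alpha,
        significant=bool(p < alpha), shapiro_p=(float(sp_a), float(sp_b)),
        notes=notes)


def repeatability(profiles) -> RepeatabilityResult:
    """All pairwise Pearson r and RMSD across >= 2 aligned time series."""
    arrays = [np.asarray(p, dtype=float) for p in profiles]
    if len(arrays) < 2:
        raise ValueError("need at least two profiles")
    n = arrays[0].size
    if any(a.size != n for a in arrays):
        raise ValueError("profiles must have equal length (aligned time base)")
    pearson, rmsd = {}, {}
    for i, j in itertools.combinations(range(len(arrays)), 2):
        x, y = arrays[i], arrays[j]
        if np.ptp(x) == 0 and np.ptp(y) == 0:
            r = 1.0 if np.allclose(x - x.mean(), y - y.mean()) else 0.0
        else:
            r = float(sps.pearsonr(x, y).statistic)
        pearson[(i, j)] = r
        rmsd[(i, j)] = float(np.sqrt(np.mean((x - y) ** 2)))
    return RepeatabilityResult(pearson=pearson, rmsd=rmsd)
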