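"""Prediction-error summaries and paired method comparison.

Prediction error (PE) is achieved minus predicted postoperative spherical
equivalent; after myopic laser correction a positive PE is the classic
hyperopic surprise.  Methods are compared the way post-refractive IOL
studies report them: per-method numeric-PE statistics, absolute PE,
percentages of eyes within +/-0.5 D and +/-1.0 D (inclusive bounds), a
one-sample t test of mean PE against zero, pairwise two-sided
variance-ratio F tests on numeric PE (plus a one-way ANOVA omnibus),
a Friedman omnibus on absolute PE with Wilcoxon signed-rank post hocs,
McNemar tests on the within-threshold indicators, and Bonferroni
adjustment of all pairwise p-values.

Degenerate inputs (zero variance, all-tied differences, no discordant
pairs) yield explicit "not computable" notes rather than exceptions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, asdict, field
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.contingency_tables import mcnemar as _mcnemar

ALPHA = 0.05


def prediction_error(actual_se, predicted_se):
    """PE = achieved SE - predicted SE (D); positive = hyperopic surprise."""
    out = np.asarray(actual_se, dtype=float) - np.asarray(predicted_se, dtype=float)
    return out.item() if np.ndim(out) == 0 else out


def pct_within(pe_list, threshold: float) -> float:
    """Percentage of eyes with |PE| <= threshold (inclusive)."""
    pe = np.asarray(pe_list, dtype=float)
    if pe.size == 0:
        raise ValueError("empty prediction-error list")
    return float(np.mean(np.abs(pe) <= threshold) * 100.0)


@dataclass(frozen=True)
class ErrorSummary:
    """Per-method PE statistics (one summary-table row)."""

    method_label: str
    mean_numeric_pe: float
    sd_numeric_pe: float
    variance_numeric_pe: float
    mean_absolute_pe: float
    median_absolute_pe: float
    pct_within_0_50: float
    pct_within_1_00: float
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


def summarize_errors(pe_list, label: str = "") -> ErrorSummary:
    """Summary statistics of a list of prediction errors (D).

    SD/variance are the sample (ddof=1) values, matching clinical reporting;
    a single-eye list gets SD 0.  Both mean and median absolute PE are
    carried so either flavour of comparison can be reproduced.
    """
    pe = np.asarray(pe_list, dtype=float)
    if pe.size == 0:
        raise ValueError("empty prediction-error list")
    sd = float(np.std(pe, ddof=1)) if pe.size > 1 else 0.0
    return ErrorSummary(
        method_label=label,
        mean_numeric_pe=float(np.mean(pe)),
        sd_numeric_pe=sd,
        variance_numeric_pe=sd**2,
        mean_absolute_pe=float(np.mean(np.abs(pe))),
        median_absolute_pe=float(np.median(np.abs(pe))),
        pct_within_0_50=pct_within(pe, 0.50),
        pct_within_1_00=pct_within(pe, 1.00),
        n=int(pe.size),
    )


@dataclass
class TestResult:
    """One statistical test: statistic, raw p, optional adjusted p, a note
    when the test was not computable."""

    statistic: float | None
    p_value: float | None
    p_adjusted: float | None = None
    significant: bool | None = None
    note: str = ""

    def to_dict(self) -> dict:
        return asdict(self)


def _bonferroni(p: float | None, m: int) -> float | None:
    return None if p is None else min(1.0, p * m)


def _finish(res: TestResult, m: int) -> TestResult:
    res.p_adjusted = _bonferroni(res.p_value, m)
    if res.p_adjusted is not None:
        res.significant = bool(res.p_adjusted < ALPHA)
    return res


def _one_sample_t(col: np.ndarray) -> TestResult:
    if np.ptp(col) == 0:
        return TestResult(None, None, note="constant column; t test degenerate")
    t, p = stats.ttest_1samp(col, 0.0)
    return TestResult(float(t), float(p), significant=bool(p < ALPHA))

def _variance_f(a: np.ndarray, b: np.ndarray) -> TestResult:
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0 or vb == 0:
        return TestResult(None, None, note="zero variance; F test degenerate")
    f = va / vb
    dfa, dfb = len(a) - 1, len(b) - 1
    p = 2.0 * min(stats.f.sf(f, dfa, dfb), stats.f.cdf(f, dfa, dfb))
    return TestResult(float(f), float(min(p, 1.0)))


def _wilcoxon(a: np.ndarray, b: np.ndarray) -> TestResult:
    diff = a - b
    if np.all(diff == 0):
        return TestResult(None, 1.0, note="all differences zero")
    stat, p = stats.wilcoxon(a, b)
    return TestResult(float(stat), float(p))


def _mcnemar_pair(ind_a: np.ndarray, ind_b: np.ndarray) -> TestResult:
    b01 = int(np.sum(ind_a & ~ind_b))
    b10 = int(np.sum(~ind_a & ind_b))
    if b01 + b10 == 0:
        return TestResult(None, 1.0, note="no discordant pairs")
    table = [
        [int(np.sum(ind_a & ind_b)), b01],
        [b10, int(np.sum(~ind_a & ~ind_b))],
    ]
    res = _mcnemar(table, exact=True)
    return TestResult(float(res.statistic), float(res.pvalue))


@dataclass
class ComparisonReport:
    """Full paired comparison of >=2 methods on the same eyes."""

    labels: list[str]
    n_eyes: int
    summaries: dict[str, ErrorSummary]
    one_sample_t: dict[str, TestResult]
    anova_numeric_pe: TestResult
    friedman_absolute_pe: TestResult
    variance_f: dict[str, TestResult] = field(default_factory=dict)
    wilcoxon_absolute_pe: dict[str, TestResult] = field(default_factory=dict)
    mcnemar_within_0_50: dict[str, TestResult] = field(default_factory=dict)
    mcnemar_within_1_00: dict[str, TestResult] = field(default_factory=dict)

    def to_dict(self) -> dict:
        def conv(d):
            return {k: v.to_dict() for k, v in d.items()}

        return {
            "labels": self.labels,
            "n_eyes": self.n_eyes,
            "alpha": ALPHA,
            "summaries": conv(self.summaries),
            "one_sample_t": conv(self.one_sample_t),
            "anova_numeric_pe": self.anova_numeric_pe.to_dict(),
            "friedman_absolute_pe": self.friedman_absolute_pe.to_dict(),
            "variance_f": conv(self.variance_f),
            "wilcoxon_absolute_pe": conv(self.wilcoxon_absolute_pe),
            "mcnemar_within_0_50": conv(self.mcnemar_within_0_50),
            "mcnemar_within_1_00": conv(self.mcnemar_within_1_00),
        }


def compare_methods(
    pe_table: np.ndarray | Sequence[Sequence[float]],
    labels: Sequence[str],
) -> ComparisonReport:
    """Compare methods column-wise on a paired eyes x methods PE matrix.

    Pairwise p-values (F, Wilcoxon, McNemar) are Bonferroni-adjusted by the
    number of pairwise comparisons; significance is flagged at alpha=0.05
    on the adjusted value.
    """
    pe = np.asarray(pe_table, dtype=float)
    if pe.ndim != 2:
        raise ValueError("pe_table must be 2-D (eyes x methods)")
    n_eyes, n_methods = pe.shape
    if n_methods < 2:
        raise ValueError("need at least 2 methods")
    if len(labels) != n_methods:
        raise ValueError(
            f"{len(labels)} labels for {n_methods} methods — rows must be "
            "paired observations of the same eyes"
        )
    labels = [str(l) for l in labels]

    summaries = {l: summarize_errors(pe[:, j], l) for j, l in enumerate(labels)}
    t_tests = {l: _one_sample_t(pe[:, j]) for j, l in enumerate(labels)}

    cols = [pe[:, j] for j in range(n_methods)]
    if all(np.ptp(c) == 0 for c in cols):
        anova = TestResult(None, None, note="all columns constant")
    else:
        f, p = stats.f_oneway(*cols)
        anova = TestResult(float(f), float(p), significant=bool(p < ALPHA))

    abs_pe = np.abs(pe)
    if n_methods >= 3:
        if np.ptp(abs_pe - abs_pe[:, [0]]) == 0:
            friedman = TestResult(None, 1.0, note="no variation between methods")
        else:
            stat, p = stats.friedmanchisquare(*[abs_pe[:, j] for j in range(n_methods)])
            friedman = TestResult(float(stat), float(p), significant=bool(p < ALPHA))
    else:
        friedman = _wilcoxon(abs_pe[:, 0], abs_pe[:, 1])
        friedman.note = (friedman.note + " (2 methods: Wilcoxon in place of Friedman)").strip()
        if friedman.p_value is not None:
            friedman.significant = bool(friedman.p_value < ALPHA)

    pairs = list(itertools.combinations(range(n_methods), 2))
    m = len(pairs)
    report = ComparisonReport(
        labels=labels,
        n_eyes=n_eyes,
        summaries=summaries,
        one_sample_t=t_tests,
        anova_numeric_pe=anova,
        friedman_absolute_pe=friedman,
    )
    within05 = np.abs(pe) <= 0.50
    within10 = np.abs(pe) <= 1.00
    for i, j in pairs:
        key = f"{labels[i]} vs {labels[j]}"
        report.variance_f[key] = _finish(_variance_f(pe[:, i], pe[:, j]), m)
        report.wilcoxon_absolute_pe[key] = _finish(
            _wilcoxon(abs_pe[:, i], abs_pe[:, j]), m
        )
        report.mcnemar_within_0_50[key] = _finish(
            _mcnemar_pair(within05[:, i], within05[:, j]), m
        )
        report.mcnemar_within_1_00[key] = _finish(
            _mcnemar_pair(within10[:, i], within10[:, j]), m
        )
    return report
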