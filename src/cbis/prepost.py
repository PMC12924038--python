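"""Single-arm pre/post pilot statistics.

For each outcome variable, per-participant change scores are computed over
5-day averaging windows (Δ = post-intervention value − pre-intervention
value), binary daily symptoms are converted to frequency percentages
(days present / 5 × 100), and the Δ sample is routed by a Shapiro–Wilk
normality gate (α = .05): normal → paired two-tailed t test with Cohen
d = mean(Δ)/sd(Δ) = t/√n; non-normal → Wilcoxon signed-rank with the
tie-corrected normal approximation (zeros dropped), effect size
r = |z|/√(2n) with N = 2n paired observations.  Spearman rank correlation
explores associations between change scores.  No multiplicity adjustment is
applied (exploratory single-arm design).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PrePostRecord",
    "PrePostResult",
    "WINDOW_DAYS",
    "window_mean",
    "symptom_frequency",
    "normality_gate",
    "paired_t",
    "wilcoxon_signed_rank",
    "spearman_delta",
    "analyze_variable",
    "build_report",
]

#: Fixed pre/post averaging window length (days).
WINDOW_DAYS = 5

#: Descriptive alpha for the Shapiro-Wilk normality gate.
NORMALITY_ALPHA = 0.05


@dataclass(frozen=True)
class PrePostRecord:
    """One participant's pre/post daily values for one variable."""

    patient_id: str
    variable: str
    pre_window: tuple[float, ...]
    post_window: tuple[float, ...]

    def __post_init__(self) -> None:
        for name, w in (("pre_window", self.pre_window), ("post_window", self.post_window)):
            if len(w) != WINDOW_DAYS:
                raise ValueError(f"{name} must hold exactly {WINDOW_DAYS} daily values "
                                 f"(got {len(w)})")

    @property
    def pre_mean(self) -> float:
        return float(np.mean(self.pre_window))

    @property
    def post_mean(self) -> float:
        return float(np.mean(self.post_window))

    @property
    def delta(self) -> float:
        return self.post_mean - self.pre_mean


@dataclass(frozen=True)
class PrePostResult:
    """Per-variable test summary (one row of a results table)."""

    variable: str
    n: int
    test: str                     # "paired_t" | "wilcoxon"
    statistic: float              # t or z
    df: int | None
    p_value: float
    difference: float             # mean or median difference (post − pre)
    ci_95: tuple[float, float] | None
    effect_size: float            # Cohen d or r
    effect_size_type: str         # "cohen_d" | "r"

    def __post_init__(self) -> None:
        expected = "cohen_d" if self.test == "paired_t" else "r"
        if self.effect_size_type != expected:
            raise ValueError("effect size type inconsistent with test type")


def window_mean(daily: Sequence[float]) -> float:
    """Arithmetic mean of a 5-day observation window (no missing days)."""
    if len(daily) != WINDOW_DAYS:
        raise ValueError(f"a pre/post window requires exactly {WINDOW_DAYS} daily values")
    return float(np.mean(daily))


def symptom_frequency(presence: Sequence[bool | int]) -> float:
    """Days a binary symptom was present over a 5-day window, as a percent."""
    if len(presence) != WINDOW_DAYS:
        raise ValueError(f"symptom window requires exactly {WINDOW_DAYS} daily indicators")
    vals = []
    for p in presence:
        if p in (0, 1, False, True):
            vals.append(int(p))
        else:
            raise ValueError(f"symptom indicator must be binary, got {p!r}")
    return 100.0 * sum(vals) / WINDOW_DAYS


def normality_gate(deltas: Sequence[float]) -> str:
    """Shapiro-Wilk gate on the change scores: "normal" routes to the paired
    t path, "non_normal" to Wilcoxon.  A degenerate all-identical sample is
    non-normal (W is undefined)."""
    d = np.asarray(deltas, dtype=float)
    if d.size < 3:
        raise ValueError("normality gate requires n >= 3 change scores")
    if np.ptp(d) == 0:
        return "non_normal"
    _, p = stats.shapiro(d)
    return "normal" if p >= NORMALITY_ALPHA else "non_normal"


def paired_t(deltas: Sequence[float], variable: str = "") -> PrePostResult:
    """Paired-sample two-tailed t test on the change scores.

    t = mean(Δ)/(sd(Δ)/√n), df = n−1; Cohen d = mean(Δ)/sd(Δ) (so d·√n = t
    exactly); 95% CI = mean ± t_crit·se.
    """
    d = np.asarray(deltas, dtype=float)
    n = d.size
    if n < 2:
        raise ValueError("paired t requires n >= 2")
    sd = float(np.std(d, ddof=1))
    if sd == 0:
        raise ValueError("paired t undefined for zero-variance change scores")
    mean = float(np.mean(d))
    se = sd / math.sqrt(n)
    t = mean / se
    df = n - 1
    p = 2 * stats.t.sf(abs(t), df)
    tcrit = stats.t.ppf(0.975, df)
    ci = (mean - tcrit * se, mean + tcrit * se)
    return PrePostResult(variable=variable, n=n, test="paired_t", statistic=float(t),
                         df=df, p_value=float(p), difference=mean, ci_95=ci,
                         effect_size=mean / sd, effect_size_type="cohen_d")


def wilcoxon_signed_rank(deltas: Sequence[float], variable: str = "",
                         pre: Sequence[float] | None = None,
                         post: Sequence[float] | None = None) -> PrePostResult:
    """Wilcoxon signed-rank test, tie-corrected normal approximation.

    Zero differences are dropped (Wilcoxon's original treatment); ties are
    mid-ranked with the variance correction.  Effect size r = |z|/√(2n) with
    N = 2n paired observations, n the original pair count.  The reported
    difference is median(post) − median(pre) when the raw windows are given,
    else the median of Δ.
    """
    d = np.asarray(deltas, dtype=float)
    n = d.size
    nz = d[d != 0]
    if nz.size == 0:
        raise ValueError("Wilcoxon undefined: all change scores are zero")
    if nz.size < 5:
        raise ValueError("Wilcoxon requires n >= 5 nonzero change scores")
    res = stats.wilcoxon(nz, zero_method="wilcox", correction=False,
                         method="approx", alternative="two-sided")
    z = float(res.zstatistic)
    if pre is not None and post is not None:
        diff = float(np.median(post) - np.median(pre))
    else:
        diff = float(np.median(d))
    r = abs(z) / math.sqrt(2 * n)
    return PrePostResult(variable=variable, n=n, test="wilcoxon", statistic=z,
                         df=None, p_value=float(res.pvalue), difference=diff,
                         ci_95=None, effect_size=r, effect_size_type="r")


def spearman_delta(x_deltas: Sequence[float], y_deltas: Sequence[float]
                   ) -> tuple[float, float]:
    """Spearman rank correlation between two sets of change scores."""
    x = np.asarray(x_deltas, dtype=float)
    y = np.asarray(y_deltas, dtype=float)
    if x.size != y.size or x.size < 5:
        raise ValueError("Spearman requires paired samples with n >= 5")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman undefined for a constant sample")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def analyze_variable(records: Sequence[PrePostRecord]) -> PrePostResult:
    """Route one variable's records through the gate to the right paired test."""
    if not records:
        raise ValueError("no records")
    variable = records[0].variable
    deltas = [r.delta for r in records]
    pre_means = [r.pre_mean for r in records]
    post_means = [r.post_mean for r in records]
    gate = normality_gate(deltas)
    if gate == "normal":
        return paired_t(deltas, variable=variable)
    return wilcoxon_signed_rank(deltas, variable=variable,
                                pre=pre_means, post=post_means)


_FOOTER = ("Exploratory single-arm pre-post comparison; no adjustment for "
           "multiple comparisons; not evidence of causal treatment effect.")


def build_report(records: Sequence[PrePostRecord]) -> pd.DataFrame:
    """Per-variable summary table.

    Mean-based rows report pre/post mean (SD), mean difference, t(df), p and
    Cohen d; median-based rows report pre/post median (IQR), median
    difference, z, p and r.  Deterministic under fixed input; the exploratory
    framing is attached as ``DataFrame.attrs['footer']``.
    """
    by_var: dict[str, list[PrePostRecord]] = {}
    for rec in records:
        by_var.setdefault(rec.variable, []).append(rec)
    rows = []
    for variable, recs in by_var.items():
        res = analyze_variable(recs)
        pre = np.array([r.pre_mean for r in recs])
        post = np.array([r.post_mean for r in recs])
        if res.test == "paired_t":
            rows.append({
                "variable": variable, "n": res.n, "test": "paired_t",
                "pre_summary": f"{pre.mean():.2f} ({pre.std(ddof=1):.2f})",
                "post_summary": f"{post.mean():.2f} ({post.std(ddof=1):.2f})",
                "difference": res.difference, "statistic": res.statistic,
                "df": res.df, "p_value": res.p_value,
                "ci_low": res.ci_95[0], "ci_high": res.ci_95[1],
                "effect_size": res.effect_size, "effect_size_type": "cohen_d",
            })
        else:
            q = np.percentile
            rows.append({
                "variable": variable, "n": res.n, "test": "wilcoxon",
                "pre_summary": f"{np.median(pre):.1f} ({q(pre, 25):.1f}-{q(pre, 75):.1f})",
                "post_summary": f"{np.median(post):.1f} ({q(post, 25):.1f}-{q(post, 75):.1f})",
                "difference": res.difference, "statistic": res.statistic,
                "df": None, "p_value": res.p_value,
                "ci_low": None, "ci_high": None,
                "effect_size": res.effect_size, "effect_size_type": "r",
            })
    report = pd.DataFrame(rows)
    report.attrs["footer"] = _FOOTER
    return report
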