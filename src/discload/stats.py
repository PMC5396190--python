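"""Statistical layer: group comparisons and the bin-wise correlation curve.

Runner groups are compared to the non-sport referent with two-sample
t-tests (Welch by default — the safer choice under unequal variances, with
the pooled test available) and percent differences relative to the
referent mean.  A group x gender interaction is tested with a two-way
type-II ANOVA.  The activity-intensity analysis correlates, bin by bin
across the 98 MAD bins, each subject's epochs-per-day count with their
nucleus T2-time, attaching Fisher-z 95% confidence intervals, and
identifies the peak intensity band: the maximal contiguous run of bins
whose CI excludes zero containing the strongest correlation.  No
multiple-testing correction is applied across bins by default (per-bin CIs
are reported as-is); Benjamini-Hochberg is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "GroupComparison",
    "CorrelationCurve",
    "group_ttest",
    "anova_group_gender",
    "interaction_p",
    "binwise_correlation",
    "peak_band",
    "band_jaccard",
    "percent_difference",
]

ALPHA = 0.05


@dataclass
class GroupComparison:
    group_ref: str
    group_other: str
    mean_ref: float
    mean_other: float
    percent_difference: float
    t_statistic: float
    p_value: float
    n_ref: int
    n_other: int
    alpha: float = ALPHA

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


@dataclass
class CorrelationCurve:
    """Per-bin Pearson r against the outcome, with Fisher-z 95% CIs."""

    bin_edges_g: np.ndarray  # n_bins + 1
    r: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_subjects: int
    defined: np.ndarray  # bool: bin had variance across subjects
    excludes_zero: np.ndarray  # bool: 95% CI excludes 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_low_g": self.bin_edges_g[:-1],
                "bin_high_g": self.bin_edges_g[1:],
                "r": self.r,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "n": self.n_subjects,
                "defined": self.defined,
                "ci_excludes_zero": self.excludes_zero,
            }
        )


def percent_difference(ref_mean: float, group_mean: float) -> float:
    """100 * (group - ref) / ref."""
    if ref_mean == 0:
        raise ValueError("referent mean is zero; percent difference undefined")
    return 100.0 * (group_mean - ref_mean) / ref_mean


def group_ttest(
    values_ref,
    values_group,
    group_ref: str = "no-sport",
    group_other: str = "group",
    welch: bool = True,
) -> GroupComparison:
    """Two-sample t-test of a group against the referent.

    Welch (unequal variances) by default; set ``welch=False`` for the
    pooled-variance test.  Two groups with zero variance and equal means
    get p = 1 by convention (no evidence of any difference).
    """
    a = np.asarray(values_ref, dtype=float)
    b = np.asarray(values_group, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            t, p = np.inf * np.sign(b.mean() - a.mean()), 0.0
    else:
        t, p = sps.ttest_ind(a, b, equal_var=not welch)
    return GroupComparison(
        group_ref=group_ref,
        group_other=group_other,
        mean_ref=float(a.mean()),
        mean_other=float(b.mean()),
        percent_difference=percent_difference(a.mean(), b.mean()),
        t_statistic=float(t),
        p_value=float(p),
        n_ref=int(a.size),
        n_other=int(b.size),
    )


def anova_group_gender(outcome, group, gender) -> pd.DataFrame:
    """Two-way type-II ANOVA of outcome on group, gender and their interaction.

    Returns the statsmodels ANOVA table with rows for ``C(group)``,
    ``C(gender)`` and ``C(group):C(gender)``; read the interaction p from
    the last of these.  Raises ``ValueError`` naming the first empty
    group x gender cell.
    """
    df = pd.DataFrame(
        {"outcome": np.asarray(outcome, dtype=float), "group": group, "gender": gender}
    )
    counts = df.groupby(["group", "gender"], observed=True).size()
    for g in df.group.unique():
        for s in df.gender.unique():
            if (g, s) not in counts.index:
                raise ValueError(f"empty design cell: group={g!r}, gender={s!r}")
    n_cells = df.group.nunique() * df.gender.nunique()
    if len(df) <= n_cells:
        raise ValueError(
            "saturated design: the interaction model leaves no residual "
            f"degrees of freedom ({len(df)} observations, {n_cells} cells)"
        )
    model = smf.ols("outcome ~ C(group) * C(gender)", data=df).fit()
    return sm.stats.anova_lm(model, typ=2)


def interaction_p(anova_table: pd.DataFrame) -> float:
    """Interaction p-value from an :func:`anova_group_gender` table."""
    return float(anova_table.loc["C(group):C(gender)", "PR(>F)"])


def _fisher_ci(r: np.ndarray, n: int, confidence: float = 0.95):
    z = np.arctanh(np.clip(r, -1.0 + 1e-15, 1.0 - 1e-15))
    half = sps.norm.ppf(0.5 + confidence / 2.0) / np.sqrt(n - 3)
    lo, hi = np.tanh(z - half), np.tanh(z + half)
    # a perfect correlation pins the matching interval endpoint at +/-1
    hi = np.where(r == 1.0, 1.0, hi)
    lo = np.where(r == -1.0, -1.0, lo)
    return lo, hi


def binwise_correlation(
    counts,
    outcome,
    bin_edges_g,
    method: str = "pearson",
    fdr: bool = False,
) -> CorrelationCurve:
    """Correlate each MAD bin's counts with the outcome across subjects.

    Parameters
    ----------
    counts
        (n_subjects, n_bins) per-subject histogram counts sharing
        ``bin_edges_g``.
    outcome
        Per-subject nucleus T2 (ms), length n_subjects.
    method
        'pearson' (default) or 'spearman' (ranks first, then the same
        machinery).
    fdr
        When True, additionally requires Benjamini-Hochberg-adjusted
        two-sided p < 0.05 for ``excludes_zero``.

    Bins with zero variance across subjects (e.g. all-zero counts) are
    flagged undefined, not reported as r = 0.
    """
    X = np.asarray(counts, dtype=float)
    y = np.asarray(outcome, dtype=float)
    edges = np.asarray(bin_edges_g, dtype=float)
    if X.ndim != 2 or X.shape[1] != edges.size - 1:
        raise ValueError(
            f"counts shape {X.shape} does not match {edges.size - 1} bins — "
            "histograms must share identical bin edges"
        )
    n = X.shape[0]
    if y.shape != (n,):
        raise ValueError("outcome length must match the number of subjects")
    if n < 4:
        raise ValueError("need >= 4 subjects for a Fisher-z confidence interval")

    if method == "spearman":
        X = sps.rankdata(X, axis=0)
        y = sps.rankdata(y)
    elif method != "pearson":
        raise ValueError("method must be 'pearson' or 'spearman'")

    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    defined = (sx > 0) & (sy > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc * yc[:, None]).sum(axis=0) / (sx * sy)
    r = np.where(defined, np.clip(r, -1.0, 1.0), np.nan)
    lo, hi = _fisher_ci(r, n)
    lo = np.where(defined, lo, np.nan)
    hi = np.where(defined, hi, np.nan)
    excludes = defined & ((lo > 0) | (hi < 0))

    if fdr:
        with np.errstate(divide="ignore", invalid="ignore"):
            t = r * np.sqrt((n - 2) / (1.0 - r**2))
        p = 2.0 * sps.t.sf(np.abs(t), n - 2)
        p = np.where(np.abs(r) == 1.0, 0.0, p)
        from statsmodels.stats.multitest import multipletests

        ok = defined
        reject = np.zeros_like(excludes)
        reject[ok] = multipletests(p[ok], alpha=ALPHA, method="fdr_bh")[0]
        excludes = excludes & reject

    return CorrelationCurve(
        bin_edges_g=edges,
        r=r,
        ci_low=lo,
        ci_high=hi,
        n_subjects=n,
        defined=defined,
        excludes_zero=excludes,
    )


def peak_band(curve: CorrelationCurve) -> tuple[int, int] | None:
    """Peak intensity band: half-open bin index range, or None if no bin's
    CI excludes zero.

    The band is the maximal contiguous run of CI-excluding-zero bins that
    contains the strongest |r| among such bins; ties break toward lower
    acceleration.
    """
    if not curve.defined.any():
        raise ValueError("curve has no defined bin")
    sig = np.nonzero(curve.excludes_zero)[0]
    if sig.size == 0:
        return None
    abs_r = np.where(curve.excludes_zero, np.abs(curve.r), -np.inf)
    best = int(np.argmax(abs_r))  # argmax takes the first (lowest-g) maximum
    lo = best
    while lo - 1 >= 0 and curve.excludes_zero[lo - 1]:
        lo -= 1
    hi = best
    while hi + 1 < curve.r.size and curve.excludes_zero[hi + 1]:
        hi += 1
    return (lo, hi + 1)


def band_jaccard(band_a: tuple[int, int], band_b: tuple[int, int]) -> float:
    """Jaccard overlap of two half-open bin ranges."""
    inter = max(0, min(band_a[1], band_b[1]) - max(band_a[0], band_b[0]))
    union = (band_a[1] - band_a[0]) + (band_b[1] - band_b[0]) - inter
    return inter / union if union else 0.0
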