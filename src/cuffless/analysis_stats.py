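"""Statistical characterization of the timing features.

Two families of analyses: distribution summaries per feature and protocol
state (sample mean/SD, Gaussian-kernel density estimate, Shapiro-Wilk
normality test), and feature-versus-SBP association (Pearson and Spearman
correlations with two-sided p-values, plus a robust straight-line fit under
Huber loss so single gross outliers cannot dominate the trend line).
Associations are computed on per-session medians by default, matching how
the features' global estimates are defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import DataError
from .features import FEATURE_NAMES, FeatureDataset, aggregate_medians

__all__ = ["DistributionSummary", "AssociationResult", "summarize_distribution",
           "correlate_feature_sbp", "analyze_dataset", "plot_distribution",
           "plot_association"]

#: Huber tuning constant: 95% efficiency at the Gaussian model.
HUBER_T = 1.345


@dataclass
class DistributionSummary:
    feature: str
    state: str
    n: int
    mean: float
    sd: float
    shapiro_w: float | None
    shapiro_p: float | None
    kde_grid: np.ndarray | None
    kde_density: np.ndarray | None
    flag: str | None = None


@dataclass
class AssociationResult:
    feature: str
    n: int
    r_pearson: float
    p_pearson: float
    r_spearman: float
    p_spearman: float
    huber_slope: float
    huber_intercept: float


def summarize_distribution(values: np.ndarray, feature: str = "",
                           state: str = "", kde_points: int = 256) -> DistributionSummary:
    """Sample statistics, Scott-bandwidth Gaussian KDE, and Shapiro-Wilk test.

    Degenerate samples (n < 3, or zero spread where the normality statistic
    is undefined) return a flagged summary without the Shapiro fields.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n == 0:
        raise DataError("empty sample")
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if n > 1 else 0.0
    shapiro_w = shapiro_p = None
    kde_grid = kde_density = None
    flag = None
    if n < 3:
        flag = "n<3: Shapiro-Wilk not computed"
    elif sd == 0.0:
        flag = "zero variance: Shapiro-Wilk undefined"
    else:
        w, p = stats.shapiro(values)
        shapiro_w, shapiro_p = float(w), float(p)
        kde = stats.gaussian_kde(values)  # Scott's rule bandwidth
        lo = values.min() - 3.0 * kde.factor * sd
        hi = values.max() + 3.0 * kde.factor * sd
        kde_grid = np.linspace(lo, hi, kde_points)
        kde_density = kde(kde_grid)
    return DistributionSummary(feature=feature, state=state, n=n, mean=mean, sd=sd,
                               shapiro_w=shapiro_w, shapiro_p=shapiro_p,
                               kde_grid=kde_grid, kde_density=kde_density, flag=flag)


def correlate_feature_sbp(x: np.ndarray, y: np.ndarray,
                          feature: str = "") -> AssociationResult:
    """Pearson/Spearman correlation of a feature with SBP plus a Huber line fit.

    Spearman uses average ranks on ties; p-values are the standard two-sided
    t transforms.  The Huber fit minimizes Huber loss with tuning constant
    1.345 times the robust residual scale.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise DataError("x and y must have equal length >= 3")
    if np.std(y) == 0.0:
        raise DataError("SBP values are constant; association undefined")
    rp, pp = stats.pearsonr(x, y)
    rs, ps = stats.spearmanr(x, y)
    rlm = sm.RLM(y, sm.add_constant(x), M=sm.robust.norms.HuberT(t=HUBER_T)).fit()
    intercept, slope = rlm.params
    return AssociationResult(feature=feature, n=len(x),
                             r_pearson=float(rp), p_pearson=float(pp),
                             r_spearman=float(rs), p_spearman=float(ps),
                             huber_slope=float(slope), huber_intercept=float(intercept))


def analyze_dataset(ds: FeatureDataset, per_cycle: bool = False
                    ) -> tuple[list[DistributionSummary], list[AssociationResult]]:
    """Distribution summaries per feature/state and associations versus SBP.

    By default both analyses run on per-(subject, state, repetition) medians;
    ``per_cycle=True`` switches to raw per-cycle values.
    """
    table = ds.to_frame() if per_cycle else aggregate_medians(ds)
    if table.empty:
        return [], []
    summaries = []
    for feature in FEATURE_NAMES:
        for state, group in table.groupby("state"):
            if len(group) >= 1:
                summaries.append(summarize_distribution(
                    group[feature].to_numpy(), feature=feature, state=str(state)))
    associations = [
        correlate_feature_sbp(table[feature].to_numpy(), table["sbp"].to_numpy(),
                              feature=feature)
        for feature in FEATURE_NAMES
    ]
    return summaries, associations


def associations_frame(associations: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(a) for a in associations])


def plot_distribution(summary: DistributionSummary, values: np.ndarray, path):
    """Histogram plus KDE curve for one feature/state (PNG side output)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3))
    ax.hist(values, bins="auto", density=True, alpha=0.5)
    if summary.kde_grid is not None:
        ax.plot(summary.kde_grid, summary.kde_density)
    title = f"{summary.feature} ({summary.state})"
    if summary.shapiro_w is not None:
        title += f"  S={summary.shapiro_w:.3f} p={summary.shapiro_p:.3g}"
    ax.set_title(title, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_association(x: np.ndarray, y: np.ndarray, assoc: AssociationResult, path):
    """Scatter of feature vs SBP with the robust fit line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3))
    ax.scatter(x, y, s=12, alpha=0.6)
    xs = np.linspace(min(x), max(x), 50)
    ax.plot(xs, assoc.huber_intercept + assoc.huber_slope * xs, "r-")
    ax.set_xlabel(assoc.feature)
    ax.set_ylabel("SBP (mmHg)")
    ax.set_title(f"rp={assoc.r_pearson:.2f} rs={assoc.r_spearman:.2f}", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
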