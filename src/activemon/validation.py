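"""Cross-sectional validation statistics.

Three surfaces, mirroring the validation design of a remote-monitoring
study:

* **test-retest reliability** — intraclass correlation between the first-
  and second-2-week interval medians (two-way random effects, absolute
  agreement, single measurement), with F-distribution confidence bounds;
* **convergent validity** — Pearson or Spearman correlation between
  interval-1 medians and the analogous in-clinic score;
* **known-groups validity** — age-adjusted, study-adjusted residuals
  (mixed linear model with a random intercept per study) compared across
  the five study/cohort groups with Kruskal-Wallis and all pairwise
  Mann-Whitney U tests.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import InsufficientDataError

logger = logging.getLogger(__name__)

#: Convergent-validity pairings: feature -> (clinical score, default method).
#: Pearson is used for the pairings whose in-clinic analog shares the same
#: pseudo-continuous scale; Spearman otherwise.
CONVERGENT_PAIRINGS = {
    "sdmt_correct": ("sdmt_clinic", "pearson"),
    "swr_correct": ("swr_clinic", "pearson"),
    "intertap_mean_ms": ("intertap_clinic_ms", "pearson"),
    "spiral_speed_cv": ("finger_taps", "spearman"),  # resolved per hand
    "sway_path:chorea": ("chorea", "spearman"),  # resolved per hand
    "sway_path:balance": ("balance_score", "spearman"),
    "turn_speed_median": ("tms", "spearman"),
    "step_freq_variance": ("tms", "spearman"),
}


# ---------------------------------------------------------------------------
# test-retest ICC
# ---------------------------------------------------------------------------

@dataclass
class IccResult:
    estimate: float
    ci_low: float
    ci_high: float
    n: int
    model: str = "two-way random, absolute agreement, single measurement"

    def __post_init__(self) -> None:
        if not self.ci_low <= self.estimate <= self.ci_high:
            raise ValueError("CI must bracket the estimate")


def test_retest_icc(
    interval1: Sequence[float],
    interval2: Sequence[float],
    alpha: float = 0.05,
) -> IccResult:
    """ICC(2,1) between paired interval medians with its F-based 95% CI.

    Pairs with a missing value in either interval must be dropped by the
    caller; NaNs here are dropped pairwise as a convenience.
    """
    x = np.asarray(interval1, dtype=float)
    y = np.asarray(interval2, dtype=float)
    if x.shape != y.shape:
        raise ValueError("intervals must be paired")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise InsufficientDataError(f"ICC needs >= 3 complete pairs, got {n}")

    data = np.column_stack([x, y])
    k = 2
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

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise InsufficientDataError("zero total variance: ICC undefined")
    icc = (msr - mse) / denom

    # McGraw & Wong CI for ICC(A,1) via Satterthwaite df.
    a = k * icc / (n * (1 - icc)) if icc < 1 else np.inf
    b = 1 + k * icc * (n - 1) / (n * (1 - icc)) if icc < 1 else np.inf
    if np.isfinite(a) and (a * msc + b * mse) > 0:
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
        ci_low = n * (msr - f_l * mse) / (
            f_l * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        ci_high = n * (f_u * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_u * msr
        )
    else:
        ci_low = ci_high = 1.0
    ci_low = min(ci_low, icc)
    ci_high = max(ci_high, icc)
    return IccResult(estimate=float(icc), ci_low=float(ci_low), ci_high=float(ci_high), n=n)


# ---------------------------------------------------------------------------
# convergent validity
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    method: str
    coefficient: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int


def _fisher_ci(r: float, n: int, method: str, alpha: float = 0.05) -> tuple[float, float]:
    """Fisher-z interval; Fieller variance approximation for Spearman."""
    if abs(r) >= 1.0:
        return r, r
    z = np.arctanh(r)
    se = np.sqrt(1.06 / (n - 3)) if method == "spearman" else np.sqrt(1.0 / (n - 3))
    zcrit = stats.norm.ppf(1 - alpha / 2)
    return float(np.tanh(z - zcrit * se)), float(np.tanh(z + zcrit * se))


def convergent_validity(
    feature_values: Sequence[float],
    clinical_scores: Sequence[float],
    method: str = "spearman",
    alpha: float = 0.05,
) -> CorrelationResult:
    """Correlation between interval-1 feature medians and a clinical score."""
    x = np.asarray(feature_values, dtype=float)
    y = np.asarray(clinical_scores, dtype=float)
    if x.shape != y.shape:
        raise ValueError("inputs must be paired")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 5:
        raise InsufficientDataError(f"correlation needs >= 5 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InsufficientDataError("constant input: correlation undefined")

    if method == "auto":
        normal = all(stats.shapiro(v).pvalue > 0.05 for v in (x, y))
        method = "pearson" if normal else "spearman"
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    ci_low, ci_high = _fisher_ci(float(r), n, method, alpha)
    return CorrelationResult(
        method=method,
        coefficient=float(r),
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=float(p),
        n=n,
    )


# ---------------------------------------------------------------------------
# known-groups validity
# ---------------------------------------------------------------------------

@dataclass
class KnownGroupsResult:
    groups: list[str]
    group_sizes: dict[str, int]
    kruskal_h: float
    kruskal_p: float
    pairwise: list[dict]  # {group_a, group_b, u, p}
    age_coefficient: float
    residuals: pd.DataFrame = field(repr=False, default_factory=pd.DataFrame)
    model: str = "mixed"


def age_study_residuals(
    df: pd.DataFrame, conditional: bool = False
) -> tuple[pd.Series, float, str]:
    """Residuals of value ~ age with a random intercept per study.

    By default the *marginal* residual (value minus the fixed-part
    prediction) is returned: the random study intercept regularizes the age
    coefficient but is not subtracted, so groups that coincide with a whole
    study keep their level differences — subtracting BLUPs would absorb
    exactly the between-group signal being tested and makes the downstream
    rank tests conservative. ``conditional=True`` subtracts the estimated
    (BLUP) study intercepts as well.

    Falls back to a fixed-intercept OLS when the mixed fit is degenerate
    (e.g., a single study).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    data = df.dropna(subset=["value", "age", "study"]).copy()
    n_studies = data["study"].nunique()
    if n_studies >= 2:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm("value ~ age", data, groups=data["study"])
                fit = model.fit(reml=True)
            beta0 = float(fit.fe_params["Intercept"])
            beta_age = float(fit.fe_params["age"])
            resid = data["value"] - beta0 - beta_age * data["age"]
            if conditional:
                re = {g: float(v.iloc[0]) for g, v in fit.random_effects.items()}
                resid = resid - data["study"].map(re).fillna(0.0)
            return resid, beta_age, "mixed"
        except (np.linalg.LinAlgError, ValueError) as exc:
            logger.warning("mixed model failed (%s); falling back to OLS", exc)
    X = sm.add_constant(data["age"].to_numpy())
    ols = sm.OLS(data["value"].to_numpy(), X).fit()
    resid = pd.Series(ols.resid, index=data.index)
    return resid, float(ols.params[1]), "ols"


def known_groups(df: pd.DataFrame, conditional: bool = False) -> KnownGroupsResult:
    """Known-groups comparison on age/study-adjusted residuals.

    Parameters
    ----------
    df : DataFrame
        Columns ``value``, ``age``, ``study``, ``group`` — one row per
        participant (interval-1 median of one feature).
    """
    required = {"value", "age", "study", "group"}
    if not required.issubset(df.columns):
        raise ValueError(f"data must have columns {sorted(required)}")
    data = df.dropna(subset=["value", "age", "study", "group"]).copy()
    groups = sorted(data["group"].unique())
    if len(groups) < 2:
        raise InsufficientDataError("need at least 2 nonempty groups")

    resid, beta_age, model_kind = age_study_residuals(data, conditional=conditional)
    data = data.loc[resid.index]
    data["resid"] = resid

    samples = [data.loc[data["group"] == g, "resid"].to_numpy() for g in groups]
    pooled = np.concatenate(samples)
    # residuals identical up to solver round-off: H is exactly 0
    scale = max(1.0, float(np.abs(data["value"]).max()))
    if np.ptp(pooled) <= 1e-10 * scale:
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*samples)

    pairwise = []
    for (ga, sa), (gb, sb) in itertools.combinations(zip(groups, samples), 2):
        u, up = stats.mannwhitneyu(sa, sb, alternative="two-sided")
        pairwise.append({"group_a": ga, "group_b": gb, "u": float(u), "p": float(up)})

    return KnownGroupsResult(
        groups=groups,
        group_sizes={g: int((data["group"] == g).sum()) for g in groups},
        kruskal_h=float(h),
        kruskal_p=float(p),
        pairwise=pairwise,
        age_coefficient=beta_age,
        residuals=data[["group", "resid"]],
        model=model_kind,
    )
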