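"""Group comparisons: normality gate, two-way ANOVA with Dunnett contrasts,
and the paired Wilcoxon signed-rank test.

The ANOVA itself is ordinary least squares (statsmodels); the Dunnett
many-to-one adjustment is the classical single-step multivariate-t procedure:
for treatment-vs-control t statistics sharing the ANOVA residual variance,
the joint distribution has the one-factor correlation structure
``corr(T_i, T_j) = lambda_i * lambda_j`` with
``lambda_i = sqrt(m_i / (m_i + m_0))`` (``m`` = observations per group), and
the adjusted p-value of contrast i is ``P(max_j |T_j| >= |t_i|)``. That tail
probability is evaluated by deterministic quadrature (Gauss-Hermite over the
shared normal factor, an equal-probability chi grid over the pooled scale),
so adjusted p-values are reproducible to ~1e-4 without Monte Carlo.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import stats as sps
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm

from .errors import ConfigurationError, DegenerateDataError, InsufficientDataError

__all__ = [
    "ComparisonResult",
    "normality_gate",
    "groupwise_anova_dunnett",
    "paired_wilcoxon",
    "dunnett_sf",
]

logger = logging.getLogger(__name__)

_HERM_NODES, _HERM_WEIGHTS = hermgauss(64)


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of one statistical comparison, with per-group contrasts."""

    test_name: str
    statistic: float
    df: tuple[float, float] | float | None
    p_value: float
    group_contrasts: tuple = ()
    table: pd.DataFrame | None = field(default=None, repr=False)


@dataclass(frozen=True)
class Contrast:
    """One treatment-vs-control contrast with raw and Dunnett-adjusted p."""

    group: str
    estimate: float
    statistic: float
    p_raw: float
    p_adjusted: float


def normality_gate(samples: dict[str, np.ndarray], alpha: float = 0.05) -> dict[str, bool]:
    """Shapiro-Wilk normality check per group at significance ``alpha``.

    Returns ``{group: passed}``; failures are logged as warnings and the
    caller proceeds (the gate informs, it does not abort). Groups with fewer
    than 3 observations raise :class:`InsufficientDataError`.
    """
    results = {}
    for group, values in samples.items():
        values = np.asarray(values, dtype=float)
        if len(values) < 3:
            raise InsufficientDataError(
                f"group {group!r} has {len(values)} < 3 observations"
            )
        _, p = sps.shapiro(values)
        passed = bool(p >= alpha)
        if not passed:
            logger.warning(
                "group %s fails Shapiro-Wilk normality (p=%.4g); proceeding", group, p
            )
        results[group] = passed
    return results


def dunnett_sf(t_value: float, df: float, lambdas, n_chi: int = 128) -> float:
    """Two-sided single-step Dunnett tail probability ``P(max_i |T_i| >= t)``.

    ``lambdas`` are the one-factor loadings ``sqrt(m_i/(m_i+m_0))`` of the
    treatment-vs-control t statistics; ``df`` is the shared residual degrees
    of freedom. Conditional on the control-group factor Z0 and the pooled
    scale S, the statistics are independent normals, so the orthant
    probability reduces to a two-dimensional integral evaluated on fixed
    quadrature grids.
    """
    t_value = abs(float(t_value))
    if t_value == 0.0:
        return 1.0
    lam = np.asarray(lambdas, dtype=float)
    comp = np.sqrt(np.clip(1.0 - lam**2, 1e-12, None))
    z = np.sqrt(2.0) * _HERM_NODES  # shared-factor nodes, N(0,1) weightings
    wz = _HERM_WEIGHTS / np.sqrt(np.pi)
    q = sps.chi2.ppf((np.arange(n_chi) + 0.5) / n_chi, df)
    s = np.sqrt(q / df)  # equal-probability chi(df)/sqrt(df) grid
    # inner product over contrasts: shape (n_chi, n_z, k)
    ts = t_value * s[:, None, None]
    lz = lam[None, None, :] * z[None, :, None]
    upper = (ts - lz) / comp[None, None, :]
    lower = (-ts - lz) / comp[None, None, :]
    probs = np.prod(sps.norm.cdf(upper) - sps.norm.cdf(lower), axis=2)
    cdf = float(np.mean(probs @ wz))
    return float(np.clip(1.0 - cdf, 0.0, 1.0))


def groupwise_anova_dunnett(
    data: pd.DataFrame,
    control: str,
    value: str = "value",
    group: str = "group",
    time: str | None = "time",
) -> ComparisonResult:
    """Two-way (group x time) ANOVA with Dunnett-adjusted contrasts vs control.

    ``data`` holds one row per observation. When the time factor is absent or
    constant a one-way ANOVA is fitted instead. The reported F and p are the
    group main effect; each treatment group's contrast against ``control``
    uses the marginal group means with the ANOVA residual variance, and the
    Dunnett adjustment is the multivariate-t single-step procedure. An effect
    with zero sum of squares (identical groups) reports F = 0.
    """
    if control not in set(data[group]):
        raise ConfigurationError(f"control group {control!r} not present in data")
    groups = list(dict.fromkeys(data[group]))
    if len(groups) < 2:
        raise ConfigurationError("need at least 2 groups")
    df = data.rename(columns={value: "_y", group: "_g"}).copy()
    has_time = time is not None and time in data.columns and data[time].nunique() > 1
    if np.ptp(df["_y"].to_numpy(dtype=float)) == 0.0:
        # identical observations everywhere: every effect has zero sum of squares
        k_groups = len(groups)
        n_obs = len(df)
        return ComparisonResult(
            test_name="two-way ANOVA (Dunnett vs control)" if has_time
            else "one-way ANOVA (Dunnett vs control)",
            statistic=0.0,
            df=(float(k_groups - 1), float(n_obs - k_groups)),
            p_value=1.0,
            group_contrasts=tuple(
                Contrast(group=g, estimate=0.0, statistic=0.0, p_raw=1.0, p_adjusted=1.0)
                for g in groups
                if g != control
            ),
        )
    if has_time:
        df["_t"] = data[time].to_numpy()
        model = ols("_y ~ C(_g) + C(_t) + C(_g):C(_t)", data=df).fit()
    else:
        model = ols("_y ~ C(_g)", data=df).fit()
    with np.errstate(divide="ignore", invalid="ignore"):
        table = anova_lm(model, typ=2)
    resid_df = float(model.df_resid)
    mse = float(model.mse_resid)
    row = table.loc["C(_g)"]
    f_stat = float(row["F"])
    p_f = float(row["PR(>F)"])
    if row["sum_sq"] == 0.0 or not np.isfinite(f_stat):
        f_stat, p_f = (0.0, 1.0) if row["sum_sq"] == 0.0 else (f_stat, p_f)
    df_pair = (float(row["df"]), resid_df)

    counts = df.groupby("_g")["_y"].count()
    means = df.groupby("_g")["_y"].mean()
    m0 = float(counts[control])
    treatments = [g for g in groups if g != control]
    lambdas = np.array([np.sqrt(counts[g] / (counts[g] + m0)) for g in treatments])
    contrasts = []
    tstats = []
    for g in treatments:
        est = float(means[g] - means[control])
        se = np.sqrt(mse * (1.0 / counts[g] + 1.0 / m0))
        tstats.append(est / se if se > 0 else 0.0)
        contrasts.append((g, est))
    out = []
    for (g, est), tv in zip(contrasts, tstats):
        p_raw = float(2.0 * sps.t.sf(abs(tv), resid_df)) if resid_df > 0 else 1.0
        p_adj = dunnett_sf(tv, resid_df, lambdas)
        out.append(
            Contrast(
                group=g, estimate=est, statistic=float(tv),
                p_raw=p_raw, p_adjusted=max(p_adj, p_raw),
            )
        )
    return ComparisonResult(
        test_name="two-way ANOVA (Dunnett vs control)" if has_time
        else "one-way ANOVA (Dunnett vs control)",
        statistic=f_stat,
        df=df_pair,
        p_value=p_f,
        group_contrasts=tuple(out),
        table=table,
    )


def paired_wilcoxon(pre, post) -> ComparisonResult:
    """Two-sided Wilcoxon matched-pairs signed-rank test on post - pre.

    Uses the exact null distribution for n <= 25 (no ties/zeros), so with n=8
    one-signed differences the smallest attainable two-sided p is
    2/2^8 = 0.0078125. Requires n >= 5 pairs; all-zero differences are a
    degenerate-data error.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must have equal length")
    n = len(pre)
    if n < 5:
        raise InsufficientDataError(f"need at least 5 pairs, got {n}")
    diffs = post - pre
    if np.all(diffs == 0):
        raise DegenerateDataError("all paired differences are zero")
    method = "exact" if n <= 25 and not np.any(diffs == 0) else "auto"
    res = sps.wilcoxon(post, pre, alternative="two-sided", method=method)
    return ComparisonResult(
        test_name="Wilcoxon signed-rank (paired, two-sided)",
        statistic=float(res.statistic),
        df=None,
        p_value=float(res.pvalue),
    )
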