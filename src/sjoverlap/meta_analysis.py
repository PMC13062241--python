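"""Familial-aggregation meta-analysis of relative risks.

Study-level relative risks (RR) compare the probability of having an affected
first-degree relative between probands with a given autoimmune disease ("cases")
and probands without it ("controls"):

    RR = (a / (a + c)) / (b / (b + d))

with ``a``/``c`` the case counts with/without affected relatives and ``b``/``d``
the corresponding control counts.  Pooling is inverse-variance on the log-RR
scale, either common-effect or random-effects with the DerSimonian-Laird
between-study variance, with Cochran's Q, I² and τ² heterogeneity statistics
and Egger / Begg small-study (publication-bias) tests.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


class MetaAnalysisError(ValueError):
    """Raised for degenerate meta-analysis inputs (zero cells, too few studies)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StudyCounts:
    """2x2 familial-aggregation counts for one study.

    a: cases (probands with the index disease) having >=1 affected FDR
    b: controls having >=1 affected FDR
    c: cases without affected FDRs
    d: controls without affected FDRs
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise MetaAnalysisError("counts must be non-negative")
        if self.a + self.c == 0 or self.b + self.d == 0:
            raise MetaAnalysisError("empty case or control group")


@dataclass(frozen=True)
class EffectEstimate:
    """One study's log relative risk and its standard error."""

    study_label: str
    log_rr: float
    se: float
    rr: float = field(default=math.nan)
    ci_low: float = field(default=math.nan)
    ci_high: float = field(default=math.nan)

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise MetaAnalysisError(f"se must be positive, got {self.se}")
        if math.isnan(self.rr):
            object.__setattr__(self, "rr", math.exp(self.log_rr))
        if math.isnan(self.ci_low) or math.isnan(self.ci_high):
            lo, hi = ci_from_effect(self.log_rr, self.se)
            object.__setattr__(self, "ci_low", lo)
            object.__setattr__(self, "ci_high", hi)


@dataclass(frozen=True)
class PooledResult:
    """Pooled effect with heterogeneity statistics.

    ``q``, ``df``, ``i2`` and ``tau2`` always come from the fixed-weight stage,
    so the random-effects result reports the same heterogeneity as the
    common-effect one.  ``i2`` is a percentage in [0, 100].
    """

    model: str  # "common" | "random"
    pooled_log_rr: float
    pooled_se: float
    pooled_rr: float
    ci_low: float
    ci_high: float
    q: float
    df: int
    i2: float
    tau2: float
    weights: np.ndarray

    @property
    def p_q(self) -> float:
        """P-value of Cochran's Q against chi-square with ``df`` dof."""
        return float(stats.chi2.sf(self.q, self.df)) if self.df > 0 else math.nan


@dataclass(frozen=True)
class BiasTestResult:
    method: str  # "egger" | "begg"
    statistic: float
    p_value: float
    se: float = math.nan  # Egger intercept SE only


@dataclass(frozen=True)
class SubgroupResult:
    groups: dict[str, PooledResult | EffectEstimate]
    q_between: float
    df_between: int
    p_between: float


# ---------------------------------------------------------------------------
# Study-level effects
# ---------------------------------------------------------------------------


def rr_from_counts(
    counts: StudyCounts,
    study_label: str = "",
    continuity_correction: bool = False,
) -> EffectEstimate:
    """Relative risk RR = (a/(a+c)) / (b/(b+d)) with delta-method SE of log RR.

    Zero ``a`` or ``b`` cells make the RR (or its log) undefined; such studies
    are rejected by default — mirroring the exclusion of zero-proband studies
    from the pooled analyses — unless ``continuity_correction`` adds 0.5 to
    every cell.
    """
    a, b, c, d = counts.a, counts.b, counts.c, counts.d
    if a == 0 or b == 0:
        if not continuity_correction:
            raise MetaAnalysisError(
                "zero-cell: RR undefined for a=0 or b=0 (enable continuity_correction to pool anyway)"
            )
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    rr = (a / (a + c)) / (b / (b + d))
    se = math.sqrt(1 / a - 1 / (a + c) + 1 / b - 1 / (b + d))
    return EffectEstimate(study_label=study_label, log_rr=math.log(rr), se=se)


def ci_from_effect(log_rr: float, se: float, level: float = 0.95) -> tuple[float, float]:
    """Wald confidence bounds on the RR scale: exp(logRR ± z·SE)."""
    if not se > 0:
        raise MetaAnalysisError("se must be positive")
    if not 0 < level < 1:
        raise MetaAnalysisError("level must be in (0, 1)")
    z = stats.norm.ppf(0.5 + level / 2)
    return math.exp(log_rr - z * se), math.exp(log_rr + z * se)


# ---------------------------------------------------------------------------
# Pooling
# ---------------------------------------------------------------------------


def _check_estimates(estimates: Sequence[EffectEstimate], minimum: int = 2) -> None:
    if len(estimates) < minimum:
        raise MetaAnalysisError(f"insufficient studies: need >= {minimum}, got {len(estimates)}")


def _heterogeneity(theta: np.ndarray, w: np.ndarray) -> tuple[float, int, float, float]:
    """Cochran's Q, dof, I² (%) and DL τ² from fixed-effect weights."""
    mu = float(np.sum(w * theta) / np.sum(w))
    q = float(np.sum(w * (theta - mu) ** 2))
    df = len(theta) - 1
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (q - df) / denom) if denom > 0 else 0.0
    return q, df, i2, tau2


def pool_fixed(estimates: Sequence[EffectEstimate]) -> PooledResult:
    """Common-effect (inverse-variance) pooled log RR."""
    _check_estimates(estimates)
    theta = np.array([e.log_rr for e in estimates])
    se = np.array([e.se for e in estimates])
    w = 1.0 / se**2
    mu = float(np.sum(w * theta) / np.sum(w))
    pooled_se = float(np.sqrt(1.0 / np.sum(w)))
    q, df, i2, tau2 = _heterogeneity(theta, w)
    lo, hi = ci_from_effect(mu, pooled_se)
    return PooledResult(
        model="common",
        pooled_log_rr=mu,
        pooled_se=pooled_se,
        pooled_rr=math.exp(mu),
        ci_low=lo,
        ci_high=hi,
        q=q,
        df=df,
        i2=i2,
        tau2=tau2,
        weights=w,
    )


def pool_random_dl(estimates: Sequence[EffectEstimate]) -> PooledResult:
    """Random-effects pooled log RR with DerSimonian-Laird τ².

    τ² = max(0, (Q − df) / (Σw − Σw²/Σw)) from the fixed-effect weights
    w = 1/SE²; the pooled estimate then uses w* = 1/(SE² + τ²).  Q, df, I² and
    τ² are reported from the fixed-weight stage.
    """
    _check_estimates(estimates)
    theta = np.array([e.log_rr for e in estimates])
    se = np.array([e.se for e in estimates])
    w_fixed = 1.0 / se**2
    q, df, i2, tau2 = _heterogeneity(theta, w_fixed)
    w = 1.0 / (se**2 + tau2)
    mu = float(np.sum(w * theta) / np.sum(w))
    pooled_se = float(np.sqrt(1.0 / np.sum(w)))
    lo, hi = ci_from_effect(mu, pooled_se)
    return PooledResult(
        model="random",
        pooled_log_rr=mu,
        pooled_se=pooled_se,
        pooled_rr=math.exp(mu),
        ci_low=lo,
        ci_high=hi,
        q=q,
        df=df,
        i2=i2,
        tau2=tau2,
        weights=w,
    )


def subgroup_pool(
    estimates: Sequence[EffectEstimate], group_labels: Sequence[str]
) -> SubgroupResult:
    """Random-effects pooling within groups plus a between-group Q test.

    Groups of size one are reported as their single (unpooled) estimate and
    still contribute to the between-group comparison with weight 1/SE².
    """
    if len(estimates) != len(group_labels):
        raise MetaAnalysisError("every estimate needs a group label")
    order = list(dict.fromkeys(group_labels))
    groups: dict[str, PooledResult | EffectEstimate] = {}
    g_theta, g_se = [], []
    for g in order:
        members = [e for e, lab in zip(estimates, group_labels) if lab == g]
        if len(members) == 1:
            groups[g] = members[0]
            g_theta.append(members[0].log_rr)
            g_se.append(members[0].se)
        else:
            pooled = pool_random_dl(members)
            groups[g] = pooled
            g_theta.append(pooled.pooled_log_rr)
            g_se.append(pooled.pooled_se)
    if not any(isinstance(v, PooledResult) for v in groups.values()):
        raise MetaAnalysisError("need at least one group with >= 2 studies")
    gt = np.array(g_theta)
    gw = 1.0 / np.array(g_se) ** 2
    overall = float(np.sum(gw * gt) / np.sum(gw))
    q_between = float(np.sum(gw * (gt - overall) ** 2))
    df_between = len(order) - 1
    p_between = float(stats.chi2.sf(q_between, df_between)) if df_between > 0 else math.nan
    return SubgroupResult(groups=groups, q_between=q_between, df_between=df_between, p_between=p_between)


# ---------------------------------------------------------------------------
# Publication-bias and agreement statistics
# ---------------------------------------------------------------------------


def egger_test(estimates: Sequence[EffectEstimate]) -> BiasTestResult:
    """Egger regression asymmetry test.

    Ordinary least squares of the standardized effect θ/SE on precision 1/SE;
    the intercept measures funnel-plot asymmetry and is tested against a
    t distribution with n − 2 degrees of freedom.
    """
    _check_estimates(estimates, minimum=3)
    theta = np.array([e.log_rr for e in estimates])
    se = np.array([e.se for e in estimates])
    y = theta / se
    x = 1.0 / se
    n = len(y)
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        warnings.warn("degenerate Egger regression: identical studies", stacklevel=2)
        return BiasTestResult(method="egger", statistic=0.0, p_value=1.0, se=math.nan)
    import statsmodels.api as sm

    fit = sm.OLS(y, sm.add_constant(x)).fit()
    intercept = float(fit.params[0])
    se_int = float(fit.bse[0])
    t_stat = intercept / se_int if se_int > 0 else 0.0
    p = float(2 * stats.t.sf(abs(t_stat), n - 2))
    return BiasTestResult(method="egger", statistic=intercept, p_value=min(p, 1.0), se=se_int)


def begg_test(estimates: Sequence[EffectEstimate]) -> BiasTestResult:
    """Begg-Mazumdar rank correlation test.

    Kendall's τ-b between the variance-standardized deviations from the
    common-effect pooled value, (θ − θ̂)/sqrt(SE² − SE_pooled²), and the study
    variances, with the normal-approximation two-sided p-value.
    """
    _check_estimates(estimates, minimum=3)
    pooled = pool_fixed(estimates)
    theta = np.array([e.log_rr for e in estimates])
    var = np.array([e.se for e in estimates]) ** 2
    vstar = np.maximum(var - pooled.pooled_se**2, 1e-12)
    dev = (theta - pooled.pooled_log_rr) / np.sqrt(vstar)
    tau, p = stats.kendalltau(dev, var)
    if math.isnan(tau):  # constant input on either side
        tau, p = 0.0, 1.0
    return BiasTestResult(method="begg", statistic=float(tau), p_value=float(p))


def cohens_kappa(ratings1: Sequence, ratings2: Sequence) -> float:
    """Cohen's κ chance-corrected agreement between two raters.

    κ = (p_o − p_e)/(1 − p_e).  When both raters are constant and identical
    p_e = 1 and κ is defined as 1 (perfect, if trivial, agreement).
    """
    if len(ratings1) != len(ratings2) or len(ratings1) == 0:
        raise MetaAnalysisError("ratings must be equal-length and non-empty")
    r1 = pd.Categorical(ratings1)
    cats = sorted(set(r1.categories) | set(pd.Categorical(ratings2).categories))
    c1 = pd.Categorical(ratings1, categories=cats).codes
    c2 = pd.Categorical(ratings2, categories=cats).codes
    n = len(c1)
    p_o = float(np.mean(c1 == c2))
    p_e = 0.0
    for k in range(len(cats)):
        p_e += (np.sum(c1 == k) / n) * (np.sum(c2 == k) / n)
    if p_e >= 1.0:
        return 1.0
    return (p_o - p_e) / (1.0 - p_e)


# ---------------------------------------------------------------------------
# Forest-table serialization
# ---------------------------------------------------------------------------


def forest_table(
    estimates: Sequence[EffectEstimate],
    pooled_common: PooledResult,
    pooled_random: PooledResult,
) -> pd.DataFrame:
    """Tabular forest-plot content: one row per study plus the two pooled rows.

    Per-study weight columns are percentages that sum to 100 under each model.
    Heterogeneity (Q, df, p_Q, I², τ²) is attached as DataFrame ``attrs``.
    """
    wc = pooled_common.weights / pooled_common.weights.sum() * 100.0
    wr = pooled_random.weights / pooled_random.weights.sum() * 100.0
    rows = []
    for e, pc, pr in zip(estimates, wc, wr):
        rows.append(
            {
                "label": e.study_label,
                "rr": e.rr,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "weight_common_pct": pc,
                "weight_random_pct": pr,
            }
        )
    for pooled in (pooled_common, pooled_random):
        rows.append(
            {
                "label": f"Pooled ({pooled.model})",
                "rr": pooled.pooled_rr,
                "ci_low": pooled.ci_low,
                "ci_high": pooled.ci_high,
                "weight_common_pct": math.nan,
                "weight_random_pct": math.nan,
            }
        )
    table = pd.DataFrame(rows)
    table.attrs["heterogeneity"] = {
        "q": pooled_common.q,
        "df": pooled_common.df,
        "p_q": pooled_common.p_q,
        "i2": pooled_common.i2,
        "tau2": pooled_common.tau2,
    }
    return table


# ---------------------------------------------------------------------------
# Packaged fixture access
# ---------------------------------------------------------------------------


def load_familial_fixture(path: str | None = None) -> pd.DataFrame:
    """Study table of published familial relative risks (one row per estimate)."""
    if path is None:
        with resources.files("sjoverlap.data").joinpath("familial_studies.tsv").open() as fh:
            return pd.read_csv(fh, sep="\t")
    return pd.read_csv(path, sep="\t")


def load_poolings(path: str | None = None) -> dict:
    """Named study groupings (which studies enter which pooled estimate)."""
    if path is None:
        text = resources.files("sjoverlap.data").joinpath("poolings.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    return yaml.safe_load(text)["poolings"]


def estimates_for_pooling(
    fixture: pd.DataFrame, pooling: dict
) -> list[EffectEstimate]:
    """Select the fixture rows for one named grouping, in listed study order."""
    sel = fixture[
        (fixture.proband_disease == pooling["proband_disease"])
        & (fixture.fdr_disease == pooling["fdr_disease"])
        & (fixture.relative_class == pooling["relative_class"])
    ]
    out = []
    for label in pooling["studies"]:
        row = sel[sel.study_label == label]
        if len(row) != 1:
            raise MetaAnalysisError(f"pooling references unknown or ambiguous study {label!r}")
        r = row.iloc[0]
        out.append(EffectEstimate(study_label=label, log_rr=float(r.log_rr), se=float(r.se)))
    return out


def pool_grouping(grouping: str, model: str = "random") -> PooledResult:
    """Pool one named grouping from the packaged fixture."""
    fixture = load_familial_fixture()
    poolings = load_poolings()
    if grouping not in poolings:
        raise MetaAnalysisError(f"unknown grouping {grouping!r}; have {sorted(poolings)}")
    estimates = estimates_for_pooling(fixture, poolings[grouping])
    if model == "random":
        return pool_random_dl(estimates)
    if model == "common":
        return pool_fixed(estimates)
    raise MetaAnalysisError(f"unknown model {model!r}")
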