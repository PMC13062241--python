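"""LD score regression: SNP heritability and cross-trait genetic correlation.

Under a polygenic model, the expected association chi-square of variant j grows
linearly in its LD score ℓ_j (the amount of genome it tags):

    E[chi²_j] = N h² ℓ_j / M + intercept

so the slope of a weighted regression of chi² on ℓ estimates h² (after scaling
by M/N) and the intercept captures confounding / miscalibration.  The
bivariate analogue regresses z1·z2 on ℓ:

    E[z1_j z2_j] = sqrt(N1 N2) ρg ℓ_j / M + ρs Ns / sqrt(N1 N2)

whose slope estimates the genetic covariance ρg while the intercept absorbs
sample-overlap correlation; the genetic correlation is rg = ρg / sqrt(h1² h2²).
Standard errors come from a contiguous block jackknife (200 blocks by
default).  LD scores are supplied, not computed: reference-panel LD estimation
is out of scope.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .locus_architecture import HLA_REGION
from .sumstats_io import AlignedPair, SumStats, align_pair

DEFAULT_N_BLOCKS = 200
MIN_REGRESSION_SNPS = 200


class LdscError(ValueError):
    pass


@dataclass
class LdscInputs:
    """Per-variant LD scores plus the regression constants.

    ldscores: DataFrame with chrom, pos, ldscore (>= 0)
    m: total number of SNPs the LD scores were computed over (>= #regression SNPs)
    """

    ldscores: pd.DataFrame
    m: int

    def __post_init__(self) -> None:
        need = {"chrom", "pos", "ldscore"}
        if not need <= set(self.ldscores.columns):
            raise LdscError(f"LD score table needs columns {sorted(need)}")
        if (self.ldscores.ldscore < 0).any():
            raise LdscError("negative LD scores")
        self.ldscores = self.ldscores.assign(chrom=self.ldscores.chrom.astype(str))

    def match(self, frame: pd.DataFrame) -> np.ndarray:
        """LD scores for the variants of ``frame`` (chrom, pos), order preserved."""
        merged = frame[["chrom", "pos"]].merge(
            self.ldscores, on=["chrom", "pos"], how="left", validate="many_to_one"
        )
        if merged.ldscore.isna().any():
            raise LdscError(f"{int(merged.ldscore.isna().sum())} variants lack LD scores")
        return merged.ldscore.to_numpy()


@dataclass
class LdscFit:
    """Result of one LD score regression."""

    kind: str  # "h2" | "gencov"
    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    value: float  # h2 (univariate) or genetic covariance rho_g (bivariate)
    value_se: float
    n_variants: int
    rg: float = math.nan
    rg_se: float = math.nan
    p_rg: float = math.nan
    flagged: str = ""

    @property
    def h2_reported(self) -> float:
        """h² clipped to [0, 1] for reporting; the raw value stays in ``value``."""
        return float(np.clip(self.value, 0.0, 1.0))

    @property
    def neg_log10_p(self) -> float:
        return -math.log10(self.p_rg) if 0 < self.p_rg <= 1 else math.inf


# ---------------------------------------------------------------------------
# Weighted regression with block jackknife
# ---------------------------------------------------------------------------


def _wls_beta(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    X = np.column_stack([x, np.ones_like(x)])
    A = (X * w[:, None]).T @ X
    c = (X * w[:, None]).T @ y
    return np.linalg.solve(A, c)


def _wls_jackknife(
    x: np.ndarray, y: np.ndarray, w: np.ndarray, n_blocks: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Full (slope, intercept) plus delete-one-block estimates and their SEs."""
    n = len(x)
    n_blocks = min(n_blocks, n)
    X = np.column_stack([x, np.ones_like(x)])
    XtWX = np.zeros((n_blocks, 2, 2))
    XtWy = np.zeros((n_blocks, 2))
    bounds = np.linspace(0, n, n_blocks + 1).astype(int)
    for b in range(n_blocks):
        s = slice(bounds[b], bounds[b + 1])
        Xb, wb = X[s], w[s]
        XtWX[b] = (Xb * wb[:, None]).T @ Xb
        XtWy[b] = (Xb * wb[:, None]).T @ y[s]
    A, c = XtWX.sum(axis=0), XtWy.sum(axis=0)
    beta = np.linalg.solve(A, c)
    deletes = np.stack([np.linalg.solve(A - XtWX[b], c - XtWy[b]) for b in range(n_blocks)])
    se = np.sqrt((n_blocks - 1) / n_blocks * ((deletes - deletes.mean(0)) ** 2).sum(0))
    return beta, deletes, se


def _h2_weights(ell: np.ndarray, n: float, m: int, h2: float) -> np.ndarray:
    h2 = float(np.clip(h2, 0.0, 1.0))
    return 1.0 / (1.0 + n * h2 * ell / m) ** 2


# ---------------------------------------------------------------------------
# Fits
# ---------------------------------------------------------------------------


def _hla_filter(frame: pd.DataFrame, region=HLA_REGION) -> np.ndarray:
    chrom, start, end = region
    inside = (frame.chrom.astype(str) == chrom) & (frame.pos >= start) & (frame.pos < end)
    return ~inside.to_numpy()


def fit_h2(
    z: np.ndarray,
    n: float,
    ld: LdscInputs,
    variant_frame: pd.DataFrame,
    exclude_hla: bool = True,
    n_blocks: int = DEFAULT_N_BLOCKS,
) -> LdscFit:
    """SNP heritability from the regression of chi² = z² on the LD score.

    Heteroskedasticity-motivated weights 1/(1 + N h² ℓ/M)² are iterated twice
    from an unweighted first pass; SEs are contiguous-block jackknife.
    ``variant_frame`` supplies (chrom, pos) for LD-score matching, genomic
    ordering and the optional HLA exclusion (chr6:25-34 Mb).
    """
    z = np.asarray(z, dtype=float)
    ell = ld.match(variant_frame)
    keep = np.isfinite(z)
    if exclude_hla:
        keep &= _hla_filter(variant_frame)
    z, ell = z[keep], ell[keep]
    if len(z) < MIN_REGRESSION_SNPS:
        raise LdscError(f"too few regression variants ({len(z)})")
    if np.ptp(ell) == 0:
        raise LdscError("no LD-score variation")
    chi2 = z**2
    beta = _wls_beta(ell, chi2, np.ones_like(ell))
    for _ in range(2):
        h2_cur = beta[0] * ld.m / n
        w = _h2_weights(ell, n, ld.m, h2_cur)
        beta = _wls_beta(ell, chi2, w)
    beta, _, se = _wls_jackknife(ell, chi2, w, n_blocks)
    h2 = beta[0] * ld.m / n
    return LdscFit(
        kind="h2",
        slope=float(beta[0]),
        intercept=float(beta[1]),
        slope_se=float(se[0]),
        intercept_se=float(se[1]),
        value=float(h2),
        value_se=float(se[0] * ld.m / n),
        n_variants=len(z),
    )


def fit_rg(
    pair: AlignedPair,
    n1: float,
    n2: float,
    ld: LdscInputs,
    exclude_hla: bool = True,
    n_blocks: int = DEFAULT_N_BLOCKS,
) -> LdscFit:
    """Genetic covariance and correlation from the regression of z1·z2 on ℓ.

    The intercept absorbs sample-overlap-induced cross-trait error correlation
    (shared controls), so it is never constrained.  rg and its jackknife SE are
    formed per delete-block from the three slopes (cov, h1², h2²), making the
    SE account for correlated estimation noise in numerator and denominator.
    """
    frame = pair.variants
    ell = ld.match(frame)
    keep = np.isfinite(pair.z1) & np.isfinite(pair.z2)
    if exclude_hla:
        keep &= _hla_filter(frame)
    z1, z2, ell = pair.z1[keep], pair.z2[keep], ell[keep]
    if len(z1) < MIN_REGRESSION_SNPS:
        raise LdscError(f"too few regression variants ({len(z1)})")
    if np.ptp(ell) == 0:
        raise LdscError("no LD-score variation")
    m = ld.m

    # univariate fits on the same variant set and blocks
    def _h2_fit(z, n):
        chi2 = z**2
        beta = _wls_beta(ell, chi2, np.ones_like(ell))
        for _ in range(2):
            w = _h2_weights(ell, n, m, beta[0] * m / n)
            beta = _wls_beta(ell, chi2, w)
        return w, _wls_jackknife(ell, chi2, w, n_blocks)

    w1, (b1, d1, se1) = _h2_fit(z1, n1)
    w2, (b2, d2, se2) = _h2_fit(z2, n2)
    h1, h2 = b1[0] * m / n1, b2[0] * m / n2

    y = z1 * z2
    scale = math.sqrt(n1 * n2) / m
    beta = _wls_beta(ell, y, np.ones_like(ell))
    for _ in range(2):
        mean_y = beta[0] * ell + beta[1]
        het1 = 1.0 + n1 * max(h1, 0.0) * ell / m
        het2 = 1.0 + n2 * max(h2, 0.0) * ell / m
        w = 1.0 / (het1 * het2 + mean_y**2)
        beta = _wls_beta(ell, y, w)
    beta, dg, seg = _wls_jackknife(ell, y, w, n_blocks)
    rho_g = beta[0] / scale

    fit = LdscFit(
        kind="gencov",
        slope=float(beta[0]),
        intercept=float(beta[1]),
        slope_se=float(seg[0]),
        intercept_se=float(seg[1]),
        value=float(rho_g),
        value_se=float(seg[0] / scale),
        n_variants=len(z1),
    )
    if h1 <= 0 or h2 <= 0:
        fit.flagged = "non-positive heritability; rg undefined"
        return fit
    rg = rho_g / math.sqrt(h1 * h2)
    if abs(rg) > 1:
        warnings.warn(f"rg outside [-1, 1]: {rg:.3f}", stacklevel=2)
    # per-block rg from the three delete-block slopes
    h1_d = np.maximum(d1[:, 0] * m / n1, 1e-12)
    h2_d = np.maximum(d2[:, 0] * m / n2, 1e-12)
    rg_d = (dg[:, 0] / scale) / np.sqrt(h1_d * h2_d)
    nb = len(rg_d)
    rg_se = math.sqrt((nb - 1) / nb * float(((rg_d - rg_d.mean()) ** 2).sum()))
    p = float(2 * stats.norm.sf(abs(rg) / rg_se)) if rg_se > 0 else 0.0
    fit.rg, fit.rg_se, fit.p_rg = float(rg), rg_se, p
    return fit


def significance_stars(p: float) -> str:
    if not 0 <= p <= 1:
        return ""
    return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""


def rg_matrix(
    sumstats: list[SumStats],
    sample_sizes: dict[str, float],
    ld: LdscInputs,
    exclude_hla: bool = True,
    n_blocks: int = DEFAULT_N_BLOCKS,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """All-pairs genetic-correlation matrix with −log10(P) and stars.

    Returns (rg, neg_log10_p, stars) square DataFrames; the diagonal is the
    rg = 1 self-comparison convention.  A pair whose alignment or fit fails is
    left missing and the run continues.
    """
    if len(sumstats) < 2:
        raise LdscError("need >= 2 diseases")
    labels = [s.disease_label for s in sumstats]
    rg = pd.DataFrame(np.eye(len(labels)), index=labels, columns=labels)
    logp = pd.DataFrame(np.full((len(labels),) * 2, np.nan), index=labels, columns=labels)
    star = pd.DataFrame("", index=labels, columns=labels)
    for i, j in itertools.combinations(range(len(labels)), 2):
        li, lj = labels[i], labels[j]
        try:
            pair = align_pair(sumstats[i], sumstats[j])
            fit = fit_rg(pair, sample_sizes[li], sample_sizes[lj], ld, exclude_hla, n_blocks)
            if fit.flagged:
                raise LdscError(fit.flagged)
        except (LdscError, ValueError) as exc:
            warnings.warn(f"rg({li},{lj}) failed: {exc}", stacklevel=2)
            rg.loc[li, lj] = rg.loc[lj, li] = np.nan
            continue
        rg.loc[li, lj] = rg.loc[lj, li] = fit.rg
        logp.loc[li, lj] = logp.loc[lj, li] = fit.neg_log10_p
        star.loc[li, lj] = star.loc[lj, li] = significance_stars(fit.p_rg)
    return rg, logp, star
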