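"""SNP-level pleiotropy via the variance/correlation-adjusted product-of-Z test.

For a variant with allele-aligned z-scores (z1, z2) in two traits, the test
statistic is T = z1'·z2' after the raw scores are (i) rescaled by the empirical
null standard deviation of each trait (variance inflation) and (ii) whitened
with the symmetric inverse square root of the 2x2 null correlation matrix
(cross-trait correlation from shared controls / sample overlap).  Both
calibration moments come from approximately null variants, defined as those
with both marginal p-values above ``p_screen`` (1e-4 by default).

Pleiotropy is tested against the composite null that the variant is associated
with at most one trait.  The reported p-value is the intersection-union bound

    p = max( P(|XY| >= |T|),  two-sided p of z1',  two-sided p of z2' )

where X, Y are independent standard normals: the first term is exact under the
neither-trait null (product-normal tail, Bessel-K0 density), and the marginal
p of the *other* trait bounds the tail under each single-trait sub-null, so the
test is level-alpha under all three.  Only variants small in both traits reach
small p — the composite-null protection against one-trait-driven hits.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, special, stats

from .locus_architecture import GWS_THRESHOLD, HLA_REGION
from .sumstats_io import AlignedPair

P_SCREEN_DEFAULT = 1e-4


class PlacoError(ValueError):
    pass


@dataclass(frozen=True)
class PlacoCalibration:
    """Null-SNP moments used to adjust the z-scores before the product test."""

    var_z1: float
    var_z2: float
    cor_z: float
    p_screen: float
    n_null_snps: int


# ---------------------------------------------------------------------------
# Calibration and decorrelation
# ---------------------------------------------------------------------------


def calibrate(pair: AlignedPair, p_screen: float = P_SCREEN_DEFAULT) -> PlacoCalibration:
    """Estimate VarZ per trait and CorZ from jointly null variants.

    A variant is "approximately null" when BOTH marginal p-values exceed
    ``p_screen`` — the joint requirement keeps genuinely associated variants
    out of the covariance estimate.
    """
    null = (pair.p1 > p_screen) & (pair.p2 > p_screen)
    n_null = int(null.sum())
    if n_null < 10:
        raise PlacoError(f"insufficient null SNPs for calibration ({n_null})")
    if n_null < 100:
        warnings.warn(f"only {n_null} null SNPs for calibration", stacklevel=2)
    z1, z2 = pair.z1[null], pair.z2[null]
    var1, var2 = float(np.var(z1, ddof=1)), float(np.var(z2, ddof=1))
    cor = float(np.corrcoef(z1, z2)[0, 1])
    if abs(cor) >= 1.0:
        warnings.warn("null z-scores perfectly correlated; truncating", stacklevel=2)
        cor = math.copysign(0.9999, cor)
    return PlacoCalibration(
        var_z1=var1, var_z2=var2, cor_z=cor, p_screen=p_screen, n_null_snps=n_null
    )


def decorrelate(
    z1: np.ndarray, z2: np.ndarray, cal: PlacoCalibration
) -> tuple[np.ndarray, np.ndarray]:
    """Rescale by sqrt(VarZ), then whiten with the symmetric inverse root.

    The symmetric (matrix) square root keeps the transform invariant under
    swapping the traits.  After the transform, the calibration-null covariance
    of the pair is the identity.
    """
    if abs(cal.cor_z) >= 0.999:
        raise PlacoError("collinear traits: |cor_z| >= 0.999")
    a = np.asarray(z1, float) / math.sqrt(cal.var_z1)
    b = np.asarray(z2, float) / math.sqrt(cal.var_z2)
    r = cal.cor_z
    # inverse symmetric square root of [[1, r], [r, 1]]
    sp, sm = math.sqrt(1.0 + r), math.sqrt(1.0 - r)
    d, o = 0.5 * (1 / sp + 1 / sm), 0.5 * (1 / sp - 1 / sm)
    return d * a + o * b, o * a + d * b


# ---------------------------------------------------------------------------
# Product-normal tail
# ---------------------------------------------------------------------------


def _pn_sf_scalar(t: float) -> float:
    """P(|XY| >= t) for independent standard normals, t >= 0.

    The product density is K0(|x|)/pi; the tail is (2/pi)∫_t^∞ K0(x) dx,
    computed with the exponentially scaled Bessel function k0e so the
    integrand stays O(1) and the e^{-t} factor is applied analytically
    (stable far into the tail).
    """
    if t <= 0:
        return 1.0
    val, _ = integrate.quad(
        lambda u: special.k0e(t + u) * math.exp(-u), 0.0, np.inf, epsabs=1e-15, epsrel=1e-13
    )
    return min(1.0, 2.0 / math.pi * math.exp(-t) * val)


def product_normal_sf(t):
    """Two-sided tail of the product of two independent standard normals.

    Vectorized; symmetric in the sign of ``t`` and strictly decreasing in |t|.
    """
    t_arr = np.abs(np.atleast_1d(np.asarray(t, dtype=float)))
    uniq, inv = np.unique(t_arr, return_inverse=True)
    vals = np.array([_pn_sf_scalar(u) for u in uniq])
    out = vals[inv].reshape(np.shape(np.abs(np.asarray(t, dtype=float))))
    return float(out) if np.isscalar(t) or np.ndim(t) == 0 else out


# ---------------------------------------------------------------------------
# Composite-null p-value and scan
# ---------------------------------------------------------------------------


def placo_pvalue(z1p, z2p):
    """Composite-null pleiotropy p-value for decorrelated scores.

    max of the product-normal tail of T = z1'·z2' and the two-sided marginal
    p-values of each score (the conditional sub-null tails); valid under all
    three sub-nulls and symmetric under trait swap.  Vectorized.
    """
    z1p = np.asarray(z1p, dtype=float)
    z2p = np.asarray(z2p, dtype=float)
    t = z1p * z2p
    p0 = product_normal_sf(t)
    # trait-1-only sub-null: z1' fixed, so P(|z1'Z| >= |t|) = marginal p of z2'
    p1 = 2 * stats.norm.sf(np.abs(z2p))
    p2 = 2 * stats.norm.sf(np.abs(z1p))
    return np.maximum(p0, np.maximum(p1, p2))


def placo_scan(
    pair: AlignedPair,
    cal: PlacoCalibration,
    threshold: float = GWS_THRESHOLD,
    exclude_hla: bool = False,
    hla_region: tuple[str, int, int] = HLA_REGION,
) -> pd.DataFrame:
    """Per-variant pleiotropy scan for one disease pair.

    Returns a Manhattan-ready frame with the adjusted scores, T_PLACO,
    P_PLACO, the HLA flag and a ``significant`` column (strict p < threshold).
    With ``exclude_hla`` the chr6:25-34 Mb variants are removed before
    reporting; the remaining p-values are unchanged by the exclusion.
    """
    frame = pair.variants
    keep = np.isfinite(pair.z1) & np.isfinite(pair.z2)
    chrom, start, end = hla_region
    is_hla = (
        (frame.chrom.astype(str) == chrom) & (frame.pos >= start) & (frame.pos < end)
    ).to_numpy()
    if exclude_hla:
        keep &= ~is_hla
    z1p, z2p = decorrelate(pair.z1[keep], pair.z2[keep], cal)
    t = z1p * z2p
    p = placo_pvalue(z1p, z2p)
    out = frame.loc[keep, ["chrom", "pos", "effect_allele", "other_allele"]].reset_index(drop=True)
    out["z1"] = pair.z1[keep]
    out["z2"] = pair.z2[keep]
    out["z1_adj"] = z1p
    out["z2_adj"] = z2p
    out["t_placo"] = t
    out["p_placo"] = p
    out["is_hla"] = is_hla[keep]
    out["significant"] = p < threshold
    return out
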