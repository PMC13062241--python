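"""Synthetic familial study tables and multi-trait GWAS summary statistics.

Both generators emit data with a machine-readable truth record so every
pipeline stage can be tested for parameter recovery without external
downloads.

Familial studies are simulated at the 2x2-count level: each study draws a
log relative risk from Normal(mu, tau²), controls acquire affected relatives
at a baseline rate, cases at baseline·RR.

GWAS z-scores are simulated directly at the summary level (the downstream
methods consume only summary moments).  Per variant j with LD score ℓ_j the
K-trait score vector is multivariate normal with

    Var(z_kj)        = 1 + N_k h_k² ℓ_j / M
    Cov(z_kj, z_lj)  = ρs_kl + sqrt(N_k N_l) · rg_kl · sqrt(h_k² h_l²) · ℓ_j / M

i.e. the exact moment structure LD score regression inverts, with ρs the
sample-overlap (shared-control) error correlation that lands in the LDSC
intercept.  LD scores are drawn from a shifted gamma (minimum 1) to mimic the
right-skewed genome-wide LD-score distribution.  Large-effect variants can be
overlaid inside an HLA-like window on chromosome 6 and at listed non-HLA
pleiotropic positions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ldsc_regression import LdscInputs
from .meta_analysis import StudyCounts
from .sumstats_io import SumStats


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Familial studies
# ---------------------------------------------------------------------------


@dataclass
class FamilialSimParams:
    """Study conditions for the familial-aggregation simulator.

    Defaults mirror the scale of the published registry studies: three cohorts
    whose proband groups span a few hundred to a few thousand cases, controls
    ten times larger, and a 0.2% baseline probability that a control proband
    has an affected first-degree relative.
    """

    true_log_rr: float = math.log(10.5)
    tau2: float = 0.0
    n_cases: tuple[int, ...] = (800, 5000, 8500)
    n_controls: tuple[int, ...] = (8000, 50000, 85000)
    baseline_rate: float = 0.002
    seed: int = 0

    @property
    def n_studies(self) -> int:
        return len(self.n_cases)

    def __post_init__(self) -> None:
        if not 0 < self.baseline_rate < 1:
            raise SimulationError("baseline_rate must be in (0, 1)")
        if self.tau2 < 0:
            raise SimulationError("tau2 must be >= 0")
        if len(self.n_cases) != len(self.n_controls):
            raise SimulationError("n_cases and n_controls must have equal length")
        if min(self.n_cases) <= 0 or min(self.n_controls) <= 0:
            raise SimulationError("study sizes must be positive")


def simulate_familial_studies(
    params: FamilialSimParams, rng: np.random.Generator | None = None
) -> tuple[list[StudyCounts], dict]:
    """Draw per-study 2x2 counts under a random-effects relative-risk model."""
    rng = np.random.default_rng(params.seed) if rng is None else rng
    counts, thetas = [], []
    for n_case, n_ctrl in zip(params.n_cases, params.n_controls):
        theta = float(rng.normal(params.true_log_rr, math.sqrt(params.tau2)))
        case_rate = params.baseline_rate * math.exp(theta)
        if case_rate > 1:
            raise SimulationError(
                f"RR incompatible with baseline: implied case rate {case_rate:.3f} > 1"
            )
        a = int(rng.binomial(n_case, case_rate))
        b = int(rng.binomial(n_ctrl, params.baseline_rate))
        counts.append(StudyCounts(a=a, b=b, c=n_case - a, d=n_ctrl - b))
        thetas.append(theta)
    truth = {
        "true_log_rr": params.true_log_rr,
        "tau2": params.tau2,
        "baseline_rate": params.baseline_rate,
        "study_log_rr": thetas,
        "n_cases": list(params.n_cases),
        "n_controls": list(params.n_controls),
    }
    return counts, truth


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------


@dataclass
class SumstatsSimParams:
    """Study conditions for the multi-trait summary-statistic simulator.

    The default two-trait setting matches the scale used throughout the
    recovery tests: M = 20,000 variants spread over chromosomes 1-22,
    N = 50,000 per trait, h² = 0.3, and LD scores from 1 + Gamma(1.5, 6)
    (mean ≈ 10, right-skewed).  ``rg`` and ``rho_s`` are full matrices so any
    number of traits with arbitrary genetic and sample-overlap structure can
    be generated; spikes inject large fixed z-scores into the HLA window
    (chr6:25-34 Mb) or at listed non-HLA pleiotropic positions in every trait.
    """

    trait_labels: tuple[str, ...] = ("trait1", "trait2")
    m_snps: int = 20_000
    chromosomes: tuple[str, ...] = tuple(str(i) for i in range(1, 23))
    h2: tuple[float, ...] = (0.3, 0.3)
    n: tuple[float, ...] = (50_000.0, 50_000.0)
    rg: np.ndarray | None = None  # defaults to identity
    rho_s: np.ndarray | None = None  # defaults to zeros off-diagonal
    ld_gamma_shape: float = 1.5
    ld_gamma_scale: float = 6.0
    hla_spike_count: int = 0
    hla_spike_z: float = 8.0
    pleiotropic_spikes: tuple[tuple[str, int, float], ...] = ()  # (chrom, pos, z)
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.trait_labels)
        if len(self.h2) != k or len(self.n) != k:
            raise SimulationError("h2 and n must match the number of traits")
        if any(not 0 <= h < 1 for h in self.h2):
            raise SimulationError("h2 must be in [0, 1)")
        if self.rg is None:
            self.rg = np.eye(k)
        self.rg = np.asarray(self.rg, dtype=float)
        if self.rg.shape != (k, k) or not np.allclose(self.rg, self.rg.T):
            raise SimulationError("rg must be a symmetric KxK matrix")
        if not np.allclose(np.diag(self.rg), 1.0):
            raise SimulationError("rg must have unit diagonal")
        if np.linalg.eigvalsh(self.rg).min() < -1e-9:
            raise SimulationError("rg must be positive semi-definite")
        if self.rho_s is None:
            self.rho_s = np.zeros((k, k))
        self.rho_s = np.asarray(self.rho_s, dtype=float)
        np.fill_diagonal(self.rho_s, 0.0)


def _variant_grid(params: SumstatsSimParams) -> pd.DataFrame:
    """Evenly spaced positions, 100 kb apart, so chr6 spans the HLA window."""
    n_chr = len(params.chromosomes)
    base = params.m_snps // n_chr
    counts = [base + (1 if i < params.m_snps % n_chr else 0) for i in range(n_chr)]
    chroms, positions = [], []
    for chrom, cnt in zip(params.chromosomes, counts):
        chroms.extend([chrom] * cnt)
        positions.extend(1_000_000 + 100_000 * np.arange(cnt))
    ea = np.where(np.arange(params.m_snps) % 2 == 0, "A", "C")
    oa = np.where(np.arange(params.m_snps) % 2 == 0, "G", "T")
    return pd.DataFrame(
        {"chrom": chroms, "pos": np.array(positions, dtype=int), "effect_allele": ea, "other_allele": oa}
    )


def simulate_sumstats(
    params: SumstatsSimParams, rng: np.random.Generator | None = None
) -> tuple[dict[str, SumStats], LdscInputs, dict]:
    """Generate per-trait summary statistics with the LDSC moment structure.

    Returns ({label: SumStats}, LdscInputs, truth).  All traits share the
    variant grid and allele coding, so pairwise alignment keeps every variant.
    """
    rng = np.random.default_rng(params.seed) if rng is None else rng
    grid = _variant_grid(params)
    m = params.m_snps
    k = len(params.trait_labels)
    ell = 1.0 + rng.gamma(params.ld_gamma_shape, params.ld_gamma_scale, size=m)

    n_arr = np.asarray(params.n, float)
    h_arr = np.asarray(params.h2, float)
    # per-ld-unit genetic covariance slope B and ld-free error covariance A
    hh = np.sqrt(np.outer(h_arr, h_arr))
    b_mat = params.rg * hh * np.sqrt(np.outer(n_arr, n_arr)) / m
    a_mat = params.rho_s + np.eye(k)

    cov = a_mat[None, :, :] + ell[:, None, None] * b_mat[None, :, :]
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        eigmin = np.linalg.eigvalsh(cov).min(axis=1)
        j = int(np.argmin(eigmin))
        raise SimulationError(
            f"non-PSD z covariance at variant {grid.chrom[j]}:{grid.pos[j]}"
        ) from None
    z = np.einsum("jkl,jl->jk", chol, rng.standard_normal((m, k)))

    # spikes: fixed large z in every trait
    spike_idx: list[int] = []
    if params.hla_spike_count:
        window = (grid.chrom == "6") & (grid.pos >= 25_000_000) & (grid.pos < 34_000_000)
        candidates = np.flatnonzero(window.to_numpy())
        if len(candidates) < params.hla_spike_count:
            raise SimulationError("not enough chr6:25-34 Mb variants for the HLA spike")
        chosen = rng.choice(candidates, size=params.hla_spike_count, replace=False)
        z[chosen, :] = params.hla_spike_z
        spike_idx.extend(int(i) for i in chosen)
    pleio_positions = []
    for chrom, pos, zval in params.pleiotropic_spikes:
        hits = np.flatnonzero((grid.chrom == str(chrom)) & (grid.pos == int(pos)))
        if len(hits) != 1:
            raise SimulationError(f"pleiotropic spike position {chrom}:{pos} not on the grid")
        z[hits[0], :] = zval
        spike_idx.append(int(hits[0]))
        pleio_positions.append((str(chrom), int(pos)))

    out: dict[str, SumStats] = {}
    for t, label in enumerate(params.trait_labels):
        se = np.full(m, 1.0 / math.sqrt(n_arr[t]))
        records = grid.copy()
        records["beta"] = z[:, t] * se
        records["se"] = se
        records["p"] = np.clip(2 * stats.norm.sf(np.abs(z[:, t])), 1e-300, 1.0)
        records["n"] = n_arr[t]
        out[label] = SumStats(disease_label=label, records=records)

    ld = LdscInputs(
        ldscores=grid[["chrom", "pos"]].assign(ldscore=ell), m=m
    )
    truth = {
        "trait_labels": list(params.trait_labels),
        "m_snps": m,
        "h2": list(params.h2),
        "n": list(params.n),
        "rg": params.rg.tolist(),
        "rho_s": params.rho_s.tolist(),
        "mean_ldscore": float(ell.mean()),
        "hla_spike_count": params.hla_spike_count,
        "hla_spike_z": params.hla_spike_z,
        "pleiotropic_spikes": [list(s) for s in params.pleiotropic_spikes],
        "spike_indices": spike_idx,
    }
    return out, ld, truth


def write_truth(truth: dict, path) -> None:
    """Write the truth record as a JSON sidecar."""
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2)
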