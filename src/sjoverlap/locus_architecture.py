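"""Genome-wide-significant locus definition, HLA partitioning and overlap.

Association signal is compared across diseases at the locus level, not the
variant level: every variant with p < 5e-8 is expanded to a ±250 kb window and
overlapping (or touching) windows on a chromosome are merged into one
independent locus, a positional proxy for linkage disequilibrium.  Loci
intersecting the MHC/HLA region (chr6:25-34 Mb, GRCh38) are analyzed
separately, because its outsized contribution to autoimmune risk would
otherwise dominate every cross-disease comparison.  Cross-disease sharing is
measured in union-locus space — loci of all diseases merged into non-
overlapping union loci, each carrying a per-disease presence bit — via shared
counts and the Jaccard index, with and without HLA loci.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sumstats_io import SumStats

GWS_THRESHOLD = 5e-8
LOCUS_FLANK_BP = 250_000
#: MHC region on GRCh38, half-open [start, end)
HLA_REGION = ("6", 25_000_000, 34_000_000)


@dataclass(frozen=True)
class GenomicInterval:
    """1-based inclusive genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start <= other.end and other.start <= self.end

    def overlaps_halfopen(self, chrom: str, start: int, end: int) -> bool:
        """Overlap with a half-open [start, end) region such as the HLA window."""
        return self.chrom == chrom and self.start < end and self.end >= start


@dataclass(frozen=True)
class Locus:
    interval: GenomicInterval
    disease_label: str
    n_gws_variants: int
    lead_p: float
    is_hla: bool = False


@dataclass
class LocusDiseaseMatrix:
    """Union loci with a per-disease binary presence matrix (loci x diseases)."""

    union_loci: list[GenomicInterval]
    presence: np.ndarray
    diseases: list[str]

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=int)
        if self.presence.shape != (len(self.union_loci), len(self.diseases)):
            raise ValueError("presence matrix shape mismatch")
        if len(self.union_loci) and not (self.presence.sum(axis=1) >= 1).all():
            raise ValueError("every union locus must be present in >= 1 disease")

    def hla_mask(self, region: tuple[str, int, int] = HLA_REGION) -> np.ndarray:
        return np.array([iv.overlaps_halfopen(*region) for iv in self.union_loci], dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        rows = {
            "chrom": [iv.chrom for iv in self.union_loci],
            "start": [iv.start for iv in self.union_loci],
            "end": [iv.end for iv in self.union_loci],
        }
        for j, d in enumerate(self.diseases):
            rows[d] = self.presence[:, j] if len(self.union_loci) else []
        return pd.DataFrame(rows)


@dataclass
class OverlapStats:
    diseases: list[str]
    shared_counts: pd.DataFrame
    jaccard_all: pd.DataFrame
    jaccard_non_hla: pd.DataFrame
    delta_jaccard: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        self.delta_jaccard = self.jaccard_all - self.jaccard_non_hla


# ---------------------------------------------------------------------------
# Locus definition
# ---------------------------------------------------------------------------


def gws_variants(s: SumStats, threshold: float = GWS_THRESHOLD) -> pd.DataFrame:
    """Variants with p strictly below the genome-wide significance threshold."""
    df = s.records
    return df[df.p < threshold].reset_index(drop=True)


def merge_intervals(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping-or-touching intervals per chromosome (sort-merge)."""
    out: list[GenomicInterval] = []
    bychrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        bychrom.setdefault(iv.chrom, []).append(iv)
    for chrom in bychrom:
        ivs = sorted(bychrom[chrom], key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end + 1:  # touching end-to-start merges too
                cur_end = max(cur_end, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_start, cur_end))
    return sorted(out, key=lambda iv: (_chrom_rank(iv.chrom), iv.start))


def _chrom_rank(chrom: str) -> int:
    return 23 if chrom == "X" else int(chrom)


def define_loci(
    variants: pd.DataFrame,
    disease_label: str = "",
    window: int = LOCUS_FLANK_BP,
    hla_region: tuple[str, int, int] = HLA_REGION,
) -> list[Locus]:
    """Expand each GWS variant ±window bp (floored at 1) and merge into loci.

    One :class:`Locus` per merged interval, carrying its variant count, lead
    (minimum) p-value and HLA flag.
    """
    if variants.empty:
        return []
    windows = [
        GenomicInterval(str(c), max(1, int(p) - window), int(p) + window)
        for c, p in zip(variants.chrom, variants.pos)
    ]
    merged = merge_intervals(windows)
    loci = []
    for iv in merged:
        inside = variants[
            (variants.chrom == iv.chrom) & (variants.pos >= iv.start) & (variants.pos <= iv.end)
        ]
        loci.append(
            Locus(
                interval=iv,
                disease_label=disease_label,
                n_gws_variants=len(inside),
                lead_p=float(inside.p.min()),
                is_hla=iv.overlaps_halfopen(*hla_region),
            )
        )
    return loci


def classify_hla(
    loci: list[Locus], region: tuple[str, int, int] = HLA_REGION
) -> tuple[list[Locus], list[Locus]]:
    """Partition loci into (HLA, non-HLA); partial overlap with the region suffices."""
    hla, non_hla = [], []
    for locus in loci:
        flagged = locus.interval.overlaps_halfopen(*region)
        locus = Locus(
            interval=locus.interval,
            disease_label=locus.disease_label,
            n_gws_variants=locus.n_gws_variants,
            lead_p=locus.lead_p,
            is_hla=flagged,
        )
        (hla if flagged else non_hla).append(locus)
    return hla, non_hla


# ---------------------------------------------------------------------------
# Union loci and overlap
# ---------------------------------------------------------------------------


def union_loci(loci_by_disease: dict[str, list[Locus]]) -> LocusDiseaseMatrix:
    """Merge all diseases' loci into union loci with per-disease presence bits.

    A disease is present in a union locus iff one of its own loci intersects it
    (each disease locus contains >= 1 GWS variant by construction).  Rows are
    ordered by the number of sharing diseases (descending), then genomic
    position.
    """
    diseases = list(loci_by_disease)
    all_ivs = [loc.interval for locs in loci_by_disease.values() for loc in locs]
    if not all_ivs:
        return LocusDiseaseMatrix(union_loci=[], presence=np.zeros((0, len(diseases)), int), diseases=diseases)
    unions = merge_intervals(all_ivs)
    presence = np.zeros((len(unions), len(diseases)), dtype=int)
    for j, d in enumerate(diseases):
        for loc in loci_by_disease[d]:
            for i, u in enumerate(unions):
                if u.overlaps(loc.interval):
                    presence[i, j] = 1
    order = sorted(
        range(len(unions)),
        key=lambda i: (-presence[i].sum(), _chrom_rank(unions[i].chrom), unions[i].start),
    )
    return LocusDiseaseMatrix(
        union_loci=[unions[i] for i in order], presence=presence[order], diseases=diseases
    )


def _jaccard_matrix(presence: np.ndarray, diseases: list[str]) -> tuple[pd.DataFrame, pd.DataFrame]:
    k = len(diseases)
    jac = np.ones((k, k))
    shared = np.zeros((k, k), dtype=int)
    for i, j in itertools.combinations_with_replacement(range(k), 2):
        both = int(np.sum((presence[:, i] == 1) & (presence[:, j] == 1)))
        either = int(np.sum((presence[:, i] == 1) | (presence[:, j] == 1)))
        shared[i, j] = shared[j, i] = both
        jac[i, j] = jac[j, i] = both / either if either else 0.0
    return (
        pd.DataFrame(jac, index=diseases, columns=diseases),
        pd.DataFrame(shared, index=diseases, columns=diseases),
    )


def overlap_stats(
    matrix: LocusDiseaseMatrix, hla_region: tuple[str, int, int] = HLA_REGION
) -> OverlapStats:
    """Pairwise shared-locus counts and Jaccard indices in union-locus space.

    Jaccard = (# union loci where both diseases present) / (# where either is).
    Computed over all union loci and again after removing those overlapping the
    HLA region; their difference quantifies HLA-driven sharing.
    """
    jac_all, shared = _jaccard_matrix(matrix.presence, matrix.diseases)
    non_hla = matrix.presence[~matrix.hla_mask(hla_region)]
    jac_non_hla, _ = _jaccard_matrix(non_hla, matrix.diseases)
    return OverlapStats(
        diseases=matrix.diseases,
        shared_counts=shared,
        jaccard_all=jac_all,
        jaccard_non_hla=jac_non_hla,
    )


def sharing_summary(
    matrix: LocusDiseaseMatrix,
    min_diseases: int = 4,
    hla_region: tuple[str, int, int] = HLA_REGION,
) -> pd.DataFrame:
    """Per-union-locus disease counts, flagging loci shared by >= min_diseases."""
    frame = matrix.to_frame()
    frame["n_diseases"] = matrix.presence.sum(axis=1) if len(matrix.union_loci) else []
    frame["is_hla"] = matrix.hla_mask(hla_region) if len(matrix.union_loci) else []
    frame["multi_disease"] = frame["n_diseases"] >= min_diseases
    return frame


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------


def loci_to_bed(loci: list[Locus]) -> pd.DataFrame:
    """BED representation (0-based half-open) of a locus list."""
    return pd.DataFrame(
        {
            "chrom": [f"chr{l.interval.chrom}" for l in loci],
            "start": [l.interval.start - 1 for l in loci],
            "end": [l.interval.end for l in loci],
            "name": [l.disease_label for l in loci],
            "score": [l.n_gws_variants for l in loci],
        }
    )
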