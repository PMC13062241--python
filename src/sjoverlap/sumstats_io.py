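"""Reading, validation and pairwise allele alignment of GWAS summary statistics.

Every downstream module consumes the canonical representation produced here: a
:class:`SumStats` wrapping a DataFrame with columns ``chrom, pos, effect_allele,
other_allele, beta, se, p, n, z`` on GRCh38, sorted by (chrom, pos) and unique
on (chrom, pos, allele pair).  Cross-trait analyses use :func:`align_pair`,
which intersects two traits on position, reconciles allele coding (flipping the
sign of z where effect/other are swapped), and drops strand-ambiguous
palindromic variants (A/T, C/G) — without allele frequencies these cannot be
oriented reliably.
"""

from __future__ import annotations

import gzip
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CANONICAL_COLUMNS = ["chrom", "pos", "effect_allele", "other_allele", "beta", "se", "p", "n"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

_CHROM_ORDER = {str(i): i for i in range(1, 23)} | {"X": 23}


class SumStatsError(ValueError):
    pass


def _normalize_chrom(values: pd.Series) -> pd.Series:
    s = values.astype(str).str.upper().str.replace("^CHR", "", regex=True)
    bad = ~s.isin(_CHROM_ORDER)
    if bad.any():
        raise SumStatsError(f"unrecognized chromosome labels: {sorted(s[bad].unique())[:5]}")
    return s


def _chrom_sort_key(chrom: pd.Series) -> pd.Series:
    return chrom.map(_CHROM_ORDER)


@dataclass
class SumStats:
    """One disease's harmonized per-variant association records (GRCh38)."""

    disease_label: str
    records: pd.DataFrame
    build: str = "GRCh38"
    n_dropped: int = 0

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
        if missing:
            raise SumStatsError(f"missing canonical columns: {missing}")
        if "z" not in df.columns:
            df = df.assign(z=df.beta / df.se)
        key = df[["chrom", "pos", "effect_allele", "other_allele"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0]
            raise SumStatsError(f"duplicate variant key at {dup.chrom}:{dup.pos}")
        df = df.sort_values(
            ["chrom", "pos"], key=lambda s: _chrom_sort_key(s) if s.name == "chrom" else s
        ).reset_index(drop=True)
        self.records = df

    def __len__(self) -> int:
        return len(self.records)


def read_sumstats(
    path,
    disease_label: str = "",
    column_map: dict[str, str] | None = None,
) -> SumStats:
    """Read a delimited summary-statistics file into the canonical form.

    ``column_map`` maps canonical names to the file's column names; identity by
    default.  Rows violating per-variant invariants (se <= 0, p outside (0, 1],
    identical alleles, non-finite values) are dropped with a single summary
    warning; duplicated variant keys are a hard error.
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        df = pd.read_csv(fh, sep=None, engine="python")
    if df.empty:
        raise SumStatsError(f"empty summary-statistics file: {path}")
    column_map = column_map or {}
    rename = {src: dst for dst, src in column_map.items()}
    df = df.rename(columns=rename)
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise SumStatsError(f"missing mandatory column(s) {missing} in {path}")
    df = df[CANONICAL_COLUMNS].copy()
    df["chrom"] = _normalize_chrom(df["chrom"])
    for al in ("effect_allele", "other_allele"):
        df[al] = df[al].astype(str).str.upper()

    ok = (
        np.isfinite(df.beta)
        & np.isfinite(df.se)
        & (df.se > 0)
        & (df.p > 0)
        & (df.p <= 1)
        & (df.n > 0)
        & (df.effect_allele != df.other_allele)
    )
    n_dropped = int((~ok).sum())
    if n_dropped:
        warnings.warn(
            f"{disease_label or path}: dropped {n_dropped} rows failing validation",
            stacklevel=2,
        )
    df = df[ok].reset_index(drop=True)
    df["z"] = df.beta / df.se
    return SumStats(disease_label=disease_label, records=df, n_dropped=n_dropped)


def write_sumstats(s: SumStats, path) -> None:
    s.records[CANONICAL_COLUMNS].to_csv(path, sep="\t", index=False)


def _is_palindromic(ea: pd.Series, oa: pd.Series) -> pd.Series:
    return oa == ea.map(_COMPLEMENT)


@dataclass
class AlignedPair:
    """Two traits' z-scores aligned to a common effect allele on shared variants."""

    label1: str
    label2: str
    variants: pd.DataFrame  # chrom, pos, effect_allele, other_allele, z1, z2, p1, p2
    n_kept: int = 0
    n_flipped: int = 0
    n_dropped_palindromic: int = 0
    n_dropped_mismatch: int = 0

    z1: np.ndarray = field(init=False)
    z2: np.ndarray = field(init=False)
    p1: np.ndarray = field(init=False)
    p2: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.z1 = self.variants["z1"].to_numpy()
        self.z2 = self.variants["z2"].to_numpy()
        self.p1 = self.variants["p1"].to_numpy()
        self.p2 = self.variants["p2"].to_numpy()

    def __len__(self) -> int:
        return len(self.variants)


def align_pair(s1: SumStats, s2: SumStats) -> AlignedPair:
    """Intersect two traits on (chrom, pos) and reconcile allele coding.

    Per shared position: identical allele pair → keep z2 as is; swapped
    effect/other → negate z2; palindromic (A/T or C/G) or entirely mismatched
    allele pairs → drop.  Strand flips of non-palindromic variants are resolved
    by complementing s2's alleles before the swap check.
    """
    if s1.build != "GRCh38" or s2.build != "GRCh38":
        raise SumStatsError("both traits must be on GRCh38")
    a = s1.records[["chrom", "pos", "effect_allele", "other_allele", "z", "p"]]
    b = s2.records[["chrom", "pos", "effect_allele", "other_allele", "z", "p"]]
    merged = a.merge(b, on=["chrom", "pos"], suffixes=("_1", "_2"))
    if merged.empty:
        raise SumStatsError(
            f"no shared variants between {s1.disease_label!r} and {s2.disease_label!r}"
        )
    ea1, oa1 = merged.effect_allele_1, merged.other_allele_1
    ea2, oa2 = merged.effect_allele_2, merged.other_allele_2
    palindromic = _is_palindromic(ea1, oa1) | _is_palindromic(ea2, oa2)

    same = (ea1 == ea2) & (oa1 == oa2)
    swapped = (ea1 == oa2) & (oa1 == ea2)
    # strand-flipped codings (complement both alleles of trait 2)
    cea2, coa2 = ea2.map(_COMPLEMENT), oa2.map(_COMPLEMENT)
    strand_same = (ea1 == cea2) & (oa1 == coa2) & ~same & ~swapped
    strand_swapped = (ea1 == coa2) & (oa1 == cea2) & ~same & ~swapped

    keep_same = (same | strand_same) & ~palindromic
    keep_flip = (swapped | strand_swapped) & ~palindromic
    mismatch = ~(same | swapped | strand_same | strand_swapped)

    keep = keep_same | keep_flip
    out = merged[keep].copy()
    z2 = out["z_2"].to_numpy().copy()
    z2[keep_flip[keep].to_numpy()] *= -1.0
    variants = pd.DataFrame(
        {
            "chrom": out.chrom,
            "pos": out.pos,
            "effect_allele": out.effect_allele_1,
            "other_allele": out.other_allele_1,
            "z1": out.z_1.to_numpy(),
            "z2": z2,
            "p1": out.p_1.to_numpy(),
            "p2": out.p_2.to_numpy(),
        }
    ).reset_index(drop=True)
    return AlignedPair(
        label1=s1.disease_label,
        label2=s2.disease_label,
        variants=variants,
        n_kept=int(keep.sum()),
        n_flipped=int(keep_flip.sum()),
        n_dropped_palindromic=int((palindromic & ~mismatch).sum()),
        n_dropped_mismatch=int(mismatch.sum()),
    )


def alignment_report(pair: AlignedPair) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "trait1": pair.label1,
                "trait2": pair.label2,
                "kept": pair.n_kept,
                "flipped": pair.n_flipped,
                "dropped_palindromic": pair.n_dropped_palindromic,
                "dropped_mismatch": pair.n_dropped_mismatch,
            }
        ]
    )
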