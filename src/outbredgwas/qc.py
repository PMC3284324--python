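"""Genotype and phenotype quality control.

SNP filters follow strict comparisons: MAF > ``maf_min``, Hardy-Weinberg
chi-square < ``hwe_max``, missingness < ``miss_max``.  Identical SNPs within
a physical window are collapsed to their left-most representative.  Missing
calls are imputed by sampling from each SNP's observed genotype frequencies
(a deliberately simple stand-in for haplotype-model imputation; at the ~1%
missingness this pipeline targets the choice of imputer is immaterial).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .genotypes import MISSING, GenotypeMatrix


# --------------------------------------------------------------------------
# per-SNP statistics
# --------------------------------------------------------------------------

def genotype_counts(G: GenotypeMatrix) -> np.ndarray:
    """(3, n_snps) counts of genotypes 0/1/2 over non-missing calls."""
    g = G.genotypes
    return np.stack([(g == k).sum(axis=0) for k in (0, 1, 2)])


def compute_maf(G: GenotypeMatrix) -> np.ndarray:
    """Minor-allele frequency per SNP over non-missing calls (NaN if all missing)."""
    c = genotype_counts(G)
    n = c.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (2 * c[2] + c[1]) / (2 * n)
    maf = np.minimum(p, 1.0 - p)
    maf[n == 0] = np.nan
    return maf


def missing_rate(G: GenotypeMatrix) -> np.ndarray:
    return (G.genotypes == MISSING).mean(axis=0)


def hwe_chisq(G: GenotypeMatrix) -> np.ndarray:
    """1-df Pearson chi-square of genotype counts against Hardy-Weinberg
    expectations n*p^2, 2n*p*q, n*q^2 at the sample allele frequency.

    Monomorphic SNPs are defined to have chi-square 0; all-missing SNPs NaN.
    """
    c = genotype_counts(G).astype(float)
    n = c.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (2 * c[0] + c[1]) / (2 * n)
    q = 1.0 - p
    exp = np.stack([n * p**2, 2 * n * p * q, n * q**2])
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = (c - exp) ** 2 / exp
    chi2 = np.where(exp > 0, terms, 0.0).sum(axis=0)
    mono = (p == 0) | (p == 1)
    chi2[mono] = 0.0
    chi2[n == 0] = np.nan
    return chi2


# --------------------------------------------------------------------------
# filtering
# --------------------------------------------------------------------------

@dataclass
class QCReport:
    """Counts through the SNP QC pipeline; non-increasing by construction."""

    n_input_snps: int
    n_polymorphic: int
    n_pass_filters: int
    n_after_collapse: int | None = None
    removed_maf: int = 0
    removed_hwe: int = 0
    removed_missing: int = 0
    removed_undefined: int = 0
    thresholds: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "QCReport":
        with open(path) as fh:
            return cls(**json.load(fh))


def filter_snps(
    G: GenotypeMatrix,
    maf_min: float = 0.02,
    hwe_max: float = 20.0,
    miss_max: float = 0.40,
) -> tuple[GenotypeMatrix, QCReport]:
    """Keep SNPs with MAF > maf_min, HWE chi2 < hwe_max, missingness < miss_max.

    A SNP failing several filters is counted once, under the first failing
    rule in the order MAF -> HWE -> missingness.  SNPs with undefined
    statistics (all calls missing) are counted separately.
    """
    maf = compute_maf(G)
    chi2 = hwe_chisq(G)
    miss = missing_rate(G)

    undefined = np.isnan(maf)
    fail_maf = ~undefined & ~(maf > maf_min)
    fail_hwe = ~undefined & ~fail_maf & ~(chi2 < hwe_max)
    fail_miss = ~undefined & ~fail_maf & ~fail_hwe & ~(miss < miss_max)
    keep = ~(undefined | fail_maf | fail_hwe | fail_miss)

    report = QCReport(
        n_input_snps=G.n_snps,
        n_polymorphic=int(np.nansum(maf > 0)),
        n_pass_filters=int(keep.sum()),
        removed_maf=int(fail_maf.sum()),
        removed_hwe=int(fail_hwe.sum()),
        removed_missing=int(fail_miss.sum()),
        removed_undefined=int(undefined.sum()),
        thresholds={"maf_min": maf_min, "hwe_max": hwe_max, "miss_max": miss_max},
        metadata={
            "imputer": "genotype-frequency sampling (haplotype-model imputation not used)"
        },
    )
    return G.take_snps(np.flatnonzero(keep)), report


# --------------------------------------------------------------------------
# identical-SNP collapsing
# --------------------------------------------------------------------------

def _identical_over_joint(a: np.ndarray, b: np.ndarray) -> bool:
    both = (a != MISSING) & (b != MISSING)
    return bool(both.any()) and bool(np.array_equal(a[both], b[both]))


def collapse_identical(
    G: GenotypeMatrix, window: int = 2_000_000
) -> tuple[GenotypeMatrix, dict[str, list[str]]]:
    """Collapse SNPs with identical genotype vectors within ``window`` bp.

    Scanning left-to-right per chromosome, a SNP whose genotype vector is
    identical (over jointly non-missing entries) to an already retained SNP
    within ``window`` bp is collapsed onto that (left-most) representative.
    Returns the reduced matrix plus a mapping representative id -> list of
    collapsed ids, so scan hits can be expanded back.
    """
    if not G.is_position_sorted():
        raise ValueError("SNPs must be sorted by (chrom, pos); call sort_by_position()")
    geno = G.genotypes
    keep: list[int] = []
    mapping: dict[str, list[int]] = {}
    for c in G.chromosomes():
        cols = np.flatnonzero(G.chrom == c)
        retained: list[int] = []  # indices into G of retained SNPs on this chrom
        lo = 0
        for j in cols:
            pj = G.pos[j]
            while lo < len(retained) and pj - G.pos[retained[lo]] > window:
                lo += 1
            rep = None
            for r in retained[lo:]:
                if _identical_over_joint(geno[:, r], geno[:, j]):
                    rep = r
                    break
            if rep is None:
                retained.append(j)
                keep.append(j)
            else:
                mapping.setdefault(str(G.snp_ids[rep]), []).append(j)
    keep_arr = np.sort(np.array(keep, dtype=np.int64))
    out_map = {str(G.snp_ids[k]): [str(G.snp_ids[j]) for j in mapping.get(str(G.snp_ids[k]), [])]
               for k in keep_arr}
    return G.take_snps(keep_arr), out_map


def expand_collapsed(mapping: dict[str, list[str]]) -> dict[str, str]:
    """Invert the collapse mapping: collapsed id -> representative id."""
    inv: dict[str, str] = {}
    for rep, collapsed in mapping.items():
        for s in collapsed:
            inv[s] = rep
    return inv


# --------------------------------------------------------------------------
# imputation
# --------------------------------------------------------------------------

def impute_missing(G: GenotypeMatrix, seed: int = 0) -> GenotypeMatrix:
    """Fill missing calls by sampling from observed genotype frequencies.

    Deterministic given the seed; never alters a non-missing call.  SNPs
    with no observed calls raise (they should have been pre-filtered).
    """
    geno = G.genotypes.copy()
    rng = np.random.default_rng(seed)
    counts = genotype_counts(G)
    for j in np.flatnonzero((geno == MISSING).any(axis=0)):
        c = counts[:, j].astype(float)
        tot = c.sum()
        if tot == 0:
            raise ValueError(f"SNP {G.snp_ids[j]} has no observed genotypes to impute from")
        rows = np.flatnonzero(geno[:, j] == MISSING)
        geno[rows, j] = rng.choice(3, size=rows.size, p=c / tot).astype(np.int8)
    return G.with_genotypes(geno)


# --------------------------------------------------------------------------
# phenotype preprocessing
# --------------------------------------------------------------------------

def log_acr(acr: np.ndarray) -> np.ndarray:
    """Natural log of (value + 1), elementwise; negative input is a domain error."""
    v = np.asarray(acr, dtype=float)
    if np.any(v < 0):
        raise ValueError("log_acr requires nonnegative values")
    return np.log1p(v)


@dataclass
class TrimResult:
    mean: float
    sd: float
    n_retained: int
    passed: bool
    retained: np.ndarray


def trim_readings(readings: np.ndarray, k: float = 2.0, min_retained: int = 40) -> TrimResult:
    """One discard-and-recalculate pass over repeated readings.

    Readings more than ``k`` sample standard deviations from the mean are
    discarded once, then mean and SD are recomputed; the pass flag requires
    at least ``min_retained`` surviving readings.  With zero SD nothing is
    removed.
    """
    x = np.asarray(readings, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 readings")
    m, s = float(np.mean(x)), float(np.std(x, ddof=1))
    kept = x if s == 0 else x[np.abs(x - m) <= k * s]
    sd = float(np.std(kept, ddof=1)) if kept.size > 1 else 0.0
    return TrimResult(
        mean=float(np.mean(kept)),
        sd=sd,
        n_retained=int(kept.size),
        passed=bool(kept.size >= min_retained),
        retained=kept,
    )


def drop_duplicate_samples(
    G: GenotypeMatrix, threshold: float = 0.99, drop: str = "both"
) -> tuple[GenotypeMatrix, list[tuple[str, str, float]]]:
    """Remove samples whose pairwise genotype identity reaches ``threshold``.

    ``drop='both'`` removes every member of a flagged pair; ``drop='one'``
    keeps the first-listed sample of each pair.
    """
    if drop not in ("both", "one"):
        raise ValueError("drop must be 'both' or 'one'")
    from .structure import pairwise_identity  # local import avoids a module cycle

    summary = pairwise_identity(G, duplicate_threshold=threshold)
    flagged = summary.duplicate_pairs
    to_drop: set[str] = set()
    for a, b, _ in flagged:
        if drop == "both":
            to_drop.update((a, b))
        else:
            to_drop.add(b)
    keep = [i for i, s in enumerate(G.sample_ids) if s not in to_drop]
    return G.take_samples(np.array(keep, dtype=np.int64)), flagged
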