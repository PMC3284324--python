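"""Population-structure and marker-information descriptors.

Identity-by-state kinship, pairwise identity summaries with duplicate
flagging, windowed LD (genotypic r-squared) with a LOWESS-smoothed
median-decay curve, symmetric Shannon entropy of SNPs, and hierarchical
clustering of samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average as _average_linkage, leaves_list
from scipy.spatial.distance import squareform
from statsmodels.nonparametric.smoothers_lowess import lowess as _lowess

from .genotypes import MISSING, GenotypeMatrix


# --------------------------------------------------------------------------
# kinship and identity
# --------------------------------------------------------------------------

@dataclass
class KinshipMatrix:
    """Symmetric n x n identity-by-state similarity with unit diagonal."""

    matrix: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        K = np.asarray(self.matrix, dtype=float)
        if K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise ValueError("kinship matrix must be square")
        if len(self.sample_ids) != K.shape[0]:
            raise ValueError("sample_ids length does not match matrix")
        if not np.allclose(K, K.T, atol=1e-8):
            raise ValueError("kinship matrix must be symmetric")
        if np.any(K < -1e-8) or np.any(K > 1 + 1e-8):
            raise ValueError("kinship entries must lie in [0, 1]")
        if not np.allclose(np.diag(K), 1.0, atol=1e-8):
            raise ValueError("kinship diagonal must be 1")
        self.matrix = K

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def _onehot(G: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    g = G.genotypes
    return (
        (g == 0).astype(np.float64),
        (g == 1).astype(np.float64),
        (g == 2).astype(np.float64),
        (g != MISSING).astype(np.float64),
    )


def ibs_kinship(G: GenotypeMatrix) -> KinshipMatrix:
    """Mean identity-by-state allele sharing: K[i,j] = mean over SNPs of
    (2 - |g_i - g_j|)/2.

    Missing calls are handled pairwise-complete; a pair with zero jointly
    observed SNPs is an error.  The diagonal is forced to exactly 1.
    """
    I0, I1, I2, N = _onehot(G)
    same = I0 @ I0.T + I1 @ I1.T + I2 @ I2.T
    half = I0 @ I1.T + I1 @ I0.T + I1 @ I2.T + I2 @ I1.T
    denom = N @ N.T
    if np.any(denom == 0):
        raise ValueError("a sample pair shares zero jointly non-missing SNPs")
    K = (same + 0.5 * half) / denom
    K = (K + K.T) / 2.0
    np.fill_diagonal(K, 1.0)
    return KinshipMatrix(np.clip(K, 0.0, 1.0), list(G.sample_ids))


@dataclass
class IdentitySummary:
    mean: float
    min: float
    max: float
    duplicate_pairs: list[tuple[str, str, float]]


def pairwise_identity(
    G: GenotypeMatrix, duplicate_threshold: float = 0.99
) -> IdentitySummary:
    """Fraction of identical genotype calls over all sample pairs.

    Returns mean/min/max over off-diagonal pairs plus every pair whose
    identity reaches ``duplicate_threshold``.
    """
    if G.n_samples < 2:
        raise ValueError("need at least 2 samples")
    I0, I1, I2, N = _onehot(G)
    same = I0 @ I0.T + I1 @ I1.T + I2 @ I2.T
    denom = N @ N.T
    if np.any(denom == 0):
        raise ValueError("a sample pair shares zero jointly non-missing SNPs")
    P = same / denom
    iu = np.triu_indices(G.n_samples, k=1)
    vals = P[iu]
    dup = [
        (G.sample_ids[i], G.sample_ids[j], float(P[i, j]))
        for i, j in zip(*iu)
        if P[i, j] >= duplicate_threshold
    ]
    return IdentitySummary(float(vals.mean()), float(vals.min()), float(vals.max()), dup)


# --------------------------------------------------------------------------
# linkage disequilibrium
# --------------------------------------------------------------------------

def ld_pairs(G: GenotypeMatrix, window: int = 50_000_000) -> pd.DataFrame:
    """Squared dosage correlation for all within-chromosome SNP pairs closer
    than ``window`` bp.

    Missing calls are not allowed (impute first); monomorphic SNPs are
    skipped.  Returns a DataFrame with columns snp_a, snp_b, distance, r2.
    """
    if G.has_missing:
        raise ValueError("ld_pairs requires complete genotypes; impute first")
    if not G.is_position_sorted():
        raise ValueError("SNPs must be sorted by (chrom, pos)")
    n = G.n_samples
    out_a, out_b, out_d, out_r2 = [], [], [], []
    for c in G.chromosomes():
        cols = np.flatnonzero(G.chrom == c)
        X = G.genotypes[:, cols].astype(np.float64)
        sd = X.std(axis=0)
        poly = sd > 0
        X = X - X.mean(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            X = np.where(poly[None, :], X / np.where(sd > 0, sd, 1.0), np.nan)
        pos = G.pos[cols]
        ids = G.snp_ids[cols]
        m = cols.size
        for i in range(m - 1):
            if not poly[i]:
                continue
            hi = int(np.searchsorted(pos, pos[i] + window, side="left"))
            js = np.arange(i + 1, hi)
            js = js[poly[js]]
            if js.size == 0:
                continue
            r = (X[:, i] @ X[:, js]) / n
            r2 = np.clip(r * r, 0.0, 1.0)
            out_a.extend([ids[i]] * js.size)
            out_b.extend(ids[js].tolist())
            out_d.append(pos[js] - pos[i])
            out_r2.append(r2)
    dist = np.concatenate(out_d) if out_d else np.array([], dtype=np.int64)
    r2v = np.concatenate(out_r2) if out_r2 else np.array([], dtype=float)
    return pd.DataFrame(
        {"snp_a": out_a, "snp_b": out_b, "distance": dist, "r2": r2v}
    )


@dataclass
class LDDecayCurve:
    bin_center: np.ndarray
    median_r2: np.ndarray
    smoothed_r2: np.ndarray
    decay_radius: float | None  # bp; None when the curve never crosses threshold
    threshold: float = 0.5
    n_pairs: int = 0


def ld_decay(
    pairs: pd.DataFrame,
    lowess_frac: float = 0.05,
    bin_width: float | None = None,
    threshold: float = 0.5,
    window: int = 50_000_000,
) -> LDDecayCurve:
    """Median r2 per distance bin, LOWESS-smoothed, plus the decay radius.

    The decay radius is the smallest distance at which the smoothed curve
    first drops below ``threshold`` (linear interpolation between bin
    centers); ``None`` when the curve never crosses.
    """
    if len(pairs) < 100:
        raise ValueError("need at least 100 SNP pairs for a decay curve")
    dist = pairs["distance"].to_numpy(dtype=float)
    r2 = pairs["r2"].to_numpy(dtype=float)
    if bin_width is None:
        bin_width = window / 500.0
    edges = np.arange(0.0, dist.max() + bin_width, bin_width)
    if edges.size < 2:
        edges = np.array([0.0, dist.max() + 1.0])
    idx = np.digitize(dist, edges) - 1
    centers, medians = [], []
    for b in range(edges.size - 1):
        sel = idx == b
        if sel.any():
            centers.append((edges[b] + edges[b + 1]) / 2.0)
            medians.append(np.median(r2[sel]))
    centers = np.asarray(centers)
    medians = np.asarray(medians)
    if centers.size >= 5:
        sm = _lowess(medians, centers, frac=lowess_frac, return_sorted=False)
    else:
        sm = medians.copy()
    radius: float | None = None
    below = sm < threshold
    if below[0]:
        radius = float(centers[0])
    else:
        for k in range(1, sm.size):
            if below[k]:
                x0, x1 = centers[k - 1], centers[k]
                y0, y1 = sm[k - 1], sm[k]
                radius = float(x0 + (y0 - threshold) / (y0 - y1) * (x1 - x0)) if y0 != y1 else float(x1)
                break
    return LDDecayCurve(centers, medians, sm, radius, threshold, n_pairs=len(pairs))


# --------------------------------------------------------------------------
# SNP information content
# --------------------------------------------------------------------------

def snp_entropy(maf: np.ndarray | float) -> np.ndarray | float:
    """Symmetric Shannon entropy -(p ln p + (1-p) ln(1-p)) in nats.

    ``0 * ln 0`` is taken as 0; maf must lie in [0, 0.5].
    """
    p = np.asarray(maf, dtype=float)
    if np.any((p < 0) | (p > 0.5)):
        raise ValueError("maf must lie in [0, 0.5]")
    q = 1.0 - p
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -(np.where(p > 0, p * np.log(p), 0.0) + np.where(q > 0, q * np.log(q), 0.0))
    h = np.clip(h, 0.0, None)
    return float(h) if np.isscalar(maf) or h.ndim == 0 else h


def entropy_windows(G: GenotypeMatrix, window: int = 4_000_000) -> pd.DataFrame:
    """Mean SNP entropy in non-overlapping ``window``-bp tiles per chromosome.

    Tiles cover [1, max position]; tiles without SNPs get NaN.
    """
    from .qc import compute_maf  # local import avoids a module cycle

    maf = compute_maf(G)
    ent = snp_entropy(np.nan_to_num(maf, nan=0.0))
    rows = []
    for c in G.chromosomes():
        cols = np.flatnonzero(G.chrom == c)
        pos = G.pos[cols]
        n_bins = int((pos.max() - 1) // window) + 1
        bins = (pos - 1) // window
        for b in range(n_bins):
            sel = cols[bins == b]
            rows.append(
                {
                    "chrom": c,
                    "start": b * window + 1,
                    "end": (b + 1) * window,
                    "n_snps": int(sel.size),
                    "mean_entropy": float(np.mean(ent[sel])) if sel.size else np.nan,
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# clustering
# --------------------------------------------------------------------------

@dataclass
class ClusterResult:
    linkage: np.ndarray
    leaf_order: list[int]
    sample_ids: list[str]


def cluster_samples(K: KinshipMatrix) -> ClusterResult:
    """Average-linkage hierarchical clustering on distance 1 - K."""
    if K.n == 1:
        return ClusterResult(np.empty((0, 4)), [0], list(K.sample_ids))
    D = np.clip(1.0 - K.matrix, 0.0, None)
    np.fill_diagonal(D, 0.0)
    Z = _average_linkage(squareform(D, checks=False))
    return ClusterResult(Z, leaves_list(Z).tolist(), list(K.sample_ids))
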