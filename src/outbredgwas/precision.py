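"""Simulation-based estimate of genome-wide mapping precision.

Each replicate samples a random polymorphic target SNP, builds a trait in
which that SNP explains a fixed fraction of total variance on top of a
kinship-structured polygenic term and residual noise, removes the target
from the data, rescans, and records the distance from the association peak
to the target.  Tied peaks contribute their median distance; peaks on
another chromosome are tallied but excluded from the distance distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .qc import compute_maf
from .scan import run_scan
from .structure import KinshipMatrix

logger = logging.getLogger(__name__)

_TIE_TOL = 1e-9


@dataclass
class PrecisionRun:
    """Outcome of one precision-simulation replicate."""

    sim: int
    target_snp: str
    peak_snps: list[str]
    tie_count: int
    same_chromosome: bool
    distance_bp: float | None

    def __post_init__(self) -> None:
        if self.tie_count < 1:
            raise ValueError("tie_count must be >= 1")
        if self.same_chromosome != (self.distance_bp is not None):
            raise ValueError("distance is defined iff the peak is on the target chromosome")


def peak_distance(
    stat: np.ndarray,
    chrom: np.ndarray,
    pos: np.ndarray,
    target_chrom,
    target_pos: int,
    tie_tol: float = _TIE_TOL,
) -> tuple[np.ndarray, bool, float | None]:
    """Locate the (possibly tied) peak and apply the distance rules.

    Returns (indices of tied peaks, same_chromosome flag, distance or None).
    Distance is the median |pos - target_pos| over tied peaks on the target
    chromosome; if no tied peak is on that chromosome, distance is None.
    """
    valid = ~np.isnan(stat)
    if not valid.any():
        raise ValueError("no defined scan statistic")
    mx = stat[valid].max()
    ties = np.flatnonzero(valid & (stat >= mx - tie_tol))
    on_target = ties[chrom[ties] == target_chrom]
    if on_target.size == 0:
        return ties, False, None
    dist = float(np.median(np.abs(pos[on_target] - target_pos)))
    return ties, True, dist


def precision_simulation(
    G: GenotypeMatrix,
    K: np.ndarray | KinshipMatrix,
    var_explained: float,
    sigma_g2: float,
    sigma_e2: float,
    n_sim: int = 1000,
    test: str = "mixed",
    seed: int = 0,
) -> list[PrecisionRun]:
    """Run ``n_sim`` causal-SNP injection replicates.

    The target effect is scaled so that ``beta^2 Var(score) /
    (beta^2 Var(score) + sigma_g2 + sigma_e2) = var_explained``.  Monomorphic
    targets are redrawn (logged).  The target SNP is removed before the scan.
    """
    if not (0.0 < var_explained < 1.0):
        raise ValueError("var_explained must be in (0, 1)")
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    if G.has_missing:
        raise ValueError("precision simulation requires complete genotypes")
    Km = K.matrix if isinstance(K, KinshipMatrix) else np.asarray(K, dtype=float)
    Km = (Km + Km.T) / 2.0
    n = G.n_samples
    maf = compute_maf(G)
    poly = np.flatnonzero(maf > 0)
    if poly.size == 0:
        raise ValueError("no polymorphic SNPs available as targets")
    S = G.scores()
    w, U = np.linalg.eigh(Km)
    wc = np.clip(w, 0.0, None)
    sqrt_g = np.sqrt(sigma_g2 * wc)
    total_bg = sigma_g2 + sigma_e2

    runs: list[PrecisionRun] = []
    ss = np.random.SeedSequence(seed)
    streams = ss.spawn(n_sim)
    for sim in range(n_sim):
        rng = np.random.default_rng(streams[sim])
        while True:
            j = int(rng.choice(poly))
            var_s = float(S[:, j].var())
            if var_s > 0:
                break
            logger.info("redrew monomorphic target %s", G.snp_ids[j])
        beta = np.sqrt(var_explained * total_bg / ((1 - var_explained) * var_s))
        u = U @ (sqrt_g * rng.standard_normal(n)) if sigma_g2 > 0 else np.zeros(n)
        e = rng.standard_normal(n) * np.sqrt(sigma_e2)
        y = beta * S[:, j] + u + e
        target_id = str(G.snp_ids[j])
        target_chrom = G.chrom[j]
        target_pos = int(G.pos[j])
        Gs = G.drop_snps([target_id])
        res = run_scan(
            y, Gs, Km if test == "mixed" else None, test=test,
            **({"kinship_eig": (w, U)} if test == "mixed" else {}),
        )
        stat = res.table["neg_log10_p"].to_numpy(dtype=float)
        ties, same_chrom, dist = peak_distance(
            stat, Gs.chrom, Gs.pos, target_chrom, target_pos
        )
        runs.append(
            PrecisionRun(
                sim=sim,
                target_snp=target_id,
                peak_snps=[str(s) for s in Gs.snp_ids[ties]],
                tie_count=int(ties.size),
                same_chromosome=same_chrom,
                distance_bp=dist,
            )
        )
    return runs


def runs_to_frame(runs: list[PrecisionRun]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sim": [r.sim for r in runs],
            "target": [r.target_snp for r in runs],
            "peak": [",".join(r.peak_snps) for r in runs],
            "distance_bp": [r.distance_bp for r in runs],
            "same_chrom": [r.same_chromosome for r in runs],
            "ties": [r.tie_count for r in runs],
        }
    )


@dataclass
class DistanceSummary:
    quantiles: dict[float, float]  # bp
    same_chromosome_rate: float
    cross_chromosome_rate: float
    n_runs: int
    n_with_distance: int


def distance_summary(
    runs: list[PrecisionRun], quantiles: tuple[float, ...] = (0.5, 0.8, 0.95)
) -> DistanceSummary:
    """Empirical distance quantiles over same-chromosome runs plus the
    same-chromosome rate."""
    if not runs:
        raise ValueError("no runs supplied")
    dists = np.array([r.distance_bp for r in runs if r.distance_bp is not None], dtype=float)
    if dists.size == 0:
        raise ValueError("no run produced a defined distance")
    same = sum(1 for r in runs if r.same_chromosome)
    qs = {float(q): float(np.quantile(dists, q)) for q in quantiles}
    return DistanceSummary(
        quantiles=qs,
        same_chromosome_rate=same / len(runs),
        cross_chromosome_rate=1.0 - same / len(runs),
        n_runs=len(runs),
        n_with_distance=int(dists.size),
    )
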