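"""Synthetic outbred-population generator with ground truth.

Founders carry haplotypes drawn with independent per-SNP allele frequencies;
linkage disequilibrium arises purely from the limited founder pool, the
intermediate-population bottleneck, and a few generations of random mating
with Poisson crossovers (no interference).  Traits are built as additive QTL
effects plus a kinship-structured polygenic term and iid residual noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict
from typing import Sequence

import numpy as np

from .genotypes import MISSING, GenotypeMatrix


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the outbred-population simulator.

    ``recomb_rate`` is the expected number of crossovers per chromosome per
    meiosis.  ``pop_size`` is the size of the intermediate random-mating
    generations (a small value acts as a bottleneck that builds LD by drift);
    the final generation is expanded to ``n_samples``.
    """

    n_founders: int = 8
    n_samples: int = 288
    n_snps_per_chrom: int = 250
    n_chroms: int = 4
    chrom_length: int = 100_000_000
    n_generations: int = 10
    recomb_rate: float = 5.0
    maf_floor: float = 0.02
    missing_rate: float = 0.0
    seed: int = 0
    pop_size: int | None = None
    freq_spectrum: str = "ushaped"  # "ushaped" | "uniform"

    def __post_init__(self) -> None:
        for name in ("n_founders", "n_samples", "n_snps_per_chrom", "n_chroms"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_generations < 0:
            raise ValueError("n_generations must be >= 0")
        if self.chrom_length <= 0:
            raise ValueError("chrom_length must be > 0")
        if self.n_snps_per_chrom > self.chrom_length:
            raise ValueError("more SNPs than available positions on a chromosome")
        if self.recomb_rate < 0:
            raise ValueError("recomb_rate must be >= 0")
        if not (0.0 <= self.maf_floor <= 0.5):
            raise ValueError("maf_floor must be in [0, 0.5]")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.pop_size is not None and self.pop_size < 1:
            raise ValueError("pop_size must be >= 1 when given")
        if self.freq_spectrum not in ("ushaped", "uniform"):
            raise ValueError("freq_spectrum must be 'ushaped' or 'uniform'")


def nmri_like(**overrides) -> SimConfig:
    """Preset emulating a 288-sample commercial outbred cohort.

    Tuned so the simulated population shows a broad MAF spectrum, weak
    family structure, and a median-r2 LD decay radius on the order of 1 Mb.
    SNP density is kept modest by default; raise ``n_snps_per_chrom`` to
    approach array-scale data.
    """
    base = dict(
        n_founders=4,
        n_samples=288,
        n_snps_per_chrom=250,
        n_chroms=10,
        chrom_length=100_000_000,
        n_generations=25,
        recomb_rate=2.0,
        maf_floor=0.02,
        pop_size=10,
        freq_spectrum="ushaped",
        seed=0,
    )
    base.update(overrides)
    return SimConfig(**base)


def tiny(**overrides) -> SimConfig:
    """Small preset (64 samples, 500 SNPs) for fast tests."""
    base = dict(
        n_founders=6,
        n_samples=64,
        n_snps_per_chrom=125,
        n_chroms=4,
        chrom_length=50_000_000,
        n_generations=6,
        recomb_rate=3.0,
        maf_floor=0.05,
        pop_size=30,
        freq_spectrum="uniform",
        seed=0,
    )
    base.update(overrides)
    return SimConfig(**base)


PRESETS = {"nmri-like": nmri_like, "tiny": tiny}


@dataclass
class TruthRecord:
    """Ground truth of a simulated trait, for recovery tests."""

    causal_snp_ids: list[str]
    beta_per_snp: list[float]
    sigma_g2: float
    sigma_e2: float
    var_explained_per_snp: list[float] | None = None
    realized_heritability: float | None = None

    def __post_init__(self) -> None:
        if len(self.causal_snp_ids) != len(self.beta_per_snp):
            raise ValueError("causal_snp_ids and beta_per_snp must have equal length")
        if self.sigma_g2 < 0 or self.sigma_e2 < 0:
            raise ValueError("variance components must be >= 0")
        if self.var_explained_per_snp is not None:
            v = np.asarray(self.var_explained_per_snp, dtype=float)
            if np.any(v < -1e-9) or np.any(v > 1 + 1e-9) or v.sum() > 1 + 1e-6:
                raise ValueError("variance fractions must lie in [0,1] and sum to <= 1")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "TruthRecord":
        with open(path) as fh:
            return cls(**json.load(fh))


# --------------------------------------------------------------------------
# population simulation
# --------------------------------------------------------------------------

def _founder_freqs(rng: np.random.Generator, m: int, cfg: SimConfig) -> np.ndarray:
    if cfg.freq_spectrum == "ushaped":
        p = rng.beta(0.5, 0.5, size=m)
    else:
        p = rng.uniform(0.0, 1.0, size=m)
    return np.clip(p, cfg.maf_floor, 1.0 - cfg.maf_floor)


def _snp_positions(rng: np.random.Generator, cfg: SimConfig) -> np.ndarray:
    """Strictly increasing 1-based positions for one chromosome."""
    pos: set[int] = set()
    while len(pos) < cfg.n_snps_per_chrom:
        need = cfg.n_snps_per_chrom - len(pos)
        pos.update(rng.integers(1, cfg.chrom_length + 1, size=2 * need).tolist())
    return np.sort(np.array(sorted(pos), dtype=np.int64)[: cfg.n_snps_per_chrom])


def _gamete(rng: np.random.Generator, haps: np.ndarray, pos: np.ndarray,
            chrom_length: int, recomb_rate: float) -> np.ndarray:
    """One recombinant gamete from a (2, m) pair of parental haplotypes."""
    n_xo = rng.poisson(recomb_rate)
    start = rng.integers(0, 2)
    if n_xo == 0:
        return haps[start]
    xo = np.sort(rng.integers(1, chrom_length + 1, size=n_xo))
    which = (start + np.searchsorted(xo, pos, side="left")) % 2
    return haps[which, np.arange(pos.size)]


def simulate_population(config: SimConfig) -> GenotypeMatrix:
    """Simulate a diploid outbred population; deterministic given the seed.

    Founders are sampled with independent per-SNP allele frequencies; the
    founder generation is then mated (each offspring from two random,
    distinct-when-possible parents, with Poisson crossovers) for
    ``n_generations + 1`` rounds: round 0 produces the F1, the final round is
    expanded to ``n_samples`` offspring.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    pop_size = cfg.pop_size if cfg.pop_size is not None else cfg.n_samples

    positions = []
    haplos = []  # per chrom: (n_ind, 2, m) int8
    for _ in range(cfg.n_chroms):
        pos = _snp_positions(rng, cfg)
        freqs = _founder_freqs(rng, pos.size, cfg)
        founder = (
            rng.random((cfg.n_founders, 2, pos.size)) < freqs[None, None, :]
        ).astype(np.int8)
        positions.append(pos)
        haplos.append(founder)

    n_parents = cfg.n_founders
    for gen in range(cfg.n_generations + 1):
        size = cfg.n_samples if gen == cfg.n_generations else pop_size
        children = [np.empty((size, 2, p.size), dtype=np.int8) for p in positions]
        for child in range(size):
            if n_parents >= 2:
                pa, pb = rng.choice(n_parents, size=2, replace=False)
            else:
                pa = pb = 0
            for c in range(cfg.n_chroms):
                children[c][child, 0] = _gamete(
                    rng, haplos[c][pa], positions[c], cfg.chrom_length, cfg.recomb_rate
                )
                children[c][child, 1] = _gamete(
                    rng, haplos[c][pb], positions[c], cfg.chrom_length, cfg.recomb_rate
                )
        haplos = children
        n_parents = size

    geno = np.concatenate([h[:, 0, :] + h[:, 1, :] for h in haplos], axis=1)
    chrom = np.concatenate(
        [np.full(p.size, str(c + 1), dtype=object) for c, p in enumerate(positions)]
    )
    pos = np.concatenate(positions)
    snp_ids = np.array(
        [f"snp_{c}_{p}" for c, p in zip(chrom, pos)], dtype=object
    )
    sample_ids = [f"ind{str(i).zfill(4)}" for i in range(cfg.n_samples)]
    G = GenotypeMatrix(geno, sample_ids, snp_ids, chrom, pos)
    if cfg.missing_rate > 0:
        G = inject_missing(G, cfg.missing_rate, seed=rng.integers(0, 2**31 - 1))
    return G


# --------------------------------------------------------------------------
# traits
# --------------------------------------------------------------------------

def _polygenic_draw(rng: np.random.Generator, K: np.ndarray, sigma_g2: float) -> np.ndarray:
    n = K.shape[0]
    if sigma_g2 == 0:
        return np.zeros(n)
    w, U = np.linalg.eigh((K + K.T) / 2.0)
    w = np.clip(w, 0.0, None)
    return U @ (np.sqrt(sigma_g2 * w) * rng.standard_normal(n))


def simulate_trait(
    G: GenotypeMatrix,
    K: np.ndarray | None,
    truth: TruthRecord,
    seed: int = 0,
) -> tuple[np.ndarray, TruthRecord]:
    """Simulate ``y = sum_m beta_m * score_m + u + e``.

    ``u`` is multivariate normal with covariance ``sigma_g2 * K`` and ``e``
    is iid normal with variance ``sigma_e2``.  Genotype scores are -1/0/1.
    Returns the trait and a copy of ``truth`` with realized variance
    fractions filled in.
    """
    rng = np.random.default_rng(seed)
    n = G.n_samples
    if truth.sigma_g2 > 0 and K is None:
        raise ValueError("kinship matrix required when sigma_g2 > 0")
    beta = np.asarray(truth.beta_per_snp, dtype=float)
    if truth.causal_snp_ids:
        idx = G.snp_index(truth.causal_snp_ids)
        S = G.scores()[:, idx]
        if np.isnan(S).any():
            raise ValueError("causal SNPs must have no missing calls")
        fixed_parts = S * beta[None, :]
        fixed = fixed_parts.sum(axis=1)
    else:
        fixed_parts = np.zeros((n, 0))
        fixed = np.zeros(n)
    u = _polygenic_draw(rng, np.asarray(K, dtype=float), truth.sigma_g2) if truth.sigma_g2 > 0 else np.zeros(n)
    e = rng.standard_normal(n) * np.sqrt(truth.sigma_e2)
    y = fixed + u + e
    vy = float(np.var(y))
    if vy > 0:
        fracs = [float(np.var(col) / vy) for col in fixed_parts.T]
        h2 = float(np.var(u) / vy)
    else:
        fracs = [0.0 for _ in range(fixed_parts.shape[1])]
        h2 = 0.0
    out = replace(truth, var_explained_per_snp=fracs, realized_heritability=h2)
    return y, out


def effect_for_variance_fraction(
    G: GenotypeMatrix, snp_id: str, var_explained: float,
    sigma_g2: float, sigma_e2: float,
) -> float:
    """Per-allele effect beta such that the SNP explains ``var_explained`` of
    the total variance ``beta^2 Var(score) + sigma_g2 + sigma_e2``."""
    if not (0 < var_explained < 1):
        raise ValueError("var_explained must be in (0, 1)")
    s = G.scores()[:, G.snp_index([snp_id])[0]]
    var_s = float(np.nanvar(s))
    if var_s == 0:
        raise ValueError(f"SNP {snp_id} is monomorphic; cannot scale an effect")
    return float(np.sqrt(var_explained * (sigma_g2 + sigma_e2) / ((1 - var_explained) * var_s)))


def simulate_acr_like(
    G: GenotypeMatrix,
    K: np.ndarray | None,
    truth: TruthRecord,
    zero_fraction: float,
    seed: int = 0,
) -> np.ndarray:
    """Zero-inflated, right-skewed nonnegative trait.

    Zeros occur with probability ``zero_fraction``; the positive part is the
    exponentiated (standardized) ``simulate_trait`` construction, giving a
    log-normal-like right tail.
    """
    if not (0.0 <= zero_fraction < 1.0):
        raise ValueError("zero_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    y, _ = simulate_trait(G, K, truth, seed=int(rng.integers(0, 2**31 - 1)))
    sd = float(np.std(y))
    z = (y - np.mean(y)) / sd if sd > 0 else y - np.mean(y)
    positive = np.exp(z)
    zeros = rng.random(G.n_samples) < zero_fraction
    return np.where(zeros, 0.0, positive)


def inject_missing(G: GenotypeMatrix, rate: float, seed: int = 0) -> GenotypeMatrix:
    """Mask each genotype independently with probability ``rate``."""
    if not (0.0 <= rate < 1.0):
        raise ValueError("rate must be in [0, 1)")
    if rate == 0.0:
        return G.with_genotypes(G.genotypes.copy())
    rng = np.random.default_rng(seed)
    mask = rng.random(G.genotypes.shape) < rate
    geno = G.genotypes.copy()
    geno[mask] = MISSING
    return G.with_genotypes(geno)
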