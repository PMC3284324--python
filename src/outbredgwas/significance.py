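"""Genome-wide significance thresholds.

The structured (kinship-preserving) permutation draws a multivariate normal
vector with the estimated trait covariance ``sigma_g2 K + sigma_e2 I`` and
reassigns the observed trait values by rank matching, producing an exact
permutation of the data that retains the familial correlation structure.
Per-replicate genome-scan maxima are summarized by a maximum-likelihood
generalized extreme value fit whose upper quantiles give the thresholds.
A plain free permutation is provided for comparison.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .genotypes import GenotypeMatrix
from .scan import VarianceComponents, _as_design, reml_fit, run_scan
from .structure import KinshipMatrix

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# rank transforms and structured permutation
# --------------------------------------------------------------------------

def vdw_scores(y: np.ndarray) -> np.ndarray:
    """Van der Waerden normal scores: rank i of n maps to Phi^-1(i / (n+1)).

    Ties receive mid-ranks.
    """
    y = np.asarray(y, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 observations")
    ranks = stats.rankdata(y, method="average")
    return stats.norm.ppf(ranks / (y.size + 1))


def _mvn_draw(rng: np.random.Generator, cov_eig: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    w, U = cov_eig
    return U @ (np.sqrt(np.clip(w, 0.0, None)) * rng.standard_normal(w.size))


def structured_permute(
    y: np.ndarray,
    K: np.ndarray | KinshipMatrix,
    vc: VarianceComponents,
    seed: int | np.random.Generator = 0,
    *,
    cov_eig: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Kinship-preserving permutation of ``y`` by rank-matching a
    multivariate normal draw with covariance ``sigma_g2 K + sigma_e2 I``.

    The observed value of rank k goes to the sample holding rank k in the
    simulated vector, so the output is an exact permutation of the input.
    Ties in the observed trait are broken by original sample order (stable).
    """
    y = np.asarray(y, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if cov_eig is None:
        Km = K.matrix if isinstance(K, KinshipMatrix) else np.asarray(K, dtype=float)
        w, U = np.linalg.eigh((Km + Km.T) / 2.0)
        cov_eig = (vc.sigma_g2 * np.clip(w, 0.0, None) + vc.sigma_e2, U)
    z = _mvn_draw(rng, cov_eig)
    order_z = np.argsort(z, kind="stable")  # ties in z broken by stable order
    out = np.empty_like(y)
    out[order_z] = np.sort(y, kind="stable")
    return out


# --------------------------------------------------------------------------
# null maxima
# --------------------------------------------------------------------------

def null_maxima(
    y: np.ndarray,
    G: GenotypeMatrix,
    K: np.ndarray | KinshipMatrix | None,
    test: str = "mixed",
    R: int = 100,
    seed: int = 0,
    method: str = "structured",
    covariates: np.ndarray | None = None,
    vc: VarianceComponents | None = None,
) -> np.ndarray:
    """Per-replicate genome-wide maxima of -log10 p under permutation.

    ``method='structured'`` uses the kinship-preserving permutation (variance
    components estimated by REML on the van der Waerden-transformed trait,
    in that order); ``method='free'`` permutes uniformly.  Replicates draw
    from per-replicate substreams of ``seed``; a failed replicate is retried
    on the next substream.
    """
    if method not in ("structured", "free"):
        raise ValueError("method must be 'structured' or 'free'")
    y = np.asarray(y, dtype=float)
    Km = None
    if K is not None:
        Km = K.matrix if isinstance(K, KinshipMatrix) else np.asarray(K, dtype=float)
        Km = (Km + Km.T) / 2.0
    cov_eig = None
    kin_eig = None
    if method == "structured":
        if Km is None:
            raise ValueError("structured permutation requires a kinship matrix")
        if vc is None:
            yt = vdw_scores(y)
            X0 = _as_design(y.size, covariates)
            vc = reml_fit(yt, Km, X0)
        w, U = np.linalg.eigh(Km)
        kin_eig = (w, U)
        cov_eig = (vc.sigma_g2 * np.clip(w, 0.0, None) + vc.sigma_e2, U)
    elif test == "mixed":
        if Km is None:
            raise ValueError("mixed-model scan requires a kinship matrix")
        w, U = np.linalg.eigh(Km)
        kin_eig = (w, U)

    ss = np.random.SeedSequence(seed)
    streams = ss.spawn(4 * R)  # spare substreams for retries
    maxima = np.empty(R)
    stream_i = 0
    for r in range(R):
        while True:
            rng = np.random.default_rng(streams[stream_i])
            stream_i += 1
            if method == "structured":
                yp = structured_permute(y, Km, vc, rng, cov_eig=cov_eig)
            else:
                yp = y[rng.permutation(y.size)]
            try:
                res = run_scan(
                    yp, G, Km, test=test, covariates=covariates,
                    **({"kinship_eig": kin_eig} if test == "mixed" else {}),
                )
                maxima[r] = res.max_neg_log10_p()
                break
            except ValueError as exc:  # pragma: no cover - defensive retry
                logger.warning("replicate %d failed (%s); retrying on next substream", r, exc)
                if stream_i >= len(streams):
                    raise
    return maxima


# --------------------------------------------------------------------------
# GEV thresholds
# --------------------------------------------------------------------------

@dataclass
class ThresholdResult:
    """Fitted genome-wide threshold for one trait x test combination."""

    trait: str
    test: str
    method: str  # structured | free | empirical
    n_reps: int
    maxima: np.ndarray
    gev_shape: float | None
    gev_loc: float | None
    gev_scale: float | None
    thresholds: dict[float, float]

    def __post_init__(self) -> None:
        self.maxima = np.asarray(self.maxima, dtype=float)
        if self.n_reps != self.maxima.size:
            raise ValueError("n_reps must equal the number of maxima")
        if self.gev_scale is not None and self.gev_scale <= 0:
            raise ValueError("GEV scale must be positive")

    def threshold(self, alpha: float = 0.05) -> float:
        return self.thresholds[alpha]

    def to_json(self, path) -> None:
        d = asdict(self)
        d["maxima"] = self.maxima.tolist()
        d["thresholds"] = {str(a): v for a, v in self.thresholds.items()}
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)


def gev_threshold(
    maxima: np.ndarray,
    alphas: tuple[float, ...] = (0.05,),
    trait: str = "",
    test: str = "",
    method: str = "structured",
) -> ThresholdResult:
    """Maximum-likelihood GEV fit to scan maxima; threshold(alpha) is the
    fitted 1-alpha quantile.

    Requires at least 30 non-degenerate maxima; for degenerate input use
    ``empirical_threshold`` instead.
    """
    maxima = np.asarray(maxima, dtype=float)
    if maxima.size < 30:
        raise ValueError("need at least 30 maxima for a GEV fit (use --empirical)")
    if np.ptp(maxima) == 0:
        raise ValueError("degenerate maxima; use the empirical quantile fallback (--empirical)")
    c, loc, scale = stats.genextreme.fit(maxima)
    thresholds = {float(a): float(stats.genextreme.ppf(1 - a, c, loc=loc, scale=scale)) for a in alphas}
    return ThresholdResult(
        trait=trait,
        test=test,
        method=method,
        n_reps=maxima.size,
        maxima=maxima,
        gev_shape=float(c),
        gev_loc=float(loc),
        gev_scale=float(scale),
        thresholds=thresholds,
    )


def empirical_threshold(
    maxima: np.ndarray,
    alphas: tuple[float, ...] = (0.05,),
    trait: str = "",
    test: str = "",
) -> ThresholdResult:
    """Order-statistic quantile fallback for small or degenerate replicates."""
    maxima = np.asarray(maxima, dtype=float)
    if maxima.size < 1:
        raise ValueError("no maxima supplied")
    thresholds = {float(a): float(np.quantile(maxima, 1 - a)) for a in alphas}
    return ThresholdResult(
        trait=trait,
        test=test,
        method="empirical",
        n_reps=maxima.size,
        maxima=maxima,
        gev_shape=None,
        gev_loc=None,
        gev_scale=None,
        thresholds=thresholds,
    )


def permutation_threshold(
    y: np.ndarray,
    G: GenotypeMatrix,
    K: np.ndarray | KinshipMatrix | None,
    test: str = "mixed",
    R: int = 100,
    alphas: tuple[float, ...] = (0.05,),
    seed: int = 0,
    method: str = "structured",
    trait: str = "",
    covariates: np.ndarray | None = None,
) -> ThresholdResult:
    """Full pipeline: permutation null maxima -> GEV fit -> thresholds."""
    maxima = null_maxima(
        y, G, K, test=test, R=R, seed=seed, method=method, covariates=covariates
    )
    res = gev_threshold(maxima, alphas=alphas, trait=trait, test=test, method=method)
    return res


def free_permutation_threshold(
    y: np.ndarray,
    G: GenotypeMatrix,
    test: str = "trend",
    R: int = 100,
    alphas: tuple[float, ...] = (0.05,),
    seed: int = 0,
    K: np.ndarray | KinshipMatrix | None = None,
    trait: str = "",
    covariates: np.ndarray | None = None,
) -> ThresholdResult:
    """Uniform-permutation thresholds (valid only under exchangeability)."""
    return permutation_threshold(
        y, G, K, test=test, R=R, alphas=alphas, seed=seed, method="free",
        trait=trait, covariates=covariates,
    )
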