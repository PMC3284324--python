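"""Single-locus genome scans: additive trend test, 2-df ANOVA, and a
kinship mixed-model trend test, plus conditional scans and nested-model
variance decompositions.

The mixed model is ``y ~ N(X beta, sigma_g2 * K + sigma_e2 * I)``.  Variance
components are estimated by restricted maximum likelihood profiled over
``delta = sigma_e2 / sigma_g2`` after a spectral decomposition of the
kinship projected off the fixed effects; the genome scan then whitens the
data once with the null-model components (or refits per SNP on request) and
applies a generalized-least-squares trend test.  P-values use the F
reference distribution with residual degrees of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genotypes import GenotypeMatrix
from .structure import KinshipMatrix

logger = logging.getLogger(__name__)

_LN10 = np.log(10.0)
_RANK_TOL = 1e-9


# --------------------------------------------------------------------------
# design helpers
# --------------------------------------------------------------------------

def _as_design(n: int, covariates: np.ndarray | None) -> np.ndarray:
    """Intercept plus optional covariate columns, as an (n, q) design."""
    X = np.ones((n, 1))
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        if C.shape[0] != n:
            raise ValueError("covariates must have one row per sample")
        X = np.hstack([X, C])
    return X


def _qr_basis(X: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space of X (rank-revealing)."""
    Q, R = np.linalg.qr(X)
    d = np.abs(np.diag(R))
    keep = d > _RANK_TOL * max(1.0, d.max() if d.size else 1.0)
    return Q[:, keep]


def _residualize(Q: np.ndarray, A: np.ndarray) -> np.ndarray:
    return A - Q @ (Q.T @ A)


def _neg_log10_sf_f(F: np.ndarray, df1: np.ndarray | int, df2: int) -> np.ndarray:
    """-log10 p for an F statistic, stable for extreme statistics."""
    with np.errstate(invalid="ignore"):
        out = -stats.f.logsf(F, df1, df2) / _LN10
    return out


# --------------------------------------------------------------------------
# single-SNP tests
# --------------------------------------------------------------------------

def trend_test(
    y: np.ndarray, g: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[float, float]:
    """1-df additive trend test: regress y on -1/0/1 genotype scores.

    Returns (F statistic, p-value) for the score coefficient, with the F
    reference distribution on (1, n - q - 1) degrees of freedom.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    if np.isnan(g).any() or np.isnan(y).any():
        raise ValueError("missing values not allowed; impute genotypes first")
    s = g - 1.0 if g.min() >= 0 else g  # accept dosages 0/1/2 or scores -1/0/1
    if np.unique(s).size < 2:
        raise ValueError("constant genotype; trend test undefined")
    X0 = _as_design(y.size, covariates)
    F, p, _ = _score_test_core(y, s[:, None], X0)
    return float(F[0]), float(p[0])


def anova_test(
    y: np.ndarray, g: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[float, float, int]:
    """Genotype-as-factor F test (up to 2 df) against the covariates-only model.

    Returns (F, p, df1) where df1 = number of genotype classes present - 1.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    classes = np.unique(g)
    if classes.size < 2:
        raise ValueError("fewer than 2 genotype classes; ANOVA undefined")
    X0 = _as_design(y.size, covariates)
    Q0 = _qr_basis(X0)
    yr = _residualize(Q0, y)
    D = np.column_stack([(g == c).astype(float) for c in classes[1:]])
    Dr = _residualize(Q0, D)
    Qd = _qr_basis(Dr)
    df1 = Qd.shape[1]
    proj = Qd.T @ yr
    ss_model = float(proj @ proj)
    rss0 = float(yr @ yr)
    rss1 = rss0 - ss_model
    df2 = y.size - Q0.shape[1] - df1
    if df2 <= 0:
        raise ValueError("not enough residual degrees of freedom")
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_model / df1) / (rss1 / df2) if rss1 > 0 else np.inf
    p = float(stats.f.sf(F, df1, df2))
    return float(F), p, int(df1)


def _score_test_core(
    y: np.ndarray, S: np.ndarray, X0: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized 1-df F tests of each column of S added to the design X0.

    Returns (F, p, valid); invalid columns (collinear with X0) get NaN.
    """
    n = y.size
    Q0 = _qr_basis(X0)
    q = Q0.shape[1]
    df2 = n - q - 1
    if df2 <= 0:
        raise ValueError("not enough residual degrees of freedom")
    yr = _residualize(Q0, y)
    Sr = _residualize(Q0, S)
    ss_s = np.einsum("ij,ij->j", Sr, Sr)
    ss_y = float(yr @ yr)
    cov = Sr.T @ yr
    scale = np.einsum("ij,ij->j", S, S)
    valid = ss_s > _RANK_TOL * np.maximum(scale, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = cov**2 / (ss_s * ss_y)
        r2 = np.clip(r2, 0.0, 1.0)
        F = np.where(r2 < 1.0, r2 / (1.0 - r2) * df2, np.inf)
    F = np.where(valid, F, np.nan)
    if ss_y <= 0:
        F = np.full(S.shape[1], np.nan)
        valid = np.zeros(S.shape[1], dtype=bool)
    p = np.where(np.isfinite(F), stats.f.sf(np.where(np.isfinite(F), F, 0.0), 1, df2), 0.0)
    p = np.where(np.isnan(F), np.nan, p)
    return F, p, valid


# --------------------------------------------------------------------------
# REML variance components
# --------------------------------------------------------------------------

@dataclass
class VarianceComponents:
    """REML estimates under y ~ N(X beta, sigma_g2 K + sigma_e2 I)."""

    sigma_g2: float
    sigma_e2: float
    delta: float  # sigma_e2 / sigma_g2
    reml_loglik: float
    unidentifiable: bool = False
    at_boundary: bool = False

    @property
    def heritability(self) -> float:
        tot = self.sigma_g2 + self.sigma_e2
        return self.sigma_g2 / tot if tot > 0 else 0.0


@dataclass
class RemlWorkspace:
    """Cached spectral decomposition for repeated REML fits with fixed K, X."""

    lam: np.ndarray  # n - q eigenvalues of the projected kinship
    U: np.ndarray    # corresponding eigenvectors (n, n - q)
    q: int


def reml_workspace(K: np.ndarray, X: np.ndarray) -> RemlWorkspace:
    K = np.asarray(K, dtype=float)
    K = (K + K.T) / 2.0
    n = K.shape[0]
    Q0 = _qr_basis(X)
    q = Q0.shape[1]
    SKS = K - Q0 @ (Q0.T @ K)
    SKS = SKS - (SKS @ Q0) @ Q0.T
    SKS = (SKS + SKS.T) / 2.0
    w, U = np.linalg.eigh(SKS)
    if w.min() < -1e-6 * max(1.0, abs(w.max())):
        # distinguish projector null space from genuine indefiniteness of K
        wk = np.linalg.eigvalsh(K)
        if wk.min() < -1e-6 * max(1.0, abs(wk.max())):
            raise ValueError("kinship matrix is not positive semi-definite")
    keep = slice(q, n)  # drop the q (near-)zero eigenvalues of the projection
    lam = np.clip(w[keep], 0.0, None)
    return RemlWorkspace(lam=lam, U=U[:, keep], q=q)


def _restricted_loglik(delta: float, lam: np.ndarray, eta2: np.ndarray) -> float:
    nq = lam.size
    denom = lam + delta
    s = float(np.sum(eta2 / denom))
    return 0.5 * (nq * (np.log(nq / (2 * np.pi)) - 1.0 - np.log(s)) - float(np.sum(np.log(denom))))


def reml_fit(
    y: np.ndarray,
    K: np.ndarray | KinshipMatrix | None = None,
    X: np.ndarray | None = None,
    *,
    workspace: RemlWorkspace | None = None,
    n_grid: int = 100,
    delta_bounds: tuple[float, float] = (1e-5, 1e5),
) -> VarianceComponents:
    """REML fit of (sigma_g2, sigma_e2) by 1-D profiling over delta.

    The restricted likelihood is evaluated on a log-spaced delta grid and
    refined by bounded scalar optimization around the best grid point.  With
    K proportional to the identity only the total variance is identifiable;
    the likelihood is then flat in delta and ``unidentifiable`` is set.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if X is None:
        X = np.ones((n, 1))
    if workspace is None:
        if K is None:
            raise ValueError("either K or a precomputed workspace is required")
        Km = K.matrix if isinstance(K, KinshipMatrix) else np.asarray(K, dtype=float)
        workspace = reml_workspace(Km, X)
    lam, U = workspace.lam, workspace.U
    eta2 = (U.T @ y) ** 2
    lo, hi = delta_bounds
    grid = np.logspace(np.log10(lo), np.log10(hi), n_grid)
    vals = np.array([_restricted_loglik(d, lam, eta2) for d in grid])
    best = int(np.argmax(vals))
    flat = bool(vals.max() - vals.min() < 1e-8 * max(1.0, abs(vals.max())))
    a = grid[max(best - 1, 0)]
    b = grid[min(best + 1, n_grid - 1)]
    if a < b and not flat:
        res = optimize.minimize_scalar(
            lambda t: -_restricted_loglik(np.exp(t), lam, eta2),
            bounds=(np.log(a), np.log(b)),
            method="bounded",
        )
        delta = float(np.exp(res.x))
        ll = float(-res.fun)
        if ll < vals[best]:
            delta, ll = float(grid[best]), float(vals[best])
    else:
        delta, ll = float(grid[best]), float(vals[best])
    at_boundary = best in (0, n_grid - 1) and not flat
    if at_boundary:
        logger.warning("REML optimum at delta grid boundary (delta=%.3g)", delta)
    nq = lam.size
    sigma_g2 = float(np.sum(eta2 / (lam + delta)) / nq)
    sigma_e2 = float(delta * sigma_g2)
    return VarianceComponents(
        sigma_g2=sigma_g2,
        sigma_e2=sigma_e2,
        delta=delta,
        reml_loglik=ll,
        unidentifiable=flat,
        at_boundary=at_boundary,
    )


# --------------------------------------------------------------------------
# genome scans
# --------------------------------------------------------------------------

@dataclass
class ScanResult:
    """Per-SNP association results for one test."""

    table: pd.DataFrame  # snp_id chrom pos statistic df neg_log10_p p
    test: str
    covariate_snp_ids: list[str] = field(default_factory=list)
    skipped: dict[str, str] = field(default_factory=dict)
    variance_components: VarianceComponents | None = None

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.insert(3, "test", self.test)
        out.to_csv(path, sep="\t", index=False)

    def peak(self) -> pd.Series:
        idx = self.table["neg_log10_p"].idxmax()
        return self.table.loc[idx]

    def max_neg_log10_p(self) -> float:
        return float(np.nanmax(self.table["neg_log10_p"].to_numpy()))


def _result_frame(G: GenotypeMatrix, F, df1, nlp, p) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "snp_id": G.snp_ids,
            "chrom": G.chrom,
            "pos": G.pos,
            "statistic": F,
            "df": df1,
            "neg_log10_p": nlp,
            "p": p,
        }
    )


def _check_complete(G: GenotypeMatrix) -> None:
    if G.has_missing:
        raise ValueError("scan requires complete genotypes; impute first")


def trend_scan(
    y: np.ndarray, G: GenotypeMatrix, covariates: np.ndarray | None = None
) -> ScanResult:
    """Vectorized genome-wide additive trend test."""
    _check_complete(G)
    y = np.asarray(y, dtype=float)
    S = G.scores()
    X0 = _as_design(y.size, covariates)
    F, p, valid = _score_test_core(y, S, X0)
    df2 = y.size - _qr_basis(X0).shape[1] - 1
    nlp = np.where(np.isnan(F), np.nan, _neg_log10_sf_f(np.nan_to_num(F), 1, df2))
    nlp = np.where(np.isinf(F), np.inf, nlp)
    skipped = {
        str(G.snp_ids[j]): "constant or collinear with covariates"
        for j in np.flatnonzero(~valid)
    }
    for s in skipped:
        logger.info("trend_scan skipped %s: %s", s, skipped[s])
    return ScanResult(_result_frame(G, F, 1, nlp, p), "trend", skipped=skipped)


def anova_scan(
    y: np.ndarray, G: GenotypeMatrix, covariates: np.ndarray | None = None
) -> ScanResult:
    """Vectorized genotype-as-factor scan (df = classes present - 1)."""
    _check_complete(G)
    y = np.asarray(y, dtype=float)
    n, m = G.n_samples, G.n_snps
    X0 = _as_design(n, covariates)
    Q0 = _qr_basis(X0)
    q = Q0.shape[1]
    yr = _residualize(Q0, y)
    ss_y = float(yr @ yr)
    g = G.genotypes
    A = _residualize(Q0, (g == 1).astype(float))
    B = _residualize(Q0, (g == 2).astype(float))
    aa = np.einsum("ij,ij->j", A, A)
    bb = np.einsum("ij,ij->j", B, B)
    ab = np.einsum("ij,ij->j", A, B)
    ay = A.T @ yr
    by = B.T @ yr
    tol = _RANK_TOL * n
    rank_a = aa > tol
    rank_b = bb > tol
    det = aa * bb - ab**2
    full_rank = rank_a & rank_b & (det > tol * np.maximum(aa * bb, 1.0))
    ss_model = np.zeros(m)
    df1 = np.zeros(m, dtype=int)
    with np.errstate(divide="ignore", invalid="ignore"):
        ss2 = (bb * ay**2 - 2 * ab * ay * by + aa * by**2) / det
        ss_a = ay**2 / aa
        ss_b = by**2 / bb
    ss_model = np.where(full_rank, ss2, 0.0)
    df1 = np.where(full_rank, 2, 0)
    only_a = ~full_rank & rank_a
    only_b = ~full_rank & ~rank_a & rank_b
    ss_model = np.where(only_a, ss_a, ss_model)
    ss_model = np.where(only_b, ss_b, ss_model)
    df1 = np.where(only_a | only_b, 1, df1)
    valid = df1 > 0
    df2 = n - q - df1
    rss1 = np.maximum(ss_y - ss_model, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(rss1 > 0, (ss_model / np.maximum(df1, 1)) / (rss1 / np.maximum(df2, 1)), np.inf)
    F = np.where(valid & (df2 > 0), F, np.nan)
    p = np.where(np.isfinite(F), stats.f.sf(np.nan_to_num(F), np.maximum(df1, 1), np.maximum(df2, 1)), 0.0)
    p = np.where(np.isnan(F), np.nan, p)
    nlp = np.where(
        np.isnan(F),
        np.nan,
        np.where(np.isinf(F), np.inf, _neg_log10_sf_f(np.nan_to_num(F), np.maximum(df1, 1), np.maximum(df2, 1))),
    )
    skipped = {str(G.snp_ids[j]): "single genotype class" for j in np.flatnonzero(~valid)}
    return ScanResult(_result_frame(G, F, df1, nlp, p), "anova", skipped=skipped)


def _whiten(vc: VarianceComponents, w: np.ndarray, U: np.ndarray) -> np.ndarray:
    """Per-eigencomponent scaling implementing V^{-1/2} up to rotation."""
    return 1.0 / np.sqrt(vc.sigma_g2 * np.clip(w, 0.0, None) + vc.sigma_e2)


def mixed_scan(
    y: np.ndarray,
    G: GenotypeMatrix,
    K: np.ndarray | KinshipMatrix,
    covariates: np.ndarray | None = None,
    refit: str = "once",
    *,
    vc: VarianceComponents | None = None,
    kinship_eig: tuple[np.ndarray, np.ndarray] | None = None,
) -> ScanResult:
    """Kinship mixed-model trend scan.

    ``refit='once'`` estimates variance components on the null model and
    reuses them genome-wide (whitened GLS per SNP); ``refit='per_snp'``
    re-estimates the components with each SNP in the design.
    """
    if refit not in ("once", "per_snp"):
        raise ValueError("refit must be 'once' or 'per_snp'")
    _check_complete(G)
    y = np.asarray(y, dtype=float)
    Km = K.matrix if isinstance(K, KinshipMatrix) else np.asarray(K, dtype=float)
    Km = (Km + Km.T) / 2.0
    n = y.size
    X0 = _as_design(n, covariates)
    if kinship_eig is None:
        w, U = np.linalg.eigh(Km)
    else:
        w, U = kinship_eig
    if vc is None:
        vc = reml_fit(y, Km, X0)
    if refit == "once":
        d = _whiten(vc, w, U)
        yt = d * (U.T @ y)
        Xt = d[:, None] * (U.T @ X0)
        St = d[:, None] * (U.T @ G.scores())
        F, p, valid = _score_test_core(yt, St, Xt)
        df2 = n - _qr_basis(Xt).shape[1] - 1
        nlp = np.where(np.isnan(F), np.nan, _neg_log10_sf_f(np.nan_to_num(F), 1, df2))
        nlp = np.where(np.isinf(F), np.inf, nlp)
    else:
        S = G.scores()
        m = G.n_snps
        F = np.full(m, np.nan)
        p = np.full(m, np.nan)
        nlp = np.full(m, np.nan)
        valid = np.zeros(m, dtype=bool)
        for j in range(m):
            s = S[:, j]
            X = np.hstack([X0, s[:, None]])
            if np.linalg.matrix_rank(X) <= X0.shape[1]:
                continue
            vcj = reml_fit(y, Km, X)
            d = _whiten(vcj, w, U)
            yt = d * (U.T @ y)
            Xt = d[:, None] * (U.T @ X0)
            st = d * (U.T @ s)
            Fj, pj, vj = _score_test_core(yt, st[:, None], Xt)
            F[j], p[j], valid[j] = Fj[0], pj[0], vj[0]
            df2 = n - _qr_basis(Xt).shape[1] - 1
            if np.isfinite(F[j]):
                nlp[j] = _neg_log10_sf_f(np.array([F[j]]), 1, df2)[0]
            elif np.isinf(F[j]):
                nlp[j] = np.inf
    skipped = {
        str(G.snp_ids[j]): "constant or collinear with covariates"
        for j in np.flatnonzero(~valid)
    }
    return ScanResult(
        _result_frame(G, F, 1, nlp, p), "mixed", skipped=skipped, variance_components=vc
    )


def run_scan(
    y: np.ndarray,
    G: GenotypeMatrix,
    K: np.ndarray | KinshipMatrix | None = None,
    test: str = "mixed",
    covariates: np.ndarray | None = None,
    **kwargs,
) -> ScanResult:
    """Dispatch to one of the three scan statistics."""
    if test == "trend":
        return trend_scan(y, G, covariates)
    if test == "anova":
        return anova_scan(y, G, covariates)
    if test == "mixed":
        if K is None:
            raise ValueError("mixed scan requires a kinship matrix")
        return mixed_scan(y, G, K, covariates, **kwargs)
    raise ValueError(f"unknown test {test!r}")


def conditional_scan(
    y: np.ndarray,
    G: GenotypeMatrix,
    K: np.ndarray | KinshipMatrix,
    conditioning_snp_ids: list[str],
    covariates: np.ndarray | None = None,
    test: str = "mixed",
) -> ScanResult:
    """Mixed (or trend/ANOVA) scan with conditioning SNP scores as fixed
    covariates; the conditioning SNPs themselves are excluded from the scan.

    A collinear conditioning set is reduced by QR-based pruning; pruned ids
    are logged.
    """
    idx = G.snp_index(conditioning_snp_ids)
    S = G.scores()[:, idx]
    keep_cols: list[int] = []
    pruned: list[str] = []
    X = _as_design(y.size if hasattr(y, "size") else len(y), covariates)
    for k in range(S.shape[1]):
        cand = np.hstack([X, S[:, keep_cols + [k]]])
        if _qr_basis(cand).shape[1] > _qr_basis(np.hstack([X, S[:, keep_cols]])).shape[1]:
            keep_cols.append(k)
        else:
            pruned.append(str(conditioning_snp_ids[k]))
    if pruned:
        logger.info("conditional_scan pruned collinear conditioning SNPs: %s", pruned)
    cov = S[:, keep_cols]
    all_cov = cov if covariates is None else np.hstack([_as_design(cov.shape[0], covariates)[:, 1:], cov])
    Gs = G.drop_snps(conditioning_snp_ids)
    res = run_scan(y, Gs, K, test=test, covariates=all_cov)
    res.covariate_snp_ids = [str(conditioning_snp_ids[k]) for k in keep_cols]
    return res


def variance_explained(
    y: np.ndarray, G: GenotypeMatrix, snp_sets: list[list[str]]
) -> pd.DataFrame:
    """OLS R-squared for each requested SNP combination, with the
    incremental R-squared of each SNP added in the given order."""
    y = np.asarray(y, dtype=float)
    yc = y - y.mean()
    ss_tot = float(yc @ yc)
    rows = []
    for snps in snp_sets:
        prev_r2 = 0.0
        incremental = []
        for k in range(len(snps) + 1):
            subset = snps[:k]
            if subset:
                S = G.scores()[:, G.snp_index(subset)]
                X = np.hstack([np.ones((y.size, 1)), S])
            else:
                X = np.ones((y.size, 1))
            Q = _qr_basis(X)
            resid = y - Q @ (Q.T @ y)
            r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 0.0
            if k > 0:
                incremental.append(r2 - prev_r2)
            prev_r2 = r2
        rows.append(
            {
                "snps": tuple(snps),
                "r2": prev_r2,
                "incremental_r2": tuple(incremental),
            }
        )
    return pd.DataFrame(rows)
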