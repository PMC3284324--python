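"""Bootstrap forward-stepwise multilocus mapping summarized as resample
model inclusion probabilities (RMIP).

``RMIP_m = (1/R) * sum_r i_rm`` where ``i_rm = 1`` if at least one SNP
within +/- w bp of SNP m was included in the forward-stepwise model of
bootstrap resample r.  Stepwise selection is greedy on the smallest
conditional p-value of the trend-coded SNP given the current model, with
ties broken by (chromosome, position) order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .scan import _as_design, _qr_basis

logger = logging.getLogger(__name__)

_TOL = 1e-9


def forward_stepwise(
    y: np.ndarray,
    G: GenotypeMatrix,
    covariates: np.ndarray | None = None,
    max_terms: int = 20,
) -> list[str]:
    """Greedy forward selection of trend-coded SNPs.

    At each step the SNP with the smallest conditional p-value (largest
    partial F, equivalently largest partial correlation) is added.  Stops at
    ``max_terms`` or as soon as the design becomes singular / the fit is
    exact.  Returns selected SNP ids in selection order.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    X0 = _as_design(n, covariates)
    q0 = _qr_basis(X0).shape[1]
    if max_terms >= n - q0:
        raise ValueError("max_terms must be < n - #covariates - 1")
    Q0 = _qr_basis(X0)
    yr = y - Q0 @ (Q0.T @ y)
    S = G.scores()
    if np.isnan(S).any():
        raise ValueError("forward_stepwise requires complete genotypes")
    Sr = S - Q0 @ (Q0.T @ S)
    ss0 = np.einsum("ij,ij->j", Sr, Sr)
    # tie-break order: position in the (chrom, pos)-sorted matrix
    chrom_rank = {c: i for i, c in enumerate(G.chromosomes())}
    order_key = np.lexsort((G.pos, np.array([chrom_rank[c] for c in G.chrom])))
    tie_rank = np.empty(G.n_snps, dtype=np.int64)
    tie_rank[order_key] = np.arange(G.n_snps)

    available = np.ones(G.n_snps, dtype=bool)
    selected: list[str] = []
    for _ in range(max_terms):
        ss_y = float(yr @ yr)
        if ss_y <= _TOL * n:
            logger.info("forward_stepwise stopped early: residual exhausted")
            break
        ss = np.einsum("ij,ij->j", Sr, Sr)
        usable = available & (ss > _TOL * np.maximum(ss0, 1.0))
        if not usable.any():
            logger.info("forward_stepwise stopped early: no usable SNP remains")
            break
        cov = Sr.T @ yr
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = np.where(usable, cov**2 / (ss * ss_y), -np.inf)
        best_r2 = r2.max()
        if not np.isfinite(best_r2):
            break
        cand = np.flatnonzero(r2 >= best_r2 - 1e-12)
        j = cand[np.argmin(tie_rank[cand])]
        selected.append(str(G.snp_ids[j]))
        available[j] = False
        qn = Sr[:, j] / np.sqrt(ss[j])
        yr = yr - qn * (qn @ yr)
        Sr = Sr - np.outer(qn, qn @ Sr)
    return selected


@dataclass
class RMIPResult:
    """Per-SNP resample model inclusion probabilities."""

    table: pd.DataFrame  # snp_id chrom pos rmip
    window: int
    n_resamples: int
    selections: list[list[str]] = field(default_factory=list)

    def rmip(self, snp_id: str) -> float:
        row = self.table.loc[self.table["snp_id"] == snp_id, "rmip"]
        if row.empty:
            raise LookupError(f"unknown SNP id: {snp_id!r}")
        return float(row.iloc[0])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def selections_to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"window": self.window, "n_resamples": self.n_resamples,
                 "selections": self.selections},
                fh, indent=2,
            )


def rmip_from_selections(
    selections: list[list[str]], G: GenotypeMatrix, window: int
) -> RMIPResult:
    """Apply the +/- window inclusion rule to precomputed per-resample
    selections (lets several window sizes reuse one set of bootstrap runs)."""
    R = len(selections)
    counts = np.zeros(G.n_snps, dtype=np.int64)
    by_chrom = {c: np.flatnonzero(G.chrom == c) for c in G.chromosomes()}
    for sel in selections:
        if not sel:
            continue
        idx = G.snp_index(sel)
        hit = np.zeros(G.n_snps, dtype=bool)
        for c in set(G.chrom[idx].tolist()):
            cols = by_chrom[c]
            pos = G.pos[cols]
            sel_pos = np.sort(G.pos[idx[G.chrom[idx] == c]])
            lo = np.searchsorted(sel_pos, pos - window, side="left")
            hi = np.searchsorted(sel_pos, pos + window, side="right")
            hit[cols] = hi > lo
        counts += hit
    table = pd.DataFrame(
        {"snp_id": G.snp_ids, "chrom": G.chrom, "pos": G.pos, "rmip": counts / R}
    )
    return RMIPResult(table=table, window=window, n_resamples=R, selections=selections)


def rmip(
    y: np.ndarray,
    G: GenotypeMatrix,
    R: int = 100,
    window: int = 1_000_000,
    max_terms: int = 20,
    seed: int = 0,
    covariates: np.ndarray | None = None,
) -> RMIPResult:
    """Bootstrap resampling (samples drawn with replacement, trait paired
    with its genotype row) followed by forward stepwise selection on each
    resample; deterministic given the seed."""
    if window < 0:
        raise ValueError("window must be >= 0")
    if R < 1:
        raise ValueError("R must be >= 1")
    y = np.asarray(y, dtype=float)
    n = y.size
    ss = np.random.SeedSequence(seed)
    selections: list[list[str]] = []
    for child in ss.spawn(R):
        rng = np.random.default_rng(child)
        idx = rng.integers(0, n, size=n)
        Gb = G.take_samples(idx)
        cb = None
        if covariates is not None:
            C = np.atleast_2d(np.asarray(covariates, dtype=float))
            if C.shape[0] != n:
                C = C.T
            cb = C[idx]
        selections.append(forward_stepwise(y[idx], Gb, covariates=cb, max_terms=max_terms))
    return rmip_from_selections(selections, G, window)
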