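"""Core genotype container shared by every stage of the pipeline.

Genotypes are stored as diploid minor/alternate allele dosages 0/1/2 in an
``int8`` matrix of shape (n_samples, n_snps); missing calls are encoded as
``-1``.  SNP metadata (id, chromosome label, 1-based base-pair position)
travels with the matrix so that windowed operations (LD, collapsing, RMIP
windows) can be expressed in physical coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

MISSING = -1
_VALID_CODES = frozenset({-1, 0, 1, 2})


@dataclass
class GenotypeMatrix:
    """Samples x SNPs diploid dosage matrix with SNP metadata.

    Parameters
    ----------
    genotypes
        ``(n_samples, n_snps)`` integer array with entries in ``{0, 1, 2}``
        and ``-1`` for missing calls.
    sample_ids
        Sample identifiers, one per row.
    snp_ids
        SNP identifiers, one per column; must be unique.
    chrom
        Chromosome label per SNP.
    pos
        1-based base-pair position per SNP.
    """

    genotypes: np.ndarray
    sample_ids: list[str]
    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    _id_index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D (samples x SNPs) array")
        if not np.issubdtype(self.genotypes.dtype, np.integer):
            g = self.genotypes
            if not np.all(np.isfinite(g)):
                raise ValueError("non-finite genotype entries; encode missing as -1")
            self.genotypes = g.astype(np.int8)
        else:
            self.genotypes = self.genotypes.astype(np.int8, copy=False)
        codes = np.unique(self.genotypes)
        if not set(codes.tolist()) <= _VALID_CODES:
            bad = sorted(set(codes.tolist()) - _VALID_CODES)
            raise ValueError(f"invalid genotype codes {bad}; expected 0/1/2 and -1 for missing")
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        n, m = self.genotypes.shape
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match genotype rows")
        for name, arr in (("snp_ids", self.snp_ids), ("chrom", self.chrom), ("pos", self.pos)):
            if arr.shape != (m,):
                raise ValueError(f"{name} length does not match genotype columns")
        if np.any(self.pos < 1):
            raise ValueError("positions are 1-based and must be >= 1")
        if len(set(self.snp_ids.tolist())) != m:
            raise ValueError("snp_ids must be unique")
        self._id_index = {s: i for i, s in enumerate(self.snp_ids.tolist())}

    # ------------------------------------------------------------------ shape
    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean (n_samples, n_snps) mask, True where the call is missing."""
        return self.genotypes == MISSING

    @property
    def has_missing(self) -> bool:
        return bool((self.genotypes == MISSING).any())

    def is_position_sorted(self) -> bool:
        """True if positions are strictly increasing within each chromosome."""
        for c in self.chromosomes():
            p = self.pos[self.chrom == c]
            if p.size > 1 and not np.all(np.diff(p) > 0):
                return False
        return True

    def chromosomes(self) -> list:
        """Chromosome labels in first-appearance order."""
        seen: dict = {}
        for c in self.chrom.tolist():
            seen.setdefault(c, None)
        return list(seen)

    # ------------------------------------------------------------ conversions
    def scores(self) -> np.ndarray:
        """Additive genotype scores -1/0/1 as float64; missing becomes NaN."""
        s = self.genotypes.astype(np.float64) - 1.0
        s[self.genotypes == MISSING] = np.nan
        return s

    def dosages(self) -> np.ndarray:
        """Dosages 0/1/2 as float64; missing becomes NaN."""
        d = self.genotypes.astype(np.float64)
        d[self.genotypes == MISSING] = np.nan
        return d

    # -------------------------------------------------------------- indexing
    def snp_index(self, snp_ids: Iterable[str]) -> np.ndarray:
        """Column indices for the given SNP ids; unknown ids raise LookupError."""
        idx = []
        for s in snp_ids:
            try:
                idx.append(self._id_index[str(s)])
            except KeyError:
                raise LookupError(f"unknown SNP id: {s!r}") from None
        return np.asarray(idx, dtype=np.int64)

    def take_snps(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            genotypes=self.genotypes[:, index].copy(),
            sample_ids=list(self.sample_ids),
            snp_ids=self.snp_ids[index].copy(),
            chrom=self.chrom[index].copy(),
            pos=self.pos[index].copy(),
        )

    def drop_snps(self, snp_ids: Iterable[str]) -> "GenotypeMatrix":
        drop = set(self.snp_index(snp_ids).tolist())
        keep = np.array([i for i in range(self.n_snps) if i not in drop], dtype=np.int64)
        return self.take_snps(keep)

    def take_samples(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            genotypes=self.genotypes[index, :].copy(),
            sample_ids=[self.sample_ids[i] for i in index],
            snp_ids=self.snp_ids.copy(),
            chrom=self.chrom.copy(),
            pos=self.pos.copy(),
        )

    def sort_by_position(self) -> "GenotypeMatrix":
        """Return a copy sorted by (chromosome first-appearance order, position)."""
        chrom_rank = {c: i for i, c in enumerate(self.chromosomes())}
        order = np.lexsort((self.pos, np.array([chrom_rank[c] for c in self.chrom])))
        return self.take_snps(order)

    def with_genotypes(self, genotypes: np.ndarray) -> "GenotypeMatrix":
        return replace(self, genotypes=genotypes)

    def __eq__(self, other: object) -> bool:  # value equality, used in tests
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            np.array_equal(self.genotypes, other.genotypes)
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.snp_ids, other.snp_ids)
            and np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.pos, other.pos)
        )
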