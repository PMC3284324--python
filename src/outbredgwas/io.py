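"""Text-format genotype/phenotype I/O.

Supported formats: PLINK-style .ped/.map (alleles written as A/B, missing
as 0), a long-form genotype TSV (snp_id, chrom, pos, one column per sample
with dosages 0/1/2 or NA), a phenotype TSV keyed by sample id, square
kinship TSV, and an optional VCF import backed by cyvcf2.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix
from .structure import KinshipMatrix

_PED_GENO = {0: ("A", "A"), 1: ("A", "B"), 2: ("B", "B"), MISSING: ("0", "0")}


# --------------------------------------------------------------------------
# PLINK-style ped/map
# --------------------------------------------------------------------------

def write_ped_map(G: GenotypeMatrix, ped_path, map_path, phenotype: np.ndarray | None = None) -> None:
    with open(map_path, "w") as fh:
        for c, s, p in zip(G.chrom, G.snp_ids, G.pos):
            fh.write(f"{c}\t{s}\t0\t{p}\n")
    pheno = phenotype if phenotype is not None else np.full(G.n_samples, -9, dtype=object)
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(G.sample_ids):
            alleles = []
            for g in G.genotypes[i]:
                a, b = _PED_GENO[int(g)]
                alleles.append(a)
                alleles.append(b)
            fields = [sid, sid, "0", "0", "0", str(pheno[i])] + alleles
            fh.write("\t".join(fields) + "\n")


def read_ped_map(ped_path, map_path) -> GenotypeMatrix:
    mp = pd.read_csv(
        map_path, sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "pos"], dtype={"chrom": str, "snp_id": str},
    )
    sample_ids: list[str] = []
    rows: list[np.ndarray] = []
    m = len(mp)
    with open(ped_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise ValueError(
                    f"ped line for sample {parts[1] if len(parts) > 1 else '?'} has "
                    f"{len(parts) - 6} allele fields; expected {2 * m}"
                )
            sample_ids.append(parts[1])
            alleles = parts[6:]
            geno = np.empty(m, dtype=np.int8)
            for j in range(m):
                a, b = alleles[2 * j], alleles[2 * j + 1]
                if a == "0" or b == "0":
                    geno[j] = MISSING
                else:
                    geno[j] = (a != "A") + (b != "A")
            rows.append(geno)
    return GenotypeMatrix(
        np.vstack(rows), sample_ids,
        mp["snp_id"].to_numpy(dtype=object),
        mp["chrom"].to_numpy(dtype=object),
        mp["pos"].to_numpy(dtype=np.int64),
    )


# --------------------------------------------------------------------------
# genotype / phenotype / kinship tables
# --------------------------------------------------------------------------

def write_genotype_tsv(G: GenotypeMatrix, path) -> None:
    d = G.dosages().T
    df = pd.DataFrame(d, columns=G.sample_ids)
    df.insert(0, "pos", G.pos)
    df.insert(0, "chrom", G.chrom)
    df.insert(0, "snp_id", G.snp_ids)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.0f")


def read_genotype_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "snp_id": str})
    meta = ["snp_id", "chrom", "pos"]
    samples = [c for c in df.columns if c not in meta]
    vals = df[samples].to_numpy(dtype=float).T
    geno = np.where(np.isnan(vals), MISSING, vals).astype(np.int8)
    return GenotypeMatrix(
        geno, samples,
        df["snp_id"].to_numpy(dtype=object),
        df["chrom"].to_numpy(dtype=object),
        df["pos"].to_numpy(dtype=np.int64),
    )


def write_phenotype_tsv(sample_ids, traits: dict[str, np.ndarray], path) -> None:
    df = pd.DataFrame({"sample_id": list(sample_ids)})
    for name, vals in traits.items():
        df[name] = np.asarray(vals)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_phenotype_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValueError("phenotype file must have a sample_id column")
    return df.set_index("sample_id")


def write_kinship_tsv(K: KinshipMatrix, path) -> None:
    pd.DataFrame(K.matrix, index=K.sample_ids, columns=K.sample_ids).to_csv(path, sep="\t")


def read_kinship_tsv(path) -> KinshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return KinshipMatrix(df.to_numpy(dtype=float), [str(s) for s in df.columns])


# --------------------------------------------------------------------------
# optional VCF import
# --------------------------------------------------------------------------

def read_vcf(path) -> GenotypeMatrix:
    """Import dosages from the GT field of a VCF (requires cyvcf2)."""
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("VCF import requires the optional cyvcf2 dependency") from exc
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snp_ids, chrom, pos, rows = [], [], [], []
    # cyvcf2 gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
    remap = np.array([0, 1, MISSING, 2], dtype=np.int8)
    for i, var in enumerate(vcf):
        snp_ids.append(var.ID or f"{var.CHROM}_{var.POS}")
        chrom.append(str(var.CHROM))
        pos.append(int(var.POS))
        rows.append(remap[np.asarray(var.gt_types, dtype=np.int64)])
    geno = np.vstack(rows).T if rows else np.empty((len(samples), 0), dtype=np.int8)
    return GenotypeMatrix(geno, samples, np.array(snp_ids, dtype=object),
                          np.array(chrom, dtype=object), np.array(pos, dtype=np.int64))
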