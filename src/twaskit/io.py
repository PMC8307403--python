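"""Readers and writers for the plain-text interchange formats.

Genotypes travel either as a VCF 4.2 with a ``DS`` FORMAT field or as a pair
of TSVs (variant metadata + dosage matrix). Expression, phenotype, annotation
and known-variant tables are TSVs with header rows. All coordinates are
1-based inclusive.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 with per-sample DS (dosage) values.

    Variants are emitted sorted by (chrom, pos). Imputation quality is stored
    in INFO as ``RSQ``.
    """
    order = np.lexsort((gm.variants["pos"].to_numpy(), gm.variants["chrom"].to_numpy()))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=RSQ,Number=1,Type=Float,Description="Imputation R-squared">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Estimated alternate allele dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(gm.samples) + "\n")
        for j in order:
            v = gm.variants.iloc[j]
            ds = "\t".join(format(x, ".6f") for x in gm.dosage[:, j])
            fh.write(
                f"{v['chrom']}\t{int(v['pos'])}\t{v['id']}\t{v['ref']}\t{v['alt']}\t.\tPASS\t"
                f"RSQ={v['imput_rsq']:.6f}\tDS\t{ds}\n"
            )


def read_vcf(path, population: pd.Series | None = None) -> GenotypeMatrix:
    """Read a DS-field VCF into a :class:`GenotypeMatrix`.

    ``population`` optionally maps sample id -> population label; samples not
    listed get label ``"NA"``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, cols = [], []
    for var in vcf:
        rsq = var.INFO.get("RSQ")
        rows.append(
            {
                "id": var.ID,
                "chrom": var.CHROM,
                "pos": var.POS,
                "ref": var.REF,
                "alt": var.ALT[0],
                "imput_rsq": float(rsq) if rsq is not None else np.nan,
            }
        )
        cols.append(np.asarray(var.format("DS"), dtype=float).reshape(-1))
    vcf.close()
    dosage = np.column_stack(cols) if cols else np.zeros((len(samples), 0))
    if population is not None:
        pop = np.asarray([population.get(s, "NA") for s in samples], dtype=object)
    else:
        pop = np.asarray(["NA"] * len(samples), dtype=object)
    return GenotypeMatrix(samples=samples, variants=pd.DataFrame(rows), dosage=dosage, population=pop)


# ---------------------------------------------------------------------------
# Dosage TSV pair
# ---------------------------------------------------------------------------

def write_dosage_tsv(gm: GenotypeMatrix, prefix) -> None:
    """Write ``<prefix>.variants.tsv`` and ``<prefix>.dosage.tsv``.

    The dosage TSV is samples (rows) x variants (columns) with a ``sample``
    index column; the variants TSV carries all metadata columns.
    """
    prefix = str(prefix)
    gm.variants.to_csv(prefix + ".variants.tsv", sep="\t", index=False)
    df = pd.DataFrame(gm.dosage, index=pd.Index(gm.samples, name="sample"), columns=gm.variants["id"])
    df.insert(0, "population", gm.population)
    df.to_csv(prefix + ".dosage.tsv", sep="\t", float_format="%.6f")


def read_dosage_tsv(prefix) -> GenotypeMatrix:
    prefix = str(prefix)
    variants = pd.read_csv(prefix + ".variants.tsv", sep="\t", dtype={"chrom": str})
    df = pd.read_csv(prefix + ".dosage.tsv", sep="\t", index_col="sample")
    pop = df.pop("population").to_numpy(dtype=object)
    df = df[variants["id"]]
    return GenotypeMatrix(
        samples=[str(s) for s in df.index],
        variants=variants,
        dosage=df.to_numpy(dtype=float),
        population=pop,
    )


# ---------------------------------------------------------------------------
# Simple tables
# ---------------------------------------------------------------------------

def write_matrix_tsv(df: pd.DataFrame, path, index_name: str = "sample") -> None:
    df = df.copy()
    df.index.name = index_name
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_matrix_tsv(path, index_name: str = "sample") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = index_name
    return df


def write_annotation(annot: pd.DataFrame, path) -> None:
    """Gene annotation TSV: chrom, start, end, gene_id, strand (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("# coordinates: 1-based inclusive\n")
        annot[["chrom", "start", "end", "gene_id", "strand"]].to_csv(fh, sep="\t", index=False)


def read_annotation(path) -> pd.DataFrame:
    annot = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    if (annot["start"] > annot["end"]).any():
        raise ValueError("annotation rows with start > end")
    return annot


def write_known_variants(tbl: pd.DataFrame, path) -> None:
    tbl[["chrom", "pos", "ref", "alt", "trait", "source", "p"]].to_csv(path, sep="\t", index=False)


def read_known_variants(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
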