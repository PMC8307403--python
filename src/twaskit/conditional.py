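"""Two-step conditional analysis against known GWAS variants, and loci.

A marginally significant gene-trait pair is first re-tested with known
trait-associated variants within +/- 1 Mb of the gene as fixed covariates
(Step 1: "catalog" list). If it stays conditionally significant (p < 0.05),
or the catalog has no variants in the window, it is re-tested against
genome-wide-significant (p < 5e-8) variants from recent large GWAS (Step 2).
The final conditional p is the larger (less significant) of the step
p-values run; a pair with no known variants in either list is classed
``no_known_variants``.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import AdjustedPhenotype, ConditioningSet, GenotypeMatrix, Locus, SignalClass, TwasResult
from .association import EmmaxScan

CONDITIONAL_ALPHA = 0.05
RECENT_GWAS_P = 5e-8


def build_conditioning_set(
    gene: pd.Series,
    trait: str,
    known_variants: pd.DataFrame,
    genotypes: GenotypeMatrix,
    step: str,
    window_bp: int = 1_000_000,
    ld_prune_r: float = 0.95,
) -> ConditioningSet:
    """Trait-matched known variants within the gene's +/- 1 Mb window.

    ``step="recent_gwas"`` additionally requires source p < 5e-8. Listed
    variants absent from the genotypes are logged and skipped. The set is
    greedily LD-pruned at |r| > ``ld_prune_r`` (most significant source
    entry kept first) to stabilize the conditional GLS.
    """
    if step not in ("catalog", "recent_gwas"):
        raise ValueError(f"unknown step {step!r}")
    lo = int(gene["start"]) - window_bp
    hi = int(gene["end"]) + window_bp
    tbl = known_variants[
        (known_variants["trait"] == trait)
        & (known_variants["chrom"].astype(str) == str(gene["chrom"]))
        & (known_variants["pos"] >= lo)
        & (known_variants["pos"] <= hi)
    ].copy()
    if step == "recent_gwas":
        tbl = tbl[tbl["p"] < RECENT_GWAS_P]
    tbl = tbl.sort_values("p", kind="stable")

    pos_index: dict[tuple[str, int], int] = {}
    for i, (c, p) in enumerate(zip(genotypes.variants["chrom"].astype(str), genotypes.variants["pos"])):
        pos_index.setdefault((c, int(p)), i)
    cols, ids, dropped = [], [], []
    for _, row in tbl.iterrows():
        key = (str(row["chrom"]), int(row["pos"]))
        if key not in pos_index:
            dropped.append(f"{row['chrom']}:{row['pos']} absent from genotypes")
            continue
        j = pos_index[key]
        d = genotypes.dosage[:, j]
        if d.std() == 0:
            dropped.append(f"{row['chrom']}:{row['pos']} monomorphic")
            continue
        if any(abs(np.corrcoef(d, c)[0, 1]) > ld_prune_r for c in cols):
            dropped.append(f"{row['chrom']}:{row['pos']} LD-pruned")
            continue
        cols.append(d)
        ids.append(genotypes.variants["id"].iloc[j])
    dos = np.column_stack(cols) if cols else np.empty((genotypes.n_samples, 0))
    return ConditioningSet(
        gene_id=gene["gene_id"], trait=trait, step=step,
        variant_ids=ids, dosages=dos, window=(lo, hi), dropped=dropped,
    )


def conditional_association(
    predicted_expr_gene: pd.Series,
    adjusted_phenotype: AdjustedPhenotype | pd.Series,
    conditioning_dosages: np.ndarray,
    kinship: np.ndarray,
    cohort: str = "cohort",
    gene_id: str = "gene",
) -> TwasResult:
    """Gene effect re-tested with conditioning dosages as fixed covariates.

    Collinear conditioning columns are dropped to a full-rank basis inside
    the scan (with a warning); per-cohort conditional results can then be
    meta-analyzed exactly like the marginal ones.
    """
    pheno = adjusted_phenotype.values if isinstance(adjusted_phenotype, AdjustedPhenotype) else adjusted_phenotype
    conditioning_dosages = np.asarray(conditioning_dosages, dtype=float)
    if conditioning_dosages.ndim == 1:
        conditioning_dosages = conditioning_dosages[:, None]
    if conditioning_dosages.shape[1] == 0:
        raise ValueError("conditioning set is empty")
    if len(pheno) <= conditioning_dosages.shape[1] + 10:
        raise ValueError("too few samples for the conditioning set size")
    g = predicted_expr_gene.reindex(pheno.index).to_numpy(dtype=float)
    # degenerate case: gene fully collinear with the conditioning set
    X = np.column_stack([np.ones(len(g)), conditioning_dosages])
    coef, *_ = np.linalg.lstsq(X, g, rcond=None)
    if np.std(g - X @ coef) < 1e-10 * max(np.std(g), 1e-30):
        raise ValueError("predicted expression collinear with conditioning set")
    scan = EmmaxScan(pheno, kinship, covariates=conditioning_dosages, cohort=cohort).fit_null()
    return scan.test(g, gene_id=gene_id)


def classify_two_step(
    step1_p: float | None,
    step2_p: float | None,
    catalog_empty: bool,
    recent_empty: bool,
    alpha: float = CONDITIONAL_ALPHA,
) -> SignalClass:
    """Combine step p-values per the two-step rule (max of the steps run)."""
    gene_id = trait = ""  # filled by callers that know them
    if catalog_empty and recent_empty:
        return SignalClass(gene_id, trait, "no_known_variants", None, {})
    steps: dict[str, float] = {}
    if not catalog_empty:
        steps["catalog"] = float(step1_p)
        if step1_p >= alpha:
            return SignalClass(gene_id, trait, "explained_by_gwas", float(step1_p), steps)
    if not recent_empty:
        steps["recent_gwas"] = float(step2_p)
    final = max(steps.values())
    cls = "conditionally_distinct" if final < alpha else "explained_by_gwas"
    return SignalClass(gene_id, trait, cls, final, steps)


def two_step_conditional(
    gene: pd.Series,
    trait: str,
    predicted_expr_gene: pd.Series,
    adjusted_phenotype: AdjustedPhenotype | pd.Series,
    kinship: np.ndarray,
    catalog_variants: pd.DataFrame,
    recent_variants: pd.DataFrame,
    genotypes: GenotypeMatrix,
    cohort: str = "cohort",
    alpha: float = CONDITIONAL_ALPHA,
) -> SignalClass:
    """Run both conditioning steps for one gene-trait pair in one cohort."""
    sets = {
        "catalog": build_conditioning_set(gene, trait, catalog_variants, genotypes, "catalog"),
        "recent_gwas": build_conditioning_set(gene, trait, recent_variants, genotypes, "recent_gwas"),
    }

    def _p(cset: ConditioningSet) -> float | None:
        if cset.is_empty:
            return None
        res = conditional_association(
            predicted_expr_gene, adjusted_phenotype, cset.dosages, kinship,
            cohort=cohort, gene_id=gene["gene_id"],
        )
        return res.p

    p1 = _p(sets["catalog"])
    step1_sig = sets["catalog"].is_empty or (p1 is not None and p1 < alpha)
    p2 = _p(sets["recent_gwas"]) if step1_sig else None
    out = classify_two_step(
        p1, p2,
        catalog_empty=sets["catalog"].is_empty,
        recent_empty=sets["recent_gwas"].is_empty or p2 is None,
        alpha=alpha,
    )
    out.gene_id = gene["gene_id"]
    out.trait = trait
    return out


def define_loci(
    significant: pd.DataFrame,
    annotation: pd.DataFrame,
    window_bp: int = 1_000_000,
) -> list[Locus]:
    """Greedy sentinel-first locus assignment.

    ``significant`` needs gene_id and p columns. Genes are sorted by p
    ascending; each unassigned gene founds a locus spanning its start - 1 Mb
    to end + 1 Mb, and every remaining unassigned gene overlapping those
    bounds on the same chromosome joins it. The result is a partition of the
    significant genes.
    """
    if significant.empty:
        raise ValueError("no significant genes")
    annot = annotation.set_index("gene_id")
    ordered = significant.sort_values("p", kind="stable")["gene_id"].drop_duplicates().tolist()
    unassigned = set(ordered)
    loci: list[Locus] = []
    for gid in ordered:
        if gid not in unassigned:
            continue
        g = annot.loc[gid]
        lo, hi = int(g["start"]) - window_bp, int(g["end"]) + window_bp
        members = [
            m for m in ordered
            if m in unassigned
            and str(annot.loc[m, "chrom"]) == str(g["chrom"])
            and int(annot.loc[m, "end"]) >= lo
            and int(annot.loc[m, "start"]) <= hi
        ]
        unassigned -= set(members)
        loci.append(Locus(sentinel_gene=gid, chrom=str(g["chrom"]), start=lo, end=hi, member_genes=members))
    return loci
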