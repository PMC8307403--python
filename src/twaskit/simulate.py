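"""Synthetic genotype / expression / phenotype generator.

The generator reproduces the statistical structure the downstream analysis
assumes, with a ground-truth record so recovery can be checked:

* two (or more) ancestry groups whose allele frequencies diverge under the
  Balding–Nichols model at a specified FST;
* blockwise linkage disequilibrium from a first-order autoregressive latent
  Gaussian process thresholded at each variant's frequency quantile (marginal
  frequencies are preserved exactly; within-block dosage correlation is
  tunable);
* sparse cis-eQTL architecture: a few causal variants per gene inside its
  +/- 1 Mb window, Gaussian residual noise scaled so the realized cis
  heritability matches the request;
* four blood-cell traits (HGB g/dL, HCT %, WBC 1e9/L, PLT 1e9/L) combining
  expression-mediated genetic effects, age/sex/PC covariate effects and
  noise; WBC is generated on the log scale (right-skewed) with one designated
  Duffy-like large-effect variant; rare extreme outliers exceed the
  downstream exclusion bounds.

All randomness flows from the single ``seed`` argument of each operation.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import TRAITS, GenotypeMatrix, SyntheticTruth
from . import io as tio

# trait exclusion bounds applied downstream (strict inequalities): value > bound
EXCLUSION_BOUNDS = {"WBC": 200.0, "HCT": 60.0, "HGB": 20.0}

# natural-scale trait location/scale used to map standardized liabilities to units
TRAIT_SCALE = {
    "HGB": (13.5, 1.4),   # g/dL
    "HCT": (40.0, 3.5),   # %
    "PLT": (250.0, 60.0), # 1e9/L
    "WBC": (np.log(6.5), 0.35),  # log 1e9/L
}

_BASES = np.array(list("ACGT"))


def _balding_nichols_freqs(rng, p_anc: np.ndarray, fst: float, n_pop: int) -> np.ndarray:
    """Per-population frequencies: Beta(p(1-F)/F, (1-p)(1-F)/F) around p_anc."""
    if fst == 0:
        return np.tile(p_anc, (n_pop, 1))
    a = p_anc * (1 - fst) / fst
    b = (1 - p_anc) * (1 - fst) / fst
    f = rng.beta(a[None, :].repeat(n_pop, 0), b[None, :].repeat(n_pop, 0))
    return np.clip(f, 1e-4, 1 - 1e-4)


def _ar1_haplotypes(rng, n_hap: int, freqs: np.ndarray, block_size: int, rho: float) -> np.ndarray:
    """Haplotype alleles from a blockwise AR(1) latent Gaussian copula.

    Within each block the latent series follows z_j = rho * z_{j-1} +
    sqrt(1-rho^2) * e_j; blocks are independent. Allele_j = 1 iff
    z_j < Phi^{-1}(freq_j), so each variant keeps its marginal frequency.
    """
    m = len(freqs)
    z = np.empty((n_hap, m))
    for start in range(0, m, block_size):
        stop = min(start + block_size, m)
        z[:, start] = rng.standard_normal(n_hap)
        for j in range(start + 1, stop):
            z[:, j] = rho * z[:, j - 1] + np.sqrt(1 - rho**2) * rng.standard_normal(n_hap)
    thresh = stats.norm.ppf(freqs)
    return (z < thresh[None, :]).astype(float)


def simulate_ld_genotypes(
    n_samples_by_pop: dict[str, int],
    n_variants: int,
    block_size: int = 50,
    fst: float = 0.05,
    maf_range: tuple[float, float] = (0.05, 0.5),
    rho: float = 0.7,
    chrom: str = "1",
    pos_start: int = 1,
    pos_step: int = 2000,
    imput_rsq_range: tuple[float, float] = (0.2, 1.0),
    sample_prefix: str = "S",
    seed: int = 0,
) -> GenotypeMatrix:
    """Simulate LD-blocked dosages for one or more populations.

    Ancestral frequencies are Uniform over ``maf_range``; per-population
    frequencies follow the Balding–Nichols construction at the given ``fst``.
    Per-variant imputation-quality scores are Uniform over
    ``imput_rsq_range`` so downstream quality filters have bite.
    """
    if n_variants <= 0 or any(n <= 0 for n in n_samples_by_pop.values()):
        raise ValueError("sample and variant counts must be positive")
    if block_size <= 0:
        raise ValueError("block_size must be positive (empty blocks not allowed)")
    if not (0 <= fst < 1):
        raise ValueError("fst must lie in [0, 1)")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must be within (0, 0.5]")

    rng = np.random.default_rng(seed)
    pops = list(n_samples_by_pop)
    p_anc = rng.uniform(lo, hi, size=n_variants)
    pop_freqs = _balding_nichols_freqs(rng, p_anc, fst, len(pops))

    dosages, sample_ids, pop_labels = [], [], []
    for k, pop in enumerate(pops):
        n = n_samples_by_pop[pop]
        h1 = _ar1_haplotypes(rng, n, pop_freqs[k], block_size, rho)
        h2 = _ar1_haplotypes(rng, n, pop_freqs[k], block_size, rho)
        dosages.append(h1 + h2)
        sample_ids += [f"{sample_prefix}_{pop}_{i:05d}" for i in range(n)]
        pop_labels += [pop] * n

    dosage = np.vstack(dosages)
    ref = rng.choice(4, size=n_variants)
    alt = (ref + rng.integers(1, 4, size=n_variants)) % 4
    pos = pos_start + pos_step * np.arange(n_variants)
    variants = pd.DataFrame(
        {
            "id": [f"{chrom}:{p}:{_BASES[r]}:{_BASES[a]}" for p, r, a in zip(pos, ref, alt)],
            "chrom": chrom,
            "pos": pos,
            "ref": _BASES[ref],
            "alt": _BASES[alt],
            "imput_rsq": rng.uniform(*imput_rsq_range, size=n_variants),
        }
    )
    for k, pop in enumerate(pops):
        variants[f"maf_{pop}"] = np.minimum(pop_freqs[k], 1 - pop_freqs[k])
    return GenotypeMatrix(
        samples=sample_ids, variants=variants, dosage=dosage, population=np.array(pop_labels, dtype=object)
    )


def make_gene_annotation(
    gene_positions: list[tuple[str, int, int]] | None = None,
    chrom: str = "1",
    n_genes: int = 10,
    spacing: int = 2_500_000,
    start: int = 500_000,
    length: int = 50_000,
) -> pd.DataFrame:
    """Gene annotation table, either explicit or evenly spaced on one chromosome."""
    if gene_positions is None:
        gene_positions = [(chrom, start + i * spacing, start + i * spacing + length) for i in range(n_genes)]
    n = len(gene_positions)
    return pd.DataFrame(
        {
            "gene_id": [f"GENE{i:04d}" for i in range(n)],
            "chrom": [g[0] for g in gene_positions],
            "start": [g[1] for g in gene_positions],
            "end": [g[2] for g in gene_positions],
            "strand": (["+", "-"] * n)[:n],
        }
    )


def cis_window_mask(gene: pd.Series, variants: pd.DataFrame, window_bp: int = 1_000_000) -> np.ndarray:
    """Boolean mask of variants within +/- window of the gene's start/end."""
    return (
        (variants["chrom"].to_numpy() == gene["chrom"])
        & (variants["pos"].to_numpy() >= int(gene["start"]) - window_bp)
        & (variants["pos"].to_numpy() <= int(gene["end"]) + window_bp)
    )


def simulate_cis_architecture(
    genotypes: GenotypeMatrix,
    genes: pd.DataFrame,
    n_causal_per_gene: int = 3,
    h2_cis: float = 0.3,
    effect_dist: str = "fixed",
    window_bp: int = 1_000_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate expression with a sparse cis-eQTL architecture.

    expression = X_c beta + e, with the noise variance chosen per gene so the
    realized cis variance fraction equals ``h2_cis``. Causal effects default
    to equal magnitude on the standardized-genotype scale with random signs
    (``effect_dist="fixed"``), so each causal variant carries an equal share
    of the requested heritability; ``"normal"`` draws N(0,1) standardized
    effects instead.
    """
    if not (0 <= h2_cis < 1):
        raise ValueError("h2_cis must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    n = genotypes.n_samples
    expr = np.empty((n, len(genes)))
    truth = SyntheticTruth(seed=seed)

    for gi, (_, gene) in enumerate(genes.iterrows()):
        mask = cis_window_mask(gene, genotypes.variants, window_bp)
        cis_idx = np.flatnonzero(mask)
        if cis_idx.size == 0:
            raise ValueError(f"gene {gene['gene_id']} has no cis variants")
        n_causal = min(n_causal_per_gene, cis_idx.size)
        causal = np.sort(rng.choice(cis_idx, size=n_causal, replace=False))
        X = genotypes.dosage[:, causal]
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        if effect_dist == "fixed":
            beta_std = rng.choice([-1.0, 1.0], size=n_causal)
        elif effect_dist == "normal":
            beta_std = rng.standard_normal(n_causal)
        else:
            raise ValueError(f"unknown effect_dist {effect_dist!r}")
        beta = beta_std / sd  # dosage-scale effects
        if h2_cis == 0:
            beta = np.zeros_like(beta)
            g = np.zeros(n)
            e = rng.standard_normal(n)
        else:
            g = X @ beta
            g = g - g.mean()
            vg = g.var()
            e = rng.standard_normal(n) * np.sqrt(vg * (1 - h2_cis) / h2_cis)
        expr[:, gi] = g + e
        truth.genes[gene["gene_id"]] = {
            "causal_ids": genotypes.variants["id"].iloc[causal].tolist(),
            "effects": beta,
            "h2_cis": h2_cis,
        }

    expr_df = pd.DataFrame(expr, index=pd.Index(genotypes.samples, name="sample"), columns=genes["gene_id"])
    return expr_df, truth


def expression_from_truth(
    genotypes: GenotypeMatrix,
    truth: SyntheticTruth,
    seed: int = 0,
) -> pd.DataFrame:
    """Realize expression in a (new) cohort from an existing truth record.

    Uses the stored dosage-scale causal effects; per-gene noise is rescaled
    so the realized cis variance fraction in this cohort matches the
    recorded h2_cis.
    """
    rng = np.random.default_rng(seed)
    n = genotypes.n_samples
    cols = {}
    for gene_id, rec in truth.genes.items():
        h2 = float(rec["h2_cis"])
        X = genotypes.dosages_for(list(rec["causal_ids"]))
        g = X @ np.asarray(rec["effects"], dtype=float)
        g = g - g.mean()
        if h2 == 0 or g.var() == 0:
            cols[gene_id] = rng.standard_normal(n)
        else:
            e = rng.standard_normal(n) * np.sqrt(g.var() * (1 - h2) / h2)
            cols[gene_id] = g + e
    return pd.DataFrame(cols, index=pd.Index(genotypes.samples, name="sample"))


def genetic_expression_score(genotypes: GenotypeMatrix, truth: SyntheticTruth, gene_id: str) -> np.ndarray:
    """Centered cis-genetic expression value of a gene in a (possibly new) cohort."""
    rec = truth.genes[gene_id]
    X = genotypes.dosages_for(list(rec["causal_ids"]))
    g = X @ np.asarray(rec["effects"], dtype=float)
    return g - g.mean()


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    truth: SyntheticTruth,
    gene_trait_effects: dict[str, dict[str, float]] | None = None,
    covariate_effects: dict[str, dict[str, float]] | None = None,
    duffy_variant: str | None = None,
    duffy_effect: float = -0.3,
    trait_h2_env: float = 0.6,
    outlier_rate: float = 0.001,
    n_pcs: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate the four blood-cell traits plus covariates for a cohort.

    Each trait's standardized liability is the sum of expression-mediated
    genetic effects (gene-trait effect times the standardized cis-genetic
    expression score), covariate effects (age, sex and genotype PCs computed
    from the cohort dosages) and Gaussian noise with standard deviation
    ``sqrt(trait_h2_env)``. HGB/HCT/PLT are mapped linearly to natural units;
    WBC is built on the log scale and exponentiated, with the Duffy-like
    variant contributing ``duffy_effect`` per alternate allele to log WBC.
    With probability ``outlier_rate`` a sample's HGB/HCT/WBC value is replaced
    by one exceeding the downstream exclusion bound.
    """
    rng = np.random.default_rng(seed)
    gene_trait_effects = gene_trait_effects or {}
    covariate_effects = covariate_effects or {}
    n = genotypes.n_samples

    for trait, eff in gene_trait_effects.items():
        for g in eff:
            if g not in truth.genes:
                raise KeyError(f"gene {g} in gene_trait_effects not present in truth")
    if duffy_variant is not None and duffy_variant not in set(genotypes.variants["id"]):
        raise KeyError(f"duffy variant {duffy_variant} not in genotypes")

    age = rng.uniform(25, 75, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    # genotype PCs from the centered dosage matrix (captures ancestry structure)
    Xc = genotypes.dosage - genotypes.dosage.mean(axis=0)
    n_pc_avail = min(n_pcs, min(Xc.shape) - 1)
    u, s, _ = np.linalg.svd(Xc, full_matrices=False)
    pcs = u[:, :n_pc_avail] * s[:n_pc_avail]
    pcs = np.hstack([pcs, np.zeros((n, n_pcs - n_pc_avail))])
    pcs = (pcs - pcs.mean(axis=0)) / np.where(pcs.std(axis=0) == 0, 1, pcs.std(axis=0))

    cov_table = {"age": (age - age.mean()) / age.std(), "sex": sex - sex.mean()}
    for j in range(n_pcs):
        cov_table[f"PC{j + 1}"] = pcs[:, j]

    pheno = pd.DataFrame(index=pd.Index(genotypes.samples, name="sample"))
    pheno["population"] = genotypes.population
    pheno["age"] = age
    pheno["sex"] = sex
    for j in range(n_pcs):
        pheno[f"PC{j + 1}"] = pcs[:, j]

    for trait in TRAITS:
        liab = np.zeros(n)
        for gene_id, beta in gene_trait_effects.get(trait, {}).items():
            g = genetic_expression_score(genotypes, truth, gene_id)
            sd = g.std()
            if sd > 0:
                liab += beta * g / sd
        for cov, beta in covariate_effects.get(trait, {}).items():
            liab += beta * cov_table[cov]
        if trait == "WBC" and duffy_variant is not None:
            liab = liab + duffy_effect * genotypes.dosages_for([duffy_variant])[:, 0]
        noise_sd = np.sqrt(trait_h2_env)
        liab = liab + rng.standard_normal(n) * noise_sd
        loc, scale = TRAIT_SCALE[trait]
        if trait == "WBC":
            values = np.exp(loc + scale * liab)
        else:
            values = loc + scale * liab
        if trait in EXCLUSION_BOUNDS and outlier_rate > 0:
            hit = rng.random(n) < outlier_rate
            bound = EXCLUSION_BOUNDS[trait]
            values[hit] = bound * rng.uniform(1.05, 1.5, size=hit.sum())
        pheno[trait] = values
        truth.traits[trait] = {
            "gene_effects": gene_trait_effects.get(trait, {}),
            "covariate_effects": covariate_effects.get(trait, {}),
            "duffy_variant": duffy_variant if trait == "WBC" else None,
            "duffy_effect": duffy_effect if trait == "WBC" else 0.0,
            "noise_sd": noise_sd,
        }
    return pheno


def simulate_known_variants(
    genotypes: GenotypeMatrix,
    truth: SyntheticTruth,
    traits: list[str] | None = None,
    mode: str = "decoys",
    n_decoys: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Emit a synthetic known-variant ("GWAS catalog") table from truth + decoys.

    ``mode="causal"`` tags every causal eQTL of every trait-associated gene;
    ``mode="decoys"`` lists only random non-causal variants, so conditional
    analysis should leave truth signals intact.
    """
    rng = np.random.default_rng(seed)
    traits = traits or list(TRAITS)
    causal_ids = truth.all_causal_variants()
    rows = []
    vidx = genotypes.variants.set_index("id")
    if mode in ("causal", "both"):
        for trait in traits:
            for gene_id in truth.traits.get(trait, {}).get("gene_effects", {}):
                for vid in truth.causal_variants(gene_id):
                    v = vidx.loc[vid]
                    rows.append(
                        {
                            "chrom": v["chrom"], "pos": int(v["pos"]), "ref": v["ref"], "alt": v["alt"],
                            "trait": trait, "source": "catalog", "p": 1e-12,
                        }
                    )
    if mode in ("decoys", "both"):
        decoy_pool = [v for v in genotypes.variants["id"] if v not in causal_ids]
        for trait in traits:
            for vid in rng.choice(decoy_pool, size=min(n_decoys, len(decoy_pool)), replace=False):
                v = vidx.loc[vid]
                rows.append(
                    {
                        "chrom": v["chrom"], "pos": int(v["pos"]), "ref": v["ref"], "alt": v["alt"],
                        "trait": trait, "source": "catalog", "p": 10 ** rng.uniform(-12, -8),
                    }
                )
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "trait", "source", "p"])


def write_fixtures(
    genotypes: GenotypeMatrix,
    expression: pd.DataFrame | None,
    phenotypes: pd.DataFrame | None,
    annotation: pd.DataFrame,
    truth: SyntheticTruth | None,
    outdir,
    vcf: bool = True,
) -> dict[str, str]:
    """Write the fixture file set; round-trips losslessly through the readers."""
    out = tio.ensure_dir(outdir)
    if expression is not None and list(expression.index) != list(genotypes.samples):
        raise ValueError("expression sample ids do not match genotypes")
    if phenotypes is not None and list(phenotypes.index) != list(genotypes.samples):
        raise ValueError("phenotype sample ids do not match genotypes")
    paths: dict[str, str] = {}
    if vcf:
        paths["vcf"] = str(out / "genotypes.vcf")
        tio.write_vcf(genotypes, paths["vcf"])
        pd.DataFrame({"sample": genotypes.samples, "population": genotypes.population}).to_csv(
            out / "samples.tsv", sep="\t", index=False
        )
        paths["samples"] = str(out / "samples.tsv")
    else:
        tio.write_dosage_tsv(genotypes, out / "genotypes")
        paths["dosage_prefix"] = str(out / "genotypes")
    if expression is not None:
        paths["expression"] = str(out / "expression.tsv")
        tio.write_matrix_tsv(expression, paths["expression"])
    if phenotypes is not None:
        paths["phenotypes"] = str(out / "phenotypes.tsv")
        tio.write_matrix_tsv(phenotypes, paths["phenotypes"])
    paths["annotation"] = str(out / "genes.tsv")
    tio.write_annotation(annotation, paths["annotation"])
    if truth is not None:
        paths["truth"] = str(out / "truth.json")
        truth.to_json(paths["truth"])
    return paths
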