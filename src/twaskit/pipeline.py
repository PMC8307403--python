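"""End-to-end discovery orchestration and the two-tier replication protocol.

``run_discovery`` drives the seven discovery stages — simulate, train,
predict, associate, meta-analyze (with ACAT aggregation), conditional
analysis, fine-mapping — on synthetic cohorts whose ground truth is kept for
validation, writing a per-stage manifest. ``run_replication`` retrains the
large panel under stricter variant filters for an external replication
cohort and routes each signal through the two replication tiers.
"""
from __future__ import annotations

import hashlib
import pickle
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .association import (
    EmmaxScan,
    acat_combine,
    compute_kinship,
    meta_analyze_table,
    prepare_phenotype,
)
from .conditional import build_conditioning_set, classify_two_step, conditional_association, define_loci
from .datatypes import TRAITS, GenotypeMatrix, SyntheticTruth, WeightModel
from .expression import adjust_expression, filter_models, train_panel
from .finemap import expression_correlation, finemap_locus
from .predict import predict_expression
from .simulate import (
    make_gene_annotation,
    simulate_cis_architecture,
    expression_from_truth,
    simulate_known_variants,
    simulate_ld_genotypes,
    simulate_phenotypes,
)

STAGES = ["simulate", "train", "predict", "associate", "meta", "conditional", "finemap"]


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Bonferroni-corrected per-test significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


@dataclass
class PipelineConfig:
    """Study-design knobs with defaults mirroring the discovery protocol.

    Thresholds: training variants need MAF > 0.05 and imputation R2 > 0.3
    (0.8 for replication retraining); genes need model R2 >= 0.05; the
    suggestive meta-analysis screen is p < 1e-4; conditional significance
    uses the lenient 0.05; tier-2 replication triggers below model R2 0.01.
    """

    seed: int = 0
    # reference panels: name -> (population, n)
    panels: dict = field(default_factory=lambda: {
        "PANEL_EA": {"population": "EA", "n": 350},
        "PANEL_AA": {"population": "AA", "n": 220},
        "PANEL_HL": {"population": "HL", "n": 240},
    })
    # GWAS cohorts: name -> (population/ancestry, n)
    cohorts: dict = field(default_factory=lambda: {
        "AA1": {"population": "AA", "n": 600},
        "AA2": {"population": "AA", "n": 600},
        "HL1": {"population": "HL", "n": 600},
        "HL2": {"population": "HL", "n": 600},
    })
    # which panel predicts into which ancestry (panel, ancestry) analysis sets
    analysis_sets: list = field(default_factory=lambda: [
        ("PANEL_EA", "AA"), ("PANEL_EA", "HL"), ("PANEL_AA", "AA"), ("PANEL_HL", "HL"),
    ])
    # thresholds
    maf_min: float = 0.05
    rsq_train: float = 0.3
    rsq_replication: float = 0.8
    model_r2_min: float = 0.05
    suggestive_p: float = 1e-4
    conditional_alpha: float = 0.05
    tier2_model_r2: float = 0.01
    alpha: float = 0.05
    n_folds: int = 10
    mixing_alpha: float = 0.5
    n_hidden_factors: int = 10
    window_bp: int = 1_000_000
    finemap_k_max: int = 3
    # simulation design
    fst: float = 0.05
    block_size: int = 50
    ld_rho: float = 0.7
    pos_step: int = 20_000
    n_single_loci: int = 12
    n_clusters: int = 2
    cluster_size: int = 3
    h2_cis: float = 0.3
    n_causal_per_gene: int = 3
    gene_trait_effect: float = 0.2
    n_causal_pairs: int = 10
    covariate_effects: dict = field(default_factory=lambda: {
        t: {"age": 0.2, "sex": 0.3, "PC1": 0.1} for t in TRAITS
    })
    duffy_effect: float = -0.3
    outlier_rate: float = 0.001
    shared_cluster_eqtls: int = 2  # causal variants shared within a gene cluster
    known_variants_mode: str = "decoys"
    n_decoys: int = 80
    replication_n: int = 1500
    replication_population: str = "EA"

    def validate(self) -> "PipelineConfig":
        for name, v in [
            ("maf_min", self.maf_min), ("rsq_train", self.rsq_train),
            ("rsq_replication", self.rsq_replication), ("model_r2_min", self.model_r2_min),
            ("suggestive_p", self.suggestive_p), ("conditional_alpha", self.conditional_alpha),
            ("tier2_model_r2", self.tier2_model_r2), ("alpha", self.alpha),
        ]:
            if not (0 < v < 1):
                raise ValueError(f"threshold {name}={v} outside (0, 1)")
        return self

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "analysis_sets" in d:
            d["analysis_sets"] = [tuple(x) for x in d["analysis_sets"]]
        return cls(**d).validate()

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["analysis_sets"] = [list(x) for x in self.analysis_sets]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def _digest(obj) -> str:
    if isinstance(obj, pd.DataFrame):
        data = pd.util.hash_pandas_object(obj, index=True).to_numpy().tobytes()
    elif isinstance(obj, np.ndarray):
        data = np.ascontiguousarray(obj).tobytes()
    else:
        data = repr(obj).encode()
    return hashlib.sha256(data).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Stage 1: simulation
# ---------------------------------------------------------------------------

def _gene_layout(cfg: PipelineConfig) -> pd.DataFrame:
    """Single-gene loci spaced far apart plus a few clustered multi-gene loci."""
    spacing, gene_len, gap = 2_500_000, 50_000, 200_000
    positions = []
    pos = 1_200_000
    for _ in range(cfg.n_single_loci):
        positions.append(("1", pos, pos + gene_len))
        pos += spacing
    for _ in range(cfg.n_clusters):
        for k in range(cfg.cluster_size):
            positions.append(("1", pos + k * gap, pos + k * gap + gene_len))
        pos += spacing
    return make_gene_annotation(gene_positions=positions)


def simulate_study(cfg: PipelineConfig) -> dict:
    """Generate panels, cohorts, phenotypes, truth and known-variant tables."""
    rng = np.random.default_rng(cfg.seed)
    annot = _gene_layout(cfg)
    span = int(annot["end"].max()) + 1_200_000
    n_variants = span // cfg.pos_step + 1

    n_by_pop: dict[str, int] = {}
    for entry in list(cfg.panels.values()) + list(cfg.cohorts.values()):
        n_by_pop[entry["population"]] = n_by_pop.get(entry["population"], 0) + entry["n"]
    n_by_pop[cfg.replication_population] = (
        n_by_pop.get(cfg.replication_population, 0) + cfg.replication_n
    )
    master = simulate_ld_genotypes(
        n_by_pop, n_variants, block_size=cfg.block_size, fst=cfg.fst,
        rho=cfg.ld_rho, pos_step=cfg.pos_step, seed=int(rng.integers(2**31)),
    )

    # carve per-panel / per-cohort sample subsets out of each population
    offsets = {p: 0 for p in n_by_pop}
    pop_idx = {p: np.flatnonzero(master.population == p) for p in n_by_pop}

    # per-cohort imputation quality: a shared per-variant base score (quality
    # tracks the variant, not the cohort) plus small cohort-specific jitter
    base_rsq = master.variants["imput_rsq"].to_numpy()

    def _take(pop: str, n: int) -> GenotypeMatrix:
        sl = pop_idx[pop][offsets[pop]: offsets[pop] + n]
        offsets[pop] += n
        gm = master.subset_samples(sl)
        gm.variants = gm.variants.copy()
        gm.variants["imput_rsq"] = np.clip(base_rsq + rng.uniform(-0.05, 0.05, size=gm.n_variants), 0.0, 1.0)
        return gm

    panels = {name: _take(s["population"], s["n"]) for name, s in cfg.panels.items()}
    cohorts = {name: _take(s["population"], s["n"]) for name, s in cfg.cohorts.items()}
    replication_geno = _take(cfg.replication_population, cfg.replication_n)

    # training requires variants well-imputed in the panel and all cohorts:
    # fold the minimum across-cohort quality into each panel's variant table
    min_rsq = np.min(
        np.vstack([gm.variants["imput_rsq"].to_numpy() for gm in cohorts.values()]), axis=0
    )
    for gm in panels.values():
        gm.variants["imput_rsq"] = np.minimum(gm.variants["imput_rsq"].to_numpy(), min_rsq)

    # shared cis-eQTL architecture drawn once, expression realized per panel
    first_panel = next(iter(panels.values()))
    _, truth = simulate_cis_architecture(
        first_panel, annot, n_causal_per_gene=cfg.n_causal_per_gene,
        h2_cis=cfg.h2_cis, seed=int(rng.integers(2**31)),
    )
    # clustered genes share part of their causal set with the cluster's first
    # gene (shared cis-eQTLs make the cluster co-significant, which is what
    # gives fine-mapping multi-gene loci to work on)
    n_shared = min(cfg.shared_cluster_eqtls, cfg.n_causal_per_gene)
    for c in range(cfg.n_clusters):
        base = cfg.n_single_loci + c * cfg.cluster_size
        lead = annot["gene_id"].iloc[base]
        lead_rec = truth.genes[lead]
        for k in range(1, cfg.cluster_size):
            gid = annot["gene_id"].iloc[base + k]
            rec = truth.genes[gid]
            ids = list(lead_rec["causal_ids"][:n_shared]) + list(rec["causal_ids"][n_shared:])
            own = master.dosages_for(ids[n_shared:])
            sd = np.where(own.std(axis=0) == 0, 1.0, own.std(axis=0))
            rec["causal_ids"] = ids
            # shared eQTLs act with the lead gene's effect (same direction);
            # the remaining private variants keep random signs
            rec["effects"] = np.concatenate([
                np.asarray(lead_rec["effects"][:n_shared], dtype=float),
                rng.choice([-1.0, 1.0], size=len(ids) - n_shared) / sd,
            ])
    panel_expr = {
        name: expression_from_truth(gm, truth, seed=int(rng.integers(2**31)))
        for name, gm in panels.items()
    }

    # gene-trait effects: single-locus genes first, then one gene per cluster
    gene_ids = annot["gene_id"].tolist()
    cluster_first = [gene_ids[cfg.n_single_loci + c * cfg.cluster_size] for c in range(cfg.n_clusters)]
    causal_genes = (gene_ids[: cfg.n_causal_pairs - cfg.n_clusters] + cluster_first)[: cfg.n_causal_pairs]
    gene_trait_effects: dict[str, dict[str, float]] = {t: {} for t in TRAITS}
    for i, g in enumerate(causal_genes):
        trait = TRAITS[i % len(TRAITS)]
        gene_trait_effects[trait][g] = cfg.gene_trait_effect * (1 if i % 2 == 0 else -1)

    # Duffy-like WBC variant: nearest variant to a trait-null gene's start
    null_gene = annot.iloc[cfg.n_causal_pairs % len(annot)]
    duffy = master.variants.iloc[
        (master.variants["pos"] - int(null_gene["start"])).abs().idxmin()
    ]["id"]

    panel_cov = {
        name: simulate_phenotypes(gm, SyntheticTruth(genes=truth.genes), seed=int(rng.integers(2**31)))
        for name, gm in panels.items()
    }
    cohort_pheno = {
        name: simulate_phenotypes(
            gm, truth, gene_trait_effects=gene_trait_effects,
            covariate_effects=cfg.covariate_effects, duffy_variant=duffy,
            duffy_effect=cfg.duffy_effect, outlier_rate=cfg.outlier_rate,
            seed=int(rng.integers(2**31)),
        )
        for name, gm in cohorts.items()
    }
    known = {
        "catalog": simulate_known_variants(
            master, truth, mode=cfg.known_variants_mode, n_decoys=cfg.n_decoys,
            seed=int(rng.integers(2**31)),
        ),
        "recent_gwas": simulate_known_variants(
            master, truth, mode=cfg.known_variants_mode, n_decoys=cfg.n_decoys,
            seed=int(rng.integers(2**31)),
        ),
    }
    replication_pheno = simulate_phenotypes(
        replication_geno, truth, gene_trait_effects=gene_trait_effects,
        covariate_effects=cfg.covariate_effects, duffy_variant=duffy,
        duffy_effect=cfg.duffy_effect, outlier_rate=cfg.outlier_rate,
        seed=int(rng.integers(2**31)),
    )
    return {
        "annotation": annot, "truth": truth, "panels": panels, "panel_expr": panel_expr,
        "panel_cov": panel_cov, "cohorts": cohorts, "cohort_pheno": cohort_pheno,
        "known": known, "gene_trait_effects": gene_trait_effects, "duffy_variant": duffy,
        "replication": {"genotypes": replication_geno, "phenotypes": replication_pheno},
        "master": master,
    }


# ---------------------------------------------------------------------------
# Discovery
# ---------------------------------------------------------------------------

def run_discovery(cfg: PipelineConfig, outdir=None, resume: bool = False) -> dict:
    """Execute the seven discovery stages; returns the results bundle.

    With ``outdir`` set, each stage's outputs are cached (pickle) and key
    tables exported as TSV; ``resume=True`` reloads completed stages instead
    of recomputing them. The manifest records stage name, seed, a content
    digest and row counts; stage failures abort with the stage named.
    """
    cfg.validate()
    out = tio.ensure_dir(outdir) if outdir is not None else None
    manifest: list[dict] = []
    bundle: dict = {"config": cfg}

    def _cache(stage: str):
        return None if out is None else out / f"stage_{stage}.pkl"

    def _run(stage: str, fn):
        cache = _cache(stage)
        if resume and cache is not None and cache.exists():
            with open(cache, "rb") as fh:
                result, entry = pickle.load(fh)
            entry = {**entry, "resumed": True}
        else:
            try:
                result, entry = fn()
            except Exception as exc:  # noqa: BLE001
                raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
            entry = {"stage": stage, "seed": cfg.seed, **entry, "resumed": False}
            if cache is not None:
                with open(cache, "wb") as fh:
                    pickle.dump((result, entry), fh)
        manifest.append(entry)
        return result

    # 1 -- simulate
    def _simulate():
        data = simulate_study(cfg)
        return data, {
            "digest": _digest(data["master"].dosage),
            "rows": {"variants": data["master"].n_variants, "samples": data["master"].n_samples,
                     "genes": len(data["annotation"])},
        }

    data = _run("simulate", _simulate)
    bundle["data"] = data
    annot, truth = data["annotation"], data["truth"]

    # 2 -- train expression models per panel
    def _train():
        models: dict[str, list[WeightModel]] = {}
        counts = {}
        # hidden-factor count capped by gene count: with only a few dozen
        # simulated genes, PCs of the residual expression matrix would soak
        # up cis-genetic signal rather than shared technical variation
        k_hidden = min(cfg.n_hidden_factors, len(annot) // 6)
        for name, gm in data["panels"].items():
            covs = data["panel_cov"][name][["age", "sex"] + [f"PC{i}" for i in range(1, 11)]]
            adj = adjust_expression(data["panel_expr"][name], covs, k_hidden)
            trained, untrainable = train_panel(
                adj, gm, annot, window_bp=cfg.window_bp, maf_min=cfg.maf_min,
                rsq_min=cfg.rsq_train, mixing_alpha=cfg.mixing_alpha,
                n_folds=cfg.n_folds, panel=name, seed=cfg.seed,
            )
            kept = filter_models(trained, cfg.model_r2_min)
            models[name] = kept
            counts[name] = {"trained": len(trained), "kept": len(kept), "untrainable": len(untrainable)}
        return models, {"digest": _digest(pd.DataFrame(counts)), "rows": counts}

    models = _run("train", _train)
    bundle["models"] = models

    # 3 -- predict expression into every cohort with every panel
    def _predict():
        pred: dict[tuple[str, str], object] = {}
        for pname, mset in models.items():
            for cname, gm in data["cohorts"].items():
                if mset:
                    pred[(pname, cname)] = predict_expression(mset, gm)
        rows = {f"{p}->{c}": v.values.shape[1] for (p, c), v in pred.items()}
        return pred, {"digest": _digest(pd.Series(rows)), "rows": rows}

    predictions = _run("predict", _predict)
    bundle["predictions"] = predictions

    # 4 -- kinship-adjusted association per cohort x trait x panel
    def _associate():
        pheno_adj: dict[tuple[str, str], object] = {}
        scans: dict[tuple[str, str], EmmaxScan] = {}
        rows = []
        for cname, gm in data["cohorts"].items():
            K = compute_kinship(gm)
            sample_pos = {s: i for i, s in enumerate(gm.samples)}
            duffy_d = pd.Series(gm.dosages_for([data["duffy_variant"]])[:, 0], index=gm.samples)
            for trait in TRAITS:
                adj = prepare_phenotype(
                    data["cohort_pheno"][cname], trait,
                    duffy_dosage=duffy_d if trait == "WBC" else None,
                )
                pos = [sample_pos[s] for s in adj.values.index]
                scan = EmmaxScan(
                    adj.values, K[np.ix_(pos, pos)], cohort=cname, trait=trait
                ).fit_null()
                pheno_adj[(cname, trait)] = adj
                scans[(cname, trait)] = scan
                for pname in models:
                    key = (pname, cname)
                    if key not in predictions:
                        continue
                    res = scan.test_matrix(predictions[key].values)
                    res["panel"] = pname
                    rows.append(res)
        assoc = pd.concat(rows, ignore_index=True)
        state = {"assoc": assoc, "pheno_adj": pheno_adj, "scans": scans}
        return state, {"digest": _digest(assoc[["gene_id", "beta", "p"]]), "rows": {"associations": len(assoc)}}

    assoc_state = _run("associate", _associate)
    assoc = assoc_state["assoc"]
    bundle["associations"] = assoc

    # 5 -- meta-analysis within ancestry per panel, then ACAT across sets
    def _meta():
        ancestry_cohorts = {}
        for cname, s in cfg.cohorts.items():
            ancestry_cohorts.setdefault(s["population"], []).append(cname)
        meta_rows = []
        for pname, ancestry in cfg.analysis_sets:
            cnames = ancestry_cohorts.get(ancestry, [])
            sub = assoc[(assoc["panel"] == pname) & (assoc["cohort"].isin(cnames)) & (assoc["skipped"] == "")]
            if sub.empty:
                continue
            mt = meta_analyze_table(sub, cohort_order=cnames)
            mt["panel"], mt["ancestry"] = pname, ancestry
            meta_rows.append(mt)
        meta = pd.concat(meta_rows, ignore_index=True)
        acat_rows = []
        for (gene, trait), grp in meta.groupby(["gene_id", "trait"], sort=False):
            acat_rows.append(
                {"gene_id": gene, "trait": trait, "acat_p": acat_combine(grp["meta_p"].to_numpy()),
                 "n_sets": len(grp)}
            )
        acat = pd.DataFrame(acat_rows)
        n_genes_tested = meta["gene_id"].nunique()
        thresholds = {
            "suggestive_p": cfg.suggestive_p,
            "bonferroni": bonferroni_threshold(cfg.alpha, max(n_genes_tested, 1)),
        }
        state = {"meta": meta, "acat": acat, "thresholds": thresholds}
        return state, {"digest": _digest(meta[["gene_id", "meta_p"]]),
                       "rows": {"meta": len(meta), "acat": len(acat)}}

    meta_state = _run("meta", _meta)
    meta, acat = meta_state["meta"], meta_state["acat"]
    bundle["meta"], bundle["acat"] = meta, acat
    bundle["thresholds"] = meta_state["thresholds"]

    # 6 -- two-step conditional analysis of suggestive pairs
    def _conditional():
        suggestive = meta[meta["meta_p"] < cfg.suggestive_p].copy()
        ancestry_cohorts = {}
        for cname, s in cfg.cohorts.items():
            ancestry_cohorts.setdefault(s["population"], []).append(cname)
        annot_ix = annot.set_index("gene_id")
        rows = []
        for _, sig in suggestive.iterrows():
            gene = annot_ix.loc[sig["gene_id"]]
            gene = pd.concat([gene, pd.Series({"gene_id": sig["gene_id"]})])
            cnames = ancestry_cohorts[sig["ancestry"]]

            def _step_meta_p(step: str) -> float | None:
                per = []
                for cname in cnames:
                    gm = data["cohorts"][cname]
                    cset = build_conditioning_set(
                        gene, sig["trait"], data["known"][step], gm, step,
                        window_bp=cfg.window_bp,
                    )
                    if cset.is_empty:
                        return None
                    adj = assoc_state["pheno_adj"][(cname, sig["trait"])]
                    pos = [i for i, s in enumerate(gm.samples) if s in set(adj.values.index)]
                    K = compute_kinship(gm)[np.ix_(pos, pos)]
                    dos = cset.dosages[pos]
                    pred = predictions[(sig["panel"], cname)].values[sig["gene_id"]]
                    per.append(
                        conditional_association(
                            pred, adj, dos, K, cohort=cname, gene_id=sig["gene_id"]
                        )
                    )
                from .association import meta_analyze

                return meta_analyze(per, cnames).p

            p1 = _step_meta_p("catalog")
            run_step2 = p1 is None or p1 < cfg.conditional_alpha
            p2 = _step_meta_p("recent_gwas") if run_step2 else None
            sc = classify_two_step(
                p1, p2, catalog_empty=p1 is None, recent_empty=p2 is None,
                alpha=cfg.conditional_alpha,
            )
            rows.append(
                {"gene_id": sig["gene_id"], "trait": sig["trait"], "panel": sig["panel"],
                 "ancestry": sig["ancestry"], "meta_p": sig["meta_p"],
                 "conditional_p": sc.conditional_p, "signal_class": sc.signal_class}
            )
        signals = pd.DataFrame(
            rows, columns=["gene_id", "trait", "panel", "ancestry", "meta_p",
                           "conditional_p", "signal_class"],
        )
        return signals, {"digest": _digest(signals), "rows": {"suggestive": len(signals)}}

    signals = _run("conditional", _conditional)
    bundle["signals"] = signals

    # 7 -- loci and fine-mapping of multi-gene loci
    def _finemap():
        loci_out, fm_out = [], {}
        suggestive = meta[meta["meta_p"] < cfg.suggestive_p]
        for (trait, pname, ancestry), grp in suggestive.groupby(["trait", "panel", "ancestry"], sort=False):
            sig = grp.rename(columns={"meta_p": "p"})[["gene_id", "p"]]
            loci = define_loci(sig, annot, window_bp=cfg.window_bp)
            cname = next(c for c, s in cfg.cohorts.items() if s["population"] == ancestry)
            for locus in loci:
                loci_out.append(
                    {"trait": trait, "panel": pname, "ancestry": ancestry,
                     "sentinel": locus.sentinel_gene, "chrom": locus.chrom,
                     "start": locus.start, "end": locus.end, "n_genes": len(locus.member_genes)}
                )
                if len(locus.member_genes) < 2:
                    continue
                pred = predictions[(pname, cname)].values
                genes_avail = [g for g in locus.member_genes if g in pred.columns]
                if len(genes_avail) < 2:
                    continue
                zmap = grp.set_index("gene_id")
                zs = pd.Series(
                    {g: zmap.loc[g, "meta_beta"] / zmap.loc[g, "meta_se"] for g in genes_avail}
                )
                R = expression_correlation(pred, genes_avail)
                n_eff = float(zmap["n"].max())
                fm = finemap_locus(zs, R, k_max=cfg.finemap_k_max, n_eff=n_eff)
                fm_out[(trait, pname, ancestry, locus.sentinel_gene)] = fm
        loci_df = pd.DataFrame(loci_out)
        state = {"loci": loci_df, "finemap": fm_out}
        return state, {"digest": _digest(loci_df), "rows": {"loci": len(loci_df), "finemapped": len(fm_out)}}

    fm_state = _run("finemap", _finemap)
    bundle["loci"], bundle["finemap"] = fm_state["loci"], fm_state["finemap"]
    bundle["manifest"] = manifest

    if out is not None:
        _export_tables(bundle, out)
    return bundle


def final_report(bundle: dict) -> pd.DataFrame:
    """Table-1-shaped report: suggestive pairs with conditional classification."""
    meta = bundle["meta"]
    cfg: PipelineConfig = bundle["config"]
    signals = bundle["signals"]
    annot = bundle["data"]["annotation"].set_index("gene_id")
    model_ix = {
        (p, m.gene_id): m for p, mods in bundle["models"].items() for m in mods
    }
    rows = []
    for _, s in signals.iterrows():
        mrow = meta[
            (meta["gene_id"] == s["gene_id"]) & (meta["trait"] == s["trait"])
            & (meta["panel"] == s["panel"]) & (meta["ancestry"] == s["ancestry"])
        ].iloc[0]
        m = model_ix.get((s["panel"], s["gene_id"]))
        g = annot.loc[s["gene_id"]]
        rows.append(
            {"gene_id": s["gene_id"], "chrom": g["chrom"], "start": g["start"], "end": g["end"],
             "trait": s["trait"], "meta_beta": mrow["meta_beta"], "meta_se": mrow["meta_se"],
             "direction": mrow["direction"], "marginal_p": mrow["meta_p"],
             "conditional_p": s["conditional_p"] if s["conditional_p"] is not None else "NA",
             "signal_class": s["signal_class"],
             "model_r2": m.model_r2 if m else np.nan, "cv_r2": m.cv_r2 if m else np.nan,
             "panel": s["panel"], "population": s["ancestry"]}
        )
    cols = ["gene_id", "chrom", "start", "end", "trait", "meta_beta", "meta_se", "direction",
            "marginal_p", "conditional_p", "signal_class", "model_r2", "cv_r2", "panel", "population"]
    return pd.DataFrame(rows, columns=cols)


def _export_tables(bundle: dict, out: Path) -> None:
    bundle["associations"].to_csv(out / "associations.tsv", sep="\t", index=False, float_format="%.10g")
    bundle["meta"].to_csv(out / "meta.tsv", sep="\t", index=False, float_format="%.10g")
    bundle["acat"].to_csv(out / "acat.tsv", sep="\t", index=False, float_format="%.10g")
    bundle["signals"].to_csv(out / "signals.tsv", sep="\t", index=False, float_format="%.10g")
    bundle["loci"].to_csv(out / "loci.tsv", sep="\t", index=False, float_format="%.10g")
    final_report(bundle).to_csv(out / "report.tsv", sep="\t", index=False, float_format="%.10g")
    pd.DataFrame(bundle["manifest"]).astype(str).to_csv(out / "manifest.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# Replication
# ---------------------------------------------------------------------------

def run_replication(cfg: PipelineConfig, bundle: dict, tier1_panel: str = "PANEL_EA") -> pd.DataFrame:
    """Two-tier replication of the discovery signals in the held-out cohort.

    Tier-1 weights are retrained from the ``tier1_panel`` restricted to
    variants common (MAF > 0.05) and well-imputed (R2 > 0.8) in both the
    panel and the replication cohort; tier 2 falls back to the discovery
    ancestry-panel weights. The Bonferroni threshold uses the number of
    signals carried into replication.
    """
    data = bundle["data"]
    repl = data["replication"]
    annot = data["annotation"]
    k_hidden = min(cfg.n_hidden_factors, len(annot) // 6)
    covs = data["panel_cov"][tier1_panel][["age", "sex"] + [f"PC{i}" for i in range(1, 11)]]
    adj = adjust_expression(data["panel_expr"][tier1_panel], covs, k_hidden)
    tier1_list = retrain_for_replication(
        adj, data["panels"][tier1_panel], annot, repl["genotypes"],
        maf_min=cfg.maf_min, rsq_min=cfg.rsq_replication,
        panel=f"{tier1_panel}_for_replication", mixing_alpha=cfg.mixing_alpha,
        n_folds=cfg.n_folds, seed=cfg.seed,
    )
    tier1 = {m.gene_id: m for m in tier1_list}
    ancestry_models = {p: {m.gene_id: m for m in ms} for p, ms in bundle["models"].items()}
    signals = bundle["signals"]
    signals = signals[signals["signal_class"].isin(["conditionally_distinct", "no_known_variants"])]
    cohort = {
        "genotypes": repl["genotypes"],
        "phenotypes": repl["phenotypes"],
        "kinship": compute_kinship(repl["genotypes"]),
        "duffy_variant": data["duffy_variant"],
    }
    return replication_tiers(
        signals, tier1, ancestry_models, cohort, n_tests=max(len(signals), 1),
        alpha=cfg.alpha, tier2_model_r2=cfg.tier2_model_r2,
    )


def retrain_for_replication(
    panel_adjusted_expr: pd.DataFrame,
    panel_geno: GenotypeMatrix,
    annotation: pd.DataFrame,
    replication_geno: GenotypeMatrix,
    maf_min: float = 0.05,
    rsq_min: float = 0.8,
    panel: str = "panel_for_replication",
    **train_kwargs,
) -> list[WeightModel]:
    """Retrain the panel on variants common and well-imputed in BOTH datasets.

    The intersection keeps variants with folded MAF > maf_min in panel and
    replication cohort alike and imputation R2 > ``rsq_min`` in both; the
    elastic-net procedure is otherwise unchanged. Genes losing all their cis
    variants get no replication model (they route to tier 2).
    """
    repl_ix = replication_geno.variants.set_index("id")
    repl_maf = pd.Series(replication_geno.maf(), index=replication_geno.variants["id"])
    panel_maf = panel_geno.maf()
    keep = []
    for j, vid in enumerate(panel_geno.variants["id"]):
        if vid not in repl_ix.index:
            continue
        if panel_maf[j] <= maf_min or repl_maf[vid] <= maf_min:
            continue
        if panel_geno.variants["imput_rsq"].iloc[j] <= rsq_min or repl_ix.loc[vid, "imput_rsq"] <= rsq_min:
            continue
        keep.append(vid)
    if not keep:
        return []
    sub = panel_geno.subset_variants(keep)
    # filters already applied on the intersection; disable the in-training ones
    models, _ = train_panel(
        panel_adjusted_expr, sub, annotation, maf_min=0.0, rsq_min=0.0,
        panel=panel, **train_kwargs,
    )
    return models


def replication_tiers(
    signals: pd.DataFrame,
    tier1_models: dict[str, WeightModel],
    ancestry_models: dict[str, dict[str, WeightModel]],
    replication_cohort: dict,
    n_tests: int,
    alpha: float = 0.05,
    tier2_model_r2: float = 0.01,
) -> pd.DataFrame:
    """Route each signal through the two replication tiers.

    Tier 1 uses the panel-for-replication retrained weights; a signal falls
    through to tier 2 (the original ancestry-panel weights) when the tier-1
    model is absent, poorly predictive (model R2 < ``tier2_model_r2``) or
    not significant at the Bonferroni-adjusted threshold. Every input signal
    yields exactly one record.
    """
    thr = bonferroni_threshold(alpha, n_tests)
    geno: GenotypeMatrix = replication_cohort["genotypes"]
    pheno: pd.DataFrame = replication_cohort["phenotypes"]
    kinship = replication_cohort.get("kinship")
    if kinship is None:
        kinship = np.eye(geno.n_samples)
    duffy = replication_cohort.get("duffy_variant")

    scans: dict[str, EmmaxScan] = {}
    sample_pos = {s: i for i, s in enumerate(geno.samples)}

    def _scan(trait: str) -> EmmaxScan:
        if trait not in scans:
            duffy_d = None
            if trait == "WBC" and duffy is not None:
                duffy_d = pd.Series(geno.dosages_for([duffy])[:, 0], index=geno.samples)
            adj = prepare_phenotype(pheno, trait, duffy_dosage=duffy_d)
            pos = [sample_pos[s] for s in adj.values.index]
            scans[trait] = EmmaxScan(
                adj.values, np.asarray(kinship)[np.ix_(pos, pos)], cohort="replication", trait=trait
            ).fit_null()
        return scans[trait]

    def _try(model: WeightModel | None, trait: str):
        if model is None:
            return None
        try:
            pred = predict_expression([model], geno)
        except ValueError:
            return None
        if model.gene_id in pred.skipped:
            return None
        x = pred.values[model.gene_id]
        if x.std() == 0:
            return None
        return _scan(trait).test(x, gene_id=model.gene_id)

    rows = []
    for _, s in signals.iterrows():
        gene, trait = s["gene_id"], s["trait"]
        t1 = tier1_models.get(gene)
        reason = ""
        tier_used, res = None, None
        r1 = None
        if t1 is None:
            reason = "no tier-1 model"
        elif t1.model_r2 < tier2_model_r2:
            reason = f"tier-1 model R2 {t1.model_r2:.3g} < {tier2_model_r2:g}"
        else:
            r1 = _try(t1, trait)
            if r1 is None:
                reason = "tier-1 prediction failed in replication cohort"
            elif r1.p >= thr:
                reason = "tier-1 not significant at Bonferroni threshold"
            else:
                tier_used, res = 1, r1
        if res is None:
            t2 = ancestry_models.get(s.get("panel", ""), {}).get(gene)
            r2 = _try(t2, trait)
            if r2 is not None:
                tier_used, res = 2, r2
            elif r1 is not None:
                tier_used, res = 1, r1
                reason += "; no tier-2 model, reporting tier-1 result"
        rows.append(
            {"gene_id": gene, "trait": trait, "tier": tier_used,
             "beta": res.beta if res else np.nan, "se": res.se if res else np.nan,
             "p": res.p if res else np.nan,
             "replicated": bool(res.p < thr) if res else None,
             "threshold": thr, "note": reason}
        )
    return pd.DataFrame(rows)
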