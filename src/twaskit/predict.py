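"""Apply weight models to external genotypes and evaluate prediction quality.

"True R2" is the squared Pearson correlation between predicted and measured
expression in an evaluation cohort — the cross-panel yardstick for comparing
training reference panels. The subsampling experiment retrains a large panel
at a smaller target size to isolate the effect of sample size on true R2.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, PredictedExpression, WeightModel
from .expression import train_panel


def predict_expression(models: list[WeightModel], genotypes: GenotypeMatrix) -> PredictedExpression:
    """Weighted dosage sums per gene, with allele-orientation reconciliation.

    A weight variant matches the target when its (ref, alt) strings equal the
    target's; if its alleles are swapped relative to the target, the dosage is
    flipped (2 - dosage) before weighting. Variants absent from the target
    (or with mismatched allele pairs) are dropped and counted as missing;
    genes with no matched variant are omitted with a logged reason.
    """
    vmeta = genotypes.variants.set_index("id")
    cols: dict[str, np.ndarray] = {}
    n_found: dict[str, int] = {}
    n_missing: dict[str, int] = {}
    skipped: dict[str, str] = {}
    for m in models:
        pred = np.full(genotypes.n_samples, m.intercept, dtype=float)
        found = 0
        for vid, ref, alt, w in zip(m.variant_ids, m.ref, m.alt, m.weights):
            if vid not in vmeta.index:
                continue
            t = vmeta.loc[vid]
            d = genotypes.dosages_for([vid])[:, 0]
            if (ref, alt) == (t["ref"], t["alt"]):
                pass
            elif (alt, ref) == (t["ref"], t["alt"]):
                d = 2.0 - d
            else:
                continue
            pred += w * d
            found += 1
        n_found[m.gene_id] = found
        n_missing[m.gene_id] = m.n_variants - found
        if found == 0:
            skipped[m.gene_id] = "no weight variants found in target genotypes"
            continue
        cols[m.gene_id] = pred
    if not cols:
        raise ValueError("no overlapping variants for any gene")
    values = pd.DataFrame(cols, index=pd.Index(genotypes.samples, name="sample"))
    return PredictedExpression(values=values, n_found=n_found, n_missing=n_missing, skipped=skipped)


def evaluate_true_r2(
    predicted: PredictedExpression | pd.DataFrame,
    measured: pd.DataFrame,
    panel: str = "panel",
) -> pd.DataFrame:
    """Per-gene squared Pearson correlation of predicted vs measured expression.

    Returns a frame with columns gene_id, panel, true_r2, n, zero_variance.
    Genes whose prediction has zero variance over the shared samples get
    true_r2 = 0 with the flag set.
    """
    pred = predicted.values if isinstance(predicted, PredictedExpression) else predicted
    samples = pred.index.intersection(measured.index)
    if len(samples) < 3:
        raise ValueError("fewer than 3 shared samples")
    genes = [g for g in pred.columns if g in measured.columns]
    rows = []
    for g in genes:
        x = pred.loc[samples, g].to_numpy(dtype=float)
        y = measured.loc[samples, g].to_numpy(dtype=float)
        zero_var = x.std() == 0 or y.std() == 0
        r2 = 0.0 if zero_var else float(np.corrcoef(x, y)[0, 1] ** 2)
        rows.append({"gene_id": g, "panel": panel, "true_r2": r2, "n": len(samples), "zero_variance": zero_var})
    return pd.DataFrame(rows)


def overlap_report(
    true_r2_by_panel: dict[str, pd.DataFrame],
    threshold: float = 0.05,
    sweep: list[float] | None = None,
) -> dict:
    """Venn-style counts of well-predicted genes (true_r2 > threshold) per panel.

    Returns per-panel counts plus 'both'/'either' (genes well-predicted by
    all panels / by at least one) and a threshold sweep table.
    """
    if len(true_r2_by_panel) < 2:
        raise ValueError("need at least 2 panels")

    def _counts(thr: float) -> dict:
        sets = {
            p: set(df.loc[df["true_r2"] > thr, "gene_id"]) for p, df in true_r2_by_panel.items()
        }
        all_sets = list(sets.values())
        both = set.intersection(*all_sets)
        either = set.union(*all_sets)
        out = {f"only_{p}": len(s - set.union(*(o for q, o in sets.items() if q != p))) for p, s in sets.items()}
        out.update({p: len(s) for p, s in sets.items()})
        out["both"] = len(both)
        out["either"] = len(either)
        return out

    report = {"threshold": threshold, "counts": _counts(threshold)}
    if sweep:
        report["sweep"] = pd.DataFrame(
            [{"threshold": t, **_counts(t)} for t in sweep]
        )
    return report


@dataclass
class SubsampleResult:
    per_rep_models: list[list[WeightModel]]
    per_rep_true_r2: list[pd.DataFrame]
    full_true_r2: pd.DataFrame
    mean_subsample_true_r2: float
    mean_full_true_r2: float
    target_n: int


def subsample_experiment(
    panel_expr: pd.DataFrame,
    panel_geno: GenotypeMatrix,
    annotation: pd.DataFrame,
    eval_geno: GenotypeMatrix,
    eval_expr: pd.DataFrame,
    target_n: int,
    n_reps: int = 5,
    seed: int = 0,
    model_r2_min: float = 0.0,
    **train_kwargs,
) -> SubsampleResult:
    """Retrain at a reduced panel size ``n_reps`` times and compare true R2.

    Each repetition draws a seeded subsample (without replacement) of the
    panel, retrains every gene from scratch, predicts into the evaluation
    cohort, and records per-gene true R2; the full-panel models are trained
    once for reference. Mean true R2 is averaged over genes present in every
    repetition and the full panel.
    """
    n_panel = len(panel_expr)
    if target_n > n_panel:
        raise ValueError("target_n exceeds panel size")
    n_folds = train_kwargs.get("n_folds", 10)
    if target_n <= n_folds:
        raise ValueError("target_n too small to train (<= folds)")
    rng = np.random.default_rng(seed)

    full_models, _ = train_panel(panel_expr, panel_geno, annotation, seed=seed, **train_kwargs)
    full_models = [m for m in full_models if m.model_r2 >= model_r2_min]
    full_r2 = evaluate_true_r2(predict_expression(full_models, eval_geno), eval_expr, panel="full")

    per_rep_models, per_rep_r2 = [], []
    for rep in range(n_reps):
        idx = rng.choice(n_panel, size=target_n, replace=False)
        sub_expr = panel_expr.iloc[np.sort(idx)]
        sub_geno = panel_geno.subset_samples_by_id(list(sub_expr.index))
        models, _ = train_panel(sub_expr, sub_geno, annotation, seed=seed, **train_kwargs)
        models = [m for m in models if m.model_r2 >= model_r2_min]
        per_rep_models.append(models)
        if models:
            r2 = evaluate_true_r2(predict_expression(models, eval_geno), eval_expr, panel=f"rep{rep}")
        else:
            r2 = pd.DataFrame(columns=["gene_id", "panel", "true_r2", "n", "zero_variance"])
        per_rep_r2.append(r2)

    shared = set(full_r2["gene_id"])
    for r2 in per_rep_r2:
        shared &= set(r2["gene_id"])
    shared = sorted(shared)
    if shared:
        sub_mean = float(
            np.mean([r2.set_index("gene_id").loc[shared, "true_r2"].mean() for r2 in per_rep_r2])
        )
        full_mean = float(full_r2.set_index("gene_id").loc[shared, "true_r2"].mean())
    else:
        sub_mean = full_mean = float("nan")
    return SubsampleResult(
        per_rep_models=per_rep_models,
        per_rep_true_r2=per_rep_r2,
        full_true_r2=full_r2,
        mean_subsample_true_r2=sub_mean,
        mean_full_true_r2=full_mean,
        target_n=target_n,
    )
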