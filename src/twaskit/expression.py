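"""Reference-panel expression normalization and elastic-net cis model training.

The training recipe follows the PrediXcan family of methods: for each gene,
dosages of common, well-imputed variants within +/- 1 Mb of the gene's start
and end are fed to an elastic net (mixing parameter alpha = 0.5) whose
penalty strength is chosen by 10-fold cross-validation; genes whose model R2
(in-sample squared Pearson correlation of fitted vs observed expression)
reaches 0.05 are carried forward. A pooled out-of-fold cross-validation R2
is reported alongside.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold

from .datatypes import GenotypeMatrix, WeightModel


def rank_inverse_normal(x: np.ndarray, offset: float = 0.5) -> np.ndarray:
    """Rank-based inverse-normal transform: Phi^-1((rank - offset) / n)."""
    x = np.asarray(x, dtype=float)
    r = stats.rankdata(x)
    return stats.norm.ppf((r - offset) / len(x))


def adjust_expression(
    expression: pd.DataFrame,
    covariates: pd.DataFrame,
    n_hidden_factors: int = 10,
) -> pd.DataFrame:
    """Residualize expression on covariates + hidden factors, then inverse-normalize.

    The covariate model mirrors standard eQTL-panel processing: sex, age, age
    squared and genotype PCs enter as fixed covariates; ``n_hidden_factors``
    latent factors (principal components of the covariate-residualized
    expression matrix, a surrogate for PEER factors) are then removed, and
    each gene column is rank-based inverse-normal transformed.

    Note the hidden factors are estimated from expression alone, so strong
    cis-genetic signals are not regressed out by construction, but a gene's
    own broad expression variance can partially load on factors.
    """
    if n_hidden_factors < 0:
        raise ValueError("n_hidden_factors must be >= 0")
    if n_hidden_factors >= len(expression):
        raise ValueError("n_hidden_factors must be < n_samples")
    covariates = covariates.loc[expression.index]
    X = np.column_stack([np.ones(len(expression)), covariates.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient covariate matrix")
    E = expression.to_numpy(dtype=float)
    coef, *_ = np.linalg.lstsq(X, E, rcond=None)
    R = E - X @ coef
    if n_hidden_factors > 0:
        u, s, _ = np.linalg.svd(R, full_matrices=False)
        F = u[:, :n_hidden_factors]
        coef_f, *_ = np.linalg.lstsq(F, R, rcond=None)
        R = R - F @ coef_f
    out = np.column_stack([rank_inverse_normal(R[:, j]) for j in range(R.shape[1])])
    return pd.DataFrame(out, index=expression.index, columns=expression.columns)


def select_cis_variants(
    gene: pd.Series,
    genotypes: GenotypeMatrix,
    window_bp: int = 1_000_000,
    maf_min: float = 0.05,
    rsq_min: float = 0.3,
    dedup_tol: float = 1e-12,
) -> list[str]:
    """Cis-window variant selection with MAF / imputation-quality filters.

    Variants must lie within ``window_bp`` of the gene's [start, end], have
    empirical folded MAF strictly above ``maf_min`` and imputation R2
    strictly above ``rsq_min``. Among any group of perfectly correlated
    dosage columns (|r| = 1 within ``dedup_tol``) only the first by position
    is retained. An empty result is not an error: the gene is untrainable.
    """
    v = genotypes.variants
    mask = (
        (v["chrom"].to_numpy() == gene["chrom"])
        & (v["pos"].to_numpy() >= int(gene["start"]) - window_bp)
        & (v["pos"].to_numpy() <= int(gene["end"]) + window_bp)
        & (genotypes.maf() > maf_min)
        & (v["imput_rsq"].to_numpy() > rsq_min)
    )
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    order = idx[np.argsort(v["pos"].to_numpy()[idx], kind="stable")]
    X = genotypes.dosage[:, order]
    sd = X.std(axis=0)
    keep_idx = order[sd > 0]
    X = genotypes.dosage[:, keep_idx]
    if keep_idx.size > 1:
        C = np.corrcoef(X, rowvar=False)
        keep_mask = np.ones(keep_idx.size, dtype=bool)
        for j in range(1, keep_idx.size):
            if np.any(np.abs(C[j, :j][keep_mask[:j]]) >= 1 - dedup_tol):
                keep_mask[j] = False
        keep_idx = keep_idx[keep_mask]
    return v["id"].to_numpy()[keep_idx].tolist()


def _squared_pearson(pred: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation, zeroed for degenerate or anti-correlated
    predictions (a negative predicted-observed correlation carries no
    predictive value; squaring it would mistake the out-of-fold intercept
    artifact for signal)."""
    if np.std(pred) == 0 or np.std(y) == 0:
        return 0.0
    r = float(np.corrcoef(pred, y)[0, 1])
    return r**2 if r > 0 else 0.0


def train_elastic_net(
    expr_gene: pd.Series | np.ndarray,
    genotypes: GenotypeMatrix,
    variant_ids: list[str],
    gene_id: str,
    mixing_alpha: float = 0.5,
    n_folds: int = 10,
    panel: str = "panel",
    seed: int = 0,
    max_iter: int = 5000,
    tol: float = 1e-3,
) -> WeightModel:
    """Train one gene's elastic-net model with CV-chosen penalty strength.

    Columns are standardized before fitting and weights back-transformed to
    the raw dosage scale. ``model_r2`` is the in-sample squared Pearson
    correlation of fitted vs observed expression; ``cv_r2`` pools the
    out-of-fold predictions from the same fold partition (seeded permutation)
    and squares their correlation with the observed values. Deterministic
    under a fixed seed.
    """
    y = np.asarray(expr_gene, dtype=float)
    if len(variant_ids) < 2:
        raise ValueError("need at least 2 cis variants to train")
    if y.std() == 0:
        raise ValueError("all-constant expression")
    n = len(y)
    if n <= n_folds:
        raise ValueError("fewer samples than folds")

    X = genotypes.dosages_for(variant_ids)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    Xs = (X - mu) / sd

    cv = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(cv.split(Xs))
    path = ElasticNetCV(l1_ratio=mixing_alpha, alphas=100, cv=folds, max_iter=max_iter, tol=tol)
    path.fit(Xs, y)
    # one-standard-error rule: the strongest penalty whose CV error is within
    # one SE of the minimum; guards against the min rule's tendency to admit
    # noise variables when the CV curve is flat
    mse = path.mse_path_.mean(axis=1)
    se = path.mse_path_.std(axis=1, ddof=1) / np.sqrt(n_folds)
    best = int(np.argmin(mse))
    ok = np.flatnonzero(mse <= mse[best] + se[best])
    alpha = float(path.alphas_[ok.min()])  # alphas_ descends: min index = largest alpha

    enet = ElasticNet(alpha=alpha, l1_ratio=mixing_alpha, max_iter=max_iter, tol=tol)
    enet.fit(Xs, y)
    fitted = enet.predict(Xs)
    model_r2 = _squared_pearson(fitted, y)

    oof = np.empty(n)
    for tr, te in folds:
        m = ElasticNet(alpha=alpha, l1_ratio=mixing_alpha, max_iter=max_iter, tol=tol)
        m.fit(Xs[tr], y[tr])
        oof[te] = m.predict(Xs[te])
    cv_r2 = _squared_pearson(oof, y)

    nz = np.flatnonzero(enet.coef_)
    w_raw = enet.coef_[nz] / sd[nz]
    intercept = float(enet.intercept_ - np.sum(enet.coef_[nz] * mu[nz] / sd[nz]))
    vmeta = genotypes.variants.set_index("id").loc[[variant_ids[j] for j in nz]]
    return WeightModel(
        gene_id=gene_id,
        variant_ids=[variant_ids[j] for j in nz],
        ref=vmeta["ref"].tolist(),
        alt=vmeta["alt"].tolist(),
        weights=w_raw,
        intercept=intercept,
        model_r2=model_r2,
        cv_r2=cv_r2,
        panel=panel,
        n_train=n,
        cv_seed=seed,
    )


def train_panel(
    adjusted_expression: pd.DataFrame,
    genotypes: GenotypeMatrix,
    annotation: pd.DataFrame,
    window_bp: int = 1_000_000,
    maf_min: float = 0.05,
    rsq_min: float = 0.3,
    mixing_alpha: float = 0.5,
    n_folds: int = 10,
    panel: str = "panel",
    seed: int = 0,
) -> tuple[list[WeightModel], list[str]]:
    """Train models for every gene in the annotation; returns (models, untrainable)."""
    models, untrainable = [], []
    for _, gene in annotation.iterrows():
        gid = gene["gene_id"]
        if gid not in adjusted_expression.columns:
            untrainable.append(gid)
            continue
        cis = select_cis_variants(gene, genotypes, window_bp, maf_min, rsq_min)
        if len(cis) < 2:
            untrainable.append(gid)
            continue
        models.append(
            train_elastic_net(
                adjusted_expression[gid].to_numpy(), genotypes, cis, gid,
                mixing_alpha=mixing_alpha, n_folds=n_folds, panel=panel, seed=seed,
            )
        )
    return models, untrainable


def filter_models(models: list[WeightModel], model_r2_min: float = 0.05) -> list[WeightModel]:
    """Keep models with model_r2 >= threshold (inclusive bound)."""
    return [m for m in models if m.model_r2 >= model_r2_min]


def write_weights(models: list[WeightModel], path) -> None:
    """Weight TSV (gene_id, variant_id, ref, alt, weight) + per-gene summary TSV.

    The summary is written next to ``path`` with suffix ``.summary.tsv``.
    """
    rows = []
    for m in models:
        for vid, r, a, w in zip(m.variant_ids, m.ref, m.alt, m.weights):
            rows.append({"gene_id": m.gene_id, "variant_id": vid, "ref": r, "alt": a, "weight": w})
    pd.DataFrame(rows, columns=["gene_id", "variant_id", "ref", "alt", "weight"]).to_csv(
        path, sep="\t", index=False, float_format="%.12g"
    )
    summary = pd.DataFrame(
        [
            {
                "gene_id": m.gene_id, "panel": m.panel, "intercept": m.intercept,
                "model_r2": m.model_r2, "cv_r2": m.cv_r2, "n_train": m.n_train,
                "n_variants": m.n_variants, "cv_seed": m.cv_seed,
            }
            for m in models
        ]
    )
    summary.to_csv(_summary_path(path), sep="\t", index=False, float_format="%.12g")


def _summary_path(path) -> str:
    s = str(path)
    return (s[: -len(".tsv")] if s.endswith(".tsv") else s) + ".summary.tsv"


def read_weights(path) -> list[WeightModel]:
    wt = pd.read_csv(path, sep="\t")
    required = {"gene_id", "variant_id", "ref", "alt", "weight"}
    if not required.issubset(wt.columns):
        raise ValueError(f"malformed weight table, need columns {sorted(required)}")
    summary = pd.read_csv(_summary_path(path), sep="\t").set_index("gene_id")
    models = []
    for gid, grp in wt.groupby("gene_id", sort=False):
        s = summary.loc[gid]
        models.append(
            WeightModel(
                gene_id=gid,
                variant_ids=grp["variant_id"].tolist(),
                ref=grp["ref"].tolist(),
                alt=grp["alt"].tolist(),
                weights=grp["weight"].to_numpy(),
                intercept=float(s["intercept"]),
                model_r2=float(s["model_r2"]),
                cv_r2=float(s["cv_r2"]),
                panel=str(s["panel"]),
                n_train=int(s["n_train"]),
                cv_seed=None if pd.isna(s["cv_seed"]) else int(s["cv_seed"]),
            )
        )
    return models
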