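"""Kinship-adjusted association of predicted expression with blood-cell traits.

The association engine follows the EMMAX strategy: a single genetic variance
component is estimated by REML on the null model (phenotype ~ covariates with
random effect u ~ N(0, sigma_g^2 K)), and the resulting covariance is then
held fixed while each gene's predicted expression is tested by generalized
least squares with a Wald p-value. Per-cohort results are combined by
fixed-effect inverse-variance meta-analysis (METAL-style, with a +/-/?
direction string), and p-values across panel x ancestry analyses are
aggregated with the Cauchy combination test (ACAT).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datatypes import AdjustedPhenotype, GenotypeMatrix, MetaResult, TwasResult
from .expression import rank_inverse_normal
from .simulate import EXCLUSION_BOUNDS


# ---------------------------------------------------------------------------
# Phenotype preparation
# ---------------------------------------------------------------------------

def prepare_phenotype(
    raw: pd.DataFrame,
    trait: str,
    covariate_cols: list[str] | None = None,
    duffy_dosage: pd.Series | None = None,
) -> AdjustedPhenotype:
    """Exclusions, transformation, covariate residualization, inverse-normal.

    Extreme outliers are excluded (WBC > 200 x 10^9/L, HCT > 60%, HGB >
    20 g/dL; strict inequalities; platelets have no bound). WBC is log
    transformed. Residuals from a linear model on age, age squared, sex and
    the top 10 PCs (plus the Duffy-variant dosage for WBC, when supplied) are
    rank-based inverse-normal transformed.
    """
    if trait not in ("HGB", "HCT", "WBC", "PLT"):
        raise ValueError(f"unknown trait {trait!r}")
    if covariate_cols is None:
        covariate_cols = ["age", "sex"] + [f"PC{i}" for i in range(1, 11) if f"PC{i}" in raw.columns]

    y = raw[trait].astype(float)
    keep = y.notna()
    reasons = pd.Series("missing", index=raw.index[~keep], dtype=object)
    bound = EXCLUSION_BOUNDS.get(trait)
    if bound is not None:
        out = keep & (y > bound)
        reasons = pd.concat([reasons, pd.Series(f"{trait} > {bound:g}", index=raw.index[out])])
        keep &= ~out
    excluded = pd.DataFrame(
        {"sample": reasons.index, "value": raw.loc[reasons.index, trait], "reason": reasons.values}
    ).reset_index(drop=True)

    y = y[keep]
    if trait == "WBC":
        if (y <= 0).any():
            raise ValueError("WBC must be positive for log transform")
        y = np.log(y)

    covs = raw.loc[keep.index[keep], covariate_cols].astype(float).copy()
    if "age" in covs.columns and "age2" not in covs.columns:
        covs["age2"] = covs["age"] ** 2
    if trait == "WBC":
        if duffy_dosage is not None:
            covs["duffy"] = duffy_dosage.reindex(covs.index).fillna(duffy_dosage.mean())
        else:
            warnings.warn("WBC prepared without Duffy-variant adjustment", stacklevel=2)

    X = np.column_stack([np.ones(len(covs)), covs.to_numpy()])
    coef, *_ = np.linalg.lstsq(X, y.to_numpy(), rcond=None)
    resid = y.to_numpy() - X @ coef
    values = pd.Series(rank_inverse_normal(resid), index=y.index, name=trait)
    return AdjustedPhenotype(
        trait=trait, values=values, excluded=excluded, covariates=list(covs.columns)
    )


# ---------------------------------------------------------------------------
# Kinship
# ---------------------------------------------------------------------------

def compute_kinship(genotypes: GenotypeMatrix, maf_min: float = 0.01) -> np.ndarray:
    """Genetic relationship matrix from centered, scaled dosages.

    K = Z Z' / m with Z_ij = (x_ij - 2 p_j) / sqrt(2 p_j (1 - p_j)) over the
    variants with folded MAF > maf_min. Symmetric and PSD by construction.
    """
    if genotypes.n_variants < 100:
        raise ValueError("need at least 100 variants for a stable kinship estimate")
    keep = genotypes.maf() > maf_min
    if not keep.any():
        raise ValueError("no polymorphic variants above the MAF threshold")
    X = genotypes.dosage[:, keep]
    p = X.mean(axis=0) / 2.0
    Z = (X - 2 * p) / np.sqrt(2 * p * (1 - p))
    K = Z @ Z.T / Z.shape[1]
    return (K + K.T) / 2.0


# ---------------------------------------------------------------------------
# EMMAX mixed-model scan
# ---------------------------------------------------------------------------

@dataclass
class NullFit:
    delta: float       # ratio sigma_e^2 / sigma_g^2
    h2: float          # sigma_g^2 / (sigma_g^2 + sigma_e^2)
    reml_loglik: float


class EmmaxScan:
    """Mixed-model association scan with a kinship random effect.

    Statsmodels-flavored usage::

        scan = EmmaxScan(phenotype, kinship).fit_null()
        res = scan.test(predicted_expression_gene)   # -> TwasResult fields
        table = scan.test_matrix(predicted_expression_frame)

    The model is y = X b + g beta + u + e with u ~ N(0, sigma_g^2 K) and
    e ~ N(0, sigma_e^2 I). The ratio delta = sigma_e^2 / sigma_g^2 is fit by
    REML once on the null model (EMMAX approximation) and reused for every
    gene, which reduces each test to weighted least squares in the
    eigenbasis of K.
    """

    def __init__(
        self,
        phenotype: pd.Series,
        kinship: np.ndarray,
        covariates: pd.DataFrame | np.ndarray | None = None,
        cohort: str = "cohort",
        trait: str | None = None,
    ):
        self.phenotype = phenotype
        self.samples = list(phenotype.index)
        n = len(self.samples)
        kinship = np.asarray(kinship)
        if kinship.shape != (n, n):
            raise ValueError("kinship shape does not match phenotype length")
        if not np.allclose(kinship, kinship.T, atol=1e-8):
            raise ValueError("kinship matrix is not symmetric")
        self.kinship = kinship
        self.cohort = cohort
        self.trait = trait if trait is not None else str(phenotype.name)
        if covariates is None:
            C = np.empty((n, 0))
        else:
            C = np.asarray(covariates, dtype=float)
            if C.ndim == 1:
                C = C[:, None]
        self.X0 = np.column_stack([np.ones(n), C])
        # drop collinear covariate columns (keep a full-rank basis)
        q, r = np.linalg.qr(self.X0)
        keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())
        if not keep.all():
            warnings.warn("collinear covariates dropped from conditioning set", stacklevel=2)
            self.X0 = self.X0[:, keep]
        self.null_: NullFit | None = None

    # -- variance components --------------------------------------------
    def fit_null(self) -> "EmmaxScan":
        S, U = np.linalg.eigh(self.kinship)
        if S.min() < -1e-6:
            raise ValueError("kinship matrix is not positive semi-definite")
        S = np.clip(S, 0.0, None)
        self._S, self._U = S, U
        self._y = U.T @ self.phenotype.to_numpy(dtype=float)
        self._X0r = U.T @ self.X0

        def neg_reml(log_delta: float) -> float:
            return -self._reml_loglik(10.0 ** log_delta)

        res = optimize.minimize_scalar(neg_reml, bounds=(-6.0, 6.0), method="bounded")
        delta = 10.0 ** res.x
        self.null_ = NullFit(delta=delta, h2=1.0 / (1.0 + delta), reml_loglik=-res.fun)
        self._w = 1.0 / (self._S + delta)
        return self

    def _reml_loglik(self, delta: float) -> float:
        w = 1.0 / (self._S + delta)
        X, y = self._X0r, self._y
        n, q = X.shape
        XtWX = X.T @ (w[:, None] * X)
        XtWy = X.T @ (w * y)
        try:
            beta = np.linalg.solve(XtWX, XtWy)
        except np.linalg.LinAlgError:
            return -np.inf
        r = y - X @ beta
        rss = float(r @ (w * r))
        sign, logdet_XtWX = np.linalg.slogdet(XtWX)
        _, logdet_XtX = np.linalg.slogdet(X.T @ X)
        df = n - q
        return -0.5 * (
            df * np.log(2 * np.pi * rss / df) + df
            + np.sum(np.log(self._S + delta))
            + logdet_XtWX - logdet_XtX
        )

    # -- per-gene tests ---------------------------------------------------
    def _require_fit(self):
        if self.null_ is None:
            raise RuntimeError("call fit_null() first")

    def test(self, g: pd.Series | np.ndarray, gene_id: str = "gene") -> TwasResult:
        """GLS Wald test of one gene's predicted expression."""
        self._require_fit()
        if isinstance(g, pd.Series):
            g = g.reindex(self.samples).to_numpy(dtype=float)
        g = np.asarray(g, dtype=float)
        if g.std() == 0:
            raise ValueError("zero-variance predicted expression")
        gr = self._U.T @ g
        X = np.column_stack([self._X0r, gr])
        w, y = self._w, self._y
        XtWX = X.T @ (w[:, None] * X)
        XtWy = X.T @ (w * y)
        beta = np.linalg.solve(XtWX, XtWy)
        r = y - X @ beta
        df = len(y) - X.shape[1]
        sigma2 = float(r @ (w * r)) / df
        cov = sigma2 * np.linalg.inv(XtWX)
        b, se = float(beta[-1]), float(np.sqrt(cov[-1, -1]))
        z = b / se
        p = float(2 * stats.norm.sf(abs(z)))
        return TwasResult(
            gene_id=gene_id, trait=self.trait, cohort=self.cohort,
            beta=b, se=se, p=max(p, 5e-324), n=len(y),
        )

    def test_matrix(self, G: pd.DataFrame) -> pd.DataFrame:
        """Test every column of a samples x genes frame; skips zero-variance genes."""
        self._require_fit()
        rows = []
        for gene in G.columns:
            x = G[gene].reindex(self.samples).to_numpy(dtype=float)
            if np.isnan(x).any() or x.std() == 0:
                rows.append(
                    {"gene_id": gene, "trait": self.trait, "cohort": self.cohort,
                     "beta": np.nan, "se": np.nan, "p": np.nan, "n": len(self.samples),
                     "skipped": "zero_variance_or_missing"}
                )
                continue
            r = self.test(x, gene_id=gene)
            rows.append(
                {"gene_id": r.gene_id, "trait": r.trait, "cohort": r.cohort,
                 "beta": r.beta, "se": r.se, "p": r.p, "n": r.n, "skipped": ""}
            )
        return pd.DataFrame(rows)


def lmm_association(
    predicted_expr_gene: pd.Series,
    adjusted_phenotype: AdjustedPhenotype | pd.Series,
    kinship: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
    cohort: str = "cohort",
    gene_id: str = "gene",
    min_shared: int = 30,
) -> TwasResult:
    """One-gene mixed-model association (convenience wrapper around EmmaxScan).

    ``kinship`` must be indexed in the order of the phenotype's samples; the
    gene's predicted expression is aligned by sample id.
    """
    pheno = adjusted_phenotype.values if isinstance(adjusted_phenotype, AdjustedPhenotype) else adjusted_phenotype
    shared = pheno.index.intersection(predicted_expr_gene.index)
    if len(shared) < min_shared:
        raise ValueError(f"fewer than {min_shared} shared samples")
    if len(shared) != len(pheno):
        pos = [pheno.index.get_loc(s) for s in shared]
        kinship = np.asarray(kinship)[np.ix_(pos, pos)]
        pheno = pheno.loc[shared]
        if covariates is not None:
            covariates = np.asarray(covariates)[pos]
    scan = EmmaxScan(pheno, kinship, covariates=covariates, cohort=cohort).fit_null()
    return scan.test(predicted_expr_gene.loc[shared], gene_id=gene_id)


# ---------------------------------------------------------------------------
# Meta-analysis
# ---------------------------------------------------------------------------

def meta_analyze(
    cohort_results: list[TwasResult | None],
    cohort_order: list[str] | None = None,
) -> MetaResult:
    """Fixed-effect inverse-variance meta-analysis with a direction string.

    meta_beta = sum(b_i / se_i^2) / sum(1 / se_i^2); meta_se =
    sum(1/se_i^2)^(-1/2); two-sided normal p. The direction string has one
    +/-/? character per cohort in the fixed order ("?" for missing).
    """
    present = [r for r in cohort_results if r is not None]
    if not present:
        raise ValueError("all cohorts missing")
    w = np.array([1.0 / r.se**2 for r in present])
    b = np.array([r.beta for r in present])
    beta = float(np.sum(w * b) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    z = beta / se
    p = float(2 * stats.norm.sf(abs(z)))
    direction = "".join("?" if r is None else ("+" if r.beta >= 0 else "-") for r in cohort_results)
    return MetaResult(
        gene_id=present[0].gene_id, trait=present[0].trait,
        beta=beta, se=se, p=max(p, 5e-324), direction=f"({direction})",
    )


def meta_analyze_table(results: pd.DataFrame, cohort_order: list[str]) -> pd.DataFrame:
    """Meta-analyze a per-cohort results frame over (gene_id, trait)."""
    rows = []
    for (gene, trait), grp in results.groupby(["gene_id", "trait"], sort=False):
        by_cohort = {r["cohort"]: r for _, r in grp.iterrows() if np.isfinite(r["p"])}
        per = [
            None if c not in by_cohort else TwasResult(
                gene_id=gene, trait=trait, cohort=c,
                beta=by_cohort[c]["beta"], se=by_cohort[c]["se"],
                p=by_cohort[c]["p"], n=int(by_cohort[c]["n"]),
            )
            for c in cohort_order
        ]
        if all(r is None for r in per):
            continue
        m = meta_analyze(per, cohort_order)
        n_total = int(sum(by_cohort[c]["n"] for c in by_cohort))
        rows.append(
            {"gene_id": gene, "trait": trait, "meta_beta": m.beta, "meta_se": m.se,
             "meta_p": m.p, "direction": m.direction, "n": n_total}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ACAT / Cauchy combination
# ---------------------------------------------------------------------------

def acat_combine(p_values, weights=None) -> float:
    """Cauchy combination (ACAT) of p-values.

    T = sum_i w_i tan((0.5 - p_i) pi) / sum_i w_i, combined p = Cauchy upper
    tail of T. Robust to dependence among the inputs. Missing entries are
    dropped with weight renormalization; p below 1e-15 uses the small-p
    linearization tan((0.5 - p) pi) ~ 1 / (p pi) to avoid loss of precision;
    exact 0/1 inputs are clamped to [1e-300, 1 - 1e-16] with a warning.
    """
    p = np.asarray(p_values, dtype=float)
    if weights is None:
        w = np.ones_like(p)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != p.shape:
            raise ValueError("weights shape mismatch")
    keep = np.isfinite(p)
    p, w = p[keep], w[keep]
    if p.size == 0:
        raise ValueError("empty p-value set")
    if ((p <= 0) | (p >= 1)).any():
        warnings.warn("p-values at 0 or 1 clamped", stacklevel=2)
        p = np.clip(p, 1e-300, 1 - 1e-16)
    t = np.where(p < 1e-15, 1.0 / (p * np.pi), np.tan((0.5 - p) * np.pi))
    T = float(np.sum(w * t) / np.sum(w))
    return float(stats.cauchy.sf(T))
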