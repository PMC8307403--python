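"""Core in-memory containers shared across the pipeline.

Conventions
-----------
* Genomic coordinates are 1-based inclusive throughout (VCF convention).
* Dosages are expected alternate-allele counts in [0, 2].
* Minor-allele frequencies are folded: always in (0, 0.5].
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

VARIANT_COLUMNS = ["id", "chrom", "pos", "ref", "alt", "imput_rsq"]

#: hematological traits analysed throughout: hemoglobin (g/dL), hematocrit (%),
#: white blood cell count (1e9/L), platelet count (1e9/L)
TRAITS = ("HGB", "HCT", "WBC", "PLT")


@dataclass
class GenotypeMatrix:
    """Per-sample imputed dosages plus variant metadata.

    Parameters
    ----------
    samples : list of str
        Unique sample identifiers, ordered as the rows of ``dosage``.
    variants : pandas.DataFrame
        One row per variant, ordered as the columns of ``dosage``. Required
        columns: ``id, chrom, pos, ref, alt, imput_rsq``; optional per-
        population folded frequency columns ``maf_<pop>``.
    dosage : ndarray of shape (n_samples, n_variants)
        Expected alternate-allele counts in [0, 2].
    population : ndarray of str
        Per-sample population label.
    """

    samples: list[str]
    variants: pd.DataFrame
    dosage: np.ndarray
    population: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        self.population = np.asarray(self.population, dtype=object)
        if len(self.samples) != len(set(self.samples)):
            raise ValueError("duplicate sample ids")
        if self.dosage.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        if self.dosage.size and (self.dosage.min() < -1e-9 or self.dosage.max() > 2 + 1e-9):
            raise ValueError("dosages must lie in [0, 2]")
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise ValueError(f"variant table missing columns: {missing}")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def alt_frequency(self) -> np.ndarray:
        """Unfolded alternate-allele frequency from the dosages."""
        return self.dosage.mean(axis=0) / 2.0

    def maf(self) -> np.ndarray:
        """Empirical folded minor-allele frequency from the dosages."""
        f = self.alt_frequency()
        return np.minimum(f, 1.0 - f)

    def variant_index(self) -> dict[str, int]:
        return {v: i for i, v in enumerate(self.variants["id"])}

    def subset_samples(self, idx: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            variants=self.variants.copy(),
            dosage=self.dosage[idx],
            population=self.population[idx],
        )

    def subset_samples_by_id(self, ids: Sequence[str]) -> "GenotypeMatrix":
        lookup = {s: i for i, s in enumerate(self.samples)}
        return self.subset_samples([lookup[s] for s in ids])

    def subset_variants(self, ids: Sequence[str]) -> "GenotypeMatrix":
        lookup = self.variant_index()
        cols = [lookup[v] for v in ids]
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=self.variants.iloc[cols].reset_index(drop=True),
            dosage=self.dosage[:, cols],
            population=self.population,
        )

    def dosages_for(self, ids: Sequence[str]) -> np.ndarray:
        lookup = self.variant_index()
        return self.dosage[:, [lookup[v] for v in ids]]


@dataclass
class WeightModel:
    """Sparse per-gene expression prediction model (PredictDB-style)."""

    gene_id: str
    variant_ids: list[str]
    ref: list[str]
    alt: list[str]
    weights: np.ndarray
    intercept: float
    model_r2: float
    cv_r2: float
    panel: str
    n_train: int
    cv_seed: int | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.variant_ids)
        if not (len(self.ref) == len(self.alt) == len(self.weights) == n):
            raise ValueError("variant_ids/ref/alt/weights lengths differ")

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)


@dataclass
class PredictedExpression:
    """Genetically predicted expression in a target cohort."""

    values: pd.DataFrame  # samples x genes
    n_found: dict[str, int]
    n_missing: dict[str, int]
    skipped: dict[str, str] = field(default_factory=dict)

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class AdjustedPhenotype:
    """Covariate-adjusted, inverse-normalized trait residuals."""

    trait: str
    values: pd.Series  # indexed by retained sample id
    excluded: pd.DataFrame  # sample, value, reason
    covariates: list[str]


@dataclass
class TwasResult:
    gene_id: str
    trait: str
    cohort: str
    beta: float
    se: float
    p: float
    n: int


@dataclass
class MetaResult:
    gene_id: str
    trait: str
    beta: float
    se: float
    p: float
    direction: str


@dataclass
class ConditioningSet:
    gene_id: str
    trait: str
    step: str  # "catalog" or "recent_gwas"
    variant_ids: list[str]
    dosages: np.ndarray  # (n_samples, n_variants) in cohort sample order
    window: tuple[int, int]
    dropped: list[str] = field(default_factory=list)

    @property
    def is_empty(self) -> bool:
        return len(self.variant_ids) == 0


@dataclass
class SignalClass:
    gene_id: str
    trait: str
    signal_class: str  # conditionally_distinct | explained_by_gwas | no_known_variants
    conditional_p: float | None
    step_ps: dict[str, float] = field(default_factory=dict)


@dataclass
class Locus:
    sentinel_gene: str
    chrom: str
    start: int
    end: int
    member_genes: list[str]


@dataclass
class FineMapResult:
    genes: list[str]
    pip: np.ndarray
    configurations: list[tuple[int, ...]]
    config_posterior: np.ndarray
    credible_set: list[str]
    credible_level: float
    k_max: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.genes,
                "pip": self.pip,
                "in_credible_set": [g in self.credible_set for g in self.genes],
            }
        )


@dataclass
class SyntheticTruth:
    """Ground-truth record for synthetic fixtures.

    ``genes`` maps gene_id -> {causal_ids, effects (dosage scale), h2_cis};
    ``traits`` maps trait -> {gene_effects, covariate_effects, duffy_variant,
    duffy_effect, noise_sd}.
    """

    genes: dict[str, dict] = field(default_factory=dict)
    traits: dict[str, dict] = field(default_factory=dict)
    seed: int | None = None

    def causal_variants(self, gene_id: str) -> list[str]:
        return list(self.genes[gene_id]["causal_ids"])

    def all_causal_variants(self) -> set[str]:
        out: set[str] = set()
        for rec in self.genes.values():
            out.update(rec["causal_ids"])
        return out

    def to_json(self, path) -> None:
        def _clean(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if isinstance(o, dict):
                return {k: _clean(v) for k, v in o.items()}
            if isinstance(o, (list, tuple)):
                return [_clean(v) for v in o]
            return o

        with open(path, "w") as fh:
            json.dump(
                {"genes": _clean(self.genes), "traits": _clean(self.traits), "seed": self.seed},
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(genes=d["genes"], traits=d["traits"], seed=d.get("seed"))


def results_to_frame(results: Sequence[TwasResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "trait": r.trait,
                "cohort": r.cohort,
                "beta": r.beta,
                "se": r.se,
                "p": r.p,
                "n": r.n,
            }
            for r in results
        ]
    )
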