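"""Per-feature linear-model differential abundance with covariates.

For every feature of an omics layer, ordinary least squares regresses
the (normalized, transformed) abundance on the phenotype of interest
plus covariates; two-sided t-tests on the coefficients are corrected
across features within each model term by Benjamini-Hochberg. This is
the workhorse differential-abundance stage applied to amplicon taxa,
metagenomic/metatranscriptomic functions, and metaproteomic peptides
or taxa alike.

Defaults: total-sum scaling, log2 transform, pseudocount 0.5 added on
the raw scale (all entries, only when the matrix contains zeros, before
normalization), prevalence filter at 10%. All logs are base 2, so
coefficients for a two-level phenotype read directly as log2 fold
changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .core import AbundanceMatrix, MetaomixError, SampleMetadata, ValidationError

__all__ = [
    "DAConfig",
    "DAResults",
    "DifferentialAbundanceModel",
    "filter_features",
    "normalize_transform",
    "fit_models",
    "bh_adjust",
    "da_plot_data",
]


@dataclass(frozen=True)
class DAConfig:
    """Settings for the differential-abundance stage."""

    normalization: str = "TSS"  # {"TSS", "none"}
    transform: str = "log"  # {"log", "CLR", "none"}
    pseudocount: float = 0.5
    min_prevalence: float = 0.1
    min_abundance: float = 0.0
    phenotype: str | None = None
    covariates: tuple = ()
    reference_levels: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.pseudocount <= 0:
            raise ValidationError("pseudocount must be > 0")
        if not 0 <= self.min_prevalence <= 1:
            raise ValidationError("min_prevalence must be in [0, 1]")
        if self.normalization not in ("TSS", "none"):
            raise ValidationError(f"unknown normalization {self.normalization!r}")
        if self.transform not in ("log", "CLR", "none"):
            raise ValidationError(f"unknown transform {self.transform!r}")
        object.__setattr__(self, "covariates", tuple(self.covariates))


def filter_features(
    m: AbundanceMatrix, cfg: DAConfig
) -> tuple[AbundanceMatrix, pd.DataFrame]:
    """Keep features exceeding ``min_abundance`` in at least
    ``min_prevalence`` of samples; return the kept matrix and a ledger
    of removals."""
    values = m.values
    prevalence = (values > cfg.min_abundance).mean(axis=1)
    keep = prevalence >= cfg.min_prevalence
    ledger = pd.DataFrame(
        {
            "feature": values.index[~keep],
            "reason": [
                f"prevalence {prevalence[f]:.3f} < {cfg.min_prevalence}"
                for f in values.index[~keep]
            ],
        }
    )
    if keep.sum() == 0:
        raise MetaomixError(
            "all features removed by the prevalence/abundance filter; "
            "lower min_prevalence or min_abundance"
        )
    kept = m.copy_with(
        values.loc[keep],
        None if m.feature_annotations is None else m.feature_annotations.loc[keep],
    )
    return kept, ledger


def normalize_transform(m: AbundanceMatrix, cfg: DAConfig) -> pd.DataFrame:
    """Apply pseudocount (raw scale, zero-containing data only), then
    normalization, then transform. Returns a plain DataFrame: transformed
    values may be negative, which AbundanceMatrix forbids."""
    values = m.values.copy()
    if cfg.transform in ("log", "CLR") and (values.to_numpy() == 0).any():
        values = values + cfg.pseudocount
    if cfg.normalization == "TSS":
        totals = values.sum(axis=0)
        zero = totals[totals <= 0].index.tolist()
        if zero:
            raise ValidationError(f"samples with zero total under TSS: {zero}")
        values = values.div(totals, axis=1)
    if cfg.transform == "log":
        values = np.log2(values)
    elif cfg.transform == "CLR":
        logged = np.log2(values)
        values = logged.sub(logged.mean(axis=0), axis=1)
    return values


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaN p-values propagate as
    NaN and are excluded from the number of tests."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    if ((p[mask] < 0) | (p[mask] > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    if mask.sum():
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


def _design_matrix(meta: SampleMetadata, cfg: DAConfig) -> pd.DataFrame:
    """Intercept + phenotype + covariates; categoricals dummy-coded
    against a reference level (first sorted level by default)."""
    if cfg.phenotype is None:
        raise ValidationError("DAConfig.phenotype must be set to fit models")
    cols = [cfg.phenotype, *cfg.covariates]
    X = pd.DataFrame(index=meta.table.index)
    X["Intercept"] = 1.0
    for col in cols:
        series = meta.table[col]
        if pd.api.types.is_numeric_dtype(series):
            X[col] = series.astype(float)
        else:
            levels = sorted(series.astype(str).unique())
            ref = cfg.reference_levels.get(col, levels[0])
            if ref not in levels:
                raise ValidationError(
                    f"reference level {ref!r} not found in column {col!r}"
                )
            for level in levels:
                if level == ref:
                    continue
                X[f"{col}[{level}]"] = (series.astype(str) == level).astype(float)
    return X


@dataclass
class DAResults:
    """Fitted differential-abundance results.

    ``table`` has one row per (feature, term) with the coefficient,
    standard error, two-sided p-value, BH q-value (within term, across
    features) and the number of samples used.
    """

    table: pd.DataFrame
    filter_ledger: pd.DataFrame
    config: DAConfig
    transformed: pd.DataFrame
    design: pd.DataFrame
    phenotype_values: pd.Series

    @property
    def terms(self) -> list[str]:
        return list(dict.fromkeys(self.table["term"]))

    def significant(self, term: str, alpha: float = 0.05) -> pd.DataFrame:
        sub = self.table[(self.table["term"] == term) & (self.table["qvalue"] < alpha)]
        return sub.sort_values("qvalue").reset_index(drop=True)

    def summary(self, term: str | None = None, max_rows: int = 20) -> str:
        lines = [
            "Differential abundance (OLS per feature, BH within term)",
            f"  features tested : {self.table['feature'].nunique()}",
            f"  features filtered: {len(self.filter_ledger)}",
            f"  normalization/transform: {self.config.normalization}/{self.config.transform}",
        ]
        for t in [term] if term else self.terms:
            sig = self.significant(t)
            lines.append(f"  term {t}: {len(sig)} features at q<0.05")
            for _, row in sig.head(max_rows).iterrows():
                lines.append(
                    f"    {row.feature:<24s} coef={row.coef:+.3f} "
                    f"se={row.se:.3f} p={row.pvalue:.2e} q={row.qvalue:.2e}"
                )
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


class DifferentialAbundanceModel:
    """Linear differential-abundance model over one omics layer.

    statsmodels-style entry point: construct from an abundance matrix
    and metadata, call :meth:`fit`, inspect the returned
    :class:`DAResults`.
    """

    def __init__(self, matrix: AbundanceMatrix, metadata: SampleMetadata, config: DAConfig):
        self.config = config
        meta = metadata.aligned_to(matrix.samples)
        self.matrix = matrix
        self.metadata = meta

    @classmethod
    def from_dataframes(
        cls,
        values: pd.DataFrame,
        metadata: pd.DataFrame,
        phenotype: str,
        covariates: Sequence[str] = (),
        **cfg_kwargs,
    ) -> "DifferentialAbundanceModel":
        cfg = DAConfig(phenotype=phenotype, covariates=tuple(covariates), **cfg_kwargs)
        return cls(
            AbundanceMatrix(values),
            SampleMetadata(metadata, phenotype=phenotype, covariates=covariates),
            cfg,
        )

    def fit(self) -> DAResults:
        cfg = self.config
        kept, ledger = filter_features(self.matrix, cfg)
        transformed = normalize_transform(kept, cfg)
        X = _design_matrix(self.metadata, cfg)
        n, p = X.shape
        if np.linalg.matrix_rank(X.to_numpy()) < p:
            raise MetaomixError(
                "design matrix is rank deficient; collinear terms among: "
                + ", ".join(c for c in X.columns if c != "Intercept")
            )
        if n - p < 3:
            raise MetaomixError(
                f"only {n - p} residual degrees of freedom; need at least 3"
            )
        rows = []
        skipped = []
        for feature in transformed.index:
            y = transformed.loc[feature, X.index].to_numpy(dtype=float)
            if np.ptp(y) == 0:
                skipped.append(feature)
                continue
            fit = sm.OLS(y, X).fit()
            for term in X.columns:
                if term == "Intercept":
                    continue
                rows.append(
                    {
                        "feature": feature,
                        "term": term,
                        "coef": fit.params[term],
                        "se": fit.bse[term],
                        "pvalue": fit.pvalues[term],
                        "n": n,
                    }
                )
        if skipped:
            ledger = pd.concat(
                [
                    ledger,
                    pd.DataFrame(
                        {"feature": skipped, "reason": "constant after transform"}
                    ),
                ],
                ignore_index=True,
            )
        if not rows:
            raise MetaomixError("no features could be fitted")
        table = pd.DataFrame(rows)
        table["qvalue"] = np.nan
        for term in table["term"].unique():
            sel = table["term"] == term
            table.loc[sel, "qvalue"] = bh_adjust(table.loc[sel, "pvalue"].to_numpy())
        return DAResults(
            table=table.reset_index(drop=True),
            filter_ledger=ledger,
            config=cfg,
            transformed=transformed,
            design=X,
            phenotype_values=self.metadata.table[cfg.phenotype],
        )


def fit_models(m: AbundanceMatrix, meta: SampleMetadata, cfg: DAConfig) -> DAResults:
    """Functional wrapper around :class:`DifferentialAbundanceModel`."""
    return DifferentialAbundanceModel(m, meta, cfg).fit()


def da_plot_data(result: DAResults, feature: str) -> pd.DataFrame:
    """Long table (sample, group, abundance) for group-wise boxplots of
    one feature, on the transformed scale used by the model."""
    if feature not in result.transformed.index:
        raise KeyError(feature)
    rows = [
        {
            "sample": sample,
            "group": result.phenotype_values.loc[sample],
            "abundance": float(result.transformed.loc[feature, sample]),
        }
        for sample in result.transformed.columns
    ]
    return pd.DataFrame(rows, columns=["sample", "group", "abundance"])
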