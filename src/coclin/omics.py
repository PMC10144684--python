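"""Simulated on-treatment expression and cross-cohort gene harmonization.

On-treatment (T1) expression is simulated from a baseline (T0) gene-by-sample
table by a factor-permutation scheme: for each sample a vector of 4
multiplicative factors is drawn uniformly from [0.5, 1.5] and fixed for that
sample; each gene's count is then multiplied by one of the 4 factors, chosen
uniformly at random per gene. The scheme perturbs every data point while
keeping the simulated sample moderately correlated with its baseline, and the
full factor assignment is retained so any downstream quantity can be audited.

Gene harmonization restricts patient and PDX tables to their shared gene
symbols so associations can be compared across cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptyOverlapError, InvalidInputError


@dataclass
class ExpressionMatrix:
    """Gene-by-sample nonnegative expression values (raw or normalized counts)."""

    values: pd.DataFrame        # index: gene symbols, columns: sample ids
    cohort: str = "patient"     # "patient" or "PDX"
    timepoint: str = "T0"

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise InvalidInputError(f"duplicate gene symbols: {list(dupes[:5])}")
        if self.values.columns.has_duplicates:
            raise InvalidInputError("duplicate sample ids")
        arr = self.values.to_numpy()
        if arr.size and (np.any(~np.isfinite(arr)) or np.any(arr < 0)):
            raise InvalidInputError("expression values must be finite and nonnegative")

    @property
    def gene_symbols(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class FactorAssignment:
    """Audit trail of the T1 simulation.

    ``factors``: (n_samples, 4) multiplicative factors, one row per sample;
    ``indices``: (n_genes, n_samples) integer in {0..3} selecting, per data
    point, which of the sample's factors was applied; ``seed``: the RNG seed.
    """

    factors: np.ndarray
    indices: np.ndarray
    sample_ids: list[str]
    gene_symbols: list[str]
    seed: int

    def applied_factor(self) -> np.ndarray:
        """The (n_genes, n_samples) matrix of factors actually applied."""
        cols = np.arange(len(self.sample_ids))[None, :]
        return self.factors[cols, self.indices]

    def to_frame(self) -> pd.DataFrame:
        """Per-gene applied factors as a gene-by-sample table for TSV export."""
        return pd.DataFrame(
            self.applied_factor(), index=self.gene_symbols, columns=self.sample_ids
        )


def simulate_on_treatment(
    t0: ExpressionMatrix, seed: int
) -> tuple[ExpressionMatrix, FactorAssignment]:
    """Simulate a T1 expression table from T0 by per-sample 4-factor permutation.

    Each sample gets an independent RNG stream spawned from ``seed`` (keyed by
    sample position), so extending the cohort leaves earlier samples'
    simulated values untouched. Deterministic given (t0, seed).
    """
    n_genes, n_samples = t0.shape
    if n_genes == 0 or n_samples == 0:
        raise InvalidInputError("cannot simulate from an empty expression matrix")

    streams = np.random.SeedSequence(seed).spawn(n_samples)
    factors = np.empty((n_samples, 4))
    indices = np.empty((n_genes, n_samples), dtype=np.int64)
    for j, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        factors[j] = rng.uniform(0.5, 1.5, size=4)
        indices[:, j] = rng.integers(0, 4, size=n_genes)

    assignment = FactorAssignment(
        factors=factors,
        indices=indices,
        sample_ids=t0.sample_ids,
        gene_symbols=t0.gene_symbols,
        seed=seed,
    )
    t1_values = t0.values.to_numpy() * assignment.applied_factor()
    t1 = ExpressionMatrix(
        values=pd.DataFrame(t1_values, index=t0.values.index, columns=t0.values.columns),
        cohort=t0.cohort,
        timepoint="T1",
    )
    return t1, assignment


def per_sample_r2(
    t0: ExpressionMatrix,
    t1: ExpressionMatrix,
    method: str = "pearson",
    expected_range: tuple[float, float] = (0.5, 0.8),
) -> pd.Series:
    """Squared correlation between each sample's T0 and T1 gene vectors.

    A diagnostic reported with every simulation run; values outside
    ``expected_range`` (the band typically seen on real count data) trigger a
    warning, not an error, since r^2 depends on the dispersion of the count
    distribution.
    """
    if method not in ("pearson", "spearman"):
        raise InvalidInputError(f"unknown method {method!r}")
    if t0.shape != t1.shape or t0.sample_ids != t1.sample_ids:
        raise InvalidInputError("T0/T1 matrices must have matching dimensions and samples")
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    a, b = t0.values.to_numpy(), t1.values.to_numpy()
    r2 = np.array([corr(a[:, j], b[:, j]).statistic ** 2 for j in range(a.shape[1])])
    out = pd.Series(r2, index=t0.sample_ids, name=f"{method}_r2")
    lo, hi = expected_range
    outside = out[(out < lo) | (out > hi)]
    if len(outside):
        warnings.warn(
            f"{len(outside)} sample(s) have {method} r^2 outside [{lo}, {hi}]: "
            f"min={out.min():.3f}, max={out.max():.3f}",
            stacklevel=2,
        )
    return out


def harmonize_gene_sets(
    a: ExpressionMatrix, b: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix, list[str]]:
    """Restrict both matrices to their shared gene symbols, rows sorted lexicographically."""
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise InvalidInputError("cannot harmonize an empty expression matrix")
    shared = sorted(set(a.gene_symbols) & set(b.gene_symbols))
    if not shared:
        raise EmptyOverlapError("no gene symbols shared between the two matrices")
    a2 = ExpressionMatrix(a.values.loc[shared], cohort=a.cohort, timepoint=a.timepoint)
    b2 = ExpressionMatrix(b.values.loc[shared], cohort=b.cohort, timepoint=b.timepoint)
    return a2, b2, shared
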