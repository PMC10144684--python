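"""Per-gene association of an imaging/clinical feature with expression.

For a chosen feature (a baseline value, or its pre- vs on-treatment delta)
Spearman's rank correlation is computed against every gene, with average-rank
tie handling. Two-sided p-values use the t-approximation
``t = rho * sqrt((n-2)/(1-rho^2))`` for n > 9 samples; for n <= 9 (the
typical size of a PDX arm) an exact permutation p-value is computed by full
enumeration of sample relabelings, conditional on the observed rank vectors.
Benjamini–Hochberg q-values are reported over all tested genes.

Ranked output follows the convention of cohort association portals: the top
list holds up to N positively associated genes sorted by descending rho, the
bottom list up to N negatively associated genes, and the two cohorts' lists
are compared by set overlap (Venn counts).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError
from .omics import ExpressionMatrix

#: Largest sample count for which p-values are computed by exact permutation
#: enumeration (n! relabelings; 9! = 362,880 is still tractable).
EXACT_PERMUTATION_MAX_N = 9


@dataclass
class AssociationResult:
    """Per-gene Spearman statistics with ranked top/bottom gene lists."""

    table: pd.DataFrame             # index: gene symbol; rho, p_value, q_value, n
    top_list: list[str]             # rho > 0, descending rho, <= n_top entries
    bottom_list: list[str]          # rho < 0, ascending rho, <= n_top entries
    feature_name: str = ""
    cohort: str = "patient"
    timepoint_mode: str = "T0"      # "T0", "T1" or "delta"
    n_top: int = 500


@dataclass
class OverlapSummary:
    """Venn-style decomposition of two cohorts' ranked gene lists."""

    counts: dict[str, int]
    genes: dict[str, list[str]] = field(default_factory=dict)


def delta_feature(
    t0: pd.Series, t1: pd.Series, mode: str = "absolute"
) -> tuple[pd.Series, list[str]]:
    """Per-subject feature change between timepoints.

    ``absolute``: t1 - t0; ``percent``: 100 * (t1 - t0) / t0, with zero-baseline
    subjects excluded (returned in the exclusion list).
    """
    if mode not in ("absolute", "percent"):
        raise InvalidInputError(f"unknown delta mode {mode!r}")
    shared = t0.index.intersection(t1.index)
    if len(shared) == 0:
        raise InvalidInputError("no shared subjects between timepoints")
    a, b = t0.loc[shared].astype(float), t1.loc[shared].astype(float)
    excluded: list[str] = []
    if mode == "absolute":
        delta = b - a
    else:
        zero = a == 0
        excluded = list(shared[zero])
        a, b = a[~zero], b[~zero]
        delta = 100.0 * (b - a) / a
    return delta, excluded


def _spearman_rho(expr: np.ndarray, feature: np.ndarray) -> np.ndarray:
    """Vectorized Spearman rho of each expression row against the feature.

    Average ranks, then Pearson on ranks. Constant rows yield NaN.
    """
    rf = stats.rankdata(feature)
    rg = stats.rankdata(expr, axis=1)
    rf_c = rf - rf.mean()
    rg_c = rg - rg.mean(axis=1, keepdims=True)
    denom = np.sqrt((rg_c**2).sum(axis=1) * (rf_c**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (rg_c @ rf_c) / denom
    rho[denom == 0] = np.nan
    return rho


@lru_cache(maxsize=4)
def _all_permutations(n: int) -> np.ndarray:
    """All n! permutations of range(n), as an (n!, n) int array."""
    return np.array(list(itertools.permutations(range(n))), dtype=np.intp)


def _exact_permutation_p(expr: np.ndarray, feature: np.ndarray) -> np.ndarray:
    """Exact two-sided permutation p for Spearman rho, conditional on ranks.

    For every gene, counts the fraction of the n! sample relabelings whose
    |rho| meets or exceeds the observed |rho|. Since rho is, per gene, an
    affine function of the dot product of the two rank vectors, only the dot
    product needs enumerating; ties are handled exactly because the observed
    (average-) rank vectors themselves are permuted.
    """
    n = len(feature)
    rf = stats.rankdata(feature)
    rg = stats.rankdata(expr, axis=1)
    rg_c = rg - rg.mean(axis=1, keepdims=True)
    sd_g = np.sqrt((rg_c**2).sum(axis=1))
    rf_c = rf - rf.mean()
    sd_f = np.sqrt((rf_c**2).sum())
    obs = np.abs(rg_c @ rf_c)                       # |rho| * sd_g * sd_f per gene

    perms = _all_permutations(n)
    n_perm = perms.shape[0]
    counts = np.zeros(expr.shape[0], dtype=np.int64)
    # chunk the enumeration to bound memory at ~n_genes x chunk doubles
    chunk = max(1, int(1e7 // max(expr.shape[0], 1)))
    permuted_rf = rf_c[perms]                       # (n_perm, n)
    for start in range(0, n_perm, chunk):
        block = permuted_rf[start : start + chunk]
        dots = np.abs(rg_c @ block.T)               # (n_genes, block)
        counts += (dots >= obs[:, None] - 1e-12).sum(axis=1)
    p = counts / n_perm
    p[sd_g == 0] = np.nan
    return p if sd_f > 0 else np.full(expr.shape[0], np.nan)


def _t_approximation_p(rho: np.ndarray, n: int) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(rho), 1.0)] = 0.0
    return p


def spearman_associate(
    expr: "ExpressionMatrix | pd.DataFrame",
    feature: pd.Series,
    n_top: int = 500,
    feature_name: str = "",
    timepoint_mode: str = "T0",
    cohort: str = "",
) -> AssociationResult:
    """Rank genes by Spearman association with a per-sample feature.

    ``expr`` is either an :class:`~coclin.omics.ExpressionMatrix` or a plain
    gene-by-sample DataFrame (the latter admits signed values, e.g. per-gene
    expression deltas). Samples are matched by id between the expression
    table and the feature vector; at least 3 shared samples are required and
    a constant feature is rejected. Constant gene rows get rho = NaN and are
    excluded from the ranked lists. The top list contains only positively
    associated genes (rho > 0) and the bottom list only negative ones, each
    truncated to ``n_top``; ties are broken by smaller p, then gene symbol.
    """
    if isinstance(expr, ExpressionMatrix):
        frame = expr.values
        cohort = cohort or expr.cohort
    else:
        frame = expr
        cohort = cohort or "patient"
    gene_symbols = list(frame.index)
    shared = [s for s in frame.columns if s in set(feature.index)]
    if len(shared) < 3:
        raise InvalidInputError(
            f"need >= 3 shared samples, got {len(shared)}"
        )
    f = feature.loc[shared].to_numpy(dtype=float)
    if np.all(f == f[0]):
        raise InvalidInputError("feature vector is constant across samples")
    x = frame[shared].to_numpy(dtype=float)
    n = len(shared)

    rho = _spearman_rho(x, f)
    if n <= EXACT_PERMUTATION_MAX_N:
        p = _exact_permutation_p(x, f)
    else:
        p = _t_approximation_p(rho, n)
    p[np.isnan(rho)] = np.nan

    q = np.full_like(p, np.nan)
    tested = np.isfinite(p)
    if tested.any():
        q[tested] = stats.false_discovery_control(p[tested], method="bh")

    table = pd.DataFrame(
        {"rho": rho, "p_value": p, "q_value": q, "n": n},
        index=pd.Index(gene_symbols, name="gene_symbol"),
    )

    ranked = table[np.isfinite(table["rho"])].copy()
    ranked["_sym"] = ranked.index
    pos = ranked[ranked["rho"] > 0].sort_values(
        ["rho", "p_value", "_sym"], ascending=[False, True, True]
    )
    neg = ranked[ranked["rho"] < 0].sort_values(
        ["rho", "p_value", "_sym"], ascending=[True, True, True]
    )
    return AssociationResult(
        table=table,
        top_list=list(pos.index[:n_top]),
        bottom_list=list(neg.index[:n_top]),
        feature_name=feature_name or (feature.name or ""),
        cohort=cohort,
        timepoint_mode=timepoint_mode,
        n_top=n_top,
    )


def cohort_overlap(
    patient: AssociationResult, pdx: AssociationResult, region: str = "top"
) -> OverlapSummary:
    """Shared and cohort-specific genes between two ranked lists."""
    if region not in ("top", "bottom"):
        raise InvalidInputError(f"unknown region {region!r}")
    p_universe = set(patient.table.index)
    x_universe = set(pdx.table.index)
    if p_universe != x_universe:
        warnings.warn(
            "association results cover different gene universes; "
            "overlap restricted to the shared universe",
            stacklevel=2,
        )
    universe = p_universe & x_universe
    p_list = {g for g in getattr(patient, f"{region}_list") if g in universe}
    x_list = {g for g in getattr(pdx, f"{region}_list") if g in universe}
    shared = p_list & x_list
    return OverlapSummary(
        counts={
            "patient_only": len(p_list - shared),
            "pdx_only": len(x_list - shared),
            "shared": len(shared),
        },
        genes={
            "patient_only": sorted(p_list - shared),
            "pdx_only": sorted(x_list - shared),
            "shared": sorted(shared),
        },
    )


def volcano_data(result: AssociationResult, alpha: float = 0.05) -> pd.DataFrame:
    """Plotting-ready volcano table: rho vs -log10 p, flagged at q < alpha."""
    t = result.table[np.isfinite(result.table["rho"])]
    with np.errstate(divide="ignore"):
        neglog = -np.log10(t["p_value"].to_numpy())
    out = pd.DataFrame(
        {
            "rho": t["rho"].to_numpy(),
            "neg_log10_p": neglog,
            "significant": (t["q_value"].to_numpy() < alpha),
        },
        index=t.index,
    )
    return out.sort_values(["rho", "neg_log10_p"]).rename_axis("gene_symbol")
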