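"""Correspondence statistics between parcellated maps.

The central operation is :func:`test_correspondence`: Spearman's rank
correlation between two regional maps, with significance assessed against
the distribution of correlations obtained when one map is replaced by
spatial-autocorrelation-preserving surrogates (see :mod:`maplink.nulls`).
Batch wrappers benchmark gene-receptor pairings — overall and per cortical
layer — and summarise the proportion of significant pairs per
neurotransmitter system. Supporting statistics: Benjamini-Hochberg FDR,
chi-squared contrasts of proportions, pooled-variance t tests with Cohen's
d, and within-region across-layer rank correlations with exact permutation
p-values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import permutations
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .datamodel import FeatureMatrix, PairingTable
from .exceptions import InputError, PreconditionError
from .nulls import SpatialBasis, empirical_pvalue, generate_surrogates

logger = logging.getLogger(__name__)

__all__ = [
    "CorrespondenceResult",
    "BenchmarkTable",
    "spearman_r",
    "test_correspondence",
    "benchmark_pairs",
    "layerwise_benchmark",
    "within_region_layer_correlation",
    "cross_layer_matrix",
    "fdr_bh",
    "chi2_proportions",
    "group_difference",
]


@dataclass(frozen=True)
class CorrespondenceResult:
    """One map-pair correspondence test."""

    feature_a: str
    feature_b: str
    n_regions_used: int
    spearman_r: float
    p_empirical: float
    tail: str
    n_null: int
    seed: int | None
    p_fdr: float | None = None
    significant: bool | None = None

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.spearman_r <= 1.0 + 1e-12:
            raise InputError(f"spearman_r out of [-1, 1]: {self.spearman_r}")
        if self.n_regions_used < 3:
            raise InputError("n_regions_used must be >= 3")


@dataclass
class BenchmarkTable:
    """Tidy table of correspondence tests plus per-class summary."""

    table: pd.DataFrame
    summary: dict
    skipped: list[str] = field(default_factory=list)


def _complete_pairs(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be 1-D of equal length")
    mask = np.isfinite(x) & np.isfinite(y)
    if mask.sum() < 3:
        raise PreconditionError("need >= 3 pairwise-complete observations")
    return x[mask], y[mask]


def spearman_r(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation (mid-ranks for ties, pairwise-complete)."""
    xs, ys = _complete_pairs(x, y)
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise PreconditionError("constant vector: Spearman correlation undefined")
    return float(sps.spearmanr(xs, ys).statistic)


def _rank_corr_batch(surrogates: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Spearman r of each surrogate row against y (vectorised)."""
    rx = rankdata(surrogates, axis=1)
    ry = rankdata(y)
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean()
    num = rx @ ry
    den = np.sqrt((rx * rx).sum(axis=1) * (ry * ry).sum())
    return num / den


def test_correspondence(
    map_a: np.ndarray,
    map_b: np.ndarray,
    basis: SpatialBasis,
    n_null: int = 10_000,
    seed: int | None = None,
    tail: str = "two_sided",
    feature_a: str = "map_a",
    feature_b: str = "map_b",
    randomize: str = "a",
) -> CorrespondenceResult:
    """Spearman correspondence between two maps under the surrogate null.

    The observed statistic is Spearman's r on the pairwise-complete region
    subset; the null distribution is the same statistic with `map_a`
    replaced by each of `n_null` autocorrelation-preserving surrogates
    (``randomize="b"`` randomizes the second map instead). The empirical
    p-value uses the (1+count)/(1+n_null) convention.
    """
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != (basis.n_regions,) or b.shape != (basis.n_regions,):
        raise InputError("maps must match the basis region count")
    mask = np.isfinite(a) & np.isfinite(b)
    if mask.sum() < 3:
        raise PreconditionError("need >= 3 pairwise-complete regions")
    sub = basis if mask.all() else basis.subset(mask)
    a_sub, b_sub = a[mask], b[mask]
    if np.ptp(a_sub) == 0 or np.ptp(b_sub) == 0:
        raise PreconditionError("constant map on the shared region subset")
    r_obs = float(sps.spearmanr(a_sub, b_sub).statistic)

    if randomize == "a":
        src, fixed = a_sub, b_sub
    elif randomize == "b":
        src, fixed = b_sub, a_sub
    else:
        raise InputError(f"randomize must be 'a' or 'b', got {randomize!r}")
    surr = generate_surrogates(src, sub, n_null=n_null, seed=seed)
    null_r = _rank_corr_batch(surr.surrogates, fixed)
    p = empirical_pvalue(r_obs, null_r, tail=tail)
    return CorrespondenceResult(
        feature_a=feature_a,
        feature_b=feature_b,
        n_regions_used=int(mask.sum()),
        spearman_r=r_obs,
        p_empirical=p,
        tail=tail,
        n_null=int(n_null),
        seed=None if seed is None else int(seed),
    )


def _benchmark_rows(
    gene_lookup: Mapping[str, FeatureMatrix],
    receptors: FeatureMatrix,
    pairing: PairingTable,
    basis: SpatialBasis,
    n_null: int,
    seed: int,
    tail: str,
) -> tuple[list[dict], list[str]]:
    """One correspondence test per (pairing row, layer); layer=None key means
    the aggregate (non-layered) matrix. Per-row seeds are seed + row index so
    batches are reproducible and order-independent."""
    rows: list[dict] = []
    skipped: list[str] = []
    row_index = 0
    for gene, receptor, system_class in pairing.rows:
        for layer, genes in gene_lookup.items():
            if not genes.has_feature(gene):
                skipped.append(f"{gene} (layer {layer}): gene not in matrix")
                logger.warning("skipping %s: gene absent from matrix", gene)
                row_index += 1
                continue
            if not receptors.has_feature(receptor):
                skipped.append(f"{receptor}: receptor not in matrix")
                logger.warning("skipping %s: receptor absent from matrix", receptor)
                row_index += 1
                continue
            res = test_correspondence(
                genes.feature(gene),
                receptors.feature(receptor),
                basis,
                n_null=n_null,
                seed=seed + row_index,
                tail=tail,
                feature_a=gene,
                feature_b=receptor,
            )
            rows.append(
                {
                    "gene": gene,
                    "receptor": receptor,
                    "system_class": system_class,
                    "layer": layer,
                    "n_regions_used": res.n_regions_used,
                    "spearman_r": res.spearman_r,
                    "p_empirical": res.p_empirical,
                    "seed": seed + row_index,
                }
            )
            row_index += 1
    return rows, skipped


def _summarise(df: pd.DataFrame, alpha: float, n_null: int, seed: int) -> dict:
    by_class = {}
    for cls, grp in df.groupby("system_class"):
        k, n = int(grp["significant"].sum()), len(grp)
        by_class[cls] = {"n_tested": n, "n_significant": k, "proportion": k / n}
    k, n = int(df["significant"].sum()), len(df)
    return {
        "alpha": alpha,
        "n_null": n_null,
        "seed": seed,
        "n_tested": n,
        "n_significant": k,
        "proportion_significant": k / n,
        "by_class": by_class,
    }


def benchmark_pairs(
    genes: FeatureMatrix,
    receptors: FeatureMatrix,
    pairing: PairingTable,
    basis: SpatialBasis,
    n_null: int = 10_000,
    seed: int | None = None,
    alpha: float = 0.05,
    tail: str = "two_sided",
) -> BenchmarkTable:
    """Correspondence test for every gene-receptor pairing row.

    Returns a tidy table (one row per pairing) with empirical and
    FDR-adjusted p-values, plus per-neurotransmitter-class counts and
    proportions of significant pairs.
    """
    if seed is None:
        raise InputError("seed is required")
    rows, skipped = _benchmark_rows(
        {"aggregate": genes}, receptors, pairing, basis, n_null, seed, tail
    )
    if not rows:
        raise InputError("no testable pairing rows (all references missing)")
    df = pd.DataFrame(rows).drop(columns="layer")
    df["significant"] = df["p_empirical"] <= alpha
    p_adj, reject = fdr_bh(df["p_empirical"].to_numpy(), alpha)
    df["p_fdr"] = p_adj
    df["significant_fdr"] = reject
    return BenchmarkTable(df, _summarise(df, alpha, n_null, seed), skipped)


def layerwise_benchmark(
    layer_genes: Mapping[str, FeatureMatrix],
    receptors: FeatureMatrix,
    pairing: PairingTable,
    basis: SpatialBasis,
    n_null: int = 10_000,
    seed: int | None = None,
    alpha: float = 0.05,
    tail: str = "two_sided",
) -> BenchmarkTable:
    """Benchmark each pairing against each layer-specific expression matrix.

    The receptor map has no layer specificity; each layer's regional gene
    expression is tested against it. The summary adds per-layer proportions
    and the number of pairs significant in at least 1 and at least 2 layers.
    """
    if seed is None:
        raise InputError("seed is required")
    rows, skipped = _benchmark_rows(
        dict(layer_genes), receptors, pairing, basis, n_null, seed, tail
    )
    if not rows:
        raise InputError("no testable pairing rows (all references missing)")
    df = pd.DataFrame(rows)
    df["significant"] = df["p_empirical"] <= alpha
    p_adj, reject = fdr_bh(df["p_empirical"].to_numpy(), alpha)
    df["p_fdr"] = p_adj
    df["significant_fdr"] = reject
    summary = _summarise(df, alpha, n_null, seed)
    summary["by_layer"] = {
        layer: {
            "n_tested": len(grp),
            "n_significant": int(grp["significant"].sum()),
            "proportion": float(grp["significant"].mean()),
        }
        for layer, grp in df.groupby("layer")
    }
    sig_layers = df.groupby(["gene", "receptor"])["significant"].sum()
    summary["pairs_significant_in_ge1_layers"] = int((sig_layers >= 1).sum())
    summary["pairs_significant_in_ge2_layers"] = int((sig_layers >= 2).sum())
    return BenchmarkTable(df, summary, skipped)


def _permutation_pvalue_spearman(
    x: np.ndarray, y: np.ndarray, n_perm: int, seed: int | None
) -> tuple[float, float, str]:
    """Two-sided permutation p for Spearman r: exhaustive for <= 7 points."""
    r_obs = spearman_r(x, y)
    n = len(x)
    rx, ry = rankdata(x), rankdata(y)
    ry_c = ry - ry.mean()
    if n <= 7:
        perms = np.array(list(permutations(range(n))))
        tag = "exact_enumeration"
    else:
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(n) for _ in range(n_perm)])
        tag = f"monte_carlo_{n_perm}"
    rx_perm = rx[perms]
    rx_c = rx_perm - rx_perm.mean(axis=1, keepdims=True)
    null_r = (rx_c @ ry_c) / np.sqrt((rx_c * rx_c).sum(axis=1) * (ry_c * ry_c).sum())
    if tag == "exact_enumeration":
        p = float(np.mean(np.abs(null_r) >= np.abs(r_obs) - 1e-12))
    else:
        p = (1 + int(np.sum(np.abs(null_r) >= np.abs(r_obs) - 1e-12))) / (1 + n_perm)
    return r_obs, p, tag


def within_region_layer_correlation(
    gene_profile: np.ndarray,
    receptor_profile: np.ndarray,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> CorrespondenceResult:
    """Rank correlation across cortical layers within one region.

    Each layer is one data point: the gene's laminar expression profile is
    correlated against the receptor's laminar density profile. With <= 7
    layers the permutation p-value enumerates all layer orderings; beyond
    that a seeded Monte-Carlo permutation is used. Two-sided.
    """
    x = np.asarray(gene_profile, dtype=float)
    y = np.asarray(receptor_profile, dtype=float)
    xs, ys = _complete_pairs(x, y)
    r, p, tag = _permutation_pvalue_spearman(xs, ys, n_perm, seed)
    n_null = math.factorial(len(xs)) if tag == "exact_enumeration" else n_perm
    return CorrespondenceResult(
        feature_a="gene_layers",
        feature_b="receptor_layers",
        n_regions_used=len(xs),
        spearman_r=r,
        p_empirical=p,
        tail="two_sided",
        n_null=n_null,
        seed=seed,
    )


def cross_layer_matrix(
    gene_layer_values: pd.DataFrame,
    receptor_layer_values: pd.DataFrame,
    alpha: float = 0.05,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Layer x layer correlation matrix across gene-receptor pairs.

    Inputs are pair x layer tables (rows aligned: one gene-receptor pair per
    row; layer sets may differ between the two). Entry (a, b) is the
    Spearman correlation across pairs between gene values in layer a and
    receptor values in layer b, with a permutation p-value and FDR flags
    computed over all entries jointly. Negative entries are reported as-is.
    """
    g = gene_layer_values
    r = receptor_layer_values
    if len(g) != len(r):
        raise InputError("gene and receptor tables must have the same pair rows")
    if len(g) < 3:
        raise PreconditionError("need >= 3 gene-receptor pairs")
    corr = pd.DataFrame(index=g.columns, columns=r.columns, dtype=float)
    pval = corr.copy()
    base = 0 if seed is None else int(seed)
    for i, la in enumerate(g.columns):
        for j, lb in enumerate(r.columns):
            x = g[la].to_numpy(float)
            y = r[lb].to_numpy(float)
            xs, ys = _complete_pairs(x, y)
            rr, pp, _ = _permutation_pvalue_spearman(
                xs, ys, n_perm, base + i * len(r.columns) + j
            )
            corr.loc[la, lb] = rr
            pval.loc[la, lb] = pp
    flat = pval.to_numpy(float).ravel()
    _, reject = fdr_bh(flat, alpha)
    flags = pd.DataFrame(
        reject.reshape(pval.shape), index=pval.index, columns=pval.columns
    )
    return corr, pval, flags


def fdr_bh(p_values: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR: (adjusted p-values, rejection flags)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise InputError("empty p-value list")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise InputError("p-values must lie in (0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return p_adj, reject


def chi2_proportions(
    k1: int, n1: int, k2: int, n2: int, correction: bool = False
) -> tuple[float, float]:
    """Pearson chi-squared test comparing two proportions k1/n1 vs k2/n2.

    2x2 table, 1 df; no Yates continuity correction unless requested.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n < 1 or not 0 <= k <= n:
            raise InputError(f"invalid counts k={k}, n={n}")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if np.any(table.sum(axis=0) == 0):
        raise InputError("degenerate 2x2 table: a column margin is zero")
    if np.all(table[:, 0] == 0) or np.all(table[:, 1] == 0):
        raise InputError("degenerate 2x2 table")
    res = sps.chi2_contingency(table, correction=correction)
    return float(res.statistic), float(res.pvalue)


def group_difference(
    values_a: np.ndarray, values_b: np.ndarray
) -> tuple[float, int, float, float]:
    """Pooled-variance independent-samples t test with Cohen's d.

    Returns (t, df, d, p) with df = n_a + n_b - 2 and
    d = (mean_a - mean_b) / pooled SD.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise PreconditionError("each group needs >= 2 finite values")
    df = len(a) + len(b) - 2
    sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / df
    if sp2 == 0:
        return 0.0, df, 0.0, 1.0
    res = sps.ttest_ind(a, b, equal_var=True)
    d = float((a.mean() - b.mean()) / np.sqrt(sp2))
    return float(res.statistic), df, d, float(res.pvalue)
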