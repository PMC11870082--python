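"""Principal gradients and region-wise cross-dataset correlation profiles.

A region x gene matrix is summarised by its dominant principal component
("gene PC1"): the regional score pattern capturing the most expression
variance. Columns are z-scored before the decomposition so genes of
different dynamic range contribute equally (covariance-matrix PCA is
available as a toggle). Since a principal axis has arbitrary sign, PC1 is
oriented to correlate positively with the row-mean of the z-scored matrix,
and gradient-to-map correspondence is assessed two-sided on |r|.

Complementary to correlating one feature across regions, the region-wise
profile correlates all shared features within each region between two
datasets (e.g. macaque vs human orthologous expression) — each data point
is a gene — yielding one correlation per region, which can then be
contrasted between region classes (unimodal vs transmodal) or correlated
against an external map such as cortical expansion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datamodel import FeatureMatrix
from .exceptions import InputError, PreconditionError
from .nulls import SpatialBasis
from .stats import CorrespondenceResult, group_difference, spearman_r, test_correspondence

__all__ = [
    "GradientResult",
    "principal_gradient",
    "gradient_correspondence",
    "regionwise_correlation",
    "class_contrast",
    "map_vs_external_map",
]


@dataclass(frozen=True)
class GradientResult:
    """PCA gradient decomposition of a region x feature matrix."""

    region_labels: tuple[str, ...]
    feature_names: tuple[str, ...]
    scores: np.ndarray               # (n_regions, k), PC1 first
    loadings: np.ndarray             # (n_features, k)
    variance_explained: np.ndarray   # fraction per retained component
    preprocessing_tag: str
    dropped_features: tuple[str, ...] = ()

    @property
    def pc1(self) -> np.ndarray:
        return self.scores[:, 0].copy()


def principal_gradient(
    matrix: FeatureMatrix,
    n_components: int = 5,
    scale: bool = True,
) -> GradientResult:
    """Principal components of a region x feature matrix via SVD.

    Features with any missing value or zero variance are dropped (and
    reported); columns are centred and, with ``scale=True`` (default),
    z-scored. Components are ordered by variance explained; each score
    vector is oriented to correlate positively with the row-mean of the
    preprocessed matrix (falling back to a positive largest-magnitude entry
    when that correlation vanishes).
    """
    vals = matrix.values
    complete = np.all(np.isfinite(vals), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sd = np.nanstd(vals, axis=0, ddof=0)
    usable = complete & (sd > 0)
    dropped = tuple(f for f, u in zip(matrix.feature_names, usable) if not u)
    if dropped:
        warnings.warn(f"features dropped before PCA: {list(dropped)}")
    if usable.sum() < 2:
        raise PreconditionError("need >= 2 usable features for PCA")
    if matrix.n_regions < 3:
        raise PreconditionError("need >= 3 regions for PCA")

    x = vals[:, usable]
    x = x - x.mean(axis=0)
    if scale:
        x = x / x.std(axis=0, ddof=0)
        tag = "zscore"
    else:
        tag = "center"
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    total = float(np.sum(s**2))
    k = int(min(n_components, s.size))
    scores = u[:, :k] * s[:k]
    loadings = vt[:k].T
    var_exp = (s[:k] ** 2) / total

    row_mean = x.mean(axis=1)
    for j in range(k):
        ref = float(scores[:, j] @ (row_mean - row_mean.mean()))
        if abs(ref) > 1e-12:
            flip = ref < 0
        else:
            peak = int(np.argmax(np.abs(scores[:, j])))
            flip = scores[peak, j] < 0
        if flip:
            scores[:, j] *= -1
            loadings[:, j] *= -1

    return GradientResult(
        region_labels=matrix.parcellation.region_labels,
        feature_names=tuple(f for f, u_ in zip(matrix.feature_names, usable) if u_),
        scores=scores,
        loadings=loadings,
        variance_explained=var_exp,
        preprocessing_tag=tag,
        dropped_features=dropped,
    )


def gradient_correspondence(
    grad_a: GradientResult,
    grad_b_or_map: "GradientResult | np.ndarray",
    basis: SpatialBasis,
    n_null: int = 10_000,
    seed: int | None = None,
) -> tuple[CorrespondenceResult, float]:
    """Correspondence between a PC1 gradient and another gradient or map.

    Delegates to the surrogate test on PC1 scores; because PCA sign is
    arbitrary in principle, the r under sign flip (= -r) is returned
    alongside and significance is two-sided on |r|.
    """
    other = (
        grad_b_or_map.pc1
        if isinstance(grad_b_or_map, GradientResult)
        else np.asarray(grad_b_or_map, dtype=float)
    )
    res = test_correspondence(
        grad_a.pc1,
        other,
        basis,
        n_null=n_null,
        seed=seed,
        tail="two_sided",
        feature_a="PC1_a",
        feature_b="PC1_b" if isinstance(grad_b_or_map, GradientResult) else "map",
    )
    return res, -res.spearman_r


def regionwise_correlation(
    a: FeatureMatrix,
    b: FeatureMatrix,
    min_features: int = 3,
) -> FeatureMatrix:
    """Per-region Spearman correlation across shared features.

    Inputs must already be feature-aligned (see ``align_features``). Each
    region with >= `min_features` shared non-missing features receives the
    rank correlation of its two feature profiles; other regions are missing.
    """
    if a.feature_names != b.feature_names:
        raise InputError("matrices must be feature-aligned (run align_features)")
    if a.parcellation.region_labels != b.parcellation.region_labels:
        raise InputError("matrices must share a parcellation")
    out = np.full((a.n_regions, 1), np.nan)
    for i in range(a.n_regions):
        x, y = a.values[i], b.values[i]
        mask = np.isfinite(x) & np.isfinite(y)
        if mask.sum() < min_features:
            continue
        if np.ptp(x[mask]) == 0 or np.ptp(y[mask]) == 0:
            continue
        out[i, 0] = spearman_r(x[mask], y[mask])
    if not np.any(np.isfinite(out)):
        raise PreconditionError(
            f"no region has >= {min_features} shared non-missing features"
        )
    return FeatureMatrix(a.parcellation, ("regionwise_r",), out, {"derived": "regionwise_correlation"})


def class_contrast(
    regionwise_map: FeatureMatrix,
    classes: "tuple[str, ...] | None" = None,
) -> dict:
    """Contrast a per-region map between two region classes.

    Classes come from the parcellation's ``region_class`` tags unless given
    explicitly. Returns per-class means and the pooled-variance t test with
    Cohen's d (first class minus second, in sorted class-name order).
    """
    tags = classes if classes is not None else regionwise_map.parcellation.region_class
    if tags is None:
        raise InputError("no region classes available")
    vals = regionwise_map.values[:, 0]
    names = sorted(set(tags))
    if len(names) != 2:
        raise InputError(f"exactly two classes required, got {names}")
    groups = {
        c: vals[np.array([t == c for t in tags]) & np.isfinite(vals)] for c in names
    }
    t, df, d, p = group_difference(groups[names[0]], groups[names[1]])
    return {
        "classes": names,
        "means": {c: float(np.mean(groups[c])) for c in names},
        "n": {c: int(len(groups[c])) for c in names},
        "t": t,
        "df": df,
        "cohens_d": d,
        "p": p,
    }


def map_vs_external_map(
    regionwise_map: FeatureMatrix,
    external: FeatureMatrix,
    basis: SpatialBasis,
    n_null: int = 10_000,
    seed: int | None = None,
    tail: str = "two_sided",
) -> CorrespondenceResult:
    """Surrogate correspondence between a per-region profile and an external
    scalar map (e.g. cortical expansion)."""
    return test_correspondence(
        regionwise_map.values[:, 0],
        external.values[:, 0],
        basis,
        n_null=n_null,
        seed=seed,
        tail=tail,
        feature_a=regionwise_map.feature_names[0],
        feature_b=external.feature_names[0],
    )
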