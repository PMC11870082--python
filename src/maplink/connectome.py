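"""Connectome-weighted projection of regional expression.

Tests whether a receptor's regional density tracks the gene expression of
the regions a given region projects to, rather than local expression: each
region's value is replaced by the connection-strength-weighted average of
its structurally connected neighbours,

    x'_i = sum_{j in N(i)} w_ij x_j / sum_{j in N(i)} w_ij

where N(i) is the set of regions region i has outgoing connections to and
w_ij the connection weight. The projected map is then compared against the
receptor map with the usual surrogate correspondence test.
"""

from __future__ import annotations

import warnings

import numpy as np

from .datamodel import Connectome, FeatureMatrix, normalize_label
from .exceptions import InputError

__all__ = ["neighbor_weighted_expression"]


def neighbor_weighted_expression(
    x: FeatureMatrix,
    connectome: Connectome,
    direction: str = "out",
    threshold: float = 0.0,
) -> FeatureMatrix:
    """Weighted average of each region's connected neighbours' values.

    Parameters
    ----------
    x
        Feature matrix whose regions match the connectome's labels.
    connectome
        Directed non-negative weights, zero diagonal.
    direction
        "out" (default) averages over outgoing connections w_ij, as in the
        projection equation; "in" uses incoming connections (sensitivity
        toggle).
    threshold
        Weights <= threshold are treated as absent (default keeps every
        positive weight).

    Regions with no retained neighbours — or none with a non-missing value —
    become missing and are reported in a warning.
    """
    if direction not in ("out", "in"):
        raise InputError(f"direction must be 'out' or 'in', got {direction!r}")
    a = [normalize_label(r) for r in x.parcellation.region_labels]
    b = [normalize_label(r) for r in connectome.region_labels]
    if a != b:
        raise InputError("matrix and connectome region labels differ")
    w = connectome.weights if direction == "out" else connectome.weights.T
    w = np.where(w > threshold, w, 0.0)

    vals = x.values
    finite = np.isfinite(vals)
    filled = np.where(finite, vals, 0.0)
    numer = w @ filled                 # (n_regions, n_features)
    denom = w @ finite.astype(float)   # weight mass over observed neighbours
    out = np.where(denom > 0, numer / np.where(denom > 0, denom, 1.0), np.nan)

    isolated = [
        r for r, row in zip(x.parcellation.region_labels, w) if not np.any(row > 0)
    ]
    if isolated:
        warnings.warn(f"regions with no retained connections (left missing): {isolated}")
    meta = dict(x.meta)
    meta["projection"] = f"neighbor_weighted_{direction}"
    return FeatureMatrix(x.parcellation, x.feature_names, out, meta)
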