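"""Core data model for parcellated cortical molecular maps.

A :class:`Parcellation` is the spatial frame: an ordered set of labelled
cortical regions with 3-D centroid coordinates (mm), optionally annotated
with hemisphere and functional class (e.g. unimodal / transmodal).
A :class:`FeatureMatrix` holds region x feature values (gene expression,
receptor density per neuron, or scalar maps such as T1w:T2w) on one
parcellation; missing values are NaN and are propagated, never imputed.
A :class:`PairingTable` lists gene <-> receptor pairings with their
neurotransmitter system class; multimeric receptors appear in several rows,
one per subunit gene. A :class:`Connectome` is a weighted directed
region x region matrix of structural connectivity.

Region labels are matched exactly after whitespace/case normalisation;
fuzzy matching is deliberately refused so that every cross-atlas
correspondence is explicit in a :class:`RegionMappingTable`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .exceptions import InputError

SYSTEM_CLASSES = ("GABA", "glutamate", "neuromodulatory")
HEMISPHERES = ("L", "R", "bilateral")


def normalize_label(label: str) -> str:
    """Canonical form used for all region/feature label matching."""
    return str(label).strip().lower()


@dataclass(frozen=True)
class Parcellation:
    """Labelled cortical regions with centroid coordinates.

    Parameters
    ----------
    region_labels
        Ordered unique, non-empty region names; at least 3.
    centroids
        (n_regions, 3) finite coordinates in mm.
    hemisphere
        Optional per-region tag in {"L", "R", "bilateral"}.
    region_class
        Optional per-region class tag (e.g. "unimodal" / "transmodal").
    """

    region_labels: tuple[str, ...]
    centroids: np.ndarray
    hemisphere: tuple[str, ...] | None = None
    region_class: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        labels = tuple(str(r).strip() for r in self.region_labels)
        if len(labels) < 3:
            raise InputError(f"parcellation needs >= 3 regions, got {len(labels)}")
        if any(not r for r in labels):
            raise InputError("empty region label")
        norm = [normalize_label(r) for r in labels]
        if len(set(norm)) != len(norm):
            dupes = sorted({r for r in norm if norm.count(r) > 1})
            raise InputError(f"duplicate region labels: {dupes}")
        cent = np.asarray(self.centroids, dtype=float)
        if cent.shape != (len(labels), 3):
            raise InputError(
                f"centroids must be ({len(labels)}, 3), got {cent.shape}"
            )
        if not np.all(np.isfinite(cent)):
            raise InputError("non-finite centroid coordinates")
        object.__setattr__(self, "region_labels", labels)
        cent.setflags(write=False)
        object.__setattr__(self, "centroids", cent)
        for name in ("hemisphere", "region_class"):
            tags = getattr(self, name)
            if tags is not None:
                tags = tuple(str(t).strip() for t in tags)
                if len(tags) != len(labels):
                    raise InputError(f"{name} tags must cover every region")
                object.__setattr__(self, name, tags)
        if self.hemisphere is not None:
            bad = sorted(set(self.hemisphere) - set(HEMISPHERES))
            if bad:
                raise InputError(f"invalid hemisphere tags {bad}; allowed {HEMISPHERES}")

    @property
    def n_regions(self) -> int:
        return len(self.region_labels)

    def index_of(self, labels: Iterable[str]) -> np.ndarray:
        """Positional indices of `labels` (whitespace/case-normalised match)."""
        lut = {normalize_label(r): i for i, r in enumerate(self.region_labels)}
        idx = []
        for lab in labels:
            key = normalize_label(lab)
            if key not in lut:
                raise InputError(f"unknown region label {lab!r}")
            idx.append(lut[key])
        return np.asarray(idx, dtype=int)

    def subset(self, labels: Sequence[str]) -> "Parcellation":
        """Sub-parcellation restricted to `labels`, in the given order."""
        idx = self.index_of(labels)
        return Parcellation(
            region_labels=tuple(self.region_labels[i] for i in idx),
            centroids=self.centroids[idx],
            hemisphere=tuple(self.hemisphere[i] for i in idx) if self.hemisphere else None,
            region_class=tuple(self.region_class[i] for i in idx) if self.region_class else None,
        )


@dataclass(frozen=True)
class FeatureMatrix:
    """Region x feature values on one parcellation; NaN marks missing.

    ``meta`` carries provenance tags such as ``species``, ``modality`` and
    ``layer`` ("L1".."L6" or an aggregate tag).
    """

    parcellation: Parcellation
    feature_names: tuple[str, ...]
    values: np.ndarray
    meta: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = tuple(str(f).strip() for f in self.feature_names)
        if len(set(names)) != len(names):
            raise InputError("duplicate feature names")
        if any(not f for f in names):
            raise InputError("empty feature name")
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2 or vals.shape != (self.parcellation.n_regions, len(names)):
            raise InputError(
                f"values must be ({self.parcellation.n_regions}, {len(names)}), "
                f"got {vals.shape}"
            )
        vals = vals.copy()
        vals.setflags(write=False)
        object.__setattr__(self, "feature_names", names)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "meta", dict(self.meta))

    @property
    def n_regions(self) -> int:
        return self.parcellation.n_regions

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def feature(self, name: str) -> np.ndarray:
        """Column of values for one feature (normalised name match)."""
        lut = {normalize_label(f): j for j, f in enumerate(self.feature_names)}
        key = normalize_label(name)
        if key not in lut:
            raise InputError(f"unknown feature {name!r}")
        return self.values[:, lut[key]].copy()

    def has_feature(self, name: str) -> bool:
        return normalize_label(name) in {normalize_label(f) for f in self.feature_names}

    def degenerate_features(self, min_values: int = 3) -> tuple[str, ...]:
        """Features with fewer than `min_values` non-missing regions."""
        counts = np.sum(np.isfinite(self.values), axis=0)
        return tuple(f for f, c in zip(self.feature_names, counts) if c < min_values)

    def with_values(self, values: np.ndarray) -> "FeatureMatrix":
        return replace(self, values=values)


@dataclass(frozen=True)
class RegionMappingTable:
    """Many-to-one mapping from source-atlas regions to target-atlas regions."""

    rows: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        rows = tuple((str(s).strip(), str(t).strip()) for s, t in self.rows)
        if any(not s or not t for s, t in rows):
            raise InputError("empty label in region mapping")
        sources = [normalize_label(s) for s, _ in rows]
        if len(set(sources)) != len(sources):
            dupes = sorted({s for s in sources if sources.count(s) > 1})
            raise InputError(f"source region mapped more than once: {dupes}")
        object.__setattr__(self, "rows", rows)

    def targets(self) -> tuple[str, ...]:
        seen: dict[str, str] = {}
        for _, t in self.rows:
            seen.setdefault(normalize_label(t), t)
        return tuple(seen.values())


@dataclass(frozen=True)
class PairingTable:
    """Gene <-> receptor pairings with neurotransmitter system class.

    A multimeric receptor (GABA_A, NMDA, ...) pairs with every gene coding
    one of its subunits, so the same receptor may appear in many rows.
    """

    rows: tuple[tuple[str, str, str], ...]

    def __post_init__(self) -> None:
        rows = tuple(
            (str(g).strip(), str(r).strip(), str(c).strip()) for g, r, c in self.rows
        )
        if any(not g or not r for g, r, _ in rows):
            raise InputError("empty gene or receptor label in pairing table")
        keys = [(normalize_label(g), normalize_label(r)) for g, r, _ in rows]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise InputError(f"duplicate (gene, receptor) rows: {dupes}")
        bad = sorted({c for _, _, c in rows} - set(SYSTEM_CLASSES))
        if bad:
            raise InputError(f"invalid system_class {bad}; allowed {SYSTEM_CLASSES}")
        object.__setattr__(self, "rows", rows)

    def __len__(self) -> int:
        return len(self.rows)


@dataclass(frozen=True)
class Connectome:
    """Weighted directed structural connectivity, zero diagonal, weights >= 0."""

    region_labels: tuple[str, ...]
    weights: np.ndarray

    def __post_init__(self) -> None:
        labels = tuple(str(r).strip() for r in self.region_labels)
        w = np.asarray(self.weights, dtype=float)
        n = len(labels)
        if w.shape != (n, n):
            raise InputError(f"connectome weights must be ({n}, {n}), got {w.shape}")
        if not np.all(np.isfinite(w)):
            raise InputError("non-finite connectome weights")
        if np.any(w < 0):
            raise InputError("negative connectome weights")
        if np.any(np.diagonal(w) != 0):
            raise InputError("connectome diagonal must be exactly zero")
        w = w.copy()
        w.setflags(write=False)
        object.__setattr__(self, "region_labels", labels)
        object.__setattr__(self, "weights", w)


# ---------------------------------------------------------------------------
# Harmonisation operations
# ---------------------------------------------------------------------------


def remap_regions(
    matrix: FeatureMatrix,
    mapping: RegionMappingTable,
    target: Parcellation,
    aggregator: str = "mean",
) -> FeatureMatrix:
    """Resample a feature matrix onto another parcellation via a mapping table.

    Each target region receives the `aggregator` (mean or median) of all its
    mapped source regions' non-missing values; target regions with no mapped
    source stay missing. Source regions named in the mapping but absent from
    `matrix` are skipped with a warning.
    """
    if aggregator not in ("mean", "median"):
        raise InputError(f"aggregator must be 'mean' or 'median', got {aggregator!r}")
    agg = np.nanmean if aggregator == "mean" else np.nanmedian

    src_lut = {normalize_label(r): i for i, r in enumerate(matrix.parcellation.region_labels)}
    tgt_lut = {normalize_label(r): i for i, r in enumerate(target.region_labels)}
    bad_targets = sorted({t for _, t in mapping.rows if normalize_label(t) not in tgt_lut})
    if bad_targets:
        raise InputError(f"mapping targets not in target parcellation: {bad_targets}")

    groups: dict[int, list[int]] = {}
    skipped: list[str] = []
    for src, tgt in mapping.rows:
        i = src_lut.get(normalize_label(src))
        if i is None:
            skipped.append(src)
            continue
        groups.setdefault(tgt_lut[normalize_label(tgt)], []).append(i)
    if skipped:
        warnings.warn(f"mapping sources absent from matrix, skipped: {sorted(skipped)}")

    out = np.full((target.n_regions, matrix.n_features), np.nan)
    for tgt_i, src_idx in groups.items():
        block = matrix.values[src_idx]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
            out[tgt_i] = agg(block, axis=0)
    empty = [r for i, r in enumerate(target.region_labels) if i not in groups]
    if empty:
        warnings.warn(f"target regions with no mapped sources (left missing): {empty}")
    return FeatureMatrix(target, matrix.feature_names, out, dict(matrix.meta))


def mirror_hemispheres(
    matrix: FeatureMatrix,
    lr_pairs: Sequence[tuple[str, str]],
    pool: bool = False,
) -> FeatureMatrix:
    """Share values between homologous left/right regions.

    Where exactly one side of a pair is non-missing, the value is copied to
    the other side. Where both are present, each keeps its own value unless
    ``pool=True``, in which case both sides receive their mean.
    """
    vals = np.array(matrix.values)
    for left, right in lr_pairs:
        li, ri = matrix.parcellation.index_of([left, right])
        a, b = vals[li].copy(), vals[ri].copy()
        only_a = np.isfinite(a) & ~np.isfinite(b)
        only_b = np.isfinite(b) & ~np.isfinite(a)
        vals[ri, only_a] = a[only_a]
        vals[li, only_b] = b[only_b]
        if pool:
            both = np.isfinite(a) & np.isfinite(b)
            pooled = (a[both] + b[both]) / 2.0
            vals[li, both] = pooled
            vals[ri, both] = pooled
    return matrix.with_values(vals)


def align_features(
    a: FeatureMatrix,
    b: FeatureMatrix,
    ortholog_map: Sequence[tuple[str, str]] | None = None,
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Restrict two matrices to shared (or ortholog-mapped) features and to
    regions non-missing in both.

    Without a map, features are matched by normalised name. With an ortholog
    map of (a_name, b_name) rows, the mapped pairs define the shared set and
    the output columns of `b` are renamed to the `a` symbols so downstream
    code can treat the matrices as feature-aligned.
    """
    if tuple(a.parcellation.region_labels) != tuple(b.parcellation.region_labels):
        raise InputError("matrices must share a parcellation; remap first")
    a_lut = {normalize_label(f): j for j, f in enumerate(a.feature_names)}
    b_lut = {normalize_label(f): j for j, f in enumerate(b.feature_names)}

    pairs: list[tuple[int, int, str]] = []  # (a column, b column, output name)
    if ortholog_map is None:
        for f in a.feature_names:
            key = normalize_label(f)
            if key in b_lut:
                pairs.append((a_lut[key], b_lut[key], f))
    else:
        for a_name, b_name in ortholog_map:
            ka, kb = normalize_label(a_name), normalize_label(b_name)
            if ka in a_lut and kb in b_lut:
                pairs.append((a_lut[ka], b_lut[kb], str(a_name).strip()))
    if not pairs:
        raise InputError("no shared features between the two matrices")

    kept = {j for j, _, _ in pairs}
    dropped_a = tuple(f for j, f in enumerate(a.feature_names) if j not in kept)
    kept_b = {j for _, j, _ in pairs}
    dropped_b = tuple(f for j, f in enumerate(b.feature_names) if j not in kept_b)
    if dropped_a or dropped_b:
        warnings.warn(
            f"features dropped by alignment: a={list(dropped_a)}, b={list(dropped_b)}"
        )

    ja = [p[0] for p in pairs]
    jb = [p[1] for p in pairs]
    names = tuple(p[2] for p in pairs)
    va, vb = a.values[:, ja], b.values[:, jb]
    keep_regions = np.any(np.isfinite(va), axis=1) & np.any(np.isfinite(vb), axis=1)
    sub = [r for r, k in zip(a.parcellation.region_labels, keep_regions) if k]
    if len(sub) < a.parcellation.n_regions:
        parc = a.parcellation.subset(sub)
        va, vb = va[keep_regions], vb[keep_regions]
    else:
        parc = a.parcellation
    return (
        FeatureMatrix(parc, names, va, dict(a.meta)),
        FeatureMatrix(parc, names, vb, dict(b.meta)),
    )
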