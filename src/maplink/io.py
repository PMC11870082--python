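"""Delimited-text I/O for the data model.

All tables are CSV/TSV with a header row. Feature matrices, parcellations
and mapping tables carry the region label in a column named ``region``;
connectomes are square CSVs with region labels as both header and first
column. Numeric output is written with 10 significant digits so that
read -> write -> read round-trips are exact at the textual representation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    Connectome,
    FeatureMatrix,
    PairingTable,
    Parcellation,
    RegionMappingTable,
    normalize_label,
)
from .exceptions import InputError

FLOAT_FMT = "%.10g"


@dataclass
class LoadReport:
    """What happened while aligning a file onto a parcellation."""

    missing_regions: list[str] = field(default_factory=list)  # in parcellation, not in file
    unknown_regions: list[str] = field(default_factory=list)  # in file, not in parcellation


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        return pd.read_csv(path, sep=sep)
    except FileNotFoundError:
        raise InputError(f"file not found: {path}") from None
    except Exception as exc:  # malformed text
        raise InputError(f"cannot parse {path}: {exc}") from None


def read_parcellation(path: str | Path) -> Parcellation:
    """Read a parcellation table (region, x, y, z[, hemisphere][, region_class])."""
    df = _read_table(path)
    required = {"region", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise InputError(f"{path}: parcellation needs columns {sorted(required)}")
    return Parcellation(
        region_labels=tuple(df["region"].astype(str)),
        centroids=df[["x", "y", "z"]].to_numpy(float),
        hemisphere=tuple(df["hemisphere"].astype(str)) if "hemisphere" in df else None,
        region_class=tuple(df["region_class"].astype(str)) if "region_class" in df else None,
    )


def write_parcellation(path: str | Path, parc: Parcellation) -> None:
    df = pd.DataFrame(
        {"region": parc.region_labels,
         "x": parc.centroids[:, 0], "y": parc.centroids[:, 1], "z": parc.centroids[:, 2]}
    )
    if parc.hemisphere is not None:
        df["hemisphere"] = parc.hemisphere
    if parc.region_class is not None:
        df["region_class"] = parc.region_class
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_feature_matrix(
    path: str | Path,
    parcellation: Parcellation,
    return_report: bool = False,
) -> FeatureMatrix | tuple[FeatureMatrix, LoadReport]:
    """Read a region x feature table and align its rows to `parcellation`.

    Rows are re-ordered to parcellation order. Parcellation regions absent
    from the file become all-missing rows (warned); file regions unknown to
    the parcellation are dropped and reported. Duplicate region rows are an
    error.
    """
    df = _read_table(path)
    if "region" not in df.columns:
        raise InputError(f"{path}: missing 'region' column")
    feature_cols = [c for c in df.columns if c != "region"]
    if not feature_cols:
        raise InputError(f"{path}: no feature columns")

    keys = df["region"].astype(str).map(normalize_label)
    if keys.duplicated().any():
        dupes = sorted(df["region"].astype(str)[keys.duplicated()].unique())
        raise InputError(f"{path}: duplicate region rows: {dupes}")

    lut = {normalize_label(r): i for i, r in enumerate(parcellation.region_labels)}
    report = LoadReport()
    values = np.full((parcellation.n_regions, len(feature_cols)), np.nan)
    file_vals = df[feature_cols].to_numpy(float)
    seen = set()
    for row, (key, raw) in enumerate(zip(keys, df["region"].astype(str))):
        if key in lut:
            values[lut[key]] = file_vals[row]
            seen.add(key)
        else:
            report.unknown_regions.append(raw)
    if not seen:
        raise InputError(f"{path}: no region overlaps the parcellation")
    report.missing_regions = [
        r for r in parcellation.region_labels if normalize_label(r) not in seen
    ]
    if report.missing_regions:
        warnings.warn(f"{path}: regions missing from file: {report.missing_regions}")
    if report.unknown_regions:
        warnings.warn(f"{path}: unknown regions dropped: {report.unknown_regions}")

    fm = FeatureMatrix(parcellation, tuple(feature_cols), values)
    return (fm, report) if return_report else fm


def write_feature_matrix(path: str | Path, matrix: FeatureMatrix) -> None:
    df = pd.DataFrame(matrix.values, columns=list(matrix.feature_names))
    df.insert(0, "region", matrix.parcellation.region_labels)
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_region_mapping(path: str | Path) -> RegionMappingTable:
    df = _read_table(path)
    if not {"source_region", "target_region"}.issubset(df.columns):
        raise InputError(f"{path}: mapping needs source_region and target_region columns")
    return RegionMappingTable(
        rows=tuple(zip(df["source_region"].astype(str), df["target_region"].astype(str)))
    )


def write_region_mapping(path: str | Path, mapping: RegionMappingTable) -> None:
    pd.DataFrame(mapping.rows, columns=["source_region", "target_region"]).to_csv(
        path, index=False
    )


def read_pairing_table(path: str | Path) -> PairingTable:
    df = _read_table(path)
    if not {"gene", "receptor", "system_class"}.issubset(df.columns):
        raise InputError(f"{path}: pairing needs gene, receptor, system_class columns")
    return PairingTable(
        rows=tuple(
            zip(df["gene"].astype(str), df["receptor"].astype(str),
                df["system_class"].astype(str))
        )
    )


def write_pairing_table(path: str | Path, pairing: PairingTable) -> None:
    pd.DataFrame(pairing.rows, columns=["gene", "receptor", "system_class"]).to_csv(
        path, index=False
    )


def read_connectome(path: str | Path) -> Connectome:
    """Square CSV with region labels as header and first column."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except FileNotFoundError:
        raise InputError(f"file not found: {path}") from None
    rows = [normalize_label(r) for r in df.index.astype(str)]
    cols = [normalize_label(c) for c in df.columns.astype(str)]
    if rows != cols:
        raise InputError(f"{path}: connectome row and column labels differ")
    return Connectome(tuple(df.index.astype(str)), df.to_numpy(float))


def write_connectome(path: str | Path, connectome: Connectome) -> None:
    pd.DataFrame(
        connectome.weights,
        index=list(connectome.region_labels),
        columns=list(connectome.region_labels),
    ).to_csv(path, float_format=FLOAT_FMT)


def read_ortholog_map(path: str | Path) -> tuple[tuple[str, str], ...]:
    """Two-column (a_name, b_name) feature/ortholog correspondence table."""
    df = _read_table(path)
    if df.shape[1] < 2:
        raise InputError(f"{path}: ortholog map needs two columns")
    a, b = df.columns[:2]
    return tuple(zip(df[a].astype(str), df[b].astype(str)))
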