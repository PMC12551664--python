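"""Tabular data model, feature registry, readers/writers and matrix preparation.

The analysis operates on flat per-survey tables keyed by ``(site_id,
cycle_id)``: a *site* is a stream reach monitored repeatedly, a *cycle*
is one multi-year monitoring rotation.  Four named feature sets drive
the pipeline:

``TIER1``
    8 catchment/watershed climate and geology features (elevation,
    slope, soil permeability and depths, annual rainfall, CaO and S
    lithology) used for the regional clustering.
``TIER2``
    19 reach-scale habitat and chemistry features (sinuosity, watershed
    area, cover, six-part substrate composition, channel geometry,
    three-part channel-unit composition, alkalinity, conductivity) used
    for the within-region clustering.
``CHEM_BCA``
    12 additional water-chemistry medians used only in the post-hoc
    between-class comparison, never in group formation.
``STRESSOR``
    15 anthropogenic land-use / catchment-integrity features used in
    the stressor bias screen.

Features flagged ``log_offset`` are transformed as ``log10(x + 1)``
(the offset absorbs structural zeros in substrate percentages); by
default all clustering/ordination columns are z-scored because the
features span incompatible units (mm of rainfall next to percent
substrate).  Missing data are handled by complete-case deletion per
analysis matrix, never by imputation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

KEY_COLUMNS = ("site_id", "cycle_id")

TRANSFORMS = ("none", "log_offset")
SCALES = ("zscore", "none")
ROLES = ("tier1", "tier2", "chem_bca", "stressor", "meta")

#: Right-skewed ratio/percentage features that get the log10(x + 1) transform.
LOG_OFFSET_FEATURES = frozenset(
    {"Cobble", "Boulder", "W.D", "WS_Area", "Conductivity", "Alkalinity"}
)

_TIER1_NAMES = ("Elevation", "Slope", "PermCat", "RockDep", "WTDep", "AnRainC", "CaOWs", "SWs")
_TIER2_NAMES = (
    "Sin", "WS_Area", "Rocky.Cover", "Woody.Cover", "Veg.Cover",
    "Silt", "Sand", "Gravel", "Cobble", "Boulder", "Bedrock",
    "W.D", "Depth.Var", "Max.Pool.Depth", "Pools", "Runs", "Riffles",
    "Alkalinity", "Conductivity",
)
_CHEM_NAMES = (
    "TN", "Available.N", "TP", "OP", "Chloride", "Sulfate",
    "DO", "DO.perc", "pH", "TSS", "Turbidity", "Temperature.Water",
)
_STRESSOR_NAMES = (
    "OpenUrb", "LowUrb", "MedUrb", "HiUrb", "Hay", "Crop",
    "CBNF", "Fert", "Manure", "ICI", "CCHEM", "RoadDens",
    "Road_Xing", "Houses", "Population",
)

_EXPECTED_SIZES = {"TIER1": 8, "TIER2": 19, "CHEM_BCA": 12, "STRESSOR": 15}

#: Substrate composition features (percentages, close to 100).
SUBSTRATE_FEATURES = ("Silt", "Sand", "Gravel", "Cobble", "Boulder", "Bedrock")
#: Channel-unit composition features (percentages, close to 100).
CHANNEL_UNIT_FEATURES = ("Pools", "Runs", "Riffles")


class SchemaError(ValueError):
    """A table is missing mandatory columns or a feature set is malformed."""


class IntegrityError(ValueError):
    """A table violates a structural invariant (e.g. duplicated keys)."""


class EmptyMatrixError(ValueError):
    """Complete-case filtering removed every row."""


@dataclass(frozen=True)
class FeatureSpec:
    """One named feature with its transform and scaling rule."""

    name: str
    units: str = ""
    transform: str = "none"
    scale: str = "zscore"
    role: str = "tier2"

    def __post_init__(self) -> None:
        if self.transform not in TRANSFORMS:
            raise SchemaError(f"unknown transform {self.transform!r} for {self.name}")
        if self.scale not in SCALES:
            raise SchemaError(f"unknown scale {self.scale!r} for {self.name}")
        if self.role not in ROLES:
            raise SchemaError(f"unknown role {self.role!r} for {self.name}")


@dataclass(frozen=True)
class FeatureSet:
    """Ordered collection of :class:`FeatureSpec` defining an analysis matrix."""

    set_id: str
    specs: tuple[FeatureSpec, ...]

    def __post_init__(self) -> None:
        names = [s.name for s in self.specs]
        if len(set(names)) != len(names):
            raise SchemaError(f"duplicate feature names in set {self.set_id}")
        expected = _EXPECTED_SIZES.get(self.set_id)
        if expected is not None and len(self.specs) != expected:
            raise SchemaError(
                f"feature set {self.set_id} must have {expected} features, got {len(self.specs)}"
            )

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.specs]

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.specs)


def _make_specs(names: tuple[str, ...], role: str) -> tuple[FeatureSpec, ...]:
    return tuple(
        FeatureSpec(
            name=n,
            transform="log_offset" if n in LOG_OFFSET_FEATURES else "none",
            scale="zscore",
            role=role,
        )
        for n in names
    )


_REGISTRY: dict[str, FeatureSet] = {
    "TIER1": FeatureSet("TIER1", _make_specs(_TIER1_NAMES, "tier1")),
    "TIER2": FeatureSet("TIER2", _make_specs(_TIER2_NAMES, "tier2")),
    "CHEM_BCA": FeatureSet("CHEM_BCA", _make_specs(_CHEM_NAMES, "chem_bca")),
    "STRESSOR": FeatureSet("STRESSOR", _make_specs(_STRESSOR_NAMES, "stressor")),
    # Habitat + chemistry: the matrix used for the group-vs-ecoregion
    # between-class comparison (Tier-II habitat features plus the 12
    # post-hoc chemistry medians).
    "HABCHEM": FeatureSet(
        "HABCHEM", _make_specs(_TIER2_NAMES, "tier2") + _make_specs(_CHEM_NAMES, "chem_bca")
    ),
}


def feature_set(set_id: str) -> FeatureSet:
    """Return a registered feature set (``TIER1``, ``TIER2``, ``CHEM_BCA``,
    ``STRESSOR`` or the combined ``HABCHEM``)."""
    try:
        return _REGISTRY[set_id]
    except KeyError:
        raise SchemaError(f"unknown feature set {set_id!r}") from None


@dataclass
class SampleTable:
    """One row per (site, cycle) survey, with numeric features and optional labels.

    Wraps a :class:`pandas.DataFrame` that must carry the key columns
    ``site_id`` and ``cycle_id`` with unique pairs.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        for col in KEY_COLUMNS:
            if col not in self.data.columns:
                raise SchemaError(f"missing mandatory key column {col!r}")
        dup = self.data.duplicated(subset=list(KEY_COLUMNS), keep=False)
        if dup.any():
            pairs = (
                self.data.loc[dup, list(KEY_COLUMNS)]
                .drop_duplicates()
                .itertuples(index=False, name=None)
            )
            raise IntegrityError(f"duplicated (site, cycle) pairs: {sorted(pairs)}")
        self.data = self.data.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def sites(self) -> list[str]:
        return list(pd.unique(self.data["site_id"]))


@dataclass
class AnalysisMatrix:
    """Dense, complete, transformed/scaled feature matrix ready for analysis."""

    values: np.ndarray
    row_index: list[tuple[str, str]]
    column_names: list[str]
    dropped_report: dict = field(default_factory=dict)

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def sites(self) -> list[str]:
        return [s for s, _ in self.row_index]

    def rows_for_site(self, site_id: str) -> np.ndarray:
        mask = np.array([s == site_id for s, _ in self.row_index])
        return self.values[mask]


def read_sample_table(path, fset: FeatureSet) -> SampleTable:
    """Read a survey CSV into a :class:`SampleTable`.

    The header must name at least ``site_id``, ``cycle_id`` and every
    feature of *fset*.  Feature cells are coerced to numeric;
    unparseable cells become missing (the row is retained).  Columns are
    reordered to keys, metadata, then feature-set order.
    """
    df = pd.read_csv(path, dtype={c: str for c in KEY_COLUMNS})
    for col in KEY_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing mandatory key column {col!r} in {path}")
    missing = [n for n in fset.names if n not in df.columns]
    if missing:
        raise SchemaError(f"missing feature columns {missing} in {path}")
    for name in fset.names:
        df[name] = pd.to_numeric(df[name], errors="coerce")
    meta = [c for c in df.columns if c not in fset.names and c not in KEY_COLUMNS]
    df = df[list(KEY_COLUMNS) + meta + fset.names]
    return SampleTable(df)


def aggregate_medians(measurements: pd.DataFrame, analytes: list[str]) -> pd.DataFrame:
    """Collapse long-format chemistry measurements to per-(site, cycle) medians.

    *measurements* has columns ``site_id, cycle_id, analyte, value``.
    One output row per observed (site, cycle); each requested analyte's
    cell is the median of its measurements in that cell (the midpoint of
    the two central order statistics for even counts), or missing when
    the analyte was never measured there.
    """
    for col in ("site_id", "cycle_id", "analyte", "value"):
        if col not in measurements.columns:
            raise SchemaError(f"measurements table missing column {col!r}")
    if measurements.empty:
        return pd.DataFrame(columns=list(KEY_COLUMNS) + list(analytes))
    sub = measurements[measurements["analyte"].isin(analytes)].copy()
    sub["value"] = pd.to_numeric(sub["value"], errors="coerce")
    wide = (
        sub.groupby(["site_id", "cycle_id", "analyte"], sort=True)["value"]
        .median()
        .unstack("analyte")
        .reindex(columns=list(analytes))
        .reset_index()
    )
    wide.columns.name = None
    return wide


def build_feature_matrix(
    table: SampleTable, fset: FeatureSet, scale: bool = True
) -> AnalysisMatrix:
    """Turn a :class:`SampleTable` into a complete-case :class:`AnalysisMatrix`.

    Rows with any missing feature are dropped and counted in
    ``dropped_report``; ``log_offset`` features become ``log10(x + 1)``;
    z-score features are centred and scaled (sample SD, ``ddof=1``)
    using the retained rows.  A constant column under z-scoring keeps
    scale 1 with a warning.  Set ``scale=False`` to keep transformed but
    unscaled columns (used e.g. for interpretable tree thresholds).
    """
    df = table.data
    missing = [n for n in fset.names if n not in df.columns]
    if missing:
        raise SchemaError(f"table missing features {missing}")
    feats = df[fset.names].astype(float)
    complete = feats.notna().all(axis=1)
    per_feature_missing = feats.isna().sum().to_dict()
    retained = feats.loc[complete]
    if retained.empty:
        raise EmptyMatrixError("no complete-case rows for feature set " + fset.set_id)
    values = retained.to_numpy(dtype=float, copy=True)
    for j, spec in enumerate(fset.specs):
        if spec.transform == "log_offset":
            values[:, j] = np.log10(values[:, j] + 1.0)
        if scale and spec.scale == "zscore":
            col = values[:, j]
            mu = col.mean()
            sd = col.std(ddof=1) if len(col) > 1 else 0.0
            if sd == 0.0 or not np.isfinite(sd):
                warnings.warn(
                    f"constant column {spec.name!r} under zscore; scale left at 1",
                    stacklevel=2,
                )
                sd = 1.0
            values[:, j] = (col - mu) / sd
    keys = df.loc[complete, list(KEY_COLUMNS)]
    row_index = list(keys.itertuples(index=False, name=None))
    report = {
        "n_input": int(len(df)),
        "n_retained": int(complete.sum()),
        "n_dropped": int((~complete).sum()),
        "per_feature_missing": {k: int(v) for k, v in per_feature_missing.items()},
    }
    return AnalysisMatrix(values, row_index, list(fset.names), report)


_ASSIGNMENT_COLUMNS = ["site_id", "region", "subgroup", "archetype", "provenance"]


def write_assignments(path, assignment: pd.DataFrame) -> None:
    """Write a per-site group assignment to CSV (round-trip lossless)."""
    if assignment.empty:
        raise ValueError("refusing to write an empty assignment")
    missing = [c for c in _ASSIGNMENT_COLUMNS if c not in assignment.columns]
    if missing:
        raise SchemaError(f"assignment missing columns {missing}")
    extra = [c for c in assignment.columns if c not in _ASSIGNMENT_COLUMNS]
    assignment[_ASSIGNMENT_COLUMNS + extra].to_csv(path, index=False, float_format="%.12g")


def read_assignments(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"site_id": str})
    missing = [c for c in _ASSIGNMENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"assignment file missing columns {missing}")
    return df
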