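"""File formats: delimited feature/case tables, QuPath-style GeoJSON
annotations, YAML configuration and JSON run manifests.

Conventions
-----------
* Delimited tables are UTF-8 with a mandatory header row; comma-separated by
  default, tab-separated with ``dialect="tsv"`` (or a ``.tsv`` extension).
  Missing values are empty fields, never sentinel numbers.
* Annotation coordinates are (x, y) pairs in nm in the section plane, origin
  top-left with y increasing downward (image convention).  A file whose
  ``units`` property says ``pixel`` is scaled by ``pixel_size_nm`` (default
  7.3 nm, the acquisition pixel size of the large-scale datasets) on import.
* Every pipeline run writes a :class:`RunManifest` (JSON) recording the tool
  version, config hash, master seed and the files read/written with their
  record counts, sufficient to re-run bit-identically.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, mapping, shape

from . import __version__
from .config import RubricConfig, config_hash
from .errors import AnnotationError, SchemaError
from .morphometry import CapillaryGeometry, ProcessAnnotation, TriMark
from .rubric import CapillaryFeatures, TriObservation

__all__ = [
    "FEATURE_COLUMNS",
    "RowError",
    "RunManifest",
    "read_feature_table",
    "write_feature_table",
    "features_from_frame",
    "read_case_table",
    "write_table",
    "read_annotations",
    "write_annotations",
    "write_manifest",
    "read_manifest",
]

#: Canonical feature-table columns.  The mandatory ones identify the record;
#: all measurement columns may be empty (missing).
FEATURE_COLUMNS = [
    "case_id",
    "capillary_id",
    "bm_thickness_nm",
    "bm_layer_count",
    "activation_grade",
    "endothelial_area_um2",
    "organelle_prominence",
    "process_count",
    "process_prominence",
    "tri_small",
    "tri_medium",
    "tri_large",
    "degraded",
]
_MANDATORY = ["case_id", "capillary_id"]


@dataclass(frozen=True)
class RowError:
    """One rejected table row, with its 1-based data row number."""

    row: int
    message: str


def _sep(path: str | Path, dialect: str | None) -> str:
    if dialect is None:
        dialect = "tsv" if str(path).endswith(".tsv") else "csv"
    if dialect not in ("csv", "tsv"):
        raise SchemaError(f"unknown table dialect {dialect!r}")
    return "\t" if dialect == "tsv" else ","


def _opt_float(value: Any) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    return float(value)


def _opt_int(value: Any) -> int | None:
    v = _opt_float(value)
    return None if v is None else int(v)


def _opt_str(value: Any) -> str | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    return str(value)


def _row_to_features(row: Mapping[str, Any]) -> CapillaryFeatures:
    tri_counts = {
        "small": _opt_int(row.get("tri_small")),
        "medium": _opt_int(row.get("tri_medium")),
        "large": _opt_int(row.get("tri_large")),
    }
    if all(v is None for v in tri_counts.values()):
        tri: tuple[TriObservation, ...] | None = None
    else:
        tri = tuple(
            TriObservation(size_class=size, count=c)
            for size, c in tri_counts.items()
            if c is not None and c > 0
        )
    thickness = _opt_float(row.get("bm_thickness_nm"))
    if thickness is not None and (not np.isfinite(thickness) or thickness <= 0):
        raise SchemaError(f"bm_thickness_nm must be positive, got {thickness}")
    layers = _opt_int(row.get("bm_layer_count"))
    if layers is not None and layers < 1:
        raise SchemaError(f"bm_layer_count must be >= 1, got {layers}")
    procs = _opt_int(row.get("process_count"))
    if procs is not None and procs < 0:
        raise SchemaError(f"process_count must be >= 0, got {procs}")
    degraded = row.get("degraded")
    if isinstance(degraded, str):
        degraded = degraded.strip().lower() in ("true", "1", "yes")
    return CapillaryFeatures(
        bm_thickness_nm=thickness,
        bm_layer_count=layers,
        activation_grade=_opt_str(row.get("activation_grade")),
        endothelial_area_um2=_opt_float(row.get("endothelial_area_um2")),
        organelle_prominence=_opt_str(row.get("organelle_prominence")),
        process_count=procs,
        process_prominence=_opt_str(row.get("process_prominence")) or "prominent",
        tri=tri,
        degraded=bool(degraded) if degraded is not None else False,
    )


def read_feature_table(
    path: str | Path,
    dialect: str | None = None,
    strict: bool = False,
) -> tuple[list[tuple[str, str, CapillaryFeatures]], list[RowError]]:
    """Read a per-capillary feature table.

    Returns ``(records, errors)`` where each record is
    ``(case_id, capillary_id, CapillaryFeatures)``.  Rows failing validation
    are collected into ``errors`` with their row number and excluded; with
    ``strict=True`` the first failure raises :class:`SchemaError`.
    """
    sep = _sep(path, dialect)
    try:
        frame = pd.read_csv(
            path, sep=sep, dtype={"case_id": str, "capillary_id": str},
            float_precision="round_trip",
        )
    except (ValueError, OSError) as exc:
        raise SchemaError(f"cannot read feature table {path}: {exc}") from exc
    missing = [c for c in _MANDATORY if c not in frame.columns]
    if missing:
        raise SchemaError(f"feature table {path} is missing mandatory columns: {missing}")

    records: list[tuple[str, str, CapillaryFeatures]] = []
    errors: list[RowError] = []
    for i, row in enumerate(frame.to_dict("records"), start=1):
        try:
            if not _opt_str(row["case_id"]) or not _opt_str(row["capillary_id"]):
                raise SchemaError("empty case_id or capillary_id")
            records.append((str(row["case_id"]), str(row["capillary_id"]), _row_to_features(row)))
        except Exception as exc:
            if strict:
                raise SchemaError(f"{path} row {i}: {exc}") from exc
            errors.append(RowError(row=i, message=str(exc)))
    return records, errors


def write_feature_table(
    frame: pd.DataFrame, path: str | Path, dialect: str | None = None
) -> None:
    """Write a feature table (canonical column order first, extras after)."""
    sep = _sep(path, dialect)
    cols = [c for c in FEATURE_COLUMNS if c in frame.columns]
    cols += [c for c in frame.columns if c not in cols]
    frame.to_csv(path, sep=sep, index=False, columns=cols)


def features_from_frame(frame: pd.DataFrame) -> list[tuple[str, str, CapillaryFeatures]]:
    """In-memory counterpart of :func:`read_feature_table` (strict)."""
    out = []
    for i, row in enumerate(frame.to_dict("records"), start=1):
        try:
            out.append((str(row["case_id"]), str(row["capillary_id"]), _row_to_features(row)))
        except Exception as exc:
            raise SchemaError(f"row {i}: {exc}") from exc
    return out


def write_table(frame: pd.DataFrame, path: str | Path, dialect: str | None = None) -> None:
    """Write any tabular report (case table, group summary) as CSV/TSV."""
    frame.to_csv(path, sep=_sep(path, dialect), index=False)


def read_case_table(path: str | Path, dialect: str | None = None) -> pd.DataFrame:
    """Read a case-level table; requires at least a ``case_id`` column."""
    frame = pd.read_csv(
        path, sep=_sep(path, dialect), dtype={"case_id": str}, float_precision="round_trip"
    )
    if "case_id" not in frame.columns:
        raise SchemaError(f"case table {path} is missing the case_id column")
    return frame


# ---------------------------------------------------------------------------
# GeoJSON annotations
# ---------------------------------------------------------------------------

_CLASSES = {"lumen", "endothelium", "bm_layer", "process", "tri"}


def _classification_name(props: Mapping[str, Any]) -> str | None:
    """Accept both a plain string and the QuPath-style nested object
    ``{"classification": {"name": ...}}``."""
    cls = props.get("classification")
    if isinstance(cls, Mapping):
        cls = cls.get("name")
    if cls is None:
        cls = props.get("class")
    return str(cls).lower() if cls is not None else None


def read_annotations(path: str | Path) -> list[CapillaryGeometry]:
    """Read a GeoJSON FeatureCollection of capillary annotations.

    Features are grouped into capillaries by their ``capillary_id`` property;
    polygons are classified as lumen / endothelium / bm_layer / process, TRI
    marks are Point features with a ``diameter_nm`` property.  Coordinates in
    pixel units (top-level or per-feature ``units: "pixel"``) are scaled by
    ``pixel_size_nm``.  Unclassified features are skipped with a warning;
    a capillary without a lumen raises :class:`AnnotationError`.
    """
    import logging

    logger = logging.getLogger(__name__)
    with open(path, "r", encoding="utf-8") as fh:
        data = json.load(fh)
    if data.get("type") != "FeatureCollection":
        raise AnnotationError(f"{path}: expected a GeoJSON FeatureCollection")
    top_units = str(data.get("units", "nm")).lower()
    top_scale = float(data.get("pixel_size_nm", 7.3))

    groups: dict[str, dict[str, Any]] = {}
    for feat in data.get("features", []):
        props = feat.get("properties") or {}
        cls = _classification_name(props)
        if cls not in _CLASSES:
            logger.warning("%s: skipping feature with classification %r", path, cls)
            continue
        cap_id = str(props.get("capillary_id", "capillary-1"))
        units = str(props.get("units", top_units)).lower()
        scale = float(props.get("pixel_size_nm", top_scale)) if units == "pixel" else 1.0
        geom = shape(feat["geometry"])
        if units == "pixel":
            from shapely.affinity import scale as _scale

            geom = _scale(geom, xfact=scale, yfact=scale, origin=(0, 0))
        bucket = groups.setdefault(
            cap_id,
            {"lumen": None, "endothelium": None, "bm_layers": [], "processes": [], "tri": [],
             "pixel_size_nm": top_scale},
        )
        if cls == "lumen":
            bucket["lumen"] = geom
        elif cls == "endothelium":
            bucket["endothelium"] = geom
        elif cls == "bm_layer":
            bucket["bm_layers"].append((int(props.get("layer_index", len(bucket["bm_layers"]))), geom))
        elif cls == "process":
            bucket["processes"].append(
                ProcessAnnotation(polygon=geom, size_tag=_opt_str(props.get("size_tag")))
            )
        else:  # tri
            d = float(props.get("diameter_nm", 0.0)) * (scale if units == "pixel" else 1.0)
            bucket["tri"].append(TriMark(x_nm=geom.x, y_nm=geom.y, diameter_nm=d))

    geometries = []
    for cap_id in sorted(groups):
        b = groups[cap_id]
        if b["lumen"] is None:
            raise AnnotationError(f"{path}: capillary {cap_id!r} has no lumen annotation")
        layers = [g for _, g in sorted(b["bm_layers"], key=lambda t: t[0])]
        geometries.append(
            CapillaryGeometry(
                lumen=b["lumen"],
                endothelium_outer=b["endothelium"],
                bm_layers=layers,
                processes=b["processes"],
                tri_marks=b["tri"],
                pixel_size_nm=b["pixel_size_nm"],
                capillary_id=cap_id,
            )
        )
    return geometries


def write_annotations(geometries: Sequence[CapillaryGeometry], path: str | Path) -> None:
    """Write capillary geometries as a GeoJSON FeatureCollection in nm
    coordinates with QuPath-style classification objects."""
    features: list[dict[str, Any]] = []

    def _feat(geom, cls: str, cap_id: str, **extra: Any) -> dict[str, Any]:
        return {
            "type": "Feature",
            "geometry": mapping(geom),
            "properties": {
                "classification": {"name": cls},
                "capillary_id": cap_id,
                **extra,
            },
        }

    for g in geometries:
        cap_id = g.capillary_id or f"capillary-{len(features)}"
        features.append(_feat(g.lumen, "lumen", cap_id))
        if g.endothelium_outer is not None:
            features.append(_feat(g.endothelium_outer, "endothelium", cap_id))
        for i, layer in enumerate(g.bm_layers):
            features.append(_feat(layer, "bm_layer", cap_id, layer_index=i))
        for p in g.processes:
            features.append(_feat(p.polygon, "process", cap_id, size_tag=p.size_tag))
        for m in g.tri_marks:
            features.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Point", "coordinates": [m.x_nm, m.y_nm]},
                    "properties": {
                        "classification": {"name": "tri"},
                        "capillary_id": cap_id,
                        "diameter_nm": m.diameter_nm,
                    },
                }
            )
    doc = {"type": "FeatureCollection", "units": "nm", "features": features}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh)


# ---------------------------------------------------------------------------
# Run manifests
# ---------------------------------------------------------------------------


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    command: str
    seed: int | None = None
    config_sha256: str = ""
    inputs: list[dict[str, Any]] = field(default_factory=list)
    outputs: list[dict[str, Any]] = field(default_factory=list)
    version: str = __version__
    timestamp: str = ""

    def add_input(self, path: str | Path, n_records: int | None = None) -> None:
        self.inputs.append({"path": str(path), "n_records": n_records})

    def add_output(self, path: str | Path, n_records: int | None = None) -> None:
        self.outputs.append({"path": str(path), "n_records": n_records})


def write_manifest(manifest: RunManifest, path: str | Path) -> None:
    if not manifest.timestamp:
        manifest.timestamp = _dt.datetime.now(_dt.timezone.utc).isoformat()
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(dataclasses.asdict(manifest), fh, indent=2, sort_keys=True)


def read_manifest(path: str | Path) -> RunManifest:
    with open(path, "r", encoding="utf-8") as fh:
        return RunManifest(**json.load(fh))


def manifest_for_config(command: str, config: RubricConfig, seed: int | None = None) -> RunManifest:
    return RunManifest(command=command, seed=seed, config_sha256=config_hash(config))
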