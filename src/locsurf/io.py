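"""Text serialization of descriptor surfaces, stats, groups and fields.

Everything is JSON: human-inspectable, diffable, and stable across platforms.
A descriptor surface file carries the mesh (vertices, triangles, normals),
the named 40-feature columns per vertex, and normalization provenance.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .descriptor import (
    FEATURE_NAMES,
    DescriptorSurface,
    NormalizationStats,
)
from .geometry import TriangleMesh, vertex_areas
from .prediction import ProbabilityField
from .training import LigandModel, model_from_json, model_to_json


def save_surface(surface: DescriptorSurface, path: str | Path) -> Path:
    doc = {
        "format": "locsurf-surface", "version": 1,
        "surface_id": surface.surface_id,
        "normalized": surface.normalized,
        "stats_id": surface.stats_id,
        "feature_names": list(FEATURE_NAMES),
        "vertices": surface.mesh.vertices.tolist(),
        "triangles": surface.mesh.triangles.tolist(),
        "normals": surface.mesh.normals.tolist(),
        "features": surface.features.tolist(),
    }
    path = Path(path)
    path.write_text(json.dumps(doc))
    return path


def load_surface(path: str | Path) -> DescriptorSurface:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "locsurf-surface":
        raise ValueError(f"{path}: not a locsurf surface file")
    if doc["feature_names"] != list(FEATURE_NAMES):
        raise ValueError(f"{path}: feature column order does not match this version")
    v = np.asarray(doc["vertices"], dtype=float)
    t = np.asarray(doc["triangles"], dtype=np.int64)
    mesh = TriangleMesh(
        vertices=v, triangles=t,
        normals=np.asarray(doc["normals"], dtype=float),
        vertex_areas=vertex_areas(v, t),
    )
    return DescriptorSurface(
        mesh=mesh,
        features=np.asarray(doc["features"], dtype=float),
        normalized=bool(doc["normalized"]),
        stats_id=doc.get("stats_id"),
        surface_id=doc.get("surface_id", ""),
    )


def save_stats(stats: NormalizationStats, path: str | Path) -> Path:
    doc = {
        "format": "locsurf-stats", "version": 1,
        "stats_id": stats.stats_id,
        "feature_names": list(FEATURE_NAMES),
        "mean": stats.mean.tolist(),
        "sd": stats.sd.tolist(),
        "corpus_ids": list(stats.corpus_ids),
    }
    path = Path(path)
    path.write_text(json.dumps(doc, indent=1))
    return path


def load_stats(path: str | Path) -> NormalizationStats:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "locsurf-stats":
        raise ValueError(f"{path}: not a locsurf stats file")
    return NormalizationStats(
        mean=np.asarray(doc["mean"]),
        sd=np.asarray(doc["sd"]),
        corpus_ids=tuple(doc["corpus_ids"]),
    )


def save_model(model: LigandModel, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(model_to_json(model)))
    return path


def load_model(path: str | Path) -> LigandModel:
    return model_from_json(json.loads(Path(path).read_text()))


def save_field(field: ProbabilityField, path: str | Path) -> Path:
    doc = {
        "format": "locsurf-field", "version": 1,
        "surface_id": field.surface_id,
        "role": field.role,
        "resolution": field.resolution,
        "sample_ids": None if field.sample_ids is None else
                      [int(i) for i in field.sample_ids],
        "values": field.values.tolist(),
    }
    path = Path(path)
    path.write_text(json.dumps(doc))
    return path


def load_field(path: str | Path) -> ProbabilityField:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "locsurf-field":
        raise ValueError(f"{path}: not a locsurf field file")
    sids = doc.get("sample_ids")
    return ProbabilityField(
        surface_id=doc["surface_id"],
        values=np.asarray(doc["values"], dtype=float),
        role=doc["role"],
        resolution=doc["resolution"],
        sample_ids=None if sids is None else np.asarray(sids, dtype=int),
    )
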