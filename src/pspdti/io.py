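"""File round-trips: NIfTI-1 volumes, feature/clinical CSVs, model JSON.

CSV dialect is fixed (UTF-8, comma separator, header row, '.' decimal).
Feature CSVs carry a ``#``-prefixed header comment block recording the
atlas id, percentile list and any dropped columns, so a table is
self-describing when it travels without its run directory.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .images import AtlasParcellation, FeatureTable, ParametricMap
from .regression import SeverityModel


# ---------------------------------------------------------------------------
# NIfTI


def write_nifti(path, values: np.ndarray, voxel_size: float = 2.0) -> None:
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    img = nib.Nifti1Image(np.asarray(values), affine)
    img.to_filename(str(path))


def read_map(path, metric: str, subject_id: str | None = None) -> ParametricMap:
    img = nib.load(str(path))
    return ParametricMap(metric, np.asarray(img.dataobj, dtype=float), subject_id=subject_id)


def read_mask(path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.dataobj) > 0


def write_atlas(path_volume, path_table, atlas: AtlasParcellation) -> None:
    write_nifti(path_volume, atlas.label_volume.astype(np.int32))
    atlas.region_table.to_csv(path_table, index=False)


def read_atlas(path_volume, path_table) -> AtlasParcellation:
    img = nib.load(str(path_volume))
    data = np.asarray(img.dataobj)
    if not np.allclose(data, np.round(data)):
        raise ValueError(f"atlas volume {path_volume} holds non-integer labels")
    table = pd.read_csv(path_table)
    return AtlasParcellation(data.astype(np.int32), table)


# ---------------------------------------------------------------------------
# feature tables


def write_feature_table(path, table: FeatureTable) -> None:
    header = [
        f"# atlas_id: {table.atlas_id}",
        f"# percentiles: {','.join(str(p) for p in table.percentiles)}",
        f"# dropped: {','.join(table.dropped) if table.dropped else '-'}",
        f"# covariates: {','.join(table.covariates) if table.covariates else '-'}",
    ]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(header) + "\n")
        table.data.to_csv(fh, float_format="%.10g")


def read_feature_table(path) -> FeatureTable:
    meta = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].partition(":")
            meta[key.strip()] = value.strip()
    data = pd.read_csv(path, comment="#", index_col="record_id")
    def _split(key):
        raw = meta.get(key, "-")
        return [] if raw in ("-", "") else raw.split(",")
    return FeatureTable(
        data=data,
        percentiles=tuple(int(p) for p in meta.get("percentiles", "90,50,10").split(",")),
        atlas_id=meta.get("atlas_id", "unknown"),
        dropped=_split("dropped"),
        covariates=_split("covariates"),
    )


def write_clinical(path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, float_format="%.10g")


def read_clinical(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="record_id")


# ---------------------------------------------------------------------------
# JSON artifacts


def write_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))


def write_model(path, model: SeverityModel) -> None:
    Path(path).write_text(model.to_json() + "\n", encoding="utf-8")


def read_model(path) -> SeverityModel:
    return SeverityModel.from_json(Path(path).read_text(encoding="utf-8"))
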