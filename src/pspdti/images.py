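"""Parcellated percentile feature extraction from diffusion parametric maps.

Given an FA or MD volume, an integer label atlas on the same voxel grid and
a binary parenchymal mask (which removes cerebrospinal fluid), each atlas
region is summarised by a small set of order statistics — by default the
10th, 50th and 90th percentiles — of its in-mask voxel values. With the
246-region atlas, two metrics and three percentiles this yields the full
1476-column feature table.

Volumes are handled in voxel-index space only: maps, atlas and mask must
already live on one grid (spatial normalisation happens upstream, outside
this package). Percentiles use the linear-interpolation order-statistic
convention; a single-voxel region returns that voxel's value for every
percentile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .naming import render_feature_name

logger = logging.getLogger(__name__)

DEFAULT_PERCENTILES = (10, 50, 90)

HEMISPHERES = ("L", "R", "midline")


@dataclass
class AtlasParcellation:
    """Integer label volume plus its region lookup table.

    ``region_table`` has one row per region with columns ``region_id``
    (positive integer matching the label volume), ``label_code`` (the
    atlas-style code used in feature names, e.g. ``PhG_L_6_1``) and
    ``hemisphere`` (``L``/``R``/``midline``). Label 0 is background.
    """

    label_volume: np.ndarray
    region_table: pd.DataFrame

    def __post_init__(self) -> None:
        self.label_volume = np.asarray(self.label_volume)
        if not np.issubdtype(self.label_volume.dtype, np.integer):
            raise TypeError("atlas label volume must hold integers")
        if self.label_volume.ndim != 3:
            raise ValueError("atlas label volume must be 3-D")
        required = {"region_id", "label_code", "hemisphere"}
        missing = required - set(self.region_table.columns)
        if missing:
            raise ValueError(f"region table missing columns: {sorted(missing)}")
        ids = self.region_table["region_id"].to_numpy()
        if len(np.unique(ids)) != len(ids):
            raise ValueError("region ids must be unique")
        if (ids < 1).any():
            raise ValueError("region ids must be >= 1")
        bad_hemi = set(self.region_table["hemisphere"]) - set(HEMISPHERES)
        if bad_hemi:
            raise ValueError(f"unknown hemisphere codes: {sorted(bad_hemi)}")
        present = np.unique(self.label_volume)
        present = present[present > 0]
        unknown = np.setdiff1d(present, ids)
        if unknown.size:
            raise ValueError(
                f"label volume contains region ids without a region-table row: {unknown[:10].tolist()}"
            )

    @property
    def n_regions(self) -> int:
        return len(self.region_table)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.label_volume.shape

    def label_code(self, region_id: int) -> str:
        row = self.region_table.loc[self.region_table["region_id"] == region_id]
        if row.empty:
            raise KeyError(f"region id {region_id} not in atlas table")
        return str(row["label_code"].iloc[0])


@dataclass
class ParametricMap:
    """One scalar diffusion map (FA or MD) on the atlas voxel grid.

    FA is dimensionless in [0, 1]; MD is in units of 1e-3 mm^2/s and must be
    non-negative. Voxels excluded by masking are stored as NaN and never
    enter percentile computation.
    """

    metric: str
    values: np.ndarray
    subject_id: str | None = None

    def __post_init__(self) -> None:
        if self.metric not in ("FA", "MD"):
            raise ValueError(f"metric must be FA or MD, got {self.metric!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("parametric map must be 3-D")
        finite = self.values[np.isfinite(self.values)]
        if self.metric == "FA" and finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("FA values must lie in [0, 1]")
        if self.metric == "MD" and finite.size and finite.min() < 0:
            raise ValueError("MD values must be non-negative")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape


def apply_parenchymal_mask(pmap: ParametricMap, mask: np.ndarray) -> ParametricMap:
    """Exclude voxels outside the parenchymal mask (CSF removal).

    Returns a new map whose out-of-mask voxels are NaN. Raises if the mask
    shape differs from the map or if masking would empty the map entirely.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.shape != pmap.shape:
        raise ValueError(f"mask shape {mask.shape} does not match map shape {pmap.shape}")
    if not mask.any():
        name = pmap.subject_id or pmap.metric
        raise ValueError(f"parenchymal mask excludes every voxel of map {name!r}")
    values = np.where(mask, pmap.values, np.nan)
    return ParametricMap(pmap.metric, values, subject_id=pmap.subject_id)


def region_percentiles(
    pmap: ParametricMap,
    atlas: AtlasParcellation,
    percentiles: tuple[int, ...] = DEFAULT_PERCENTILES,
    mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Percentiles of in-mask voxel values for every atlas region.

    Returns a frame indexed by ``region_id`` with one column per requested
    percentile. Regions with no in-mask voxel yield NaN (a missing marker
    handled downstream by the cohort-wide column drop).
    """
    if pmap.shape != atlas.shape:
        raise ValueError(f"map shape {pmap.shape} does not match atlas shape {atlas.shape}")
    for p in percentiles:
        if not 0 < p < 100:
            raise ValueError(f"percentiles must lie strictly inside (0, 100), got {p}")
    values = pmap.values
    if mask is not None:
        values = apply_parenchymal_mask(pmap, mask).values

    labels = atlas.label_volume
    out = np.full((atlas.n_regions, len(percentiles)), np.nan)
    for i, rid in enumerate(atlas.region_table["region_id"]):
        voxels = values[labels == rid]
        voxels = voxels[np.isfinite(voxels)]
        if voxels.size == 0:
            continue
        out[i] = np.percentile(voxels, percentiles, method="linear")
    return pd.DataFrame(
        out,
        index=pd.Index(atlas.region_table["region_id"].to_numpy(), name="region_id"),
        columns=list(percentiles),
    )


def feature_columns(
    atlas: AtlasParcellation,
    percentiles: tuple[int, ...] = DEFAULT_PERCENTILES,
    metrics: tuple[str, ...] = ("FA", "MD"),
) -> list[str]:
    """Canonical column order: metric, then percentile descending, then region id."""
    codes = atlas.region_table.sort_values("region_id")["label_code"]
    cols = []
    for metric in metrics:
        for p in sorted(percentiles, reverse=True):
            for code in codes:
                cols.append(render_feature_name(metric, p, code))
    return cols


@dataclass
class FeatureTable:
    """Subjects x percentile-feature matrix with provenance.

    ``data`` rows are indexed by subject/record id; imaging feature columns
    follow the METRIC+PCTL_label grammar, optional covariate columns do not.
    ``dropped`` records columns removed cohort-wide because at least one
    subject lacked them.
    """

    data: pd.DataFrame
    percentiles: tuple[int, ...] = DEFAULT_PERCENTILES
    atlas_id: str = "synthetic"
    dropped: list[str] = field(default_factory=list)
    covariates: list[str] = field(default_factory=list)

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in self.covariates]

    def __len__(self) -> int:
        return len(self.data)


def build_feature_table(
    cohort_maps: dict[str, dict[str, ParametricMap]],
    atlas: AtlasParcellation,
    mask: np.ndarray | None = None,
    percentiles: tuple[int, ...] = DEFAULT_PERCENTILES,
    atlas_id: str = "synthetic",
) -> FeatureTable:
    """Assemble the cohort feature table from per-subject FA/MD maps.

    ``cohort_maps`` maps record id -> {"FA": map, "MD": map}; both metrics
    are required for every record. Columns missing (NaN) for any subject —
    e.g. a region fully outside the mask — are dropped cohort-wide with a
    logged warning, so the table downstream stages see is complete.
    """
    pctls_desc = tuple(sorted(percentiles, reverse=True))
    columns = feature_columns(atlas, pctls_desc)
    rows = {}
    for sid, maps in cohort_maps.items():
        for metric in ("FA", "MD"):
            if metric not in maps:
                raise ValueError(f"subject {sid!r} is missing the {metric} map")
        row = []
        for metric in ("FA", "MD"):
            per = region_percentiles(maps[metric], atlas, pctls_desc, mask=mask)
            # region_percentiles returns regions x percentiles; flatten in
            # (percentile desc, region id) order to match feature_columns
            row.append(per.to_numpy().T.reshape(-1))
        rows[sid] = np.concatenate(row)

    data = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
    data.index.name = "record_id"
    incomplete = [c for c in data.columns if data[c].isna().any()]
    if incomplete:
        logger.warning(
            "dropping %d feature column(s) missing for at least one subject: %s",
            len(incomplete),
            incomplete[:12],
        )
        data = data.drop(columns=incomplete)
    return FeatureTable(
        data=data,
        percentiles=pctls_desc,
        atlas_id=atlas_id,
        dropped=incomplete,
    )
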