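"""Seeded synthetic cohorts for the PSP severity-prediction pipeline.

The clinical images behind this kind of study are not publicly deposited,
so every downstream stage is exercised on synthetic cohorts that emulate
the statistical structure the analysis assumes: 53 baseline patients
across three imaging protocols, 15 of whom return for a follow-up scan,
an atlas of 246 regions, FA/MD region distributions whose means shift
linearly with a latent disease severity, and four clinical scales tied to
that severity by affine links with noise (3 baseline PIGD values missing).

Generative model
----------------
Each subject carries a latent severity ``s ~ Uniform(0, 1)``. A small set
of planted (region, metric) couplings shifts the voxel mean of that region
by ``slope * (s + d)``, where ``d ~ N(0, plant_jitter_sd)`` is a
subject-by-plant deviation — the per-region expression of disease burden.
Clinical scores are affine links of the *effective* severity
``s_eff = s + mean(d over plants)`` plus scale noise, so each planted
region carries signal about the score that no other region duplicates;
without the deviations all plants would be perfectly collinear and no
selector could be expected to recover more than one of them.

Follow-up visits shift the latent severity by ``followup_drift``
(progressive disease), redraw the plant deviations and imaging noise
(a new scanning session), and inflate the score noise by
``followup_noise_factor`` — emulating fluctuating patient state and
scanner drift between sessions, the regime in which a frozen baseline
model shows inflated but bounded prediction error.

Two routes produce features: :func:`generate_cohort` writes actual FA/MD
volumes for extraction through the imaging stage, and
:func:`generate_feature_table` draws region percentiles directly from the
closed-form means plus order-statistic sampling noise (same subjects, same
column grammar, much faster).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .images import AtlasParcellation, FeatureTable, ParametricMap, feature_columns
from .scales import SCALE_NAMES

#: affine links score = a + b * s_eff, spanning realistic clinical ranges
SCORE_LINKS: dict[str, tuple[float, float]] = {
    "UPDRS3": (5.0, 90.0),
    "PIGD": (1.0, 17.0),
    "MHY": (1.0, 4.0),
    "LEDD": (200.0, 900.0),
}

#: default per-scale score noise SD, in scale units (~5% of the link span)
DEFAULT_SCORE_NOISE = {"UPDRS3": 4.5, "PIGD": 0.85, "MHY": 0.2, "LEDD": 45.0}

DEFAULT_VOXEL_NOISE = {"FA": 0.02, "MD": 0.03}

#: additive nuisance offsets per imaging protocol (MD only by default)
DEFAULT_PROTOCOLS = {
    "A": {"FA": 0.0, "MD": 0.0},
    "B": {"FA": 0.0, "MD": 0.01},
    "C": {"FA": 0.0, "MD": -0.01},
}

#: cohort composition emulated by default (counts per protocol / subtype / sex)
PROTOCOL_WEIGHTS = {"A": 19, "B": 11, "C": 23}
SUBTYPE_WEIGHTS = {"PAGF": 27, "PD": 15, "RS": 7, "CBS": 4}
SEX_WEIGHTS = {"M": 21, "F": 32}

#: gyrus/nucleus abbreviations used to build atlas-style label codes
_ABBREVS = (
    "SFG", "MFG", "IFG", "OrG", "PrG", "PCL", "STG", "MTG", "ITG", "FuG",
    "PhG", "pSTS", "SPL", "IPL", "Pcun", "PoG", "INS", "CG", "MVOcC", "LOcC",
    "Amyg", "Hipp", "Tha", "GP", "NAC", "Put",
)

MIN_REGION_VOXELS = 27


def default_signal_map(n_regions: int) -> dict[str, list[tuple[int, str, float]]]:
    """Five planted (region, metric, slope) couplings, shared by all scales.

    Regions are spread evenly through the atlas; MD shifts up and FA shifts
    down with severity, matching the usual direction of microstructural
    damage. Slopes are sized so the oracle regression of any score on the
    planted features explains well over 90% of its variance at default noise.
    """
    ids = [max(1, round(n_regions * (k + 1) / 6)) for k in range(5)]
    metrics = ["MD", "FA", "MD", "FA", "MD"]
    slopes = {"MD": 0.25, "FA": -0.15}
    plants = [(rid, m, slopes[m]) for rid, m in zip(ids, metrics)]
    return {scale: list(plants) for scale in SCALE_NAMES}


def _default_grid(n_regions: int) -> tuple[int, int, int]:
    # ~40 voxels per region inside a 1-voxel background border
    side = math.ceil((40 * n_regions) ** (1 / 3)) + 2
    return (side, side, side)


@dataclass
class CohortConfig:
    """Everything that determines a synthetic cohort, including the seed."""

    n_subjects: int = 53
    n_followup: int = 15
    n_regions: int = 246
    grid_shape: tuple[int, int, int] | None = None
    protocols: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_PROTOCOLS.items()}
    )
    signal_map: dict[str, list[tuple[int, str, float]]] | None = None
    voxel_noise_sd: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_VOXEL_NOISE))
    score_noise_sd: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SCORE_NOISE))
    plant_jitter_sd: float = 0.15
    pigd_missing: int = 3
    followup_drift: float = 0.15
    followup_noise_factor: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_shape is None:
            self.grid_shape = _default_grid(self.n_regions)
        self.grid_shape = tuple(int(g) for g in self.grid_shape)
        if self.signal_map is None:
            self.signal_map = default_signal_map(self.n_regions)
        if self.n_regions < 2:
            raise ValueError("need at least 2 atlas regions")
        if not 0 <= self.n_followup <= self.n_subjects:
            raise ValueError(
                f"n_followup ({self.n_followup}) must be between 0 and n_subjects ({self.n_subjects})"
            )
        if not 0 <= self.pigd_missing < self.n_subjects:
            raise ValueError(
                f"pigd_missing ({self.pigd_missing}) must be below n_subjects ({self.n_subjects})"
            )
        for sds in (self.voxel_noise_sd, self.score_noise_sd):
            if any(v < 0 for v in sds.values()):
                raise ValueError("noise SDs must be non-negative")
        if self.plant_jitter_sd < 0:
            raise ValueError("plant_jitter_sd must be non-negative")
        for scale, plants in self.signal_map.items():
            for rid, metric, _slope in plants:
                if not 1 <= rid <= self.n_regions:
                    raise ValueError(
                        f"signal_map for {scale} references region {rid}, "
                        f"but the atlas has regions 1..{self.n_regions}"
                    )
                if metric not in ("FA", "MD"):
                    raise ValueError(f"signal_map metric must be FA or MD, got {metric!r}")

    @classmethod
    def fast(cls, seed: int = 0, **overrides) -> "CohortConfig":
        """Small-atlas configuration (24 regions) used throughout the tests."""
        overrides.setdefault("n_regions", 24)
        return cls(seed=seed, **overrides)

    def noise_free(self) -> "CohortConfig":
        """Copy of this config with every noise source switched off."""
        cfg = asdict(self)
        cfg["voxel_noise_sd"] = {k: 0.0 for k in self.voxel_noise_sd}
        cfg["score_noise_sd"] = {k: 0.0 for k in self.score_noise_sd}
        cfg["plant_jitter_sd"] = 0.0
        cfg["grid_shape"] = self.grid_shape
        cfg["signal_map"] = {k: [tuple(p) for p in v] for k, v in self.signal_map.items()}
        return CohortConfig(**cfg)

    @property
    def planted_pairs(self) -> list[tuple[int, str]]:
        """Union of planted (region_id, metric) pairs across all scales."""
        pairs: list[tuple[int, str]] = []
        for plants in self.signal_map.values():
            for rid, metric, _ in plants:
                if (rid, metric) not in pairs:
                    pairs.append((rid, metric))
        return sorted(pairs)


@dataclass
class SubjectRecord:
    """One subject-timepoint: demographics, protocol, scores, latent truth."""

    record_id: str
    subject_id: str
    age: float
    sex: str
    disease_duration: float
    protocol: str
    subtype: str
    timepoint: str  # "baseline" | "followup"
    scores: dict[str, float]  # NaN marks a missing PIGD
    latent_severity: float


def records_to_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    """Flatten subject records into the clinical CSV layout."""
    rows = []
    for r in records:
        row = {
            "record_id": r.record_id,
            "subject_id": r.subject_id,
            "age": r.age,
            "sex": r.sex,
            "disease_duration": r.disease_duration,
            "protocol": r.protocol,
            "subtype": r.subtype,
            "timepoint": r.timepoint,
            "latent_severity": r.latent_severity,
        }
        row.update(r.scores)
        rows.append(row)
    return pd.DataFrame(rows).set_index("record_id")


# ---------------------------------------------------------------------------
# atlas


def generate_atlas(config: CohortConfig) -> tuple[AtlasParcellation, np.ndarray]:
    """Deterministic synthetic parcellation plus its parenchymal mask.

    The mask is the grid minus a one-voxel background border; in-mask voxels
    are split (in scan order) into ``n_regions`` contiguous, nearly equal
    blocks. Returns ``(atlas, mask)``.
    """
    shape = config.grid_shape
    mask = np.zeros(shape, dtype=bool)
    mask[1:-1, 1:-1, 1:-1] = True
    n_inmask = int(mask.sum())
    if n_inmask < MIN_REGION_VOXELS * config.n_regions:
        raise ValueError(
            f"grid {shape} has {n_inmask} in-mask voxels, too few for "
            f"{config.n_regions} regions of >= {MIN_REGION_VOXELS} voxels each"
        )
    labels = np.zeros(shape, dtype=np.int32)
    flat_idx = np.flatnonzero(mask.reshape(-1))
    for rid, chunk in enumerate(np.array_split(flat_idx, config.n_regions), start=1):
        labels.reshape(-1)[chunk] = rid

    n_ab = len(_ABBREVS)
    rows = []
    for i in range(config.n_regions):
        abbr = _ABBREVS[i % n_ab]
        hemi = "L" if (i // n_ab) % 2 == 0 else "R"
        series = i // (2 * n_ab) + 1
        code = f"{abbr}_{hemi}_{series}_{1 + i % 8}"
        rows.append({"region_id": i + 1, "label_code": code, "hemisphere": hemi})
    table = pd.DataFrame(rows)
    return AtlasParcellation(labels, table), mask


def _region_sizes(config: CohortConfig) -> np.ndarray:
    shape = config.grid_shape
    n_inmask = (shape[0] - 2) * (shape[1] - 2) * (shape[2] - 2)
    base, extra = divmod(n_inmask, config.n_regions)
    return np.array([base + (1 if i < extra else 0) for i in range(config.n_regions)])


# ---------------------------------------------------------------------------
# subjects and scores


def _clip_round_score(scale: str, raw: np.ndarray) -> np.ndarray:
    """Apply each scale's legal range and granularity."""
    if scale == "UPDRS3":
        return np.clip(raw, 0.0, 108.0) + 0.0  # +0.0 normalises -0.0
    if scale == "PIGD":
        return np.clip(np.round(raw), 0.0, 20.0) + 0.0
    if scale == "MHY":
        return np.clip(np.round(raw * 2.0) / 2.0, 1.0, 5.0) + 0.0
    if scale == "LEDD":
        return np.clip(raw, 0.0, None) + 0.0
    raise KeyError(scale)


def _sample_cohort(config: CohortConfig, rng: np.random.Generator):
    """Draw subject records plus the per-record plant deviations.

    Returns ``(records, plant_dev)`` where ``plant_dev[record_id]`` maps each
    planted (region, metric) pair to its subject-session deviation in latent
    severity units.
    """
    n = config.n_subjects
    pairs = config.planted_pairs

    severity = rng.uniform(0.0, 1.0, size=n)
    proto_ids = list(config.protocols)
    proto_w = {k: PROTOCOL_WEIGHTS.get(k, 1) for k in proto_ids}
    protocols = rng.choice(proto_ids, size=n, p=_norm_weights(proto_w))
    subtypes = rng.choice(list(SUBTYPE_WEIGHTS), size=n, p=_norm_weights(SUBTYPE_WEIGHTS))
    sexes = rng.choice(list(SEX_WEIGHTS), size=n, p=_norm_weights(SEX_WEIGHTS))
    ages = np.round(np.clip(rng.normal(65.7, 6.5, size=n), 40.0, 90.0), 1)
    durations = np.round(np.clip(rng.normal(5.4, 3.2, size=n), 0.5, None), 1)

    pigd_missing_idx = set(
        rng.choice(n, size=config.pigd_missing, replace=False).tolist()
    )
    followup_idx = set(rng.choice(n, size=config.n_followup, replace=False).tolist())

    records: list[SubjectRecord] = []
    plant_dev: dict[str, dict[tuple[int, str], float]] = {}

    def make_record(i: int, timepoint: str) -> None:
        sid = f"S{i + 1:03d}"
        rid = sid if timepoint == "baseline" else f"{sid}_fu"
        s = severity[i] + (config.followup_drift if timepoint == "followup" else 0.0)
        dev = {
            pair: rng.normal(0.0, config.plant_jitter_sd) if config.plant_jitter_sd > 0 else 0.0
            for pair in pairs
        }
        noise_factor = config.followup_noise_factor if timepoint == "followup" else 1.0
        scores: dict[str, float] = {}
        for scale in SCALE_NAMES:
            plants = config.signal_map.get(scale, [])
            if plants:
                s_eff = s + float(np.mean([dev[(r, m)] for r, m, _ in plants]))
            else:
                s_eff = s
            a, b = SCORE_LINKS[scale]
            raw = a + b * s_eff + rng.normal(0.0, config.score_noise_sd[scale] * noise_factor)
            scores[scale] = float(_clip_round_score(scale, np.asarray(raw)))
        if i in pigd_missing_idx:
            scores["PIGD"] = float("nan")
        records.append(
            SubjectRecord(
                record_id=rid,
                subject_id=sid,
                age=float(ages[i] + (1.5 if timepoint == "followup" else 0.0)),
                sex=str(sexes[i]),
                disease_duration=float(durations[i] + (1.5 if timepoint == "followup" else 0.0)),
                protocol=str(protocols[i]),
                subtype=str(subtypes[i]),
                timepoint=timepoint,
                scores=scores,
                latent_severity=float(s),
            )
        )
        plant_dev[rid] = dev

    for i in range(n):
        make_record(i, "baseline")
    for i in sorted(followup_idx):
        make_record(i, "followup")
    return records, plant_dev


def _norm_weights(weights: dict[str, int]) -> np.ndarray:
    w = np.array(list(weights.values()), dtype=float)
    return w / w.sum()


def _region_base_means(config: CohortConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Cohort-level baseline FA/MD mean per region (severity-independent)."""
    return {
        "FA": rng.uniform(0.25, 0.55, size=config.n_regions),
        "MD": rng.uniform(0.65, 0.95, size=config.n_regions),
    }


def _plant_slopes(config: CohortConfig) -> dict[tuple[int, str], float]:
    slopes: dict[tuple[int, str], float] = {}
    for plants in config.signal_map.values():
        for rid, metric, slope in plants:
            slopes[(rid, metric)] = slope
    return slopes


def _record_region_means(
    config: CohortConfig,
    record: SubjectRecord,
    dev: dict[tuple[int, str], float],
    base: dict[str, np.ndarray],
    slopes: dict[tuple[int, str], float],
    metric: str,
) -> np.ndarray:
    means = base[metric].copy()
    means += config.protocols[record.protocol].get(metric, 0.0)
    for (rid, m), slope in slopes.items():
        if m == metric:
            means[rid - 1] += slope * (record.latent_severity + dev[(rid, m)])
    return means


# ---------------------------------------------------------------------------
# volume route


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[SubjectRecord], dict[str, dict[str, ParametricMap]], AtlasParcellation, np.ndarray]:
    """Full synthetic cohort with per-record FA and MD volumes.

    Returns ``(records, maps, atlas, mask)`` where ``maps[record_id]`` holds
    the record's ``{"FA": ..., "MD": ...}`` parametric maps on the atlas
    grid. Fully reproducible from ``config.seed``.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_subjects, rng_struct, rng_voxels, _rng_fast = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    atlas, mask = generate_atlas(config)
    records, plant_dev = _sample_cohort(config, rng_subjects)
    base = _region_base_means(config, rng_struct)
    slopes = _plant_slopes(config)

    labels = atlas.label_volume
    maps: dict[str, dict[str, ParametricMap]] = {}
    for record in records:
        maps[record.record_id] = {}
        for metric in ("FA", "MD"):
            means = _record_region_means(
                config, record, plant_dev[record.record_id], base, slopes, metric
            )
            vol = np.zeros(config.grid_shape, dtype=float)
            vol[mask] = means[labels[mask] - 1]
            sd = config.voxel_noise_sd[metric]
            if sd > 0:
                vol[mask] += rng_voxels.normal(0.0, sd, size=int(mask.sum()))
            if metric == "FA":
                vol = np.clip(vol, 0.0, 1.0)
            else:
                vol = np.clip(vol, 0.0, None)
            maps[record.record_id][metric] = ParametricMap(
                metric, vol, subject_id=record.record_id
            )
    return records, maps, atlas, mask


# ---------------------------------------------------------------------------
# fast closed-form route


def generate_feature_table(
    config: CohortConfig,
) -> tuple[FeatureTable, list[SubjectRecord]]:
    """Region-percentile features drawn from their closed-form distribution.

    For a region of ``m`` voxels with mean ``mu`` and voxel noise ``sigma``,
    the p-th sample percentile is approximately Gaussian around
    ``mu + z_p * sigma`` with SD ``sigma * sqrt(p(1-p)/m) / phi(z_p)``
    (the asymptotic order-statistic law). Sampling from that law reproduces
    the statistical structure of volume-based extraction without building
    volumes — same subjects, same column grammar and count.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_subjects, rng_struct, _rng_voxels, rng_fast = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    atlas, _mask = generate_atlas(config)
    records, plant_dev = _sample_cohort(config, rng_subjects)
    base = _region_base_means(config, rng_struct)
    slopes = _plant_slopes(config)
    sizes = _region_sizes(config)

    pctls_desc = (90, 50, 10)
    z = {p: stats.norm.ppf(p / 100.0) for p in pctls_desc}
    se_factor = {
        p: math.sqrt(p / 100.0 * (1 - p / 100.0)) / stats.norm.pdf(z[p]) for p in pctls_desc
    }
    columns = feature_columns(atlas, pctls_desc)

    rows = {}
    for record in records:
        vals = []
        for metric in ("FA", "MD"):
            means = _record_region_means(
                config, record, plant_dev[record.record_id], base, slopes, metric
            )
            sd = config.voxel_noise_sd[metric]
            for p in pctls_desc:
                centre = means + z[p] * sd
                if sd > 0:
                    se = sd * se_factor[p] / np.sqrt(sizes)
                    centre = centre + rng_fast.normal(0.0, se)
                vals.append(centre)
        rows[record.record_id] = np.concatenate(vals)

    data = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
    data.index.name = "record_id"
    table = FeatureTable(data=data, percentiles=pctls_desc, atlas_id="synthetic")
    return table, records


def planted_feature_columns(config: CohortConfig, atlas: AtlasParcellation) -> dict[tuple[int, str], list[str]]:
    """Map each planted (region, metric) pair to its percentile column names."""
    from .naming import render_feature_name

    out = {}
    for rid, metric in config.planted_pairs:
        code = atlas.label_code(rid)
        out[(rid, metric)] = [render_feature_name(metric, p, code) for p in (90, 50, 10)]
    return out
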