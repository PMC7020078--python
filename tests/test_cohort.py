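"""Synthetic cohort generator: composition, determinism, noise-free limits."""

import math

import numpy as np
import pandas as pd
import pytest

import pspdti as p
from pspdti.cohort import SCORE_LINKS


def test_default_cohort_composition(fast_cohort):
    """53 baseline subjects, 15 follow-up records, exactly 3 missing PIGD."""
    clinical = fast_cohort["clinical"]
    base = clinical[clinical["timepoint"] == "baseline"]
    followup = clinical[clinical["timepoint"] == "followup"]
    assert len(base) == 53
    assert len(followup) == 15
    assert base["PIGD"].isna().sum() == 3
    assert followup["subject_id"].isin(base["subject_id"]).all()
    # follow-up severity drifted upward by the configured amount
    drift = (
        followup.set_index("subject_id")["latent_severity"]
        - base.set_index("subject_id")["latent_severity"]
    ).dropna()
    assert np.allclose(drift, fast_cohort["config"].followup_drift)


def test_score_ranges_hold_under_extreme_noise():
    """Clipping keeps every emitted score inside its declared range."""
    cfg = p.CohortConfig.fast(
        seed=11,
        score_noise_sd={"UPDRS3": 500.0, "PIGD": 100.0, "MHY": 50.0, "LEDD": 5000.0},
    )
    _table, records = p.generate_feature_table(cfg)
    frame = p.records_to_frame(records)
    assert frame["UPDRS3"].between(0, 108).all()
    assert frame["PIGD"].dropna().between(0, 20).all()
    assert frame["PIGD"].dropna().apply(float.is_integer).all()
    assert frame["MHY"].between(1, 5).all()
    assert ((frame["MHY"] * 2) % 1 == 0).all()  # half steps
    assert (frame["LEDD"] >= 0).all()


def test_atlas_partition_and_sizing():
    """Contiguous exhaustive partition; region count on demand; sizing errors."""
    cfg = p.CohortConfig(seed=0, n_regions=246)
    atlas, mask = p.generate_atlas(cfg)
    assert len(atlas.region_table) == 246
    assert atlas.region_table["label_code"].is_unique

    tiny = p.CohortConfig(seed=0, n_regions=2, grid_shape=(8, 8, 8))
    atlas2, mask2 = p.generate_atlas(tiny)
    labels = atlas2.label_volume
    assert set(np.unique(labels[mask2])) == {1, 2}
    assert (labels[~mask2] == 0).all()

    with pytest.raises(ValueError, match=r"(?s)\(6, 6, 6\).*24 regions"):
        p.generate_atlas(p.CohortConfig(seed=0, n_regions=24, grid_shape=(6, 6, 6)))


def test_unknown_plant_region_rejected():
    with pytest.raises(ValueError, match="region 999"):
        p.CohortConfig.fast(signal_map={"UPDRS3": [(999, "MD", 0.2)]})


def test_generator_determinism():
    """Equal (config, seed) reproduces atlas, volumes, records and tables bit-for-bit."""
    cfg = lambda: p.CohortConfig.fast(seed=5, n_subjects=8, n_followup=2, pigd_missing=1)
    rec1, maps1, atlas1, _ = p.generate_cohort(cfg())
    rec2, maps2, atlas2, _ = p.generate_cohort(cfg())
    assert np.array_equal(atlas1.label_volume, atlas2.label_volume)
    pd.testing.assert_frame_equal(p.records_to_frame(rec1), p.records_to_frame(rec2))
    for rid in maps1:
        for metric in ("FA", "MD"):
            assert np.array_equal(maps1[rid][metric].values, maps2[rid][metric].values)

    t1, r1 = p.generate_feature_table(cfg())
    t2, r2 = p.generate_feature_table(cfg())
    pd.testing.assert_frame_equal(t1.data, t2.data)
    # fast path shares the subject stream with the volume route
    pd.testing.assert_frame_equal(p.records_to_frame(r1), p.records_to_frame(rec1))


def test_noise_free_limit_volume_route():
    """Without noise, extracted percentiles equal planted means exactly and
    scores are affine in severity (up to each scale's quantisation)."""
    cfg = p.CohortConfig.fast(
        seed=3, n_subjects=6, n_followup=0, pigd_missing=0,
        protocols={"A": {"FA": 0.0, "MD": 0.0}},  # no nuisance offsets in this limit
    ).noise_free()
    records, maps, atlas, mask = p.generate_cohort(cfg)
    table = p.build_feature_table(maps, atlas, mask=mask)

    plants = p.planted_feature_columns(cfg, atlas)
    frame = p.records_to_frame(records)
    slopes = {(rid, m): s for pl in cfg.signal_map.values() for rid, m, s in pl}
    for (rid, metric), cols in plants.items():
        col = table.data[cols[0]]  # 90th percentile; all three equal when noise-free
        assert np.allclose(table.data[cols[0]], table.data[cols[2]], atol=1e-12)
        # regress feature on severity: slope and offsets recover the plant exactly
        s = frame.loc[col.index, "latent_severity"]
        fit = np.polyfit(s, col, 1)
        assert fit[0] == pytest.approx(slopes[(rid, metric)], abs=1e-9)

    s = frame["latent_severity"]
    a, b = SCORE_LINKS["UPDRS3"]
    assert np.allclose(frame["UPDRS3"], a + b * s, atol=1e-12)
    a, b = SCORE_LINKS["LEDD"]
    assert np.allclose(frame["LEDD"], a + b * s, atol=1e-12)
    a, b = SCORE_LINKS["MHY"]
    assert np.max(np.abs(frame["MHY"] - np.clip(a + b * s, 1, 5))) <= 0.25
    a, b = SCORE_LINKS["PIGD"]
    assert np.max(np.abs(frame["PIGD"] - np.clip(a + b * s, 0, 20))) <= 0.5


@pytest.mark.parametrize(
    "n_regions,expected", [(246, 1476), (24, 144)]
)
def test_fast_feature_table_column_count(n_regions, expected):
    cfg = p.CohortConfig(seed=1, n_regions=n_regions, n_subjects=4, n_followup=0, pigd_missing=0)
    table, _ = p.generate_feature_table(cfg)
    assert table.data.shape == (4, expected)
    assert all(p.is_feature_name(c) for c in table.data.columns)


def test_config_invariants_enforced():
    with pytest.raises(ValueError, match="n_followup"):
        p.CohortConfig.fast(n_subjects=5, n_followup=6)
    with pytest.raises(ValueError, match="pigd_missing"):
        p.CohortConfig.fast(n_subjects=5, n_followup=2, pigd_missing=5)
    with pytest.raises(ValueError, match="noise"):
        p.CohortConfig.fast(voxel_noise_sd={"FA": -0.1, "MD": 0.0})
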