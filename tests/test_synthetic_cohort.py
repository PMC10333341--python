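import numpy as np
import pandas as pd
import pytest

from ecmnet import scid_scales
from ecmnet.synthetic_cohort import (
    DEFAULT_HUB_ROIS,
    CohortConfig,
    ConfigError,
    cohort_report,
    generate_cohort,
    loading_multiplier,
    population_ec,
    read_cohort,
    write_cohort,
)
from tests.conftest import cohort_ec_table


# ---------------------------------------------------------------------------
# config validation

def test_default_config_valid():
    cfg = CohortConfig()
    assert cfg.n_subjects == 96
    assert len(cfg.hub_rois) == 9


@pytest.mark.parametrize(
    "kwargs, match",
    [
        (dict(n_ptsd=0), "positive"),
        (dict(hub_effect=1.0), "hub_effect"),
        (dict(hub_rois=(200,)), "outside"),
        (dict(interaction_rois=(5,)), "subset"),
        (dict(symptom_weights=(0.5, 0.5, 0.2, -0.2)), "non-negative"),
        (dict(symptom_weights=(0.5, 0.2, 0.2, 0.2)), "sum to 1"),
        (dict(n_missing_months=96), "usable"),
        (dict(ar_coefficient=1.0), "ar_coefficient"),
    ],
)
def test_invalid_configs_rejected(kwargs, match):
    with pytest.raises(ConfigError, match=match):
        CohortConfig(**kwargs)


def test_config_hash_stable():
    assert CohortConfig(seed=1).hash() == CohortConfig(seed=1).hash()
    assert CohortConfig(seed=1).hash() != CohortConfig(seed=2).hash()


# ---------------------------------------------------------------------------
# generation

def test_default_dimensions(planted_run):
    # generated upstream of the session fixture: 96 subjects, 111 x 396
    cfg = CohortConfig(seed=99, n_volumes=48, n_ptsd=9, n_control=9,
                       n_missing_months=2)
    subjects, pheno = generate_cohort(cfg)
    assert len(subjects) == 18
    assert subjects[0].data.shape == (111, 48)
    assert subjects[0].motion.shape == (6, 48)
    assert subjects[0].wm.shape == (48,)
    table, _, _ = planted_run
    assert table.shape[0] == 96


def test_same_seed_bit_identical(small_cohort):
    subjects, pheno, cfg = small_cohort
    again_subjects, again_pheno = generate_cohort(cfg)
    for a, b in zip(subjects, again_subjects):
        assert np.array_equal(a.data, b.data)
        assert np.array_equal(a.motion, b.motion)
    pd.testing.assert_frame_equal(pheno, again_pheno)


def test_different_seeds_differ(small_cohort):
    subjects, _, cfg = small_cohort
    other, _ = generate_cohort(
        CohortConfig(**{**cfg.__dict__, "seed": cfg.seed + 1}))
    assert not np.array_equal(subjects[0].data, other[0].data)


def test_phenotype_invariants(small_cohort):
    _, pheno, cfg = small_cohort
    assert pheno["months_on_site"].isna().sum() == cfg.n_missing_months
    months = pheno["months_on_site"].dropna()
    assert months.between(*cfg.months_range).all()
    # MDD only among cases
    assert (pheno.loc[pheno["ptsd"] == 0, "mdd"] == 0).all()
    for name, spec in scid_scales.SUBSCALES.items():
        assert pheno[name].between(*spec.score_range).all()


def test_item_columns_present_and_consistent(small_cohort):
    _, pheno, _ = small_cohort
    for name, spec in scid_scales.SUBSCALES.items():
        items = pheno[spec.item_columns]
        assert items.isin([1, 2, 3]).all().all()
        assert (items.sum(axis=1) == pheno[name]).all()


def test_null_world_multiplier_is_identity():
    cfg = CohortConfig(hub_effect=0.0, interaction_slope=0.0,
                       symptom_beta=0.0)
    mult = loading_multiplier(cfg, is_case=True, months=10.0,
                              symptom_index=1.0)
    assert np.array_equal(mult, np.ones(cfg.n_roi))


def test_planted_multiplier_reduces_hubs():
    cfg = CohortConfig(symptom_beta=0.0)
    mult = loading_multiplier(cfg, is_case=True, months=4.0)
    hubs = np.asarray(DEFAULT_HUB_ROIS)
    non_hubs = np.setdiff1d(np.arange(cfg.n_roi), hubs)
    assert (mult[non_hubs] == 1.0).all()
    assert (mult[hubs] < 1.0).all()
    inter = np.asarray(cfg.interaction_rois)
    assert np.allclose(
        mult[inter], 1.0 - cfg.hub_effect + cfg.interaction_slope * 4.0)


def test_hub_effect_monotonically_lowers_case_ec():
    # group EC deficit at planted hubs grows with hub_effect (grid of
    # effects, small fast cohorts, averaged over fixed seeds)
    diffs = []
    for effect in (0.0, 0.25, 0.5):
        acc = 0.0
        for seed in (0, 1, 2):
            cfg = CohortConfig(n_ptsd=14, n_control=14, n_volumes=100,
                               hub_effect=effect, interaction_slope=0.0,
                               symptom_beta=0.0, n_missing_months=2,
                               seed=seed)
            table, pheno = cohort_ec_table(cfg)
            hubs = [f"roi_{i}" for i in cfg.hub_rois]
            means = table.groupby("group")[hubs].mean()
            acc += float((means.loc[0] - means.loc[1]).mean())
        diffs.append(acc / 3)
    assert diffs[0] < diffs[1] < diffs[2]
    assert abs(diffs[0]) < 0.002
    assert diffs[2] > 0.004


def test_population_ec_matches_observed_deficit(planted_run):
    table, pheno, cfg = planted_run
    hubs = list(cfg.hub_rois)
    means = table.groupby("group")[[f"roi_{i}" for i in hubs]].mean()
    observed = (means.loc[0] - means.loc[1]).to_numpy()
    months_mean = pheno.loc[pheno["ptsd"] == 1, "months_on_site"].mean()
    oracle = (population_ec(cfg, is_case=False)
              - population_ec(cfg, is_case=True, months=months_mean))
    assert np.allclose(observed, oracle[hubs], atol=2e-3)


# ---------------------------------------------------------------------------
# cohort_report

def _pheno_from_arrays(case_vals, ctrl_vals):
    n1, n0 = len(case_vals), len(ctrl_vals)
    return pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n1 + n0)],
            "ptsd": [1] * n1 + [0] * n0,
            "x": np.concatenate([case_vals, ctrl_vals]),
            "flagvar": np.concatenate(
                [np.zeros(n1), np.zeros(n0)]).astype(int),
        }
    )


def test_report_layout(small_cohort):
    _, pheno, _ = small_cohort
    report = cohort_report(pheno)
    assert set(report["variable"]) == {
        "months_on_site", *scid_scales.SUBSCALES, "mdd", "psychotropic",
        "opioid",
    }
    assert {"case_summary", "control_summary", "p", "flag"} <= set(
        report.columns)


def test_planted_two_sd_shift_detected():
    rng = np.random.default_rng(0)
    pheno = _pheno_from_arrays(rng.normal(2.0, 1.0, 45),
                               rng.normal(0.0, 1.0, 51))
    report = cohort_report(pheno, continuous=["x"], categorical=[])
    assert report.loc[report["variable"] == "x", "p"].iloc[0] < 0.001


def test_null_continuous_mostly_nonsignificant():
    rng = np.random.default_rng(1)
    n_sig = 0
    for _ in range(60):
        pheno = _pheno_from_arrays(rng.normal(size=45),
                                   rng.normal(size=51))
        report = cohort_report(pheno, continuous=["x"], categorical=[])
        n_sig += report["p"].iloc[0] < 0.05
    assert n_sig <= 9  # ~5% expected; binomial upper band


def test_degenerate_variable_flagged():
    pheno = _pheno_from_arrays(np.ones(10), np.ones(12))
    report = cohort_report(pheno, continuous=["x"],
                           categorical=["flagvar"])
    assert (report["flag"] == "degenerate").all()
    assert report["p"].isna().all()


def test_empty_group_rejected(small_cohort):
    _, pheno, _ = small_cohort
    with pytest.raises(ValueError, match="two groups"):
        cohort_report(pheno[pheno["ptsd"] == 1])


# ---------------------------------------------------------------------------
# round trip

def test_write_read_roundtrip(tmp_path, small_cohort):
    subjects, pheno, cfg = small_cohort
    manifest = write_cohort(subjects[:3], pheno.iloc[:3], tmp_path, cfg)
    assert manifest.exists()
    again_subjects, again_pheno = read_cohort(tmp_path)
    assert len(again_subjects) == 3
    for a, b in zip(subjects[:3], again_subjects):
        assert a.subject_id == b.subject_id
        assert np.array_equal(a.data, b.data)
        assert np.array_equal(a.motion, b.motion)
        assert np.array_equal(a.wm, b.wm)
    pd.testing.assert_frame_equal(
        pheno.iloc[:3].reset_index(drop=True), again_pheno,
        check_dtype=False)
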