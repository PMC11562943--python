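"""Inclusion filtering, encoding, imputation, splitting, and CSV I/O."""

import math

import numpy as np
import pandas as pd
import pytest

from straticare.cohort import (
    FEATURE_NAMES,
    apply_exclusions,
    encode_cohort,
    encode_features,
    impute_missing,
    read_cohort_csv,
    split_train_test,
    write_cohort_csv,
)

from conftest import make_record


# ---------------------------------------------------------------------------
# Exclusions


def test_single_instrument_score_excluded():
    r = make_record(phq9=((0, 15),), gad7=((0, 13), (60, 7)))
    included, excluded = apply_exclusions([r])
    assert included == []
    assert excluded[0][1] == "insufficient_scores"


def test_ecbt_boundary_day_98_included():
    """The completion-window boundary day counts as complete."""
    r = make_record(delivery_format="ecbt", phq9=((0, 15), (98, 14)), gad7=((0, 13), (98, 12)))
    included, _ = apply_exclusions([r])
    assert len(included) == 1


def test_ecbt_late_finish_without_improvement_excluded():
    r = make_record(delivery_format="ecbt", phq9=((0, 15), (120, 14)), gad7=((0, 13), (120, 12)))
    included, excluded = apply_exclusions([r])
    assert included == []
    assert excluded[0][1] == "incomplete_treatment"


def test_reliable_improvement_before_cutoff_counts_as_complete():
    """A >=6-point PHQ-9 drop inside the window completes the episode even
    though sessions continue past day 98."""
    r = make_record(delivery_format="ecbt",
                    phq9=((0, 15), (50, 8), (120, 14)),
                    gad7=((0, 13), (50, 12), (120, 12)))
    included, _ = apply_exclusions([r])
    assert len(included) == 1


def test_group_window_is_147_days():
    r = make_record(modality="LICBT", delivery_format="group",
                    phq9=((0, 15), (140, 14)), gad7=((0, 13), (140, 12)))
    included, _ = apply_exclusions([r])
    assert len(included) == 1


def test_empty_input_yields_empty_outputs():
    included, excluded = apply_exclusions([])
    assert included == [] and excluded == []


def test_exclusion_reasons_partition_excluded_set(small_cohort):
    records, _ = small_cohort
    included, excluded = apply_exclusions(records)
    assert len(included) + len(excluded) == len(records)
    assert all(reason in ("insufficient_scores", "incomplete_treatment")
               for _, reason in excluded)


# ---------------------------------------------------------------------------
# Encoding


def test_initial_score_is_first_by_date():
    r = make_record(phq9=((0, 15), (60, 8)))
    assert encode_features(r, "PHQ9")["initial_score"] == 15.0
    r2 = make_record(gad7=((0, 13), (30, 4)))
    assert encode_features(r2, "GAD7")["initial_score"] == 13.0


def test_sex_indicator():
    assert encode_features(make_record(sex="female"), "PHQ9")["sex_female"] == 1.0
    assert encode_features(make_record(sex="male"), "PHQ9")["sex_female"] == 0.0


def test_quantile_one_hot_with_first_as_reference():
    feats = encode_features(make_record(instability_q=3), "PHQ9")
    assert [feats[f"instability_q{k}"] for k in (2, 3, 4, 5)] == [0.0, 1.0, 0.0, 0.0]
    ref = encode_features(make_record(instability_q=1), "PHQ9")
    assert all(ref[f"instability_q{k}"] == 0.0 for k in (2, 3, 4, 5))


def test_missing_category_blanks_whole_dummy_group():
    feats = encode_features(make_record(living_arrangement=None), "PHQ9")
    living = [v for k, v in feats.items() if k.startswith("living_")]
    assert all(math.isnan(v) for v in living)
    assert not math.isnan(feats["sex_female"])


def test_no_scores_for_instrument_errors():
    r = make_record(phq9=())
    with pytest.raises(ValueError, match="no PHQ9 scores"):
        encode_features(r, "PHQ9")


# ---------------------------------------------------------------------------
# Imputation


def test_imputed_value_is_training_mean():
    train = pd.DataFrame({"employment_not_employed": [1.0, 0.0, 1.0, np.nan]})
    out = impute_missing(train)
    assert out["employment_not_employed"].iloc[3] == pytest.approx(2 / 3)


def test_imputation_identity_on_complete_data():
    train = pd.DataFrame({"a": [1.0, 0.0], "b": [0.5, 0.25]})
    pd.testing.assert_frame_equal(impute_missing(train), train)


def test_imputation_never_touches_observed_cells():
    train = pd.DataFrame({"a": [1.0, np.nan, 0.0, np.nan]})
    out = impute_missing(train)
    assert out["a"].iloc[0] == 1.0 and out["a"].iloc[2] == 0.0


def test_entirely_missing_column_errors():
    train = pd.DataFrame({"a": [np.nan, np.nan], "b": [1.0, 2.0]})
    with pytest.raises(ValueError, match="a"):
        impute_missing(train)


def test_train_means_applied_to_apply_frame():
    train = pd.DataFrame({"a": [1.0, 0.0]})
    target = pd.DataFrame({"a": [np.nan, 1.0]})
    out = impute_missing(train, target)
    assert out["a"].iloc[0] == 0.5


def test_imputed_dummy_tracks_true_probability():
    """6% MCAR missingness on a dummy with true mean 0.44: the imputed
    constant stays within 3 binomial SEs of 0.44."""
    rng = np.random.default_rng(5)
    n = 5000
    col = (rng.random(n) < 0.44).astype(float)
    col[rng.random(n) < 0.06] = np.nan
    train = pd.DataFrame({"d": col})
    filled = impute_missing(train)
    imputed_value = filled.loc[train["d"].isna(), "d"].iloc[0]
    se = math.sqrt(0.44 * 0.56 / (~np.isnan(col)).sum())
    assert abs(imputed_value - 0.44) < 3 * se


# ---------------------------------------------------------------------------
# Split


def test_split_953_gives_477_and_476():
    records = [make_record(client_id=f"c{i}") for i in range(953)]
    split = split_train_test(records, 0.5, seed=1)
    assert (len(split.train), len(split.test)) == (477, 476)


def test_split_deterministic_under_seed():
    records = [make_record(client_id=f"c{i}") for i in range(4)]
    a = split_train_test(records, 0.5, seed=9)
    b = split_train_test(records, 0.5, seed=9)
    assert [r.client_id for r in a.train] == [r.client_id for r in b.train]


def test_split_ratio_rounding():
    records = [make_record(client_id=f"c{i}") for i in range(10)]
    split = split_train_test(records, 0.3, seed=0)
    assert (len(split.train), len(split.test)) == (3, 7)


def test_split_is_a_partition(small_cohort):
    records, _ = small_cohort
    split = split_train_test(records, 0.5, seed=2)
    train_ids = {r.client_id for r in split.train}
    test_ids = {r.client_id for r in split.test}
    assert train_ids.isdisjoint(test_ids)
    assert train_ids | test_ids == {r.client_id for r in records}


def test_split_rejects_bad_inputs():
    with pytest.raises(ValueError):
        split_train_test([], 0.5, seed=0)
    with pytest.raises(ValueError):
        split_train_test([make_record()], 1.5, seed=0)


# ---------------------------------------------------------------------------
# CSV round trip


def test_cohort_csv_round_trip(tmp_path, small_cohort):
    records, _ = small_cohort
    path = tmp_path / "cohort.csv"
    write_cohort_csv(records, path)
    back = read_cohort_csv(path)
    assert back == records


def test_design_matrix_shape(small_cohort):
    records, _ = small_cohort
    X = encode_cohort(records, "PHQ9")
    assert X.shape == (len(records), len(FEATURE_NAMES))
    assert list(X.columns) == list(FEATURE_NAMES)
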