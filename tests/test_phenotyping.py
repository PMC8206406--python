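import numpy as np
import pandas as pd
import pytest

import cohortperm as cp
from cohortperm.phenotyping import (
    CONTROL_VARIANTS,
    PhenotypingError,
    classify_case,
    classify_control,
    classify_exposure,
)

from conftest import make_dataset


def status_of(cohorts, variant, member_id):
    table = cohorts[variant]
    return table.loc[table["member_id"] == member_id, "status"].item()


def control_set(cohorts, variant):
    t = cohorts[variant]
    return set(t.loc[t["status"] == "control", "member_id"])


class TestCaseRule:
    def test_t2d_dx_plus_medication_is_case(self, toy_cohorts):
        assert status_of(toy_cohorts, "baseline", "C1") == "case"

    def test_t2d_dx_plus_abnormal_hba1c_is_case(self, toy_cohorts):
        assert status_of(toy_cohorts, "baseline", "D1") == "case"

    def test_type1_only_with_insulin_is_not_case(self, toy_cohorts):
        for variant in CONTROL_VARIANTS:
            assert status_of(toy_cohorts, variant, "T1") == "excluded"
        t = toy_cohorts["baseline"]
        assert t.loc[t["member_id"] == "T1", "exclusion_reason"].item() == "t1d_dx"

    def test_member_with_no_events_is_not_case(self):
        cfg = cp.PhenotypeConfig()
        empty = pd.DataFrame(columns=["member_id", "date", "kind", "system",
                                      "code", "value"])
        assert classify_case(empty, cfg) is False

    def test_case_set_identical_across_variants(self, toy_cohorts):
        case_sets = {v: set(t.loc[t["status"] == "case", "member_id"])
                     for v, t in toy_cohorts.items()}
        assert all(s == {"C1", "D1"} for s in case_sets.values())


class TestControlVariants:
    def test_normal_value_member_per_variant(self, toy_cohorts):
        # one normal glucose value: control under A, B, C; not under D
        assert status_of(toy_cohorts, "baseline", "N1") == "control"
        assert status_of(toy_cohorts, "ignore_lab_value", "N1") == "control"
        assert status_of(toy_cohorts, "ignore_lab", "N1") == "control"
        assert status_of(toy_cohorts, "no_lab", "N1") == "excluded"

    def test_no_lab_member_per_variant(self, toy_cohorts):
        # zero orders and values: false under A and B; true under C and D
        assert status_of(toy_cohorts, "baseline", "N2") == "excluded"
        assert status_of(toy_cohorts, "ignore_lab_value", "N2") == "excluded"
        assert status_of(toy_cohorts, "ignore_lab", "N2") == "control"
        assert status_of(toy_cohorts, "no_lab", "N2") == "control"

    def test_order_without_result_only_in_ignore_lab(self, toy_cohorts):
        assert status_of(toy_cohorts, "ignore_lab", "N3") == "control"
        for variant in ("baseline", "ignore_lab_value", "no_lab"):
            assert status_of(toy_cohorts, variant, "N3") == "excluded"

    def test_abnormal_value_fails_baseline_only(self, toy_cohorts):
        assert status_of(toy_cohorts, "baseline", "N4") == "excluded"
        assert status_of(toy_cohorts, "ignore_lab_value", "N4") == "control"
        assert status_of(toy_cohorts, "ignore_lab", "N4") == "control"
        assert status_of(toy_cohorts, "no_lab", "N4") == "excluded"

    def test_family_history_excludes_everywhere(self, toy_cohorts):
        for variant in CONTROL_VARIANTS:
            assert status_of(toy_cohorts, variant, "F1") == "excluded"

    def test_below_min_visits_excluded(self, toy_cohorts):
        for variant in CONTROL_VARIANTS:
            assert status_of(toy_cohorts, variant, "V1") == "excluded"

    def test_unknown_variant_is_error(self, toy_dataset):
        with pytest.raises(PhenotypingError, match="variant"):
            cp.build_cohorts(toy_dataset, cp.PhenotypeConfig(),
                             variants=("no_such_thing",))

    def test_single_member_classifier_agrees_with_batch(self, toy_dataset, toy_cohorts):
        cfg = cp.PhenotypeConfig()
        windows = cp.qualifying_windows(toy_dataset.enrollment)
        ev = toy_dataset.events.merge(windows, on="member_id")
        ev = ev[(ev["date"] >= ev["start"]) & (ev["date"] <= ev["end"])]
        for mid in windows["member_id"]:
            mine = ev[ev["member_id"] == mid]
            assert classify_case(mine, cfg) == \
                (status_of(toy_cohorts, "baseline", mid) == "case")
            for variant in CONTROL_VARIANTS:
                expected = status_of(toy_cohorts, variant, mid) == "control"
                is_control = (classify_control(mine, cfg, variant)
                              and not classify_case(mine, cfg))
                assert is_control == expected


class TestExposure:
    def test_depression_dx_in_window(self, toy_cohorts):
        t = toy_cohorts["ignore_lab"]
        assert t.loc[t["member_id"] == "D1", "exposed_depression"].item()

    def test_depression_dx_outside_window_not_exposed(self, toy_cohorts):
        t = toy_cohorts["ignore_lab"]
        assert not t.loc[t["member_id"] == "D2", "exposed_depression"].item()

    def test_no_events_not_exposed(self):
        empty = pd.DataFrame(columns=["member_id", "date", "kind", "system",
                                      "code", "value"])
        assert classify_exposure(empty, cp.PhenotypeConfig()) is False


class TestStructuralInvariants:
    def test_variant_nesting_and_disjointness(self, generated_cohorts):
        bl = control_set(generated_cohorts, "baseline")
        ilv = control_set(generated_cohorts, "ignore_lab_value")
        il = control_set(generated_cohorts, "ignore_lab")
        nl = control_set(generated_cohorts, "no_lab")
        assert bl <= ilv <= il
        assert nl <= il
        assert not (ilv & nl)

    def test_missingness_margin_is_order_without_result(self, generated, generated_cohorts):
        _, ds, _ = generated
        ilv = control_set(generated_cohorts, "ignore_lab_value")
        il = control_set(generated_cohorts, "ignore_lab")
        nl = control_set(generated_cohorts, "no_lab")
        margin = il - (ilv | nl)
        windows = cp.qualifying_windows(ds.enrollment)
        ev = ds.events.merge(windows, on="member_id")
        ev = ev[(ev["date"] >= ev["start"]) & (ev["date"] <= ev["end"])]
        has_order = set(ev.loc[ev["kind"] == "procedure", "member_id"])
        has_result = set(ev.loc[ev["kind"] == "lab_result", "member_id"])
        assert margin == (il & has_order) - has_result

    def test_control_count_ordering_matches_demographic_table(self, generated_cohorts):
        # ignore_lab > ignore_lab_value > baseline member counts
        sizes = {v: len(control_set(generated_cohorts, v)) for v in CONTROL_VARIANTS}
        assert sizes["ignore_lab"] > sizes["ignore_lab_value"] > sizes["baseline"]

    def test_labels_invariant_under_event_permutation(self, toy_dataset):
        cfg = cp.PhenotypeConfig()
        base = cp.build_cohorts(toy_dataset, cfg)
        shuffled = cp.ClaimsDataset(
            toy_dataset.members, toy_dataset.enrollment,
            toy_dataset.events.sample(frac=1.0, random_state=7).reset_index(drop=True))
        perm = cp.build_cohorts(shuffled, cfg)
        for variant in CONTROL_VARIANTS:
            a = base[variant].sort_values("member_id").reset_index(drop=True)
            b = perm[variant].sort_values("member_id").reset_index(drop=True)
            pd.testing.assert_frame_equal(a, b)


class TestDegenerateDatasets:
    def test_dataset_without_labs(self):
        members = [("A", "male", 1950), ("B", "female", 1960),
                   ("K", "male", 1945)]
        enrollment = [(m, "2010-01-01", "2014-12-31") for m, _, _ in members]
        events = [
            ("A", "2010-02-01", "diagnosis", "ICD9", "250.00"),
            ("A", "2010-03-01", "pharmacy", "NDC", "60000000101"),
            ("B", "2010-02-01", "diagnosis", "ICD9", "401.9"),
            ("B", "2011-02-01", "diagnosis", "ICD9", "465.9"),
            ("K", "2010-04-01", "diagnosis", "ICD9", "724.2"),
            ("K", "2012-04-01", "diagnosis", "ICD9", "272.4"),
        ]
        ds = make_dataset(members, enrollment, events)
        cfg = cp.PhenotypeConfig()
        with pytest.raises(PhenotypingError, match="baseline"):
            cp.build_cohorts(ds, cfg, variants=("baseline",))
        with pytest.raises(PhenotypingError, match="ignore_lab_value"):
            cp.build_cohorts(ds, cfg, variants=("ignore_lab_value",))
        out = cp.build_cohorts(ds, cfg, variants=("ignore_lab", "no_lab"))
        assert control_set(out, "ignore_lab") == control_set(out, "no_lab")


class TestConfigValidation:
    def test_overlapping_diabetes_code_sets_rejected(self):
        with pytest.raises(PhenotypingError, match="overlap"):
            cp.CodeSets(t2d_dx=frozenset({"250.00"}),
                        t1d_dx=frozenset({"250.00", "250.01"}))

    def test_normal_bound_above_threshold_rejected(self):
        with pytest.raises(PhenotypingError, match="bound"):
            cp.PhenotypeConfig(normal_hba1c=7.0, abnormal_hba1c=6.5)

    def test_yaml_round_trip(self, tmp_path):
        import yaml
        cfg = cp.PhenotypeConfig(min_visits=3)
        path = tmp_path / "ph.yaml"
        path.write_text(yaml.safe_dump(cfg.to_dict()))
        back = cp.PhenotypeConfig.from_yaml(path)
        assert back.min_visits == 3
        assert back.code_sets.t2d_dx == cfg.code_sets.t2d_dx
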