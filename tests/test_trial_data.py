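import math

import numpy as np
import pandas as pd
import pytest

from implicit_precision.trial_data import (
    ConfigurationError,
    ExclusionPolicy,
    SchemaError,
    apply_exclusions,
    assign_condition_roles,
    read_trials,
    validate_trials,
    write_trials,
)


def _csv(tmp_path, text, name="trials.csv"):
    path = tmp_path / name
    path.write_text(text)
    return path


HEADER = "participant_id,measure,domain,block_label,trial_index,latency_ms,accuracy,response_value\n"


class TestReadTrials:
    def test_round_trips_fields_exactly(self, tmp_path):
        path = _csv(
            tmp_path,
            HEADER
            + "p1,IAT,race,b3,1,612.5,1,612.5\n"
            + "p1,IAT,race,b6,2,710.0,0,710.0\n",
        )
        table = read_trials(path)
        assert len(table) == 2
        assert list(table["latency_ms"]) == [612.5, 710.0]
        assert list(table["block_label"]) == ["b3", "b6"]
        assert list(table["accuracy"]) == [1.0, 0.0]

    def test_schema_map_renames_columns(self, tmp_path):
        path = _csv(
            tmp_path,
            "subj,measure,domain,block_label,trial_index,rt,accuracy,response_value\n"
            "p1,IAT,race,b3,1,500,1,500\n",
        )
        table = read_trials(
            path, schema_map={"participant_id": "subj", "latency_ms": "rt"}
        )
        assert table.loc[0, "participant_id"] == "p1"
        assert table.loc[0, "latency_ms"] == 500.0

    def test_missing_latency_column_names_it(self, tmp_path):
        path = _csv(
            tmp_path,
            "participant_id,measure,domain,block_label,trial_index\np1,IAT,race,b3,1\n",
        )
        with pytest.raises(SchemaError, match="latency_ms"):
            read_trials(path)

    def test_empty_file_is_an_error(self, tmp_path):
        with pytest.raises(SchemaError, match="no trial rows"):
            read_trials(_csv(tmp_path, HEADER))

    def test_unparseable_values_become_missing(self, tmp_path):
        path = _csv(tmp_path, HEADER + "p1,IAT,race,b3,1,oops,x,500\n")
        table = read_trials(path)
        assert math.isnan(table.loc[0, "latency_ms"])
        assert math.isnan(table.loc[0, "accuracy"])

    def test_write_then_read_round_trip(self, tmp_path, tiny_trials):
        path = tmp_path / "rt.csv"
        write_trials(tiny_trials, path)
        back = read_trials(path)
        pd.testing.assert_frame_equal(
            back.drop(columns="block_role"),
            tiny_trials.drop(columns="block_role").reset_index(drop=True),
            check_dtype=False,
        )


class TestAssignRoles:
    ROLE_MAP = {"IAT": (("3", "4"), ("6", "7"))}

    def _table(self, labels):
        return pd.DataFrame(
            {
                "participant_id": "p1",
                "measure": "IAT",
                "domain": "race",
                "block_label": labels,
                "block_role": pd.NA,
                "trial_index": range(1, len(labels) + 1),
                "latency_ms": 500.0,
                "accuracy": 1.0,
                "response_value": 500.0,
            }
        )

    def test_critical_blocks_assigned_practice_dropped(self):
        table = self._table(["1", "2", "3", "4", "5", "6", "7"])
        out = assign_condition_roles(table, self.ROLE_MAP)
        assert list(out["block_label"]) == ["3", "4", "6", "7"]
        assert list(out["block_role"]) == ["A", "A", "B", "B"]

    def test_label_in_both_roles_rejected(self):
        with pytest.raises(ConfigurationError, match="both roles"):
            assign_condition_roles(self._table(["3"]), {"IAT": (("3",), ("3", "6"))})

    def test_unmapped_measure_rejected(self):
        with pytest.raises(ConfigurationError, match="no role mapping"):
            assign_condition_roles(self._table(["3"]), {"AMP": (("a",), ("b",))})

    def test_empty_label_set_rejected(self):
        with pytest.raises(ConfigurationError, match="empty label set"):
            assign_condition_roles(self._table(["3"]), {"IAT": ((), ("6",))})


class TestExclusions:
    def test_slow_trial_removed_by_window(self, tiny_trials):
        trials = tiny_trials.copy()
        trials.loc[0, "latency_ms"] = 11_000.0
        out, report = apply_exclusions(trials, ExclusionPolicy())
        assert len(out) == len(trials) - 1
        assert report.n_trials_removed_by_rule["latency_window"] == 1

    def test_fast_trial_rate_drops_participant(self, tiny_trials):
        trials = tiny_trials.copy()
        p1 = trials["participant_id"] == "p1"
        idx = trials[p1].index[:3]  # 3/16 ~ 19% fast trials
        trials.loc[idx, "latency_ms"] = 200.0
        out, report = apply_exclusions(trials, ExclusionPolicy())
        assert set(out["participant_id"]) == {"p2"}
        assert report.n_participants_removed_by_rule == {"fast_trials": 1}

    def test_low_accuracy_drops_participant(self, tiny_trials):
        trials = tiny_trials.copy()
        trials.loc[trials["participant_id"] == "p1", "accuracy"] = 0.0
        out, _ = apply_exclusions(trials, ExclusionPolicy())
        assert set(out["participant_id"]) == {"p2"}

    def test_missing_accuracy_ignored_by_accuracy_rule(self, tiny_trials):
        trials = tiny_trials.copy()
        trials["accuracy"] = np.nan  # evaluative task: no correct answer
        out, _ = apply_exclusions(trials, ExclusionPolicy())
        assert set(out["participant_id"]) == {"p1", "p2"}

    def test_identity_policy_returns_input(self, tiny_trials):
        out, report = apply_exclusions(tiny_trials, ExclusionPolicy.identity())
        pd.testing.assert_frame_equal(out, tiny_trials.reset_index(drop=True))
        assert report.n_trials_retained == report.n_trials_in

    def test_counts_reconcile(self, tiny_trials):
        trials = tiny_trials.copy()
        trials.loc[0, "latency_ms"] = 20_000.0
        trials.loc[trials["participant_id"] == "p2", "accuracy"] = 0.0
        out, report = apply_exclusions(trials, ExclusionPolicy())
        assert report.n_trials_in == report.n_trials_retained + sum(
            report.n_trials_removed_by_rule.values()
        )
        assert report.n_participants_in == report.n_participants_retained + sum(
            report.n_participants_removed_by_rule.values()
        )

    def test_idempotent_and_values_untouched(self, tiny_trials):
        policy = ExclusionPolicy()
        once, _ = apply_exclusions(tiny_trials, policy)
        twice, _ = apply_exclusions(once, policy)
        pd.testing.assert_frame_equal(once, twice)
        merged = once.merge(
            tiny_trials,
            on=["participant_id", "measure", "domain", "trial_index"],
            suffixes=("", "_orig"),
        )
        assert np.allclose(merged["latency_ms"], merged["latency_ms_orig"])

    def test_policy_validation(self):
        with pytest.raises(ConfigurationError):
            ExclusionPolicy(min_latency_ms=500, max_latency_ms=400)
        with pytest.raises(ConfigurationError):
            ExclusionPolicy(max_fast_trial_proportion=1.5)


def test_validate_trials_catches_duplicates_and_bad_latencies(tiny_trials):
    validate_trials(tiny_trials, require_roles=True)
    dup = pd.concat([tiny_trials, tiny_trials.iloc[[0]]], ignore_index=True)
    with pytest.raises(ValueError, match="unique"):
        validate_trials(dup)
    bad = tiny_trials.copy()
    bad.loc[0, "latency_ms"] = -5.0
    with pytest.raises(ValueError, match="positive"):
        validate_trials(bad)
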