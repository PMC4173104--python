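import numpy as np
import pandas as pd
import pytest

from centerbench.registry_io import (
    SchemaSpec,
    StratumTable,
    ValidationError,
    SchemaError,
    complete_case_filter,
    expand_stratum_table,
    read_registry,
    registry_from_frame,
    write_registry,
)


def _write_csv(tmp_path, rows, name="reg.csv"):
    path = tmp_path / name
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def test_read_registry_counts_and_index_order(tmp_path):
    path = _write_csv(
        tmp_path,
        {
            "died": [0, 1, 0, 1, 0, 0],
            "hospital": ["B", "B", "A", "A", "B", "A"],
            "age": [60.0, 70, 65, 80, 75, 62],
        },
    )
    reg = read_registry(path, SchemaSpec(outcome="died", center="hospital",
                                         covariates=["age"]))
    assert reg.n == 6 and reg.m == 2
    assert reg.centers == ["B", "A"]            # first-appearance order
    assert list(reg.center_sizes) == [3, 3]


def test_round_trip_is_lossless(tmp_path):
    df = pd.DataFrame(
        {
            "outcome": [0, 1, 1, 0],
            "center": ["x", "y", "x", "y"],
            "x1": [0.125, -3.5, 2.0, 7.25],
        }
    )
    reg = registry_from_frame(df, covariates=["x1"])
    path = tmp_path / "out.csv"
    write_registry(reg, path)
    back = read_registry(path, SchemaSpec(outcome="outcome", center="center",
                                          covariates=["x1"]))
    pd.testing.assert_frame_equal(
        back.data.astype({"outcome": np.int8}), reg.data
    )


def test_invalid_outcome_cites_row(tmp_path):
    path = _write_csv(
        tmp_path,
        {"outcome": [0, 1, 0, 2, 1], "center": list("aabbb")},
    )
    with pytest.raises(ValidationError, match="row 3"):
        read_registry(path, SchemaSpec(outcome="outcome", center="center"))


def test_missing_column_is_schema_error(tmp_path):
    path = _write_csv(tmp_path, {"outcome": [0, 1], "center": ["a", "b"]})
    with pytest.raises(SchemaError, match="age"):
        read_registry(path, SchemaSpec(outcome="outcome", center="center",
                                       covariates=["age"]))


def test_categorical_dummy_encoding(tmp_path):
    path = _write_csv(
        tmp_path,
        {
            "outcome": [0, 1, 0, 1],
            "center": ["a", "a", "b", "b"],
            "sex": ["F", "M", "F", "F"],
        },
    )
    reg = read_registry(
        path,
        SchemaSpec(outcome="outcome", center="center", covariates=["sex"],
                   categorical={"sex": None}),
    )
    # most frequent level (F) is the reference; one dummy for M
    assert reg.covariate_cols == ["sex__M"]
    assert reg.data["sex__M"].tolist() == [0.0, 1.0, 0.0, 0.0]


class TestCompleteCaseFilter:
    def test_drops_and_reports(self, tmp_path):
        rows = {
            "outcome": [0, 1] * 5,
            "center": ["a"] * 5 + ["b"] * 5,
            "x": ["1.0", "", "2.0", "3.0", "1.5", "0.5", "NA", "2.5", "1.0", "2.0"],
        }
        path = _write_csv(tmp_path, rows)
        raw = read_registry(
            path,
            SchemaSpec(outcome="outcome", center="center", covariates=["x"],
                       missing_values=["NA"]),
        )
        reg, report = complete_case_filter(raw)
        assert reg.n == 8
        assert report.n_dropped == 2
        assert report.dropped_per_column["x"] == 2

    def test_identity_and_idempotence(self):
        reg, _ = _toy()
        filtered, report = complete_case_filter(reg)
        assert report.n_dropped == 0
        pd.testing.assert_frame_equal(filtered.data, reg.data)
        again, rep2 = complete_case_filter(filtered)
        assert rep2.n_dropped == 0

    def test_center_lost_warns(self, tmp_path):
        rows = {
            "outcome": [0, 1, 0],
            "center": ["a", "a", "tiny"],
            "x": ["1", "2", ""],
        }
        path = _write_csv(tmp_path, rows)
        raw = read_registry(path, SchemaSpec(outcome="outcome", center="center",
                                             covariates=["x"]))
        with pytest.warns(UserWarning, match="tiny"):
            reg, report = complete_case_filter(raw)
        assert reg.m == 1

    def test_missingness_rate_matches_binomial_expectation(self, tmp_path):
        # independent missingness at the rate education is missing in a
        # typical stroke register (20.8%)
        p_miss, n = 0.208, 10_000
        rng = np.random.default_rng(42)
        x = rng.standard_normal(n).astype(object)
        x[rng.random(n) < p_miss] = ""
        rows = {
            "outcome": rng.integers(0, 2, n),
            "center": rng.choice(["a", "b", "c"], n),
            "x": x,
        }
        path = _write_csv(tmp_path, rows)
        raw = read_registry(path, SchemaSpec(outcome="outcome", center="center",
                                             covariates=["x"]))
        _, report = complete_case_filter(raw)
        frac = report.n_dropped / n
        sd = np.sqrt(p_miss * (1 - p_miss) / n)
        assert abs(frac - p_miss) < 3 * sd


def _toy():
    df = pd.DataFrame(
        {"outcome": [0, 1, 0, 1], "center": list("aabb"), "x": [1.0, 2, 3, 4]}
    )
    return registry_from_frame(df, covariates=["x"]), df


class TestExpandStratumTable:
    def test_table1_counts(self, table1, table1_registry):
        reg = table1_registry
        assert reg.n == 3000 and reg.m == 3
        assert list(reg.center_sizes) == [1000, 1000, 1000]
        # center 1, L=low: 1% of 900 patients -> 9 events
        sub = reg.data[(reg.data["center"] == "1") & (reg.data["L"] == 0)]
        assert len(sub) == 900 and sub["outcome"].sum() == 9

    def test_zero_count_row_emits_nothing(self):
        df = pd.DataFrame(
            {"L": ["a", "b"], "center": ["1", "1"], "risk": [0.5, 0.5],
             "count": [0, 4]}
        )
        reg = expand_stratum_table(StratumTable(df, pattern_cols=["L"]))
        assert reg.n == 4

    def test_non_integral_events_error_suggests_integer_mode(self):
        df = pd.DataFrame(
            {"L": ["a"], "center": ["1"], "risk": [0.015], "count": [100]}
        )
        with pytest.raises(ValueError, match="integer mode"):
            expand_stratum_table(StratumTable(df, pattern_cols=["L"]))

    def test_empirical_risks_recover_inputs_exactly(self, table1, table1_registry):
        reg = table1_registry
        got = (
            reg.data.groupby(["center", "L"])["outcome"].mean()
        )
        want = table1.data.set_index(["center", "L"])["risk"]
        for (center, lab), risk in want.items():
            code = 0 if lab == "low" else 1
            assert got.loc[(center, code)] == pytest.approx(risk, abs=1e-12)

    def test_duplicate_pattern_center_rejected(self):
        df = pd.DataFrame(
            {"L": ["a", "a"], "center": ["1", "1"], "risk": [0.1, 0.2],
             "count": [10, 10]}
        )
        with pytest.raises(ValidationError, match="duplicate"):
            StratumTable(df, pattern_cols=["L"])
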