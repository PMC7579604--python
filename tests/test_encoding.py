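"""Target-statistics encoder: oracle equivalence, limits, shrinkage, one-hot."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mineinjury.encoding import (
    TargetEncoderModel,
    fit_target_encoder,
    one_hot_encode,
    shrinkage,
    transform,
)


def brute_force_s(values, targets, m):
    """Independent counting oracle for the smoothed class probabilities."""
    n_tr = len(values)
    classes = sorted(set(targets))
    out = {}
    for cat in sorted(set(values)):
        rows = [i for i, v in enumerate(values) if v == cat]
        n_i = len(rows)
        lam = n_i / (n_i + m)
        out[cat] = {}
        for c in classes:
            n_iy = sum(1 for i in rows if targets[i] == c)
            n_y = sum(1 for t in targets if t == c)
            out[cat][c] = lam * n_iy / n_i + (1 - lam) * n_y / n_tr
    return out


def _fit(values, targets, m=1.0):
    df = pd.DataFrame({"x": values, "y": targets})
    return fit_target_encoder(df, ["x"], "y", m=m)


def test_hand_computed_example():
    # column {A,A,B}, binary target {1,0,1}, m=1
    model = _fit(["A", "A", "B"], ["1", "0", "1"], m=1.0)
    assert model.tables["x"]["A"]["1"] == pytest.approx(5 / 9, abs=1e-12)
    assert model.tables["x"]["B"]["1"] == pytest.approx(5 / 6, abs=1e-12)


def test_large_m_recovers_prior():
    model = _fit(["A", "A", "B"], ["1", "0", "1"], m=1e12)
    for cat in ("A", "B"):
        assert model.tables["x"][cat]["1"] == pytest.approx(2 / 3, abs=1e-9)


def test_small_m_recovers_empirical_conditional():
    model = _fit(["A", "A", "B"], ["1", "0", "1"], m=1e-12)
    assert model.tables["x"]["A"]["1"] == pytest.approx(0.5, abs=1e-9)
    assert model.tables["x"]["B"]["1"] == pytest.approx(1.0, abs=1e-9)


def test_oracle_equivalence_on_random_tables():
    rng = np.random.default_rng(0)
    for _ in range(50):
        n = int(rng.integers(2, 51))
        values = list(rng.choice(list("abcdef"), n))
        targets = list(rng.choice(["u", "v", "w"], n))
        m = float(rng.uniform(0.1, 20))
        model = _fit(values, targets, m=m)
        expected = brute_force_s(values, targets, m)
        for cat, row in expected.items():
            for cls, s in row.items():
                assert model.tables["x"][cat][cls] == pytest.approx(s, abs=1e-12)


def test_probabilities_sum_to_one_per_category():
    rng = np.random.default_rng(1)
    values = list(rng.choice(list("abcd"), 200))
    targets = list(rng.choice(["u", "v", "w", "z"], 200))
    model = _fit(values, targets, m=7.0)
    for cat, row in model.tables["x"].items():
        assert sum(row.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(0.0 <= s <= 1.0 for s in row.values())


@given(st.integers(0, 10_000), st.floats(0.01, 1000))
def test_shrinkage_weight_properties(n, m):
    lam = shrinkage(float(n), m)
    assert 0.0 <= lam < 1.0
    assert shrinkage(float(n + 1), m) > lam  # strictly increasing
    assert shrinkage(0.0, m) == 0.0
    assert shrinkage(m, m) == pytest.approx(0.5)


def test_shrinkage_ordering_rarer_categories_closer_to_prior():
    # A seen 2x, B seen 20x, both with the same empirical conditional (all class 1)
    values = ["A"] * 2 + ["B"] * 20 + ["C"] * 78
    targets = ["1"] * 22 + ["0"] * 78
    model = _fit(values, targets, m=10.0)
    prior = model.priors["1"]
    dist_a = abs(model.tables["x"]["A"]["1"] - prior)
    dist_b = abs(model.tables["x"]["B"]["1"] - prior)
    assert dist_a <= dist_b


def test_invalid_m_rejected():
    with pytest.raises(ValueError, match="m must be"):
        _fit(["A", "B"], ["1", "0"], m=0.0)


def test_constant_target_warns_and_degenerates():
    with pytest.warns(UserWarning, match="constant"):
        model = _fit(["A", "B", "A"], ["1", "1", "1"])
    assert model.tables["x"]["A"]["1"] == pytest.approx(1.0)


class TestTransform:
    def test_k_minus_one_derived_columns(self):
        df = pd.DataFrame({"x": list("aabbcc"), "y": list("uvwuvw"), "n": range(6)})
        model = fit_target_encoder(df, ["x"], "y", m=2.0)
        out = transform(model, df[["x", "n"]])
        derived = [c for c in out.columns if c.startswith("x__")]
        assert len(derived) == 2  # 3 classes -> 2 columns
        assert model.dropped_class == "w"
        assert list(out["n"]) == list(range(6))  # numeric passthrough

    def test_unseen_category_gets_prior(self):
        df = pd.DataFrame({"x": ["a", "a", "b"], "y": ["1", "0", "1"]})
        model = fit_target_encoder(df, ["x"], "y", m=1.0)
        out = transform(model, pd.DataFrame({"x": ["zzz"]}))
        assert out.loc[0, "x__0"] == pytest.approx(model.priors["0"])

    def test_training_round_trip_reproduces_fitted_values(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            {"x": rng.choice(list("abc"), 60), "y": rng.choice(["u", "v"], 60)}
        )
        model = fit_target_encoder(df, ["x"], "y", m=5.0)
        out = transform(model, df[["x"]])
        for i, cat in enumerate(df["x"]):
            assert out.loc[i, "x__u"] == model.tables["x"][cat]["u"]

    def test_json_round_trip(self):
        df = pd.DataFrame({"x": ["a", "b", "a"], "y": ["1", "0", "0"]})
        model = fit_target_encoder(df, ["x"], "y", m=3.0)
        back = TargetEncoderModel.from_json(model.to_json())
        assert back.tables == model.tables and back.priors == model.priors
        assert back.m == model.m and back.dropped_class == model.dropped_class


class TestOneHot:
    def test_three_colors(self):
        df = pd.DataFrame({"color": ["red", "green", "blue"]})
        out = one_hot_encode(df, "color")
        assert out.shape == (3, 3)
        assert (out.sum(axis=1) == 1).all()
        assert out.loc[0, "color__red"] == 1

    def test_single_category(self):
        out = one_hot_encode(pd.DataFrame({"c": ["x", "x"]}), "c")
        assert out.shape == (2, 1) and (out["c__x"] == 1).all()

    def test_column_count_equals_distinct_values(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"c": rng.choice(list("pqrst"), 40)})
        assert one_hot_encode(df, "c").shape[1] == df["c"].nunique()
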