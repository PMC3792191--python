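"""Training, distances and the nearest-norm decision rule."""

import math
import random

import numpy as np
import pytest

from snopair import (
    PeptideWindow,
    ProteinRecord,
    WindowConfig,
    distance,
    fit,
    predict_protein,
    predict_window,
    predict_windows,
)
from snopair.errors import DimensionMismatchError, EmptyDatasetError

from conftest import random_window
from oracles import brute_predict


def test_disjoint_toy_fit_gives_unit_norms(toy_model):
    np.testing.assert_array_equal(toy_model.norms.norm_pos, np.ones(39))
    np.testing.assert_array_equal(toy_model.norms.norm_neg, -np.ones(39))
    assert toy_model.norms.n_pos == toy_model.norms.n_neg == 1


def test_identical_classes_give_all_zero_model():
    w = [PeptideWindow("ACDEFGHIKLCMNPQRSTVWY")]
    model = fit(w, w)
    assert not model.z0.values.any()
    assert not model.z1.values.any()
    assert not model.norms.norm_pos.any()


def test_empty_class_rejected(toy_pair):
    pos, _ = toy_pair
    with pytest.raises(EmptyDatasetError):
        fit([pos], [])


class TestDistance:
    def test_identity_is_zero(self):
        v = np.linspace(-1, 1, 39)
        assert distance(v, v) == 0.0

    def test_opposite_unit_vectors_closed_form(self):
        assert distance(np.ones(39), -np.ones(39)) == pytest.approx(
            2 * math.sqrt(39), abs=1e-12
        )

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=39), rng.normal(size=39)
        assert distance(a, b) == distance(b, a)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(DimensionMismatchError):
            distance(np.ones(39), np.ones(38))


class TestPredict:
    def test_training_windows_classified_back(self, toy_model, toy_pair):
        pos, neg = toy_pair
        p = predict_window(toy_model, pos)
        assert p.label == "SNO" and p.d_pos == 0.0 and not p.tie
        n = predict_window(toy_model, neg)
        assert n.label == "non-SNO" and n.d_neg == 0.0


    def test_decision_consistency_on_random_queries(self, separable_data):
        pos, neg = separable_data
        model = fit(pos, neg)
        rng = random.Random(5)
        queries = [PeptideWindow(random_window(rng)) for _ in range(40)]
        for p in predict_windows(model, queries, rng_seed=1):
            if not p.tie:
                assert (p.label == "SNO") == (p.d_pos < p.d_neg)
            assert p.d_pos >= 0 and p.d_neg >= 0

    def test_matches_brute_force_train_and_classify(self):
        rng = random.Random(42)
        pos = [random_window(rng) for _ in range(6)]
        neg = [random_window(rng) for _ in range(8)]
        model = fit([PeptideWindow(w) for w in pos], [PeptideWindow(w) for w in neg])
        for query in [random_window(rng) for _ in range(5)] + [pos[0], neg[0]]:
            expected_label, ed_pos, ed_neg = brute_predict(query, pos, neg)
            p = predict_window(model, PeptideWindow(query))
            assert p.d_pos == pytest.approx(ed_pos, abs=1e-12)
            assert p.d_neg == pytest.approx(ed_neg, abs=1e-12)
            if not p.tie:
                assert p.label == expected_label

    def test_all_zero_model_ties_reproducibly(self):
        w = [PeptideWindow("ACDEFGHIKLCMNPQRSTVWY")]
        model = fit(w, w)
        query = PeptideWindow("Z" * 10 + "C" + "Z" * 10)
        first = [predict_window(model, query, rng_seed=s) for s in range(20)]
        second = [predict_window(model, query, rng_seed=s) for s in range(20)]
        assert all(p.tie for p in first)
        assert [p.label for p in first] == [p.label for p in second]
        assert len({p.label for p in first}) == 2  # both outcomes occur over seeds

    def test_literal_rule_reverses_decisions(self, toy_pair):
        pos, neg = toy_pair
        literal = fit([pos], [neg], rule="literal")
        assert predict_window(literal, pos).label == "non-SNO"
        assert predict_window(literal, neg).label == "SNO"


def test_duplicating_a_window_into_both_classes_dilutes_its_signal(toy_pair):
    """Adding the same window to both classes moves the propensity entries of
    the pairs it carries toward zero (its frequency rises equally in F+ and
    F-, shrinking every other pair's contribution)."""
    pos, neg = toy_pair
    extra = PeptideWindow("GECAHDIFWG" + "C" + "AGEWCDKIFG")
    base = fit([pos], [neg])
    diluted = fit([pos, extra], [neg, extra])
    assert np.all(np.abs(diluted.z0.values) <= np.abs(base.z0.values) + 1e-15)
    assert np.abs(diluted.z0.values).sum() < np.abs(base.z0.values).sum()
    assert np.all(np.abs(diluted.z1.values) <= np.abs(base.z1.values) + 1e-15)


class TestPredictProtein:
    def test_no_cysteines_empty_result(self, toy_model):
        protein = ProteinRecord("P1", "A" * 60)
        assert predict_protein(toy_model, protein) == []

    def test_one_prediction_per_cysteine_ascending(self, separable_data):
        pos, neg = separable_data
        model = fit(pos, neg)
        protein = ProteinRecord("P2", "C" + "A" * 21 + "C" + "A" * 25 + "C")
        preds = predict_protein(model, protein)
        assert [p.window.site_position for p in preds] == [1, 23, 49]
        assert all(len(p.window) == 21 for p in preds)

    def test_short_protein_warns_as_fragment(self, toy_model):
        protein = ProteinRecord("P3", "A" * 19 + "C" + "A" * 20)  # 40 residues
        with pytest.warns(UserWarning, match="fragment"):
            preds = predict_protein(toy_model, protein)
        assert len(preds) == 1


def test_fit_respects_alternative_window_geometry():
    cfg = WindowConfig(xi=2)
    pos = [PeptideWindow("AACDE"), PeptideWindow("GGCHH")]
    neg = [PeptideWindow("KKCLL")]
    model = fit(pos, neg, config=cfg)
    assert model.z0.values.shape == (441, 4)
    assert model.z1.values.shape == (441, 3)
    assert model.norms.omega == 7
    assert predict_window(model, pos[0]).label in ("SNO", "non-SNO")
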