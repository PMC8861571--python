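"""Correlation-weight optimal descriptor: attributes, vocabulary, Monte
Carlo optimization, and planted-signal recovery."""

import numpy as np
import pytest

from fdqsar import synthetic_data as sd
from fdqsar.dataset_io import assign_splits
from fdqsar.dcw import (
    CorrelationWeights,
    build_vocabulary,
    dcw_value,
    extract_attributes,
    optimize_weights,
)


class TestExtractAttributes:
    def test_two_carbon(self):
        attrs = extract_attributes("CC")
        assert attrs[("single", "C")] == 2
        assert attrs[("pair", "C+C")] == 1
        assert sum(attrs.values()) == 3

    def test_single_token(self):
        attrs = extract_attributes("C")
        assert dict(attrs) == {("single", "C"): 1}

    def test_pair_is_direction_independent(self):
        a = extract_attributes("OC")
        b = extract_attributes("CO")
        assert [k for k in a if k[0] == "pair"] == [k for k in b if k[0] == "pair"]

    def test_ring_digits_and_branches_are_attributes(self):
        attrs = extract_attributes("C1CC1")
        assert attrs[("single", "1")] == 2


class TestVocabulary:
    def test_threshold_one(self):
        w = build_vocabulary(["CC", "CO"], T=1)
        assert set(w.weights) == {
            ("single", "C"),
            ("single", "O"),
            ("pair", "C+C"),
            ("pair", "C+O"),
        }
        assert all(v == 1.0 for v in w.weights.values())

    def test_threshold_two_blocks_rare(self):
        w = build_vocabulary(["CC", "CO"], T=2)
        assert set(w.weights) == {("single", "C")}
        # blocked attributes read as exactly 0
        assert w.get(("single", "O")) == 0.0

    def test_errors(self):
        with pytest.raises(ValueError):
            build_vocabulary([], T=1)
        with pytest.raises(ValueError):
            build_vocabulary(["C"], T=0)


class TestDcwValue:
    def test_zero_weights(self):
        w = CorrelationWeights(weights={})
        assert dcw_value("c1ccccc1CCO", w) == 0.0

    def test_hand_arithmetic(self):
        w = CorrelationWeights(
            weights={("single", "C"): 1.5, ("pair", "C+C"): 2.0}
        )
        assert dcw_value("CC", w) == pytest.approx(5.0)

    def test_linearity(self):
        w1 = CorrelationWeights(
            weights={("single", "C"): 0.7, ("pair", "C+C"): 1.1}
        )
        w2 = CorrelationWeights(weights={k: 2 * v for k, v in w1.weights.items()})
        for s in ("CCC", "CCCC", "C"):
            assert dcw_value(s, w2) == pytest.approx(2 * dcw_value(s, w1))


@pytest.fixture(scope="module")
def planted_problem():
    """169 synthetic SMILES; endpoint linear in the carbon-token count with
    noise sd at 10% of the signal sd."""
    cfg = sd.SyntheticConfig()
    rng = np.random.default_rng(3)
    ids, smiles = [], []
    for i in range(169):
        cid, s = sd.generate_compound(rng, cfg, i)
        ids.append(cid)
        smiles.append(s)
    counts = np.array(
        [extract_attributes(s)[("single", "C")] for s in smiles], dtype=float
    )
    signal = 3.0 * counts
    noise = np.random.default_rng(99).normal(0, 0.1 * signal.std(), len(signal))
    y = dict(zip(ids, signal + noise))
    splits = assign_splits(ids)
    by_id = dict(zip(ids, smiles))
    groups = ("active", "passive", "calibration", "validation")
    smiles_g = {g: [by_id[i] for i in splits.group(g)] for g in groups}
    y_g = {g: np.array([y[i] for i in splits.group(g)]) for g in groups}
    return smiles_g, y_g


class TestOptimizeWeights:
    def test_planted_recovery(self, planted_problem):
        smiles_g, y_g = planted_problem
        model = optimize_weights(smiles_g, y_g, T=1, N=20, delta=0.1, seed=7)
        assert model.stats["validation"]["r2"] >= 0.8

    def test_objective_strictly_increasing(self, planted_problem):
        smiles_g, y_g = planted_problem
        model = optimize_weights(smiles_g, y_g, T=1, N=5, delta=0.1, seed=7)
        trace = model.objective_trace
        assert all(b > a for a, b in zip(trace, trace[1:]))

    def test_zero_epochs_keeps_unit_weights(self, planted_problem):
        smiles_g, y_g = planted_problem
        model = optimize_weights(smiles_g, y_g, T=1, N=0, delta=0.1, seed=7)
        assert all(v == 1.0 for v in model.weights.weights.values())
        assert np.isfinite(model.c0) and np.isfinite(model.c1)

    def test_determinism(self, planted_problem):
        smiles_g, y_g = planted_problem
        a = optimize_weights(smiles_g, y_g, T=1, N=3, delta=0.1, seed=13)
        b = optimize_weights(smiles_g, y_g, T=1, N=3, delta=0.1, seed=13)
        assert a.weights.weights == b.weights.weights
        assert (a.c0, a.c1) == (b.c0, b.c1)
        c = optimize_weights(smiles_g, y_g, T=1, N=3, delta=0.1, seed=14)
        assert a.weights.weights != c.weights.weights

    def test_blocked_attributes_never_perturbed(self, planted_problem):
        smiles_g, y_g = planted_problem
        model = optimize_weights(smiles_g, y_g, T=20, N=5, delta=0.1, seed=7)
        vocab = build_vocabulary(smiles_g["active"], T=20)
        rare = build_vocabulary(smiles_g["active"], T=1)
        blocked = set(rare.weights) - set(vocab.weights)
        assert blocked  # the fixture does have rare attributes
        for key in blocked:
            assert model.weights.get(key) == 0.0

    def test_zero_variance_endpoint_error(self, planted_problem):
        smiles_g, y_g = planted_problem
        flat = {g: np.zeros_like(v) for g, v in y_g.items()}
        with pytest.raises(ValueError, match="variance"):
            optimize_weights(smiles_g, flat, T=1, N=1, delta=0.1, seed=7)
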