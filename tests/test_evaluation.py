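import itertools

import numpy as np
import pytest

from spikeinf.datatypes import NetworkGraph, SpikeTrainSet
from spikeinf.evaluation import (
    classify_neuron_types,
    lemma1_diagnostics,
    precision_recall,
    predict_spikes,
    roc_per_type,
    standardize,
    ternarize,
    type_stats,
)
from conftest import make_block


def graph_from_incoming(w_in, target=0):
    """Ground-truth graph with prescribed incoming weights for one target."""
    n = len(w_in)
    W = np.zeros((n, n))
    W[target, :] = w_in
    W[target, target] = 0.0
    D = np.where(W != 0, 1.0, 0.0)
    types = np.array(["inhibitory" if np.any(W[:, j] < 0) else "excitatory"
                      for j in range(n)], dtype=object)
    return NetworkGraph(n=n, weight=W, delay=D, d_max=2.0, neuron_type=types)


class TestPredictSpikes:
    def test_feasible_weights_perfect_accuracy(self):
        K = np.array([[1.0], [2.0], [0.5]])
        y = np.array([1, 1, 1], dtype=np.int8)
        out = predict_spikes(np.array([1.0]), [make_block(K, y)])
        assert out["accuracy"] == 1.0

    def test_zero_weights_predict_no_spikes(self):
        K = np.abs(np.random.default_rng(0).normal(size=(10, 3)))
        y = np.array([1, -1] * 5, dtype=np.int8)
        out = predict_spikes(np.zeros(3), [make_block(K, y)])
        assert np.all(out["labels"] == -1)
        assert out["accuracy"] == 0.5  # the fraction of -1 bins

    def test_two_bin_hand_instance(self):
        K = np.array([[1.0], [1.0]])
        y = np.array([1, -1], dtype=np.int8)
        out = predict_spikes(np.array([1.0]), [make_block(K, y)])
        assert out["accuracy"] == 0.5
        assert out["true_positive_spikes"] == 1
        assert out["false_positive_spikes"] == 1


class TestTypeStats:
    def test_means_by_class(self):
        # candidates 1..4: exc {1.2, 0.8}, void {0.1}, inh {-1.0}
        g = graph_from_incoming([0.0, 1.0, 1.0, 0.0, -2.0])
        w = np.array([9.9, 1.2, 0.8, 0.1, -1.0])  # self entry ignored
        st = type_stats(w, g, target=0)
        assert st["excitatory"]["mean"] == pytest.approx(1.0)
        assert st["void"]["mean"] == pytest.approx(0.1)
        assert st["inhibitory"]["mean"] == pytest.approx(-1.0)
        assert st["excitatory"]["count"] == 2

    def test_all_zero_weights(self):
        g = graph_from_incoming([0.0, 1.0, -1.0, 0.0])
        st = type_stats(np.zeros(4), g, target=0)
        assert all(st[t]["mean"] == 0.0 for t in st)

    def test_empty_class_flagged(self):
        g = graph_from_incoming([0.0, 1.0, 1.0])  # no inhibitory inputs
        st = type_stats(np.zeros(3), g, target=0)
        assert st["inhibitory"]["mean"] is None
        assert st["inhibitory"]["count"] == 0


class TestROC:
    def test_perfect_separation_auc_one(self):
        g = graph_from_incoming([0.0, 1.0, 1.0, 0.0, 0.0, -3.0])
        w = np.array([0.0, 5.0, 4.0, 0.1, -0.1, -6.0])
        roc = roc_per_type(w, g, target=0)
        assert roc["excitatory"]["auc"] == 1.0
        assert roc["inhibitory"]["auc"] == 1.0

    def test_standardized_weights(self, rng):
        w = rng.normal(size=200)
        z = standardize(w)
        assert abs(z.mean()) < 1e-12
        assert abs(z.std() - 1.0) < 1e-12

    def test_null_weights_auc_near_half(self, rng):
        n = 2000
        w_in = np.zeros(n)
        idx = rng.choice(np.arange(1, n), size=600, replace=False)
        w_in[idx[:500]] = 1.0
        w_in[idx[500:]] = -1.0
        g = graph_from_incoming(w_in)
        w = rng.normal(size=n)  # independent of the truth
        roc = roc_per_type(w, g, target=0)
        se = np.sqrt(1.0 / 500)  # conservative AUC standard error scale
        assert abs(roc["excitatory"]["auc"] - 0.5) < 3 * se
        assert abs(roc["inhibitory"]["auc"] - 0.5) < 3 * se

    def test_auc_equals_mann_whitney_brute_force(self, rng):
        w_in = np.array([0.0, 1.0, 1.0, 0.0, -2.0, 0.0, 1.0, 0.0])
        g = graph_from_incoming(w_in)
        w = rng.normal(size=8)
        roc = roc_per_type(w, g, target=0)
        z = standardize(w[1:])
        pos = z[(w_in[1:] > 0)]
        neg = z[(w_in[1:] <= 0)]
        # brute-force pairwise comparison statistic
        mw = np.mean([(1.0 if a > b else 0.5 if a == b else 0.0)
                      for a in pos for b in neg])
        assert roc["excitatory"]["auc"] == pytest.approx(mw)

    def test_degenerate_class_flagged(self):
        g = graph_from_incoming([0.0, 1.0, 1.0])  # no inhibitory edge
        roc = roc_per_type(np.array([0.0, 1.0, 2.0]), g, target=0)
        assert roc["inhibitory"]["degenerate"]
        assert roc["inhibitory"]["auc"] is None


def brute_force_ternary(x):
    """Best 3-partition of sorted values by within-cluster variance."""
    xs = np.sort(x)
    best, best_cost = None, np.inf
    m = len(xs)
    for i, j in itertools.combinations(range(1, m), 2):
        parts = [xs[:i], xs[i:j], xs[j:]]
        cost = sum(((p - p.mean()) ** 2).sum() for p in parts if len(p))
        if cost < best_cost:
            best_cost, best = cost, (xs[i - 1], xs[j - 1])
    return best  # upper edges of the low and middle clusters


class TestTernarize:
    def test_matches_exhaustive_partition(self):
        w = np.array([2.0, 1.9, 0.05, -0.1, -3.9, -4.1])
        labels = ternarize(w)
        assert list(labels) == ["excitatory", "excitatory", "void", "void",
                                "inhibitory", "inhibitory"]
        lo_edge, mid_edge = brute_force_ternary(w)
        expect = np.where(w <= lo_edge, "inhibitory",
                          np.where(w <= mid_edge, "void", "excitatory"))
        assert np.array_equal(labels.astype(str), expect)

    def test_all_zeros_degenerate_void(self):
        assert list(ternarize(np.zeros(5))) == ["void"] * 5

    def test_scale_invariance(self, rng):
        w = rng.normal(size=30)
        assert np.array_equal(ternarize(w), ternarize(3.7 * w))

    def test_self_entry_forced_void(self):
        w = np.array([5.0, 2.0, 0.0, -2.0])
        labels = ternarize(w, self_id=0)
        assert labels[0] == "void"


class TestPrecisionRecall:
    def test_perfect_labels(self):
        g = graph_from_incoming([0.0, 1.0, 0.0, -1.0])
        labels = np.array(["void", "excitatory", "void", "inhibitory"],
                          dtype=object)
        pr = precision_recall(labels, g, target=0)
        for t in ("excitatory", "void", "inhibitory"):
            assert pr[t]["precision"] == 1.0 and pr[t]["recall"] == 1.0

    def test_partial_recall(self):
        g = graph_from_incoming([0.0, 1.0, 1.0, 0.0])
        labels = np.array(["void", "excitatory", "void", "void"], dtype=object)
        pr = precision_recall(labels, g, target=0)
        assert pr["excitatory"]["precision"] == 1.0
        assert pr["excitatory"]["recall"] == 0.5

    def test_hand_confusion_counts(self):
        truth = [0.0, 1.0, 1.0, -1.0, 0.0, 0.0]
        g = graph_from_incoming(truth)
        labels = np.array(["void", "excitatory", "inhibitory", "inhibitory",
                           "excitatory", "void"], dtype=object)
        pr = precision_recall(labels, g, target=0)
        assert pr["excitatory"] == {"precision": 0.5, "recall": 0.5,
                                    "tp": 1, "fp": 1, "fn": 1}
        assert pr["inhibitory"]["precision"] == 0.5
        assert pr["inhibitory"]["recall"] == 1.0


class TestClassifyNeuronTypes:
    def test_positive_peaks_excitatory(self, rng):
        W = rng.normal(size=(40, 40)) * 0.01
        W[[1, 5, 9, 13, 17], 3] = 1.0  # five positive peaks in column 3
        out = classify_neuron_types(W)
        assert out[3] == "excitatory"

    def test_equal_counts_unclassified(self, rng):
        W = rng.normal(size=(30, 30)) * 0.01
        W[[1, 3, 5], 2] = 1.0
        W[[7, 9, 11], 2] = -1.0
        assert classify_neuron_types(W)[2] == "unclassified"

    def test_zero_variance_unclassified(self):
        W = np.zeros((10, 10))
        assert all(t == "unclassified" for t in classify_neuron_types(W))


class TestLemma1Diagnostics:
    def test_identical_kernels_positive_definite(self, rng):
        K = np.abs(rng.normal(size=(50, 5)))
        d = lemma1_diagnostics(K, K)
        assert d.ktk_invertible and d.kptkp_invertible
        assert d.min_eig_sym_cross > 0  # Gram matrix of full-rank K

    def test_negated_kernel_flips_sign(self, rng):
        K = np.abs(rng.normal(size=(50, 5)))
        d = lemma1_diagnostics(K, -K)
        assert d.min_eig_sym_cross < 0

    def test_sigmoid_hinge_bound_violated_near_zero(self, rng):
        K = np.abs(rng.normal(size=(10, 2)))
        d = lemma1_diagnostics(K, K, beta=1.0)
        # at x=0: log f_s(0) + L(0) = -log 2 + 1 > 0
        assert d.loss_bound_max_violation >= 1.0 - np.log(2.0) - 1e-9

    def test_alpha_min_from_counts(self):
        s = SpikeTrainSet(2, 10.0, [np.array([1.0, 2.0]), np.array([5.0])])
        K = np.ones((10, 2))
        d = lemma1_diagnostics(K, K, spikes=s)
        assert d.alpha_min == pytest.approx(0.1)  # 1 spike / 10 bins

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            lemma1_diagnostics(np.ones((4, 2)), np.ones((5, 2)))
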