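"""Binarization, the two-state Bernoulli HMM, and posterior clustering.

Forward-backward is validated against exact enumeration over all state
paths, and cross-checked against hmmlearn as an independent implementation;
Baum-Welch is validated by parameter recovery on data simulated from a known
chain.
"""

import itertools
import math

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from mbdseq.intervals import GenomeLayout, GenomicInterval
from mbdseq.segmentation import (
    BinaryTrack,
    TwoStateHMM,
    binarize,
    class_sharing,
    cluster_composition,
    fit_two_state_hmm,
    kmeans_cluster,
    poisson_call_threshold,
    posterior_decode,
    signal_proportions,
    stack_posteriors,
    _forward_backward,
)


def exact_poisson_threshold(lam, p=1e-4):
    """Independent oracle: exact upper-tail summation of the Poisson pmf."""
    c = 1
    while True:
        tail = 1.0 - sum(
            math.exp(-lam) * lam**k / math.factorial(k) for k in range(c)
        )
        if tail < p:
            return c
        c += 1


def enumerate_posteriors(model, obs):
    """Exact smoothing by summing over all 2^T state paths."""
    T = len(obs)
    post = np.zeros((T, 2))
    total = 0.0
    for path in itertools.product((0, 1), repeat=T):
        p = model.initial[path[0]]
        p *= model.emission[path[0]] if obs[0] else 1 - model.emission[path[0]]
        for t in range(1, T):
            p *= model.transition[path[t - 1], path[t]]
            p *= model.emission[path[t]] if obs[t] else 1 - model.emission[path[t]]
        total += p
        for t, s in enumerate(path):
            post[t, s] += p
    return post / total, math.log(total)


def random_model(rng):
    a, b = rng.uniform(0.05, 0.95, 2)
    e0, e1 = sorted(rng.uniform(0.05, 0.95, 2))
    pi = rng.dirichlet([1, 1])
    return TwoStateHMM(
        initial=pi,
        transition=np.array([[1 - a, a], [b, 1 - b]]),
        emission=np.array([e0, e1]),
    )


def sample_chain(model, n, rng):
    states = np.empty(n, dtype=np.int64)
    obs = np.empty(n, dtype=np.uint8)
    states[0] = rng.choice(2, p=model.initial)
    for t in range(1, n):
        states[t] = rng.choice(2, p=model.transition[states[t - 1]])
    obs[:] = rng.random(n) < model.emission[states]
    return states, obs


class TestBinarize:
    @pytest.mark.parametrize("lam", [0.5, 1.0, 3.7, 12.0])
    def test_threshold_matches_exact_tail_oracle(self, lam):
        assert poisson_call_threshold(lam) == exact_poisson_threshold(lam)

    def test_lambda_one_threshold_is_seven(self):
        # P(X>=6)=5.9e-4 is not below 1e-4; P(X>=7)=8.3e-5 is
        assert poisson_call_threshold(1.0) == 7
        assert exact_poisson_threshold(1.0) == 7

    def test_zero_count_never_called(self, rng):
        layout = GenomeLayout({"chr1": 4000})
        counts = {"chr1": rng.poisson(5.0, 20)}
        counts["chr1"][3] = 0
        track = binarize(counts, layout, 200)
        assert track.calls["chr1"][3] == 0

    def test_uniform_coverage_below_threshold(self):
        layout = GenomeLayout({"chr1": 4000})
        counts = {"chr1": np.full(20, 9)}
        track = binarize(counts, layout, 200)
        assert track.calls["chr1"].sum() == 0  # all counts equal the mean

    def test_all_zero_track_warns_and_calls_nothing(self, caplog):
        layout = GenomeLayout({"chr1": 4000})
        track = binarize({"chr1": np.zeros(20, dtype=int)}, layout, 200)
        assert track.calls["chr1"].sum() == 0


class TestForwardBackward:
    def test_matches_exhaustive_enumeration(self, rng):
        for trial in range(8):
            model = random_model(rng)
            n = int(rng.integers(2, 13))
            obs = (rng.random(n) < 0.5).astype(np.uint8)
            gamma, _, ll = _forward_backward(model, obs)
            expected, expected_ll = enumerate_posteriors(model, obs)
            np.testing.assert_allclose(gamma, expected, atol=1e-10)
            assert ll == pytest.approx(expected_ll, abs=1e-10)

    def test_posteriors_sum_to_one(self, rng):
        model = random_model(rng)
        obs = (rng.random(500) < 0.3).astype(np.uint8)
        gamma, _, _ = _forward_backward(model, obs)
        np.testing.assert_allclose(gamma.sum(axis=1), 1.0, atol=1e-12)

    def test_uninformative_emissions_return_chain_marginals(self):
        model = TwoStateHMM(
            initial=np.array([0.25, 0.75]),
            transition=np.array([[0.7, 0.3], [0.3, 0.7]]),
            emission=np.array([0.5, 0.5]),
        )
        obs = np.array([0, 1, 0, 1, 1], dtype=np.uint8)
        gamma, _, _ = _forward_backward(model, obs)
        expected, _ = enumerate_posteriors(model, obs)
        np.testing.assert_allclose(gamma, expected, atol=1e-12)
        # with symmetric transitions the smoothed marginal relaxes to 0.5
        np.testing.assert_allclose(gamma[2], [0.5, 0.5], atol=0.06)

    def test_agrees_with_hmmlearn(self, rng):
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        model = random_model(rng)
        obs = (rng.random(300) < 0.4).astype(np.uint8)
        gamma, _, ll = _forward_backward(model, obs)
        ref = hmmlearn.CategoricalHMM(n_components=2, init_params="")
        ref.startprob_ = model.initial
        ref.transmat_ = model.transition
        ref.emissionprob_ = np.column_stack(
            [1 - model.emission, model.emission]
        )
        ref_ll, ref_post = ref.score_samples(obs.reshape(-1, 1))
        np.testing.assert_allclose(gamma, ref_post, atol=1e-8)
        assert ll == pytest.approx(ref_ll, abs=1e-8)


class TestBaumWelch:
    def test_recovers_planted_parameters(self, rng):
        truth = TwoStateHMM(
            initial=np.array([0.5, 0.5]),
            transition=np.array([[0.99, 0.01], [0.05, 0.95]]),
            emission=np.array([0.05, 0.9]),
        )
        _, obs = sample_chain(truth, 100_000, rng)
        layout = GenomeLayout({"chr1": len(obs) * 200})
        track = BinaryTrack(layout, 200, {"chr1": obs})
        model = fit_two_state_hmm(track, seed=1)
        np.testing.assert_allclose(model.emission, truth.emission, atol=0.02)
        np.testing.assert_allclose(model.transition, truth.transition, atol=0.02)

    def test_loglik_trace_nondecreasing(self, rng):
        _, obs = sample_chain(random_model(rng), 3000, rng)
        layout = GenomeLayout({"chr1": len(obs) * 200})
        model = fit_two_state_hmm(BinaryTrack(layout, 200, {"chr1": obs}), seed=2)
        trace = np.asarray(model.loglik_trace)
        assert (np.diff(trace) >= -1e-8).all()

    def test_state_one_is_high_emission(self, rng):
        _, obs = sample_chain(random_model(rng), 5000, rng)
        layout = GenomeLayout({"chr1": len(obs) * 200})
        model = fit_two_state_hmm(BinaryTrack(layout, 200, {"chr1": obs}), seed=3)
        assert model.emission[1] >= model.emission[0]

    def test_degenerate_constant_track(self):
        layout = GenomeLayout({"chr1": 40 * 200})
        track = BinaryTrack(layout, 200, {"chr1": np.zeros(40, dtype=np.uint8)})
        model = fit_two_state_hmm(track, seed=4)
        assert (model.emission > 0).all() and (model.emission < 1).all()

    def test_track_too_short(self):
        layout = GenomeLayout({"chr1": 5 * 200})
        with pytest.raises(ValueError):
            fit_two_state_hmm(
                BinaryTrack(layout, 200, {"chr1": np.zeros(5, dtype=np.uint8)})
            )

    def test_posterior_decode_confident_inside_planted_blocks(self, rng):
        """Long planted methylated blocks get posterior > 0.95 inside."""
        n = 5000
        state = np.zeros(n, dtype=bool)
        for start in range(200, n - 60, 500):
            state[start : start + 30] = True
        obs = (rng.random(n) < np.where(state, 0.9, 0.02)).astype(np.uint8)
        layout = GenomeLayout({"chr1": n * 200})
        track = BinaryTrack(layout, 200, {"chr1": obs})
        model = fit_two_state_hmm(track, seed=5)
        post = posterior_decode(model, track)["chr1"]
        interiors = np.concatenate(
            [np.arange(s + 5, s + 25) for s in range(200, n - 60, 500)]
        )
        assert np.median(post[interiors]) > 0.95


class TestClustering:
    def make_matrix(self, rows, layout=None):
        rows = np.asarray(rows, dtype=float)
        layout = layout or GenomeLayout({"chr1": rows.shape[0] * 200})
        return stack_posteriors(
            {f"t{j}": {"chr1": rows[:, j]} for j in range(rows.shape[1])},
            layout,
            200,
        )

    def test_planted_two_pattern_recovery(self, rng):
        a = np.tile([0.95, 0.9, 0.05], (120, 1))
        b = np.tile([0.05, 0.1, 0.9], (80, 1))
        rows = np.clip(
            np.vstack([a, b]) + rng.normal(0, 0.02, (200, 3)), 0, 1
        )
        truth = np.array([0] * 120 + [1] * 80)
        clustering = kmeans_cluster(self.make_matrix(rows), k=2, seed=0)
        assert adjusted_rand_score(truth, clustering.labels) == 1.0

    def test_identical_rows_k1_zero_inertia(self):
        rows = np.tile([0.4, 0.6], (50, 1))
        clustering = kmeans_cluster(self.make_matrix(rows), k=1, seed=0)
        assert clustering.inertia == pytest.approx(0.0)

    def test_k_larger_than_distinct_rows_errors(self):
        rows = np.tile([0.4, 0.6], (50, 1))
        with pytest.raises(ValueError):
            kmeans_cluster(self.make_matrix(rows), k=3, seed=0)

    def test_same_seed_same_assignment(self, rng):
        rows = rng.random((300, 4))
        pm = self.make_matrix(rows)
        a = kmeans_cluster(pm, k=5, seed=7)
        b = kmeans_cluster(pm, k=5, seed=7)
        assert np.array_equal(a.labels, b.labels)

    def test_signal_proportions_sum_to_one(self, rng):
        rows = rng.random((400, 3))
        clustering = kmeans_cluster(self.make_matrix(rows), k=6, seed=1)
        props = signal_proportions(clustering)
        np.testing.assert_allclose(props.sum(axis=0), 1.0, atol=1e-9)

    def test_whole_genome_feature_unit_enrichment_per_cluster(self, rng):
        rows = rng.random((200, 2))
        layout = GenomeLayout({"chr1": 200 * 200})
        clustering = kmeans_cluster(self.make_matrix(rows, layout), k=3, seed=2)
        feature = [GenomicInterval("chr1", 0, layout.length_of("chr1"))]
        enr, props = cluster_composition(
            clustering, {"all": feature}, layout, n_shuffles=50, seed=0
        )
        assert (enr["enrichment"] == 1.0).all()

    def test_class_sharing_is_symmetric_with_unit_diagonal(self, rng):
        rows = rng.random((300, 3))
        clustering = kmeans_cluster(self.make_matrix(rows), k=4, seed=3)
        share = class_sharing(clustering)
        np.testing.assert_allclose(share, share.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(share), 1.0)
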