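"""Two-state methylation segmentation and cross-tissue clustering.

Pipeline: enriched fragment counts on a fixed 200 bp window grid are
binarized against a Poisson background (call = 1 when the count exceeds the
upper-tail threshold at p < 1e-4 for lambda = genome-wide mean count per
window), a two-state Bernoulli hidden Markov model is fitted per tissue by
Baum-Welch with chromosomes as independent sequences, and the smoothed
posterior probability of the methylated state (the state with the higher
emission probability) is decoded per window.  Posteriors from several
tissues form a windows x tissues matrix that is clustered with k-means;
cluster composition is assayed with the shuffle-bootstrap enrichment engine
and per-tissue methylation-signal proportions.

Forward-backward uses per-step scaling (normalized alpha/beta), which is the
numerically stable equivalent of log-space recursions; the sequential
recursions are numba-compiled.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats
from sklearn.cluster import KMeans

from .enrichment import EnrichmentResult, bootstrap_enrichment
from .intervals import GenomeLayout, GenomicInterval

logger = logging.getLogger(__name__)

_EMISSION_FLOOR = 1e-6


@dataclass
class BinaryTrack:
    """Binarized methylation calls for one tissue on the fixed window grid."""

    layout: GenomeLayout
    window_size: int
    calls: dict[str, np.ndarray]
    tissue: str = ""
    counts: dict[str, np.ndarray] | None = None
    threshold: int | None = None

    @property
    def n_windows(self) -> int:
        return int(sum(len(v) for v in self.calls.values()))

    def sequences(self) -> list[np.ndarray]:
        return [self.calls[chrom] for chrom in self.layout.chrom_names]


def poisson_call_threshold(lam: float, p_value: float = 1e-4) -> int:
    """Smallest integer c >= 1 with P(X >= c) < p_value for X ~ Poisson(lam)."""
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    # P(X >= c) = sf(c - 1); isf gives the smallest c-1 with sf < p
    c = int(stats.poisson.isf(p_value, lam)) + 1
    while c > 1 and stats.poisson.sf(c - 2, lam) < p_value:
        c -= 1
    return max(c, 1)


def binarize(
    counts: Mapping[str, np.ndarray],
    layout: GenomeLayout,
    window_size: int = 200,
    p_value: float = 1e-4,
    tissue: str = "",
) -> BinaryTrack:
    """Poisson upper-tail binarization of per-window fragment counts."""
    all_counts = np.concatenate([np.asarray(counts[c]) for c in layout.chrom_names])
    lam = float(all_counts.mean()) if all_counts.size else 0.0
    if lam == 0.0:
        logger.warning("all-zero count track%s; all calls are 0", f" ({tissue})" if tissue else "")
        calls = {c: np.zeros(len(counts[c]), dtype=np.uint8) for c in layout.chrom_names}
        return BinaryTrack(layout, window_size, calls, tissue, dict(counts), None)
    threshold = poisson_call_threshold(lam, p_value)
    calls = {
        c: (np.asarray(counts[c]) >= threshold).astype(np.uint8)
        for c in layout.chrom_names
    }
    return BinaryTrack(layout, window_size, calls, tissue, dict(counts), threshold)


@dataclass
class TwoStateHMM:
    """Bernoulli-emission two-state HMM; state 1 is 'methylated' (the state
    with the higher emission probability)."""

    initial: np.ndarray  # (2,)
    transition: np.ndarray  # (2, 2) row-stochastic
    emission: np.ndarray  # (2,) P(call = 1 | state)
    loglik_trace: list[float] = field(default_factory=list)
    converged: bool = False

    def __post_init__(self) -> None:
        self.initial = np.asarray(self.initial, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        self.emission = np.asarray(self.emission, dtype=float)
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition rows must sum to 1")
        if not ((self.emission > 0) & (self.emission < 1)).all():
            raise ValueError("emission probabilities must lie in (0, 1)")


@njit(cache=False)
def _forward_backward_kernel(obs, pi, A, e):
    """Scaled forward-backward for one observation sequence.

    Returns (gamma, xi_sum, loglik): per-step state posteriors, summed
    expected transition counts, and the log-likelihood.
    """
    T = obs.shape[0]
    b = np.empty((T, 2))
    for t in range(T):
        if obs[t] == 1:
            b[t, 0] = e[0]
            b[t, 1] = e[1]
        else:
            b[t, 0] = 1.0 - e[0]
            b[t, 1] = 1.0 - e[1]
    alpha = np.empty((T, 2))
    c = np.empty(T)
    a0 = pi[0] * b[0, 0]
    a1 = pi[1] * b[0, 1]
    c[0] = a0 + a1
    alpha[0, 0] = a0 / c[0]
    alpha[0, 1] = a1 / c[0]
    for t in range(1, T):
        a0 = (alpha[t - 1, 0] * A[0, 0] + alpha[t - 1, 1] * A[1, 0]) * b[t, 0]
        a1 = (alpha[t - 1, 0] * A[0, 1] + alpha[t - 1, 1] * A[1, 1]) * b[t, 1]
        c[t] = a0 + a1
        alpha[t, 0] = a0 / c[t]
        alpha[t, 1] = a1 / c[t]
    beta = np.empty((T, 2))
    beta[T - 1, 0] = 1.0
    beta[T - 1, 1] = 1.0
    for t in range(T - 2, -1, -1):
        b0 = A[0, 0] * b[t + 1, 0] * beta[t + 1, 0] + A[0, 1] * b[t + 1, 1] * beta[t + 1, 1]
        b1 = A[1, 0] * b[t + 1, 0] * beta[t + 1, 0] + A[1, 1] * b[t + 1, 1] * beta[t + 1, 1]
        beta[t, 0] = b0 / c[t + 1]
        beta[t, 1] = b1 / c[t + 1]
    gamma = np.empty((T, 2))
    for t in range(T):
        g0 = alpha[t, 0] * beta[t, 0]
        g1 = alpha[t, 1] * beta[t, 1]
        s = g0 + g1
        gamma[t, 0] = g0 / s
        gamma[t, 1] = g1 / s
    xi_sum = np.zeros((2, 2))
    for t in range(T - 1):
        s = 0.0
        xi = np.empty((2, 2))
        for i in range(2):
            for j in range(2):
                v = alpha[t, i] * A[i, j] * b[t + 1, j] * beta[t + 1, j]
                xi[i, j] = v
                s += v
        for i in range(2):
            for j in range(2):
                xi_sum[i, j] += xi[i, j] / s
    loglik = 0.0
    for t in range(T):
        loglik += np.log(c[t])
    return gamma, xi_sum, loglik


def _forward_backward(
    model: TwoStateHMM, seq: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    seq = np.ascontiguousarray(seq, dtype=np.uint8)
    return _forward_backward_kernel(
        seq, model.initial, model.transition, model.emission
    )


def fit_two_state_hmm(
    track: BinaryTrack | Sequence[np.ndarray],
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int = 0,
) -> TwoStateHMM:
    """Baum-Welch fit of the two-state Bernoulli HMM.

    Chromosomes are treated as independent sequences.  The log-likelihood is
    checked to be non-decreasing every iteration; emissions are floored at
    1e-6 so degenerate all-identical tracks stay valid (with a warning).
    States are relabeled at the end so that state 1 has the higher emission
    probability.
    """
    seqs = track.sequences() if isinstance(track, BinaryTrack) else [
        np.asarray(s, dtype=np.uint8) for s in track
    ]
    seqs = [s for s in seqs if len(s) > 0]
    total_len = sum(len(s) for s in seqs)
    if total_len < 10:
        raise ValueError("track too short to fit an HMM (need >= 10 windows)")
    rng = np.random.default_rng(seed)
    mean_call = sum(float(s.sum()) for s in seqs) / total_len
    if mean_call in (0.0, 1.0):
        logger.warning("degenerate all-identical track; emissions pinned at floor")
        mean_call = min(max(mean_call, _EMISSION_FLOOR), 1 - _EMISSION_FLOOR)
    lo = max(_EMISSION_FLOOR, mean_call * 0.5)
    hi = min(1 - _EMISSION_FLOOR, 0.5 + mean_call * 0.5)
    transition = np.array([[0.95, 0.05], [0.05, 0.95]]) + rng.uniform(
        -0.01, 0.01, (2, 2)
    )
    transition /= transition.sum(axis=1, keepdims=True)
    emission = np.clip(
        np.array([lo, hi]) * rng.uniform(0.9, 1.1, 2),
        _EMISSION_FLOOR,
        1 - _EMISSION_FLOOR,
    )
    model = TwoStateHMM(
        initial=np.array([0.5, 0.5]), transition=transition, emission=emission
    )

    prev_ll = -np.inf
    for iteration in range(max_iter):
        ll = 0.0
        gamma0 = np.zeros(2)
        xi_sum = np.zeros((2, 2))
        gamma_sum = np.zeros(2)
        emit_num = np.zeros(2)
        for seq in seqs:
            gamma, xi, seq_ll = _forward_backward(model, seq)
            ll += seq_ll
            gamma0 += gamma[0]
            xi_sum += xi
            gamma_sum += gamma.sum(axis=0)
            emit_num += gamma[seq == 1].sum(axis=0)
        if ll < prev_ll - 1e-8:
            raise RuntimeError(
                f"Baum-Welch log-likelihood decreased at iteration {iteration}"
            )
        model.loglik_trace.append(ll)
        model.initial = gamma0 / gamma0.sum()
        denom = xi_sum.sum(axis=1, keepdims=True)
        denom = np.where(denom > 0, denom, 1.0)
        model.transition = np.clip(xi_sum / denom, 1e-12, None)
        model.transition /= model.transition.sum(axis=1, keepdims=True)
        model.emission = np.clip(
            emit_num / np.where(gamma_sum > 0, gamma_sum, 1.0),
            _EMISSION_FLOOR,
            1 - _EMISSION_FLOOR,
        )
        if abs(ll - prev_ll) < tol:
            model.converged = True
            break
        prev_ll = ll
    if model.emission[1] < model.emission[0]:  # relabel: state 1 = methylated
        perm = [1, 0]
        model.initial = model.initial[perm]
        model.transition = model.transition[np.ix_(perm, perm)]
        model.emission = model.emission[perm]
    return model


def posterior_decode(
    model: TwoStateHMM, track: BinaryTrack
) -> dict[str, np.ndarray]:
    """Smoothed P(methylated | all calls) per window, per chromosome."""
    out = {}
    for chrom in track.layout.chrom_names:
        seq = track.calls[chrom]
        if len(seq) == 0:
            out[chrom] = np.zeros(0)
            continue
        gamma, _, _ = _forward_backward(model, seq)
        out[chrom] = gamma[:, 1]
    return out


@dataclass
class PosteriorMatrix:
    """Windows x tissues matrix of P(methylated)."""

    matrix: np.ndarray  # (n_windows, n_tissues)
    tissues: list[str]
    layout: GenomeLayout
    window_size: int

    def __post_init__(self) -> None:
        if ((self.matrix < 0) | (self.matrix > 1)).any():
            raise ValueError("posterior entries must lie in [0, 1]")

    @property
    def n_windows(self) -> int:
        return self.matrix.shape[0]

    def _grid(self) -> tuple[np.ndarray, np.ndarray, list[str]]:
        chroms: list[str] = []
        starts: list[np.ndarray] = []
        for chrom, length in self.layout.chrom_lengths.items():
            s = np.arange(0, length, self.window_size, dtype=np.int64)
            starts.append(s)
            chroms.extend([chrom] * len(s))
        all_starts = np.concatenate(starts)
        all_ends = np.minimum(
            all_starts + self.window_size,
            np.asarray(
                [self.layout.length_of(c) for c in chroms], dtype=np.int64
            ),
        )
        return all_starts, all_ends, chroms

    def window_intervals(self, indices: np.ndarray | None = None) -> list[GenomicInterval]:
        starts, ends, chroms = self._grid()
        if indices is None:
            indices = np.arange(len(starts))
        return [
            GenomicInterval(chroms[i], int(starts[i]), int(ends[i]))
            for i in np.asarray(indices)
        ]


def stack_posteriors(
    posteriors: Mapping[str, Mapping[str, np.ndarray]],
    layout: GenomeLayout,
    window_size: int = 200,
) -> PosteriorMatrix:
    """Combine per-tissue posterior tracks into one matrix (shared grid)."""
    tissues = list(posteriors)
    columns = [
        np.concatenate([posteriors[t][c] for c in layout.chrom_names])
        for t in tissues
    ]
    return PosteriorMatrix(np.column_stack(columns), tissues, layout, window_size)


@dataclass
class Clustering:
    k: int
    labels: np.ndarray
    centroids: np.ndarray  # (k, n_tissues)
    inertia: float
    matrix: PosteriorMatrix

    def cluster_indices(self, c: int) -> np.ndarray:
        return np.flatnonzero(self.labels == c)


def kmeans_cluster(
    matrix: PosteriorMatrix, k: int = 14, restarts: int = 12, seed: int = 0
) -> Clustering:
    """Euclidean k-means (k-means++ init, best of ``restarts`` by inertia)."""
    if matrix.n_windows == 0:
        raise ValueError("posterior matrix is empty")
    distinct = np.unique(matrix.matrix, axis=0).shape[0]
    if k > distinct:
        raise ValueError(f"k={k} exceeds the {distinct} distinct posterior rows")
    km = KMeans(n_clusters=k, n_init=restarts, init="k-means++", random_state=seed)
    labels = km.fit_predict(matrix.matrix)
    return Clustering(
        k=k,
        labels=labels,
        centroids=km.cluster_centers_,
        inertia=float(km.inertia_),
        matrix=matrix,
    )


def signal_proportions(
    clustering: Clustering, threshold: float = 0.5
) -> pd.DataFrame:
    """Per tissue, the proportion of its high-posterior ('methylated')
    windows assigned to each cluster; columns sum to 1 per tissue."""
    pm = clustering.matrix
    rows = []
    for c in range(clustering.k):
        idx = clustering.cluster_indices(c)
        rows.append((pm.matrix[idx] > threshold).sum(axis=0))
    counts = np.asarray(rows, dtype=float)  # (k, tissues)
    totals = counts.sum(axis=0)
    props = np.divide(counts, totals, out=np.zeros_like(counts), where=totals > 0)
    return pd.DataFrame(props, columns=pm.tissues, index=range(clustering.k))


def cluster_composition(
    clustering: Clustering,
    features: Mapping[str, Sequence[GenomicInterval]],
    layout: GenomeLayout,
    n_shuffles: int = 1000,
    seed: int = 0,
    posterior_threshold: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cluster feature enrichments plus per-tissue signal proportions.

    Each cluster's window coordinates are treated as a peak set and run
    through the shuffle-bootstrap enrichment against every feature track;
    empty clusters are omitted.
    """
    records = []
    for c in range(clustering.k):
        idx = clustering.cluster_indices(c)
        if len(idx) == 0:
            logger.warning("cluster %d is empty; omitted", c)
            continue
        windows = clustering.matrix.window_intervals(idx)
        for name, track in features.items():
            res: EnrichmentResult = bootstrap_enrichment(
                windows,
                track,
                layout,
                n_shuffles=n_shuffles,
                seed=seed + 1000 * c,
                feature_name=name,
            )
            rec = res.to_dict()
            rec["cluster"] = c
            rec["n_windows"] = len(idx)
            records.append(rec)
    enr = pd.DataFrame(records)
    props = signal_proportions(clustering, posterior_threshold)
    return enr, props


def class_sharing(
    clustering: Clustering, threshold: float = 0.5
) -> pd.DataFrame:
    """Pairwise tissue sharing of high-posterior windows through clusters.

    For tissues a and b, share(a, b) = sum_c min(n_a(c), n_b(c)) /
    max(N_a, N_b), where n_t(c) counts windows with posterior > threshold for
    tissue t in cluster c and N_t is the tissue total.  Same-class tissues in
    the planted simulations should share the majority of their signal.
    """
    pm = clustering.matrix
    high = pm.matrix > threshold
    counts = np.zeros((clustering.k, len(pm.tissues)))
    for c in range(clustering.k):
        idx = clustering.cluster_indices(c)
        counts[c] = high[idx].sum(axis=0)
    totals = counts.sum(axis=0)
    n_t = len(pm.tissues)
    share = np.zeros((n_t, n_t))
    for i in range(n_t):
        for j in range(n_t):
            denom = max(totals[i], totals[j])
            share[i, j] = (
                np.minimum(counts[:, i], counts[:, j]).sum() / denom
                if denom > 0
                else 0.0
            )
    return pd.DataFrame(share, index=pm.tissues, columns=pm.tissues)
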