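"""Population-coding measures on spike rasters and weight snapshots.

Covers the rate-based recall measures (pattern-completion coefficient Q and
the mutual information between firing-rate distributions at learning and
recall), the PCA-based dimensionality of binned spike data, spike-time
stability against shuffled surrogates, and a ridge-regression readout of
temporal sequences from binned rasters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.linear_model import Ridge
from sklearn.metrics import r2_score

from .dynamics import SpikeRaster, bin_raster

RATE_WINDOW = 0.5  # sliding-window length [s] for firing rates


def sliding_rate(raster: SpikeRaster, t_eval: float,
                 window: float = RATE_WINDOW) -> np.ndarray:
    """Per-neuron firing rate [Hz] from spikes in the trailing window.

    Counts spikes in the half-open interval (t_eval - window, t_eval] and
    divides by the window length, so rates are non-negative multiples of
    1/window Hz (2 Hz for the default 0.5 s window).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if t_eval - window < -1e-12:
        raise ValueError("rate window extends before the start of the simulation")
    counts = raster.counts_in_window(t_eval - window, t_eval, half_open_left=True)
    return counts / window


def pattern_completion_Q(rates: np.ndarray, as_ids, ans_ids, ctrl_ids) -> float:
    """Input-defined pattern-completion coefficient.

    Q = (mean rate of assembly neurons not stimulated at recall  -
         mean rate of control neurons) / mean rate of recall-stimulated
    assembly neurons. Q = 1 is perfect completion of the input-defined
    pattern, Q = 0 no completion. Undefined (NaN) if the recall-stimulated
    subpopulation is silent.
    """
    nu_as = float(np.mean(rates[np.asarray(as_ids)]))
    nu_ans = float(np.mean(rates[np.asarray(ans_ids)]))
    nu_ctrl = float(np.mean(rates[np.asarray(ctrl_ids)]))
    if nu_as == 0.0:
        return math.nan
    return (nu_ans - nu_ctrl) / nu_as


def _entropy_bits(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-np.sum(p * np.log2(p)))


def mutual_information_MI(rates_learn: np.ndarray,
                          rates_recall: np.ndarray) -> float:
    """Mutual information [bits] between the firing-rate distributions.

    Plug-in estimate MI = H(learn) + H(recall) - H(joint) over the empirical
    per-neuron distribution of exact discrete rate values (rates from a
    fixed window are multiples of 1/window Hz, so no extra binning is
    applied). Measures how much of the self-organized rate pattern present
    at learning reappears at recall.
    """
    rates_learn = np.asarray(rates_learn)
    rates_recall = np.asarray(rates_recall)
    if rates_learn.shape != rates_recall.shape:
        raise ValueError("rate vectors must cover the same neuron set")
    h1 = _entropy_bits(rates_learn)
    h2 = _entropy_bits(rates_recall)
    joint = np.stack([rates_learn, rates_recall], axis=1)
    _, joint_inv = np.unique(joint, axis=0, return_inverse=True)
    h12 = _entropy_bits(joint_inv)
    return h1 + h2 - h12


def pca_dimensionality(binned: np.ndarray, variance_fraction: float = 0.7) -> int:
    """Number of principal components needed to retain the given variance.

    ``binned`` is a (neurons x time bins) 0/1 matrix; neurons are treated as
    samples and time bins as features. Returns the smallest k whose
    cumulative explained-variance ratio reaches ``variance_fraction``
    (0 for an all-zero or otherwise variance-free matrix).
    """
    binned = np.asarray(binned, dtype=float)
    if binned.ndim != 2:
        raise ValueError("expected a 2-D (neurons x bins) matrix")
    if not np.any(binned != binned[0]):
        return 0
    pca = PCA()
    pca.fit(binned)
    evr = pca.explained_variance_ratio_
    cum = np.cumsum(evr)
    k = int(np.searchsorted(cum, variance_fraction - 1e-12) + 1)
    return min(k, len(evr))


def spike_time_stability(learn_binned: np.ndarray, recall_binned: np.ndarray,
                         per_neuron: bool = False):
    """Fraction of learning-pulse spike bins that recur at recall.

    Both inputs are (neurons x bins) 0/1 matrices over the same 1 ms grid
    (learning = final learning pulse). Per neuron the score is
    |bins with a spike in both| / |learning spikes|; neurons without any
    learning-pulse spike have no defined score (NaN) and are excluded from
    the network average. With ``per_neuron`` the full vector is returned.
    """
    learn_binned = np.asarray(learn_binned)
    recall_binned = np.asarray(recall_binned)
    if learn_binned.shape != recall_binned.shape:
        raise ValueError("rasters must have matching shape")
    n_learn = learn_binned.sum(axis=1).astype(float)
    matches = np.logical_and(learn_binned > 0, recall_binned > 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = np.where(n_learn > 0, matches / n_learn, np.nan)
    if per_neuron:
        return scores
    valid = ~np.isnan(scores)
    return float(np.mean(scores[valid])) if valid.any() else math.nan


def shuffle_raster(binned: np.ndarray, seed) -> np.ndarray:
    """Independently permute the time bins of each neuron's row.

    Preserves per-neuron spike counts while destroying temporal structure
    (e.g. bin order [0, 1, 2, 3, ...] -> [16, 3, 89, 21, ...]); used as the
    surrogate control for spike-time stability.
    """
    rng = np.random.default_rng(seed)
    binned = np.asarray(binned)
    out = np.empty_like(binned)
    n_bins = binned.shape[1]
    for i in range(binned.shape[0]):
        out[i] = binned[i, rng.permutation(n_bins)]
    return out


def stability_weight_correlation(stability: np.ndarray,
                                 mean_late_weight: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation between per-neuron spike-time stability and
    the mean late-phase weight received from the core assembly.

    Neurons without a defined stability score (NaN) are excluded. Returns
    (rho, p-value); raises if fewer than 3 valid points remain.
    """
    stability = np.asarray(stability, dtype=float)
    mean_late_weight = np.asarray(mean_late_weight, dtype=float)
    valid = ~(np.isnan(stability) | np.isnan(mean_late_weight))
    if valid.sum() < 3:
        raise ValueError("need at least 3 neurons with defined stability")
    rho, p = stats.spearmanr(stability[valid], mean_late_weight[valid])
    return float(rho), float(p)


def gaussian_random_walk(length: int = 100, y0: float = 1.0,
                         seed=None) -> np.ndarray:
    """Target sequence y[0] = y0, y[i+1] = y[i] + N(0, 1)."""
    if length < 1:
        raise ValueError("length must be at least 1")
    rng = np.random.default_rng(seed)
    steps = rng.standard_normal(length - 1)
    return np.concatenate([[y0], y0 + np.cumsum(steps)])


@dataclass
class ReadoutResult:
    weights: np.ndarray       # ridge coefficients incl. trailing intercept weight
    r2_recall: float          # coefficient of determination on the recall segment
    neuron_subset: np.ndarray  # ids used as readout inputs


def fit_ridge_readout(learning_binned: list[np.ndarray], recall_binned: np.ndarray,
                      target: np.ndarray, p_out: float = 1.0,
                      neuron_pool=None, alpha_ridge: float = 0.1,
                      seed=None) -> ReadoutResult:
    """Train a regularized linear readout of a temporal sequence.

    The design matrix stacks the (bins x neurons) transposed rasters of the
    learning pulses and the recall pulse, restricted to a random subsample
    of ``round(p_out * pool)`` neurons (without replacement), with a
    trailing intercept column that is penalized together with the rest, as
    in the objective ||y - X w||^2 + alpha ||w||^2. The target sequence is
    repeated for every segment. Performance is the coefficient of
    determination R^2 of the prediction on the recall segment alone.
    """
    n_neurons = recall_binned.shape[0]
    pool = np.arange(n_neurons) if neuron_pool is None else np.asarray(neuron_pool)
    n_sub = int(round(p_out * len(pool)))
    if n_sub < 1:
        raise ValueError("empty readout subsample")
    rng = np.random.default_rng(seed)
    subset = np.sort(rng.choice(pool, size=n_sub, replace=False))

    segments = list(learning_binned) + [recall_binned]
    X = np.vstack([seg[subset].T for seg in segments]).astype(float)
    X = np.hstack([X, np.ones((X.shape[0], 1))])
    y = np.concatenate([target] * len(segments))
    if len(y) != X.shape[0]:
        raise ValueError("target length must match the segment bin count")

    model = Ridge(alpha=alpha_ridge, fit_intercept=False)
    model.fit(X, y)
    n_recall = recall_binned.shape[1]
    pred = model.predict(X[-n_recall:])
    r2 = r2_score(target, pred)
    return ReadoutResult(weights=model.coef_.copy(), r2_recall=float(r2),
                         neuron_subset=subset)


def readout_connectivity_curve(learning_binned: list[np.ndarray],
                               recall_binned: np.ndarray,
                               p_out_grid=None, n_targets: int = 10,
                               neuron_pool=None, alpha_ridge: float = 0.1,
                               seed=0) -> pd.DataFrame:
    """Mean readout R^2 over random-walk targets for each output connectivity.

    For every p_out in the grid, ``n_targets`` seeded random-walk targets are
    fit (each with its own neuron subsample) and the per-target recall R^2
    values are tabulated. Returns a tidy frame (p_out, target, r2).
    """
    if p_out_grid is None:
        p_out_grid = np.round(np.arange(0.1, 1.01, 0.1), 2)
    n_bins = recall_binned.shape[1]
    seed_seq = np.random.SeedSequence(seed)
    target_seeds = seed_seq.spawn(n_targets)
    targets = [gaussian_random_walk(n_bins, seed=s) for s in target_seeds]
    rows = []
    for p_out in p_out_grid:
        for j, target in enumerate(targets):
            res = fit_ridge_readout(learning_binned, recall_binned, target,
                                    p_out=float(p_out), neuron_pool=neuron_pool,
                                    alpha_ridge=alpha_ridge,
                                    seed=seed_seq.spawn(1)[0])
            rows.append({"p_out": float(p_out), "target": j,
                         "r2": res.r2_recall})
    return pd.DataFrame(rows)
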