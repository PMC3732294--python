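"""Network performance measures.

The network organises itself through spike timing, but stimulus identity is
read out from firing *rates*: each output cell's spikes are binned per
(stimulus, transform) presentation of a testing phase into a rate table,
the substrate for three measures:

* **Stimulus-specific single-cell information** ``I(s, R)``: the
  information a cell's full response set conveys about one stimulus,

      I(s, R) = sum_r P(r|s) log2( P(r|s) / P(r) ),

  with responses discretized into equal-width rate bins, transforms
  equiprobable within a stimulus and stimuli equiprobable.  A cell's score
  is its maximum over stimuli; the ceiling is log2(S).

* **Multiple-cell information**: mutual information between the true and
  the decoded stimulus.  A Gaussian Bayesian decoder with leave-one-
  transform-out (jackknife) cross-validation produces a confusion table
  P(s, s'); its plug-in mutual information is corrected for the upward
  finite-sampling bias with the first-order term of the analytic series
  and clipped to [0, log2 S].  The measure is reported as a curve over
  ensemble size, the ensembles drawn from the most informative cells per
  stimulus and averaged over resampling iterations.

* **Information score**: the fraction of output cells conveying at least
  95% of the theoretical maximum about the least well represented
  stimulus — a scalar in [0, 1] used to compare parameter sweeps.

Population auto-/cross-correlograms of the input layer diagnose the
anti-phase oscillations ("perceptual cycles") that make the learning
possible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RateTable",
    "ConfusionMatrix",
    "InfoResult",
    "compute_rates",
    "population_correlogram",
    "CorrelogramResult",
    "antiphase_metrics",
    "single_cell_information",
    "bayesian_decode",
    "mutual_information",
    "multiple_cell_information",
    "information_score",
    "evaluate_information",
]

_LOG2 = np.log(2.0)
_OCCUPIED_EPS = 1e-12


# ---------------------------------------------------------------------------
# Rates


@dataclass
class RateTable:
    """Firing rate of each cell for each (stimulus, transform) pair.

    ``rates`` has shape (n_cells, S, T) in spikes/s, computed from the
    annotated cue windows of a testing phase.
    """

    rates: np.ndarray
    cell_ids: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.rates.shape[0]

    @property
    def n_stimuli(self) -> int:
        return self.rates.shape[1]

    @property
    def n_transforms(self) -> int:
        return self.rates.shape[2]


def compute_rates(record, cells: slice) -> RateTable:
    """Bin a testing-phase record into per-(stimulus, transform) rates.

    ``cells`` selects the contiguous global id range of the cells to score
    (normally the output-layer principal cells).  Rate = spike count in the
    presentation window / window length.
    """
    test_ivs = [iv for iv in record.intervals if iv.stimulus >= 0]
    if not test_ivs:
        raise ValueError("record carries no annotated single-stimulus intervals")
    stims = sorted({iv.stimulus for iv in test_ivs})
    transforms = sorted({iv.transform for iv in test_ivs})
    cell_ids = np.arange(cells.start, cells.stop)
    n_cells = cell_ids.size
    rates = np.zeros((n_cells, len(stims), len(transforms)))
    for iv in test_ivs:
        ids, _ = record.events_in(iv.t_start, iv.t_end)
        sel = ids[(ids >= cells.start) & (ids < cells.stop)] - cells.start
        counts = np.bincount(sel, minlength=n_cells)
        window_s = (iv.t_end - iv.t_start) / 1000.0
        rates[:, stims.index(iv.stimulus), transforms.index(iv.transform)] = (
            counts / window_s)
    return RateTable(rates=rates, cell_ids=cell_ids)


# ---------------------------------------------------------------------------
# Population correlograms


@dataclass
class CorrelogramResult:
    """Normalized population-rate correlation functions.

    ``auto[p]`` is the autocorrelation of pool p's population spike-count
    series; ``cross[(p, q)]`` the cross-correlation; both are Pearson
    correlations at circular lags ``lags`` (ms).  ``envelope`` is the 95th
    percentile of the pooled correlation magnitudes obtained from
    circularly-shifted surrogates — correlations above it are unlikely
    under independent, rate-matched series.
    """

    lags: np.ndarray
    auto: dict = field(default_factory=dict)
    cross: dict = field(default_factory=dict)
    envelope: float = 0.0


def _pool_series(record, pool: np.ndarray, bin_ms: float,
                 t_start: float, t_end: float) -> np.ndarray:
    edges = np.arange(t_start, t_end + bin_ms / 2, bin_ms)
    mask = np.isin(record.neuron_ids, pool)
    counts, _ = np.histogram(record.times[mask], bins=edges)
    return counts.astype(float)


def _circular_corr(x: np.ndarray, y: np.ndarray, lags: np.ndarray) -> np.ndarray:
    x = x - x.mean()
    y = y - y.mean()
    denom = x.std() * y.std() * x.size
    if denom == 0:
        raise ValueError("correlogram undefined: a population series is constant "
                         "(empty or saturated pool)")
    return np.array([np.dot(x, np.roll(y, -lag)) for lag in lags]) / denom


def population_correlogram(record, pools: dict[int, np.ndarray],
                           bin_ms: float = 1.0, max_lag_ms: float = 100.0,
                           t_start: float | None = None,
                           t_end: float | None = None,
                           n_surrogates: int = 200,
                           rng: np.random.Generator | None = None) -> CorrelogramResult:
    """Auto- and cross-correlograms of per-stimulus population rates.

    Spikes of each pool are binned into ``bin_ms`` windows, mean-subtracted,
    and correlated at circular lags up to ``max_lag_ms``.
    """
    if bin_ms <= 0:
        raise ValueError("bin_ms must be positive")
    if rng is None:
        rng = np.random.default_rng(0)
    if t_start is None:
        t_start = 0.0
    if t_end is None:
        t_end = record.duration if record.intervals else float(record.times.max())
    series = {p: _pool_series(record, pool, bin_ms, t_start, t_end)
              for p, pool in pools.items()}
    max_lag = int(round(max_lag_ms / bin_ms))
    lags = np.arange(-max_lag, max_lag + 1)

    result = CorrelogramResult(lags=lags * bin_ms)
    keys = sorted(series)
    for p in keys:
        result.auto[p] = _circular_corr(series[p], series[p], lags)
    for a_i, p in enumerate(keys):
        for q in keys[a_i + 1:]:
            result.cross[(p, q)] = _circular_corr(series[p], series[q], lags)

    if n_surrogates > 0 and len(keys) >= 2:
        n = series[keys[0]].size
        vals = []
        for _ in range(n_surrogates):
            p, q = rng.choice(keys, size=2, replace=False)
            shift = int(rng.integers(1, n))
            vals.append(_circular_corr(series[p], np.roll(series[q], shift),
                                       lags))
        # pooled per-lag null distribution (a max-over-lags statistic would
        # be degenerate for periodic series, which realign at some shift)
        result.envelope = float(np.percentile(np.abs(np.concatenate(vals)), 95))
    return result


def antiphase_metrics(corr: CorrelogramResult, pair=None,
                      sync_tolerance_ms: float = 5.0) -> dict:
    """Summary statistics of the anti-phase (perceptual-cycle) signature.

    Returns the zero-lag cross-correlation, the lag of the strongest
    positive cross-correlation outside the synchrony window, the
    oscillation period estimated from the autocorrelations (first local
    maximum beyond the central peak), and two synchrony statistics:
    ``sync_peak``, the largest cross-correlation within
    ``sync_tolerance_ms`` of zero lag, and ``synchronized``, true when
    that peak rises above the surrogate significance envelope — i.e. the
    populations co-fire on the same oscillation cycle.  The tolerance
    absorbs the di-synaptic latency with which one population's volley can
    trail the other's within a cycle.
    """
    if pair is None:
        pair = sorted(corr.cross)[0]
    cc = corr.cross[pair]
    lags = corr.lags
    zero = float(cc[lags == 0][0])
    near_zero = np.abs(lags) <= sync_tolerance_ms
    pos = ~near_zero
    peak_idx = np.argmax(cc[pos])
    peak_lag = float(lags[pos][peak_idx])
    peak_val = float(cc[pos][peak_idx])

    periods = []
    for ac in corr.auto.values():
        right = ac[lags >= 0]
        rlags = lags[lags >= 0]
        # step beyond the central peak: first zero crossing, then argmax
        below = np.flatnonzero(right <= 0)
        if below.size == 0:
            continue
        start = below[0]
        if start < right.size - 1:
            periods.append(float(rlags[start + np.argmax(right[start:])]))
    period = float(np.mean(periods)) if periods else np.nan
    return {
        "zero_lag_cross": zero,
        "peak_lag": peak_lag,
        "peak_value": peak_val,
        "auto_period": period,
        "sync_peak": float(cc[near_zero].max()),
        "synchronized": bool(cc[near_zero].max() > corr.envelope),
        "zero_lag_is_max": bool(cc[near_zero].max() >= cc.max() - 1e-12),
    }


# ---------------------------------------------------------------------------
# Single-cell information


def single_cell_information(rates: RateTable | np.ndarray,
                            n_response_bins: int = 10) -> np.ndarray:
    """Stimulus-specific information I(s, R) per (cell, stimulus), bits.

    Each cell's S*T responses are discretized into ``n_response_bins``
    equal-width bins spanning that cell's own response range (a constant
    cell collapses into a single bin and carries 0 bits).  P(r|s) is the
    response distribution over the transforms of s (equiprobable), P(r)
    the mixture over equiprobable stimuli.
    """
    r = rates.rates if isinstance(rates, RateTable) else np.asarray(rates)
    n_cells, n_s, n_t = r.shape
    if n_s < 2:
        raise ValueError("at least two stimuli are required")
    info = np.zeros((n_cells, n_s))
    for c in range(n_cells):
        resp = r[c]
        lo, hi = resp.min(), resp.max()
        if hi <= lo:
            continue  # constant cell: zero bits, not an error
        edges = np.linspace(lo, hi, n_response_bins + 1)
        binned = np.clip(np.digitize(resp, edges) - 1, 0, n_response_bins - 1)
        p_r_given_s = np.zeros((n_s, n_response_bins))
        for s in range(n_s):
            p_r_given_s[s] = np.bincount(binned[s], minlength=n_response_bins) / n_t
        p_r = p_r_given_s.mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(p_r_given_s > 0, p_r_given_s / p_r, 1.0)
            info[c] = np.sum(p_r_given_s * np.log2(ratio), axis=1)
    return np.clip(info, 0.0, np.log2(n_s))


# ---------------------------------------------------------------------------
# Decoding and multiple-cell information


@dataclass
class ConfusionMatrix:
    """Joint probability table P(s, s') between true and decoded stimulus."""

    p: np.ndarray
    n_trials: int

    def conditional(self) -> np.ndarray:
        rows = self.p.sum(axis=1, keepdims=True)
        return np.divide(self.p, rows, out=np.zeros_like(self.p),
                         where=rows > 0)


def _gaussian_loglik(x: np.ndarray, mu: np.ndarray, sd: np.ndarray) -> np.ndarray:
    return -0.5 * ((x - mu) / sd) ** 2 - np.log(sd)


def bayesian_decode(rates: RateTable | np.ndarray,
                    ensemble=None,
                    sd_floor_frac: float = 0.01,
                    sd_floor_abs: float = 0.1) -> ConfusionMatrix:
    """Gaussian Bayesian decoding with leave-one-transform-out jackknife.

    For every held-out (stimulus, transform) response vector, each cell's
    responses to each stimulus (excluding the held-out transform of the
    true stimulus) are fitted with a Gaussian; the per-cell likelihoods of
    the held-out rates are multiplied across the ensemble and normalized
    into P(s'|response), accumulated into the joint table P(s, s').  A
    standard-deviation floor ``max(sd, sd_floor_frac * cell range,
    sd_floor_abs spikes/s)`` guards zero-variance cells.
    """
    r = rates.rates if isinstance(rates, RateTable) else np.asarray(rates)
    if ensemble is not None:
        r = r[np.asarray(ensemble)]
    n_cells, n_s, n_t = r.shape
    if n_t < 2:
        raise ValueError("jackknife decoding needs at least two transforms")
    cell_range = np.ptp(r.reshape(n_cells, -1), axis=1)
    floor = np.maximum(sd_floor_frac * cell_range, sd_floor_abs)

    joint = np.zeros((n_s, n_s))
    for s_true in range(n_s):
        for t_held in range(n_t):
            x = r[:, s_true, t_held]
            loglik = np.zeros(n_s)
            for s in range(n_s):
                resp = r[:, s, :]
                if s == s_true:
                    keep = np.arange(n_t) != t_held
                    resp = resp[:, keep]
                mu = resp.mean(axis=1)
                sd = np.maximum(resp.std(axis=1), floor)
                loglik[s] = _gaussian_loglik(x, mu, sd).sum()
            loglik -= loglik.max()
            post = np.exp(loglik)
            post /= post.sum()
            joint[s_true] += post
    joint /= n_s * n_t
    return ConfusionMatrix(p=joint, n_trials=n_s * n_t)


def mutual_information(conf: ConfusionMatrix,
                       bias_correct: bool = True) -> float:
    """Mutual information of a confusion table, bits, bias-corrected.

    The plug-in estimate is reduced by the first-order finite-sampling
    bias term ``(sum_s (R_s - 1) - (R - 1)) / (2 N ln 2)``, where ``R_s``
    counts the occupied cells of conditional row s and ``R`` those of the
    decoded-stimulus marginal, then clipped to the theoretical limits
    [0, log2 S].
    """
    p = conf.p
    if conf.n_trials <= 0:
        raise ValueError("confusion matrix requires a positive trial count")
    ps = p.sum(axis=1)
    psp = p.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(p > 0, p / (ps[:, None] * psp[None, :]), 1.0)
        raw = float(np.sum(p * np.log2(ratio)))
    if bias_correct:
        cond = conf.conditional()
        r_s = (cond > _OCCUPIED_EPS).sum(axis=1)
        r_marg = (psp > _OCCUPIED_EPS).sum()
        bias = (np.sum(r_s - 1) - (r_marg - 1)) / (2.0 * conf.n_trials * _LOG2)
        raw -= bias
    return float(np.clip(raw, 0.0, np.log2(p.shape[0])))


def _iteration_schedule(max_cells: int, iters_first: int,
                        iters_last: int) -> np.ndarray:
    if max_cells == 1:
        return np.array([iters_first])
    return np.round(np.linspace(iters_first, iters_last, max_cells)).astype(int)


def multiple_cell_information(rates: RateTable | np.ndarray,
                              max_cells: int = 5,
                              info: np.ndarray | None = None,
                              iters_first: int = 50, iters_last: int = 10,
                              rng: np.random.Generator | None = None) -> np.ndarray:
    """Decoded information (bits) versus ensemble size 1..max_cells.

    The candidate lists hold, for every stimulus, the ``max_cells`` cells
    with the most single-cell information about it.  An ensemble of size n
    is drawn stratified across stimuli — per-stimulus quotas of n // S with
    the remainder spread at random — so every stimulus is represented by
    its own most informative cells as soon as the ensemble is large enough,
    mirroring how the ensembles are assembled from the best cells *for
    each* stimulus.  For each size the decoded, bias-corrected information
    is averaged over random ensembles, the iteration count decreasing
    linearly with ensemble size to smooth sampling effects, and clipped to
    [0, log2 S].
    """
    r = rates.rates if isinstance(rates, RateTable) else np.asarray(rates)
    if max_cells < 1:
        raise ValueError("max_cells must be at least 1")
    if rng is None:
        rng = np.random.default_rng(0)
    if info is None:
        info = single_cell_information(RateTable(r, np.arange(r.shape[0])))
    n_s = r.shape[1]
    n_cells = r.shape[0]
    if n_cells < max_cells:
        warnings.warn("fewer cells than requested ensemble size; "
                      "using all available cells")
    top: list[np.ndarray] = [
        np.argsort(info[:, s])[::-1][:max_cells] for s in range(n_s)
    ]

    def draw_ensemble(n: int) -> np.ndarray:
        quotas = np.full(n_s, n // n_s)
        extra = rng.choice(n_s, size=n % n_s, replace=False)
        quotas[extra] += 1
        chosen: list[int] = []
        for s in np.argsort(-quotas):
            candidates = [c for c in top[s] if c not in chosen]
            take = min(int(quotas[s]), len(candidates))
            if take > 0:
                picked = rng.choice(len(candidates), size=take, replace=False)
                chosen.extend(int(candidates[i]) for i in picked)
        # top lists overlap between stimuli; backfill from the global ranking
        if len(chosen) < min(n, n_cells):
            overall = np.argsort(info.max(axis=1))[::-1]
            for c in overall:
                if int(c) not in chosen:
                    chosen.append(int(c))
                if len(chosen) == min(n, n_cells):
                    break
        return np.array(chosen)

    iters = _iteration_schedule(max_cells, iters_first, iters_last)
    curve = np.zeros(max_cells)
    for n in range(1, max_cells + 1):
        vals = [
            mutual_information(bayesian_decode(r, ensemble=draw_ensemble(n)))
            for _ in range(iters[n - 1])
        ]
        curve[n - 1] = np.clip(np.mean(vals), 0.0, np.log2(n_s))
    return curve


def information_score(info: np.ndarray, n_output: int | None = None,
                      threshold_frac: float = 0.95) -> float:
    """Fraction of output cells carrying near-maximal information about the
    least well represented stimulus.

    ``info`` is the (cell, stimulus) single-cell table.  Per stimulus the
    cells with I(s, R) >= threshold_frac * log2(S) are counted; the minimum
    count over stimuli is normalized by the output-layer size.
    """
    info = np.asarray(info)
    n_cells, n_s = info.shape
    if n_output is None:
        n_output = n_cells
    threshold = threshold_frac * np.log2(n_s)
    counts = (info >= threshold).sum(axis=0)
    return float(counts.min() / n_output)


@dataclass
class InfoResult:
    """Bundle of the three performance measures for one rate table."""

    single_cell: np.ndarray  # (cells, stimuli), bits
    single_cell_max: np.ndarray  # per-cell max over stimuli, bits
    multi_cell: np.ndarray  # curve over ensemble size, bits
    info_score: float
    ceiling: float  # log2(S), bits


def evaluate_information(rates: RateTable, max_cells: int = 5,
                         n_response_bins: int = 10,
                         rng: np.random.Generator | None = None) -> InfoResult:
    """Compute all three information measures for one testing phase."""
    info = single_cell_information(rates, n_response_bins=n_response_bins)
    curve = multiple_cell_information(rates, max_cells=max_cells, info=info,
                                      rng=rng)
    return InfoResult(
        single_cell=info,
        single_cell_max=info.max(axis=1),
        multi_cell=curve,
        info_score=information_score(info, n_output=rates.n_cells),
        ceiling=float(np.log2(rates.n_stimuli)),
    )
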