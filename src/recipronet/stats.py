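"""Spike-train and tuning statistics.

Implements the measures used to characterize balanced-network activity:

* orientation selectivity index (OSI), the circular-variance-style index
  |sum_k r(theta_k) e^{2 i theta_k}| / sum_k r(theta_k);
* Fano factor, spike-count variance over mean across repeated trials;
* the inter-spike-interval coefficient of variation CV and its local,
  rate-modulation-insensitive counterpart CV2;
* Spearman serial rank correlations SRC_i between ISIs i apart, and the
  renewal / non-renewal identities FF = CV^2 and
  FF = CV^2 (1 + 2 sum_i SRC_i) that link them to the Fano factor;
* the spike autocorrelation function on a 1 ms grid and the decorrelation
  time extracted from its exponential approach to the squared-rate
  asymptote.

Variance convention: plain averages (divide by n, not n-1) throughout,
switchable via ``ddof``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "TuningCurve",
    "ACFunction",
    "StatsSummary",
    "osi",
    "fano_factor",
    "cv",
    "cv2",
    "serial_rank_correlations",
    "ff_from_cv_src",
    "bin_spikes",
    "autocorrelation",
    "population_autocorrelation",
    "DecayFit",
    "decorrelation_time",
    "ac_undershoot",
    "windowed_counts",
    "summarize_population",
]


@dataclass(frozen=True)
class TuningCurve:
    """Mean firing rate (Hz) versus stimulus orientation (radians, [0, pi))
    for one neuron or one population average."""

    orientations: np.ndarray
    rates: np.ndarray

    def __post_init__(self) -> None:
        th = np.asarray(self.orientations, dtype=float)
        r = np.asarray(self.rates, dtype=float)
        if th.shape != r.shape or th.size < 3:
            raise ValueError("need matching arrays with >= 3 orientations")
        if np.any(r < 0):
            raise ValueError("rates must be nonnegative")


@dataclass(frozen=True)
class ACFunction:
    """Autocorrelation values on a millisecond lag grid.

    ``values`` has the zero-lag peak removed (lags start at one bin).  The
    raw estimator of one train converges at long lags to that neuron's
    squared mean rate; a population average converges to the *mean of the
    squared* rates, which exceeds the squared mean rate whenever rates are
    heterogeneous.  ``asymptote`` stores the applicable long-lag limit.
    ``normalization`` records which view is stored ("rate_squared" for the
    raw estimator, "rate" when divided by the mean rate so the asymptote is
    the mean activity, as in population-average displays).
    """

    lags_ms: np.ndarray
    values: np.ndarray
    mean_rate_hz: float
    asymptote: float | None = None
    normalization: str = "rate_squared"

    def long_lag_limit(self) -> float:
        if self.asymptote is not None:
            return self.asymptote
        return (self.mean_rate_hz if self.normalization == "rate"
                else self.mean_rate_hz**2)

    def excess(self) -> np.ndarray:
        """AC minus its long-lag asymptote."""
        return np.asarray(self.values, dtype=float) - self.long_lag_limit()

    def as_rate_normalized(self) -> "ACFunction":
        """View whose long-lag asymptote is the mean rate rather than its
        square (undefined for silent trains)."""
        if self.normalization == "rate":
            return self
        if self.mean_rate_hz <= 0:
            raise ValueError("cannot normalize AC of a silent train")
        return ACFunction(self.lags_ms, self.values / self.mean_rate_hz,
                          self.mean_rate_hz,
                          self.long_lag_limit() / self.mean_rate_hz, "rate")


def osi(curve: TuningCurve) -> float:
    """Orientation selectivity index in [0, 1].

    0 for a flat curve, 1 for a response confined to a single orientation.
    Raises ``ValueError`` on an all-zero curve (the index is undefined, not
    zero, for a silent neuron).
    """
    r = np.asarray(curve.rates, dtype=float)
    total = r.sum()
    if total <= 0:
        raise ValueError("OSI undefined for an all-zero tuning curve")
    z = np.sum(r * np.exp(2j * np.asarray(curve.orientations, dtype=float)))
    return float(np.abs(z) / total)


def fano_factor(counts, ddof: int = 0) -> float:
    """Trial-to-trial spike-count variance over mean.

    Raises ``ValueError`` with fewer than two trials or a zero mean count
    (for which the ratio is undefined).
    """
    c = np.asarray(counts, dtype=float)
    if c.size < 2:
        raise ValueError("Fano factor needs at least two trials")
    mean = c.mean()
    if mean <= 0:
        raise ValueError("Fano factor undefined for zero mean count")
    return float(c.var(ddof=ddof) / mean)


def _isis(x) -> np.ndarray:
    isis = np.asarray(x, dtype=float)
    if isis.ndim != 1 or isis.size < 2:
        raise ValueError("need a 1-d sequence of at least two ISIs")
    if np.any(isis <= 0):
        raise ValueError("ISIs must be positive")
    return isis


def cv(isis, ddof: int = 0) -> float:
    """Coefficient of variation of the inter-spike intervals: SD / mean."""
    x = _isis(isis)
    return float(x.std(ddof=ddof) / x.mean())


def cv2(isis) -> float:
    """Local ISI variability: mean over adjacent interval pairs of
    2 |dt_{i+1} - dt_i| / (dt_{i+1} + dt_i).  Bounded in [0, 2] and, unlike
    the CV, insensitive to slow firing-rate modulation."""
    x = _isis(isis)
    num = 2.0 * np.abs(np.diff(x))
    den = x[1:] + x[:-1]
    return float(np.mean(num / den))


def serial_rank_correlations(isis, max_order: int = 20) -> np.ndarray:
    """Spearman rank correlation between ISI pairs (dt_k, dt_{k-i}) for
    i = 1..max_order.  Ties receive average ranks."""
    x = _isis(isis)
    if x.size <= max_order + 1:
        raise ValueError("ISI sequence too short for the requested order")
    ranks = sps.rankdata(x)
    out = np.empty(max_order)
    for i in range(1, max_order + 1):
        a, b = ranks[:-i], ranks[i:]
        out[i - 1] = np.corrcoef(a, b)[0, 1]
    return out


def ff_from_cv_src(cv_value: float, src: np.ndarray) -> float:
    """Predicted long-window Fano factor of a stationary point process from
    its ISI statistics: CV^2 (1 + 2 sum_i SRC_i).  With all serial
    correlations zero this is the renewal identity FF = CV^2."""
    return float(cv_value**2 * (1.0 + 2.0 * np.sum(src)))


def windowed_counts(spike_times, duration: float, window: float) -> np.ndarray:
    """Spike counts in consecutive windows of length ``window`` (ms), used to
    estimate a single-train Fano factor."""
    n_win = int(duration // window)
    if n_win < 2:
        raise ValueError("duration must cover at least two windows")
    t = np.asarray(spike_times, dtype=float)
    edges = np.arange(n_win + 1) * window
    counts, _ = np.histogram(t[t < n_win * window], bins=edges)
    return counts


def bin_spikes(spike_times, duration: float, bin_ms: float = 1.0) -> np.ndarray:
    """Spike counts on a regular grid of ``bin_ms`` bins covering
    [0, duration)."""
    n_bins = int(round(duration / bin_ms))
    edges = np.arange(n_bins + 1) * bin_ms
    t = np.asarray(spike_times, dtype=float)
    counts, _ = np.histogram(t[(t >= 0) & (t < n_bins * bin_ms)], bins=edges)
    return counts


def autocorrelation(
    spike_times,
    duration: float,
    max_lag_ms: float = 200.0,
    bin_ms: float = 1.0,
) -> ACFunction:
    """Autocorrelation of one spike train binned at ``bin_ms``.

    The estimator is AC(tau) = <N(t) N(t+tau)>_t / dt^2 with dt in seconds,
    so at long lags it converges to the squared mean rate in Hz^2 for an
    uncorrelated train.  The zero-lag peak is removed: lags start at one bin.
    """
    counts = bin_spikes(spike_times, duration, bin_ms).astype(float)
    n_bins = counts.size
    max_lag = int(round(max_lag_ms / bin_ms))
    if max_lag >= n_bins:
        raise ValueError("duration too short for the requested maximum lag")
    # FFT-based raw correlation <N(t) N(t+tau)>, unbiased in the overlap count
    nfft = int(2 ** np.ceil(np.log2(2 * n_bins)))
    f = np.fft.rfft(counts, nfft)
    raw = np.fft.irfft(f * np.conj(f), nfft)[: max_lag + 1]
    overlap = n_bins - np.arange(max_lag + 1)
    mean_prod = raw / overlap
    dt_s = bin_ms * 1e-3
    values = mean_prod[1:] / dt_s**2
    rate = counts.sum() / (n_bins * dt_s)
    lags = np.arange(1, max_lag + 1) * bin_ms
    return ACFunction(lags_ms=lags, values=values, mean_rate_hz=rate,
                      asymptote=rate**2)


def population_autocorrelation(
    trains: list[np.ndarray],
    duration: float,
    max_lag_ms: float = 200.0,
    bin_ms: float = 1.0,
) -> ACFunction:
    """Average of the per-neuron autocorrelations; silent trains are
    skipped (their AC is identically zero and carries no timing signal)."""
    acc = None
    rates = []
    n_used = 0
    for t in trains:
        if len(t) == 0:
            continue
        ac = autocorrelation(t, duration, max_lag_ms, bin_ms)
        acc = ac.values if acc is None else acc + ac.values
        rates.append(ac.mean_rate_hz)
        n_used += 1
    if n_used == 0:
        raise ValueError("no spikes in any train")
    lags = np.arange(1, int(round(max_lag_ms / bin_ms)) + 1) * bin_ms
    rates = np.asarray(rates)
    return ACFunction(lags_ms=lags, values=acc / n_used,
                      mean_rate_hz=float(rates.mean()),
                      asymptote=float(np.mean(rates**2)))


@dataclass(frozen=True)
class DecayFit:
    """Exponential-decay fit of an AC excess above its asymptote."""

    tau_ms: float
    fit_window_ms: tuple[float, float]
    n_points: int
    slope: float
    intercept: float


def decorrelation_time(
    ac: ACFunction,
    asymptote: float | None = None,
    min_points: int = 4,
    floor_fraction: float = 0.05,
    noise_sigmas: float = 4.0,
    loglog: bool = False,
) -> DecayFit:
    """Characteristic decay time of the autocorrelation toward its asymptote.

    The excess AC(tau) - asymptote is fitted by linear regression of its
    logarithm against lag over an automatically selected window: from the
    lag of the maximal excess to the last lag before the excess first drops
    below the fit floor — the larger of ``floor_fraction`` of the peak and
    twice the estimation noise (the standard deviation of the excess over
    the last quarter of the lag range).  The decay time is -1/slope of the
    semilog fit.  With ``loglog=True`` the regression is log-excess against
    log-lag and the power-law slope magnitude is reported in ``tau_ms``
    instead.

    ``asymptote`` defaults to the AC's own long-lag limit (per-neuron
    squared rate, or mean squared rate for a population average).  A flat
    AC, a peak indistinguishable from estimation noise (below
    ``noise_sigmas`` tail standard deviations) or a non-decaying excess
    raises ``ValueError`` — the decay time is undefined there, not zero.
    """
    if asymptote is None:
        asymptote = ac.long_lag_limit()
    excess = np.asarray(ac.values, dtype=float) - asymptote
    lags = np.asarray(ac.lags_ms, dtype=float)
    tail = excess[3 * excess.size // 4:]
    noise = float(tail.std())
    i0 = int(np.argmax(excess))
    peak = excess[i0]
    if peak <= 0:
        raise ValueError("AC does not exceed its asymptote; decay undefined")
    if peak <= noise_sigmas * noise:
        raise ValueError(
            "AC excess indistinguishable from estimation noise; "
            "decay undefined"
        )
    floor = max(floor_fraction * peak, 2.0 * noise)
    bad = np.flatnonzero(excess[i0:] < floor)
    i1 = i0 + (bad[0] if bad.size else excess.size - i0)
    sel = slice(i0, i1)
    y = excess[sel]
    if y.size < min_points:
        raise ValueError("too few points above the floor to fit a decay")
    x = np.log(lags[sel]) if loglog else lags[sel]
    res = sps.linregress(x, np.log(y))
    if res.slope >= 0:
        raise ValueError("AC excess does not decay over the fit window")
    tau = -res.slope if loglog else -1.0 / res.slope
    return DecayFit(
        tau_ms=float(tau),
        fit_window_ms=(float(lags[sel][0]), float(lags[sel][-1])),
        n_points=int(y.size),
        slope=float(res.slope),
        intercept=float(res.intercept),
    )


def ac_undershoot(ac: ACFunction,
                  lag_window_ms: tuple[float, float] = (10.0, 40.0)) -> float:
    """Depth of the negative undershoot of the AC below its asymptote,
    measured as the minimum excess over ``lag_window_ms``.

    The window starts past the refractory/burst trough of the first few
    milliseconds, which every spike train shows regardless of connectivity
    (at rates of a few Hz the trough shoulder extends to almost 10 ms); a
    genuinely undershooting AC returns a clearly negative value while a
    monotone relaxation returns approximately zero.
    """
    lags = np.asarray(ac.lags_ms, dtype=float)
    sel = (lags >= lag_window_ms[0]) & (lags <= lag_window_ms[1])
    if not np.any(sel):
        raise ValueError("lag window outside the AC range")
    return float(ac.excess()[sel].min())


@dataclass(frozen=True)
class StatsSummary:
    """Per-neuron arrays plus population means of the activity statistics.
    Entries are NaN where a statistic is undefined for that neuron (too few
    spikes)."""

    rate_hz: np.ndarray
    cv: np.ndarray
    cv2: np.ndarray
    fano: np.ndarray | None = None
    osi: np.ndarray | None = None
    src: np.ndarray | None = None
    ac: ACFunction | None = None
    tau_dec_ms: float | None = None

    def mean(self, name: str) -> float:
        arr = getattr(self, name)
        return float(np.nanmean(arr))


def summarize_population(
    trains: list[np.ndarray],
    duration: float,
    max_lag_ms: float = 200.0,
    src_order: int = 20,
    min_spikes: int = 3,
) -> StatsSummary:
    """Rates, CV, CV2 and serial correlations for a list of spike-time
    arrays from one trial, plus the population AC and its decay time when
    it is well defined."""
    n = len(trains)
    rate = np.full(n, np.nan)
    cvs = np.full(n, np.nan)
    cv2s = np.full(n, np.nan)
    srcs = np.full((n, src_order), np.nan)
    for i, t in enumerate(trains):
        t = np.asarray(t, dtype=float)
        rate[i] = len(t) / (duration * 1e-3)
        if len(t) >= min_spikes:
            isis = np.diff(t)
            cvs[i] = cv(isis)
            cv2s[i] = cv2(isis)
            if len(isis) > src_order + 1:
                srcs[i] = serial_rank_correlations(isis, src_order)
    ac = None
    tau = None
    try:
        ac = population_autocorrelation(trains, duration, max_lag_ms)
        tau = decorrelation_time(ac).tau_ms
    except ValueError:
        pass
    return StatsSummary(rate_hz=rate, cv=cvs, cv2=cv2s, src=srcs,
                        ac=ac, tau_dec_ms=tau)
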