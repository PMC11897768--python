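"""Per-unit response metrics: amplitude, irradiance (Hill) fits, quality
index, step latency, ON-OFF bias, transience, and response classification.

All metrics are computed from PSTHs at the bin sizes conventional for each
quantity (25 ms for amplitude/transience, 200 ms for the quality index,
1 ms for latency) and follow the half-open [start, end) window convention
of :mod:`chirpcode.preprocess`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, signal, stats

from .preprocess import PSTHMatrix, bin_psth

__all__ = [
    "UnitMetrics",
    "HillFit",
    "response_amplitude",
    "fit_hill",
    "quality_index",
    "match_firing_rate",
    "latency_to_onset",
    "bias_index",
    "transience_index",
    "classify_response",
]

#: step timing within the chirp (s)
STEP_ONSET_S = 0.0
STEP_OFFSET_S = 3.0

#: ON-OFF bias below which a unit counts as OFF; symmetric bound for ON
BIAS_OFF_THRESHOLD = -1.0 / 3.0
BIAS_ON_THRESHOLD = 1.0 / 3.0
#: transience index separating ON transient from ON sustained
TRANSIENCE_SUSTAINED_THRESHOLD = 0.5


@dataclass
class UnitMetrics:
    unit_id: str
    amplitude: float  # spikes/s, baseline-subtracted max
    qi: float  # [0, 1]
    latency_s: float | None  # None when threshold never crossed (e.g. OFF units)
    bias_index: float  # [-1, 1]
    transience_index: float | None  # [0, 1]; None when no step response
    category: str | None  # ON_transient | ON_sustained | ON_OFF | OFF
    mean_rate: float  # spikes/s over the whole chirp


@dataclass(frozen=True)
class HillFit:
    top: float
    bottom: float
    slope: float
    ec50_log: float
    r2: float

    def __call__(self, irradiance_log: np.ndarray | float) -> np.ndarray:
        return _hill(np.asarray(irradiance_log, float),
                     self.top, self.bottom, self.slope, self.ec50_log)


# ---------------------------------------------------------------------------
# amplitude & irradiance response


def response_amplitude(
    psth: PSTHMatrix,
    step_window: tuple[float, float] = (STEP_ONSET_S, STEP_OFFSET_S + 3.0),
    baseline_window: tuple[float, float] | None = None,
) -> float:
    """Baseline-subtracted peak firing rate around the light step (spikes/s).

    Baseline is the mean rate over the 2 s preceding step onset; the peak is
    the maximum trial-mean rate during the 3 s step or the 3 s after it (so
    OFF excitation is captured too). When no pre-onset data exist —
    consecutive trials, onset at t=0 — pass a ``baseline_window`` in the
    trailing dark period, which is the same adaptation state.
    """
    if baseline_window is None:
        baseline_window = (step_window[0] - 2.0, step_window[0])
    a, b = psth.window
    if not (a <= baseline_window[0] and baseline_window[1] <= b):
        raise ValueError(
            f"PSTH window {psth.window} does not cover baseline {baseline_window}"
        )
    baseline = float(psth.restrict(baseline_window).mean_rate().mean())
    peak = float(psth.restrict(step_window).mean_rate().max())
    return peak - baseline


def _hill(x: np.ndarray, top: float, bottom: float, slope: float, ec50: float) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + 10.0 ** (slope * (ec50 - x)))


def fit_hill(
    amplitudes: Sequence[float],
    irradiances_log: Sequence[float],
    n_restarts: int = 5,
    seed: int = 0,
) -> HillFit:
    """Least-squares Hill (irradiance-response) fit with four free
    parameters: top, bottom, slope and log EC50."""
    y = np.asarray(amplitudes, dtype=float)
    x = np.asarray(irradiances_log, dtype=float)
    if y.size != x.size:
        raise ValueError("amplitudes and irradiances must align")
    if y.size < 4:
        raise ValueError("need at least 4 irradiance levels")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(x))):
        raise ValueError("non-finite inputs")

    span = y.max() - y.min()
    lo = [y.min() - 0.5 * abs(span) - 1e-9, y.min() - 0.5 * abs(span) - 1e-9, 0.05, x.min() - 2]
    hi = [y.max() + 0.5 * abs(span) + 1e-9, y.max() + 0.5 * abs(span) + 1e-9, 10.0, x.max() + 2]
    rng = np.random.default_rng(seed)
    best, best_sse = None, np.inf
    for k in range(n_restarts):
        if k == 0:
            p0 = [y.max(), y.min(), 1.0, float(np.median(x))]
        else:
            p0 = [rng.uniform(l, h) for l, h in zip(lo, hi)]
        try:
            popt, _ = optimize.curve_fit(
                _hill, x, y, p0=p0, bounds=(lo, hi), maxfev=20_000
            )
        except RuntimeError:
            continue
        sse = float(np.sum((y - _hill(x, *popt)) ** 2))
        if sse < best_sse:
            best, best_sse = popt, sse
    if best is None:
        raise RuntimeError("Hill fit failed to converge from every start")
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - best_sse / sst if sst > 0 else 0.0
    top, bottom, slope, ec50 = (float(v) for v in best)
    if top < bottom:  # enforce monotone nondecreasing orientation
        top, bottom = bottom, top
    return HillFit(top=top, bottom=bottom, slope=slope, ec50_log=ec50, r2=float(r2))


def pick_subsaturating_irradiance(
    mean_amplitudes: Sequence[float],
    irradiances_log: Sequence[float],
    target_fraction: float = 0.75,
) -> float:
    """Irradiance whose mean amplitude lies nearest ``target_fraction`` of
    the maximum — the sub-saturating level used for between-condition
    comparisons (large responses, good signal-to-noise, not ceilinged)."""
    amps = np.asarray(mean_amplitudes, dtype=float)
    irr = np.asarray(irradiances_log, dtype=float)
    if amps.size != irr.size or amps.size == 0:
        raise ValueError("amplitudes and irradiances must align and be nonempty")
    target = target_fraction * amps.max()
    return float(irr[np.argmin(np.abs(amps - target))])


# ---------------------------------------------------------------------------
# quality index


def quality_index(psth: PSTHMatrix) -> float:
    """Trial-reproducibility quality index on a 200 ms PSTH.

    QI = Var_time[mean_trials(counts)] / mean_trials[Var_time(counts)],
    with population variances throughout. 1 for identical time-varying
    trials, ~1/n_trials for stimulus-independent noise, defined 0 when
    every trial is constant over time.
    """
    if psth.n_trials < 2:
        raise ValueError("quality index needs at least 2 trials")
    c = psth.counts.astype(float)
    num = float(c.mean(axis=1).var())
    den = float(c.var(axis=0).mean())
    return num / den if den > 0 else 0.0


def match_firing_rate(
    rates_a: Sequence[float],
    rates_b: Sequence[float],
    caliper: float | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Greedy nearest-neighbour matching of two unit groups on mean firing rate.

    Returns index arrays (into a and b) of equal length; pairs differing by
    more than ``caliper`` (default: 0.25 pooled standard deviations) are not
    formed. Used to compare the quality index between conditions without a
    firing-rate confound. Processing order is randomised (seeded) so the
    greedy pass carries no ordering bias.
    """
    a = np.asarray(rates_a, dtype=float)
    b = np.asarray(rates_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if caliper is None:
        pooled_sd = float(np.concatenate([a, b]).std())
        caliper = 0.25 * pooled_sd if pooled_sd > 0 else np.inf

    rng = np.random.default_rng(seed)
    order = rng.permutation(a.size)
    available = np.ones(b.size, dtype=bool)
    pairs: list[tuple[int, int]] = []
    for i in order:
        cand = np.nonzero(available)[0]
        if cand.size == 0:
            break
        d = np.abs(b[cand] - a[i])
        k = int(np.argmin(d))
        if float(d[k]) <= caliper:
            j = int(cand[k])
            pairs.append((int(i), j))
            available[j] = False
    if not pairs:
        warnings.warn("no rate-matched pairs within caliper; returning empty match")
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    ia, ib = (np.array(x, dtype=int) for x in zip(*pairs))
    if ia.size >= 3:  # self-check: matched rate distributions should agree
        ks = stats.ks_2samp(a[ia], b[ib])
        if ks.pvalue <= 0.2:
            warnings.warn(
                f"matched rate distributions still differ (KS p={ks.pvalue:.3g})"
            )
    return ia, ib


# ---------------------------------------------------------------------------
# latency


def latency_to_onset(
    psth: PSTHMatrix,
    onset_s: float = STEP_ONSET_S,
    search_s: float = 0.3,
    baseline_window: tuple[float, float] | None = None,
    boxcar_s: float = 0.010,
) -> float | None:
    """Latency of the step-onset response from a 1 ms PSTH, or None.

    The trial-mean rate is smoothed with a zero-phase (forward-backward)
    10 ms boxcar; the detection threshold is the baseline mean plus twice
    the baseline standard deviation, both taken from a 300 ms baseline
    window (pre-onset where available, else a trailing-dark surrogate).
    Latency is the time of the first bin within (0, 300 ms] after onset
    exceeding the threshold; units that never cross (e.g. OFF units)
    return None.
    """
    if baseline_window is None:
        baseline_window = (onset_s - search_s, onset_s)
    rate = psth.mean_rate()
    width = max(1, int(round(boxcar_s / psth.bin_s)))
    if width > 1:
        kern = np.ones(width) / width
        smoothed = signal.filtfilt(kern, [1.0], rate, padlen=min(3 * width, rate.size - 1))
    else:
        smoothed = rate

    def window_idx(w: tuple[float, float]) -> slice:
        i0 = int(round((w[0] - psth.t0) / psth.bin_s))
        i1 = int(round((w[1] - psth.t0) / psth.bin_s))
        if not (0 <= i0 < i1 <= psth.n_bins):
            raise ValueError(f"window {w} outside PSTH {psth.window}")
        return slice(i0, i1)

    base = smoothed[window_idx(baseline_window)]
    threshold = float(base.mean()) + 2.0 * float(base.std())
    search = smoothed[window_idx((onset_s, onset_s + search_s))]
    above = np.nonzero(search > threshold)[0]
    if above.size == 0:
        return None
    return float((above[0] + 0.5) * psth.bin_s)  # bin centre relative to onset


# ---------------------------------------------------------------------------
# polarity & transience


def bias_index(
    trials: Sequence[np.ndarray],
    onset_s: float = STEP_ONSET_S,
    offset_s: float = STEP_OFFSET_S,
    window_s: float = 0.5,
) -> float:
    """ON-OFF bias: (ON - OFF)/(ON + OFF) of total spike counts in the
    500 ms after step onset (ON) and after step offset (OFF); 0/0 -> 0."""
    on = off = 0
    for spikes in trials:
        s = np.asarray(spikes, dtype=float)
        on += int(np.sum((s >= onset_s) & (s < onset_s + window_s)))
        off += int(np.sum((s >= offset_s) & (s < offset_s + window_s)))
    total = on + off
    return (on - off) / total if total > 0 else 0.0


def transience_index(
    psth: PSTHMatrix,
    bias: float,
    onset_s: float = STEP_ONSET_S,
    offset_s: float = STEP_OFFSET_S,
) -> float | None:
    """Normalised 1 s response area after the step (25 ms PSTH), in [0, 1].

    The trial-mean PSTH is normalised to its maximum over the step epoch
    ([onset, offset + 3 s), covering both ON and OFF excitation); the index
    is the mean normalised rate over 1 s after onset for ON units
    (bias > -1/3) or after offset for OFF units. 0 is maximally transient,
    1 sustained at peak rate throughout. None when the unit has no step
    response to normalise by.
    """
    rate = psth.restrict((onset_s, offset_s + 3.0)).mean_rate()
    peak = float(rate.max())
    if peak <= 0:
        return None
    anchor = onset_s if bias > BIAS_OFF_THRESHOLD else offset_s
    window = psth.restrict((anchor, anchor + 1.0)).mean_rate()
    return float(window.mean() / peak)


def classify_response(bias: float, transience: float | None) -> str | None:
    """Response category from bias and transience.

    OFF below bias -1/3; ON-OFF within ±1/3; ON above, split into
    transient vs sustained at transience 0.5. Returns None for ON units
    whose transience is undefined.
    """
    if bias < BIAS_OFF_THRESHOLD:
        return "OFF"
    if bias <= BIAS_ON_THRESHOLD:
        return "ON_OFF"
    if transience is None:
        return None
    return (
        "ON_sustained"
        if transience >= TRANSIENCE_SUSTAINED_THRESHOLD
        else "ON_transient"
    )


# ---------------------------------------------------------------------------
# convenience: all step metrics for one unit


def compute_unit_metrics(
    unit_id: str,
    trials: Sequence[np.ndarray],
    duration_s: float = 30.0,
    amplitude_baseline: tuple[float, float] = (28.0, 30.0),
    latency_baseline: tuple[float, float] = (29.7, 30.0),
) -> UnitMetrics:
    """Compute the full step-response metric set for one unit.

    Baselines default to the trailing dark segment, the adaptation-matched
    surrogate for pre-onset darkness when trials are presented
    back-to-back.
    """
    psth25 = bin_psth(trials, 0.025, (0.0, duration_s))
    psth200 = bin_psth(trials, 0.2, (0.0, duration_s))
    psth1 = bin_psth(trials, 0.001, (0.0, duration_s))

    amp = response_amplitude(psth25, baseline_window=amplitude_baseline)
    qi = quality_index(psth200)
    lat = latency_to_onset(psth1, baseline_window=latency_baseline)
    bias = bias_index(trials)
    trans = transience_index(psth25, bias)
    cat = classify_response(bias, trans)
    total = sum(len(np.asarray(s)[(np.asarray(s) >= 0) & (np.asarray(s) < duration_s)])
                for s in trials)
    mean_rate = total / (len(trials) * duration_s)
    return UnitMetrics(
        unit_id=unit_id,
        amplitude=amp,
        qi=qi,
        latency_s=lat,
        bias_index=bias,
        transience_index=trans,
        category=cat,
        mean_rate=mean_rate,
    )
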