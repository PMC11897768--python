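"""Contrast-response and temporal-frequency tuning from the chirp segments.

The contrast chirp (2 Hz carrier, Michelson contrast ramping 3% -> 97%)
yields one response amplitude per 0.5 s carrier cycle; amplitudes are
normalised to the amplitude in the 0.5 s before chirp onset and fitted
with a bounded Naka-Rushton function. The temporal chirp (1 -> 8 Hz sweep)
yields per-cycle amplitudes grouped into 1 Hz-wide frequency bands and
fitted with a five-parameter half-Gaussian in log2 frequency. Cycle
boundaries come analytically from the stimulus phase, so the profiles do
not drift with response latency or bin size.

Amplitude is max - min of the trial-mean firing rate within a cycle
(25 ms PSTH), matching the step-metric conventions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .preprocess import PSTHMatrix
from .stimulus import ChirpStimulus

__all__ = [
    "ContrastProfile",
    "TemporalProfile",
    "NakaRushtonFit",
    "HalfGaussianFit",
    "contrast_profile",
    "temporal_profile",
    "fit_naka_rushton",
    "fit_half_gaussian",
    "naka_rushton",
    "half_gaussian",
    "R2_INCLUSION",
    "SPREAD_INCLUSION",
]

R2_INCLUSION = 0.5
SPREAD_INCLUSION = 0.51  # octaves; narrower fits rest on too few points
MIN_ACTIVE_BIN_FRACTION = 0.10


@dataclass(frozen=True)
class ContrastProfile:
    contrast: np.ndarray  # Michelson contrast per cycle
    amplitude: np.ndarray  # normalised max-min rate per cycle
    frac_active_bins: float  # fraction of 25 ms bins with spikes in the segment
    flagged: bool  # True when the pre-chirp normaliser was zero


@dataclass(frozen=True)
class TemporalProfile:
    frequency: np.ndarray  # mean instantaneous frequency per band (Hz)
    amplitude: np.ndarray  # mean max-min rate per band (spikes/s)
    frac_active_bins: float
    flagged: bool


@dataclass(frozen=True)
class NakaRushtonFit:
    top: float
    bottom: float
    slope: float  # (0, 10]
    c50: float  # (0, 1]
    r2: float
    included: bool

    def __call__(self, contrast: np.ndarray | float) -> np.ndarray:
        return naka_rushton(np.asarray(contrast, float),
                            self.top, self.bottom, self.slope, self.c50)


@dataclass(frozen=True)
class HalfGaussianFit:
    low_baseline: float
    high_baseline: float
    spread: float  # octaves
    peak_amp: float
    peak_tf: float  # Hz in [1, 8]
    r2: float
    included: bool

    def __call__(self, freq_hz: np.ndarray | float) -> np.ndarray:
        return half_gaussian(np.asarray(freq_hz, float), self.low_baseline,
                             self.high_baseline, self.spread, self.peak_amp,
                             self.peak_tf)


def naka_rushton(c, top, bottom, slope, c50):
    c = np.asarray(c, dtype=float)
    return bottom + (top - bottom) * c**slope / (c**slope + c50**slope)


def half_gaussian(f, low_baseline, high_baseline, spread, peak_amp, peak_tf):
    """Half-Gaussian tuning in log2 frequency with side-dependent baselines."""
    f = np.asarray(f, dtype=float)
    lo_side = f < peak_tf
    base = np.where(lo_side, low_baseline, high_baseline)
    g = np.exp(-((np.log2(f) - np.log2(peak_tf)) ** 2) / (2.0 * spread**2))
    return base + (peak_amp - base) * g


# ---------------------------------------------------------------------------
# profiles


def _cycle_amplitudes(psth: PSTHMatrix, edges: np.ndarray) -> np.ndarray:
    """max - min of the trial-mean rate within each [edges[k], edges[k+1]) cycle."""
    rate = psth.mean_rate()
    amps = np.empty(edges.size - 1)
    for k in range(edges.size - 1):
        i0 = int(np.floor((edges[k] - psth.t0) / psth.bin_s + 1e-9))
        i1 = int(np.ceil((edges[k + 1] - psth.t0) / psth.bin_s - 1e-9))
        i0, i1 = max(i0, 0), min(i1, psth.n_bins)
        seg = rate[i0:i1]
        amps[k] = float(seg.max() - seg.min()) if seg.size else 0.0
    return amps


def _segment_activity(psth: PSTHMatrix, window: tuple[float, float]) -> float:
    sub = psth.restrict(window)
    return float((sub.counts.sum(axis=1) > 0).mean())


def contrast_profile(psth: PSTHMatrix, stim: ChirpStimulus) -> ContrastProfile:
    """Per-cycle contrast-response pairs from the contrast chirp.

    One amplitude per 0.5 s carrier cycle, normalised to the max-min
    amplitude in the 0.5 s before chirp onset; contrast is the stimulus
    envelope at the cycle midpoint. A zero normaliser flags the unit for
    exclusion from fitting.
    """
    edges = stim.contrast_cycle_edges()
    amps = _cycle_amplitudes(psth, edges)
    a = stim.segments["contrast_chirp"][0]
    norm = _cycle_amplitudes(psth, np.array([a - 0.5, a]))[0]
    mids = 0.5 * (edges[:-1] + edges[1:])
    contrast = stim.contrast_envelope(mids)
    flagged = norm <= 0
    amplitude = amps / norm if not flagged else np.full_like(amps, np.nan)
    frac = _segment_activity(psth, stim.segments["contrast_chirp"])
    return ContrastProfile(
        contrast=contrast, amplitude=amplitude, frac_active_bins=frac, flagged=flagged
    )


def temporal_profile(psth: PSTHMatrix, stim: ChirpStimulus) -> TemporalProfile:
    """Per-frequency-band response amplitudes from the temporal chirp.

    Cycle boundaries are solved from the analytic chirp phase; per-cycle
    max-min amplitudes are grouped by the integer frequency band
    ([1,2), ..., [7,8] Hz) of each cycle's mean instantaneous frequency and
    averaged within bands.
    """
    edges = stim.temporal_cycle_edges()
    amps = _cycle_amplitudes(psth, edges)
    mids = 0.5 * (edges[:-1] + edges[1:])
    f_mid = stim.temporal_instantaneous_frequency(mids)
    bands = np.clip(np.floor(f_mid).astype(int), 1, 7)
    freq = np.empty(0)
    amp = np.empty(0)
    fs, as_ = [], []
    for band in range(1, 8):
        m = bands == band
        if not np.any(m):
            continue
        fs.append(float(f_mid[m].mean()))
        as_.append(float(amps[m].mean()))
    freq, amp = np.array(fs), np.array(as_)
    frac = _segment_activity(psth, stim.segments["temporal_chirp"])
    flagged = bool(amp.max() <= 0) if amp.size else True
    return TemporalProfile(
        frequency=freq, amplitude=amp, frac_active_bins=frac, flagged=flagged
    )


# ---------------------------------------------------------------------------
# fits


def _multistart_fit(model, x, y, lo, hi, p0_center, n_restarts, seed, tie_param=None):
    """Bounded least squares from seeded restarts; best SSE kept, near-ties
    (within 0.1% relative) broken toward the lower value of ``tie_param``."""
    rng = np.random.default_rng(seed)
    best, best_sse = None, np.inf
    for k in range(n_restarts):
        p0 = p0_center if k == 0 else [rng.uniform(l, h) for l, h in zip(lo, hi)]
        p0 = np.clip(p0, lo, hi)
        try:
            popt, _ = optimize.curve_fit(
                model, x, y, p0=p0, bounds=(lo, hi), maxfev=20_000
            )
        except RuntimeError:
            continue
        sse = float(np.sum((y - model(x, *popt)) ** 2))
        if best is None or sse < best_sse * (1 - 1e-3):
            best, best_sse = popt, sse
        elif (
            tie_param is not None
            and sse <= best_sse * (1 + 1e-3)
            and popt[tie_param] < best[tie_param]
        ):
            best, best_sse = popt, min(sse, best_sse)
    return best, best_sse


def bootstrap_tuning_ci(
    trials,
    stim,
    which: str = "contrast",
    n_boot: int = 100,
    ci: float = 0.95,
    seed: int = 0,
    n_restarts: int = 2,
) -> tuple[float, float]:
    """Percentile bootstrap CI over trials for C50 (``which='contrast'``)
    or peak TF (``which='temporal'``).

    Trials are resampled with replacement, the profile and fit recomputed
    per replicate; replicates whose fit fails are skipped. Fewer restarts
    than the point fit keep the bootstrap affordable.
    """
    from .preprocess import bin_psth

    rng = np.random.default_rng(seed)
    n = len(trials)
    stats = []
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        psth = bin_psth([trials[i] for i in idx], 0.025, (0.0, stim.total_duration_s))
        if which == "contrast":
            fit = fit_naka_rushton(
                contrast_profile(psth, stim), n_restarts=n_restarts, seed=b
            )
            val = fit.c50
        elif which == "temporal":
            fit = fit_half_gaussian(
                temporal_profile(psth, stim), n_restarts=n_restarts, seed=b
            )
            val = fit.peak_tf
        else:
            raise ValueError(f"unknown profile kind {which!r}")
        if np.isfinite(val):
            stats.append(val)
    if len(stats) < max(10, n_boot // 4):
        raise RuntimeError("too few successful bootstrap replicates")
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def fit_naka_rushton(
    profile: ContrastProfile, n_restarts: int = 5, seed: int = 0
) -> NakaRushtonFit:
    """Bounded least-squares Naka-Rushton fit of a contrast profile.

    C50 constrained to (0, 1], slope to (0, 10]. Inclusion requires
    r2 > 0.5 and spiking in more than 10% of the segment's 25 ms bins.
    """
    if profile.flagged or not np.all(np.isfinite(profile.amplitude)):
        return NakaRushtonFit(np.nan, np.nan, np.nan, np.nan, np.nan, False)
    x, y = profile.contrast, profile.amplitude
    if x.size < 6:
        raise ValueError("need at least 6 contrast points")
    lo = [0.0, 0.0, 1e-3, 1e-3]
    hi = [float(y.max()) * 2 + 1e-6, float(y.max()) + 1e-6, 10.0, 1.0]
    p0 = [float(y.max()), float(y.min()), 3.0, 0.5]
    best, best_sse = _multistart_fit(
        naka_rushton, x, y, lo, hi, p0, n_restarts, seed, tie_param=3
    )
    if best is None:
        return NakaRushtonFit(np.nan, np.nan, np.nan, np.nan, np.nan, False)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - best_sse / sst if sst > 0 else 0.0
    top, bottom, slope, c50 = (float(v) for v in best)
    included = bool(
        r2 > R2_INCLUSION and profile.frac_active_bins > MIN_ACTIVE_BIN_FRACTION
    )
    return NakaRushtonFit(top, bottom, slope, c50, float(r2), included)


def fit_half_gaussian(
    profile: TemporalProfile, n_restarts: int = 5, seed: int = 0
) -> HalfGaussianFit:
    """Bounded least-squares half-Gaussian fit of a temporal profile.

    Peak temporal frequency constrained to [1, 8] Hz. Inclusion requires
    r2 > 0.5, spiking in more than 10% of the segment's bins, and a
    Gaussian spread above 0.51 octaves (narrower peaks rest on fewer than
    three profile points).
    """
    if profile.flagged or not np.all(np.isfinite(profile.amplitude)):
        return HalfGaussianFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, False)
    x, y = profile.frequency, profile.amplitude
    if x.size < 5:
        raise ValueError("need at least 5 frequency points")
    ymax = float(y.max())

    # fit with baselines as fractions of the peak amplitude so the curve is a
    # genuine peak (baselines can otherwise exceed peak_amp and turn "peak_tf"
    # into an inflection of a descending profile)
    def model(f, bl_frac, bh_frac, spread, peak_amp, peak_tf):
        return half_gaussian(f, bl_frac * peak_amp, bh_frac * peak_amp,
                             spread, peak_amp, peak_tf)

    lo = [0.0, 0.0, 0.05, 0.0, 1.0]
    hi = [1.0, 1.0, 5.0, 2 * ymax + 1e-6, 8.0]
    p0 = [
        min(float(y[0]) / ymax, 1.0) if ymax > 0 else 0.5,
        min(float(y[-1]) / ymax, 1.0) if ymax > 0 else 0.5,
        1.0,
        ymax,
        float(x[np.argmax(y)]),
    ]
    best, best_sse = _multistart_fit(model, x, y, lo, hi, p0, n_restarts, seed,
                                     tie_param=4)
    if best is None:
        return HalfGaussianFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, False)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - best_sse / sst if sst > 0 else 0.0
    bl_frac, bh_frac, spread, peak_amp, peak_tf = (float(v) for v in best)
    lo_b, hi_b = bl_frac * peak_amp, bh_frac * peak_amp
    included = bool(
        r2 > R2_INCLUSION
        and profile.frac_active_bins > MIN_ACTIVE_BIN_FRACTION
        and spread > SPREAD_INCLUSION
    )
    return HalfGaussianFit(lo_b, hi_b, spread, peak_amp, peak_tf, float(r2), included)
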