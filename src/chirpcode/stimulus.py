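"""Full-field chirp stimulus construction.

The chirp is a 30 s luminance sequence used to probe polarity, kinetics,
temporal-frequency tuning and contrast sensitivity of visually responsive
units in a single sweep:

* 3 s step from dark to 100% intensity,
* 2 s dark, 2 s at 50% intensity,
* 8 s temporal chirp — full-contrast sinusoid accelerating from 1 to 8 Hz,
* 2 s at 50%,
* 8 s contrast chirp — 2 Hz sinusoid whose Michelson contrast ramps from
  3% to 97%,
* 2 s at 50%, 3 s dark.

Intensity is kept normalised to [0, 1]; absolute irradiance (log10
photons/cm^2/s at 100% intensity) travels as metadata so the same waveform
can be replayed across an irradiance ladder.

Conventions: time is in seconds, 0-based at stimulus onset; all segment
intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "ChirpStimulus",
    "SEGMENT_ORDER",
    "build_chirp",
    "irradiance_ladder",
    "write_stimulus",
]

#: Segment names and durations (s), in presentation order.
SEGMENT_DURATIONS: tuple[tuple[str, float], ...] = (
    ("step", 3.0),
    ("dark1", 2.0),
    ("plateau1", 2.0),
    ("temporal_chirp", 8.0),
    ("plateau2", 2.0),
    ("contrast_chirp", 8.0),
    ("plateau3", 2.0),
    ("dark2", 3.0),
)

SEGMENT_ORDER: tuple[str, ...] = tuple(name for name, _ in SEGMENT_DURATIONS)

TOTAL_DURATION_S = float(sum(d for _, d in SEGMENT_DURATIONS))

# Temporal chirp sweeps 1 -> 8 Hz linearly over its 8 s; contrast chirp is a
# fixed 2 Hz carrier whose Michelson contrast ramps linearly 0.03 -> 0.97.
TEMPORAL_F0_HZ = 1.0
TEMPORAL_F1_HZ = 8.0
CONTRAST_CARRIER_HZ = 2.0
CONTRAST_MIN = 0.03
CONTRAST_MAX = 0.97

MIN_SAMPLE_RATE = 200.0  # resolves the 8 Hz top frequency with >=25 samples/cycle


@dataclass(frozen=True)
class ChirpStimulus:
    """A sampled chirp waveform plus its segment map and irradiance tag."""

    sample_rate: float
    waveform: np.ndarray
    segments: dict[str, tuple[float, float]]
    irradiance_log: float
    total_duration_s: float = TOTAL_DURATION_S

    @property
    def times(self) -> np.ndarray:
        """Sample times (s), 0-based at stimulus onset."""
        return np.arange(self.waveform.size) / self.sample_rate

    def segment_slice(self, name: str) -> slice:
        """Index slice of ``waveform`` covering segment ``name`` (half-open)."""
        start, end = self.segments[name]
        i0 = int(round(start * self.sample_rate))
        i1 = int(round(end * self.sample_rate))
        return slice(i0, i1)

    def temporal_instantaneous_frequency(self, t: np.ndarray | float) -> np.ndarray:
        """Instantaneous frequency (Hz) of the temporal chirp at absolute time t."""
        start, end = self.segments["temporal_chirp"]
        tl = np.asarray(t, dtype=float) - start
        slope = (TEMPORAL_F1_HZ - TEMPORAL_F0_HZ) / (end - start)
        return TEMPORAL_F0_HZ + slope * tl

    def temporal_phase_cycles(self, t: np.ndarray | float) -> np.ndarray:
        """Accumulated cycles of the temporal chirp since its start."""
        start, end = self.segments["temporal_chirp"]
        tl = np.asarray(t, dtype=float) - start
        slope = (TEMPORAL_F1_HZ - TEMPORAL_F0_HZ) / (end - start)
        return TEMPORAL_F0_HZ * tl + 0.5 * slope * tl**2

    def temporal_cycle_edges(self) -> np.ndarray:
        """Absolute times (s) of integer-cycle boundaries of the temporal chirp.

        Solved analytically from the quadratic phase, so boundaries are
        independent of the sample rate.
        """
        start, end = self.segments["temporal_chirp"]
        slope = (TEMPORAL_F1_HZ - TEMPORAL_F0_HZ) / (end - start)
        n_cycles = TEMPORAL_F0_HZ * (end - start) + 0.5 * slope * (end - start) ** 2
        k = np.arange(int(round(n_cycles)) + 1, dtype=float)
        # solve f0*t + slope/2 t^2 = k for t >= 0
        tl = (-TEMPORAL_F0_HZ + np.sqrt(TEMPORAL_F0_HZ**2 + 2.0 * slope * k)) / slope
        return start + tl

    def contrast_envelope(self, t: np.ndarray | float) -> np.ndarray:
        """Michelson contrast of the contrast chirp at absolute time t."""
        start, end = self.segments["contrast_chirp"]
        tl = np.asarray(t, dtype=float) - start
        return CONTRAST_MIN + (CONTRAST_MAX - CONTRAST_MIN) * tl / (end - start)

    def contrast_cycle_edges(self) -> np.ndarray:
        """Absolute times of the 0.5 s carrier-cycle boundaries of the contrast chirp."""
        start, end = self.segments["contrast_chirp"]
        period = 1.0 / CONTRAST_CARRIER_HZ
        return np.arange(start, end + 0.5 * period / 8, period)


def _segment_bounds() -> dict[str, tuple[float, float]]:
    bounds: dict[str, tuple[float, float]] = {}
    t = 0.0
    for name, dur in SEGMENT_DURATIONS:
        bounds[name] = (t, t + dur)
        t += dur
    return bounds


def build_chirp(sample_rate: float, irradiance_log: float) -> ChirpStimulus:
    """Construct the 30 s chirp stimulus sampled at ``sample_rate``.

    Parameters
    ----------
    sample_rate
        Samples per second; must be >= 200 so the 8 Hz top frequency is
        resolved with at least 25 samples per cycle.
    irradiance_log
        log10 photons/cm^2/s corresponding to 100% intensity. Metadata only;
        the waveform itself stays in [0, 1].
    """
    if sample_rate < MIN_SAMPLE_RATE:
        raise ValueError(
            f"sample_rate must be >= {MIN_SAMPLE_RATE} samples/s, got {sample_rate}"
        )
    segments = _segment_bounds()
    n = int(round(TOTAL_DURATION_S * sample_rate))
    t = np.arange(n) / sample_rate
    w = np.zeros(n)

    def seg_mask(name: str) -> np.ndarray:
        a, b = segments[name]
        return (t >= a) & (t < b)

    w[seg_mask("step")] = 1.0
    for name in ("plateau1", "plateau2", "plateau3"):
        w[seg_mask(name)] = 0.5
    # dark segments stay at 0

    # temporal chirp: 0.5 + 0.5*sin(2*pi*phase), phase from the linear sweep
    m = seg_mask("temporal_chirp")
    a, b = segments["temporal_chirp"]
    tl = t[m] - a
    slope = (TEMPORAL_F1_HZ - TEMPORAL_F0_HZ) / (b - a)
    phase = TEMPORAL_F0_HZ * tl + 0.5 * slope * tl**2
    w[m] = 0.5 + 0.5 * np.sin(2.0 * np.pi * phase)

    # contrast chirp: 2 Hz carrier, linearly ramping Michelson contrast
    m = seg_mask("contrast_chirp")
    a, b = segments["contrast_chirp"]
    tl = t[m] - a
    contrast = CONTRAST_MIN + (CONTRAST_MAX - CONTRAST_MIN) * tl / (b - a)
    w[m] = 0.5 + 0.5 * contrast * np.sin(2.0 * np.pi * CONTRAST_CARRIER_HZ * tl)

    return ChirpStimulus(
        sample_rate=float(sample_rate),
        waveform=w,
        segments=segments,
        irradiance_log=float(irradiance_log),
    )


def irradiance_ladder(
    min_log: float, max_log: float, step_log: float = 1.0
) -> list[float]:
    """Ascending irradiance series from ``min_log`` to ``max_log`` in
    ``step_log``-decade steps, with the last value capped at ``max_log``.

    Mirrors the presentation order of the recordings: stimuli run from the
    dimmest to the brightest intensity.
    """
    if step_log <= 0:
        raise ValueError(f"step_log must be positive, got {step_log}")
    if not min_log < max_log:
        raise ValueError(
            f"min_log must be strictly below max_log, got {min_log} >= {max_log}"
        )
    vals = list(np.arange(min_log, max_log, step_log))
    if not np.isclose(vals[-1], max_log):
        vals.append(max_log)
    else:  # floating-point landed on max already
        vals[-1] = max_log
    return [float(v) for v in vals]


def write_stimulus(stim: ChirpStimulus, csv_path: str | Path) -> None:
    """Write the waveform as a two-column CSV (time_s, relative_intensity)
    with a JSON sidecar carrying segments and irradiance."""
    csv_path = Path(csv_path)
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time_s", "relative_intensity"])
        for ti, wi in zip(stim.times, stim.waveform):
            writer.writerow([f"{ti:.6f}", f"{wi:.6f}"])
    sidecar = {
        "sample_rate": stim.sample_rate,
        "irradiance_log": stim.irradiance_log,
        "total_duration_s": stim.total_duration_s,
        "segments": {k: list(v) for k, v in stim.segments.items()},
    }
    csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
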