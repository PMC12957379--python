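"""Triggered droplet generation, detector-trace analysis and lock-in metrics.

The droplet generator behaves as a free-running relaxation oscillator near
the 10 Hz train rate; an electrical trigger pulse applied at a fixed delay
after each accelerator reference tick can reset the pinch-off phase.  This
module abstracts the electro-hydrodynamic actuation as a *phase-resetting
capture* model: when a trigger of sufficient amplitude arrives while the
oscillator is within a capture window of firing, the droplet pinch-off is
re-timed to the trigger, zeroing the accumulated phase error.  Amplitudes
below the full lock threshold capture only with probability
amplitude/threshold, producing the intermittent lock-in seen at reduced
trigger voltages.  This is a behavioural model, not a physical one.

Diagnostics mirror beamline practice: the droplet-detector voltage trace
is cut into consecutive reference-period windows and stacked into a
"waterfall" matrix (a locked droplet train appears as a vertical stripe),
per-window droplet phases are summarised with circular statistics, and
rows can be annotated with the crystal-hit record of each pulse train.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

#: period of the accelerator reference (10 Hz trains), seconds
REFERENCE_PERIOD = 0.1


@dataclass(frozen=True)
class OscillatorConfig:
    """Free-running droplet generator.

    ``natural_frequency`` (Hz) is the untriggered droplet rate;
    ``period_jitter_sd`` (s) the Gaussian jitter of each inter-droplet
    period; ``phase0`` (s) the time of the notional zeroth firing; and
    ``drift_rate`` a slow fractional period drift per second of run time.
    """

    natural_frequency: float = 10.0
    period_jitter_sd: float = 0.0
    phase0: float = 0.0
    drift_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.natural_frequency <= 0:
            raise ValueError("natural frequency must be positive")
        if self.period_jitter_sd < 0:
            raise ValueError("jitter SD must be non-negative")


@dataclass(frozen=True)
class TriggerConfig:
    """Electrical trigger: ``amplitude`` (V) applied ``delay`` s after each
    reference tick for ``duration`` s.  ``lock_threshold`` (V) is the
    amplitude giving deterministic capture; ``capture_width`` (s) how close
    to firing the oscillator must be for the trigger to act."""

    amplitude: float = 180.0
    duration: float = 0.004
    delay: float = 0.030
    lock_threshold: float = 150.0
    capture_width: float = 0.020

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("trigger amplitude must be non-negative")
        if self.duration <= 0:
            raise ValueError("trigger duration must be positive")
        if self.capture_width < 0:
            raise ValueError("capture width must be non-negative")
        if self.lock_threshold <= 0:
            raise ValueError("lock threshold must be positive")


@dataclass(frozen=True)
class DropletEvents:
    """Droplet pinch-off instants (s), strictly increasing in [0, duration]."""

    times: np.ndarray
    duration: float
    reference_period: float = REFERENCE_PERIOD

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.size and (np.any(np.diff(t) <= 0) or t[0] < 0 or t[-1] > self.duration):
            raise ValueError("event times must be strictly increasing within [0, duration]")


@dataclass(frozen=True)
class DetectorTrace:
    """Sampled droplet-detector voltage trace."""

    samples: np.ndarray
    sample_rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", s)
        if self.sample_rate <= 0:
            raise ValueError("sample rate must be positive")
        if s.size and not np.all(np.isfinite(s)):
            raise ValueError("trace samples must be finite")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate


@dataclass(frozen=True)
class WaterfallMatrix:
    """Stack of consecutive reference windows of signal or event counts.

    Row i covers [row_times[i], row_times[i] + window_length); columns are
    time within the window.  ``kind`` records whether cells hold voltage
    samples ("trace") or event counts ("events"); ``hits`` optionally
    flags rows whose pulse train produced crystal hits.
    """

    matrix: np.ndarray
    window_length: float
    row_times: np.ndarray
    kind: str = "trace"
    hits: np.ndarray | None = None

    @property
    def n_windows(self) -> int:
        return self.matrix.shape[0]

    @property
    def bin_width(self) -> float:
        return self.window_length / self.matrix.shape[1]


@dataclass(frozen=True)
class LockInReport:
    """Per-window droplet phases and lock-in summary statistics.

    Phases are seconds within the reference window (NaN where a window had
    no droplet).  ``circular_sd`` is the circular standard deviation of
    all observed phases mapped to the unit circle, expressed in seconds.
    A window counts as locked when the rolling circular SD over the
    trailing ``min_run`` windows is below the threshold used to build the
    report.
    """

    per_window_phase: np.ndarray
    circular_sd: float
    locked_fraction: float
    longest_locked_run: int
    locked: np.ndarray
    window_length: float


@dataclass(frozen=True)
class HitSeries:
    """Crystal hits per pulse train, aligned with waterfall rows."""

    hits_per_train: np.ndarray

    def __post_init__(self) -> None:
        h = np.asarray(self.hits_per_train, dtype=int)
        object.__setattr__(self, "hits_per_train", h)
        if h.size and h.min() < 0:
            raise ValueError("hit counts must be non-negative")


TriggerSchedule = list[tuple[float, float, float]]


def simulate_droplets(osc: OscillatorConfig, trig: TriggerConfig,
                      duration: float, seed: int,
                      reference_period: float = REFERENCE_PERIOD,
                      schedule: TriggerSchedule | None = None) -> DropletEvents:
    """Integrate-and-fire simulation of triggered droplet generation.

    Inter-droplet periods are 1/f₀ with Gaussian jitter and slow drift.
    Each reference tick k emits a trigger at k·T_ref + delay; if the
    oscillator's next firing lies within ``capture_width`` of the trigger
    window and the amplitude suffices (deterministically at or above
    ``lock_threshold``, else with probability amplitude/threshold), the
    firing is reset to the trigger instant.  ``schedule`` optionally
    overrides the amplitude as a list of (t_start, t_end, amplitude)
    segments (amplitude 0 outside all segments).

    Deterministic for a given ``seed``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    base_period = 1.0 / osc.natural_frequency

    def sample_period(t: float) -> float:
        p = base_period * (1.0 + osc.drift_rate * t)
        if osc.period_jitter_sd > 0:
            p += rng.normal(0.0, osc.period_jitter_sd)
        return max(p, 1e-6)

    def amplitude_at(t: float) -> float:
        if schedule is None:
            return trig.amplitude
        for t_start, t_end, amp in schedule:
            if t_start <= t < t_end:
                return amp
        return 0.0

    events: list[float] = []
    t_next = osc.phase0 + sample_period(0.0)
    k = 0
    n_triggers = int(math.floor(duration / reference_period)) + 1

    while t_next <= duration or k < n_triggers:
        tau = k * reference_period + trig.delay if k < n_triggers else math.inf
        if t_next < tau - trig.capture_width:
            # oscillator fires freely well before the next trigger
            if t_next > duration:
                break
            events.append(t_next)
            t_next += sample_period(t_next)
            continue
        if tau > duration or math.isinf(tau):
            if t_next <= duration:
                events.append(t_next)
                t_next += sample_period(t_next)
                continue
            break
        if t_next <= tau + trig.duration + trig.capture_width:
            amp = amplitude_at(tau)
            if amp >= trig.lock_threshold:
                captured = True
            elif amp > 0:
                captured = rng.random() < amp / trig.lock_threshold
            else:
                captured = False
            if captured:
                if tau <= duration and (not events or tau > events[-1]):
                    events.append(tau)
                t_next = tau + sample_period(tau)
            k += 1
        else:
            # firing is far beyond this trigger window; trigger is lost
            k += 1

    return DropletEvents(times=np.array(events), duration=duration,
                         reference_period=reference_period)


def synth_trace(events: DropletEvents, pulse_width: float = 0.002,
                pulse_amplitude: float = 1.0, noise_sd: float = 0.0,
                sample_rate: float = 10_000.0, seed: int = 0) -> DetectorTrace:
    """Synthetic detector trace: one rectangular pulse per droplet + noise."""
    if sample_rate * pulse_width < 4:
        raise ValueError("pulse must cover at least 4 samples")
    n = int(round(events.duration * sample_rate))
    samples = np.zeros(n)
    width_n = int(round(pulse_width * sample_rate))
    for t in events.times:
        i0 = int(round(t * sample_rate))
        samples[i0:i0 + width_n] = pulse_amplitude
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        samples = samples + rng.normal(0.0, noise_sd, size=n)
    return DetectorTrace(samples=samples, sample_rate=sample_rate)


def detect_events(trace: DetectorTrace, threshold: float,
                  holdoff: float = 0.002) -> DropletEvents:
    """Rising-edge threshold detection with a refractory hold-off.

    An event is recorded at each upward crossing of ``threshold``;
    crossings within ``holdoff`` seconds of the previous event are
    ignored (one droplet, one event).
    """
    s = trace.samples
    if s.size == 0:
        return DropletEvents(times=np.array([]), duration=0.0)
    above = s >= threshold
    rising = np.flatnonzero(above & ~np.concatenate(([False], above[:-1])))
    holdoff_n = int(round(holdoff * trace.sample_rate))
    kept: list[int] = []
    last = -10 * holdoff_n - 10
    for i in rising:
        if i - last > holdoff_n:
            kept.append(i)
            last = i
    times = trace.t0 + np.asarray(kept, dtype=float) / trace.sample_rate
    return DropletEvents(times=times, duration=trace.t0 + trace.duration)


def fold_waterfall(data: DetectorTrace | DropletEvents,
                   window_length: float = REFERENCE_PERIOD,
                   n_bins: int = 1000) -> WaterfallMatrix:
    """Fold a trace or event list into reference-period windows.

    For a trace, the window must hold an integer number of samples and the
    columns are the raw voltage samples; for events, columns are event
    counts in ``n_bins`` uniform phase bins.  Only whole windows are kept;
    every event (or sample) inside them is preserved.
    """
    if window_length <= 0:
        raise ValueError("window length must be positive")
    if isinstance(data, DetectorTrace):
        cols_f = window_length * data.sample_rate
        cols = int(round(cols_f))
        if cols < 1 or abs(cols_f - cols) > 1e-6:
            raise ValueError("window length must be an integer number of samples")
        rows = data.samples.size // cols
        if rows < 1:
            raise ValueError("trace shorter than one window")
        matrix = data.samples[: rows * cols].reshape(rows, cols).copy()
        row_times = data.t0 + np.arange(rows) * window_length
        return WaterfallMatrix(matrix=matrix, window_length=window_length,
                               row_times=row_times, kind="trace")
    rows = int(math.floor(data.duration / window_length + 1e-9))
    if rows < 1:
        raise ValueError("event record shorter than one window")
    matrix = np.zeros((rows, n_bins))
    for t in data.times:
        r = int(t / window_length)
        if r >= rows:
            continue
        c = int((t - r * window_length) / window_length * n_bins + 1e-9)
        matrix[r, min(c, n_bins - 1)] += 1
    row_times = np.arange(rows) * window_length
    return WaterfallMatrix(matrix=matrix, window_length=window_length,
                           row_times=row_times, kind="events")


def window_phases(events: DropletEvents,
                  window_length: float = REFERENCE_PERIOD) -> np.ndarray:
    """First-droplet phase per reference window (NaN where empty)."""
    n_windows = int(math.floor(events.duration / window_length + 1e-9))
    phases = np.full(n_windows, np.nan)
    idx = np.searchsorted(events.times, np.arange(n_windows) * window_length,
                          side="left")
    for w in range(n_windows):
        i = idx[w]
        if i < events.times.size and events.times[i] < (w + 1) * window_length:
            phases[w] = events.times[i] - w * window_length
    return phases


def circular_sd_seconds(phases: np.ndarray, window_length: float) -> float:
    """Circular standard deviation of phases (s) on the window circle.

    Phases map to angles 2π·phase/window; SD = sqrt(−2 ln R) where R is
    the mean resultant length, converted back to seconds.
    """
    valid = phases[np.isfinite(phases)]
    if valid.size < 2:
        return float("nan")
    theta = 2.0 * np.pi * valid / window_length
    r = abs(np.mean(np.exp(1j * theta)))
    r = min(r, 1.0)
    if r == 0:
        return float("inf")
    return abs(math.sqrt(max(-2.0 * math.log(r), 0.0))) * window_length / (2.0 * np.pi)


def lock_in_report(events: DropletEvents,
                   window_length: float = REFERENCE_PERIOD,
                   locked_sd_threshold: float = 0.001,
                   min_run: int = 5) -> LockInReport:
    """Summarise droplet phase stability against the reference clock.

    A window is locked when the rolling circular SD of the trailing
    ``min_run`` window phases (all of which must contain a droplet) is
    below ``locked_sd_threshold``.  The locked fraction is taken over all
    windows where the rolling statistic is defined.
    """
    phases = window_phases(events, window_length)
    n = phases.size
    if n < 2:
        raise ValueError("need at least two reference windows")
    sd_all = circular_sd_seconds(phases, window_length)

    locked = np.zeros(n, dtype=bool)
    defined = np.zeros(n, dtype=bool)
    for w in range(min_run - 1, n):
        block = phases[w - min_run + 1: w + 1]
        if np.all(np.isfinite(block)):
            defined[w] = True
            locked[w] = circular_sd_seconds(block, window_length) < locked_sd_threshold

    n_defined = int(defined.sum())
    locked_fraction = float(locked[defined].mean()) if n_defined else 0.0

    longest = run = 0
    for w in range(n):
        run = run + 1 if locked[w] else 0
        longest = max(longest, run)

    return LockInReport(per_window_phase=phases, circular_sd=sd_all,
                        locked_fraction=locked_fraction,
                        longest_locked_run=longest, locked=locked,
                        window_length=window_length)


def annotate_hits(waterfall: WaterfallMatrix, hits: HitSeries) -> WaterfallMatrix:
    """Attach per-train hit flags to a waterfall matrix."""
    if hits.hits_per_train.size != waterfall.n_windows:
        raise ValueError(
            f"hit series length {hits.hits_per_train.size} does not match "
            f"{waterfall.n_windows} waterfall rows"
        )
    return replace(waterfall, hits=hits.hits_per_train.copy())


def hit_rate(n_patterns: int, n_trains: int, pulses_per_train: int) -> float:
    """Fraction of X-ray pulses that produced a diffraction pattern."""
    if n_trains <= 0 or pulses_per_train <= 0:
        raise ValueError("train and pulse counts must be positive")
    if n_patterns < 0:
        raise ValueError("pattern count must be non-negative")
    return n_patterns / (n_trains * pulses_per_train)


def plot_waterfall(waterfall: WaterfallMatrix, path, title: str | None = None):
    """Render a waterfall plot (grayscale, hits as green row markers)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    extent = (0.0, waterfall.window_length * 1e3,
              waterfall.row_times[-1] + waterfall.window_length,
              waterfall.row_times[0])
    ax.imshow(waterfall.matrix, aspect="auto", cmap="gray_r",
              extent=extent, interpolation="nearest")
    if waterfall.hits is not None:
        hit_rows = np.flatnonzero(waterfall.hits > 0)
        if hit_rows.size:
            y = waterfall.row_times[hit_rows] + waterfall.window_length / 2
            ax.scatter(np.full(hit_rows.size, -waterfall.window_length * 20),
                       y, marker=">", color="green", clip_on=False, s=30)
    ax.set_xlabel("time within reference window (ms)")
    ax.set_ylabel("acquisition time (s)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
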