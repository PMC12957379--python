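"""Synthetic scenario generators for testing and demonstration.

Every input the rest of the package consumes can be generated here
deterministically from a (scenario, seed) pair: droplet event trains in
the qualitative regimes seen at the beamline (locked, free-running,
intermittently locked, and the amplitude-ladder trigger sequence), the
matching synthetic detector traces and hit records, and a closed-form
plug-flow mixing field used as an independent oracle for the marching
solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import sync
from .mixing import MixingField, closed_form_plug_field
from .sync import (DropletEvents, HitSeries, OscillatorConfig, TriggerConfig,
                   simulate_droplets, synth_trace, window_phases)

SCENARIOS = ("locked_train", "free_running", "intermittent",
             "amplitude_ladder", "mixing_closed_form")

#: oil / buffer flows (µL/min) used in the droplet-only synchronisation
#: tests; carried as metadata so bundles document their nominal conditions.
SYNC_TEST_FLOWS = {"q_o_ul_min": 18.5, "q_b_ul_min": 1.0}

#: trigger amplitudes (V) of the start-up ladder: full lock, trigger off,
#: insufficient, intermittent, full lock again.
LADDER_AMPLITUDES = (180.0, 0.0, 40.0, 110.0, 180.0)


@dataclass(frozen=True)
class FixtureSpec:
    """A named scenario with a seed and optional parameter overrides."""

    scenario: str
    seed: int = 0
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(
                f"unknown scenario {self.scenario!r}; known: {SCENARIOS}")


def _sync_bundle(spec: FixtureSpec, osc: OscillatorConfig,
                 trig: TriggerConfig, duration: float,
                 schedule: sync.TriggerSchedule | None = None,
                 with_trace: bool = True) -> dict:
    p = spec.parameters
    events = simulate_droplets(osc, trig, duration, seed=spec.seed,
                               schedule=schedule)
    bundle = {
        "scenario": spec.scenario,
        "seed": spec.seed,
        "events": events,
        "oscillator": osc,
        "trigger": trig,
        "schedule": schedule,
        "flows": dict(SYNC_TEST_FLOWS),
    }
    if p.get("with_trace", with_trace):
        bundle["trace"] = synth_trace(
            events,
            pulse_width=p.get("pulse_width", 0.002),
            pulse_amplitude=p.get("pulse_amplitude", 1.0),
            noise_sd=p.get("noise_sd", 0.0),
            sample_rate=p.get("sample_rate", 10_000.0),
            seed=spec.seed + 1,
        )
    return bundle


def make_scenario(spec: FixtureSpec) -> dict:
    """Build the deterministic data bundle for a scenario.

    Synchronisation scenarios return a dict with ``events`` (and usually
    ``trace``); ``mixing_closed_form`` returns a dict with a ``field``
    holding the analytic plug-flow erfc concentration field.
    """
    p = spec.parameters
    if spec.scenario == "locked_train":
        osc = OscillatorConfig(natural_frequency=p.get("f0", 10.0),
                               period_jitter_sd=p.get("jitter_sd", 0.0),
                               phase0=p.get("phase0", 0.025))
        trig = TriggerConfig(amplitude=p.get("amplitude", 180.0))
        return _sync_bundle(spec, osc, trig, p.get("duration", 20.0))

    if spec.scenario == "free_running":
        osc = OscillatorConfig(natural_frequency=p.get("f0", 10.2),
                               period_jitter_sd=p.get("jitter_sd", 0.0),
                               phase0=p.get("phase0", 0.05))
        trig = TriggerConfig(amplitude=0.0)
        return _sync_bundle(spec, osc, trig, p.get("duration", 20.0))

    if spec.scenario == "intermittent":
        osc = OscillatorConfig(natural_frequency=p.get("f0", 10.15),
                               period_jitter_sd=p.get("jitter_sd", 0.002),
                               phase0=p.get("phase0", 0.025))
        trig = TriggerConfig(amplitude=p.get("amplitude", 110.0))
        return _sync_bundle(spec, osc, trig, p.get("duration", 60.0))

    if spec.scenario == "amplitude_ladder":
        seg = p.get("segment_duration", 60.0)
        amplitudes = p.get("amplitudes", LADDER_AMPLITUDES)
        schedule = [(i * seg, (i + 1) * seg, a)
                    for i, a in enumerate(amplitudes)]
        duration = seg * len(amplitudes)
        osc = OscillatorConfig(natural_frequency=p.get("f0", 10.15),
                               period_jitter_sd=p.get("jitter_sd", 0.002),
                               phase0=p.get("phase0", 0.025))
        trig = TriggerConfig(amplitude=amplitudes[0])
        bundle = _sync_bundle(spec, osc, trig, duration, schedule=schedule,
                              with_trace=False)
        bundle["segments"] = schedule
        return bundle

    if spec.scenario == "mixing_closed_form":
        w = p.get("w", 150.0)
        v_mean = p.get("v_mean", 666.6667)
        d_um2_s = p.get("d_um2_s", 120.0)
        c0 = p.get("c0", 300.0)
        interface_y = p.get("interface_y", w / 2.0)
        nx = p.get("nx", 256)
        ny = p.get("ny", 257)
        x_max = p.get("x_max", 528.0)
        x = np.linspace(0.0, x_max, nx + 1)
        y = np.linspace(0.0, w, ny)
        c = closed_form_plug_field(v_mean, w, d_um2_s, c0, interface_y, x, y)
        field_ = MixingField(x=x, y=y, c=c, c0=c0, interface_y=interface_y,
                             v_mean=v_mean, w=w, d_um2_s=d_um2_s,
                             profile="plug")
        return {"scenario": spec.scenario, "seed": spec.seed, "field": field_}

    raise ValueError(f"unknown scenario {spec.scenario!r}")


def make_hits(events: DropletEvents, base_hit_prob: float, seed: int,
              window_length: float = sync.REFERENCE_PERIOD,
              trigger_phase: float = 0.030,
              phase_tolerance: float = 0.002) -> HitSeries:
    """Simulated crystal hits per pulse train.

    A train can only hit when its droplet actually overlaps the pulses,
    i.e. when the first droplet phase of the window is within
    ``phase_tolerance`` of the trigger phase; such windows hit with
    probability ``base_hit_prob``.
    """
    if not 0.0 <= base_hit_prob <= 1.0:
        raise ValueError("hit probability must be in [0, 1]")
    rng = np.random.default_rng(seed)
    phases = window_phases(events, window_length)
    counts = np.zeros(phases.size, dtype=int)
    aligned = np.isfinite(phases) & (np.abs(phases - trigger_phase) <= phase_tolerance)
    if base_hit_prob > 0:
        counts[aligned] = rng.random(int(aligned.sum())) < base_hit_prob
    return HitSeries(hits_per_train=counts)
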