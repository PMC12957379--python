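"""XFEL pulse-train timing, jet geometry and droplet-volume criteria.

The European XFEL delivers bursts ("trains") of MHz-spaced X-ray pulses at
a 10 Hz train repetition rate.  Segmented-droplet injection aims to place
one crystal-laden droplet in the interaction region per train; for every
pulse in the train to probe sample, the jetted droplet must span the full
train duration.  Approximating the droplet in the jet as a rod of the jet
radius moving at the jet velocity, the minimum spanning volume is

    V_min = π r_jet² · (v_jet · T_train).

Droplet volumes actually produced follow from flow balance: a generator
running at frequency f with aqueous flow Q_aq makes droplets of volume
Q_aq / f.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class PulseTrainSpec:
    """Pulse-train structure: ``n_pulses`` pulses ``intra_spacing`` µs apart,
    trains repeating at ``train_rate`` Hz. ``photon_energy`` (keV) is
    metadata only."""

    n_pulses: int = 202
    intra_spacing: float = 1.77
    train_rate: float = 10.0
    photon_energy: float | None = None

    def __post_init__(self) -> None:
        if self.n_pulses < 1:
            raise ValueError("a train needs at least one pulse")
        if self.intra_spacing <= 0 or self.train_rate <= 0:
            raise ValueError("spacing and repetition rate must be positive")
        if self.n_pulses * self.intra_spacing >= 1e6 / self.train_rate:
            raise ValueError("train duration must be shorter than the train period")


@dataclass(frozen=True)
class JetSpec:
    """GDVN jet: velocity in m/s, radius in µm."""

    jet_velocity: float = 25.0
    jet_radius: float = 5.0

    def __post_init__(self) -> None:
        if self.jet_velocity <= 0 or self.jet_radius <= 0:
            raise ValueError("jet velocity and radius must be positive")


@dataclass(frozen=True)
class DropletSpec:
    """A generated droplet: volume in nL at repetition ``frequency`` Hz."""

    volume: float
    frequency: float

    def __post_init__(self) -> None:
        if self.volume <= 0 or self.frequency <= 0:
            raise ValueError("droplet volume and frequency must be positive")


#: the pulse-train structure used in the reference TR-SFX experiments
EUXFEL_TRAIN = PulseTrainSpec(n_pulses=202, intra_spacing=1.77, train_rate=10.0)


def train_duration(train: PulseTrainSpec) -> float:
    """Train duration in µs, counted as n_pulses x intra-pulse spacing."""
    return train.n_pulses * train.intra_spacing


def rod_length(jet: JetSpec, train: PulseTrainSpec) -> float:
    """Length (µm) of jet travelling past a point during one train."""
    return jet.jet_velocity * train_duration(train)  # m/s x µs == µm


def min_spanning_volume(jet: JetSpec, train: PulseTrainSpec) -> float:
    """Minimum droplet volume (pL) that spans a whole pulse train.

    Rod-shaped droplet of the jet radius: V = π r² v T.  1 pL = 10³ µm³.
    """
    volume_um3 = math.pi * jet.jet_radius**2 * rod_length(jet, train)
    return volume_um3 / 1e3


def droplet_volume_from_flow(q_aq: float, frequency: float) -> float:
    """Droplet volume (nL) from flow balance: Q_aq (µL/min) at f (Hz)."""
    if frequency <= 0:
        raise ValueError("droplet frequency must be positive")
    if q_aq < 0:
        raise ValueError("aqueous flow must be non-negative")
    return q_aq / 60.0 / frequency * 1e3  # µL/min → nL per droplet


def spans_train(volume: float, jet: JetSpec,
                train: PulseTrainSpec) -> tuple[bool, float]:
    """Whether a droplet of ``volume`` nL spans the train; margin = V/V_min."""
    if volume <= 0:
        raise ValueError("droplet volume must be positive")
    v_min_pl = min_spanning_volume(jet, train)
    margin = volume * 1e3 / v_min_pl
    return margin >= 1.0, margin
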