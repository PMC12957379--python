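"""Mixer/droplet-generator channel geometry and residence-time computation.

A mix-and-inject droplet device is represented as three ordered channel
sections:

* section ``A`` — the Y-mixer channel where the crystal and substrate
  streams first meet; only the combined aqueous flow passes through it;
* section ``B`` — the short channel where the aqueous stream is segmented
  into droplets by the oil phase; the total (aqueous + oil) flow applies;
* section ``C`` — the joining capillary and nozzle path to the gas dynamic
  virtual nozzle (GDVN) orifice; the droplet slug travels at the mean total
  flow velocity.

The mean reaction time point probed by the X-ray pulses is the sum of the
residence times in the three sections, t_R = t_A + t_B + t_C, with each
residence time equal to section length divided by the section mean velocity
Q / area.

Units at the interface: lengths in micrometres, volumetric flows in
microlitres per minute, times in seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import pandas as pd
import yaml

#: µm³/s carried by 1 µL/min
UL_PER_MIN_TO_UM3_PER_S = 1e9 / 60.0

SECTION_LABELS = ("A", "B", "C")

#: flow scope each section must use: the mixer sees only the aqueous
#: streams, droplet-forming and capillary sections see the total flow.
SECTION_FLOW_SCOPE = {"A": "aqueous_only", "B": "total", "C": "total"}


@dataclass(frozen=True)
class CrossSection:
    """Channel cross-section, rectangular (width x height) or circular.

    All dimensions are in micrometres.
    """

    shape: str
    width: float | None = None
    height: float | None = None
    diameter: float | None = None

    def __post_init__(self) -> None:
        if self.shape == "rectangular":
            if self.width is None or self.height is None:
                raise ValueError("rectangular cross-section needs width and height")
            if self.width <= 0 or self.height <= 0:
                raise ValueError("cross-section dimensions must be positive")
        elif self.shape == "circular":
            if self.diameter is None:
                raise ValueError("circular cross-section needs a diameter")
            if self.diameter <= 0:
                raise ValueError("cross-section dimensions must be positive")
        else:
            raise ValueError(f"unknown cross-section shape {self.shape!r}")

    @classmethod
    def rectangular(cls, width: float, height: float) -> "CrossSection":
        return cls(shape="rectangular", width=width, height=height)

    @classmethod
    def circular(cls, diameter: float) -> "CrossSection":
        return cls(shape="circular", diameter=diameter)

    @property
    def area(self) -> float:
        """Cross-sectional area in µm²."""
        if self.shape == "rectangular":
            return self.width * self.height
        return math.pi * (self.diameter / 2.0) ** 2


def cross_section_area(cs: CrossSection) -> float:
    """Area of a channel cross-section in µm²."""
    return cs.area


@dataclass(frozen=True)
class ChannelSection:
    """One of the three device sections (label A, B or C), length in µm."""

    label: str
    length: float
    cross_section: CrossSection

    def __post_init__(self) -> None:
        if self.label not in SECTION_LABELS:
            raise ValueError(f"section label must be one of {SECTION_LABELS}")
        if self.length <= 0:
            raise ValueError("section length must be positive")

    @property
    def flow_scope(self) -> str:
        return SECTION_FLOW_SCOPE[self.label]


@dataclass(frozen=True)
class FlowConfig:
    """Volumetric flows in µL/min.

    ``q_x`` is the crystal-suspension stream, ``q_s`` the substrate stream
    and ``q_o`` the segmenting oil stream.  ``q_b`` optionally replaces the
    two aqueous streams with a single buffer stream (synchronisation-only
    runs without crystals or substrate).
    """

    q_x: float = 0.0
    q_s: float = 0.0
    q_o: float = 0.0
    q_b: float | None = None

    def __post_init__(self) -> None:
        for name in ("q_x", "q_s", "q_o"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.q_b is not None and self.q_b < 0:
            raise ValueError("q_b must be non-negative")
        if self.q_total <= 0:
            raise ValueError("total flow must be positive")

    @property
    def q_aq(self) -> float:
        """Combined aqueous flow (µL/min)."""
        if self.q_b is not None:
            return self.q_b
        return self.q_x + self.q_s

    @property
    def q_total(self) -> float:
        """Total flow, aqueous plus oil (µL/min)."""
        return self.q_aq + self.q_o

    def for_scope(self, scope: str) -> float:
        if scope == "aqueous_only":
            return self.q_aq
        if scope == "total":
            return self.q_total
        raise ValueError(f"unknown flow scope {scope!r}")


@dataclass(frozen=True)
class DeviceGeometry:
    """A named device: exactly one channel section per label A, B, C."""

    name: str
    sections: tuple[ChannelSection, ...]

    def __post_init__(self) -> None:
        labels = tuple(s.label for s in self.sections)
        if labels != SECTION_LABELS:
            raise ValueError(
                f"device must have exactly sections {SECTION_LABELS} in order, got {labels}"
            )

    def section(self, label: str) -> ChannelSection:
        for s in self.sections:
            if s.label == label:
                return s
        raise KeyError(label)


@dataclass(frozen=True)
class ResidenceTimeBreakdown:
    """Per-section residence times and their sum t_R, all in seconds."""

    t_a: float
    t_b: float
    t_c: float

    @property
    def t_r(self) -> float:
        return self.t_a + self.t_b + self.t_c

    def rounded(self) -> tuple[float, float, float, float]:
        """Components at 3 decimals, t_R at 1 decimal (reporting precision)."""
        return (round(self.t_a, 3), round(self.t_b, 3), round(self.t_c, 3),
                round(self.t_r, 1))


def mean_velocity(q: float, cs: CrossSection) -> float:
    """Mean velocity (µm/s) for a volumetric flow ``q`` in µL/min."""
    if q <= 0:
        raise ValueError("flow must be positive to compute a velocity")
    return q * UL_PER_MIN_TO_UM3_PER_S / cs.area


def section_residence_time(section: ChannelSection, flows: FlowConfig) -> float:
    """Residence time (s) of the section given the flow configuration."""
    q = flows.for_scope(section.flow_scope)
    if q <= 0:
        raise ValueError(
            f"section {section.label} requires positive {section.flow_scope} flow"
        )
    return section.length / mean_velocity(q, section.cross_section)


def residence_breakdown(device: DeviceGeometry, flows: FlowConfig) -> ResidenceTimeBreakdown:
    """Residence-time decomposition t_A, t_B, t_C (and t_R) for a device."""
    t = {s.label: section_residence_time(s, flows) for s in device.sections}
    return ResidenceTimeBreakdown(t_a=t["A"], t_b=t["B"], t_c=t["C"])


# ---------------------------------------------------------------------------
# presets and config I/O

#: preset file shipped with the package per device name
_PRESET_FILES = {
    "DG250-Y": "dg250_y.yaml",
    "DG300-Y": "dg300_y.yaml",
}

#: flow settings used for the reference time-resolved runs on each device
#: (crystal, substrate, oil streams in µL/min).
REFERENCE_FLOWS = {
    "DG250-Y": FlowConfig(q_x=4.9, q_s=5.0, q_o=18.2),
    "DG300-Y": FlowConfig(q_x=0.5, q_s=0.4, q_o=18.3),
}


def _normalize_name(name: str) -> str:
    key = name.strip().upper().replace("_", "-")
    if key.endswith("-MIXER"):
        key = key[: -len("-MIXER")]
    return key


def cross_section_from_dict(d: dict) -> CrossSection:
    shape = d.get("shape")
    if shape == "rectangular":
        return CrossSection.rectangular(float(d["width_um"]), float(d["height_um"]))
    if shape == "circular":
        return CrossSection.circular(float(d["diameter_um"]))
    raise ValueError(f"unknown cross-section shape {shape!r}")


def device_from_dict(d: dict) -> DeviceGeometry:
    sections = tuple(
        ChannelSection(
            label=str(s["label"]).upper(),
            length=float(s["length_um"]),
            cross_section=cross_section_from_dict(s["cross_section"]),
        )
        for s in d["sections"]
    )
    return DeviceGeometry(name=str(d["name"]), sections=sections)


def flows_from_dict(d: dict) -> FlowConfig:
    return FlowConfig(
        q_x=float(d.get("q_x_ul_min", 0.0)),
        q_s=float(d.get("q_s_ul_min", 0.0)),
        q_o=float(d.get("q_o_ul_min", 0.0)),
        q_b=None if d.get("q_b_ul_min") is None else float(d["q_b_ul_min"]),
    )


def load_device(path) -> DeviceGeometry:
    """Load a device geometry from a YAML config file."""
    with open(path) as fh:
        return device_from_dict(yaml.safe_load(fh))


def load_flows(path) -> FlowConfig:
    """Load a flow configuration from a YAML config file."""
    with open(path) as fh:
        return flows_from_dict(yaml.safe_load(fh))


def preset_device(name: str) -> DeviceGeometry:
    """Return a packaged device preset ('DG250-Y' or 'DG300-Y')."""
    key = _normalize_name(name)
    try:
        fname = _PRESET_FILES[key]
    except KeyError:
        raise KeyError(
            f"unknown device preset {name!r}; available: {sorted(_PRESET_FILES)}"
        ) from None
    text = resources.files("dropmix").joinpath("presets", fname).read_text()
    return device_from_dict(yaml.safe_load(text))


def residence_table(entries: list[tuple[DeviceGeometry, FlowConfig]]) -> pd.DataFrame:
    """Tabulate residence-time breakdowns (one row per device/flow pair).

    Components are reported at 3 decimals and t_R at 1 decimal.
    """
    rows = []
    for device, flows in entries:
        bd = residence_breakdown(device, flows)
        t_a, t_b, t_c, t_r = bd.rounded()
        rows.append(
            {"device": device.name, "t_A (s)": t_a, "t_B (s)": t_b,
             "t_C (s)": t_c, "t_R (s)": t_r}
        )
    return pd.DataFrame(rows)
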