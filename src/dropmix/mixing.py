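"""Laminar advection–diffusion mixing in the Y-mixer channel (section A).

The crystal and substrate streams meet at the Y-junction and co-flow down a
channel of width ``w``.  At the low Reynolds numbers of these devices the
flow is laminar with a parabolic velocity profile between the side walls,

    u(y) = 6 v_mean (y/w) (1 - y/w),

and the substrate spreads across streamlines only by diffusion.  When the
axial Péclet number Pe = v_mean w / D is large, axial diffusion is
negligible and the steady transport equation parabolizes to

    u(y) dc/dx = D d²c/dy²,

which this module integrates by marching downstream with an implicit
(backward-Euler) step and zero-flux side walls.  The scheme is
unconditionally stable, positivity-preserving and conserves the advective
flux of substrate exactly at the discrete level.

Mixing is judged by an *equimolarity* criterion: a crystal is considered
mixed once the substrate concentration around it equals the protein
concentration inside the crystal (23 mM for NQO1 crystals).  Because
crystals of finite size cannot approach the wall closer than about one
crystal radius, the criterion is evaluated on an offset line a distance
``y_offset`` (default 20 µm) from the crystal-side wall.  The axial
distance L to that point, combined with the fastest (centerline) and
slowest (offset-line) streamline velocities, gives the spread of reaction
initiation times Δt_m = L/u(y_offset) - L/u(w/2).

Coordinates: x = 0 where the streams first meet, y = 0 at the crystal-side
wall.  Interface units: µm, µm/s, cm²/s for diffusivities, mPa·s for
viscosities, mM for concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_banded
from scipy.optimize import brentq

from .device import DeviceGeometry, FlowConfig, mean_velocity

#: cm²/s → µm²/s
CM2_TO_UM2 = 1e8

#: reference solvent (water, room temperature) viscosity, mPa·s
ETA_WATER = 1.00
#: measured viscosity of the PEG 3350 mother liquor, mPa·s
ETA_MOTHER_LIQUOR = 5.39
#: NADH diffusion coefficient in aqueous solution, cm²/s
D_NADH_WATER = 6.7e-6

#: protein concentration inside NQO1 crystals (mM); default equimolarity target
PROTEIN_IN_CRYSTAL_MM = 23.0
#: inlet substrate (NADH) concentration used in the mixing studies, mM
C0_SUBSTRATE_MM = 300.0
#: substrate diffusion time into a shoe-box crystal (10x20x30 µm³), s
CRYSTAL_DIFFUSION_TIME_S = 0.015

#: minimum axial Péclet number for the parabolized (no axial diffusion) model
PECLET_MIN = 50.0


class PecletRegimeError(ValueError):
    """Raised when axial diffusion cannot be neglected (Pe too small)."""


def corrected_diffusivity(d_ref: float, eta_ref: float, eta: float) -> float:
    """Viscosity-corrected diffusivity via the Einstein relation.

    D scales with 1/η at fixed temperature and hydrodynamic radius, so a
    diffusivity measured in a reference solvent of viscosity ``eta_ref``
    becomes D = D_ref · η_ref / η in a liquor of viscosity ``eta``.
    Any consistent diffusivity unit may be used.
    """
    if d_ref <= 0 or eta_ref <= 0 or eta <= 0:
        raise ValueError("diffusivity and viscosities must be positive")
    return d_ref * eta_ref / eta


@dataclass(frozen=True)
class TransportProperties:
    """Substrate transport properties.

    ``d_ref`` (cm²/s) is the diffusivity in a reference solvent of
    viscosity ``eta_ref`` (mPa·s); ``eta`` is the working-liquor
    viscosity. The working diffusivity ``d`` follows from the Einstein
    relation.
    """

    d_ref: float = D_NADH_WATER
    eta_ref: float = ETA_WATER
    eta: float = ETA_MOTHER_LIQUOR

    def __post_init__(self) -> None:
        if self.d_ref <= 0 or self.eta_ref <= 0 or self.eta <= 0:
            raise ValueError("transport properties must be positive")

    @property
    def d(self) -> float:
        """Corrected diffusivity in the working liquor, cm²/s."""
        return corrected_diffusivity(self.d_ref, self.eta_ref, self.eta)

    @property
    def d_um2_s(self) -> float:
        """Corrected diffusivity in µm²/s."""
        return self.d * CM2_TO_UM2


def velocity_profile(y, w: float, v_mean: float):
    """Parabolic (plane Poiseuille) velocity profile u(y), µm/s.

    ``y`` may be a scalar or array in [0, w]; the maximum 1.5·v_mean is at
    mid-channel and the no-slip walls are at y = 0 and y = w.
    """
    y_arr = np.asarray(y, dtype=float)
    if np.any(y_arr < 0) or np.any(y_arr > w):
        raise ValueError("y must lie within [0, w]")
    r = y_arr / w
    u = 6.0 * v_mean * r * (1.0 - r)
    return float(u) if np.isscalar(y) else u


def cumulative_flow_fraction(y: float, w: float) -> float:
    """Fraction of the channel flow carried between the wall at 0 and y."""
    r = y / w
    return 3.0 * r**2 - 2.0 * r**3


def inlet_interface_position(q_s: float, q_x: float, w: float) -> float:
    """Inlet interface position y* (µm) between the two aqueous streams.

    The crystal stream hugs the y = 0 wall; y* is where the cumulative
    parabolic-profile flow equals the crystal stream's share
    q_x / (q_x + q_s), i.e. the flow between y* and the far wall is the
    substrate share.  Solved by root finding on the cubic cumulative-flow
    function.
    """
    if q_s <= 0 or q_x <= 0:
        raise ValueError("both stream flows must be positive")
    frac_x = q_x / (q_x + q_s)
    return brentq(lambda y: cumulative_flow_fraction(y, w) - frac_x, 0.0, w,
                  xtol=1e-12 * w)


@dataclass(frozen=True)
class MixingGrid:
    """Uniform marching grid: ``nx`` axial steps over ``x_max`` µm and
    ``ny`` transverse nodes over the channel width ``w`` µm."""

    nx: int = 512
    ny: int = 257
    x_max: float = 528.0
    w: float = 150.0

    def __post_init__(self) -> None:
        if self.nx < 16 or self.ny < 16:
            raise ValueError("grid must have at least 16 nodes per axis")
        if self.x_max <= 0 or self.w <= 0:
            raise ValueError("grid extents must be positive")


@dataclass(frozen=True)
class MixingField:
    """Steady substrate concentration field c(x, y) in the mixer channel.

    ``c`` has shape (nx + 1, ny); row i is the transverse profile at
    ``x[i]``. Concentrations in mM, lengths in µm, velocities in µm/s.
    """

    x: np.ndarray
    y: np.ndarray
    c: np.ndarray
    c0: float
    interface_y: float
    v_mean: float
    w: float
    d_um2_s: float
    profile: str = "parabolic"

    def velocities(self) -> np.ndarray:
        """Streamwise velocity at the transverse nodes, µm/s."""
        if self.profile == "plug":
            return np.full_like(self.y, self.v_mean)
        return velocity_profile(self.y, self.w, self.v_mean)

    def advective_flux(self, i: int) -> float:
        """∫ u(y) c(x_i, y) dy (µm²·mM/s), trapezoidal quadrature."""
        return float(np.trapezoid(self.velocities() * self.c[i], self.y))


def _march(u: np.ndarray, c_in: np.ndarray, d_um2_s: float, x: np.ndarray,
           dy: float) -> np.ndarray:
    """Backward-Euler march of u·dc/dx = D·d²c/dy² with zero-flux walls."""
    ny = c_in.size
    nx = x.size - 1
    out = np.empty((nx + 1, ny))
    out[0] = c_in
    r = d_um2_s / dy**2

    ab = np.zeros((3, ny))
    rhs_scale = np.empty(ny)
    dx = x[1] - x[0]
    # interior rows: (u/dx + 2r) c_j - r (c_{j-1} + c_{j+1}) = (u/dx) c_old
    ab[0, 2:] = -r                      # superdiagonal for rows 1..ny-2
    ab[1, 1:-1] = u[1:-1] / dx + 2.0 * r
    ab[2, :-2] = -r                     # subdiagonal
    rhs_scale[1:-1] = u[1:-1] / dx
    # wall rows enforce zero transverse gradient
    ab[1, 0] = 1.0
    ab[0, 1] = -1.0
    ab[1, -1] = 1.0
    ab[2, -2] = -1.0
    rhs_scale[0] = rhs_scale[-1] = 0.0

    c = c_in.copy()
    for i in range(1, nx + 1):
        rhs = rhs_scale * c
        c = solve_banded((1, 1), ab, rhs)
        out[i] = c
    return out


def solve_mixing_field(device: DeviceGeometry, flows: FlowConfig,
                       props: TransportProperties, c0: float = C0_SUBSTRATE_MM,
                       grid: MixingGrid | None = None,
                       profile: str = "parabolic") -> MixingField:
    """Solve the parabolized mixing problem in section A of ``device``.

    The inlet is a step profile: substrate at ``c0`` on the far-wall side
    of the interface y* set by the flow split, zero on the crystal side.
    ``profile`` may be "parabolic" (physical) or "plug" (uniform velocity;
    used to validate the solver against the closed-form erfc solution).

    Raises :class:`PecletRegimeError` if Pe = v_mean·w/D ≤ 50, where the
    neglected axial-diffusion term would matter.
    """
    section_a = device.section("A")
    cs = section_a.cross_section
    if cs.shape != "rectangular":
        raise ValueError("section A must have a rectangular cross-section")
    w = cs.width
    if grid is None:
        grid = MixingGrid(x_max=section_a.length, w=w)
    if abs(grid.w - w) > 1e-9:
        raise ValueError("grid width must equal the section A channel width")
    if grid.x_max > section_a.length * (1 + 1e-9):
        raise ValueError("grid x_max cannot exceed the section A length")

    v_mean = mean_velocity(flows.q_aq, cs)
    d = props.d_um2_s
    peclet = v_mean * w / d
    if peclet <= PECLET_MIN:
        raise PecletRegimeError(
            f"axial Péclet number {peclet:.1f} <= {PECLET_MIN:g}: the neglected "
            "axial-diffusion term D·d²c/dx² is not small relative to advection; "
            "the parabolized marching model does not apply"
        )

    y_star = inlet_interface_position(flows.q_s, flows.q_x, w)
    y = np.linspace(0.0, w, grid.ny)
    x = np.linspace(0.0, grid.x_max, grid.nx + 1)
    c_in = np.where(y > y_star, c0, 0.0)
    if profile == "parabolic":
        u = velocity_profile(y, w, v_mean)
    elif profile == "plug":
        u = np.full_like(y, v_mean)
    else:
        raise ValueError(f"unknown velocity profile {profile!r}")

    c = _march(u, c_in, d, x, y[1] - y[0])
    return MixingField(x=x, y=y, c=c, c0=c0, interface_y=y_star,
                       v_mean=v_mean, w=w, d_um2_s=d, profile=profile)


def march_concentration(v_mean: float, w: float, d_um2_s: float,
                        c_inlet: np.ndarray, x_max: float, nx: int,
                        profile: str = "parabolic") -> MixingField:
    """Low-level marching solver on an explicit inlet profile.

    Unlike :func:`solve_mixing_field` this does not tie the domain to a
    device section; useful for validation studies (e.g. the long-channel
    full-mixing limit).
    """
    ny = c_inlet.size
    y = np.linspace(0.0, w, ny)
    x = np.linspace(0.0, x_max, nx + 1)
    if profile == "parabolic":
        u = velocity_profile(y, w, v_mean)
    elif profile == "plug":
        u = np.full_like(y, v_mean)
    else:
        raise ValueError(f"unknown velocity profile {profile!r}")
    c = _march(u, np.asarray(c_inlet, dtype=float), d_um2_s, x, y[1] - y[0])
    return MixingField(x=x, y=y, c=c, c0=float(np.max(c_inlet)),
                       interface_y=float("nan"), v_mean=v_mean, w=w,
                       d_um2_s=d_um2_s, profile=profile)


def closed_form_plug_field(v_mean: float, w: float, d_um2_s: float, c0: float,
                           interface_y: float, x: np.ndarray,
                           y: np.ndarray) -> np.ndarray:
    """Analytic plug-flow solution for a semi-infinite step interface.

    c(x, y) = (c0/2)·erfc((y* − y) / (2·sqrt(D·x/v))) — valid while the
    diffusion layer is far from both walls.  Serves as an independent
    oracle for the marching solver.
    """
    from scipy.special import erfc

    xx, yy = np.meshgrid(x, y, indexing="ij")
    s = np.sqrt(np.maximum(d_um2_s * xx / v_mean, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        arg = (interface_y - yy) / (2.0 * s)
    field = 0.5 * c0 * erfc(arg)
    field[xx == 0] = np.where(yy[xx == 0] > interface_y, c0, 0.0)
    return field


def equimolar_distance(field: MixingField, c_eq: float,
                       y_offset: float) -> float | None:
    """Axial distance L (µm) to the equimolarity point on the offset line.

    Returns the smallest x at which c(x, y_offset) reaches ``c_eq``
    (linear interpolation between axial stations), or ``None`` when the
    criterion is not met within the solved domain.
    """
    if c_eq >= field.c0:
        raise ValueError("equimolar concentration must be below the inlet c0")
    if c_eq <= 0:
        return 0.0
    if not 0 <= y_offset <= field.w:
        raise ValueError("y_offset must lie within the channel")
    # linear interpolation of the transverse profile at y_offset
    prof = np.array([np.interp(y_offset, field.y, row) for row in field.c])
    reached = prof >= c_eq
    if not reached.any():
        return None
    i = int(np.argmax(reached))
    if i == 0:
        return 0.0
    x0, x1 = field.x[i - 1], field.x[i]
    c0_, c1_ = prof[i - 1], prof[i]
    if c1_ == c0_:
        return float(x1)
    return float(x0 + (c_eq - c0_) / (c1_ - c0_) * (x1 - x0))


@dataclass(frozen=True)
class MixingSpreadResult:
    """Mixing-time spread diagnostics.

    ``L`` is the distance from the stream-meeting point to equimolarity on
    the offset line; ``t_fast``/``t_slow`` are the transit times of L on
    the centerline and offset streamlines; ``delta_t_m`` their difference;
    ``delta_t_total`` additionally includes diffusion into the crystal
    interior, and ``fraction_of_t_r`` expresses it relative to the
    reaction time point.
    """

    L: float
    c_eq: float
    y_offset: float
    t_fast: float
    t_slow: float
    delta_t_m: float
    delta_t_total: float | None = None
    fraction_of_t_r: float | None = None


def mixing_spread(L: float, w: float, v_mean: float,
                  y_offset: float, c_eq: float = PROTEIN_IN_CRYSTAL_MM) -> MixingSpreadResult:
    """Streamline-resolved spread of reaction-initiation times over ``L``.

    The fastest fluid is at mid-channel (u = 1.5 v_mean) and the slowest
    relevant streamline at the crystal offset line.
    """
    if L <= 0:
        raise ValueError("L must be positive")
    u_fast = velocity_profile(w / 2.0, w, v_mean)
    u_slow = velocity_profile(y_offset, w, v_mean)
    if u_slow <= 0:
        raise ValueError("y_offset lies on a wall where the velocity vanishes")
    t_fast = L / u_fast
    t_slow = L / u_slow
    return MixingSpreadResult(L=L, c_eq=c_eq, y_offset=y_offset,
                              t_fast=t_fast, t_slow=t_slow,
                              delta_t_m=t_slow - t_fast)


def total_initiation_spread(delta_t_m: float, t_crystal: float,
                            t_r: float) -> tuple[float, float]:
    """Combine streamline spread with crystal-interior diffusion time.

    Returns (Δt_total, Δt_total / t_R).
    """
    if delta_t_m < 0 or t_crystal < 0:
        raise ValueError("time spreads must be non-negative")
    if t_r <= 0:
        raise ValueError("reaction time point must be positive")
    total = delta_t_m + t_crystal
    return total, total / t_r


def fraction_equimolar(equimolar_pos: float, interface_pos: float) -> float:
    """Fraction of the aqueous (crystal-carrying) stream past equimolarity.

    Both positions are distances from the same wall along a transverse
    analysis line; ``interface_pos`` is the aqueous/oil boundary.
    """
    if interface_pos <= 0:
        raise ValueError("interface position must be positive")
    if not 0 < equimolar_pos <= interface_pos:
        raise ValueError("equimolar position must lie within (0, interface]")
    return equimolar_pos / interface_pos
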