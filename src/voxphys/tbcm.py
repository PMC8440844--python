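"""Symmetric triangular body-cover vocal fold model.

Three lumped masses per side — lower and upper cover masses riding on a body
mass — with nonlinear springs, viscous damping, and a zipper-like gradual
collision along the triangular prephonatory glottis.  Lumped parameters are
regenerated from the prephonatory posture with empirical rules: geometry
scales with fold strain at conserved tissue volume, cover stiffness carries
the ligament+mucosa fiber tension, and body stiffness carries the (active +
passive) thyroarytenoid tension.

Left/right folds are identical; only one side is computed and glottal widths
are doubled where areas are needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .posture import PostureState, fold_tension_stresses


class NumericalBlowupError(RuntimeError):
    """NaN/Inf encountered while stepping; carries the offending time index."""

    def __init__(self, index: int):
        super().__init__(f"non-finite state at time index {index}")
        self.index = index


@dataclass(frozen=True)
class TBCMConfig:
    """Lumped dynamical parameters of the three-mass body-cover system."""

    m_l: float
    m_u: float
    m_b: float
    k_l: float
    k_u: float
    k_b: float
    k_c: float
    d_l: float
    d_u: float
    d_b: float
    eta_nl: float          # cubic spring coefficient [1/m^2]
    k_col_l: float         # collision spring per unit contact length [N/m^2]
    k_col_u: float
    d_col_l: float
    d_col_u: float
    T_l: float             # lower/upper cover thicknesses [m]
    T_u: float
    length: float          # membranous length [m]
    x_l0_offset: float     # prephonatory anterior-end half-width offsets [m]
    x_u0_offset: float

    def __post_init__(self):
        for name in ("m_l", "m_u", "m_b", "k_l", "k_u", "k_b", "T_l", "T_u", "length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"TBCMConfig.{name} must be > 0")


@dataclass
class TBCMState:
    """Displacements/velocities of (lower, upper, body) masses plus contact info."""

    x: np.ndarray = field(default_factory=lambda: np.zeros(3))
    v: np.ndarray = field(default_factory=lambda: np.zeros(3))
    contact: bool = False
    contact_fraction: float = 0.0


@dataclass(frozen=True)
class CollisionSample:
    """Mean vocal fold contact pressure and contact geometry at one instant."""

    pc: float              # mean collision pressure over the contact area [Pa]
    contact_length: float  # [m]
    contact_area: float    # [m^2]

    def __post_init__(self):
        if self.pc < 0 or (self.contact_area == 0.0 and self.pc != 0.0):
            raise ValueError("collision pressure must be >= 0 and 0 without contact")


def rules_update(posture: PostureState, params: dict, a_TA: float = 0.0) -> TBCMConfig:
    """Derive the lumped body-cover parameters from a prephonatory posture.

    Deterministic.  At zero strain and zero activation the reference
    parameters are returned unchanged (all scale factors are unity and the
    fiber-tension stiffness terms vanish because all stresses are zero).
    """
    if posture.length <= 0:
        raise ValueError("non-physical posture: membranous length <= 0")
    bc = params["body_cover"]
    eps = posture.strain
    L = bc["L0"] * (1.0 + eps)
    T = bc["T0"] / (1.0 + bc["thickness_rule"] * eps)
    # depth from tissue-volume conservation
    Dc = bc["Dc0"] * (bc["L0"] * bc["T0"]) / (L * T)
    Db = bc["Db0"] * (bc["L0"] * bc["T0"]) / (L * T)

    nodal = bc["nodal"]
    T_l, T_u = nodal * T, (1.0 - nodal) * T
    rho = bc["rho_tissue"]
    m_cov = rho * L * T * Dc
    m_l, m_u = nodal * m_cov, (1.0 - nodal) * m_cov
    m_b = rho * L * T * Db

    tissues = params["tissues"]
    s_ta, s_lig, s_muc = fold_tension_stresses(eps, a_TA, tissues)
    a_lig, a_muc = tissues["LIG"]["area"], tissues["MUC"]["area"]
    sigma_c = max((s_lig * a_lig + s_muc * a_muc) / (a_lig + a_muc), 0.0)
    sigma_b = max(s_ta, 0.0)

    pi2 = math.pi ** 2
    k_l = 2.0 * bc["mu_cover"] * L * T_l / Dc + pi2 * sigma_c * T_l * Dc / L
    k_u = 2.0 * bc["mu_cover"] * L * T_u / Dc + pi2 * sigma_c * T_u * Dc / L
    k_b = 2.0 * bc["mu_body"] * L * T / Db + pi2 * sigma_b * T * Db / L
    k_c = bc["c_kc"] * math.sqrt(k_l * k_u)

    d_l = 2.0 * bc["zeta_l"] * math.sqrt(m_l * k_l)
    d_u = 2.0 * bc["zeta_u"] * math.sqrt(m_u * k_u)
    d_b = 2.0 * bc["zeta_b"] * math.sqrt(m_b * k_b)

    kf = bc["k_col_factor"]
    return TBCMConfig(
        m_l=m_l, m_u=m_u, m_b=m_b,
        k_l=k_l, k_u=k_u, k_b=k_b, k_c=k_c,
        d_l=d_l, d_u=d_u, d_b=d_b,
        eta_nl=bc["eta_nl"],
        k_col_l=kf * k_l / L, k_col_u=kf * k_u / L,
        d_col_l=2.0 * bc["zeta_col"] * math.sqrt(m_l * k_l),
        d_col_u=2.0 * bc["zeta_col"] * math.sqrt(m_u * k_u),
        T_l=T_l, T_u=T_u, length=L,
        x_l0_offset=bc["x_l0_offset"], x_u0_offset=bc["x_u0_offset"],
    )


def pack_config(config: TBCMConfig) -> np.ndarray:
    """Flatten a TBCMConfig into the vector consumed by the numba kernels."""
    return np.array([
        config.m_l, config.m_u, config.m_b,
        config.k_l, config.k_u, config.k_b, config.k_c,
        config.d_l, config.d_u, config.d_b,
        config.eta_nl,
        config.k_col_l, config.k_col_u,
        config.d_col_l, config.d_col_u,
        config.T_l, config.T_u, config.length,
    ])


def step(
    state: TBCMState,
    config: TBCMConfig,
    driving: tuple[float, float],
    dt: float,
    posture: PostureState | None = None,
    time_index: int = 0,
) -> TBCMState:
    """Advance the three-mass system one time step under given driving pressures.

    ``driving = (P_lower, P_upper)`` are the aerodynamic pressures acting on
    the cover masses.  Collision restoring forces engage automatically when a
    cover profile penetrates the contact plane.
    """
    if not (np.all(np.isfinite(state.x)) and np.all(np.isfinite(state.v))):
        raise NumericalBlowupError(time_index)
    xi02 = posture.xi02 if posture is not None else 0.0
    cfg = pack_config(config)
    o_l = state.x[0] + config.x_l0_offset
    o_u = state.x[1] + config.x_u0_offset
    a_l, a_u, a_b, _, _, ell_l, ell_u = _kernels.mass_accels(
        state.x, state.v, driving[0], driving[1], cfg, o_l, o_u, xi02
    )
    acc = np.array([a_l, a_u, a_b])
    x_new = state.x + state.v * dt + 0.5 * acc * dt * dt
    v_new = state.v + acc * dt
    if not (np.all(np.isfinite(x_new)) and np.all(np.isfinite(v_new))):
        raise NumericalBlowupError(time_index)
    frac = max(ell_l, ell_u) / config.length
    return TBCMState(x=x_new, v=v_new, contact=frac > 0.0, contact_fraction=frac)


def zipper_collision(state: TBCMState, config: TBCMConfig, posture: PostureState) -> CollisionSample:
    """Collision pressure of the zipper-like gradual glottal closure.

    The linearly varying half-width of each cover mass defines a contacting
    anterior portion where the width is <= 0; the collision-spring stress is
    integrated over that portion in closed form and normalized by the contact
    area to yield the mean contact pressure.
    """
    o_l = state.x[0] + config.x_l0_offset
    o_u = state.x[1] + config.x_u0_offset
    L = config.length
    pen_l, ell_l = _kernels.lin_penetration_integral(o_l, o_l + posture.xi02, L)
    pen_u, ell_u = _kernels.lin_penetration_integral(o_u, o_u + posture.xi02, L)
    area = ell_l * config.T_l + ell_u * config.T_u
    if area <= 0.0:
        return CollisionSample(pc=0.0, contact_length=0.0, contact_area=0.0)
    force = config.k_col_l * pen_l + config.k_col_u * pen_u
    return CollisionSample(pc=force / area, contact_length=max(ell_l, ell_u), contact_area=area)


def mechanical_energy(state: TBCMState, config: TBCMConfig) -> float:
    """Total mechanical energy (kinetic + spring potential) of the 3-mass system."""
    m = np.array([config.m_l, config.m_u, config.m_b])
    kin = 0.5 * float(np.sum(m * state.v ** 2))
    s_l = state.x[0] - state.x[2]
    s_u = state.x[1] - state.x[2]
    eta = config.eta_nl

    def pot(k, s):
        return k * (0.5 * s * s + 0.25 * eta * s ** 4)

    return (
        kin
        + pot(config.k_l, s_l)
        + pot(config.k_u, s_u)
        + pot(config.k_b, state.x[2])
        + 0.5 * config.k_c * (state.x[0] - state.x[1]) ** 2
    )


def linearized_frequencies(config: TBCMConfig) -> np.ndarray:
    """Undamped eigenfrequencies (Hz) of the linearized 3-mass system."""
    K = np.array([
        [config.k_l + config.k_c, -config.k_c, -config.k_l],
        [-config.k_c, config.k_u + config.k_c, -config.k_u],
        [-config.k_l, -config.k_u, config.k_l + config.k_u + config.k_b],
    ])
    M = np.diag([config.m_l, config.m_u, config.m_b])
    w2 = np.linalg.eigvals(np.linalg.solve(M, K))
    return np.sort(np.sqrt(np.abs(w2.real))) / (2.0 * np.pi)


def rest_config(params: dict) -> TBCMConfig:
    """Reference configuration at zero strain and zero activation."""
    from .posture import MuscleActivation, posture_from_activations

    post = posture_from_activations(MuscleActivation.rest(), params)
    return rules_update(replace(post, strain=0.0, length=params["body_cover"]["L0"]), params, 0.0)
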