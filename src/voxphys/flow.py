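"""Glottal geometry and interactive glottal airflow.

The glottal area integrates the triangular half-width profile along the fold
using, at each point, the narrower of the two cover-mass openings (the
flow-limiting section), plus the posterior cartilaginous gap.  The airflow
solves the transglottal pressure balance coupling a lumped Bernoulli kinetic
loss with the characteristic wave impedances of the adjacent subglottal and
supraglottal tract sections (flow-sound-tissue interaction), taking the
physically admissible root.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .posture import PostureState
from .tbcm import TBCMConfig, TBCMState


@dataclass(frozen=True)
class GlottalGeometry:
    """Membranous, posterior and effective glottal areas [m^2]."""

    membranous: float
    posterior: float

    def __post_init__(self):
        if self.membranous < 0 or self.posterior < 0:
            raise ValueError("glottal areas must be >= 0")

    @property
    def effective(self) -> float:
        return self.membranous + self.posterior


@dataclass(frozen=True)
class FlowSample:
    """Glottal volume velocity and the transglottal pressure that produced it."""

    ug: float          # [m^3/s]
    p_trans: float     # [Pa]


def glottal_area(state: TBCMState, posture: PostureState, config: TBCMConfig) -> GlottalGeometry:
    """Glottal areas from the triangular geometry at the current fold state.

    Both cover profiles share the posture slope, so the pointwise minimum is
    the profile with the smaller anterior offset; its open integral has a
    closed form.  Widths are doubled for the two symmetric folds.
    """
    o_l = state.x[0] + config.x_l0_offset
    o_u = state.x[1] + config.x_u0_offset
    o_min = min(o_l, o_u)
    integ, _ = _kernels.lin_open_integral(o_min, o_min + posture.xi02, config.length)
    return GlottalGeometry(membranous=2.0 * integ, posterior=posture.gap_area)


def solve_flow(
    ps_inc: float,
    pe_inc: float,
    geom: GlottalGeometry,
    z_sub: float,
    z_sup: float,
    kt: float = 1.0,
    rho: float = 1.14,
) -> FlowSample:
    """Solve the glottal pressure balance for the volume velocity.

    ``ps_inc``/``pe_inc`` are the incident (travelling-wave) pressures of the
    topmost subglottal and first supraglottal sections; ``z_sub``/``z_sup``
    their characteristic impedances.  The total boundary pressures follow as
    ``Ps = 2 ps_inc - z_sub Ug`` and ``Pe = 2 pe_inc + z_sup Ug``.
    """
    if z_sub <= 0 or z_sup <= 0:
        raise ValueError("wave impedances must be > 0")
    ag = geom.effective
    ug = _kernels.solve_flow_scalar(2.0 * (ps_inc - pe_inc), ag, z_sub + z_sup, kt, rho)
    ps = 2.0 * ps_inc - z_sub * ug
    pe = 2.0 * pe_inc + z_sup * ug
    return FlowSample(ug=ug, p_trans=ps - pe)


def bernoulli_flow(dp: float, area: float, kt: float = 1.0, rho: float = 1.14) -> float:
    """Quasi-steady Bernoulli orifice flow (the zero-impedance limit)."""
    if area <= 0.0:
        return 0.0
    return float(np.sign(dp)) * area * np.sqrt(2.0 * abs(dp) / (kt * rho))
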