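"""Prephonatory laryngeal posturing from intrinsic-muscle activation.

The five intrinsic laryngeal muscles (LCA, IA, PCA, CT, TA) plus the vocal
ligament and mucosa are described as one-dimensional fibrous tissues with a
modified Kelvin (standard-linear-solid) constitutive law,

    tau_s * ds/dt + s = sigma_p(eps) + a * sigma_am * f_act(eps)
                        + tau_e * d/dt sigma_p(eps),

with a nonlinear passive stress ``sigma_p(eps) = sigma0 (exp(B eps) - 1)``
anchored so that the rest state carries no stress, and an active stress that
scales linearly with the normalized activation ``a`` in [0, 1] up to the
maximum isometric stress ``sigma_am`` through a parabolic length-tension
shape ``f_act``.

Posturing reduces to a scalar cricothyroid force balance along the fold axis:
CT tension, acting through a lever gain, elongates the fold against the
passive tension of the TA/ligament/mucosa assembly and the active shortening
component of TA.  Adduction follows an empirical rule mapping the effective
adductor level (LCA + IA against PCA) to the glottal half-width at the vocal
processes; the triangular prephonatory glottis and posterior cartilaginous
gap follow from it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq


class PostureConvergenceError(RuntimeError):
    """Equilibrium solver failed; carries the last residual."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


@dataclass(frozen=True)
class MuscleActivation:
    """Normalized activation of the five intrinsic laryngeal muscles."""

    a_LCA: float
    a_IA: float
    a_PCA: float
    a_CT: float
    a_TA: float

    def __post_init__(self):
        for name in ("a_LCA", "a_IA", "a_PCA", "a_CT", "a_TA"):
            v = getattr(self, name)
            if not np.isfinite(v) or not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v!r} outside the admissible range [0, 1]")

    @classmethod
    def rest(cls) -> "MuscleActivation":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class PostureState:
    """Quasi-static prephonatory laryngeal configuration."""

    strain: float          # vocal fold longitudinal strain (dimensionless)
    length: float          # membranous fold length [m]
    xi02: float            # glottal half-width at the vocal processes [m]
    gap_area: float        # posterior cartilaginous gap area [m^2]

    def __post_init__(self):
        if self.gap_area < 0:
            raise ValueError("posterior gap area must be >= 0")


def passive_stress(strain: float, tissue: dict) -> float:
    """Nonlinear passive stress, zero at zero strain by construction."""
    return tissue["sigma0"] * (math.exp(tissue["B"] * strain) - 1.0)


def active_shape(strain: float, tissue: dict) -> float:
    """Parabolic active length-tension factor, clipped at zero."""
    d = strain - tissue["eps_m"]
    return max(0.0, 1.0 - tissue["b_act"] * d * d)


def kelvin_stress(strain: float, strain_rate: float, activation: float, tissue: dict) -> float:
    """Quasi-static total Kelvin stress (Pa) at a given strain and strain rate.

    This is the instantaneous (``tau_s -> 0``) limit of the constitutive law:
    passive + viscous + activation-scaled active stress.  The viscous term is
    ``tau_e * sigma_p'(eps) * deps/dt``.
    """
    if not np.isfinite(strain):
        raise ValueError("strain must be finite")
    if not np.isfinite(activation) or not 0.0 <= activation <= 1.0:
        raise ValueError(f"activation={activation!r} outside [0, 1]")
    sp = passive_stress(strain, tissue)
    dsp = tissue["sigma0"] * tissue["B"] * math.exp(tissue["B"] * strain)
    active = activation * tissue["sigma_am"] * active_shape(strain, tissue)
    return sp + tissue["tau_e"] * dsp * strain_rate + active


def kelvin_stress_history(
    t: np.ndarray,
    strain: np.ndarray,
    activation: float,
    tissue: dict,
    s0: float = 0.0,
    rtol: float = 1e-9,
) -> np.ndarray:
    """Integrate the full Kelvin ODE for a prescribed strain trajectory.

    Solves ``tau_s s' + s = sigma_qs(eps(t), eps'(t), a)`` with a stiff solver,
    returning the stress history on the grid ``t``.  The quasi-static source is
    evaluated with :func:`kelvin_stress`, so the relaxed (``t >> tau_s``) value
    under constant strain coincides with the quasi-static call path.
    """
    t = np.asarray(t, dtype=float)
    strain = np.asarray(strain, dtype=float)
    rate = np.gradient(strain, t)

    def source(ti: float) -> float:
        e = float(np.interp(ti, t, strain))
        r = float(np.interp(ti, t, rate))
        return kelvin_stress(e, r, activation, tissue)

    tau = tissue["tau_s"]
    sol = solve_ivp(
        lambda ti, s: (source(ti) - s) / tau,
        (t[0], t[-1]),
        [s0],
        t_eval=t,
        method="BDF",
        rtol=rtol,
        atol=1e-12,
    )
    if not sol.success:  # pragma: no cover
        raise RuntimeError(f"Kelvin ODE integration failed: {sol.message}")
    return sol.y[0]


def fold_tension_stresses(strain: float, a_TA: float, tissues: dict) -> tuple[float, float, float]:
    """(sigma_TA_total, sigma_LIG, sigma_MUC) at a given fold strain."""
    s_ta = kelvin_stress(strain, 0.0, a_TA, tissues["TA"])
    s_lig = kelvin_stress(strain, 0.0, 0.0, tissues["LIG"])
    s_muc = kelvin_stress(strain, 0.0, 0.0, tissues["MUC"])
    return s_ta, s_lig, s_muc


def _length_balance_residual(eps: float, act: MuscleActivation, params: dict) -> float:
    """Net elongating force (N) on the membranous fold at strain ``eps``."""
    tissues = params["tissues"]
    post = params["posture"]
    eps_ct = -post["kappa_ct"] * eps
    f_ct = kelvin_stress(eps_ct, 0.0, act.a_CT, tissues["CT"]) * tissues["CT"]["area"]
    ta = tissues["TA"]
    s_ta_passive = passive_stress(eps, ta)
    s_ta_active = act.a_TA * ta["sigma_am"] * active_shape(eps, ta)
    f_fold = (
        (s_ta_passive + post["g_ta_active"] * s_ta_active) * ta["area"]
        + passive_stress(eps, tissues["LIG"]) * tissues["LIG"]["area"]
        + passive_stress(eps, tissues["MUC"]) * tissues["MUC"]["area"]
    )
    return post["g_ct"] * f_ct - f_fold


def posture_from_activations(
    act: MuscleActivation, params: dict, xtol: float = 1e-12, maxiter: int = 500
) -> PostureState:
    """Solve the quasi-static posture for a given muscle activation set.

    The cricothyroid balance is a scalar monotone root problem in the fold
    strain; it is solved with a bracketed root-finder over the configured
    physiologic band and clipped at the band edges when the balance cannot be
    met inside it (extreme activation combinations).
    """
    post = params["posture"]
    lo, hi = post["strain_min"], post["strain_max"]
    f_lo = _length_balance_residual(lo, act, params)
    f_hi = _length_balance_residual(hi, act, params)
    if f_lo <= 0.0:
        eps = lo
    elif f_hi >= 0.0:
        eps = hi
    else:
        try:
            eps = brentq(
                _length_balance_residual, lo, hi, args=(act, params),
                xtol=xtol, maxiter=maxiter,
            )
        except RuntimeError as exc:  # pragma: no cover - brentq is robust here
            raise PostureConvergenceError(
                f"posture equilibrium did not converge: {exc}",
                residual=_length_balance_residual(0.5 * (lo + hi), act, params),
            ) from exc

    a_lc = 0.5 * (act.a_LCA + act.a_IA) - post["k_pca"] * act.a_PCA
    xi02 = post["xi02_max"] * (1.0 - 2.0 * a_lc)
    gap = post["pgo_gain"] * post["cartilaginous_length"] * max(xi02, 0.0)
    L0 = params["body_cover"]["L0"]
    return PostureState(strain=eps, length=L0 * (1.0 + eps), xi02=xi02, gap_area=gap)
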