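"""Wave-reflection analog acoustics for the subglottal and supraglottal tracts.

Each tract is a concatenation of short uniform cylinders of length
``c * dt / 2`` (one section per half-sample of travel).  Travelling partial
pressure waves scatter at the area junctions with reflection coefficients
``r = (A_i - A_{i+1}) / (A_i + A_{i+1})`` and lose energy through an
exponential per-section attenuation factor.  The lip end carries a
first-order inertive radiation load (DC reflection -1, radiated pressure
rising ~ +6 dB/octave at low frequency); the lung end is an absorbing
termination driven by the lung pressure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _kernels
from .params import area_function_path


@dataclass(frozen=True)
class AreaFunction:
    """Ordered cross-sectional areas of the uniform cylindrical sections."""

    areas: np.ndarray      # [m^2], index 0 at the glottal (or lung) end
    section_length: float  # [m]
    label: str = ""

    def __post_init__(self):
        a = np.asarray(self.areas, dtype=float)
        if a.ndim != 1 or a.size < 2:
            raise ValueError("area function needs at least two sections")
        if np.any(a <= 0):
            raise ValueError("all section areas must be > 0")
        object.__setattr__(self, "areas", a)

    @property
    def length(self) -> float:
        return self.areas.size * self.section_length

    @property
    def reflections(self) -> np.ndarray:
        a = self.areas
        return (a[:-1] - a[1:]) / (a[:-1] + a[1:])


def load_area_function(
    source: str | Path,
    fs: float,
    c: float = 350.0,
    reverse: bool = False,
    label: str | None = None,
) -> AreaFunction:
    """Load an area-function CSV (columns: distance_cm, area_cm2) and resample.

    The profile is resampled onto sections of length ``c/(2 fs)`` by averaging
    a dense linear interpolation inside each section (area-preserving).
    ``reverse=True`` flips the profile (assets run glottis -> lips; the
    subglottal tract is used lung -> glottis).
    """
    path = Path(source)
    if not path.exists():
        path = area_function_path(str(source))
    data = np.loadtxt(path, delimiter=",", comments="#")
    x = data[:, 0] * 1e-2
    a = data[:, 1] * 1e-4
    if reverse:
        x = x[-1] - x[::-1]
        a = a[::-1]
    dx = c / (2.0 * fs)
    # the discrete ladder's effective acoustic length is (n-1) sections
    # (boundary turnarounds are instantaneous), hence the +1
    n = max(int(round(x[-1] / dx)) + 1, 2)
    fine = np.linspace(0.0, x[-1], 50 * n)
    a_fine = np.interp(fine, x, a)
    areas = a_fine[: 50 * n].reshape(n, 50).mean(axis=1)
    return AreaFunction(areas=areas, section_length=dx, label=label or path.stem)


@dataclass
class WRAState:
    """Forward/backward partial pressure waves of one tract."""

    forward: np.ndarray
    backward: np.ndarray

    @classmethod
    def zeros(cls, n: int) -> "WRAState":
        return cls(np.zeros(n), np.zeros(n))

    def copy(self) -> "WRAState":
        return WRAState(self.forward.copy(), self.backward.copy())


def scatter_and_propagate(
    state: WRAState,
    areas: AreaFunction,
    attenuation: float,
    left: str = "rigid",
    right: str = "rigid",
) -> WRAState:
    """One half-sample pass: propagate every wave one section and scatter.

    ``left``/``right`` select simple analytic terminations for standalone
    use ("rigid" reflects +1, "open" reflects -1, "absorbing" kills the
    arriving wave); the synthesizer replaces them with the glottal, lung and
    lip boundary handlers.
    """
    if not 0.0 < attenuation <= 1.0:
        raise ValueError("attenuation must lie in (0, 1]")
    f, b = state.forward, state.backward
    nf, nb = np.empty_like(f), np.empty_like(b)
    _kernels.tract_half_pass(f, b, nf, nb, areas.reflections, attenuation)
    arriving_left = attenuation * b[0]
    arriving_right = attenuation * f[-1]
    nf[0] = {"rigid": arriving_left, "open": -arriving_left, "absorbing": 0.0}[left]
    nb[-1] = {"rigid": arriving_right, "open": -arriving_right, "absorbing": 0.0}[right]
    return WRAState(nf, nb)


def wave_energy(state: WRAState, areas: AreaFunction, rho: float = 1.14, c: float = 350.0) -> float:
    """Acoustic energy carried by the travelling waves (arbitrary consistent units)."""
    w = areas.areas / (rho * c)
    return float(np.sum(w * (state.forward ** 2 + state.backward ** 2)))


def lung_source_scale(n_sections: int, attenuation: float, lung_reflection: float) -> float:
    """Source normalization for the lung-end termination.

    The per-section attenuation also damps the travelling waves that carry
    the static head, which would unphysically reduce the steady subglottal
    pressure (steady tracheal flow sees almost no viscous drop).  Scaling the
    injected source so the zero-flow steady pressure at the glottal end
    equals the lung pressure removes that artifact without touching the AC
    loss behavior.
    """
    g = attenuation ** n_sections
    denom = g * (1.0 - lung_reflection)
    if denom < 1e-12:
        return 1.0
    return (1.0 - lung_reflection * g * g) / denom


class LipRadiation:
    """First-order reflective filter implementing the inertive radiation load.

    Piston-in-baffle low-frequency network: radiation resistance
    ``R = 128 rho c / (9 pi^2 A)`` in parallel with the inertance
    ``M = 8 rho / (3 pi^2 a)`` of the end correction (``a`` = terminal
    radius).  Discretized with the bilinear transform at the half-sample
    update rate.  At DC the load vanishes and the reflection is exactly -1.
    """

    def __init__(self, area: float, fs_update: float, rho: float = 1.14, c: float = 350.0):
        if area <= 0:
            raise ValueError("terminal area must be > 0")
        radius = math.sqrt(area / math.pi)
        z0 = rho * c / area
        R = 128.0 * rho * c / (9.0 * math.pi ** 2 * area)
        M = 8.0 * rho / (3.0 * math.pi ** 2 * radius)
        tau = M / R
        K = 2.0 * fs_update
        c1 = M - z0 * tau
        c2 = M + z0 * tau
        den = c2 * K + z0
        self.b0 = (c1 * K - z0) / den
        self.b1 = -(c1 * K + z0) / den
        self.a1 = (z0 - c2 * K) / den
        self._x1 = 0.0
        self._y1 = 0.0

    def reset(self) -> None:
        self._x1 = 0.0
        self._y1 = 0.0

    def step(self, forward: float) -> tuple[float, float]:
        """Map an incident forward wave to (reflected backward wave, radiated pressure)."""
        y = self.b0 * forward + self.b1 * self._x1 - self.a1 * self._y1
        self._x1 = forward
        self._y1 = y
        return y, forward + y


def lip_radiation(forward: np.ndarray, load: LipRadiation) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized convenience wrapper over :meth:`LipRadiation.step`."""
    load.reset()
    back = np.empty_like(forward)
    pout = np.empty_like(forward)
    for i, fwd in enumerate(np.asarray(forward, dtype=float)):
        back[i], pout[i] = load.step(fwd)
    return back, pout


@dataclass
class CoupledTracts:
    """Subglottal + supraglottal tracts coupled at the glottis by a flow source.

    This mirrors, step for step, the acoustic half-pass of the fused
    simulation kernel and exists so the boundary behavior can be probed (and
    oracle-checked) in isolation with a prescribed glottal flow.
    """

    sub: AreaFunction
    sup: AreaFunction
    attenuation: float
    lung_reflection: float
    lip: LipRadiation
    rho: float = 1.14
    c: float = 350.0
    sub_state: WRAState = field(init=False)
    sup_state: WRAState = field(init=False)

    def __post_init__(self):
        self.sub_state = WRAState.zeros(self.sub.areas.size)
        self.sup_state = WRAState.zeros(self.sup.areas.size)

    @property
    def z_sub(self) -> float:
        return self.rho * self.c / self.sub.areas[-1]

    @property
    def pl_scale(self) -> float:
        return lung_source_scale(self.sub.areas.size, self.attenuation, self.lung_reflection)

    @property
    def z_sup(self) -> float:
        return self.rho * self.c / self.sup.areas[0]

    def glottal_boundary(self, ug: float, pl: float = 0.0) -> tuple[float, float]:
        """Advance both tracts one half-pass with flow ``ug`` injected at the glottis.

        Returns the total subglottal and supraglottal pressures (Ps, Pe) at
        the glottal ends.
        """
        att = self.attenuation
        fs_, bs_ = self.sub_state.forward, self.sub_state.backward
        fe_, be_ = self.sup_state.forward, self.sup_state.backward
        nfs, nbs = np.empty_like(fs_), np.empty_like(bs_)
        nfe, nbe = np.empty_like(fe_), np.empty_like(be_)
        _kernels.tract_half_pass(fs_, bs_, nfs, nbs, self.sub.reflections, att)
        _kernels.tract_half_pass(fe_, be_, nfe, nbe, self.sup.reflections, att)

        fg = att * fs_[-1]
        bg = att * be_[0]
        ps = 2.0 * fg - self.z_sub * ug
        pe = 2.0 * bg + self.z_sup * ug
        nbs[-1] = fg - self.z_sub * ug
        nfe[0] = bg + self.z_sup * ug

        bl = att * bs_[0]
        nfs[0] = self.lung_reflection * bl + (1.0 - self.lung_reflection) * 0.5 * pl * self.pl_scale

        fl = att * fe_[-1]
        nbe[-1], self.p_out = self.lip.step(fl)

        self.sub_state = WRAState(nfs, nbs)
        self.sup_state = WRAState(nfe, nbe)
        return ps, pe


def glottal_boundary(
    ug: float, tracts: CoupledTracts, pl: float = 0.0
) -> tuple[float, float, CoupledTracts]:
    """Inject glottal flow between the tracts for one half-pass (functional form)."""
    ps, pe = tracts.glottal_boundary(ug, pl)
    return ps, pe, tracts
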