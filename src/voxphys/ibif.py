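"""Subglottal impedance-based inverse filtering (IBIF) for neck-surface
acceleration, plus the single-notch oral-airflow inverse filter used as its
calibration reference.

The forward model propagates the glottal airflow down a lossy uniform
tracheal transmission line terminated by an absorbing lung load; at the
sensor position the local wall pressure drives a per-area mass-spring-damper
model of the neck skin, whose surface acceleration (scaled by the sensor
sensitivity) is the accelerometer output.  The model is linear and
time-invariant, applied in the frequency domain; the inverse applies the
conjugate transfer function with a Tikhonov floor to keep noise bounded near
transfer-function zeros.  Subject-specific parameters (skin mass/stiffness/
damping per area, tracheal length, sensor position) are calibrated by
global-best particle swarm optimization against a reference glottal airflow
obtained from oral-airflow inverse filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np


@dataclass(frozen=True)
class IBIFParams:
    """Subject-specific parameters of the trachea/skin transmission-line model."""

    skin_mass: float        # [kg/m^2]
    skin_stiffness: float   # [N/m^3]
    skin_damping: float     # [N s/m^3]
    trachea_length: float   # [m]
    sensor_depth: float     # sensor position below the glottis [m]
    sensitivity: float = 1.0  # [V/(m/s^2)]
    trachea_area: float = 2.5e-4  # [m^2]
    lung_reflection: float = -0.8
    wall_loss: float = 1.0  # propagation loss [1/m]
    rho: float = 1.14
    c: float = 350.0

    def __post_init__(self):
        for name in ("skin_mass", "skin_stiffness", "skin_damping",
                     "trachea_length", "sensor_depth", "sensitivity", "trachea_area"):
            if getattr(self, name) <= 0:
                raise ValueError(f"IBIFParams.{name} must be > 0")
        if self.sensor_depth >= self.trachea_length:
            raise ValueError("sensor position must lie above the tracheal end")

    @classmethod
    def from_params(cls, params: dict) -> "IBIFParams":
        p = params["ibif"]
        return cls(
            skin_mass=p["skin_mass"], skin_stiffness=p["skin_stiffness"],
            skin_damping=p["skin_damping"], trachea_length=p["trachea_length"],
            sensor_depth=p["sensor_depth"], sensitivity=p["sensitivity"],
            trachea_area=p["trachea_area"],
        )

    def skin_resonance(self) -> float:
        """Undamped skin resonance frequency [Hz]."""
        return float(np.sqrt(self.skin_stiffness / self.skin_mass) / (2.0 * np.pi))


@dataclass(frozen=True)
class NotchFilterSpec:
    """Conjugate zero pair with unity DC gain at the first vocal tract resonance."""

    center_hz: float
    radius: float = 1.0

    def __post_init__(self):
        if not 100.0 < self.center_hz < 1500.0:
            raise ValueError("notch center must lie in (100, 1500) Hz")
        if not 0.0 < self.radius <= 1.0:
            raise ValueError("zero radius must lie in (0, 1]")


def transfer_function(params: IBIFParams, freqs: np.ndarray) -> np.ndarray:
    """Complex ACC/Ug transfer function on a frequency grid [Hz].

    Tracheal line: flow ``Ug`` injected at the glottal end (x = 0), pressure
    at the sensor depth from the travelling-wave solution with the lung
    termination reflection; skin patch: acceleration response
    ``-w^2 / (k - w^2 m + j w d)`` to the local wall pressure.
    """
    w = 2.0 * np.pi * np.asarray(freqs, dtype=float)
    gamma = params.wall_loss + 1j * w / params.c
    z0 = params.rho * params.c / params.trachea_area
    L, xs = params.trachea_length, params.sensor_depth
    g = params.lung_reflection
    denom_line = 1.0 - g * np.exp(-2.0 * gamma * L)
    p_xs = z0 * (np.exp(-gamma * xs) + g * np.exp(-gamma * (2.0 * L - xs))) / denom_line
    skin = -(w ** 2) / (
        params.skin_stiffness - (w ** 2) * params.skin_mass + 1j * w * params.skin_damping
    )
    return params.sensitivity * skin * p_xs


def _fft_apply(x: np.ndarray, h_of_f, fs: float) -> np.ndarray:
    """Apply a frequency response via zero-padded FFT filtering."""
    x = np.asarray(x, dtype=float)
    n = x.size
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    X = np.fft.rfft(x, nfft)
    y = np.fft.irfft(X * h_of_f(freqs), nfft)
    return y[:n]


def forward_acc(ug: np.ndarray, params: IBIFParams, fs: float) -> np.ndarray:
    """Synthesize the neck-surface acceleration for a glottal flow [m^3/s].

    Linear and time-invariant; doubling the sensor sensitivity doubles the
    output.  Raises if the line response is near-singular (non-physical
    parameter combinations).
    """
    freqs = np.fft.rfftfreq(8192, 1.0 / fs)
    h = transfer_function(params, freqs)
    if not np.all(np.isfinite(h)):
        raise RuntimeError("unstable/singular transmission-line response")
    return _fft_apply(ug, lambda f: transfer_function(params, f), fs)


def ibif_inverse(
    acc: np.ndarray,
    params: IBIFParams,
    fs: float,
    tikhonov: float = 1e-4,
    band: tuple[float, float] = (60.0, 1100.0),
) -> np.ndarray:
    """Estimate the glottal airflow (mL/s) from a neck acceleration signal.

    Regularized inversion of the forward transfer function:
    ``Ug = ACC * conj(H) / (|H|^2 + (lam * max |H|)^2)`` — the floor is
    relative to the peak magnitude, so in-band bias stays negligible while
    noise near transfer-function zeros remains bounded.  The inversion is
    restricted to the conditioning band (the acceleration response falls as
    1/w^2 towards DC, so an unrestricted inverse would boost out-of-band
    leakage without physical information there); transitions are smooth
    half-cosines one third of an octave wide.
    """
    lo, hi = band

    def h_inv(freqs):
        h = transfer_function(params, freqs)
        h2 = np.abs(h) ** 2
        floor = (tikhonov * float(np.max(np.abs(h)))) ** 2
        if floor <= 0:
            raise RuntimeError("degenerate transfer function (all zero)")
        mask = np.ones_like(freqs)
        rise = (freqs >= lo * 0.8) & (freqs < lo)
        mask[freqs < lo * 0.8] = 0.0
        mask[rise] = 0.5 - 0.5 * np.cos(np.pi * (freqs[rise] - lo * 0.8) / (0.2 * lo))
        fall = (freqs > hi) & (freqs <= hi * 1.25)
        mask[freqs > hi * 1.25] = 0.0
        mask[fall] = 0.5 + 0.5 * np.cos(np.pi * (freqs[fall] - hi) / (0.25 * hi))
        return mask * np.conj(h) / (h2 + floor)

    return _fft_apply(acc, h_inv, fs) * 1e6


def band_rms_error(x: np.ndarray, ref: np.ndarray, fs: float,
                   band: tuple[float, float] = (60.0, 1100.0)) -> float:
    """Relative RMS error between two signals restricted to a frequency band.

    Both signals are demeaned and Hann-windowed before the spectral
    comparison so edge-discontinuity leakage does not set an error floor.
    """
    n = x.size
    w = np.hanning(n)
    X = np.fft.rfft((x - np.mean(x)) * w)
    R = np.fft.rfft((ref - np.mean(ref)) * w)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    m = (freqs >= band[0]) & (freqs <= band[1])
    num = np.sqrt(np.sum(np.abs(X[m] - R[m]) ** 2))
    den = np.sqrt(np.sum(np.abs(R[m]) ** 2))
    return float(num / den) if den > 0 else np.inf


_PSO_FIELDS = ("skin_mass", "skin_stiffness", "skin_damping", "trachea_length", "sensor_depth")


def default_bounds(nominal: IBIFParams, rel: float = 0.5) -> dict:
    """+/- ``rel`` bounds around nominal values for the calibrated fields."""
    return {
        f: ((1 - rel) * getattr(nominal, f), (1 + rel) * getattr(nominal, f))
        for f in _PSO_FIELDS
    }


def calibrate_pso(
    acc: np.ndarray,
    reference_flow: np.ndarray,
    fs: float,
    bounds: dict,
    seed: int = 0,
    swarm_size: int = 20,
    iters: int = 40,
    nominal: IBIFParams | None = None,
    inertia: float = 0.72,
    c_cog: float = 1.49,
    c_soc: float = 1.49,
    polish: bool = True,
) -> tuple[IBIFParams, float]:
    """Global-best PSO fit of the IBIF parameters to a reference airflow.

    Minimizes the relative RMS waveform error (60-1,100 Hz band) between the
    inverse-filtered acceleration and ``reference_flow`` (mL/s).  Particles
    are clipped to ``bounds``; seed-reproducible.  Returns the best
    parameters and the final cost.  ``swarm_size=1, iters=0`` degenerates to
    evaluating the initial particle.
    """
    if nominal is None:
        nominal = IBIFParams(
            skin_mass=2.0, skin_stiffness=1.3e6, skin_damping=600.0,
            trachea_length=0.115, sensor_depth=0.05,
        )
    rng = np.random.default_rng(seed)
    names = [f for f in _PSO_FIELDS if f in bounds]
    lo = np.array([bounds[f][0] for f in names])
    hi = np.array([bounds[f][1] for f in names])

    def make(vec: np.ndarray) -> IBIFParams:
        fields = dict(zip(names, vec))
        if "sensor_depth" in fields and "trachea_length" in fields:
            fields["sensor_depth"] = min(
                fields["sensor_depth"], 0.95 * fields["trachea_length"]
            )
        return replace(nominal, **fields)

    # waveform error is scored on the interior of the synchronized overlap:
    # the outer ~10% on each side carries finite-window inversion edge
    # effects and is excluded
    trim = max(int(0.1 * acc.size), 1)
    sl = slice(trim, acc.size - trim)

    def cost(vec: np.ndarray) -> float:
        try:
            est = ibif_inverse(acc, make(vec), fs)
        except (ValueError, RuntimeError):
            return np.inf
        return band_rms_error(est[sl], reference_flow[sl], fs)

    pos = lo + (hi - lo) * rng.random((swarm_size, len(names)))
    pos[0] = np.clip([getattr(nominal, f) for f in names], lo, hi)  # seed with nominal
    vel = 0.1 * (hi - lo) * (rng.random((swarm_size, len(names))) - 0.5)
    pbest = pos.copy()
    pcost = np.array([cost(p) for p in pos])
    gbest = pbest[int(np.argmin(pcost))].copy()
    gcost = float(np.min(pcost))
    init_cost = gcost

    for _ in range(iters):
        r1 = rng.random((swarm_size, len(names)))
        r2 = rng.random((swarm_size, len(names)))
        vel = inertia * vel + c_cog * r1 * (pbest - pos) + c_soc * r2 * (gbest - pos)
        pos = np.clip(pos + vel, lo, hi)
        for i in range(swarm_size):
            ci = cost(pos[i])
            if ci < pcost[i]:
                pcost[i] = ci
                pbest[i] = pos[i].copy()
                if ci < gcost:
                    gcost = float(ci)
                    gbest = pos[i].copy()
    if polish and iters > 0:
        # derivative-free local refinement from the swarm best; the swarm
        # handles the global structure, Powell the final basin
        from scipy.optimize import minimize

        res = minimize(
            cost, gbest, method="Powell",
            bounds=list(zip(lo, hi)),
            options={"maxfev": 2500, "xtol": 1e-7, "ftol": 1e-11},
        )
        if np.isfinite(res.fun) and res.fun < gcost:
            gbest, gcost = np.clip(res.x, lo, hi), float(res.fun)

    best = make(gbest)
    if iters > 0 and gcost >= init_cost:
        best = replace(best)  # no improvement over init; flagged via cost equality
    return best, gcost


def ovv_notch_inverse(ovv: np.ndarray, fs: float, spec: NotchFilterSpec) -> np.ndarray:
    """Single-notch inverse filter of the oral airflow (first formant removal).

    FIR with a conjugate pair of zeros at the notch center and unity gain at
    DC.  Input and output share units (mL/s).
    """
    w0 = 2.0 * np.pi * spec.center_hz / fs
    r = spec.radius
    b = np.array([1.0, -2.0 * r * np.cos(w0), r * r])
    b = b / b.sum()  # unity DC gain
    x = np.asarray(ovv, dtype=float)
    y = np.empty_like(x)
    y[0] = b[0] * x[0] + b[1:].sum() * x[0]
    y[1] = b[0] * x[1] + b[1] * x[0] + b[2] * x[0]
    y[2:] = b[0] * x[2:] + b[1] * x[1:-1] + b[2] * x[:-2]
    return y


def optimize_notch_center(
    ovv: np.ndarray,
    fs: float,
    band: tuple[float, float] = (300.0, 1200.0),
    n_grid: int = 91,
) -> NotchFilterSpec:
    """Locate the first vocal tract resonance and center the notch on it.

    The spectral envelope of the oral-airflow signal is obtained by cepstral
    smoothing (liftering below ~60% of the glottal period removes the
    harmonic comb while keeping the formant structure); the envelope maximum
    inside the candidate band, refined parabolically, is the first formant.
    ``n_grid`` is kept for interface stability but unused by this estimator.
    """
    from .features import TooFewCyclesError, UnvoicedError, _autocorr_period

    x = np.asarray(ovv, dtype=float)
    try:
        period, peak = _autocorr_period(x, fs)
    except UnvoicedError as exc:
        raise ValueError(f"cannot tune notch center: {exc}") from exc
    if peak < 0.5:
        raise ValueError("cannot tune notch center: no periodicity in the signal")

    n = int(2 ** np.ceil(np.log2(x.size)))
    logmag = np.log(np.abs(np.fft.rfft((x - np.mean(x)) * np.hanning(x.size), n)) + 1e-12)
    ceps = np.fft.irfft(logmag)
    qc = max(int(0.6 * period), 2)
    ceps[qc:n - qc + 1] = 0.0
    env = np.fft.rfft(ceps).real
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    m = (freqs >= band[0]) & (freqs <= band[1])
    idx = np.flatnonzero(m)
    k = idx[int(np.argmax(env[idx]))]
    if 0 < k < env.size - 1:  # parabolic sub-bin refinement
        den = env[k - 1] - 2 * env[k] + env[k + 1]
        if den != 0:
            k = k + float(np.clip(0.5 * (env[k - 1] - env[k + 1]) / den, -0.5, 0.5))
    center = float(k * fs / n)
    return NotchFilterSpec(center_hz=float(np.clip(center, band[0], band[1])))
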