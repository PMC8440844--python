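"""Signal conditioning and aerodynamic/acoustic feature extraction.

The conditioning chain mirrors the laboratory analysis: a 10th-order
Chebyshev type-II low-pass at 1,100 Hz, polyphase decimation to 8,192 Hz,
then a 4th-order Butterworth high-pass at 60 Hz, all applied zero-phase.

Seven features are extracted from a voiced analysis window (default 50 ms)
of the glottal airflow plus a calibrated acoustic channel:

====== ======================================================== ========
ACFL   mean per-cycle peak-to-peak amplitude of the AC airflow  mL/s
MFDR   mean per-cycle magnitude of the steepest negative slope  L/s^2
OQ     open time / cycle period                                 %
SQ     opening time / closing time                              --
H1-H2  dB difference of the first two flow harmonics            dB
fo     fundamental frequency (1 / mean period)                  Hz
SPL    20 log10(RMS / 20 uPa) of the acoustic channel           dB SPL
====== ======================================================== ========

Airflow inputs are expected in mL/s.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sig


class UnvoicedError(RuntimeError):
    """No periodicity found in the analysis window."""


class TooFewCyclesError(RuntimeError):
    """Fewer glottal cycles than the feature definitions require."""


@dataclass(frozen=True)
class ConditioningSpec:
    """Anti-alias/low-frequency conditioning applied before feature extraction."""

    lp_cutoff: float = 1100.0
    lp_order: int = 10
    lp_stop_atten: float = 60.0   # ripple spec is a design choice, not printed
    target_fs: float = 8192.0
    hp_cutoff: float = 60.0
    hp_order: int = 4
    zero_phase: bool = True

    @classmethod
    def from_params(cls, params: dict) -> "ConditioningSpec":
        c = params["conditioning"]
        return cls(
            lp_cutoff=c["lp_cutoff"], lp_order=c["lp_order"],
            lp_stop_atten=c["lp_stop_atten"], target_fs=c["target_fs"],
            hp_cutoff=c["hp_cutoff"], hp_order=c["hp_order"],
        )


@dataclass(frozen=True)
class FeatureVector:
    """The seven regression inputs."""

    acfl: float   # mL/s
    mfdr: float   # L/s^2
    oq: float     # %
    sq: float     # dimensionless
    h1h2: float   # dB
    fo: float     # Hz
    spl: float    # dB SPL

    def __post_init__(self):
        vals = [self.acfl, self.mfdr, self.oq, self.sq, self.h1h2, self.fo, self.spl]
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("all features must be finite")
        if not 0.0 < self.oq <= 100.0:
            raise ValueError(f"OQ={self.oq} outside (0, 100]")
        if self.sq <= 0 or self.fo <= 0:
            raise ValueError("SQ and fo must be > 0")

    NAMES = ("acfl", "mfdr", "oq", "sq", "h1h2", "fo", "spl")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in self.NAMES])


def condition(signal: np.ndarray, fs: float, spec: ConditioningSpec = ConditioningSpec()) -> np.ndarray:
    """Condition a signal to the common 8,192 Hz analysis rate.

    Zero-phase low-pass, rational-rate polyphase decimation, zero-phase
    high-pass, in that order.  ``fs`` must be at least twice the target rate.
    """
    signal = np.asarray(signal, dtype=float)
    if fs < 2 * spec.target_fs:
        raise ValueError(f"input rate {fs} Hz below the required {2 * spec.target_fs:.0f} Hz")
    sos_lp = sig.cheby2(
        spec.lp_order, spec.lp_stop_atten, spec.lp_cutoff, btype="low", fs=fs, output="sos"
    )
    x = sig.sosfiltfilt(sos_lp, signal) if spec.zero_phase else sig.sosfilt(sos_lp, signal)
    ratio = Fraction(int(round(spec.target_fs)), int(round(fs)))
    x = sig.resample_poly(x, ratio.numerator, ratio.denominator)
    sos_hp = sig.butter(spec.hp_order, spec.hp_cutoff, btype="high", fs=spec.target_fs, output="sos")
    return sig.sosfiltfilt(sos_hp, x) if spec.zero_phase else sig.sosfilt(sos_hp, x)


def _autocorr_period(x: np.ndarray, fs: float, fo_min: float = 70.0, fo_max: float = 500.0):
    """(period in samples, normalized peak) from the autocorrelation."""
    x = x - np.mean(x)
    if np.allclose(x, 0.0):
        raise UnvoicedError("silent window")
    r = sig.correlate(x, x, mode="full")[x.size - 1:]
    r /= r[0]
    lo = max(int(fs / fo_max), 2)
    hi = min(int(fs / fo_min), x.size - 2)
    if hi <= lo:
        raise UnvoicedError("window too short for the fo search band")
    k = lo + int(np.argmax(r[lo:hi]))
    # parabolic refinement
    if 0 < k < r.size - 1:
        denom = r[k - 1] - 2 * r[k] + r[k + 1]
        delta = 0.5 * (r[k - 1] - r[k + 1]) / denom if denom != 0 else 0.0
    else:  # pragma: no cover
        delta = 0.0
    return k + float(np.clip(delta, -0.5, 0.5)), float(r[k])


def segment_cycles(flow: np.ndarray, fs: float, oq_threshold: float = 0.10) -> dict:
    """Delimit glottal cycles at flow minima and locate per-cycle landmarks.

    Returns a dict with ``boundaries`` (cycle-start indices), ``period``
    (mean, samples) and per-cycle landmark arrays (``i_max``, ``i_min``,
    ``i_mfdr``, ``t_open``, ``t_opening``, ``t_closing`` in samples).  The
    open phase is delimited by crossings of a threshold at ``oq_threshold``
    of the cycle's peak-to-peak amplitude above its minimum.
    """
    flow = np.asarray(flow, dtype=float)
    period, peak = _autocorr_period(flow, fs)
    if peak < 0.5:
        raise UnvoicedError(f"autocorrelation peak {peak:.2f} < 0.5")

    # boundaries from a lightly smoothed copy so flat/rippled closed phases
    # do not jitter the argmin; landmarks are measured on the raw signal
    k = max(int(round(period / 8)), 1)
    kernel = np.ones(k) / k
    smooth = np.convolve(flow, kernel, mode="same")
    t0 = int(round(period))
    first = int(np.argmin(smooth[:t0]))
    bounds = [first]
    while bounds[-1] + 1.3 * period < flow.size:
        lo = bounds[-1] + int(0.7 * period)
        hi = min(bounds[-1] + int(1.3 * period) + 1, flow.size)
        bounds.append(lo + int(np.argmin(smooth[lo:hi])))
    bounds = np.asarray(bounds)
    if bounds.size < 3:
        raise TooFewCyclesError(f"only {bounds.size - 1} cycles found")

    i_max, i_min, i_mfdr = [], [], []
    t_open, t_opening, t_closing = [], [], []
    dflow = np.gradient(flow) * fs
    for a, b in zip(bounds[:-1], bounds[1:]):
        seg = flow[a:b]
        im = a + int(np.argmax(seg))
        i_max.append(im)
        i_min.append(a + int(np.argmin(seg)))
        i_mfdr.append(a + int(np.argmin(dflow[a:b])))
        thr = seg.min() + oq_threshold * (seg.max() - seg.min())
        idx = np.flatnonzero(seg >= thr) if oq_threshold == 0 else np.flatnonzero(seg > thr)
        if idx.size == 0:  # degenerate flat cycle
            t_open.append(0.0)
            t_opening.append(0.5)
            t_closing.append(0.5)
            continue
        # sub-sample threshold crossings (linear interpolation)
        i0, i1 = idx[0], idx[-1]
        open_start = float(i0)
        if i0 > 0 and seg[i0] != seg[i0 - 1]:
            open_start = i0 - 1 + (thr - seg[i0 - 1]) / (seg[i0] - seg[i0 - 1])
        open_end = float(i1)
        if i1 < seg.size - 1 and seg[i1] != seg[i1 + 1]:
            open_end = i1 + (seg[i1] - thr) / (seg[i1] - seg[i1 + 1])
        # parabolic refinement of the peak instant
        peak_rel = float(im - a)
        j = im - a
        if 0 < j < seg.size - 1:
            den = seg[j - 1] - 2 * seg[j] + seg[j + 1]
            if den != 0:
                peak_rel = j + float(np.clip(0.5 * (seg[j - 1] - seg[j + 1]) / den, -0.5, 0.5))
        if i0 == 0 and i1 == seg.size - 1:
            # no closed phase in this cycle: the open span is the cycle itself
            open_start, open_end = 0.0, float(b - a)
            t_open.append(float(b - a))
        else:
            t_open.append(max(open_end - open_start, 1.0))
        t_opening.append(max(peak_rel - open_start, 0.5))
        t_closing.append(max(open_end - peak_rel, 0.5))
    return {
        "boundaries": bounds,
        "period": float(period),  # autocorrelation-refined (sub-sample)
        "i_max": np.array(i_max),
        "i_min": np.array(i_min),
        "i_mfdr": np.array(i_mfdr),
        "t_open": np.array(t_open),
        "t_opening": np.array(t_opening),
        "t_closing": np.array(t_closing),
    }


def spl_from_pressure(p: np.ndarray, p_ref: float = 20e-6) -> float:
    """Sound pressure level in dB SPL from a pressure waveform in Pa."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty signal")
    rms = float(np.sqrt(np.mean(p ** 2)))
    if rms <= 0.0:
        raise ValueError("all-zero signal has no defined level")
    return 20.0 * np.log10(rms / p_ref)


def _harmonic_magnitude(x: np.ndarray, fs: float, f_target: float, search_hz: float) -> float:
    win = np.hanning(x.size)
    spec = np.abs(np.fft.rfft((x - np.mean(x)) * win))
    freqs = np.fft.rfftfreq(x.size, 1.0 / fs)
    mask = np.abs(freqs - f_target) <= search_hz
    if not np.any(mask):  # pragma: no cover
        raise ValueError("harmonic search band empty")
    return float(np.max(spec[mask]))


def extract_features(
    flow: np.ndarray,
    mic_or_acc: np.ndarray,
    fs: float,
    window: float = 0.05,
    cal_db: float = 0.0,
    oq_threshold: float = 0.10,
    h1h2_search_hz: float = 20.0,
    mic_fs: float | None = None,
) -> FeatureVector:
    """Extract the seven-feature vector from the final ``window`` seconds.

    ``flow`` is glottal airflow in mL/s at the common analysis rate; the
    acoustic channel (Pa) may run at its own rate ``mic_fs``.  ``cal_db`` is
    an additive SPL calibration.  Raises :class:`UnvoicedError` /
    :class:`TooFewCyclesError` when the window does not contain at least
    three delimitable cycles.
    """
    flow = np.asarray(flow, dtype=float)
    n = int(round(window * fs))
    if flow.size < n:
        raise ValueError("flow shorter than the analysis window")
    w = flow[-n:]
    cyc = segment_cycles(w, fs, oq_threshold=oq_threshold)
    n_cycles = cyc["boundaries"].size - 1
    if n_cycles < 3:
        raise TooFewCyclesError(f"{n_cycles} cycles < 3")

    acfl = float(np.mean(w[cyc["i_max"]] - w[cyc["i_min"]]))
    dflow = np.gradient(w) * fs
    mfdr = float(np.mean(-dflow[cyc["i_mfdr"]])) / 1000.0  # mL/s^2 -> L/s^2
    # sustained phonation: the autocorrelation period is the robust cycle
    # length; per-cycle boundary jitter would alias into OQ and fo otherwise
    period = cyc["period"]
    oq = float(np.mean(cyc["t_open"])) / period * 100.0
    sq = float(np.mean(cyc["t_opening"] / cyc["t_closing"]))
    fo = fs / period
    h1 = _harmonic_magnitude(w, fs, fo, h1h2_search_hz)
    h2 = _harmonic_magnitude(w, fs, 2.0 * fo, h1h2_search_hz)
    h1h2 = 20.0 * np.log10(h1 / h2)

    mfs = mic_fs if mic_fs is not None else fs
    m = np.asarray(mic_or_acc, dtype=float)
    nm = int(round(window * mfs))
    spl = spl_from_pressure(m[-nm:]) + cal_db
    return FeatureVector(acfl=acfl, mfdr=mfdr, oq=min(oq, 100.0), sq=sq, h1h2=h1h2, fo=fo, spl=spl)


def iop_reference_pressure(
    iop: np.ndarray,
    fs: float,
    syllable_marks: np.ndarray | None = None,
    lp_cutoff: float = 80.0,
    lp_order: int = 5,
    target_fs: float = 256.0,
    min_plateau_s: float = 0.03,
) -> float:
    """Subglottal reference pressure (cm H2O) from an intraoral-pressure record.

    The IOP record of a /p/-vowel syllable string is low-pass filtered
    (5th-order Butterworth, zero phase), decimated to 256 Hz, and segmented
    into occlusion plateaus.  Each vowel's driving pressure is extrapolated
    as the mean of its two flanking plateaus; the three middle syllables are
    averaged.  ``iop`` must be calibrated in cm H2O.
    """
    iop = np.asarray(iop, dtype=float)
    if fs > 2 * target_fs:
        sos = sig.butter(lp_order, lp_cutoff, btype="low", fs=fs, output="sos")
        x = sig.sosfiltfilt(sos, iop)
        ratio = Fraction(int(round(target_fs)), int(round(fs)))
        x = sig.resample_poly(x, ratio.numerator, ratio.denominator)
    else:
        x = iop
        target_fs = fs

    thr = 0.5 * np.percentile(x, 98)
    above = x > thr
    edges = np.flatnonzero(np.diff(above.astype(int)))
    runs = []
    start = 0 if above[0] else None
    for e in edges:
        if above[e]:  # falling edge
            runs.append((start, e + 1))
            start = None
        else:
            start = e + 1
    if start is not None and above[-1]:
        runs.append((start, x.size))
    min_len = int(min_plateau_s * target_fs)
    plateaus = []
    for a, b in runs:
        if b - a < min_len:
            continue
        trim = (b - a) // 4
        plateaus.append(float(np.mean(x[a + trim: b - trim])))
    n_syll = len(plateaus) - 1
    if n_syll < 5:
        raise ValueError(f"only {n_syll} syllables detected; need >= 5 to take the middle three")
    per_syllable = 0.5 * (np.array(plateaus[:-1]) + np.array(plateaus[1:]))
    mid = n_syll // 2
    chosen = per_syllable[mid - 1: mid + 2]
    return float(np.mean(chosen))
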