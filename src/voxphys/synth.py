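"""Sustained-phonation synthesis and Monte Carlo batch generation.

``simulate`` wires posturing, body-cover dynamics, glottal flow and the
wave-reflection tracts into one 800 ms run; ``sample_controls`` draws control
points from the discrete sustained-phonation lattice (muscle activations and
lung pressure); ``run_batch`` maps simulations to feature/target summary rows
for the training table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from . import _kernels, features as feat
from .params import default_params
from .posture import MuscleActivation, posture_from_activations
from .tbcm import pack_config, rules_update
from .tract import LipRadiation, load_area_function, lung_source_scale

CMH2O = 98.0665  # Pa per cm H2O


@dataclass(frozen=True)
class SimulationControls:
    """Control parameters of one sustained-phonation run."""

    pl: float                      # lung pressure [Pa]
    act: MuscleActivation
    vowel: str = "ae"              # "ae" or "aa"
    sex: str = "female"
    fs: float = 44100.0
    duration: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.pl < 0:
            raise ValueError("lung pressure must be >= 0")
        if self.vowel not in ("ae", "aa"):
            raise ValueError(f"unknown vowel {self.vowel!r}")
        if self.sex not in ("female", "male"):
            raise ValueError(f"unknown sex label {self.sex!r}")


@dataclass
class SimulationResult:
    """Time series at ``fs`` plus the controls that produced them."""

    controls: SimulationControls
    ug: np.ndarray      # glottal flow [m^3/s]
    ps: np.ndarray      # subglottal pressure at the glottal end [Pa]
    pe: np.ndarray      # supraglottal pressure [Pa]
    pc: np.ndarray      # vocal fold collision pressure [Pa]
    pout: np.ndarray    # radiated pressure at the lips [Pa]
    oscillating: bool = False
    failed: bool = False
    blowup_index: int = -1
    strain: float = 0.0
    xi02: float = 0.0

    @property
    def fs(self) -> float:
        return self.controls.fs


@lru_cache(maxsize=8)
def _tract_setup(vowel: str, sex: str, fs: float, c: float, rho: float):
    sup = load_area_function(f"area_{sex}_{vowel}.csv", fs=fs, c=c)
    sub = load_area_function("area_subglottal.csv", fs=fs, c=c, reverse=True)
    lip = LipRadiation(area=float(sup.areas[-1]), fs_update=2.0 * fs, rho=rho, c=c)
    return sub, sup, lip


def simulate(controls: SimulationControls, params: dict | None = None) -> SimulationResult:
    """Run one sustained-phonation simulation (deterministic for fixed inputs).

    Numerical blowup is flagged on the result rather than raised so Monte
    Carlo batches keep running.
    """
    if params is None:
        params = default_params()
    post = posture_from_activations(controls.act, params)
    config = rules_update(post, params, a_TA=controls.act.a_TA)

    fl = params["flow"]
    sub, sup, lip = _tract_setup(controls.vowel, controls.sex, controls.fs, fl["c_air"], fl["rho_air"])

    n_steps = int(round(controls.duration * controls.fs))
    dt = 1.0 / controls.fs
    ramp = max(int(params["simulation"]["onset_ramp"] * controls.fs), 1)

    ug, ps, pe, pc, pout, blow = _kernels.simulate_core(
        pack_config(config),
        post.xi02, config.x_l0_offset, config.x_u0_offset, post.gap_area,
        fl["k_trans"], fl["rho_air"], fl["c_air"],
        sub.areas, sub.reflections, sup.areas, sup.reflections,
        params["tract"]["attenuation"], params["tract"]["lung_reflection"],
        lung_source_scale(
            sub.areas.size, params["tract"]["attenuation"], params["tract"]["lung_reflection"]
        ),
        lip.b0, lip.b1, lip.a1,
        controls.pl, n_steps, dt, ramp,
    )
    res = SimulationResult(
        controls=controls, ug=ug, ps=ps, pe=pe, pc=pc, pout=pout,
        failed=blow >= 0, blowup_index=blow, strain=post.strain, xi02=post.xi02,
    )
    if not res.failed:
        res.oscillating = _is_oscillating(ug, controls.fs)
    return res


def _is_oscillating(ug: np.ndarray, fs: float, window: float = 0.1) -> bool:
    """Sustained AC flow with clear periodicity over the final ``window`` seconds."""
    n = int(window * fs)
    w = ug[-n:]
    if np.ptp(w) < 1e-6:  # < 1 mL/s peak-to-peak
        return False
    try:
        _, peak = feat._autocorr_period(w, fs)
    except feat.UnvoicedError:
        return False
    return bool(peak >= 0.5)


def lattice_axes(grid: dict) -> dict[str, np.ndarray]:
    """Discrete control lattice (inclusive bounds) from a grid spec."""
    axes = {}
    for name, g in grid.items():
        n = int(round((g["hi"] - g["lo"]) / g["step"])) + 1
        axes[name] = np.round(np.linspace(g["lo"], g["hi"], n), 10)
    return axes


def sample_controls(
    n: int,
    seed: int,
    params: dict | None = None,
    mode: str = "grid",
    vowel: str = "ae",
    sex: str = "female",
    fs: float = 44100.0,
    duration: float = 0.8,
) -> list[SimulationControls]:
    """Draw ``n`` control points from the sustained-phonation lattice.

    ``grid`` mode draws uniformly at random on the discrete lattice
    (Monte Carlo); ``uniform`` draws continuous values inside the ranges.
    Reproducible under ``seed``.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    if params is None:
        params = default_params()
    axes = lattice_axes(params["grid"])
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        draw = {}
        for name, vals in axes.items():
            if mode == "grid":
                draw[name] = float(rng.choice(vals))
            else:
                draw[name] = float(rng.uniform(vals[0], vals[-1]))
        act = MuscleActivation(
            a_LCA=draw["a_LCA"], a_IA=draw["a_IA"], a_PCA=draw["a_PCA"],
            a_CT=draw["a_CT"], a_TA=draw["a_TA"],
        )
        out.append(SimulationControls(
            pl=draw["P_L"], act=act, vowel=vowel, sex=sex, fs=fs, duration=duration,
        ))
    return out


def per_cycle_peak_mean(x: np.ndarray, fs: float, fo: float) -> float:
    """Mean over cycles of the per-cycle maximum of ``x`` (cycle length 1/fo)."""
    t0 = max(int(round(fs / fo)), 1)
    n_cyc = x.size // t0
    if n_cyc == 0:
        return float(np.max(x))
    return float(np.mean([np.max(x[i * t0:(i + 1) * t0]) for i in range(n_cyc)]))


def summarize(result: SimulationResult, params: dict, pc_mode: str = "peak") -> dict:
    """Feature/target summary row for one simulation.

    Features follow the laboratory conditioning chain; all scalars use the
    final feature window only.  Raises the feature extractor's errors for
    unvoiced/too-short signals (callers record them as filtered rows).
    """
    sim = params["simulation"]
    window = sim["feature_window"]
    fs = result.fs
    spec = feat.ConditioningSpec.from_params(params)
    flow_ml = feat.condition(result.ug * 1e6, fs, spec)
    fv = feat.extract_features(
        flow_ml, result.pout, spec.target_fs, window=window,
        oq_threshold=params["features"]["oq_threshold"],
        h1h2_search_hz=params["features"]["h1h2_search_hz"],
        mic_fs=fs,
    )
    nwin = int(window * fs)
    ps_mean = float(np.mean(result.ps[-nwin:])) / CMH2O
    pc_win = result.pc[-nwin:]
    if pc_mode == "peak":
        pc_scalar = per_cycle_peak_mean(pc_win, fs, fv.fo) / CMH2O
    elif pc_mode == "mean":
        contact = pc_win[pc_win > 0]
        pc_scalar = float(np.mean(contact)) / CMH2O if contact.size else 0.0
    else:
        raise ValueError(f"unknown pc_mode {pc_mode!r}")
    row = {name: getattr(fv, name) for name in feat.FeatureVector.NAMES}
    row.update(
        ps=ps_mean, pc=pc_scalar,
        a_CT=result.controls.act.a_CT, a_TA=result.controls.act.a_TA,
        a_LCA=result.controls.act.a_LCA, a_IA=result.controls.act.a_IA,
        a_PCA=result.controls.act.a_PCA, pl=result.controls.pl,
        oscillating=result.oscillating,
    )
    return row


def run_batch(
    controls_list: list[SimulationControls],
    params: dict | None = None,
    workers: int = 1,
    pc_mode: str = "peak",
) -> tuple[list[dict], list[dict]]:
    """Simulate a batch and summarize each run.

    Returns ``(rows, failures)``; failures carry the item index and reason
    (numerical blowup, no oscillation, or unvoiced/short feature window), so
    batch accounting is complete.  Rows are ordered by item index regardless
    of worker count.
    """
    if not controls_list:
        raise ValueError("empty batch")
    if params is None:
        params = default_params()

    def one(i: int, ctl: SimulationControls):
        try:
            res = simulate(ctl, params)
        except Exception as exc:  # posture/config errors
            return i, None, f"error: {exc}"
        if res.failed:
            return i, None, f"blowup at index {res.blowup_index}"
        if not res.oscillating:
            return i, None, "no oscillation"
        try:
            return i, summarize(res, params, pc_mode=pc_mode), None
        except (feat.UnvoicedError, feat.TooFewCyclesError, ValueError) as exc:
            return i, None, f"features: {exc}"

    if workers > 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=workers)(
            delayed(one)(i, c) for i, c in enumerate(controls_list)
        )
    else:
        results = [one(i, c) for i, c in enumerate(controls_list)]

    rows, failures = [], []
    for i, row, err in sorted(results, key=lambda t: t[0]):
        if row is not None:
            row["index"] = i
            rows.append(row)
        else:
            failures.append({"index": i, "reason": err})
    return rows, failures
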