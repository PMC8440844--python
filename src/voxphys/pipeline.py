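"""End-to-end orchestration: dataset generation, training, evaluation
reports, and self-contained fixture generation.

Every stage writes its artifacts under one output directory together with a
``state.json`` recording the configuration hash, so reruns with an unchanged
configuration skip completed stages.  All randomness flows from a single
root seed, split per stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from . import dataset as ds
from . import regressor as reg
from .params import default_params, load_params
from .synth import run_batch, sample_controls

log = logging.getLogger("voxphys")


@dataclass
class PipelineConfig:
    """Serializable configuration of a full training/evaluation run."""

    out_dir: str = "voxphys_run"
    n_sims: int = 4000
    seed: int = 7
    fs: float = 44100.0
    duration: float = 0.8
    vowel: str = "ae"
    sex: str = "female"
    workers: int = 1
    epochs: int = 100
    batch_size: int = 64
    learning_rate: float = 1e-3
    spl_correction_db: float = -28.5
    ps_correction_cmh2o: float = -3.37
    arch_grid: list = field(default_factory=lambda: [[4, 2], [128, 4]])
    cases: list = field(default_factory=lambda: ["I", "II"])
    params_path: str | None = None

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage_seed(root_seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2 ** 31 - 1)


def run_full_pipeline(config: PipelineConfig) -> dict:
    """make-dataset -> filter/correct/normalize -> train -> evaluate -> report.

    Returns a dict of artifact paths.  Stages completed under the same
    configuration hash are skipped on rerun.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    state_path = out / "state.json"
    chash = config.config_hash()
    state = {"config_hash": chash, "stages": {}}
    if state_path.exists():
        prev = json.loads(state_path.read_text())
        if prev.get("config_hash") == chash:
            state = prev

    params = load_params(config.params_path) if config.params_path else default_params()

    def done(stage: str) -> bool:
        rec = state["stages"].get(stage)
        return bool(rec) and all(Path(p).exists() for p in rec["artifacts"])

    def mark(stage: str, artifacts: list[str], **extra) -> None:
        state["stages"][stage] = {"artifacts": artifacts, "time": time.time(), **extra}
        state_path.write_text(json.dumps(state, indent=2, default=str))

    rows_path = out / "rows.csv"
    if not done("simulate"):
        t0 = time.time()
        ctls = sample_controls(
            config.n_sims, seed=_stage_seed(config.seed, "controls"), params=params,
            vowel=config.vowel, sex=config.sex, fs=config.fs, duration=config.duration,
        )
        rows, failures = run_batch(ctls, params, workers=config.workers)
        pd.DataFrame(rows).to_csv(rows_path, index=False)
        (out / "failures.json").write_text(json.dumps(failures, indent=1))
        log.info("simulate: %d rows, %d failures in %.1fs",
                 len(rows), len(failures), time.time() - t0)
        mark("simulate", [str(rows_path)], n_rows=len(rows), n_failures=len(failures))

    table_path = out / "table.csv"
    if not done("table"):
        rows = pd.read_csv(rows_path)
        table, tally = ds.build_table(
            rows, seed=_stage_seed(config.seed, "split"),
            spl_db=config.spl_correction_db, ps_cmh2o=config.ps_correction_cmh2o,
        )
        table.to_csv(table_path)
        log.info("table: %s", tally)
        mark("table", [str(table_path)], tally=tally)

    table = ds.TrainingTable.from_csv(table_path)
    spec = reg.TrainingSpec(
        learning_rate=config.learning_rate, epochs=config.epochs,
        batch_size=config.batch_size, seed=_stage_seed(config.seed, "train"),
    )
    metrics_rows = []
    model_paths = {}
    for case in config.cases:
        for neurons, layers in config.arch_grid:
            key = f"model_case{case}_{neurons}x{layers}"
            mpath = out / f"{key}.json"
            hpath = out / f"{key}_history.json"
            if not done(key):
                arch = reg.ArchitectureSpec.for_case(case, layers, neurons)
                model, hist = reg.train(table, arch, spec, case=case)
                reg.save_model(model, mpath)
                hpath.write_text(json.dumps(hist))
                mark(key, [str(mpath), str(hpath)])
            model = reg.load_model(mpath)
            met = reg.evaluate(model, table.test, table, case=case)
            for tgt in ds.TARGETS:
                metrics_rows.append({
                    "case": case, "neurons": neurons, "layers": layers, "target": tgt,
                    "mae": met.mae[tgt], "mae_pct": met.mae_pct[tgt],
                    "rmse": met.rmse[tgt], "r2": met.r2[tgt], "mape": met.mape[tgt],
                })
            model_paths[key] = str(mpath)

    metrics = pd.DataFrame(metrics_rows)
    metrics_path = out / "metrics.csv"
    metrics.to_csv(metrics_path, index=False)
    report_path = out / "report.md"
    with open(report_path, "w") as fh:
        fh.write(f"# voxphys evaluation report\n\nconfig hash: {chash}\n\n")
        fh.write(metrics.to_markdown(index=False))
        fh.write("\n")
    mark("report", [str(metrics_path), str(report_path)])
    return {"rows": str(rows_path), "table": str(table_path),
            "metrics": str(metrics_path), "report": str(report_path), **model_paths}


# ---------------------------------------------------------------------------
# synthetic unit-test fixtures


def glottal_pulse_train(
    fo: float, fs: float, duration: float, dc: float = 150.0, ac: float = 300.0,
    open_quotient: float = 0.6, jitter: float = 0.0, seed: int = 0,
) -> np.ndarray:
    """Rectified-power glottal-flow-like pulse train in mL/s.

    Each cycle is a raised half-sine confined to the open phase (fractional
    width ``open_quotient``); optional per-cycle amplitude jitter.
    """
    rng = np.random.default_rng(seed)
    n = int(duration * fs)
    t0 = fs / fo
    x = np.zeros(n)
    start = 0.0
    while start < n:
        width = open_quotient * t0
        idx = np.arange(int(start), min(int(start + width), n))
        phase = (idx - start) / width
        amp = ac * (1.0 + jitter * (rng.random() - 0.5))
        x[idx] = amp * np.sin(np.pi * phase) ** 2
        start += t0
    return dc + x


def trapezoid_iop_train(
    n_syllables: int, plateau: float | list, fs: float = 2000.0,
    occlusion_s: float = 0.12, vowel_s: float = 0.18, ramp_s: float = 0.03,
    noise_rms: float = 0.0, seed: int = 0,
) -> np.ndarray:
    """Intraoral-pressure record of a /p/-vowel syllable string (cm H2O).

    ``n_syllables`` vowels are flanked by ``n_syllables + 1`` occlusion
    plateaus; ``plateau`` may be a scalar or per-plateau list.
    """
    rng = np.random.default_rng(seed)
    n_plat = n_syllables + 1
    levels = np.full(n_plat, plateau, dtype=float) if np.isscalar(plateau) else np.asarray(plateau, float)
    if levels.size != n_plat:
        raise ValueError(f"need {n_plat} plateau values, got {levels.size}")
    seg = []
    ramp = int(ramp_s * fs)
    occ = int(occlusion_s * fs)
    vow = int(vowel_s * fs)
    seg.append(np.zeros(vow // 2))
    for i, lev in enumerate(levels):
        seg.append(np.linspace(0, lev, ramp))
        seg.append(np.full(occ, lev))
        seg.append(np.linspace(lev, 0, ramp))
        if i < n_plat - 1:
            seg.append(np.zeros(vow))
    seg.append(np.zeros(vow // 2))
    x = np.concatenate(seg)
    if noise_rms > 0:
        x = x + noise_rms * rng.standard_normal(x.size)
    return x


def two_harmonic_signal(fo: float, fs: float, duration: float,
                        a1: float = 1.0, a2: float = 0.1, dc: float = 0.0) -> np.ndarray:
    t = np.arange(int(duration * fs)) / fs
    return dc + a1 * np.sin(2 * np.pi * fo * t) + a2 * np.sin(2 * np.pi * 2 * fo * t)


def make_fixtures(seed: int, out_dir: str | Path = "fixtures") -> dict:
    """Generate the small WAV/CSV fixtures used by the unit tests.

    Deterministic per seed; returns (and writes) a manifest with sha256
    checksums.
    """
    from .ibif import IBIFParams, forward_acc

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fs = 20000.0
    entries = {}

    def save_wav(name: str, fsr: float, data: np.ndarray):
        path = out / name
        wavfile.write(path, int(fsr), data.astype(np.float32))
        entries[name] = hashlib.sha256(path.read_bytes()).hexdigest()

    def save_csv(name: str, data: np.ndarray):
        path = out / name
        np.savetxt(path, data, delimiter=",")
        entries[name] = hashlib.sha256(path.read_bytes()).hexdigest()

    pulse = glottal_pulse_train(200.0, fs, 0.3, seed=seed)
    save_wav("pulse_train_200hz.wav", fs, pulse)
    save_wav("pulse_train_jitter.wav", fs,
             glottal_pulse_train(200.0, fs, 0.3, jitter=0.1, seed=seed + 1))
    save_wav("two_harmonics.wav", fs, two_harmonic_signal(200.0, fs, 0.3))
    save_wav("sine_flow_200hz.wav", fs,
             100.0 + 50.0 * np.sin(2 * np.pi * 200.0 * np.arange(int(0.3 * fs)) / fs))
    save_csv("iop_trapezoid_8cmh2o.csv", trapezoid_iop_train(6, 8.0, seed=seed))
    save_csv("iop_trapezoid_mixed.csv",
             trapezoid_iop_train(5, [7.0, 9.0, 8.0, 8.0, 8.0, 8.0], seed=seed))
    rng = np.random.default_rng(seed)
    save_wav("white_noise.wav", fs, rng.standard_normal(int(0.3 * fs)))
    nominal = IBIFParams(skin_mass=2.0, skin_stiffness=1.3e6, skin_damping=600.0,
                         trachea_length=0.115, sensor_depth=0.05)
    acc = forward_acc(pulse * 1e-6, nominal, fs)
    save_wav("acc_forward_nominal.wav", fs, acc)
    save_csv("ramp_dc.csv", np.full(4096, 3.0))
    save_csv("chirp.csv",
             np.sin(2 * np.pi * (50 + 1500 * np.arange(int(0.3 * fs)) / fs / 0.6)
                    * np.arange(int(0.3 * fs)) / fs))
    manifest = {"seed": seed, "files": entries}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
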