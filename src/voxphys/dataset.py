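"""Training-table assembly: physiological filtering, bias corrections,
min-max normalization and the train/test split.

Rows come from the Monte Carlo batch generator as feature + target dicts.
The physiological filter keeps only rows whose features occur in comfortable/
loud/soft adult female phonation (AC flow amplitude >= 30 mL/s, fundamental
frequency within 120-400 Hz).  Two fixed bias corrections align the
synthesizer's output scale with laboratory recording conditions: SPL drops
by 28.5 dB (lip output referred to a 10 cm microphone distance) and the
subglottal pressure target by 3.37 cm H2O (clinical-vs-synthetic mean
offset; a constant documented with the model, recomputable against any
user-supplied reference table via :func:`recalibrate_ps_offset`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FEATURES = ["acfl", "mfdr", "oq", "sq", "h1h2", "fo", "spl"]
TARGETS = ["ps", "pc", "a_CT", "a_TA"]

ACFL_MIN = 30.0      # mL/s
FO_RANGE = (120.0, 400.0)  # Hz


@dataclass
class TrainingTable:
    """Normalized feature/target rows with split assignment and provenance."""

    frame: pd.DataFrame                    # normalized columns + 'split'
    col_min: pd.Series
    col_max: pd.Series
    provenance: dict = field(default_factory=dict)

    @property
    def train(self) -> pd.DataFrame:
        return self.frame[self.frame["split"] == "train"]

    @property
    def test(self) -> pd.DataFrame:
        return self.frame[self.frame["split"] == "test"]

    def denormalize(self, values: np.ndarray, columns: list[str]) -> np.ndarray:
        """Map normalized values back to physical units for ``columns``."""
        lo = self.col_min[columns].to_numpy()
        hi = self.col_max[columns].to_numpy()
        return np.asarray(values) * (hi - lo) + lo

    def normalize(self, values: np.ndarray, columns: list[str]) -> np.ndarray:
        lo = self.col_min[columns].to_numpy()
        hi = self.col_max[columns].to_numpy()
        return (np.asarray(values) - lo) / (hi - lo)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# provenance: " + json.dumps(self.provenance, default=str) + "\n")
            fh.write("# col_min: " + json.dumps(self.col_min.to_dict()) + "\n")
            fh.write("# col_max: " + json.dumps(self.col_max.to_dict()) + "\n")
            self.frame.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "TrainingTable":
        meta = {}
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                key, payload = line[1:].split(":", 1)
                meta[key.strip()] = json.loads(payload)
        frame = pd.read_csv(path, comment="#")
        return cls(
            frame=frame,
            col_min=pd.Series(meta["col_min"]),
            col_max=pd.Series(meta["col_max"]),
            provenance=meta.get("provenance", {}),
        )


def physiological_filter(rows: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Keep rows occurring in the laboratory population; tally rejections.

    Bounds are inclusive: ACFL >= 30 mL/s and 120 <= fo <= 400 Hz.
    Non-oscillating/failed simulations must already have been excluded.
    """
    acfl_bad = rows["acfl"] < ACFL_MIN
    fo_bad = (rows["fo"] < FO_RANGE[0]) | (rows["fo"] > FO_RANGE[1])
    tally = {
        "input": int(len(rows)),
        "rejected_acfl": int((acfl_bad & ~fo_bad).sum()),
        "rejected_fo": int((fo_bad & ~acfl_bad).sum()),
        "rejected_both": int((acfl_bad & fo_bad).sum()),
        "kept": int((~acfl_bad & ~fo_bad).sum()),
    }
    return rows[~acfl_bad & ~fo_bad].reset_index(drop=True), tally


def bias_correct(
    rows: pd.DataFrame, spl_db: float = -28.5, ps_cmh2o: float = -3.37
) -> pd.DataFrame:
    """Apply the fixed SPL and subglottal-pressure corrections exactly once.

    A provenance attribute guards against double application.
    """
    if rows.attrs.get("bias_corrected"):
        raise RuntimeError("bias corrections already applied to this table")
    out = rows.copy()
    out["spl"] = out["spl"] + spl_db
    out["ps"] = out["ps"] + ps_cmh2o
    out.attrs["bias_corrected"] = {"spl_db": spl_db, "ps_cmh2o": ps_cmh2o}
    return out


def recalibrate_ps_offset(synthetic_ps: np.ndarray, reference_ps: np.ndarray) -> float:
    """Offset (cm H2O) aligning the synthetic Ps mean with a reference corpus."""
    return float(np.mean(reference_ps) - np.mean(synthetic_ps))


def normalize_and_split(
    rows: pd.DataFrame,
    seed: int,
    test_fraction: float = 0.2,
    columns: list[str] | None = None,
) -> TrainingTable:
    """Min-max normalize on the training split and assign an 80/20 split.

    The split is drawn after filtering; normalization constants come from the
    training split only and are stored so predictions can be denormalized.
    """
    if columns is None:
        columns = [c for c in FEATURES + TARGETS if c in rows.columns]
    rng = np.random.default_rng(seed)
    n = len(rows)
    n_test = int(round(test_fraction * n))
    idx = rng.permutation(n)
    split = np.full(n, "train", dtype=object)
    split[idx[:n_test]] = "test"

    frame = rows.copy().reset_index(drop=True)
    frame["split"] = split
    train_mask = frame["split"] == "train"
    col_min = frame.loc[train_mask, columns].min()
    col_max = frame.loc[train_mask, columns].max()
    degenerate = col_min[col_min == col_max]
    if len(degenerate):
        raise ValueError(f"constant column(s) cannot be normalized: {list(degenerate.index)}")
    frame[columns] = (frame[columns] - col_min) / (col_max - col_min)
    prov = {
        "seed": int(seed),
        "n_rows": int(n),
        "test_fraction": test_fraction,
        "bias_corrected": rows.attrs.get("bias_corrected"),
    }
    return TrainingTable(frame=frame, col_min=col_min, col_max=col_max, provenance=prov)


def build_table(
    rows: list[dict] | pd.DataFrame,
    seed: int,
    spl_db: float = -28.5,
    ps_cmh2o: float = -3.37,
) -> tuple[TrainingTable, dict]:
    """Filter -> bias-correct -> normalize/split; returns the table and tally."""
    frame = pd.DataFrame(rows) if not isinstance(rows, pd.DataFrame) else rows
    kept, tally = physiological_filter(frame)
    corrected = bias_correct(kept, spl_db=spl_db, ps_cmh2o=ps_cmh2o)
    table = normalize_and_split(corrected, seed=seed)
    return table, tally
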