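"""Feed-forward regression networks mapping voice features to vocal measures.

The mapping takes the aerodynamic/acoustic feature vector (six features in
Case I, seven including SPL in Case II) to four vocal-function outputs:
subglottal pressure, collision pressure, and cricothyroid/thyroarytenoid
activation.  Networks are fully connected ReLU stacks with 10% inverted
dropout after every hidden layer, trained with Adam (learning rate 0.001)
on the mean squared error of the min-max-normalized outputs for a fixed
number of epochs.

Implemented directly on numpy: the architecture calls for dropout and
per-epoch train/validation error traces, and the implementation doubles as
a fully deterministic, dependency-light training path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import FEATURES, TARGETS, TrainingTable

CASE_FEATURES = {
    "I": [f for f in FEATURES if f != "spl"],
    "II": list(FEATURES),
}


@dataclass(frozen=True)
class ArchitectureSpec:
    """Hidden-layer layout of the regression network."""

    n_inputs: int = 7
    hidden_layers: int = 2
    neurons: int = 4
    dropout: float = 0.10
    n_outputs: int = 4

    def __post_init__(self):
        if self.n_inputs not in (6, 7):
            raise ValueError("n_inputs must be 6 (Case I) or 7 (Case II)")
        if self.hidden_layers < 1 or self.neurons < 1:
            raise ValueError("need at least one hidden layer and one neuron")

    @classmethod
    def for_case(cls, case: str, hidden_layers: int, neurons: int) -> "ArchitectureSpec":
        return cls(n_inputs=len(CASE_FEATURES[case]), hidden_layers=hidden_layers, neurons=neurons)


@dataclass(frozen=True)
class TrainingSpec:
    """Optimization hyper-parameters."""

    learning_rate: float = 1e-3
    epochs: int = 100
    batch_size: int = 64
    seed: int = 0
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8


@dataclass(frozen=True)
class EvalMetrics:
    """Per-target regression metrics in denormalized physical units."""

    mae: dict
    mae_pct: dict      # MAE as % of the observed target range in the split
    rmse: dict
    r2: dict
    mape: dict

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"MAE": self.mae, "MAE_pct": self.mae_pct, "RMSE": self.rmse,
             "R2": self.r2, "MAPE": self.mape}
        )


class MLPRegressor:
    """Plain-numpy multilayer perceptron with inverted dropout and Adam."""

    def __init__(self, arch: ArchitectureSpec, seed: int = 0):
        self.arch = arch
        rng = np.random.default_rng(seed)
        sizes = [arch.n_inputs] + [arch.neurons] * arch.hidden_layers + [arch.n_outputs]
        self.W = [
            rng.normal(0.0, np.sqrt(2.0 / sizes[i]), size=(sizes[i], sizes[i + 1]))
            for i in range(len(sizes) - 1)
        ]
        self.b = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]

    def forward(self, X: np.ndarray, rng: np.random.Generator | None = None):
        """Forward pass; dropout is active only when ``rng`` is supplied."""
        acts = [X]
        h = X
        masks = []
        p = self.arch.dropout
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = h @ W + b
            if i < len(self.W) - 1:
                h = np.maximum(z, 0.0)
                if rng is not None and p > 0.0:
                    mask = (rng.random(h.shape) >= p) / (1.0 - p)
                    h = h * mask
                    masks.append(mask)
                else:
                    masks.append(None)
            else:
                h = z  # linear output layer
            acts.append(h)
        return acts, masks

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Deterministic prediction (dropout disabled)."""
        acts, _ = self.forward(np.asarray(X, dtype=float))
        return acts[-1]

    def _backward(self, acts, masks, Y):
        n = Y.shape[0]
        grads_W = [None] * len(self.W)
        grads_b = [None] * len(self.b)
        delta = 2.0 * (acts[-1] - Y) / (n * Y.shape[1])
        for i in reversed(range(len(self.W))):
            grads_W[i] = acts[i].T @ delta
            grads_b[i] = delta.sum(axis=0)
            if i > 0:
                delta = delta @ self.W[i].T
                delta = delta * (acts[i] > 0)
                if masks[i - 1] is not None:
                    delta = delta * masks[i - 1]
        return grads_W, grads_b


def mse(pred: np.ndarray, ref: np.ndarray) -> float:
    return float(np.mean((pred - ref) ** 2))


def train(
    table: TrainingTable,
    arch: ArchitectureSpec,
    spec: TrainingSpec,
    case: str | None = None,
) -> tuple[MLPRegressor, dict]:
    """Train a network on the table's training split.

    Returns the fitted model plus per-epoch MSE traces for the training and
    validation (held-out test) splits, both computed with dropout disabled.
    Raises on a NaN loss with the offending epoch index.
    """
    if case is None:
        case = "II" if arch.n_inputs == 7 else "I"
    cols = CASE_FEATURES[case]
    if len(cols) != arch.n_inputs:
        raise ValueError(f"architecture expects {arch.n_inputs} inputs, case {case} has {len(cols)}")
    Xtr = table.train[cols].to_numpy()
    Ytr = table.train[TARGETS].to_numpy()
    Xva = table.test[cols].to_numpy()
    Yva = table.test[TARGETS].to_numpy()

    model = MLPRegressor(arch, seed=spec.seed)
    rng = np.random.default_rng(spec.seed + 1)
    mW = [np.zeros_like(W) for W in model.W]
    vW = [np.zeros_like(W) for W in model.W]
    mb = [np.zeros_like(b) for b in model.b]
    vb = [np.zeros_like(b) for b in model.b]
    t_adam = 0
    history = {"train_mse": [], "val_mse": []}

    n = Xtr.shape[0]
    for epoch in range(spec.epochs):
        order = rng.permutation(n)
        for start in range(0, n, spec.batch_size):
            idx = order[start:start + spec.batch_size]
            acts, masks = model.forward(Xtr[idx], rng=rng)
            gW, gb = model._backward(acts, masks, Ytr[idx])
            t_adam += 1
            corr1 = 1.0 - spec.beta1 ** t_adam
            corr2 = 1.0 - spec.beta2 ** t_adam
            for i in range(len(model.W)):
                mW[i] = spec.beta1 * mW[i] + (1 - spec.beta1) * gW[i]
                vW[i] = spec.beta2 * vW[i] + (1 - spec.beta2) * gW[i] ** 2
                mb[i] = spec.beta1 * mb[i] + (1 - spec.beta1) * gb[i]
                vb[i] = spec.beta2 * vb[i] + (1 - spec.beta2) * gb[i] ** 2
                model.W[i] -= spec.learning_rate * (mW[i] / corr1) / (np.sqrt(vW[i] / corr2) + spec.eps)
                model.b[i] -= spec.learning_rate * (mb[i] / corr1) / (np.sqrt(vb[i] / corr2) + spec.eps)
        tr = mse(model.predict(Xtr), Ytr)
        if not np.isfinite(tr):
            raise RuntimeError(f"NaN training loss at epoch {epoch}")
        history["train_mse"].append(tr)
        history["val_mse"].append(mse(model.predict(Xva), Yva) if len(Xva) else np.nan)
    return model, history


def evaluate(
    model: MLPRegressor,
    rows: pd.DataFrame,
    table: TrainingTable,
    case: str | None = None,
) -> EvalMetrics:
    """Denormalized per-target metrics on ``rows`` (normally the test split).

    MAE(%) is MAE over the observed target range in the split; R^2 is
    ``1 - SS_res / SS_tot``.
    """
    if len(rows) == 0:
        raise ValueError("empty evaluation rows")
    if case is None:
        case = "II" if model.arch.n_inputs == 7 else "I"
    cols = CASE_FEATURES[case]
    pred_n = model.predict(rows[cols].to_numpy())
    pred = table.denormalize(pred_n, TARGETS)
    ref = table.denormalize(rows[TARGETS].to_numpy(), TARGETS)

    mae, mae_pct, rmse, r2, mape = {}, {}, {}, {}, {}
    for j, name in enumerate(TARGETS):
        err = pred[:, j] - ref[:, j]
        mae[name] = float(np.mean(np.abs(err)))
        rng_ = float(np.ptp(ref[:, j]))
        mae_pct[name] = 100.0 * mae[name] / rng_ if rng_ > 0 else np.nan
        rmse[name] = float(np.sqrt(np.mean(err ** 2)))
        ss_res = float(np.sum(err ** 2))
        ss_tot = float(np.sum((ref[:, j] - ref[:, j].mean()) ** 2))
        r2[name] = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
        nz = np.abs(ref[:, j]) > 1e-9
        mape[name] = (
            100.0 * float(np.mean(np.abs(err[nz] / ref[:, j][nz]))) if nz.any() else np.nan
        )
    return EvalMetrics(mae=mae, mae_pct=mae_pct, rmse=rmse, r2=r2, mape=mape)


def architecture_sweep(
    table: TrainingTable,
    grid: list[tuple[int, int]] | None = None,
    spec: TrainingSpec = TrainingSpec(),
    cases: tuple[str, ...] = ("I", "II"),
) -> pd.DataFrame:
    """Train/evaluate a (neurons, layers) grid for each feature case.

    Default grid mirrors the evaluation protocol: two-hidden-layer networks
    of 4..128 neurons plus 128-neuron networks of 4..8 layers.  Failures in
    one cell are recorded and the sweep continues.
    """
    if grid is None:
        grid = [(n, 2) for n in (4, 8, 16, 32, 64, 128)] + [(128, L) for L in (4, 6, 8)]
    records = []
    for case in cases:
        for neurons, layers in grid:
            arch = ArchitectureSpec.for_case(case, layers, neurons)
            try:
                model, _ = train(table, arch, spec, case=case)
                met = evaluate(model, table.test, table, case=case)
                records.append({
                    "case": case, "neurons": neurons, "layers": layers,
                    **{f"mae_{t}": met.mae[t] for t in TARGETS},
                    **{f"rmse_{t}": met.rmse[t] for t in TARGETS},
                    **{f"r2_{t}": met.r2[t] for t in TARGETS},
                })
            except Exception as exc:  # keep sweeping
                records.append({"case": case, "neurons": neurons, "layers": layers, "error": str(exc)})
    return pd.DataFrame(records)


def save_model(model: MLPRegressor, path) -> None:
    """Persist weights and the architecture descriptor as portable JSON."""
    import json

    payload = {
        "arch": {
            "n_inputs": model.arch.n_inputs,
            "hidden_layers": model.arch.hidden_layers,
            "neurons": model.arch.neurons,
            "dropout": model.arch.dropout,
            "n_outputs": model.arch.n_outputs,
        },
        "W": [W.tolist() for W in model.W],
        "b": [b.tolist() for b in model.b],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> MLPRegressor:
    import json

    with open(path) as fh:
        payload = json.load(fh)
    model = MLPRegressor(ArchitectureSpec(**payload["arch"]))
    model.W = [np.asarray(W) for W in payload["W"]]
    model.b = [np.asarray(b) for b in payload["b"]]
    return model
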