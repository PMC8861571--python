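"""Counter-propagation artificial neural network (CPANN).

Two exactly superimposed neuron grids: a Kohonen input layer holding one
weight per input variable per neuron, and an output layer holding one weight
per response.  The winning neuron for an object is the Kohonen neuron
closest (Euclidean) to its input vector — winner selection never consults
the output layer.  During training both layers of every neuron within the
(shrinking) neighborhood of the winner move toward the presented input and
response; prediction returns the winner's output weights.  Compounds
projecting to nearby cells are structurally similar, so the trained map
doubles as a visualization device (top maps and per-plane weight maps).

Training schedule: learning rate decays linearly from ``eta_max`` to
``eta_min``, the neighborhood radius from ``r0`` to 0; the neighborhood
kernel is triangular, 1 − d/(r+1), with Chebyshev grid distance and a
planar (non-toroidal) boundary by default.  Objects are presented in
dataset order, so training is bit-for-bit reproducible from
(seed, object order, schedule).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numba import njit

from .dataset_io import NormalizationParams, normalize
from .regression_stats import pearson_r2


@dataclass
class TrainingSchedule:
    """Learning-rate / radius decay parameters of one CPANN training run."""

    epochs: int
    eta_max: float = 0.5
    eta_min: float = 0.01
    r0: int | None = None  # default: round(max(Nx, Ny) / 2)
    boundary: str = "planar"  # or "toroidal"

    def validate(self, nx: int, ny: int) -> "TrainingSchedule":
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not (0 < self.eta_min <= self.eta_max <= 1):
            raise ValueError("need 0 < eta_min <= eta_max <= 1")
        r0 = self.r0 if self.r0 is not None else int(round(max(nx, ny) / 2))
        if r0 > max(nx, ny):
            raise ValueError("initial radius exceeds the grid")
        if self.boundary not in ("planar", "toroidal"):
            raise ValueError(f"unknown boundary {self.boundary!r}")
        return replace(self, r0=r0)


@dataclass
class CPANNModel:
    """Kohonen input layer + superimposed output layer on an Nx×Ny grid."""

    nx: int
    ny: int
    kohonen: np.ndarray  # (Nx*Ny, n_inputs), row-major grid order
    output: np.ndarray  # (Nx*Ny, n_outputs)
    input_names: list[str] = field(default_factory=list)
    output_names: list[str] = field(default_factory=list)
    norm_in: NormalizationParams | None = None
    norm_out: NormalizationParams | None = None
    schedule: TrainingSchedule | None = None
    seed: int = 0

    @property
    def n_neurons(self) -> int:
        return self.nx * self.ny

    def cell(self, k: int) -> tuple[int, int]:
        return divmod(k, self.ny)


def init(
    grid: tuple[int, int], n_inputs: int, n_outputs: int, seed: int = 0
) -> CPANNModel:
    """Fresh model with Uniform(0,1) weights from a seeded generator."""
    nx, ny = grid
    if nx < 1 or ny < 1 or n_inputs < 1 or n_outputs < 1:
        raise ValueError("grid and layer dimensions must be positive")
    rng = np.random.default_rng(seed)
    return CPANNModel(
        nx=nx,
        ny=ny,
        kohonen=rng.uniform(0, 1, size=(nx * ny, n_inputs)),
        output=rng.uniform(0, 1, size=(nx * ny, n_outputs)),
        seed=seed,
    )


def grid_distances(nx: int, ny: int, boundary: str = "planar") -> np.ndarray:
    """(K, K) matrix of Chebyshev distances between grid cells."""
    rows, cols = np.divmod(np.arange(nx * ny), ny)
    di = np.abs(rows[:, None] - rows[None, :])
    dj = np.abs(cols[:, None] - cols[None, :])
    if boundary == "toroidal":
        di = np.minimum(di, nx - di)
        dj = np.minimum(dj, ny - dj)
    return np.maximum(di, dj)


def find_winner(model: CPANNModel, x: np.ndarray) -> tuple[int, int]:
    """Grid coordinates of the Kohonen neuron nearest to x.

    Ties break toward the smallest row-major index; output weights are
    never consulted.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (model.kohonen.shape[1],):
        raise ValueError(
            f"input length {x.shape} does not match {model.kohonen.shape[1]} inputs"
        )
    dist2 = ((model.kohonen - x) ** 2).sum(axis=1)
    return model.cell(int(np.argmin(dist2)))


@njit(cache=True)
def _run_schedule_jit(W, O, X, Y, epochs, eta_max, eta_min, r0, D, leave_one_out):
    """Sequential CPANN updates, batched over parallel folds.

    ``W``/``O`` have shape (F, K, ·) for F independently trained replicas
    sharing the presentation sequence.  With ``leave_one_out`` the f-th
    replica skips object f, which reproduces retraining on the n−1
    remainder in dataset order.  Winner ties break toward the smallest
    row-major neuron index; the radius uses half-up rounding.
    """
    F, K, n_in = W.shape
    n_out = O.shape[2]
    n = X.shape[0]
    for t in range(epochs):
        frac = 1.0 - t / epochs
        eta = eta_min + (eta_max - eta_min) * frac
        r = int(r0 * frac + 0.5)
        inv = 1.0 / (r + 1.0)
        for idx in range(n):
            for f in range(F):
                if leave_one_out and f == idx:
                    continue
                best = 0
                best_d = np.inf
                for k in range(K):
                    s = 0.0
                    for i in range(n_in):
                        dlt = W[f, k, i] - X[idx, i]
                        s += dlt * dlt
                    if s < best_d:
                        best_d = s
                        best = k
                for k in range(K):
                    d = D[best, k]
                    if d <= r:
                        c = eta * (1.0 - d * inv)
                        for i in range(n_in):
                            W[f, k, i] += c * (X[idx, i] - W[f, k, i])
                        for i in range(n_out):
                            O[f, k, i] += c * (Y[idx, i] - O[f, k, i])


def _run_schedule(
    W: np.ndarray,
    O: np.ndarray,
    X: np.ndarray,
    Y: np.ndarray,
    schedule: TrainingSchedule,
    D: np.ndarray,
    leave_one_out: bool = False,
) -> None:
    _run_schedule_jit(
        W,
        O,
        np.ascontiguousarray(X, dtype=np.float64),
        np.ascontiguousarray(Y, dtype=np.float64),
        schedule.epochs,
        float(schedule.eta_max),
        float(schedule.eta_min),
        float(schedule.r0),
        D.astype(np.float64),
        leave_one_out,
    )


def train(
    model: CPANNModel,
    X: np.ndarray,
    Y: np.ndarray,
    schedule: TrainingSchedule,
) -> CPANNModel:
    """Train both layers on normalized inputs/responses (dataset order)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if len(X) == 0:
        raise ValueError("empty training set")
    if len(X) != len(Y):
        raise ValueError("X and Y row counts differ")
    schedule = schedule.validate(model.nx, model.ny)
    D = grid_distances(model.nx, model.ny, schedule.boundary)
    W = model.kohonen[None].copy()
    O = model.output[None].copy()
    _run_schedule(W, O, X, Y, schedule, D)
    return replace(model, kohonen=W[0], output=O[0], schedule=schedule)


def predict(model: CPANNModel, x: np.ndarray) -> np.ndarray:
    """Winner's output weights, inverse-normalized when params are stored."""
    i, j = find_winner(model, x)
    out = model.output[i * model.ny + j].copy()
    if model.norm_out is not None:
        out = out * model.norm_out.scale + model.norm_out.offset
    return out


def predict_batch(model: CPANNModel, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    dist2 = ((model.kohonen[None] - X[:, None, :]) ** 2).sum(axis=2)
    winners = np.argmin(dist2, axis=1)
    out = model.output[winners]
    if model.norm_out is not None:
        out = out * model.norm_out.scale + model.norm_out.offset
    return out


def loo_cv(
    X: np.ndarray,
    Y: np.ndarray,
    grid: tuple[int, int],
    schedule: TrainingSchedule,
    seed: int = 0,
    response_names: list[str] | None = None,
    norm_out: NormalizationParams | None = None,
) -> pd.DataFrame:
    """Leave-one-out cross-validation: retrain per fold, predict the held-out.

    Every fold restarts from the same seeded initial weights and presents
    the remaining objects in dataset order (implemented as one batched
    tensor over folds, which is update-for-update identical to n separate
    retrainings).  Returns per-response Q²cv (squared Pearson correlation
    of held-out predictions vs observations) and RMSEcv on the original
    scale when ``norm_out`` is given.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n = len(X)
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 objects")
    if np.any(np.ptp(Y, axis=0) == 0):
        raise ValueError("constant response; Q2cv is undefined")
    nx, ny = grid
    schedule = schedule.validate(nx, ny)
    base = init(grid, X.shape[1], Y.shape[1], seed)
    D = grid_distances(nx, ny, schedule.boundary)
    W = np.repeat(base.kohonen[None], n, axis=0)
    O = np.repeat(base.output[None], n, axis=0)
    _run_schedule(W, O, X, Y, schedule, D, leave_one_out=True)

    # held-out prediction of object f from fold f
    dist2 = ((W - X[:, None, :]) ** 2).sum(axis=2)  # (n, K)
    winners = np.argmin(dist2, axis=1)
    preds = O[np.arange(n), winners]  # (n, n_out)

    obs = Y
    if norm_out is not None:
        preds = preds * norm_out.scale + norm_out.offset
        obs = Y * norm_out.scale + norm_out.offset
    names = response_names or [f"y{i}" for i in range(Y.shape[1])]
    rows = {}
    for j, name in enumerate(names):
        rows[name] = {
            "q2cv": pearson_r2(obs[:, j], preds[:, j]),
            "rmse_cv": float(np.sqrt(np.mean((preds[:, j] - obs[:, j]) ** 2))),
        }
    return pd.DataFrame(rows).T


def weight_map(model: CPANNModel, plane: str) -> np.ndarray:
    """(Nx, Ny) grid of one input- or output-plane weight, denormalized."""
    if plane in model.input_names:
        j = model.input_names.index(plane)
        vals = model.kohonen[:, j].copy()
        norm = model.norm_in
    elif plane in model.output_names:
        j = model.output_names.index(plane)
        vals = model.output[:, j].copy()
        norm = model.norm_out
    else:
        raise KeyError(f"unknown plane {plane!r}")
    if norm is not None:
        k = norm.columns.index(plane)
        vals = vals * norm.scale[k] + norm.offset[k]
    return vals.reshape(model.nx, model.ny)


def top_map(
    model: CPANNModel, X: np.ndarray, ids: list[str]
) -> dict[tuple[int, int], list[str]]:
    """Assign each object id to its winning cell."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    cells: dict[tuple[int, int], list[str]] = {}
    for x, cid in zip(X, ids):
        cells.setdefault(find_winner(model, x), []).append(cid)
    return cells


def save_model(model: CPANNModel, path: str) -> None:
    """Serialize to a single versioned JSON file (text format)."""
    payload = {
        "format": "fdqsar-cpann",
        "version": 1,
        "nx": model.nx,
        "ny": model.ny,
        "seed": model.seed,
        "input_names": model.input_names,
        "output_names": model.output_names,
        "kohonen": model.kohonen.tolist(),
        "output": model.output.tolist(),
    }
    for label in ("norm_in", "norm_out"):
        norm = getattr(model, label)
        payload[label] = (
            None
            if norm is None
            else {
                "method": norm.method,
                "columns": norm.columns,
                "offset": norm.offset.tolist(),
                "scale": norm.scale.tolist(),
            }
        )
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def load_model(path: str) -> CPANNModel:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    if payload.get("format") != "fdqsar-cpann":
        raise ValueError("not a CPANN model file")
    norms = {}
    for label in ("norm_in", "norm_out"):
        raw = payload[label]
        norms[label] = (
            None
            if raw is None
            else NormalizationParams(
                method=raw["method"],
                columns=raw["columns"],
                offset=np.asarray(raw["offset"]),
                scale=np.asarray(raw["scale"]),
            )
        )
    return CPANNModel(
        nx=payload["nx"],
        ny=payload["ny"],
        kohonen=np.asarray(payload["kohonen"]),
        output=np.asarray(payload["output"]),
        input_names=payload["input_names"],
        output_names=payload["output_names"],
        norm_in=norms["norm_in"],
        norm_out=norms["norm_out"],
        seed=payload["seed"],
    )


def fit_cpann(
    frame: pd.DataFrame,
    inputs: list[str],
    responses: list[str],
    train_ids: list[str],
    test_ids: list[str] | None,
    grid: tuple[int, int],
    schedule: TrainingSchedule,
    seed: int = 0,
    loo: bool = True,
) -> tuple[CPANNModel, pd.DataFrame]:
    """Normalize, train, and score a CPANN on a compound table.

    Min-max normalization of inputs and responses is fitted on the training
    group only.  Returns the trained model and a per-response stats table
    (training R²/RMSE, external Q²/RMSE, and LOO Q²cv/RMSEcv over the
    training group when ``loo``), all on the original response scale.
    """
    if frame[inputs + responses].isna().to_numpy().any():
        bad = [c for c in inputs + responses if frame[c].isna().any()]
        raise ValueError(f"missing values in column(s) {bad}")
    Xn, norm_in = normalize(frame, fit_rows=train_ids, columns=inputs)
    Yn, norm_out = normalize(frame, fit_rows=train_ids, columns=responses)

    model = init(grid, len(inputs), len(responses), seed)
    model = train(
        model,
        Xn.loc[train_ids].to_numpy(),
        Yn.loc[train_ids].to_numpy(),
        schedule,
    )
    model = replace(
        model,
        input_names=list(inputs),
        output_names=list(responses),
        norm_in=norm_in,
        norm_out=norm_out,
    )

    stats: dict[str, dict[str, float]] = {r: {} for r in responses}

    def score(ids: list[str], prefix: str, r2_name: str) -> None:
        preds = predict_batch(model, Xn.loc[ids].to_numpy())
        obs = frame.loc[ids, responses].to_numpy(dtype=float)
        for j, name in enumerate(responses):
            stats[name][r2_name] = pearson_r2(obs[:, j], preds[:, j])
            stats[name][f"rmse_{prefix}"] = float(
                np.sqrt(np.mean((preds[:, j] - obs[:, j]) ** 2))
            )

    score(train_ids, "train", "r2_train")
    if test_ids:
        score(test_ids, "test", "q2_test")
    if loo:
        cv = loo_cv(
            Xn.loc[train_ids].to_numpy(),
            Yn.loc[train_ids].to_numpy(),
            grid,
            schedule,
            seed=seed,
            response_names=responses,
            norm_out=norm_out,
        )
        for name in responses:
            stats[name]["q2cv"] = cv.loc[name, "q2cv"]
            stats[name]["rmse_cv"] = cv.loc[name, "rmse_cv"]
    return model, pd.DataFrame(stats).T
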