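"""Self-organizing GMDH-type polynomial network.

The Group Method of Data Handling (GMDH) grows a network of small two-input
polynomial regressors ("partial descriptions" of the Kolmogorov–Gabor
polynomial) layer by layer.  Every layer enumerates all unordered input
pairs, fits each candidate neuron by (ridge) least squares on a training
subset A, scores it with an *external criterion* computed on data the fit
did not use — validation MSE on subset B, a two-fit bias term, or their sum
— and keeps only the best K neurons as inputs to the next layer
(select-and-drop).  Growth stops when the best criterion has not improved
by more than ``epsilon`` within a lookback window of layers, or when the
maximum depth is reached.  The final model is the globally best neuron plus
the neurons on its dependency path.

A forecasting front-end frames a univariate series as lag-window → next
sample and offers a residual-feedback variant that models the *increment*
over the last observed sample and adds it back at prediction time, so the
network carries previous-time-step information explicitly.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field, asdict
from itertools import combinations
from typing import Sequence

import numpy as np

from .preprocessing import DEFAULT_LAG, to_supervised

#: reference function name -> number of polynomial basis terms
REF_FUNCTIONS = {"linear": 3, "linear_cov": 4, "quadratic": 6}

CRITERIA = ("validate", "bias", "validate_bias")


class TrainingError(RuntimeError):
    """Raised when no candidate neuron can be scored."""


def basis_size(ref_function: str) -> int:
    try:
        return REF_FUNCTIONS[ref_function]
    except KeyError:
        raise ValueError(f"unknown reference function {ref_function!r}") from None


def polynomial_terms(ref_function: str, u, v) -> np.ndarray:
    """Evaluate the two-input polynomial basis.

    linear → [1, u, v]; linear_cov → [1, u, v, uv];
    quadratic → [1, u, v, uv, u², v²].  Vector inputs give an (n, k) design
    matrix, scalars a length-k vector.
    """
    basis_size(ref_function)
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    cols = [np.ones_like(u), u, v]
    if ref_function in ("linear_cov", "quadratic"):
        cols.append(u * v)
    if ref_function == "quadratic":
        cols.extend([u**2, v**2])
    return np.stack(cols, axis=-1)


def _ridge_fit(B: np.ndarray, y: np.ndarray, l2: float) -> tuple[np.ndarray, bool]:
    """Least squares with optional ridge penalty on all coefficients.

    Returns (weights, degenerate): with l2 = 0 a rank-deficient design falls
    back to the minimum-norm solution and is flagged degenerate.
    """
    if l2 == 0.0:
        w, _, rank, _ = np.linalg.lstsq(B, y, rcond=None)
        return w, rank < B.shape[1]
    # augmented least-squares form of ridge: numerically stable even when
    # the two inputs are nearly collinear (normal equations are not)
    k = B.shape[1]
    B_aug = np.vstack([B, np.sqrt(l2) * np.eye(k)])
    y_aug = np.concatenate([y, np.zeros(k)])
    w = np.linalg.lstsq(B_aug, y_aug, rcond=None)[0]
    return w, False


def fit_neuron(u, v, y, ref_function: str, l2: float = 0.0) -> np.ndarray:
    """Fit one candidate neuron's coefficients by (ridge) least squares.

    Solves argmin ‖Bw − y‖² + l2‖w‖² over the polynomial basis B(u, v);
    the ridge penalty covers all coefficients including the constant.
    """
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if not (u.size == v.size == y.size):
        raise ValueError("u, v, y must have equal lengths")
    k = basis_size(ref_function)
    if u.size < k:
        raise ValueError(f"need at least {k} rows to fit {ref_function!r}")
    if l2 < 0:
        raise ValueError("l2 must be >= 0")
    B = polynomial_terms(ref_function, u, v)
    return _ridge_fit(B, y, l2)[0]


def external_criterion(
    weights_a,
    weights_b,
    u,
    v,
    y,
    subset_b_index,
    kind: str = "validate_bias",
) -> float:
    """Score a candidate neuron on data its coefficients were not fitted to.

    ``validate`` is the MSE on validation subset B under the subset-A fit;
    ``bias`` is the mean squared disagreement of the A-fit and B-fit
    predictions over *all* rows; ``validate_bias`` is their sum.
    """
    if kind not in CRITERIA:
        raise ValueError(f"unknown criterion {kind!r}")
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    subset_b_index = np.asarray(subset_b_index)
    if subset_b_index.dtype == bool:
        subset_b_index = np.flatnonzero(subset_b_index)
    if subset_b_index.size == 0:
        raise ValueError("validation subset B is empty")
    ref = {3: "linear", 4: "linear_cov", 6: "quadratic"}[len(np.asarray(weights_a))]
    B = polynomial_terms(ref, u, v)
    pred_a = B @ np.asarray(weights_a, dtype=float)
    score = 0.0
    if kind in ("validate", "validate_bias"):
        resid = pred_a[subset_b_index] - y[subset_b_index]
        score += float(np.mean(resid**2))
    if kind in ("bias", "validate_bias"):
        pred_b = B @ np.asarray(weights_b, dtype=float)
        score += float(np.mean((pred_a - pred_b) ** 2))
    return score


@dataclass
class GmdhConfig:
    """Training hyperparameters of the self-organizing network.

    Defaults follow common GMDH practice for this kind of signal work:
    linear-with-covariance reference function, validate+bias selection,
    ridge penalty 0.5, minimum criterion improvement 0.001, stop after 5
    layers without improvement, keep the best 30 neurons per layer, split
    rows sequentially in half (time order preserved for forecasting).
    """

    ref_function: str = "linear_cov"
    criterion: str = "validate_bias"
    l2: float = 0.5
    epsilon: float = 0.001
    max_layers: int = 15
    criterion_lookback: int = 5
    best_neurons_count: int = 30
    split_ratio: float = 0.5
    shuffle_split: bool = False
    seed: int | None = None
    raw_passthrough: bool = False
    prune: bool = True

    def __post_init__(self) -> None:
        basis_size(self.ref_function)
        if self.criterion not in CRITERIA:
            raise ValueError(f"unknown criterion {self.criterion!r}")
        if self.l2 < 0:
            raise ValueError("l2 must be >= 0")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.max_layers < 1:
            raise ValueError("max_layers must be >= 1")
        if self.criterion_lookback < 1:
            raise ValueError("criterion_lookback must be >= 1")
        if self.best_neurons_count < 1:
            raise ValueError("best_neurons_count must be >= 1")
        if not 0.0 < self.split_ratio < 1.0:
            raise ValueError("split_ratio must be in (0, 1)")


@dataclass
class Neuron:
    """One fitted partial polynomial: two input indices, weights, score."""

    input_a: int
    input_b: int
    ref_function: str
    weights: np.ndarray
    criterion_score: float
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "input_a": int(self.input_a),
            "input_b": int(self.input_b),
            "ref_function": self.ref_function,
            "weights": [float(w) for w in self.weights],
            "criterion_score": float(self.criterion_score),
            "degenerate": bool(self.degenerate),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Neuron":
        return cls(
            input_a=d["input_a"],
            input_b=d["input_b"],
            ref_function=d["ref_function"],
            weights=np.asarray(d["weights"], dtype=float),
            criterion_score=d["criterion_score"],
            degenerate=d.get("degenerate", False),
        )


@dataclass
class GmdhModel:
    """A trained layered polynomial network.

    ``layers[l]`` holds the surviving neurons of layer l; neuron input
    indices refer to the previous layer's output vector (raw input columns
    for layer 0, optionally appended after the survivors on deeper layers
    when raw passthrough is enabled).  ``selected_output`` locates the best
    neuron; prediction evaluates only its dependency path.
    """

    layers: list[list[Neuron]]
    selected_output: tuple[int, int]
    config: GmdhConfig
    n_inputs: int
    history: list[dict] = field(default_factory=list)

    def _layer_inputs(self, prev_outputs: np.ndarray, X: np.ndarray, layer_idx: int) -> np.ndarray:
        if layer_idx == 0:
            return X
        if self.config.raw_passthrough:
            return np.hstack([prev_outputs, X])
        return prev_outputs

    def predict(self, X) -> np.ndarray:
        """Feed-forward evaluation; returns one prediction per row of X."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_inputs:
            raise ValueError(
                f"model expects {self.n_inputs} input columns, got {X.shape[1]}"
            )
        sel_layer, sel_idx = self.selected_output
        outputs = np.empty((X.shape[0], 0))
        for l, layer in enumerate(self.layers[: sel_layer + 1]):
            Z = self._layer_inputs(outputs, X, l)
            outputs = np.stack(
                [
                    polynomial_terms(nr.ref_function, Z[:, nr.input_a], Z[:, nr.input_b])
                    @ nr.weights
                    for nr in layer
                ],
                axis=1,
            )
        return outputs[:, sel_idx]

    @property
    def criterion_score(self) -> float:
        l, i = self.selected_output
        return self.layers[l][i].criterion_score

    def n_neurons(self) -> int:
        return sum(len(layer) for layer in self.layers)

    def to_dict(self) -> dict:
        return {
            "layers": [[nr.to_dict() for nr in layer] for layer in self.layers],
            "selected_output": list(self.selected_output),
            "config": asdict(self.config),
            "n_inputs": int(self.n_inputs),
            "history": self.history,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GmdhModel":
        return cls(
            layers=[[Neuron.from_dict(nd) for nd in layer] for layer in d["layers"]],
            selected_output=tuple(d["selected_output"]),
            config=GmdhConfig(**d["config"]),
            n_inputs=d["n_inputs"],
            history=list(d["history"]),
        )


def _split_indices(n: int, config: GmdhConfig) -> tuple[np.ndarray, np.ndarray]:
    order = np.arange(n)
    if config.shuffle_split:
        order = np.random.default_rng(config.seed).permutation(n)
    n_a = math.ceil(config.split_ratio * n)
    if n_a == 0 or n_a == n:
        raise ValueError("split leaves an empty subset; adjust split_ratio or n")
    return order[:n_a], order[n_a:]


def _prune(layers: list[list[Neuron]], selected: tuple[int, int],
           raw_passthrough: bool) -> tuple[list[list[Neuron]], tuple[int, int]]:
    """Drop neurons off the selected neuron's dependency path and remap indices."""
    sel_layer, sel_idx = selected
    needed: list[set[int]] = [set() for _ in range(sel_layer + 1)]
    needed[sel_layer].add(sel_idx)
    for l in range(sel_layer, 0, -1):
        m_prev = len(layers[l - 1])
        for idx in needed[l]:
            nr = layers[l][idx]
            for inp in (nr.input_a, nr.input_b):
                if inp < m_prev:  # otherwise a raw passthrough column
                    needed[l - 1].add(inp)
    kept = [sorted(needed[l]) for l in range(sel_layer + 1)]
    new_layers: list[list[Neuron]] = []
    for l in range(sel_layer + 1):
        remap = {old: new for new, old in enumerate(kept[l - 1])} if l > 0 else {}
        new_layer = []
        for idx in kept[l]:
            nr = layers[l][idx]
            if l == 0:
                new_layer.append(nr)
            else:
                m_prev_old = len(layers[l - 1])

                def _map(i: int) -> int:
                    if i < m_prev_old:
                        return remap[i]
                    return i - m_prev_old + len(kept[l - 1])

                new_layer.append(
                    Neuron(
                        _map(nr.input_a),
                        _map(nr.input_b),
                        nr.ref_function,
                        nr.weights,
                        nr.criterion_score,
                        nr.degenerate,
                    )
                )
        new_layers.append(new_layer)
    return new_layers, (sel_layer, kept[sel_layer].index(sel_idx))


def train(X, y, config: GmdhConfig | None = None) -> GmdhModel:
    """Grow a GMDH network on a design matrix and targets.

    Rows are split into fitting subset A and validation subset B; every
    layer enumerates unordered input pairs, fits candidates on A, scores
    them with the external criterion, and keeps the best K as the next
    layer's inputs.  A layer is *accepted* when its best score improves on
    the best so far by more than ``epsilon``; growth stops when no layer in
    the last ``criterion_lookback`` was accepted or at ``max_layers``.
    The returned model is pruned to the best neuron's dependency path
    (disable with ``config.prune = False``).
    """
    if config is None:
        config = GmdhConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("X must be 2-D with at least 2 input columns")
    if X.shape[0] != y.size:
        raise ValueError("X and y row counts differ")
    k = basis_size(config.ref_function)
    if X.shape[0] < 2 * k:
        raise ValueError(f"need at least {2 * k} rows to train with {config.ref_function!r}")

    idx_a, idx_b = _split_indices(X.shape[0], config)
    need_bias = config.criterion in ("bias", "validate_bias")
    need_validate = config.criterion in ("validate", "validate_bias")

    layers: list[list[Neuron]] = []
    history: list[dict] = []
    Z = X
    best_score = math.inf
    best_loc: tuple[int, int] | None = None
    since_accept = 0

    for layer_idx in range(config.max_layers):
        t0 = time.perf_counter()
        inputs = Z if layer_idx == 0 else (
            np.hstack([Z, X]) if config.raw_passthrough else Z
        )
        m = inputs.shape[1]
        if m < 2:
            break
        candidates = []
        for a, b in combinations(range(m), 2):
            B = polynomial_terms(config.ref_function, inputs[:, a], inputs[:, b])
            w_a, degen = _ridge_fit(B[idx_a], y[idx_a], config.l2)
            pred_a = B @ w_a
            score = 0.0
            if need_validate:
                resid = pred_a[idx_b] - y[idx_b]
                score += float(np.mean(resid**2))
            if need_bias:
                w_b, _ = _ridge_fit(B[idx_b], y[idx_b], config.l2)
                score += float(np.mean((pred_a - B @ w_b) ** 2))
            if not math.isfinite(score):
                continue
            candidates.append((score, a, b, w_a, degen, pred_a))
        if not candidates:
            raise TrainingError(
                f"layer {layer_idx + 1}: no candidate neuron produced a finite score"
            )
        candidates.sort(key=lambda c: (c[0], c[1], c[2]))
        survivors = candidates[: min(config.best_neurons_count, len(candidates))]
        layer = [
            Neuron(a, b, config.ref_function, w, s, degen)
            for s, a, b, w, degen, _ in survivors
        ]
        layers.append(layer)
        Z = np.stack([pred for *_, pred in survivors], axis=1)

        layer_best = survivors[0][0]
        accepted = layer_best < best_score - config.epsilon
        if accepted:
            best_score = layer_best
            best_loc = (layer_idx, 0)
            since_accept = 0
        else:
            since_accept += 1
        history.append(
            {
                "layer": layer_idx + 1,
                "best_score": layer_best,
                "n_candidates": len(candidates),
                "n_kept": len(survivors),
                "accepted": bool(accepted),
                "wall_time_s": time.perf_counter() - t0,
            }
        )
        if since_accept >= config.criterion_lookback:
            break

    assert best_loc is not None  # first layer is always accepted (inf baseline)
    model_layers, selected = (layers, best_loc)
    if config.prune:
        model_layers, selected = _prune(layers, best_loc, config.raw_passthrough)
    return GmdhModel(
        layers=model_layers,
        selected_output=selected,
        config=config,
        n_inputs=X.shape[1],
        history=history,
    )


def predict(model: GmdhModel, X) -> np.ndarray:
    """Functional alias for :meth:`GmdhModel.predict`."""
    return model.predict(X)


@dataclass
class ForecastMeta:
    """How a forecasting model was framed: lag width and residual mode."""

    lag: int
    residual: bool
    source_channel: str = ""


def forecast_fit(
    series,
    lag: int = DEFAULT_LAG,
    config: GmdhConfig | None = None,
    residual: bool = False,
) -> tuple[GmdhModel, ForecastMeta]:
    """Train a one-step-ahead forecaster on a univariate series.

    The series is framed as ``lag`` past samples → next sample.  With
    ``residual=True`` the network is trained on increments
    d_t = y_t − x_{t,last} (target minus the last window sample) and the
    last sample is added back at prediction time, so the model carries
    previous-time-step information explicitly (a learned correction to the
    persistence baseline).

    When no config is given, forecasting defaults to the ``linear``
    reference function: purely affine neurons cannot blow up when the test
    segment wanders outside the training amplitude range, which the
    covariance/quadratic forms can do through their product terms.
    """
    if config is None:
        config = GmdhConfig(ref_function="linear")
    series = np.asarray(series, dtype=float).ravel()
    if series.size <= 2 * lag:
        raise ValueError(f"series of length {series.size} too short for lag {lag}")
    ds = to_supervised(series, lag)
    targets = ds.y - ds.X[:, -1] if residual else ds.y
    model = train(ds.X, targets, config)
    return model, ForecastMeta(lag=lag, residual=residual)


def forecast_predict(model: GmdhModel, meta: ForecastMeta, window) -> float:
    """Predict the next sample from the most recent ``lag`` samples."""
    window = np.asarray(window, dtype=float).ravel()
    if window.size != meta.lag:
        raise ValueError(f"window must have exactly lag = {meta.lag} samples")
    out = float(model.predict(window[None, :])[0])
    return out + float(window[-1]) if meta.residual else out


def forecast_predict_series(
    model: GmdhModel, meta: ForecastMeta, series
) -> tuple[np.ndarray, np.ndarray]:
    """One-step-ahead predictions over every window of a series.

    Returns (predictions, true next samples); both have length
    ``len(series) − lag``.
    """
    ds = to_supervised(series, meta.lag)
    preds = model.predict(ds.X)
    if meta.residual:
        preds = preds + ds.X[:, -1]
    return preds, ds.y


def forecast_backtest(
    series,
    lag: int = DEFAULT_LAG,
    config: GmdhConfig | None = None,
    residual: bool = False,
    train_fraction: float = 0.5,
) -> dict:
    """Train on the head of a series, score one-step predictions on the tail.

    Returns a dict with the model, meta, and held-out RMSE/NRMSE/R² plus
    wall-clock train/test times — the row shape of a prediction report.
    """
    from . import metrics

    series = np.asarray(series, dtype=float).ravel()
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    n_train = int(series.size * train_fraction)
    t0 = time.perf_counter()
    model, meta = forecast_fit(series[:n_train], lag=lag, config=config, residual=residual)
    train_time = time.perf_counter() - t0
    t0 = time.perf_counter()
    preds, truth = forecast_predict_series(model, meta, series[n_train - lag :])
    test_time = time.perf_counter() - t0
    return {
        "model": model,
        "meta": meta,
        "rmse": metrics.rmse(truth, preds),
        "nrmse": metrics.nrmse(truth, preds),
        "r_squared": metrics.r_squared(truth, preds),
        "layers": len(model.layers),
        "train_time_s": train_time,
        "test_time_s": test_time,
        "predictions": preds,
        "targets": truth,
    }
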