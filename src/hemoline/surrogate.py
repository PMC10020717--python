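"""Bi-directional LSTM sequence surrogate.

Maps per-centerline-point feature sequences (coordinates, area, Q/A, shape
code) to per-point pressure (mmHg) and WSS (Pa).  The centerline sequence is
processed in both directions; the two hidden-state sequences are
concatenated and a per-timestep fully connected head (one tanh hidden layer,
then linear) emits the two output channels in standardized units, which are
de-standardized at prediction time.

Training minimizes masked MSE on z-scored channels with Adam (gradient-norm
clipping at 1.0); variable sequence lengths (typically 110-130 points) are
handled by padding with a validity mask, so padded points contribute zero
loss and prediction works for any N without retraining.

The reference configuration uses LSTM hidden size 900 with a 200-unit head;
the desk-scale default (hidden 64, head 32) trains in minutes on one CPU and
is what the test suite and examples exercise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._nn import (
    Adam,
    glorot,
    init_lstm,
    lstm_backward,
    lstm_forward,
    pad_sequences,
    reverse_sequences,
)
from .dataset import DatasetSplit, FeatureSequence, Standardizer
from .exceptions import ConfigurationError, InputError, TrainingError
from .oracle import HemodynamicProfile


@dataclass(frozen=True)
class SurrogateConfig:
    """Hyperparameters of the sequence surrogate."""

    lstm_hidden: int = 64  # reference optimum 900
    fc_size: int = 32  # reference optimum 200
    m: int = 4  # AE code size (feature width = 5 + m)
    learning_rate: float = 3e-3
    epochs: int = 300
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("lstm_hidden", "fc_size", "m", "epochs", "batch_size"):
            if int(getattr(self, name)) <= 0:
                raise ConfigurationError(f"{name} must be a positive integer")

    @property
    def n_features(self) -> int:
        return 5 + self.m

    def n_parameters(self) -> int:
        F, H, C = self.n_features, self.lstm_hidden, self.fc_size
        lstm = 2 * (F * 4 * H + H * 4 * H + 4 * H)
        head = 2 * H * C + C + C * 2 + 2
        return lstm + head


@dataclass
class SurrogateModel:
    """Trained network plus the standardization stats needed for inference."""

    params: dict[str, np.ndarray]
    config: SurrogateConfig
    feature_stats: Standardizer
    target_stats: Standardizer
    loss_history: list[float] = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.params,
                 f_mean=self.feature_stats.mean_, f_scale=self.feature_stats.scale_,
                 t_mean=self.target_stats.mean_, t_scale=self.target_stats.scale_)
        meta = {"config": self.config.__dict__, "loss_history": self.loss_history}
        path.with_suffix(".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "SurrogateModel":
        path = Path(path)
        arrays = dict(np.load(path.with_suffix(".npz")))
        meta = json.loads(path.with_suffix(".json").read_text())
        fs, ts = Standardizer(), Standardizer()
        fs.mean_, fs.scale_ = arrays.pop("f_mean"), arrays.pop("f_scale")
        ts.mean_, ts.scale_ = arrays.pop("t_mean"), arrays.pop("t_scale")
        return cls(params=arrays, config=SurrogateConfig(**meta["config"]),
                   feature_stats=fs, target_stats=ts,
                   loss_history=list(meta["loss_history"]))


# ---------------------------------------------------------------------------
# forward / backward through the whole network


def _init_params(config: SurrogateConfig) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(config.seed)
    F, H, C = config.n_features, config.lstm_hidden, config.fc_size
    params: dict[str, np.ndarray] = {}
    for tag in ("f", "b"):
        lstm = init_lstm(rng, F, H)
        params[f"Wx_{tag}"] = lstm["Wx"]
        params[f"Wh_{tag}"] = lstm["Wh"]
        params[f"b_{tag}"] = lstm["b"]
    params["W1"] = glorot(rng, 2 * H, C)
    params["b1"] = np.zeros(C)
    params["W2"] = glorot(rng, C, 2)
    params["b2"] = np.zeros(2)
    return params


def _forward(params, x: np.ndarray, lengths: np.ndarray):
    """x: (B, T, F) standardized features -> (B, T, 2) standardized outputs."""
    pf = {"Wx": params["Wx_f"], "Wh": params["Wh_f"], "b": params["b_f"]}
    pb = {"Wx": params["Wx_b"], "Wh": params["Wh_b"], "b": params["b_b"]}
    h_f, cache_f = lstm_forward(x, pf)
    x_rev = reverse_sequences(x, lengths)
    h_brev, cache_b = lstm_forward(x_rev, pb)
    h_b = reverse_sequences(h_brev, lengths)
    hcat = np.concatenate([h_f, h_b], axis=2)  # (B, T, 2H)
    a1 = hcat @ params["W1"] + params["b1"]
    z1 = np.tanh(a1)
    y = z1 @ params["W2"] + params["b2"]
    cache = (x, lengths, pf, pb, cache_f, cache_b, hcat, z1)
    return y, cache


def _backward(params, cache, dy: np.ndarray) -> dict[str, np.ndarray]:
    x, lengths, pf, pb, cache_f, cache_b, hcat, z1 = cache
    B, T, _ = dy.shape
    H = params["Wh_f"].shape[0]

    dz1 = (dy @ params["W2"].T) * (1.0 - z1 * z1)
    grads = {
        "W2": np.einsum("btc,bto->co", z1, dy),
        "b2": dy.sum(axis=(0, 1)),
        "W1": np.einsum("bth,btc->hc", hcat, dz1),
        "b1": dz1.sum(axis=(0, 1)),
    }
    dhcat = dz1 @ params["W1"].T
    dh_f = dhcat[:, :, :H]
    dh_b = reverse_sequences(dhcat[:, :, H:], lengths)
    g_f, _ = lstm_backward(dh_f, pf, cache_f)
    g_b, _ = lstm_backward(dh_b, pb, cache_b)
    for k, v in g_f.items():
        grads[f"{k}_f"] = v
    for k, v in g_b.items():
        grads[f"{k}_b"] = v
    return grads


# ---------------------------------------------------------------------------
# training


def _prepare(features, profiles, config, feature_stats=None, target_stats=None):
    xs = [f.values for f in features]
    ys = [np.column_stack([p.pressure, p.wss]) for p in profiles]
    for f, p in zip(features, profiles):
        if f.n_points != p.n_points:
            raise InputError("feature/profile length mismatch")
        if f.width != config.n_features:
            raise InputError(
                f"feature width {f.width} does not match config (5 + m = {config.n_features})"
            )
    if feature_stats is None:
        feature_stats = Standardizer().fit(xs)
    if target_stats is None:
        target_stats = Standardizer().fit(ys)
    xs = [feature_stats.transform(a) for a in xs]
    ys = [target_stats.transform(a) for a in ys]
    return xs, ys, feature_stats, target_stats


def train_surrogate(
    features: list[FeatureSequence],
    profiles: list[HemodynamicProfile],
    config: SurrogateConfig | None = None,
    min_records: int = 30,
) -> SurrogateModel:
    """Train the bi-LSTM on (feature sequence, reference profile) pairs.

    Standardization stats are fitted here on the training data only and
    stored on the model, so held-out data is always scaled with training
    statistics.  Deterministic given ``config.seed``.
    """
    config = config or SurrogateConfig()
    if len(features) < min_records:
        raise InputError(f"need at least {min_records} training records, got {len(features)}")
    xs, ys, feature_stats, target_stats = _prepare(features, profiles, config)
    x, mask, lengths = pad_sequences(xs)
    y_ref, _, _ = pad_sequences(ys)
    w = mask[:, :, None].astype(float)

    params = _init_params(config)
    opt = Adam(params, lr=config.learning_rate, clip_norm=1.0)
    rng = np.random.default_rng(config.seed + 1)
    n = x.shape[0]
    history: list[float] = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            yb, cache = _forward(params, x[idx], lengths[idx])
            diff = (yb - y_ref[idx]) * w[idx]
            n_valid = w[idx].sum() * 2.0
            loss = float((diff**2).sum() / n_valid)
            if not np.isfinite(loss):
                raise TrainingError(f"NaN/inf loss; config={config}")
            epoch_loss += loss * len(idx)
            dy = 2.0 * diff / n_valid
            opt.step(_backward(params, cache, dy))
        history.append(epoch_loss / n)
    return SurrogateModel(
        params=params, config=config, feature_stats=feature_stats,
        target_stats=target_stats, loss_history=history,
    )


def predict(model: SurrogateModel, features: FeatureSequence) -> HemodynamicProfile:
    """Predict the pressure/WSS profile for one feature sequence.

    Output length always equals the input length; WSS is floored at zero
    after de-standardization (shear magnitudes are non-negative).
    """
    if features.width != model.config.n_features:
        raise InputError(
            f"feature width {features.width} != model width {model.config.n_features}"
        )
    x = model.feature_stats.transform(features.values)[None]
    lengths = np.array([features.n_points])
    y, _ = _forward(model.params, x, lengths)
    out = model.target_stats.inverse_transform(y[0])
    return HemodynamicProfile(
        pressure=out[:, 0],
        wss=np.maximum(out[:, 1], 0.0),
        source="surrogate",
    )


# ---------------------------------------------------------------------------
# cross-validation and grid search


def _rmse_channels(model, features, profiles) -> tuple[float, float]:
    dp, dw = [], []
    for f, p in zip(features, profiles):
        pred = predict(model, f)
        dp.append(float(np.sqrt(np.mean((pred.pressure - p.pressure) ** 2))))
        dw.append(float(np.sqrt(np.mean((pred.wss - p.wss) ** 2))))
    return float(np.mean(dp)), float(np.mean(dw))


def cross_validate(
    features: list[FeatureSequence],
    profiles: list[HemodynamicProfile],
    split: DatasetSplit,
    config: SurrogateConfig | None = None,
) -> pd.DataFrame:
    """k-fold CV rotating over the non-test subsets of a geometry-grouped split.

    Each fold trains on k-1 subsets and validates on the held-out one; the
    test subset never participates.  Returns one row per fold with mean
    validation RMSE per channel plus their standardized-combined value.
    """
    config = config or SurrogateConfig()
    folds = [k for k in range(split.n_subsets) if k != split.test_subset_index]
    if len(folds) < 3:
        raise InputError("need at least 3 non-test subsets for cross-validation")
    by_id: dict[str, list[int]] = {}
    for i, f in enumerate(features):
        by_id.setdefault(f.geometry_id, []).append(i)

    rows = []
    for fold in folds:
        val_ids = set(split.subsets[fold])
        train_ids = split.train_ids(exclude_subset=fold)
        if val_ids & train_ids:
            raise ConfigurationError("train/validation geometry overlap in fold")
        tr = [i for i, f in enumerate(features) if f.geometry_id in train_ids]
        va = [i for i, f in enumerate(features) if f.geometry_id in val_ids]
        model = train_surrogate(
            [features[i] for i in tr], [profiles[i] for i in tr], config, min_records=3
        )
        rmse_p, rmse_wss = _rmse_channels(
            model, [features[i] for i in va], [profiles[i] for i in va]
        )
        # combine on the training target scales so mmHg and Pa are commensurate
        scale = model.target_stats.scale_
        combined = float(np.hypot(rmse_p / scale[0], rmse_wss / scale[1]))
        rows.append(
            {"fold_subset": fold, "n_train": len(tr), "n_val": len(va),
             "rmse_p": rmse_p, "rmse_wss": rmse_wss, "rmse_combined": combined}
        )
    return pd.DataFrame(rows)


def grid_search(
    features: list[FeatureSequence],
    profiles: list[HemodynamicProfile],
    split: DatasetSplit,
    grid: list[SurrogateConfig],
) -> tuple[SurrogateConfig, pd.DataFrame]:
    """Exhaustive grid search by cross-validated combined RMSE.

    Ties are broken toward the smaller model (fewer parameters), then by
    grid order.
    """
    if not grid:
        raise InputError("empty hyperparameter grid")
    rows = []
    for order, config in enumerate(grid):
        cv = cross_validate(features, profiles, split, config)
        rows.append(
            {"order": order, "config": config,
             "mean_rmse_p": float(cv["rmse_p"].mean()),
             "mean_rmse_wss": float(cv["rmse_wss"].mean()),
             "mean_rmse_combined": float(cv["rmse_combined"].mean()),
             "n_parameters": config.n_parameters()}
        )
    table = pd.DataFrame(rows)
    best = table.sort_values(
        ["mean_rmse_combined", "n_parameters", "order"], kind="stable"
    ).iloc[0]
    return best["config"], table
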