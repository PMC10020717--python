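"""Single-hidden-layer shape autoencoder.

Compresses binary cross-section rasters (default 68x68) to an m-dimensional
code (default m=4) that the sequence surrogate consumes as a per-point
feature.  Encoder and decoder are single dense layers with logistic sigmoid
activations trained on mean squared reconstruction error with Adam; images
are flattened row-major, and binary metrics threshold the reconstruction at
0.5.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._nn import Adam, glorot, sigmoid
from .centerline import ShapeImage
from .exceptions import InputError, TrainingError


@dataclass
class AEModel:
    """Trained autoencoder weights plus training metadata."""

    W1: np.ndarray  # (D, m) encoder
    b1: np.ndarray
    W2: np.ndarray  # (m, D) decoder
    b2: np.ndarray
    m: int
    grid_size: int
    loss_history: list[float] = field(default_factory=list)
    seed: int = 0

    @property
    def final_loss(self) -> float:
        return self.loss_history[-1] if self.loss_history else float("nan")

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(
            path.with_suffix(".npz"),
            W1=self.W1, b1=self.b1, W2=self.W2, b2=self.b2,
        )
        meta = {
            "m": self.m,
            "grid_size": self.grid_size,
            "seed": self.seed,
            "loss_history": self.loss_history,
        }
        path.with_suffix(".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "AEModel":
        path = Path(path)
        arrays = np.load(path.with_suffix(".npz"))
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(
            W1=arrays["W1"], b1=arrays["b1"], W2=arrays["W2"], b2=arrays["b2"],
            m=meta["m"], grid_size=meta["grid_size"], seed=meta["seed"],
            loss_history=list(meta["loss_history"]),
        )

    # -- inference ---------------------------------------------------------

    def _flat(self, image: ShapeImage | np.ndarray) -> np.ndarray:
        grid = image.grid if isinstance(image, ShapeImage) else np.asarray(image)
        if grid.shape != (self.grid_size, self.grid_size):
            raise InputError(
                f"image grid {grid.shape} does not match model input "
                f"({self.grid_size}x{self.grid_size})"
            )
        return grid.astype(float).ravel()

    def encode(self, image: ShapeImage | np.ndarray) -> np.ndarray:
        """m-dimensional shape code of one raster."""
        return sigmoid(self._flat(image) @ self.W1 + self.b1)

    def decode(self, code: np.ndarray) -> np.ndarray:
        """Reconstructed (grid_size, grid_size) image with values in [0, 1]."""
        code = np.asarray(code, dtype=float)
        if code.shape != (self.m,):
            raise InputError(f"code length {code.shape} != m={self.m}")
        flat = sigmoid(code @ self.W2 + self.b2)
        return flat.reshape(self.grid_size, self.grid_size)

    def reconstruct(self, image: ShapeImage | np.ndarray) -> np.ndarray:
        return self.decode(self.encode(image))


def _stack(images: list[ShapeImage | np.ndarray]) -> tuple[np.ndarray, int]:
    grids = [im.grid if isinstance(im, ShapeImage) else np.asarray(im) for im in images]
    sizes = {g.shape for g in grids}
    if len(sizes) != 1:
        raise InputError(f"inconsistent image sizes: {sorted(sizes)}")
    (shape,) = sizes
    if shape[0] != shape[1]:
        raise InputError("images must be square")
    x = np.stack([g.astype(float).ravel() for g in grids])
    return x, shape[0]


def train_autoencoder(
    images: list[ShapeImage | np.ndarray],
    m: int = 4,
    seed: int = 0,
    epochs: int = 60,
    lr: float = 5e-3,
    batch_size: int = 256,
    min_images: int = 100,
) -> AEModel:
    """Train the autoencoder on a pooled cross-section raster corpus.

    Minibatch Adam on MSE; deterministic given the seed (initialization and
    batch order both derive from it).  The corpus should pool vessel and
    valve-region sections so codes are meaningful everywhere along the
    centerline.  ``epochs`` counts full passes over the corpus.
    """
    if len(images) < min_images:
        raise InputError(f"need at least {min_images} images, got {len(images)}")
    x, grid_size = _stack(images)
    D = x.shape[1]
    rng = np.random.default_rng(seed)
    # decoder bias starts at the logit of the mean occupancy per pixel, so
    # the decoder begins at the corpus mean image instead of uniform grey --
    # without this the sigmoid output layer converges an order of magnitude
    # more slowly on mostly-empty binary rasters
    p_mean = np.clip(x.mean(axis=0), 1e-3, 1.0 - 1e-3)
    params = {
        "W1": glorot(rng, D, m),
        "b1": np.zeros(m),
        "W2": glorot(rng, m, D),
        "b2": np.log(p_mean / (1.0 - p_mean)),
    }
    opt = Adam(params, lr=lr, clip_norm=None)
    history: list[float] = []
    n = x.shape[0]
    for _ in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            xb = x[order[start : start + batch_size]]
            h = sigmoid(xb @ params["W1"] + params["b1"])
            y = sigmoid(h @ params["W2"] + params["b2"])
            err = y - xb
            loss = float((err**2).mean())
            if not np.isfinite(loss):
                raise TrainingError("autoencoder loss diverged")
            epoch_loss += loss * len(xb)
            dy = 2.0 * err / err.size
            dz2 = dy * y * (1.0 - y)
            dW2 = h.T @ dz2
            db2 = dz2.sum(axis=0)
            dh = dz2 @ params["W2"].T
            dz1 = dh * h * (1.0 - h)
            dW1 = xb.T @ dz1
            db1 = dz1.sum(axis=0)
            opt.step({"W1": dW1, "b1": db1, "W2": dW2, "b2": db2})
        history.append(epoch_loss / n)
    return AEModel(
        W1=params["W1"], b1=params["b1"], W2=params["W2"], b2=params["b2"],
        m=m, grid_size=grid_size, loss_history=history, seed=seed,
    )


def iou(a: np.ndarray, b: np.ndarray, threshold: float = 0.5) -> float:
    """Pixel-count intersection-over-union of two images after thresholding."""
    ab = np.asarray(a) > threshold
    bb = np.asarray(b) > threshold
    union = np.logical_or(ab, bb).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(ab, bb).sum() / union)


def reconstruction_iou(model: AEModel, images: list[ShapeImage | np.ndarray]) -> float:
    """Mean round-trip IoU over an image set."""
    vals = []
    for im in images:
        grid = im.grid if isinstance(im, ShapeImage) else np.asarray(im)
        vals.append(iou(grid.astype(float), model.reconstruct(im)))
    return float(np.mean(vals))
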