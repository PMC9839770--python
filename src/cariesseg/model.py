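"""Trainable segmentation backbones.

The package defines a minimal model contract (:class:`SegmentationModel`)
so that any dense predictor — including large encoder–decoder networks —
can plug into the teacher–student pipeline. The built-in backbone,
:class:`FilterBankSegmenter`, is a compact per-pixel classifier: each pixel
is described by a fixed bank of multi-scale Gaussian, difference-of-
Gaussian and local-texture features, and a small one-hidden-layer network
maps the feature vector to a foreground probability. Because the feature
extractor is fixed and the head is tiny, the model trains in seconds on a
CPU while still capturing the signature of a lesion: a locally dark,
blob-scale intensity deficit sitting on otherwise bright tooth structure.

Inference is fully deterministic; parameters are serialisable to a single
``.npz`` checkpoint.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from pathlib import Path

import numpy as np
from scipy import ndimage

from .core import Radiograph, SegmentationMask

__all__ = ["SegmentationModel", "FilterBankSegmenter", "extract_features"]

_SIGMAS = (1.0, 2.0, 4.0)

#: feature order produced by :func:`extract_features`
FEATURE_NAMES = (
    "intensity",
    "gauss_s1",
    "gauss_s2",
    "gauss_s4",
    "dog_0_2",
    "dog_1_4",
    "local_sd_s2",
    "grad_mag_s1",
)


def extract_features(pixels: np.ndarray) -> np.ndarray:
    """Per-pixel multi-scale feature stack, shape ``(H*W, n_features)``.

    Features: raw intensity; Gaussian means at sigma 1/2/4 px (lesion-,
    blob- and tooth-scale context); two difference-of-Gaussian channels
    (centre-minus-surround contrast, strongly negative inside a dark blob);
    local standard deviation at sigma 2 (texture/edges); and the Gaussian
    gradient magnitude at sigma 1 (edges). Filters use reflective
    boundaries so small crops remain well-behaved.
    """
    img = np.asarray(pixels, dtype=np.float64)
    g = [ndimage.gaussian_filter(img, s, mode="reflect") for s in _SIGMAS]
    sq = ndimage.gaussian_filter(img * img, _SIGMAS[1], mode="reflect")
    local_var = np.clip(sq - g[1] * g[1], 0.0, None)
    feats = np.stack(
        [
            img,
            g[0],
            g[1],
            g[2],
            img - g[1],
            g[0] - g[2],
            np.sqrt(local_var),
            ndimage.gaussian_gradient_magnitude(img, _SIGMAS[0], mode="reflect"),
        ],
        axis=-1,
    )
    return feats.reshape(-1, feats.shape[-1])


class SegmentationModel(ABC):
    """Contract every backbone must satisfy to join the pipeline."""

    @abstractmethod
    def predict(self, pixels: np.ndarray) -> np.ndarray:
        """Per-pixel foreground probabilities in [0, 1], same shape as input."""

    @abstractmethod
    def save(self, path) -> None:
        """Serialise all parameters to a checkpoint file."""

    def predict_mask(self, image: Radiograph, threshold: float = 0.5) -> SegmentationMask:
        """Binarise the probability map at ``threshold``."""
        prob = self.predict(image.pixels)
        return SegmentationMask((prob >= threshold).astype(np.uint8))


class FilterBankSegmenter(SegmentationModel):
    """Fixed multi-scale filter bank + small MLP head, sigmoid output.

    Parameters
    ----------
    hidden_units:
        Width of the single tanh hidden layer (default 32).
    seed:
        Seed for parameter initialisation; two models built with the same
        seed start from identical parameters.
    """

    def __init__(self, hidden_units: int = 32, seed: int = 0):
        if hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        self.hidden_units = int(hidden_units)
        self.seed = int(seed)
        n_feat = len(FEATURE_NAMES)
        rng = np.random.default_rng(seed)
        scale = 1.0 / np.sqrt(n_feat)
        self.params: dict[str, np.ndarray] = {
            "W1": rng.normal(0.0, scale, size=(n_feat, hidden_units)),
            "b1": np.zeros(hidden_units),
            "w2": rng.normal(0.0, 1.0 / np.sqrt(hidden_units), size=(hidden_units,)),
            "b2": np.zeros(1),
        }
        # feature standardisation, fitted from the training set by the trainer
        self.feat_mean = np.zeros(n_feat)
        self.feat_std = np.ones(n_feat)

    # ---- numerics -------------------------------------------------------

    def set_normalisation(self, mean: np.ndarray, std: np.ndarray) -> None:
        self.feat_mean = np.asarray(mean, dtype=np.float64)
        self.feat_std = np.maximum(np.asarray(std, dtype=np.float64), 1e-8)

    def normalise(self, feats: np.ndarray) -> np.ndarray:
        return (feats - self.feat_mean) / self.feat_std

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, dict]:
        """Probabilities plus the cache needed for a backward pass.

        ``x`` must already be normalised, shape ``(n, n_features)``.
        """
        h = np.tanh(x @ self.params["W1"] + self.params["b1"])
        z = h @ self.params["w2"] + self.params["b2"][0]
        p = 1.0 / (1.0 + np.exp(-z))
        return p, {"x": x, "h": h}

    def backward(self, cache: dict, p: np.ndarray, y: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of mean BCE w.r.t. all parameters."""
        n = len(y)
        dz = (p - y) / n  # d(mean BCE)/dz for sigmoid output
        dh = np.outer(dz, self.params["w2"]) * (1.0 - cache["h"] ** 2)
        return {
            "W1": cache["x"].T @ dh,
            "b1": dh.sum(axis=0),
            "w2": cache["h"].T @ dz,
            "b2": np.array([dz.sum()]),
        }

    # ---- contract -------------------------------------------------------

    def predict(self, pixels: np.ndarray) -> np.ndarray:
        pixels = np.asarray(pixels, dtype=np.float64)
        feats = self.normalise(extract_features(pixels))
        p, _ = self.forward(feats)
        return p.reshape(pixels.shape)

    def save(self, path) -> None:
        np.savez(
            Path(path),
            hidden_units=self.hidden_units,
            seed=self.seed,
            feat_mean=self.feat_mean,
            feat_std=self.feat_std,
            **self.params,
        )

    @classmethod
    def load(cls, path) -> "FilterBankSegmenter":
        with np.load(Path(path)) as data:
            model = cls(hidden_units=int(data["hidden_units"]), seed=int(data["seed"]))
            model.params = {k: data[k].copy() for k in ("W1", "b1", "w2", "b2")}
            model.feat_mean = data["feat_mean"].copy()
            model.feat_std = data["feat_std"].copy()
        return model

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        self.params = {k: v.copy() for k, v in params.items()}
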