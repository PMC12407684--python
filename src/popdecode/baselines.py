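"""Comparator decoders sharing the evaluation stack with the network.

Two linear baselines:

* ``fit_logistic``: one class-weighted multinomial logistic regression
  per feature dimension on window-flattened input features (optionally
  time-averaged within the window);
* ``fit_pca_latent``: an unsupervised PCA projection standing in for
  the learned latent space, followed by the same linear classifier
  heads on the projection.  The latent size is chosen by a cumulative
  explained-variance target.

Both consume the same fold splits and report through the same
balanced-accuracy metrics as the autoencoder model, so differences in
accuracy isolate the effect of the nonlinear latent representation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

logger = logging.getLogger("popdecode.baselines")


@dataclass
class BaselineConfig:
    kind: str = "logistic"  # or "pca_latent"
    pca_variance_target: float = 0.95
    pca_max_components: int | None = None
    regularization_strength: float = 1.0  # C of the logistic fit
    time_averaged: bool = False


def _features(windows: np.ndarray, time_averaged: bool) -> np.ndarray:
    """(n, S, C, Wb, A) -> (n*S, F) window-flattened (or time-averaged)
    feature rows, window-major within each trial."""
    n, s = windows.shape[:2]
    if time_averaged:
        feats = windows.mean(axis=3).reshape(n * s, -1)
    else:
        feats = windows.reshape(n * s, -1)
    return feats


class LinearDecoder:
    """Per-dimension multinomial logistic heads over a fixed feature map."""

    def __init__(self, config: BaselineConfig, dim_sizes: list[int]):
        self.config = config
        self.dim_sizes = list(dim_sizes)
        self.heads: list[LogisticRegression] = []
        self.pca: PCA | None = None
        self.single_class_: list[int | None] = []

    def _transform(self, windows: np.ndarray) -> np.ndarray:
        feats = _features(windows, self.config.time_averaged)
        if self.pca is not None:
            feats = self.pca.transform(feats)
        return feats

    def fit(self, windows: np.ndarray, labels: np.ndarray) -> "LinearDecoder":
        n, s = windows.shape[:2]
        feats = _features(windows, self.config.time_averaged)
        if self.config.kind == "pca_latent":
            n_max = min(feats.shape[0], feats.shape[1])
            want = self.config.pca_max_components or n_max
            if want > n_max:
                logger.info("reducing PCA components from %d to %d", want, n_max)
            pca = PCA(n_components=min(want, n_max), random_state=0).fit(feats)
            cum = np.cumsum(pca.explained_variance_ratio_)
            keep = int(np.searchsorted(cum, self.config.pca_variance_target) + 1)
            keep = min(keep, pca.n_components_)
            self.pca = PCA(n_components=keep, random_state=0).fit(feats)
            feats = self.pca.transform(feats)
        y_all = np.repeat(labels, s, axis=0)
        self.heads, self.single_class_ = [], []
        for j, nj in enumerate(self.dim_sizes):
            y = y_all[:, j]
            present = np.unique(y)
            if present.size < 2:
                # degenerate training fold: constant prediction
                self.heads.append(None)
                self.single_class_.append(int(present[0]))
                continue
            counts = np.bincount(y, minlength=nj).astype(float)
            weight = {
                k: (y.size / (present.size * counts[k])) for k in present
            }
            clf = LogisticRegression(
                max_iter=300,
                C=self.config.regularization_strength,
                class_weight=weight,
            )
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                clf.fit(feats, y)
            self.heads.append(clf)
            self.single_class_.append(None)
        return self

    def predict_proba(self, windows: np.ndarray) -> list[np.ndarray]:
        n, s = windows.shape[:2]
        feats = self._transform(windows)
        out = []
        for j, nj in enumerate(self.dim_sizes):
            probs = np.zeros((n * s, nj))
            head = self.heads[j]
            if head is None:
                probs[:, self.single_class_[j]] = 1.0
            else:
                p = head.predict_proba(feats)
                probs[:, head.classes_] = p
            out.append(probs.reshape(n, s, nj))
        return out

    @property
    def latent_size(self) -> int | None:
        return None if self.pca is None else self.pca.n_components_


def fit_logistic(
    windows: np.ndarray,
    labels: np.ndarray,
    dim_sizes: list[int],
    config: BaselineConfig | None = None,
) -> LinearDecoder:
    """Class-weighted multinomial logistic decoder on window features."""
    config = config or BaselineConfig(kind="logistic")
    return LinearDecoder(config, dim_sizes).fit(windows, labels)


def fit_pca_latent(
    windows: np.ndarray,
    labels: np.ndarray,
    dim_sizes: list[int],
    config: BaselineConfig | None = None,
) -> LinearDecoder:
    """PCA latent projection followed by the same linear heads."""
    config = config or BaselineConfig(kind="pca_latent")
    config.kind = "pca_latent"
    return LinearDecoder(config, dim_sizes).fit(windows, labels)
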