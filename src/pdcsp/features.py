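"""Feature functionals applied to spatially filtered segments.

Each functional maps a ``d x N`` component matrix ``S`` (rows are the CSP
component time series) to a length-``d`` feature vector, one scalar per
component:

========= =====================================================
VAR       log of the component variance normalised by the total
BP        log of the mean squared amplitude (band power)
ENG       sum of squared amplitudes (energy)
THEN      threshold entropy: #samples with |s| > alpha
NOEN      norm entropy: sum |s|^p
SUEN      sure entropy: N - #{|s| <= q} + sum min(s^2, q^2)
LOGEN     log-energy entropy: sum log s^2 (zero samples contribute 0)
SHEN      Shannon entropy: sum s^2 log s^2 (zero samples contribute 0)
========= =====================================================

All logarithms are natural.  The entropies are the wavelet-entropy family
evaluated directly on the raw component samples, so the thresholds
``alpha`` and ``q`` are amplitude thresholds on whatever scale the input
signal uses.  The Shannon functional keeps its sign as defined above (no
leading minus); a global sign flip is irrelevant to every downstream
classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "Metric",
    "FeatureConfig",
    "FeatureMatrix",
    "SegmentFeatures",
    "feat_variance",
    "feat_bandpower",
    "feat_energy",
    "feat_threshold_entropy",
    "feat_norm_entropy",
    "feat_sure_entropy",
    "feat_log_energy_entropy",
    "feat_shannon_entropy",
    "extract_features",
    "METRICS",
]

METRICS = ("VAR", "BP", "ENG", "THEN", "NOEN", "SUEN", "LOGEN", "SHEN")
Metric = str


@dataclass(frozen=True)
class FeatureConfig:
    """Metric choice plus the entropy hyperparameters.

    ``alpha`` (threshold entropy) and ``q`` (sure entropy) are amplitude
    thresholds; ``p`` is the norm-entropy exponent (>= 1).
    """

    metric: Metric = "LOGEN"
    alpha: float = 0.2
    p: float = 1.1
    q: float = 3.0

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}; choose from {METRICS}")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.p < 1:
            raise ValueError("norm-entropy power p must be >= 1")
        if self.q <= 2:
            warnings.warn(f"sure-entropy threshold q={self.q} <= 2; q > 2 is recommended",
                          stacklevel=2)


def _as_components(S: np.ndarray) -> np.ndarray:
    S = np.asarray(S, dtype=float)
    if S.ndim == 1:
        S = S[None]
    if S.ndim != 2:
        raise ValueError(f"expected d x N component matrix, got shape {S.shape}")
    return S


def feat_variance(S: np.ndarray) -> np.ndarray:
    """log( var(s_j) / sum_j' var(s_j') ), population variance (divide by N)."""
    S = _as_components(S)
    v = S.var(axis=1)  # ddof=0, mean removed per row
    total = v.sum()
    if total <= 0:
        raise ValueError("degenerate input: every component has zero variance")
    return np.log(v / total)


def feat_bandpower(S: np.ndarray) -> np.ndarray:
    """log of the mean squared amplitude per component."""
    S = _as_components(S)
    return np.log(np.mean(S**2, axis=1))


def feat_energy(S: np.ndarray) -> np.ndarray:
    """Sum of squared amplitudes per component."""
    S = _as_components(S)
    return np.sum(S**2, axis=1)


def feat_threshold_entropy(S: np.ndarray, alpha: float = 0.2) -> np.ndarray:
    """Number of samples with |s| strictly above ``alpha``."""
    S = _as_components(S)
    return np.count_nonzero(np.abs(S) > alpha, axis=1).astype(float)


def feat_norm_entropy(S: np.ndarray, p: float = 1.1) -> np.ndarray:
    """sum |s|^p per component (p >= 1)."""
    S = _as_components(S)
    return np.sum(np.abs(S) ** p, axis=1)


def feat_sure_entropy(S: np.ndarray, q: float = 3.0) -> np.ndarray:
    """Stein-risk style functional: N - #{|s| <= q} + sum min(s^2, q^2)."""
    S = _as_components(S)
    N = S.shape[1]
    below = np.count_nonzero(np.abs(S) <= q, axis=1)
    return (N - below) + np.sum(np.minimum(S**2, q**2), axis=1)


def _safe_x2_log_x2(S: np.ndarray, weight: bool) -> np.ndarray:
    # log(s^2) with exact zeros contributing 0 (wavelet-entropy convention)
    x2 = S**2
    log_term = np.zeros_like(x2)
    nz = x2 > 0
    log_term[nz] = np.log(x2[nz])
    return np.sum(x2 * log_term if weight else log_term, axis=1)


def feat_log_energy_entropy(S: np.ndarray) -> np.ndarray:
    """sum log(s^2); zero samples contribute 0."""
    return _safe_x2_log_x2(_as_components(S), weight=False)


def feat_shannon_entropy(S: np.ndarray) -> np.ndarray:
    """sum s^2 log(s^2); zero samples contribute 0; sign as defined."""
    return _safe_x2_log_x2(_as_components(S), weight=True)


def compute_metric(S: np.ndarray, config: FeatureConfig) -> np.ndarray:
    table = {
        "VAR": feat_variance,
        "BP": feat_bandpower,
        "ENG": feat_energy,
        "THEN": lambda s: feat_threshold_entropy(s, config.alpha),
        "NOEN": lambda s: feat_norm_entropy(s, config.p),
        "SUEN": lambda s: feat_sure_entropy(s, config.q),
        "LOGEN": feat_log_energy_entropy,
        "SHEN": feat_shannon_entropy,
    }
    return table[config.metric](S)


@dataclass
class FeatureMatrix:
    """M x d feature values with labels; the classifier input."""

    values: np.ndarray
    labels: np.ndarray
    config: FeatureConfig

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.shape[0] != len(self.labels):
            raise ValueError("row count must equal label count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains NaN/Inf")

    @property
    def M(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values,
                          columns=[f"f{j + 1}" for j in range(self.d)])
        df["label"] = self.labels
        df.to_csv(path, index=False)


class SegmentFeatures(BaseEstimator, TransformerMixin):
    """Transformer from filtered segments ``(M, d, N)`` to features ``(M, d)``.

    Stateless (``fit`` records nothing); exists so the full
    CSP -> features -> classifier chain composes as a sklearn Pipeline.
    """

    def __init__(self, metric: Metric = "LOGEN", alpha: float = 0.2,
                 p: float = 1.1, q: float = 3.0):
        self.metric = metric
        self.alpha = alpha
        self.p = p
        self.q = q

    def _config(self) -> FeatureConfig:
        return FeatureConfig(metric=self.metric, alpha=self.alpha, p=self.p, q=self.q)

    def fit(self, X, y=None):
        self._config()  # validate parameters
        return self

    def transform(self, X):
        config = self._config()
        X = np.asarray(X, dtype=float)
        single = X.ndim == 2
        if single:
            X = X[None]
        rows = []
        for i, seg in enumerate(X):
            try:
                rows.append(compute_metric(seg, config))
            except ValueError as exc:
                raise ValueError(f"segment {i}: {exc}") from exc
        out = np.stack(rows)
        return out[0] if single else out


def extract_features(model, segment_set, config: FeatureConfig) -> FeatureMatrix:
    """Spatially filter every segment with ``model`` and apply the metric.

    ``model`` is a :class:`~pdcsp.csp.CSPModel`; ``segment_set`` a
    :class:`~pdcsp.preprocess.SegmentSet` (or a bare ``(M, ch, N)`` array
    plus ``labels`` attribute-compatible object).
    """
    from .csp import spatial_filter

    rows = []
    for i, seg in enumerate(segment_set.segments):
        try:
            rows.append(compute_metric(spatial_filter(model, seg), config))
        except ValueError as exc:
            raise ValueError(f"segment {i}: {exc}") from exc
    return FeatureMatrix(values=np.stack(rows), labels=np.asarray(segment_set.labels),
                         config=config)
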