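"""Common spatial pattern estimation and spatial filtering.

CSP finds linear channel combinations (spatial filters) whose output
variance is maximal for one class and minimal for the other, by
simultaneously diagonalising the two class-averaged normalised covariance
matrices.  The procedure:

1. per-segment normalised covariance ``C = E E' / trace(E E')``, averaged
   per class to give ``C_A_bar`` and ``C_B_bar``;
2. eigendecompose the composite ``C_C = C_A_bar + C_B_bar`` (eigenvalues
   descending) and form the whitening transform ``P = diag(l)^(-1/2) U'``
   so that ``P C_C P' = I``;
3. eigendecompose the whitened class-A covariance ``S_A = P C_A_bar P'``
   (eigenvalues descending) to obtain the orthonormal ``B`` and
   eigenvalues ``lambda_A``; since ``S_A + S_B = I``, the eigenvalues of
   the two classes sum to one component-wise;
4. the full projection is ``W = B' P`` (rows are spatial filters); the
   first row maximises class-A variance, the last maximises class-B
   variance.  Retaining the first and last ``m`` rows gives the reduced
   ``d x ch`` projection with reduction number ``d = 2m``.

The whitening exponent is -1/2: that is the unique choice under which the
class eigenvalues satisfy the sum-to-identity contract above.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "CSP",
    "CSPModel",
    "normalized_covariance",
    "class_mean_covariances",
    "csp_from_covariances",
    "fit_csp",
    "reduce_model",
    "spatial_filter",
]

# Groups treated as the "positive"/class-A side when labels allow it.
_POSITIVE_PRIORITY = ("PD_OFF", "PD_ON")


def normalized_covariance(segment: np.ndarray, mean_center: bool = True) -> np.ndarray:
    """Trace-normalised spatial covariance ``E E' / trace(E E')`` of one segment.

    ``mean_center`` subtracts the per-channel mean within the segment first
    (default on), making the result a proper covariance rather than a raw
    scatter matrix.
    """
    E = np.asarray(segment, dtype=float)
    if E.ndim != 2 or E.shape[1] < 2:
        raise ValueError(f"segment must be ch x N with N >= 2, got shape {E.shape}")
    if mean_center:
        E = E - E.mean(axis=1, keepdims=True)
    C = E @ E.T
    tr = np.trace(C)
    if tr <= 0:
        raise ValueError("degenerate segment: zero total power, covariance undefined")
    return C / tr


def class_mean_covariances(
    segments: np.ndarray | Sequence[np.ndarray],
    labels: Sequence,
    class_a,
    class_b,
    mean_center: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Arithmetic mean of per-segment normalised covariances for each class."""
    labels = np.asarray(labels)
    covs = {class_a: [], class_b: []}
    for seg, lab in zip(segments, labels):
        if lab in covs:
            covs[lab].append(normalized_covariance(seg, mean_center=mean_center))
    for cls, lst in covs.items():
        if not lst:
            raise ValueError(f"no training segments for class {cls!r}")
    return (np.mean(covs[class_a], axis=0), np.mean(covs[class_b], axis=0))


@dataclass
class CSPModel:
    """A fitted CSP projection.

    ``W_full`` rows are the ch spatial filters ordered by descending
    class-A eigenvalue; ``W_reduced`` keeps the first and last ``m`` rows
    (reduction number ``d = 2m``).
    """

    W_full: np.ndarray
    eigvals_A: np.ndarray
    m: int
    class_A: str
    class_B: str

    def __post_init__(self) -> None:
        self.W_full = np.asarray(self.W_full, dtype=float)
        self.eigvals_A = np.asarray(self.eigvals_A, dtype=float)
        ch = self.W_full.shape[0]
        if not 1 <= self.m <= ch // 2:
            raise ValueError(f"m must be in [1, ch/2] = [1, {ch // 2}], got {self.m}")

    @property
    def ch(self) -> int:
        return self.W_full.shape[0]

    @property
    def d(self) -> int:
        return 2 * self.m

    @property
    def eigvals_B(self) -> np.ndarray:
        return 1.0 - self.eigvals_A

    @property
    def W_reduced(self) -> np.ndarray:
        ch, m = self.ch, self.m
        return self.W_full[np.r_[0:m, ch - m:ch]]

    def save(self, path: str | Path) -> None:
        """Archive the projection as JSON (portable, text-only)."""
        payload = {
            "W_full": self.W_full.tolist(),
            "eigvals_A": self.eigvals_A.tolist(),
            "m": int(self.m),
            "class_A": self.class_A,
            "class_B": self.class_B,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "CSPModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            W_full=np.array(payload["W_full"]),
            eigvals_A=np.array(payload["eigvals_A"]),
            m=payload["m"],
            class_A=payload["class_A"],
            class_B=payload["class_B"],
        )


def _canonical_signs(W: np.ndarray) -> np.ndarray:
    """Flip each row so its largest-magnitude entry is positive (determinism)."""
    idx = np.argmax(np.abs(W), axis=1)
    signs = np.sign(W[np.arange(W.shape[0]), idx])
    signs[signs == 0] = 1.0
    return W * signs[:, None]


def csp_from_covariances(
    C_a: np.ndarray,
    C_b: np.ndarray,
    class_a: str = "A",
    class_b: str = "B",
    m: int | None = None,
    on_singular: str = "error",
    rank_rtol: float = 1e-10,
) -> CSPModel:
    """Solve the CSP algebra for given class-averaged covariances.

    ``on_singular`` controls rank-deficient composites: ``"error"`` (default)
    raises; ``"regularize"`` floors the composite eigenvalues by
    ``1e-10 * max`` before whitening.
    """
    C_a = np.asarray(C_a, dtype=float)
    C_b = np.asarray(C_b, dtype=float)
    ch = C_a.shape[0]
    if C_a.shape != (ch, ch) or C_b.shape != (ch, ch):
        raise ValueError("class covariances must be square and same shape")
    C_c = C_a + C_b
    lam_c, U_c = np.linalg.eigh(C_c)
    lam_c, U_c = lam_c[::-1], U_c[:, ::-1]  # descending
    if lam_c[-1] < rank_rtol * lam_c[0]:
        if on_singular == "regularize":
            lam_c = lam_c + 1e-10 * lam_c[0]
        else:
            raise np.linalg.LinAlgError(
                "composite covariance is rank deficient "
                f"(min/max eigenvalue ratio {lam_c[-1] / lam_c[0]:.2e}); "
                "pass on_singular='regularize' to floor the spectrum"
            )
    P = (U_c / np.sqrt(lam_c)).T  # diag(lam)^(-1/2) U'
    S_a = P @ C_a @ P.T
    lam_a, B = np.linalg.eigh(S_a)
    lam_a, B = lam_a[::-1], B[:, ::-1]  # descending: row 1 maximises class A
    W_full = _canonical_signs(B.T @ P)
    if m is None:
        m = ch // 2
    return CSPModel(W_full=W_full, eigvals_A=lam_a, m=m,
                    class_A=class_a, class_B=class_b)


def fit_csp(
    train_segments: np.ndarray | Sequence[np.ndarray],
    train_labels: Sequence,
    class_a,
    class_b,
    m: int | None = None,
    mean_center: bool = True,
    on_singular: str = "error",
) -> CSPModel:
    """Fit CSP from labelled training segments (never from test data)."""
    C_a, C_b = class_mean_covariances(train_segments, train_labels,
                                      class_a, class_b, mean_center=mean_center)
    return csp_from_covariances(C_a, C_b, class_a=str(class_a), class_b=str(class_b),
                                m=m, on_singular=on_singular)


def reduce_model(model: CSPModel, m: int) -> CSPModel:
    """Return a copy retaining the first and last ``m`` filters (d = 2m)."""
    if not 1 <= m <= model.ch // 2:
        raise ValueError(f"m must be in [1, {model.ch // 2}], got {m}")
    return CSPModel(W_full=model.W_full.copy(), eigvals_A=model.eigvals_A.copy(),
                    m=m, class_A=model.class_A, class_B=model.class_B)


def spatial_filter(model: CSPModel, segment: np.ndarray) -> np.ndarray:
    """Apply the reduced projection: returns the d x N component matrix."""
    segment = np.asarray(segment, dtype=float)
    if segment.shape[0] != model.ch:
        raise ValueError(
            f"segment has {segment.shape[0]} channels, model expects {model.ch}"
        )
    return model.W_reduced @ segment


class CSP(BaseEstimator, TransformerMixin):
    """Scikit-learn style CSP transformer over segment arrays.

    Parameters
    ----------
    m : int or None
        Number of filters retained from each end of the spectrum; the
        reduction number is ``d = 2m``.  ``None`` keeps everything
        (``m = ch // 2``).
    class_a : str or None
        Label treated as class A (the "positive", variance-maximised
        class).  ``None`` picks a Parkinson's group if present in ``y``,
        else the first label in sorted order.
    mean_center : bool
        Subtract the per-channel mean within each segment before the
        covariance (default True).
    on_singular : {"error", "regularize"}
        Handling of rank-deficient composite covariances.

    Attributes
    ----------
    model_ : CSPModel
        The fitted projection.
    filters_ : ndarray of shape (d, ch)
        Reduced spatial filters (rows).
    eigenvalues_ : ndarray of shape (ch,)
        Class-A eigenvalues, descending, in [0, 1].
    classes_ : ndarray
        ``[class_a, class_b]``.
    """

    def __init__(self, m: int | None = None, class_a: str | None = None,
                 mean_center: bool = True, on_singular: str = "error"):
        self.m = m
        self.class_a = class_a
        self.mean_center = mean_center
        self.on_singular = on_singular

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 3:
            raise ValueError("X must be (n_segments, ch, N)")
        uniq = sorted(np.unique(y).tolist())
        if len(uniq) != 2:
            raise ValueError(f"CSP is two-class; got labels {uniq}")
        if self.class_a is not None:
            if self.class_a not in uniq:
                raise ValueError(f"class_a={self.class_a!r} not among labels {uniq}")
            class_a = self.class_a
        else:
            class_a = next((g for g in _POSITIVE_PRIORITY if g in uniq), uniq[0])
        class_b = next(u for u in uniq if u != class_a)
        self.model_ = fit_csp(X, y, class_a, class_b, m=self.m,
                              mean_center=self.mean_center,
                              on_singular=self.on_singular)
        self.classes_ = np.array([class_a, class_b])
        self.filters_ = self.model_.W_reduced
        self.eigenvalues_ = self.model_.eigvals_A
        return self

    def transform(self, X):
        if not hasattr(self, "model_"):
            raise RuntimeError("CSP instance is not fitted yet")
        X = np.asarray(X, dtype=float)
        single = X.ndim == 2
        if single:
            X = X[None]
        out = np.einsum("dc,mcn->mdn", self.filters_, X)
        return out[0] if single else out
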