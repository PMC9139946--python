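"""Synthetic two-class multichannel datasets with planted spatial structure.

The generator draws latent band-limited Gaussian sources, scales the
variance of the first and last source in opposite directions for the two
classes, and mixes the sources into channel space with a random (by
default orthogonal) mixing matrix, plus band-limited sensor noise:

    x(t) = A s(t) + n(t)

Class A multiplies source 1's variance by ``1 + separation`` and divides
source ch's variance by the same factor; class B is the mirror image.
``separation = 0`` therefore makes the class distributions identical (the
null condition), and increasing it plants exactly the class-dependent
covariance structure that common spatial patterns are designed to find —
the minimal model under which CSP is adequate.  No attempt is made to
imitate real EEG spectra (1/f background, artifacts, nonstationarity).

Everything is reproducible from the two seeds: ``mixing_seed`` fixes the
mixing matrix, ``noise_seed`` the source and noise draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io import Eyes, Group, Recording
from .preprocess import BandSpec

__all__ = ["SynthSpec", "mixing_matrix", "source_variances",
           "generate_dataset", "theoretical_covariances"]


@dataclass(frozen=True)
class SynthSpec:
    """Generator parameters.

    separation is the variance ratio knob: class-discriminative source
    variances are ``(1 + separation)^{+/-1}``.  ``noise_std`` is the sensor
    noise standard deviation relative to the unit source variance.
    """

    ch: int = 8
    fs: float = 256.0
    duration_s: float = 100.0
    n_recordings: int = 4          # per class
    separation: float = 4.0
    mixing_seed: int = 7
    noise_seed: int = 11
    band_hz: tuple[float, float] = (10.0, 30.0)
    noise_band_hz: tuple[float, float] = (1.0, 45.0)
    noise_std: float = 0.2
    n_discriminative: int = 1      # sources boosted/attenuated at each end
    orthogonal_mixing: bool = True
    class_a: Group = Group.PD_OFF
    class_b: Group = Group.HC

    def __post_init__(self) -> None:
        if self.ch < 2:
            raise ValueError("need at least 2 channels")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")
        if not 1 <= self.n_discriminative <= self.ch // 2:
            raise ValueError("n_discriminative must be in [1, ch/2]")
        for band in (self.band_hz, self.noise_band_hz):
            if not 0 < band[0] < band[1] < self.fs / 2:
                raise ValueError(f"band {band} invalid for fs={self.fs}")


def mixing_matrix(spec: SynthSpec) -> np.ndarray:
    """The ch x ch mixing matrix, deterministic in ``mixing_seed``.

    Orthogonal by default (QR of a Gaussian matrix with a sign fix making
    the factorisation unique); optionally a general invertible Gaussian
    matrix for robustness experiments.
    """
    rng = np.random.default_rng(spec.mixing_seed)
    G = rng.standard_normal((spec.ch, spec.ch))
    if not spec.orthogonal_mixing:
        return G
    Q, R = np.linalg.qr(G)
    return Q * np.sign(np.diag(R))


def source_variances(spec: SynthSpec, class_a: bool) -> np.ndarray:
    """Latent source variance profile for one class (before band-limiting).

    The first ``n_discriminative`` sources are boosted by ``1 + separation``
    and the last ``n_discriminative`` attenuated by the same factor (class B
    mirrored), so the class-discriminative variance occupies exactly
    ``2 * n_discriminative`` spatial components.
    """
    v = np.ones(spec.ch)
    boost = 1.0 + spec.separation
    nd = spec.n_discriminative
    if class_a:
        v[:nd] *= boost
        v[-nd:] /= boost
    else:
        v[:nd] /= boost
        v[-nd:] *= boost
    return v


def _band_limited_noise(rng: np.random.Generator, shape, sos) -> np.ndarray:
    return signal.sosfiltfilt(sos, rng.standard_normal(shape), axis=-1)


def _white_noise_power_gain(sos: np.ndarray, n_freqs: int = 4096) -> float:
    """Output variance of unit white noise through forward-backward filtering.

    Forward-backward application squares the magnitude response, so the
    gain is the frequency average of |H|^4.
    """
    _, H = signal.sosfreqz(sos, worN=n_freqs)
    return float(np.mean(np.abs(H) ** 4))


def generate_dataset(spec: SynthSpec) -> list[Recording]:
    """Draw ``2 * n_recordings`` labelled recordings (class A first)."""
    A = mixing_matrix(spec)
    rng = np.random.default_rng(spec.noise_seed)
    sos_src = signal.butter(5, spec.band_hz, btype="bandpass", fs=spec.fs, output="sos")
    sos_noise = signal.butter(5, spec.noise_band_hz, btype="bandpass", fs=spec.fs,
                              output="sos")
    n = int(round(spec.duration_s * spec.fs))
    recordings = []
    for group, is_a in ((spec.class_a, True), (spec.class_b, False)):
        std = np.sqrt(source_variances(spec, is_a))
        for r in range(spec.n_recordings):
            sources = _band_limited_noise(rng, (spec.ch, n), sos_src) * std[:, None]
            noise = _band_limited_noise(rng, (spec.ch, n), sos_noise) * spec.noise_std
            recordings.append(Recording(
                data=A @ sources + noise,
                fs=spec.fs,
                subject_id=f"{group.value}_{r:02d}",
                group=group,
                eyes=Eyes.UNKNOWN,
            ))
    return recordings


def theoretical_covariances(spec: SynthSpec, A: np.ndarray | None = None
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form unit-trace class covariances of the generated data.

    ``g_s A D A' + g_n noise_std^2 I`` with the band-limiting power gains
    ``g`` of the source and noise filters; these are exact targets for the
    averaged normalised covariances the CSP fit estimates from raw
    (unfiltered) generated segments.
    """
    if A is None:
        A = mixing_matrix(spec)
    g_src = _white_noise_power_gain(
        signal.butter(5, spec.band_hz, btype="bandpass", fs=spec.fs, output="sos"))
    g_noise = _white_noise_power_gain(
        signal.butter(5, spec.noise_band_hz, btype="bandpass", fs=spec.fs, output="sos"))
    covs = []
    for is_a in (True, False):
        C = g_src * A @ np.diag(source_variances(spec, is_a)) @ A.T
        C = C + g_noise * spec.noise_std**2 * np.eye(spec.ch)
        covs.append(C / np.trace(C))
    return covs[0], covs[1]
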