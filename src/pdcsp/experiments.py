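"""Sweep drivers: frequency band, reduction number, and segment length.

Each sweep re-runs the full cross-validated pipeline once per swept value
with everything else held fixed, and collects a long-format table of
fold-mean +/- fold-std for every performance metric — the shape of the
result tables these investigations are usually reported in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .evaluate import ClassifierSpec, run_pipeline
from .features import FeatureConfig
from .preprocess import BAND_PRESETS, BandSpec

__all__ = ["SweepSpec", "run_sweep", "SWEEP_AXES"]

logger = logging.getLogger(__name__)

SWEEP_AXES = ("BAND", "REDUCTION", "SEGMENT_LENGTH")

_REPORT_METRICS = ("accuracy", "sensitivity", "specificity", "precision", "f_score", "auc")


@dataclass
class SweepSpec:
    """One swept axis plus the fixed configuration of everything else.

    values:
      BAND            -> (low_hz, high_hz) pairs or preset names
      REDUCTION       -> even reduction numbers d (m = d / 2)
      SEGMENT_LENGTH  -> durations T in seconds
    fixed: keyword arguments for :func:`pdcsp.evaluate.run_pipeline`
    (band, T, m, feature_config, classifier_spec, k, seed, cv_mode).
    """

    axis: str
    values: list
    fixed: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.axis not in SWEEP_AXES:
            raise ValueError(f"axis must be one of {SWEEP_AXES}, got {self.axis!r}")
        if not self.values:
            raise ValueError("sweep needs at least one value")


def _resolve_band(value) -> BandSpec:
    if isinstance(value, str):
        return BandSpec.preset(value)
    low, high = value
    return BandSpec(float(low), float(high))


def _cell_kwargs(spec: SweepSpec, value) -> tuple[dict, str]:
    kwargs = dict(spec.fixed)
    if spec.axis == "BAND":
        band = _resolve_band(value)
        kwargs["band"] = band
        label = f"{band.low_hz:g}-{band.high_hz:g}"
    elif spec.axis == "REDUCTION":
        d = int(value)
        if d < 2 or d % 2:
            raise ValueError(f"reduction number d must be even and >= 2, got {d}")
        kwargs["m"] = d // 2
        label = str(d)
    else:  # SEGMENT_LENGTH
        kwargs["T"] = float(value)
        label = f"{float(value):g}"
    return kwargs, label


def run_sweep(recordings: Sequence, spec: SweepSpec) -> pd.DataFrame:
    """One pipeline run per swept value; returns a long-format table.

    Columns: axis, value, metric (feature functional), classifier, one
    ``<name>_mean``/``<name>_std`` pair per performance metric, and an
    ``error`` column (a failing cell records its error and the sweep
    continues).
    """
    rows = []
    for value in spec.values:
        kwargs, label = _cell_kwargs(spec, value)
        feature_config: FeatureConfig = kwargs.get("feature_config") or FeatureConfig()
        classifier_spec: ClassifierSpec = kwargs.get("classifier_spec") or ClassifierSpec()
        row = {
            "axis": spec.axis,
            "value": label,
            "metric": feature_config.metric,
            "classifier": classifier_spec.kind,
            "error": "",
        }
        try:
            result = run_pipeline(recordings, **kwargs)
            for name in _REPORT_METRICS:
                row[f"{name}_mean"] = result.mean(name)
                row[f"{name}_std"] = result.std(name)
        except Exception as exc:  # record and continue with remaining cells
            logger.warning("sweep cell %s=%s failed: %s", spec.axis, label, exc)
            row["error"] = str(exc)
            for name in _REPORT_METRICS:
                row[f"{name}_mean"] = float("nan")
                row[f"{name}_std"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
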