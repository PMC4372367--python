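"""White-matter internal-standard calibration and VOI extraction.

Quantitative DSC maps are only defined up to an overall scale; following
common practice the maps are rescaled so normal white matter attains preset
literature values (22 ml/100 g/min, 2.7 ml/100 g).  Relative rCBF/rCBV are
VOI means divided by the white-matter reference mean, computed on the same
inclusion-masked basis, and are independent of calibration altogether.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .deconv import PerfusionMaps
from .errors import DataError, ParameterError, StateError
from .masking import BinaryMask

__all__ = [
    "CalibrationConstants",
    "VOIMeasurement",
    "calibrate_maps",
    "extract_voi_values",
    "measurements_to_frame",
]


@dataclass(frozen=True)
class CalibrationConstants:
    """White-matter internal standard presets."""

    wm_cbf: float = 22.0  # ml/100 g/min
    wm_cbv: float = 2.7  # ml/100 g

    def __post_init__(self) -> None:
        if self.wm_cbf <= 0 or self.wm_cbv <= 0:
            raise ParameterError("calibration constants must be positive")


@dataclass(frozen=True)
class VOIMeasurement:
    """Per-structure, per-hemisphere perfusion summary for one subject."""

    subject_id: str
    group: str  # patient | control
    structure: str
    side: str  # left | right
    n_voxels: int
    cbf_mean: float
    cbv_mean: float
    rcbf: float
    rcbv: float


def calibrate_maps(
    maps: PerfusionMaps,
    wm_voi: np.ndarray,
    constants: CalibrationConstants = CalibrationConstants(),
) -> PerfusionMaps:
    """Rescale maps so the white-matter VOI means hit the presets exactly."""
    if maps.calibrated:
        raise StateError("maps are already calibrated")
    wm_voi = np.asarray(wm_voi, dtype=bool)
    if not wm_voi.any():
        raise DataError("white-matter VOI is empty")
    wm_cbf_mean = float(maps.cbf[wm_voi].mean())
    wm_cbv_mean = float(maps.cbv[wm_voi].mean())
    if wm_cbf_mean <= 0 or wm_cbv_mean <= 0:
        raise DataError("white-matter mean is zero; cannot calibrate")
    fc = constants.wm_cbf / wm_cbf_mean
    fv = constants.wm_cbv / wm_cbv_mean
    return PerfusionMaps(
        cbf=maps.cbf * fc,
        cbv=maps.cbv * fv,
        svd_threshold=maps.svd_threshold,
        calibrated=True,
        scale_cbf=fc,
        scale_cbv=fv,
    )


def _split_name(name: str) -> tuple[str, str]:
    for side in ("left", "right"):
        if name.endswith("_" + side):
            return name[: -len(side) - 1], side
    return name, "both"


def extract_voi_values(
    maps: PerfusionMaps,
    label_map: np.ndarray,
    inclusion: BinaryMask,
    label_table: dict[str, int],
    wm_label: int,
    subject_id: str = "subject",
    group: str = "control",
) -> list[VOIMeasurement]:
    """Mean CBF/CBV and rCBF/rCBV per structure and side.

    Every mean is taken over VOI intersected with the inclusion mask; the
    white-matter reference mean uses the identical masking.  A VOI whose
    intersection is empty is reported with n_voxels = 0 and NaN values
    (missing, not zero) and a warning.
    """
    label_map = np.asarray(label_map)
    incl = inclusion.data
    if label_map.shape != maps.cbf.shape or incl.shape != maps.cbf.shape:
        raise DataError("label map, maps and inclusion mask must share a grid")
    wm_mask = (label_map == wm_label) & incl
    if not np.any(label_map == wm_label):
        raise DataError(f"white-matter label {wm_label} absent from label map")
    if not wm_mask.any():
        raise DataError("white-matter reference VOI empty after inclusion masking")
    wm_cbf = float(maps.cbf[wm_mask].mean())
    wm_cbv = float(maps.cbv[wm_mask].mean())
    out: list[VOIMeasurement] = []
    for name, code in label_table.items():
        if code == wm_label:
            continue
        structure, side = _split_name(name)
        voi = (label_map == code) & incl
        n = int(voi.sum())
        if n == 0:
            warnings.warn(f"VOI {name!r} empty after inclusion masking", stacklevel=2)
            out.append(
                VOIMeasurement(subject_id, group, structure, side, 0, np.nan, np.nan, np.nan, np.nan)
            )
            continue
        cbf_mean = float(maps.cbf[voi].mean())
        cbv_mean = float(maps.cbv[voi].mean())
        out.append(
            VOIMeasurement(
                subject_id,
                group,
                structure,
                side,
                n,
                cbf_mean,
                cbv_mean,
                cbf_mean / wm_cbf if wm_cbf > 0 else np.nan,
                cbv_mean / wm_cbv if wm_cbv > 0 else np.nan,
            )
        )
    return out


def measurements_to_frame(measurements: list[VOIMeasurement]) -> pd.DataFrame:
    """Tidy DataFrame: one row per subject x structure x side."""
    return pd.DataFrame([m.__dict__ for m in measurements])
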