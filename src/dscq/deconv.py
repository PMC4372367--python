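"""Truncated-SVD deconvolution for CBF and integral-ratio CBV.

The tissue curve is modelled as C_t = CBF * (AIF * R); discretising the
convolution gives C_t = A r with A the lower-triangular Toeplitz matrix
A[i, j] = dt * AIF[i-j] (j <= i).  Standard SVD (sSVD) regularisation
zeroes singular values below a fixed fraction of the largest before
pseudo-inverting; CBF is read out as the maximum of the deconvolved
flow-scaled residue, which tolerates bolus delay.  CBV is the ratio of the
tissue and arterial curve integrals (indicator dilution).

Raw maps are in arbitrary units until the quant module calibrates them to
the white-matter internal standard.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import toeplitz

from .aif import ArterialInputFunction
from .errors import DataError, ParameterError, ShapeError
from .kinetics import ConcentrationVolume

__all__ = [
    "PerfusionMaps",
    "convolution_matrix",
    "truncated_svd_pinv",
    "svd_deconvolve",
    "compute_cbv",
    "make_maps",
]

DEFAULT_SVD_THRESHOLD = 0.2


@dataclass
class PerfusionMaps:
    """CBF/CBV volumes plus calibration state.

    Uncalibrated values are in arbitrary units; after calibration CBF is in
    ml/100 g/min and CBV in ml/100 g.
    """

    cbf: np.ndarray
    cbv: np.ndarray
    svd_threshold: float
    calibrated: bool = False
    scale_cbf: float = 1.0
    scale_cbv: float = 1.0


def convolution_matrix(aif_curve: np.ndarray, dt: float) -> np.ndarray:
    """Lower-triangular Toeplitz matrix A[i, j] = dt * aif[i - j], j <= i."""
    aif_curve = np.asarray(aif_curve, dtype=float)
    col = dt * aif_curve
    row = np.zeros_like(col)
    row[0] = col[0]
    return toeplitz(col, row)


def truncated_svd_pinv(a: np.ndarray, threshold: float) -> np.ndarray:
    """Pseudo-inverse with singular values below threshold*sigma_max zeroed."""
    if not (0.0 < threshold < 1.0):
        raise ParameterError("svd_threshold must lie in (0, 1)")
    u, s, vt = np.linalg.svd(a, full_matrices=False)
    keep = s >= threshold * s[0]
    s_inv = np.where(keep, 1.0 / np.where(s > 0, s, 1.0), 0.0)
    return (vt.T * s_inv) @ u.T


def svd_deconvolve(
    tissue_curve: np.ndarray,
    aif: ArterialInputFunction | np.ndarray,
    dt: float,
    svd_threshold: float = DEFAULT_SVD_THRESHOLD,
) -> tuple[float, np.ndarray]:
    """Deconvolve one tissue curve; returns (cbf_raw, residue_curve).

    cbf_raw is the peak of the flow-scaled residue A+ . tissue;
    residue_curve is normalised to peak 1 when cbf_raw > 0.
    """
    aif_curve = aif.curve if isinstance(aif, ArterialInputFunction) else np.asarray(aif, float)
    tissue_curve = np.asarray(tissue_curve, dtype=float)
    if tissue_curve.shape != aif_curve.shape:
        raise ShapeError("tissue and AIF curves must have equal length")
    if dt <= 0:
        raise ParameterError("dt must be positive")
    if not np.all(np.isfinite(tissue_curve)) or not np.all(np.isfinite(aif_curve)):
        raise DataError("non-finite values in deconvolution input")
    if np.trapezoid(np.clip(aif_curve, 0, None), dx=dt) <= 0:
        raise DataError("AIF has no positive mass")
    a_inv = truncated_svd_pinv(convolution_matrix(aif_curve, dt), svd_threshold)
    residue_scaled = a_inv @ tissue_curve
    cbf_raw = float(residue_scaled.max())
    if cbf_raw > 0:
        residue = residue_scaled / cbf_raw
    else:
        cbf_raw = max(cbf_raw, 0.0)
        residue = residue_scaled
    return cbf_raw, residue


def compute_cbv(tissue_curve: np.ndarray, aif_curve: np.ndarray, dt: float) -> float:
    """Indicator-dilution CBV: trapezoidal integral ratio tissue / AIF.

    Negative samples (noise) are clipped to zero before integrating.
    """
    tissue = np.clip(np.asarray(tissue_curve, dtype=float), 0.0, None)
    art = np.clip(np.asarray(aif_curve, dtype=float), 0.0, None)
    denom = np.trapezoid(art, dx=dt)
    if denom <= 0:
        raise DataError("AIF has no positive mass")
    return float(np.trapezoid(tissue, dx=dt) / denom)


def make_maps(
    conc: ConcentrationVolume,
    aif: ArterialInputFunction,
    mask: np.ndarray,
    svd_threshold: float = DEFAULT_SVD_THRESHOLD,
) -> PerfusionMaps:
    """Voxelwise CBF/CBV maps over a mask (zero outside).

    The truncated pseudo-inverse is built once from the AIF and applied to
    all in-mask curves; negative outputs are clipped to zero.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != conc.data.shape[:3]:
        raise ShapeError("mask shape does not match the concentration volume")
    if not mask.any():
        raise DataError("empty analysis mask")
    dt = conc.dt
    a_inv = truncated_svd_pinv(convolution_matrix(aif.curve, dt), svd_threshold)
    curves = conc.data[mask]  # (n_voxels, n_t)
    residues = curves @ a_inv.T
    cbf_vals = np.clip(residues.max(axis=1), 0.0, None)
    art_mass = np.trapezoid(np.clip(aif.curve, 0, None), dx=dt)
    if art_mass <= 0:
        raise DataError("AIF has no positive mass")
    cbv_vals = np.trapezoid(np.clip(curves, 0.0, None), dx=dt, axis=1) / art_mass
    cbf = np.zeros(mask.shape)
    cbv = np.zeros(mask.shape)
    cbf[mask] = cbf_vals
    cbv[mask] = np.clip(cbv_vals, 0.0, None)
    return PerfusionMaps(cbf=cbf, cbv=cbv, svd_threshold=svd_threshold)
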