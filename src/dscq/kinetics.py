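"""Signal-to-concentration conversion and per-voxel curve descriptors.

Concentration follows the usual DSC relation C(t) = -ln(S(t)/S0) / (TE*k)
with S0 the mean pre-bolus baseline signal.  Descriptors are the three
quantities used for automatic AIF detection: peak concentration (Cmax),
time to peak (TTP) and the first-moment transit time (fMTT).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, ShapeError
from .phantom import AcquisitionParams, K_SUSCEPTIBILITY

__all__ = [
    "DynamicSeries",
    "ConcentrationVolume",
    "CurveDescriptors",
    "default_baseline_window",
    "signal_to_concentration",
    "curve_descriptors",
    "descriptor_maps",
]


@dataclass
class DynamicSeries:
    """4D bolus-tracking signal with its acquisition parameters."""

    data: np.ndarray  # (x, y, z, t)
    acq: AcquisitionParams

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ShapeError("DynamicSeries.data must be 4D (x, y, z, t)")
        if self.data.shape[-1] != self.acq.n_timepoints:
            raise ShapeError("time axis length does not match acq.n_timepoints")

    @property
    def t_axis(self) -> np.ndarray:
        return self.acq.t_axis


@dataclass
class ConcentrationVolume:
    """4D contrast concentration in arbitrary units."""

    data: np.ndarray  # (x, y, z, t)
    t_axis: np.ndarray
    baseline_window: tuple[int, int]  # half-open [start, stop)
    n_clipped: int = 0  # nonpositive-signal samples zeroed during conversion

    @property
    def dt(self) -> float:
        return float(self.t_axis[1] - self.t_axis[0])


@dataclass(frozen=True)
class CurveDescriptors:
    cmax: float
    ttp: float
    fmtt: float
    zero_mass: bool = False


def default_baseline_window(series: DynamicSeries, max_len: int = 8, drop: float = 0.05) -> tuple[int, int]:
    """Pre-bolus baseline window.

    Timepoints 0..7, or all points before the global-mean signal first drops
    `drop` below its running pre-arrival mean, whichever is shorter.
    """
    mean = series.data.reshape(-1, series.data.shape[-1]).mean(axis=0)
    stop = max_len
    run_sum = 0.0
    for i in range(series.acq.n_timepoints):
        if i > 0 and mean[i] < (1.0 - drop) * (run_sum / i):
            stop = i
            break
        run_sum += mean[i]
    stop = max(1, min(stop, max_len))
    return (0, stop)


def signal_to_concentration(
    series: DynamicSeries,
    baseline_window: tuple[int, int] | None = None,
    mask: np.ndarray | None = None,
) -> ConcentrationVolume:
    """Invert the susceptibility signal relation per voxel.

    S0 is the mean over the baseline window; nonpositive signal samples
    (noise excursions) yield C = 0 and are counted in `n_clipped`.  Voxels
    with nonpositive baseline mean inside `mask` (default: voxels with any
    signal) raise a DataError naming the first offender.
    """
    if baseline_window is None:
        baseline_window = default_baseline_window(series)
    b0, b1 = baseline_window
    if b1 <= b0:
        raise DataError("baseline window is empty")
    sig = np.asarray(series.data, dtype=float)
    s0 = sig[..., b0:b1].mean(axis=-1)
    if mask is None:
        # default: every voxel carrying signal anywhere in the series
        mask = np.any(sig != 0, axis=-1)
    bad = mask & (s0 <= 0)
    if np.any(bad):
        idx = tuple(int(i) for i in np.argwhere(bad)[0])
        raise DataError(f"nonpositive baseline mean in voxel {idx}")
    te_k = series.acq.te * K_SUSCEPTIBILITY
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = sig / np.where(s0 == 0, 1.0, s0)[..., None]
        conc = -np.log(np.clip(ratio, 1e-300, None)) / te_k
    invalid = (sig <= 0) | (s0 <= 0)[..., None]
    n_clipped = int(np.count_nonzero(invalid & mask[..., None]))
    conc[invalid] = 0.0
    conc[~mask] = 0.0
    return ConcentrationVolume(
        data=conc, t_axis=series.t_axis, baseline_window=(b0, b1), n_clipped=n_clipped
    )


def curve_descriptors(curve: np.ndarray, t_axis: np.ndarray) -> CurveDescriptors:
    """Cmax, TTP and first-moment MTT of one concentration curve.

    The curve is clipped at zero for the moment computation (tracer mass is
    nonnegative); TTP ties resolve to the earliest timepoint.  A zero-mass
    curve gets fmtt = 0 and is flagged.
    """
    curve = np.asarray(curve, dtype=float)
    t_axis = np.asarray(t_axis, dtype=float)
    if curve.shape != t_axis.shape:
        raise ShapeError("curve and t_axis lengths differ")
    if not np.all(np.isfinite(curve)):
        raise DataError("curve contains non-finite values")
    pos = np.clip(curve, 0.0, None)
    peak = int(np.argmax(curve))
    mass = pos.sum()
    if mass > 0:
        fmtt = float((t_axis * pos).sum() / mass)
        zero_mass = False
    else:
        fmtt = 0.0
        zero_mass = True
    return CurveDescriptors(
        cmax=float(curve[peak]), ttp=float(t_axis[peak]), fmtt=fmtt, zero_mass=zero_mass
    )


def descriptor_maps(conc: ConcentrationVolume) -> dict[str, np.ndarray]:
    """Vectorised Cmax/TTP/fMTT maps over the whole volume."""
    data = conc.data
    t = conc.t_axis
    pos = np.clip(data, 0.0, None)
    peak_idx = np.argmax(data, axis=-1)
    cmax = np.take_along_axis(data, peak_idx[..., None], axis=-1)[..., 0]
    ttp = t[peak_idx]
    mass = pos.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fmtt = np.where(mass > 0, (pos * t).sum(axis=-1) / np.where(mass > 0, mass, 1.0), 0.0)
    return {"cmax": cmax, "ttp": ttp, "fmtt": fmtt}
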