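"""Automatic arterial input function selection.

Arterial voxels have high Cmax, short TTP and short fMTT.  Candidates are
scored by an equal-weight rank sum over the three descriptors, the best
`n` (default 20) voxel curves are averaged, smoothed with a short moving
average, and truncated after the first post-peak local minimum to remove
the recirculation (second pass) of the tracer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .errors import DataError, ParameterError
from .kinetics import ConcentrationVolume

__all__ = ["ArterialInputFunction", "rank_aif_candidates", "build_aif"]


@dataclass
class ArterialInputFunction:
    """Averaged, smoothed, first-pass arterial concentration curve."""

    curve: np.ndarray
    t_axis: np.ndarray
    voxel_indices: np.ndarray  # (n_selected, 3) int
    truncation_index: int  # last retained timepoint

    @property
    def n_selected(self) -> int:
        return int(self.voxel_indices.shape[0])


def rank_aif_candidates(
    descriptors: dict[str, np.ndarray],
    search_mask: np.ndarray,
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> np.ndarray:
    """Order in-mask voxels from most to least arterial.

    Composite score = w_c*rank(-cmax) + w_t*rank(ttp) + w_f*rank(fmtt)
    (average ranks, ascending); ties break toward higher Cmax, then
    lexicographic voxel index, so the ordering is independent of voxel
    storage order.  Returns an (n, 3) array of voxel coordinates.
    """
    search_mask = np.asarray(search_mask, dtype=bool)
    if not search_mask.any():
        raise DataError("empty AIF search mask")
    coords = np.argwhere(search_mask)
    cmax = descriptors["cmax"][search_mask]
    ttp = descriptors["ttp"][search_mask]
    fmtt = descriptors["fmtt"][search_mask]
    composite = (
        weights[0] * rankdata(-cmax)
        + weights[1] * rankdata(ttp)
        + weights[2] * rankdata(fmtt)
    )
    order = np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0], -cmax, composite))
    return coords[order]


def _moving_average(curve: np.ndarray, window: int) -> np.ndarray:
    if window % 2 != 1 or window < 1:
        raise ParameterError("smooth_window must be a positive odd integer")
    if window == 1:
        return curve.copy()
    half = window // 2
    padded = np.pad(curve, half, mode="edge")
    kernel = np.full(window, 1.0 / window)
    return np.convolve(padded, kernel, mode="valid")


def _first_pass_truncation(curve: np.ndarray) -> int:
    """Index of the first local minimum after the global peak.

    If the curve decays monotonically to the end (no recirculation), the
    final index is returned and nothing is removed.
    """
    peak = int(np.argmax(curve))
    i = peak
    n = curve.size
    while i + 1 < n and curve[i + 1] <= curve[i]:
        i += 1
    return i


def build_aif(
    conc: ConcentrationVolume,
    ranked_voxels: np.ndarray,
    n: int = 20,
    smooth_window: int = 3,
    truncate: bool = True,
) -> ArterialInputFunction:
    """Average the best `n` candidate curves, smooth, and cut the second pass.

    Fewer than `n` available candidates degrades gracefully (all available
    are used, with a warning).  The returned curve is clipped at zero and
    zeroed beyond the truncation index.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    ranked_voxels = np.asarray(ranked_voxels)
    if ranked_voxels.shape[0] < n:
        warnings.warn(
            f"only {ranked_voxels.shape[0]} AIF candidates available (requested {n}); "
            "using all of them",
            stacklevel=2,
        )
        n = ranked_voxels.shape[0]
        if n == 0:
            raise DataError("no AIF candidate voxels")
    sel = ranked_voxels[:n]
    curves = conc.data[sel[:, 0], sel[:, 1], sel[:, 2], :]
    mean_curve = curves.mean(axis=0)
    smooth = _moving_average(mean_curve, smooth_window)
    smooth = np.clip(smooth, 0.0, None)
    if truncate:
        ti = _first_pass_truncation(smooth)
    else:
        ti = smooth.size - 1
    out = smooth.copy()
    out[ti + 1 :] = 0.0
    return ArterialInputFunction(
        curve=out, t_axis=np.asarray(conc.t_axis), voxel_indices=sel, truncation_index=ti
    )
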