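"""Parenchyma, vessel, and inclusion masks.

Parenchyma is segmented from the anatomical volume by intensity only:
a 2-class background/head split followed by a 3-class split of head voxels
keeping the upper two classes (tissue), then the largest connected
component.  Both splits run on the empirical-CDF (rank) scale, so the
mask is invariant under any strictly monotone intensity rescaling.

Vessels are voxels whose Cmax exceeds 3.0 times the median Cmax of the
parenchyma (the empirical distribution of parenchyma-masked Cmax values,
strict inequality).  The analysis inclusion mask is parenchyma AND NOT
vessel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_multiotsu, threshold_otsu

from .errors import DataError, ParameterError, ShapeError

__all__ = ["BinaryMask", "parenchyma_mask", "vessel_mask", "inclusion_mask"]


@dataclass
class BinaryMask:
    data: np.ndarray  # 3D bool
    kind: str  # parenchyma | vessel | inclusion
    provenance: dict[str, Any] = field(default_factory=dict)

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.data))


def _cdf_ranks(values: np.ndarray) -> np.ndarray:
    """Average ranks normalised to (0, 1]: the empirical CDF at each voxel.

    Strictly monotone intensity rescaling leaves ranks unchanged, so every
    threshold derived from them is quantile-based by construction.
    """
    from scipy.stats import rankdata

    flat = rankdata(values, method="average") / values.size
    return flat.reshape(values.shape)


def parenchyma_mask(anatomical: np.ndarray) -> BinaryMask:
    """Brain-tissue mask from an anatomical (T1-like) volume.

    Otsu splits on the empirical-CDF (rank) scale: background vs head,
    then three head classes of which the two brightest are kept (drops
    CSF-like low intensities); finally the largest connected component.
    """
    anatomical = np.asarray(anatomical, dtype=float)
    if not np.all(np.isfinite(anatomical)):
        raise DataError("anatomical volume contains non-finite values")
    if anatomical.min() == anatomical.max():
        raise DataError("anatomical volume is constant")
    ranks = _cdf_ranks(anatomical)
    thr = threshold_otsu(ranks, nbins=512)
    head = ranks > thr
    head_vals = anatomical[head]
    nh = np.unique(head_vals).size
    if nh >= 3:
        head_ranks = _cdf_ranks(head_vals)
        t_lo, _ = threshold_multiotsu(head_ranks, classes=3, nbins=512)
        tissue_in_head = head_ranks > t_lo
    else:
        tissue_in_head = np.ones(head_vals.shape, dtype=bool)
    tissue = np.zeros(anatomical.shape, dtype=bool)
    tissue[head] = tissue_in_head
    labeled, n_comp = ndimage.label(tissue)
    if n_comp > 1:
        sizes = ndimage.sum_labels(tissue, labeled, index=np.arange(1, n_comp + 1))
        tissue = labeled == (1 + int(np.argmax(sizes)))
    return BinaryMask(
        data=tissue,
        kind="parenchyma",
        provenance={"n_components": int(n_comp), "n_voxels": int(tissue.sum())},
    )


def vessel_mask(cmax_map: np.ndarray, parenchyma: BinaryMask, factor: float = 3.0) -> BinaryMask:
    """Voxels whose Cmax strictly exceeds factor * median(parenchymal Cmax)."""
    if factor <= 0:
        raise ParameterError("factor must be positive")
    par = parenchyma.data
    if not par.any():
        raise DataError("parenchyma mask is empty")
    cmax_map = np.asarray(cmax_map, dtype=float)
    if cmax_map.shape != par.shape:
        raise ShapeError("Cmax map and parenchyma mask shapes differ")
    median = float(np.median(cmax_map[par]))
    if median <= 0:
        raise DataError("parenchymal Cmax median is zero; vessel rule degenerates")
    vessels = cmax_map > factor * median
    return BinaryMask(
        data=vessels,
        kind="vessel",
        provenance={"factor": factor, "median_cmax": median, "n_voxels": int(vessels.sum())},
    )


def inclusion_mask(parenchyma: BinaryMask, vessel: BinaryMask) -> BinaryMask:
    """Analysis mask: within parenchyma but not in a vessel."""
    if parenchyma.data.shape != vessel.data.shape:
        raise ShapeError("parenchyma and vessel mask shapes differ")
    incl = parenchyma.data & ~vessel.data
    mask = BinaryMask(
        data=incl, kind="inclusion", provenance={"n_voxels": int(incl.sum())}
    )
    if not incl.any():
        mask.provenance["fatal"] = "inclusion mask is empty; VOI statistics impossible"
    return mask
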