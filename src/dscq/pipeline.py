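"""End-to-end orchestration: signal -> concentration -> AIF -> maps -> VOI.

`quantify_study` chains the per-subject stages in the order a DSC analysis
runs them: concentration conversion, descriptor maps, parenchyma mask,
automatic AIF selection (searched over the whole parenchyma, vessels
included), vessel/inclusion masks, SVD deconvolution, white-matter
calibration and VOI extraction.  `analyze_cohort` maps it over a cohort
and runs the group statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import aif as aif_mod
from . import deconv, kinetics, masking, quant, stats
from .errors import DataError
from .phantom import SIDES, STRUCTURES, Study, WM_LABEL

log = logging.getLogger("dscq")

__all__ = ["PipelineParams", "SubjectResult", "quantify_study", "analyze_cohort", "default_label_table"]


@dataclass(frozen=True)
class PipelineParams:
    """Everything tunable between the raw series and the VOI table."""

    baseline_window: tuple[int, int] | None = None  # None = automatic
    n_aif_voxels: int = 20
    aif_smooth_window: int = 3
    aif_truncate: bool = True
    svd_threshold: float = 0.2
    vessel_factor: float = 3.0
    constants: quant.CalibrationConstants = quant.CalibrationConstants()


@dataclass
class SubjectResult:
    subject_id: str
    group: str
    conc: kinetics.ConcentrationVolume
    descriptors: dict[str, np.ndarray]
    parenchyma: masking.BinaryMask
    vessel: masking.BinaryMask
    inclusion: masking.BinaryMask
    aif: aif_mod.ArterialInputFunction
    maps: deconv.PerfusionMaps
    measurements: list[quant.VOIMeasurement]


def default_label_table(truths) -> dict[str, int]:
    """name -> label code for every non-background, non-arterial region."""
    return {
        t.name: t.label_id
        for t in truths
        if not t.is_arterial and t.name not in ("csf",)
    }


def quantify_study(study: Study, params: PipelineParams = PipelineParams()) -> SubjectResult:
    """Run the full per-subject quantification chain on one study."""
    series = kinetics.DynamicSeries(data=study.signal, acq=study.acq)
    conc = kinetics.signal_to_concentration(series, params.baseline_window)
    desc = kinetics.descriptor_maps(conc)
    par = masking.parenchyma_mask(study.anatomical)
    ranked = aif_mod.rank_aif_candidates(desc, par.data)
    arterial = aif_mod.build_aif(
        conc,
        ranked,
        n=params.n_aif_voxels,
        smooth_window=params.aif_smooth_window,
        truncate=params.aif_truncate,
    )
    ves = masking.vessel_mask(desc["cmax"], par, factor=params.vessel_factor)
    incl = masking.inclusion_mask(par, ves)
    if "fatal" in incl.provenance:
        raise DataError(incl.provenance["fatal"])
    raw = deconv.make_maps(conc, arterial, par.data, params.svd_threshold)
    wm_voi = (study.labels == WM_LABEL) & incl.data
    calibrated = quant.calibrate_maps(raw, wm_voi, params.constants)
    label_table = default_label_table(study.truths)
    measurements = quant.extract_voi_values(
        calibrated,
        study.labels,
        incl,
        label_table,
        wm_label=WM_LABEL,
        subject_id=study.subject_id,
        group=study.group,
    )
    log.debug(
        "%s: parenchyma %d, vessel %d, inclusion %d voxels; AIF truncated at %d",
        study.subject_id, par.n_voxels, ves.n_voxels, incl.n_voxels, arterial.truncation_index,
    )
    return SubjectResult(
        subject_id=study.subject_id,
        group=study.group,
        conc=conc,
        descriptors=desc,
        parenchyma=par,
        vessel=ves,
        inclusion=incl,
        aif=arterial,
        maps=calibrated,
        measurements=measurements,
    )


def analyze_cohort(
    studies: list[Study],
    params: PipelineParams = PipelineParams(),
    alpha: float = 0.05,
    mode: str = "auto",
) -> tuple[pd.DataFrame, list[stats.GroupComparisonResult]]:
    """Quantify every subject and run the group/side statistics."""
    measurements: list[quant.VOIMeasurement] = []
    for study in studies:
        result = quantify_study(study, params)
        measurements.extend(m for m in result.measurements if m.side in SIDES)
    df = quant.measurements_to_frame(measurements)
    return df, stats.run_group_analysis(df, alpha=alpha, mode=mode)
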