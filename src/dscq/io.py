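"""NIfTI / CSV / JSON input-output for studies and results."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .aif import ArterialInputFunction
from .deconv import PerfusionMaps
from .errors import DataError
from .kinetics import ConcentrationVolume
from .masking import BinaryMask
from .phantom import AcquisitionParams, Study, TissueTruth

__all__ = ["write_study", "read_study", "write_subject_outputs", "write_aif_csv"]


def _affine(acq: AcquisitionParams) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = acq.voxel_size
    return aff


def _save(path: Path, data: np.ndarray, acq: AcquisitionParams, dtype=None) -> None:
    arr = data.astype(dtype) if dtype is not None else data
    nib.save(nib.Nifti1Image(arr, _affine(acq)), str(path))


def write_study(out_dir: str | Path, study: Study) -> Path:
    """Write one subject's volumes plus a JSON sidecar; returns the dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    acq = study.acq
    _save(out / "pwi.nii.gz", study.signal, acq)
    _save(out / "anat.nii.gz", study.anatomical, acq)
    _save(out / "labels.nii.gz", study.labels, acq, dtype=np.int16)
    _save(out / "truth_cbf.nii.gz", study.truth_cbf, acq)
    _save(out / "truth_cbv.nii.gz", study.truth_cbv, acq)
    sidecar = {
        "subject_id": study.subject_id,
        "group": study.group,
        "acquisition": dataclasses.asdict(acq),
        "truths": [dataclasses.asdict(t) for t in study.truths],
    }
    (out / "study.json").write_text(json.dumps(sidecar, indent=2))
    return out


def read_study(subject_dir: str | Path) -> Study:
    """Load a subject directory written by `write_study`."""
    d = Path(subject_dir)
    sidecar_path = d / "study.json"
    if not sidecar_path.exists():
        raise DataError(f"{d}: missing study.json sidecar")
    for name in ("pwi.nii.gz", "anat.nii.gz", "labels.nii.gz"):
        if not (d / name).exists():
            raise DataError(f"{d}: missing expected volume {name}")
    meta = json.loads(sidecar_path.read_text())
    acq_d = meta["acquisition"]
    acq = AcquisitionParams(
        tr=acq_d["tr"],
        te=acq_d["te"],
        n_timepoints=acq_d["n_timepoints"],
        matrix_shape=tuple(acq_d["matrix_shape"]),
        voxel_size=tuple(acq_d["voxel_size"]),
    )
    truths = [TissueTruth(**t) for t in meta["truths"]]

    def load(name):
        return np.asanyarray(nib.load(str(d / name)).dataobj)

    truth_cbf = load("truth_cbf.nii.gz") if (d / "truth_cbf.nii.gz").exists() else np.zeros(acq.matrix_shape)
    truth_cbv = load("truth_cbv.nii.gz") if (d / "truth_cbv.nii.gz").exists() else np.zeros(acq.matrix_shape)
    from .phantom import arterial_input_curve, BolusParams

    full, fp = arterial_input_curve(acq, BolusParams())
    return Study(
        signal=load("pwi.nii.gz").astype(float),
        anatomical=load("anat.nii.gz").astype(float),
        labels=load("labels.nii.gz").astype(np.int32),
        truth_cbf=truth_cbf,
        truth_cbv=truth_cbv,
        acq=acq,
        truths=truths,
        aif_true=full,
        aif_first_pass=fp,
        subject_id=meta.get("subject_id", d.name),
        group=meta.get("group", "control"),
    )


def write_aif_csv(out_dir: Path, aif: ArterialInputFunction) -> None:
    pd.DataFrame({"time_s": aif.t_axis, "concentration": aif.curve}).to_csv(
        out_dir / "aif.csv", index=False
    )
    (out_dir / "aif.json").write_text(
        json.dumps(
            {
                "voxel_indices": aif.voxel_indices.tolist(),
                "n_selected": aif.n_selected,
                "truncation_index": int(aif.truncation_index),
            },
            indent=2,
        )
    )


def write_subject_outputs(out_dir: str | Path, result, acq: AcquisitionParams) -> Path:
    """Maps, masks, AIF and VOI table for one quantified subject."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    maps: PerfusionMaps = result.maps
    _save(out / "cbf.nii.gz", maps.cbf, acq)
    _save(out / "cbv.nii.gz", maps.cbv, acq)
    for name, arr in result.descriptors.items():
        _save(out / f"{name}.nii.gz", arr, acq)
    for mask_name in ("parenchyma", "vessel", "inclusion"):
        mask: BinaryMask = getattr(result, mask_name)
        _save(out / f"mask_{mask_name}.nii.gz", mask.data.astype(np.uint8), acq)
    write_aif_csv(out, result.aif)
    from .quant import measurements_to_frame

    measurements_to_frame(result.measurements).to_csv(out / "voi.csv", index=False)
    (out / "maps.json").write_text(
        json.dumps(
            {
                "svd_threshold": maps.svd_threshold,
                "calibrated": maps.calibrated,
                "scale_cbf": maps.scale_cbf,
                "scale_cbv": maps.scale_cbv,
                "aif_n_selected": result.aif.n_selected,
                "aif_truncation_index": int(result.aif.truncation_index),
                "vessel_provenance": result.vessel.provenance,
            },
            indent=2,
        )
    )
    return out
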