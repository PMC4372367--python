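"""Digital DSC perfusion phantom with known regional ground truth.

Generates 4D bolus-tracking signal series, a T1-like anatomical volume, an
integer label map of bilateral subcortical structures, and ground-truth
CBF/CBV maps, plus matched patient/control cohorts with a regional
hypoperfusion effect.

The forward model is the standard indicator-dilution one: each tissue
voxel's contrast concentration is

    C_tissue(t) = (CBF / 6000) * (AIF * R)(t)

with R the residue function (R(0) = 1, nonincreasing) and CBF in
ml/100 g/min (the 6000 converts to ml/g/s).  The MR signal follows the
single-exponential susceptibility relation

    S(t) = S0 * exp(-TE * k * C(t)) + noise,      k := 1 (arbitrary units)

so only relative concentrations are meaningful, exactly as in bolus-tracking
practice where the proportionality constant cancels from all ratios.

The arterial input is a gamma-variate first pass plus a delayed, dispersed
recirculation bump at 30% of the first-pass amplitude; arterial voxels carry
this curve undispersed, so they have the highest Cmax and earliest TTP in
the volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError, DataError, ParameterError

#: susceptibility proportionality constant (arbitrary concentration units)
K_SUSCEPTIBILITY = 1.0

#: labels used by the default geometry
BACKGROUND_LABEL = 0
WM_LABEL = 1
CSF_LABEL = 2
ARTERY_LABEL = 90

#: the six bilateral subcortical structures analysed in the study,
#: in canonical report order
STRUCTURES = (
    "amygdala",
    "hippocampus",
    "thalamus",
    "putamen",
    "globus_pallidus",
    "caudate_nucleus",
)
SIDES = ("right", "left")


@dataclass(frozen=True)
class AcquisitionParams:
    """DSC acquisition geometry and timing.

    tr/te are in seconds (typical clinical DSC protocols use TR around
    1.43-1.5 s and TE 30-46 ms at 1.5 T).
    """

    tr: float = 1.5
    te: float = 0.046
    n_timepoints: int = 60
    matrix_shape: tuple[int, int, int] = (48, 48, 12)
    voxel_size: tuple[float, float, float] = (1.8, 1.8, 5.0)

    def __post_init__(self) -> None:
        if self.tr <= 0 or self.te <= 0:
            raise ParameterError("tr and te must be positive")
        if self.n_timepoints < 10:
            raise ParameterError("n_timepoints must be >= 10")
        if any(int(s) < 1 for s in self.matrix_shape):
            raise ParameterError("all matrix_shape entries must be >= 1")

    @property
    def t_axis(self) -> np.ndarray:
        return np.arange(self.n_timepoints) * self.tr


#: compact geometry for Monte-Carlo cohort simulations
COMPACT_ACQUISITION = AcquisitionParams(matrix_shape=(28, 28, 7), voxel_size=(3.0, 3.0, 8.0))


@dataclass(frozen=True)
class TissueTruth:
    """Ground-truth perfusion state of one labelled region.

    mtt_true is tied to cbf/cbv by the central volume theorem
    MTT [s] = 60 * CBV [ml/100 g] / CBF [ml/100 g/min].
    """

    label_id: int
    name: str
    cbf_true: float  # ml/100 g/min
    cbv_true: float  # ml/100 g
    mtt_true: float  # seconds
    s0: float = 100.0
    is_arterial: bool = False
    t1_intensity: float = 110.0

    def __post_init__(self) -> None:
        if self.cbf_true < 0 or self.cbv_true < 0:
            raise ParameterError(f"{self.name}: cbf/cbv must be nonnegative")
        if self.cbf_true > 0:
            if self.mtt_true <= 0:
                raise ParameterError(f"{self.name}: mtt must be positive where cbf > 0")
            expected = 60.0 * self.cbv_true / self.cbf_true
            if not math.isclose(self.mtt_true, expected, rel_tol=1e-9):
                raise ParameterError(
                    f"{self.name}: mtt {self.mtt_true} violates the central volume "
                    f"theorem (60*cbv/cbf = {expected})"
                )

    @classmethod
    def from_cbf_cbv(cls, label_id: int, name: str, cbf: float, cbv: float, **kw) -> "TissueTruth":
        mtt = 60.0 * cbv / cbf if cbf > 0 else 1.0
        return cls(label_id, name, cbf, cbv, mtt, **kw)


@dataclass(frozen=True)
class BolusParams:
    """First-pass gamma-variate bolus and its recirculation.

    Arrival at 12 s (clinical injection-to-brain delay is a free parameter;
    this leaves 8 baseline timepoints at TR 1.5 s).  Recirculation arrives
    24 s later, dispersed (doubled beta) at 30% of first-pass amplitude.
    """

    t0: float = 12.0
    alpha: float = 3.0
    beta: float = 1.5
    amplitude: float = 30.0
    recirc_delay: float = 24.0
    recirc_beta: float = 3.0
    recirc_fraction: float = 0.3


@dataclass(frozen=True)
class CohortDesign:
    """Matched patient/control cohort layout.

    Defaults mirror the study design: 5 patients, each with 3 age/sex
    matched controls, and a multiplicative hypoperfusion effect in the
    hippocampus of patients.  `between_subject_cv` is the lognormal
    coefficient of variation of regional truth values across subjects
    (regional perfusion varies by roughly 5-10% between healthy adults);
    `global_cv` additionally scales each subject's whole perfusion state
    (cancels from all ratios to the white-matter reference).
    """

    n_patients: int = 5
    controls_per_patient: int = 3
    effect_regions: tuple[str, ...] = ("hippocampus",)
    effect_fraction: float = 0.8
    noise_sigma: float = 2.0
    seed: int = 0
    between_subject_cv: float = 0.06
    global_cv: float = 0.10

    def __post_init__(self) -> None:
        if self.controls_per_patient < 1:
            raise ParameterError("controls_per_patient must be >= 1")
        if not (0.0 < self.effect_fraction <= 1.0):
            raise ParameterError("effect_fraction must be in (0, 1]")
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be nonnegative")


def default_truth_table() -> list[TissueTruth]:
    """Literature-typical perfusion truth for the default phantom.

    White matter carries the internal-standard values (22 ml/100 g/min,
    2.7 ml/100 g); gray-matter subcortical structures sit at typical
    50-60 / 3.9-4.5; arterial voxels carry the input function directly and
    have no tissue truth.
    """
    gm = 150.0
    rows = [
        TissueTruth.from_cbf_cbv(WM_LABEL, "white_matter", 22.0, 2.7, t1_intensity=110.0),
        TissueTruth.from_cbf_cbv(CSF_LABEL, "csf", 0.0, 0.0, t1_intensity=70.0),
        TissueTruth(ARTERY_LABEL, "artery", 0.0, 0.0, 1.0, is_arterial=True, t1_intensity=190.0),
    ]
    values = {
        "amygdala": (50.0, 4.0),
        "hippocampus": (55.0, 4.2),
        "thalamus": (60.0, 4.5),
        "putamen": (58.0, 4.3),
        "globus_pallidus": (52.0, 3.9),
        "caudate_nucleus": (56.0, 4.2),
    }
    for i, name in enumerate(STRUCTURES):
        cbf, cbv = values[name]
        for j, side in enumerate(SIDES):
            rows.append(
                TissueTruth.from_cbf_cbv(
                    10 * (i + 1) + j + 1, f"{name}_{side}", cbf, cbv, t1_intensity=gm
                )
            )
    return rows


def gamma_variate_curve(
    t_axis: np.ndarray, t0: float, alpha: float, beta: float, amplitude: float
) -> np.ndarray:
    """Peak-normalised gamma-variate bolus curve.

    Zero for t <= t0, then amplitude * ((t-t0)^alpha) * exp(-(t-t0)/beta)
    rescaled so the maximum of the continuous curve equals `amplitude`
    (attained at t0 + alpha*beta).
    """
    if alpha <= 0 or beta <= 0:
        raise ParameterError("alpha and beta must be positive")
    if amplitude < 0:
        raise ParameterError("amplitude must be nonnegative")
    t_axis = np.asarray(t_axis, dtype=float)
    tt = np.clip(t_axis - t0, 0.0, None)
    peak = (alpha * beta) ** alpha * math.exp(-alpha)
    curve = amplitude * tt**alpha * np.exp(-tt / beta) / peak
    return curve


def gamma_variate_area(t0: float, alpha: float, beta: float, amplitude: float) -> float:
    """Closed-form area of the peak-normalised gamma-variate."""
    peak = (alpha * beta) ** alpha * math.exp(-alpha)
    return amplitude * math.gamma(alpha + 1.0) * beta ** (alpha + 1.0) / peak


def residue_function(mtt: float, dt: float, n: int, model: str = "exponential") -> np.ndarray:
    """Discrete residue R[k] with R[0] = 1, nonincreasing.

    The discrete mass dt * sum(R) is made to equal MTT exactly.  For the
    exponential model the decay constant is solved from
    dt / (1 - exp(-dt/tau)) = mtt, which removes the O(dt/2) mass inflation
    of naively sampling exp(-t/mtt) on the grid; for MTT <= dt the residue
    collapses to a single fractional bin.  The boxcar model fills whole
    bins and one fractional bin.
    """
    if model == "exponential":
        r = np.zeros(n)
        if mtt <= dt:
            # sub-grid transit: all mass in one fractional bin
            r[0] = mtt / dt
            return r
        q = 1.0 - dt / mtt  # = exp(-dt/tau)
        r[:] = q ** np.arange(n)
        return r
    if model == "boxcar":
        bins = mtt / dt
        r = np.zeros(n)
        full = min(int(math.floor(bins)), n)
        r[:full] = 1.0
        if full < n:
            r[full] = bins - full
        return r
    raise ConfigurationError(f"unknown residue model {model!r}")


def synthesize_tissue_curve(
    aif_true: np.ndarray,
    cbf_true: float,
    mtt_true: float,
    dt: float,
    residue_model: str = "exponential",
) -> np.ndarray:
    """Forward indicator-dilution tissue curve.

    Returns (cbf/6000) * dt * (aif * R) on the acquisition grid.  By the
    central volume theorem the integral ratio tissue/AIF equals
    cbv_true / 100 up to discretisation error.
    """
    if dt <= 0:
        raise ParameterError("dt must be positive")
    if cbf_true < 0:
        raise ParameterError("cbf_true must be nonnegative")
    aif_true = np.asarray(aif_true, dtype=float)
    n = aif_true.size
    if cbf_true == 0:
        return np.zeros(n)
    r = residue_function(mtt_true, dt, n, residue_model)
    conv = np.convolve(aif_true, r)[:n]
    return (cbf_true / 6000.0) * dt * conv


# ---------------------------------------------------------------------------
# geometry


def _box(center: float, half: float, n: int) -> slice:
    lo = int(round((center - half) * n))
    hi = int(round((center + half) * n))
    lo = max(0, min(lo, n - 1))
    hi = max(lo + 1, min(hi, n))
    return slice(lo, hi)


# fractional (center, half-extent) per axis; right hemisphere at x < 0.5,
# the left variant mirrors x -> 1 - x
_STRUCT_GEOM = {
    "amygdala": ((0.36, 0.050), (0.38, 0.042), (0.32, 0.10)),
    "hippocampus": ((0.35, 0.050), (0.54, 0.060), (0.45, 0.12)),
    "thalamus": ((0.41, 0.048), (0.62, 0.050), (0.60, 0.12)),
    "putamen": ((0.30, 0.042), (0.46, 0.060), (0.60, 0.12)),
    "globus_pallidus": ((0.38, 0.034), (0.46, 0.042), (0.55, 0.10)),
    "caudate_nucleus": ((0.40, 0.036), (0.32, 0.050), (0.68, 0.12)),
}
_ARTERY_GEOM = (
    ((0.50, 0.050), (0.72, 0.050), (0.50, 0.28)),
    ((0.50, 0.050), (0.24, 0.050), (0.50, 0.28)),
)


def build_label_map(shape: tuple[int, int, int]) -> np.ndarray:
    """Deterministic integer label map for the phantom head.

    Head = ellipsoid; outer shell is CSF, interior is white matter with six
    bilateral subcortical boxes and two midline arterial columns embedded.
    Later structures never overwrite earlier ones.
    """
    nx, ny, nz = shape
    labels = np.zeros(shape, dtype=np.int32)
    ix, iy, iz = np.meshgrid(
        (np.arange(nx) + 0.5) / nx - 0.5,
        (np.arange(ny) + 0.5) / ny - 0.5,
        (np.arange(nz) + 0.5) / nz - 0.5,
        indexing="ij",
    )
    r2 = (ix / 0.46) ** 2 + (iy / 0.46) ** 2 + (iz / 0.48) ** 2
    inner = (ix / 0.40) ** 2 + (iy / 0.40) ** 2 + (iz / 0.42) ** 2
    labels[r2 <= 1.0] = CSF_LABEL
    labels[inner <= 1.0] = WM_LABEL

    name_to_id = {t.name: t.label_id for t in default_truth_table()}
    for name, ((cx, hx), (cy, hy), (cz, hz)) in _STRUCT_GEOM.items():
        for side in SIDES:
            cx_s = cx if side == "right" else 1.0 - cx
            sl = (_box(cx_s, hx, nx), _box(cy, hy, ny), _box(cz, hz, nz))
            region = labels[sl]
            region[region == WM_LABEL] = name_to_id[f"{name}_{side}"]
    for (cx, hx), (cy, hy), (cz, hz) in _ARTERY_GEOM:
        sl = (_box(cx, hx, nx), _box(cy, hy, ny), _box(cz, hz, nz))
        region = labels[sl]
        region[region == WM_LABEL] = ARTERY_LABEL
    return labels


# ---------------------------------------------------------------------------
# study generation


@dataclass
class Study:
    """One synthetic subject: raw series plus everything the truth knows."""

    signal: np.ndarray  # (x, y, z, t)
    anatomical: np.ndarray  # (x, y, z)
    labels: np.ndarray  # (x, y, z) int
    truth_cbf: np.ndarray  # (x, y, z)
    truth_cbv: np.ndarray  # (x, y, z)
    acq: AcquisitionParams
    truths: list[TissueTruth]
    aif_true: np.ndarray  # full arterial curve (first pass + recirculation)
    aif_first_pass: np.ndarray  # recirculation-free arterial curve
    conc_true: np.ndarray | None = None  # noise-free concentration (x, y, z, t)
    subject_id: str = "subject"
    group: str = "control"


def arterial_input_curve(acq: AcquisitionParams, bolus: BolusParams) -> tuple[np.ndarray, np.ndarray]:
    """(full, first-pass-only) true arterial concentration curves."""
    t = acq.t_axis
    fp = gamma_variate_curve(t, bolus.t0, bolus.alpha, bolus.beta, bolus.amplitude)
    rc = gamma_variate_curve(
        t,
        bolus.t0 + bolus.recirc_delay,
        bolus.alpha,
        bolus.recirc_beta,
        bolus.recirc_fraction * bolus.amplitude,
    )
    return fp + rc, fp


def generate_study(
    acq: AcquisitionParams,
    truths: list[TissueTruth],
    noise_sigma: float = 0.0,
    seed: int = 0,
    bolus: BolusParams = BolusParams(),
    residue_model: str = "exponential",
    keep_concentration: bool = False,
) -> Study:
    """Generate one synthetic DSC study with ground truth.

    Same seed => bit-identical output.  Arterial voxels carry the
    undispersed full AIF; every tissue curve inherits the recirculation
    bump through the convolution with its residue.
    """
    if noise_sigma < 0:
        raise ParameterError("noise_sigma must be nonnegative")
    shape = tuple(acq.matrix_shape)
    labels = build_label_map(shape)
    present = set(np.unique(labels)) - {BACKGROUND_LABEL}
    by_id = {t.label_id: t for t in truths}
    missing = present - set(by_id)
    if missing:
        raise DataError(f"label map contains labels without truth rows: {sorted(missing)}")

    aif_full, aif_fp = arterial_input_curve(acq, bolus)
    nt = acq.n_timepoints
    conc = np.zeros(shape + (nt,))
    s0_map = np.full(shape, 100.0)
    anat = np.zeros(shape)
    truth_cbf = np.zeros(shape)
    truth_cbv = np.zeros(shape)
    for lid in sorted(present):
        t = by_id[lid]
        vox = labels == lid
        anat[vox] = t.t1_intensity
        s0_map[vox] = t.s0
        truth_cbf[vox] = t.cbf_true
        truth_cbv[vox] = t.cbv_true
        if t.is_arterial:
            conc[vox] = aif_full
        elif t.cbf_true > 0:
            conc[vox] = synthesize_tissue_curve(
                aif_full, t.cbf_true, t.mtt_true, acq.tr, residue_model
            )
    signal = s0_map[..., None] * np.exp(-acq.te * K_SUSCEPTIBILITY * conc)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sigma, signal.shape)
    return Study(
        signal=signal,
        anatomical=anat,
        labels=labels,
        truth_cbf=truth_cbf,
        truth_cbv=truth_cbv,
        acq=acq,
        truths=list(truths),
        aif_true=aif_full,
        aif_first_pass=aif_fp,
        conc_true=conc if keep_concentration else None,
    )


def _jitter_truths(
    truths: list[TissueTruth], design: CohortDesign, rng: np.random.Generator
) -> list[TissueTruth]:
    """Per-subject lognormal perturbation of regional truth values."""
    g_cbf = float(np.exp(rng.normal(0.0, design.global_cv))) if design.global_cv > 0 else 1.0
    g_cbv = float(np.exp(rng.normal(0.0, design.global_cv))) if design.global_cv > 0 else 1.0
    out = []
    for t in truths:
        if t.is_arterial or t.cbf_true == 0:
            out.append(t)
            continue
        f_cbf = g_cbf
        f_cbv = g_cbv
        if design.between_subject_cv > 0:
            f_cbf *= float(np.exp(rng.normal(0.0, design.between_subject_cv)))
            f_cbv *= float(np.exp(rng.normal(0.0, design.between_subject_cv)))
        out.append(
            TissueTruth.from_cbf_cbv(
                t.label_id,
                t.name,
                t.cbf_true * f_cbf,
                t.cbv_true * f_cbv,
                s0=t.s0,
                is_arterial=t.is_arterial,
                t1_intensity=t.t1_intensity,
            )
        )
    return out


def _apply_effect(truths: list[TissueTruth], design: CohortDesign) -> list[TissueTruth]:
    known = {t.name for t in truths}
    matched = set()
    out = list(truths)
    for region in design.effect_regions:
        hit = [t for t in truths if t.name == region or t.name.startswith(region + "_")]
        if not hit:
            raise ConfigurationError(f"effect region {region!r} not in the truth table")
        matched |= {t.name for t in hit}
    if design.effect_fraction == 1.0 or not matched:
        return out
    result = []
    for t in out:
        if t.name in matched and t.cbf_true > 0:
            result.append(
                TissueTruth.from_cbf_cbv(
                    t.label_id,
                    t.name,
                    t.cbf_true * design.effect_fraction,
                    t.cbv_true * design.effect_fraction,
                    s0=t.s0,
                    is_arterial=t.is_arterial,
                    t1_intensity=t.t1_intensity,
                )
            )
        else:
            result.append(t)
    return result


def generate_cohort(
    design: CohortDesign,
    acq: AcquisitionParams = AcquisitionParams(),
    truths: list[TissueTruth] | None = None,
    bolus: BolusParams = BolusParams(),
    keep_concentration: bool = False,
) -> list[Study]:
    """Matched patient/control cohort of synthetic studies.

    Patients have cbf/cbv multiplied by effect_fraction in the effect
    regions; per-subject RNG streams derive deterministically from
    design.seed.
    """
    base = truths if truths is not None else default_truth_table()
    # validate effect regions regardless of effect size
    _apply_effect(base, replace(design, effect_fraction=min(design.effect_fraction, 0.999999)))
    n_total = design.n_patients + design.n_patients * design.controls_per_patient
    seeds = np.random.SeedSequence(design.seed).generate_state(2 * n_total) % (2**31)
    studies = []
    for i in range(n_total):
        group = "patient" if i < design.n_patients else "control"
        jrng = np.random.default_rng(int(seeds[2 * i]))
        subject_truths = _jitter_truths(base, design, jrng)
        if group == "patient":
            subject_truths = _apply_effect(subject_truths, design)
        study = generate_study(
            acq,
            subject_truths,
            noise_sigma=design.noise_sigma,
            seed=int(seeds[2 * i + 1]),
            bolus=bolus,
            keep_concentration=keep_concentration,
        )
        study.subject_id = f"{group}_{i:02d}" if group == "patient" else f"{group}_{i - design.n_patients:02d}"
        study.group = group
        studies.append(study)
    return studies
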