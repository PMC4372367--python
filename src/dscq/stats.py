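"""Nonparametric group comparison of VOI-level perfusion ratios.

Patient-vs-control contrasts use the Mann-Whitney U test; within-patient
left-vs-right contrasts use the Wilcoxon signed-rank test; all tests are
two-sided at the 0.05 level with no multiplicity correction (the number of
comparisons is reported so users can apply their own).  For small samples
(total n <= 12) exact p-values are computed by full enumeration — all
C(n+m, n) group labelings for Mann-Whitney, all 2^k sign patterns for
Wilcoxon — which also handles ties correctly; larger samples use the
normal approximation with tie-corrected variance and continuity
correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, sqrt

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .errors import DataError
from .phantom import SIDES, STRUCTURES
from .quant import VOIMeasurement, measurements_to_frame

__all__ = [
    "GroupComparisonResult",
    "mann_whitney_u",
    "wilcoxon_signed_rank",
    "median_iqr",
    "run_group_analysis",
    "format_report",
]

EXACT_LIMIT = 12


@dataclass(frozen=True)
class GroupComparisonResult:
    structure: str
    side: str  # right | left | left_vs_right
    metric: str  # rcbf | rcbv
    test: str  # mann_whitney | wilcoxon
    mode_used: str  # exact | asymptotic | undefined | missing
    median_patients: float
    iqr_patients: tuple[float, float]
    median_controls: float
    iqr_controls: tuple[float, float]
    statistic: float
    p_value: float
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return bool(self.p_value < self.alpha)


def _rank_sum_u(pooled_ranks: np.ndarray, idx: tuple[int, ...] | np.ndarray, n: int) -> float:
    return float(pooled_ranks[list(idx)].sum() - n * (n + 1) / 2.0)


def mann_whitney_u(x, y, mode: str = "auto") -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    U counts pairs (x_i, y_j) with x_i > y_j (ties count 1/2) and the
    reported statistic is min(U, nm - U).  Exact p enumerates every group
    labeling; the asymptotic path uses the tie-corrected normal
    approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DataError("both samples must be nonempty")
    n, m = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    u_x = _rank_sum_u(ranks, np.arange(n), n)
    u_obs = min(u_x, n * m - u_x)
    if mode not in ("exact", "asymptotic", "auto"):
        raise DataError(f"unknown mode {mode!r}")
    use_exact = mode == "exact" or (mode == "auto" and n + m <= EXACT_LIMIT)
    if use_exact:
        total = comb(n + m, n)
        hits = 0
        for idx in combinations(range(n + m), n):
            u = _rank_sum_u(ranks, idx, n)
            if min(u, n * m - u) <= u_obs + 1e-12:
                hits += 1
        return u_obs, hits / total
    # normal approximation, tie-corrected variance
    big_n = n + m
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum())) / (big_n * (big_n - 1))
    sigma2 = n * m / 12.0 * ((big_n + 1) - tie_term)
    if sigma2 <= 0:
        return u_obs, 1.0  # all values identical
    z = (abs(u_x - n * m / 2.0) - 0.5) / sqrt(sigma2)
    z = max(z, 0.0)
    return u_obs, min(1.0, 2.0 * norm.sf(z))


def wilcoxon_signed_rank(left, right, mode: str = "auto") -> tuple[float, float, dict]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped (count reported in the info dict).  The
    statistic is W = min(W+, W-) over signed ranks of nonzero differences;
    exact p enumerates all 2^k sign patterns for k <= 12.  If every
    difference is zero the test is undefined and flagged as such.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.size != right.size or left.size == 0:
        raise DataError("paired samples must be nonempty and of equal length")
    d = left - right
    nonzero = d != 0
    n_zero = int((~nonzero).sum())
    d = d[nonzero]
    k = d.size
    info = {"n_zero": n_zero, "k": k}
    if k == 0:
        info["status"] = "undefined"
        return np.nan, np.nan, info
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    s = float(ranks.sum())  # = k(k+1)/2
    w_obs = min(w_plus, s - w_plus)
    if mode not in ("exact", "asymptotic", "auto"):
        raise DataError(f"unknown mode {mode!r}")
    use_exact = mode == "exact" or (mode == "auto" and k <= EXACT_LIMIT)
    if use_exact:
        hits = 0
        for pattern in range(2**k):
            w = sum(ranks[i] for i in range(k) if pattern >> i & 1)
            if min(w, s - w) <= w_obs + 1e-12:
                hits += 1
        info["status"] = "exact"
        return w_obs, hits / 2**k, info
    mu = k * (k + 1) / 4.0
    _, counts = np.unique(np.abs(d), return_counts=True)
    sigma2 = k * (k + 1) * (2 * k + 1) / 24.0 - float((counts**3 - counts).sum()) / 48.0
    if sigma2 <= 0:
        info["status"] = "degenerate"
        return w_obs, 1.0, info
    z = max((abs(w_plus - mu) - 0.5) / sqrt(sigma2), 0.0)
    info["status"] = "asymptotic"
    return w_obs, min(1.0, 2.0 * norm.sf(z)), info


def median_iqr(values) -> tuple[float, float, float]:
    """Median and quartiles by linear interpolation (positions p*(n-1)+1)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise DataError("empty sample")
    med, q1, q3 = np.percentile(values, [50, 25, 75], method="linear")
    return float(med), float(q1), float(q3)


def _one_contrast(
    structure: str,
    side: str,
    metric: str,
    pat: np.ndarray,
    ctl: np.ndarray,
    alpha: float,
    mode: str,
) -> GroupComparisonResult:
    if pat.size == 0 or ctl.size == 0:
        return GroupComparisonResult(
            structure, side, metric, "mann_whitney", "missing",
            np.nan, (np.nan, np.nan), np.nan, (np.nan, np.nan), np.nan, np.nan, alpha,
        )
    u, p = mann_whitney_u(pat, ctl, mode=mode)
    mp, q1p, q3p = median_iqr(pat)
    mc, q1c, q3c = median_iqr(ctl)
    used = "exact" if (mode == "exact" or (mode == "auto" and pat.size + ctl.size <= EXACT_LIMIT)) else "asymptotic"
    return GroupComparisonResult(
        structure, side, metric, "mann_whitney", used,
        mp, (q1p, q3p), mc, (q1c, q3c), u, p, alpha,
    )


def run_group_analysis(
    measurements: list[VOIMeasurement] | pd.DataFrame,
    alpha: float = 0.05,
    mode: str = "auto",
) -> list[GroupComparisonResult]:
    """Full statistical report for one cohort.

    One Mann-Whitney row per structure x side x metric (patients vs
    controls, right listed before left) plus one Wilcoxon row per
    structure x metric for the within-patient left-vs-right contrast.
    p-values are unadjusted.
    """
    df = measurements if isinstance(measurements, pd.DataFrame) else measurements_to_frame(measurements)
    if df.empty:
        raise DataError("no measurements")
    df = df.dropna(subset=["rcbf", "rcbv"])
    groups = set(df["group"])
    if not {"patient", "control"} <= groups:
        raise DataError("both patient and control groups are required")
    results: list[GroupComparisonResult] = []
    structures = [s for s in STRUCTURES if s in set(df["structure"])]
    structures += [s for s in sorted(set(df["structure"])) if s not in structures]
    for metric in ("rcbf", "rcbv"):
        for structure in structures:
            for side in SIDES:  # right before left
                sub = df[(df.structure == structure) & (df.side == side)]
                pat = sub[sub.group == "patient"][metric].to_numpy()
                ctl = sub[sub.group == "control"][metric].to_numpy()
                if pat.size == 0 and ctl.size == 0:
                    continue
                results.append(_one_contrast(structure, side, metric, pat, ctl, alpha, mode))
        for structure in structures:
            sub = df[(df.structure == structure) & (df.group == "patient")]
            piv = sub.pivot_table(index="subject_id", columns="side", values=metric)
            if not {"left", "right"} <= set(piv.columns):
                continue
            piv = piv.dropna()
            lft = piv["left"].to_numpy()
            rgt = piv["right"].to_numpy()
            if lft.size == 0:
                continue
            w, p, info = wilcoxon_signed_rank(lft, rgt, mode=mode)
            ml, q1l, q3l = median_iqr(lft)
            mr, q1r, q3r = median_iqr(rgt)
            results.append(
                GroupComparisonResult(
                    structure, "left_vs_right", metric, "wilcoxon", info.get("status", "exact"),
                    ml, (q1l, q3l), mr, (q1r, q3r), w,
                    p if p == p else np.nan, alpha,
                )
            )
    return results


def results_to_frame(results: list[GroupComparisonResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "structure": r.structure,
                "side": r.side,
                "metric": r.metric,
                "test": r.test,
                "mode": r.mode_used,
                "median_patients": r.median_patients,
                "iqr_patients_low": r.iqr_patients[0],
                "iqr_patients_high": r.iqr_patients[1],
                "median_controls": r.median_controls,
                "iqr_controls_low": r.iqr_controls[0],
                "iqr_controls_high": r.iqr_controls[1],
                "statistic": r.statistic,
                "p_value": r.p_value,
                "significant": r.significant,
                "alpha": r.alpha,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["n_comparisons"] = len(df)
    return df


def format_report(results: list[GroupComparisonResult]) -> str:
    """Markdown tables in the study's layout: one per metric, group contrast
    rows as `Side Structure | patients median (IQR) | controls median (IQR) | p`,
    followed by the within-patient side-difference tests."""
    lines: list[str] = []
    for metric, title in (("rcbf", "rCBF"), ("rcbv", "rCBV")):
        lines.append(f"## Group comparison of {title} (median (IQR)), Mann-Whitney U")
        lines.append("| Region | TGA patients | Controls | p |")
        lines.append("|---|---|---|---|")
        for r in results:
            if r.metric != metric or r.test != "mann_whitney":
                continue
            tag = "R" if r.side == "right" else "L"
            name = r.structure.replace("_", " ")
            lines.append(
                f"| {tag} {name} | {r.median_patients:.2f} "
                f"({r.iqr_patients[0]:.2f}-{r.iqr_patients[1]:.2f}) | "
                f"{r.median_controls:.2f} ({r.iqr_controls[0]:.2f}-{r.iqr_controls[1]:.2f}) | "
                f"{r.p_value:.3f}{'*' if r.significant else ''} |"
            )
        lines.append("")
        lines.append(f"## Side differences in {title} within patients, Wilcoxon signed-rank")
        lines.append("| Region | Left | Right | p |")
        lines.append("|---|---|---|---|")
        for r in results:
            if r.metric != metric or r.test != "wilcoxon":
                continue
            name = r.structure.replace("_", " ")
            p_txt = "undefined" if r.p_value != r.p_value else f"{r.p_value:.3f}{'*' if r.significant else ''}"
            lines.append(
                f"| {name} | {r.median_patients:.2f} | {r.median_controls:.2f} | {p_txt} |"
            )
        lines.append("")
    lines.append("`*` p < 0.05 (two-sided, unadjusted); "
                 f"{sum(1 for r in results)} comparisons reported.")
    return "\n".join(lines)
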