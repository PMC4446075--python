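"""Wilcoxon signed-rank statistics, cohort summaries and pipeline orchestration.

The wall-versus-lumen SNR comparison uses the two-sided Wilcoxon signed-rank
test: exact null distribution (over all 2^n sign assignments, computed by
convolution) for n <= 25 pairs, normal approximation with tie correction
beyond. Zero differences are dropped (Wilcoxon's convention); ties receive
mid-ranks. No multiple-testing correction is applied, matching the reference
analysis; the report notes this.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger("vwisim")

__all__ = [
    "WilcoxonResult",
    "PairedSample",
    "wilcoxon_signed_rank",
    "exact_wilcoxon_enumeration",
    "CohortSummary",
    "summarize_cohort",
    "run_all",
]


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W+ = sum of positive mid-ranks
    p_value: float
    n: int  # pairs after dropping zero differences
    method: str  # 'exact' | 'normal'
    all_zero: bool = False


@dataclass
class PairedSample:
    """Paired per-subject values (e.g. wall vs lumen SNR) at one location or
    pooled over locations."""

    first: np.ndarray
    second: np.ndarray
    subject_ids: list | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.first = np.asarray(self.first, dtype=float)
        self.second = np.asarray(self.second, dtype=float)
        if self.first.shape != self.second.shape:
            raise ValueError("paired sample halves differ in length")
        if np.any(~np.isfinite(self.first)) or np.any(~np.isfinite(self.second)):
            raise ValueError("paired sample contains missing values; filter first")

    @property
    def differences(self) -> np.ndarray:
        return self.first - self.second


def _midranks(abs_d: np.ndarray) -> np.ndarray:
    order = np.argsort(abs_d, kind="stable")
    ranks = np.empty(abs_d.size)
    sorted_d = abs_d[order]
    i = 0
    r = 1
    while i < abs_d.size:
        j = i
        while j < abs_d.size and sorted_d[j] == sorted_d[i]:
            j += 1
        mid = (r + (r + (j - i) - 1)) / 2.0
        ranks[order[i:j]] = mid
        r += j - i
        i = j
    return ranks


def _exact_cdf(ranks2: np.ndarray) -> np.ndarray:
    """Probability mass of 2*W+ over all sign assignments, by convolution.

    ``ranks2`` are doubled mid-ranks (integers). Identical to literal 2^n
    enumeration, in O(n * sum(ranks)) time.
    """
    total = int(ranks2.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in ranks2.astype(int):
        shifted = np.zeros_like(pmf)
        shifted[r:] = pmf[: total + 1 - r]
        pmf = 0.5 * (pmf + shifted)
    return pmf


def wilcoxon_signed_rank(
    sample: PairedSample | np.ndarray,
    exact_max_n: int = 25,
) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped; at least 5 nonzero pairs are required
    (all-zero input returns p = 1 with a flag). Exact two-sided p is
    2 min(P(W <= w), P(W >= w)) capped at 1.
    """
    d = sample.differences if isinstance(sample, PairedSample) else np.asarray(sample, float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return WilcoxonResult(0.0, 1.0, 0, "degenerate", all_zero=True)
    if n < 5:
        raise ValueError(f"need at least 5 nonzero differences, got {n}")
    ranks = _midranks(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        ranks2 = np.round(2 * ranks).astype(int)
        pmf = _exact_cdf(ranks2)
        w2 = int(round(2 * w_plus))
        p_le = float(pmf[: w2 + 1].sum())
        p_ge = float(pmf[w2:].sum())
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return WilcoxonResult(w_plus, p, n, "exact")
    # normal approximation with tie correction and continuity correction
    mu = n * (n + 1) / 4.0
    _, counts = np.unique(np.abs(d), return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    z = (w_plus - mu - 0.5 * np.sign(w_plus - mu)) / np.sqrt(var)
    from scipy.stats import norm

    p = float(2.0 * norm.sf(abs(z)))
    return WilcoxonResult(w_plus, min(1.0, p), n, "normal")


def exact_wilcoxon_enumeration(differences: np.ndarray) -> WilcoxonResult:
    """Literal 2^n enumeration over sign assignments; test oracle for small n."""
    d = np.asarray(differences, float)
    d = d[d != 0]
    n = d.size
    if n > 20:
        raise ValueError("enumeration oracle is for small n only")
    ranks = _midranks(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    ws = np.zeros(2**n)
    for mask in range(2**n):
        signs = np.array([(mask >> k) & 1 for k in range(n)], dtype=bool)
        ws[mask] = ranks[signs].sum()
    p_le = np.mean(ws <= w_obs + 1e-12)
    p_ge = np.mean(ws >= w_obs - 1e-12)
    p = min(1.0, 2.0 * min(p_le, p_ge))
    return WilcoxonResult(w_obs, float(p), n, "enumeration")


# ---------------------------------------------------------------------------
# Cohort summary


@dataclass
class CohortSummary:
    """Summary tables of one synthetic cohort run."""

    per_location: pd.DataFrame  # mean +- SD of SNR_w / SNR_l per sequence x location
    cnr_table: pd.DataFrame  # wall-lumen CNR per sequence x location
    pooled_tests: pd.DataFrame  # per-sequence pooled wall-vs-lumen test
    per_location_tests: pd.DataFrame
    n_subjects_analyzed: int
    n_subjects_excluded: int

    def to_markdown(self) -> str:
        lines = ["# Cohort summary", ""]
        lines.append(
            f"Subjects analyzed: {self.n_subjects_analyzed} "
            f"(excluded: {self.n_subjects_excluded})"
        )
        lines.append("\n## SNR by location (mean ± SD)\n")
        lines.append(self.per_location.to_string(index=False))
        lines.append("\n## Wall-lumen CNR by location (mean ± SD)\n")
        lines.append(self.cnr_table.to_string(index=False))
        lines.append("\n## Pooled wall-vs-lumen Wilcoxon signed-rank tests\n")
        lines.append(self.pooled_tests.to_string(index=False))
        lines.append("\nNo multiple-testing correction applied.")
        return "\n".join(lines) + "\n"


def summarize_cohort(
    measurements: pd.DataFrame,
    side_mode: str = "average",
    alpha: float = 0.05,
) -> CohortSummary:
    """Cohort tables and wall-vs-lumen tests from tidy measurement rows.

    Subjects with any excluded (missing) measurement are dropped entirely
    before pooling, and the dropped count reported. ``side_mode`` 'average'
    averages left/right per subject and location before testing;
    'independent' treats sides as separate pairs.
    """
    if measurements.empty:
        raise ValueError("no measurements")
    excluded_subjects = set(measurements.loc[measurements["excluded"], "subject_id"])
    df = measurements[~measurements["subject_id"].isin(excluded_subjects)].copy()
    n_excl = len(excluded_subjects)
    n_subj = df["subject_id"].nunique()
    if df.empty:
        raise ValueError("all subjects excluded")

    if side_mode == "average":
        unit = (
            df.groupby(["sequence", "location", "subject_id"], as_index=False)
            .agg(snr_w=("snr_w", "mean"), snr_l=("snr_l", "mean"), cnr_w_l=("cnr_w_l", "mean"))
        )
    elif side_mode == "independent":
        unit = df.rename(columns={})[
            ["sequence", "location", "subject_id", "side", "snr_w", "snr_l", "cnr_w_l"]
        ].copy()
        unit["subject_id"] = unit["subject_id"] + "_" + unit["side"]
    else:
        raise ValueError("side_mode must be 'average' or 'independent'")

    per_location = (
        unit.groupby(["sequence", "location"], as_index=False)
        .agg(
            snr_w_mean=("snr_w", "mean"),
            snr_w_sd=("snr_w", "std"),
            snr_l_mean=("snr_l", "mean"),
            snr_l_sd=("snr_l", "std"),
            n=("subject_id", "nunique"),
        )
    )
    cnr_table = (
        unit.groupby(["sequence", "location"], as_index=False)
        .agg(cnr_mean=("cnr_w_l", "mean"), cnr_sd=("cnr_w_l", "std"), n=("subject_id", "nunique"))
    )

    def _test(sub: pd.DataFrame) -> dict:
        if sub["subject_id"].nunique() < 5:
            return {"statistic": np.nan, "p_value": np.nan, "n": sub["subject_id"].nunique(),
                    "significant": False, "skipped": True}
        res = wilcoxon_signed_rank(PairedSample(sub["snr_w"].values, sub["snr_l"].values))
        return {"statistic": res.statistic, "p_value": res.p_value, "n": res.n,
                "significant": bool(res.p_value < alpha), "skipped": False}

    pooled_rows = []
    for seq, g in unit.groupby("sequence"):
        pooled = g.groupby("subject_id", as_index=False).agg(
            snr_w=("snr_w", "mean"), snr_l=("snr_l", "mean")
        )
        row = {"sequence": seq, **_test(pooled)}
        pooled_rows.append(row)
    per_loc_rows = []
    for (seq, loc), g in unit.groupby(["sequence", "location"]):
        per_loc_rows.append({"sequence": seq, "location": loc, **_test(g)})

    return CohortSummary(
        per_location=per_location,
        cnr_table=cnr_table,
        pooled_tests=pd.DataFrame(pooled_rows),
        per_location_tests=pd.DataFrame(per_loc_rows),
        n_subjects_analyzed=n_subj,
        n_subjects_excluded=n_excl,
    )


# ---------------------------------------------------------------------------
# End-to-end pipeline


def run_all(
    out_dir,
    n_subjects: int = 25,
    seed: int = 0,
    scene_factory=None,
    protocols: dict | None = None,
    side_mode: str = "average",
    write_nifti: bool = False,
) -> dict:
    """Cohort generation -> acquisition -> quantification -> statistics.

    Writes measurements.csv, the summary tables, a Markdown report and a
    provenance record (seed, versions, configuration hash) into ``out_dir``;
    returns the summary and the measurement frame. Deterministic for a given
    seed.
    """
    from .params import default_protocols
    from .phantom import compact_scene, build_phantom, acquire, synthetic_cohort
    from .quantify import measure_volume, measurements_to_frame

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scene_factory = scene_factory or compact_scene
    protocols = protocols or default_protocols()
    scenes = synthetic_cohort(n_subjects, seed=seed, scene_factory=scene_factory,
                              protocols=protocols)
    all_meas = []
    for scene in scenes:
        log.info("subject %s (seed %d, occluded=%s)", scene.subject_id, scene.seed,
                 scene.occluded_location)
        built = build_phantom(scene)
        for kind, proto in protocols.items():
            acq = acquire(built, proto, seed=scene.seed)
            if write_nifti:
                acq.save_nifti(out / f"{scene.subject_id}_{kind.lower()}.nii.gz")
            all_meas.extend(measure_volume(acq, built))
    meas = measurements_to_frame(all_meas)
    meas_path = out / "measurements.csv"
    meas.to_csv(meas_path, index=False)
    n_analyzable = meas[~meas["subject_id"].isin(meas.loc[meas["excluded"], "subject_id"])][
        "subject_id"
    ].nunique()
    if n_analyzable >= 5:
        summary = summarize_cohort(meas, side_mode=side_mode)
        summary.per_location.to_csv(out / "snr_by_location.csv", index=False)
        summary.cnr_table.to_csv(out / "cnr_by_location.csv", index=False)
        summary.pooled_tests.to_csv(out / "pooled_tests.csv", index=False)
        summary.per_location_tests.to_csv(out / "per_location_tests.csv", index=False)
        (out / "report.md").write_text(summary.to_markdown())
    else:
        summary = None
        log.warning("too few analyzable subjects (%d); statistics skipped", n_analyzable)
    from . import __version__

    provenance = {
        "seed": seed,
        "n_subjects": n_subjects,
        "n_analyzable": int(n_analyzable),
        "side_mode": side_mode,
        "vwisim_version": __version__,
        "numpy_version": np.__version__,
        "protocol_kinds": sorted(protocols),
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return {"summary": summary, "measurements": meas, "out_dir": out}
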