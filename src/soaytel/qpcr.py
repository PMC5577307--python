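"""qPCR amplification-curve processing and relative telomere length (RTL).

The measurement pipeline mirrors the standard single-calibrator,
efficiency-corrected qPCR workflow for relative telomere length:

1. per-well linear baseline correction over the early cycles;
2. window-of-linearity search on the log fluorescence to estimate the
   well-specific reaction efficiency E (per-cycle fold change) and the
   quantification cycle Cq at a fixed amplicon-group threshold;
3. quality control: triplicate Cq coefficient of variation (> 5% fails),
   well efficiency deviating > 5% from the plate x amplicon mean, and
   DNA-extraction QC (yield, absorbance ratios, gel integrity);
4. calibrator normalisation:

       RTL = E_TEL^(CqTEL[cal] - CqTEL[sample]) / E_B2M^(CqB2M[cal] - CqB2M[sample])

   with E the plate-mean efficiencies and Cq triplicate means, so the
   calibrator itself scores RTL = 1 on every plate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import DomainError, EstimationError, InputError

__all__ = [
    "AmplificationCurve",
    "WellEstimate",
    "PlateSummary",
    "DNASampleQC",
    "QCResult",
    "correct_baseline",
    "estimate_efficiency_and_cq",
    "set_group_threshold",
    "triplicate_cv_qc",
    "well_efficiency_qc",
    "dna_sample_qc",
    "apply_dna_qc",
    "compute_rtl",
    "plate_summary",
    "process_plates",
]

MAX_EFFICIENCY = 2.2

# Printed defaults of the protocol this pipeline reproduces.
DEFAULT_THRESHOLDS = {"TEL": 0.222, "B2M": 0.193}
DEFAULT_CV_LIMIT = 0.05
DEFAULT_EFF_DEV_LIMIT = 0.05
DEFAULT_FIRST_K_PLATES = 6


@dataclass
class AmplificationCurve:
    plate_id: str
    well_id: str
    sample_id: str
    amplicon: str  # TEL | B2M
    role: str  # sample | calibrator | NTC
    cycles: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self):
        self.cycles = np.asarray(self.cycles, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.cycles.size < 30:
            raise InputError(f"curve {self.well_id}: needs >= 30 cycles")
        if self.cycles.size != self.fluorescence.size:
            raise InputError(f"curve {self.well_id}: cycle/fluorescence length mismatch")
        if np.any(np.diff(self.cycles) <= 0):
            raise InputError(f"curve {self.well_id}: cycles must be strictly increasing")
        if not np.all(np.isfinite(self.fluorescence)):
            raise InputError(f"curve {self.well_id}: non-finite fluorescence")


@dataclass
class WellEstimate:
    well_id: str
    sample_id: str = ""
    plate_id: str = ""
    amplicon: str = ""
    role: str = ""
    efficiency: float = np.nan
    cq: float = np.nan
    window: tuple[int, int] | None = None
    qc_pass: bool = False
    reasons: tuple[str, ...] = ()


@dataclass
class PlateSummary:
    plate_id: str
    mean_eff_tel: float
    mean_eff_b2m: float
    calib_cq_tel: float
    calib_cq_b2m: float


@dataclass
class DNASampleQC:
    sample_id: str
    yield_ng_per_ul: float
    a260_280: float
    a260_230: float
    integrity_score: int


@dataclass
class QCResult:
    passed: bool
    reasons: tuple[str, ...] = ()
    value: float | None = None  # e.g. the CV or efficiency deviation


def correct_baseline(
    curve: AmplificationCurve,
    n_baseline_cycles: int = 6,
    negligible_level: float | None = None,
) -> AmplificationCurve:
    """Subtract a linear baseline fitted to the first cycles.

    If ``negligible_level`` is given and the raw fluorescence over the
    baseline region never exceeds it, the signal there is too small to carry
    a meaningful baseline and the curve is returned unchanged (a real
    baseline of any size would be visible in the early cycles).
    """
    if n_baseline_cycles < 2:
        return curve
    if curve.cycles.size <= n_baseline_cycles:
        raise InputError(
            f"curve {curve.well_id}: fewer cycles than n_baseline_cycles"
        )
    c = curve.cycles[:n_baseline_cycles]
    f = curve.fluorescence[:n_baseline_cycles]
    if negligible_level is not None and np.max(np.abs(f)) < negligible_level:
        return curve
    slope, intercept = np.polyfit(c, f, 1)
    corrected = curve.fluorescence - (intercept + slope * curve.cycles)
    return AmplificationCurve(
        curve.plate_id, curve.well_id, curve.sample_id, curve.amplicon,
        curve.role, curve.cycles, corrected,
    )


def _window_candidates(f, plateau_frac, wmin, wmax, lo=None, hi=None, min_last=None):
    """Index windows of length wmin..wmax with positive fluorescence, ending
    before the plateau onset (first cycle within (1-plateau_frac) of max).

    ``lo``/``hi`` restrict window start/end indices to the exponential-phase
    region of interest; ``min_last`` requires the window to reach a minimum
    signal level, keeping baseline-noise segments out of the search.
    """
    fmax = np.max(f)
    if fmax <= 0:
        return []
    onset = int(np.argmax(f >= plateau_frac * fmax))  # first index at plateau
    lo = 0 if lo is None else max(0, lo)
    hi = onset - 1 if hi is None else min(onset - 1, hi)
    out = []
    for w in range(wmin, wmax + 1):
        for start in range(lo, hi - w + 2):
            seg = f[start : start + w]
            if (
                np.all(seg > 0)
                and seg[-1] > seg[0]
                and (min_last is None or seg[-1] >= min_last)
            ):
                out.append((start, start + w - 1))
    return out


def estimate_efficiency_and_cq(
    curve: AmplificationCurve,
    threshold: float,
    window_min: int = 4,
    window_max: int = 6,
    plateau_frac: float = 0.95,
) -> WellEstimate:
    """Window-of-linearity efficiency and threshold-crossing Cq for one well.

    The window maximising the R^2 of the regression of log fluorescence on
    cycle (ties broken toward windows whose span contains the threshold,
    then toward longer and earlier windows) gives E = exp(slope).  Cq is the
    log-linear interpolated cycle at which the corrected fluorescence first
    crosses ``threshold``.  Wells that never reach the threshold are flagged
    non-amplifying (the expected outcome for NTC wells).
    """
    est = WellEstimate(
        well_id=curve.well_id, sample_id=curve.sample_id, plate_id=curve.plate_id,
        amplicon=curve.amplicon, role=curve.role,
    )
    f = curve.fluorescence
    c = curve.cycles
    if np.max(f) < threshold:
        est.reasons = ("non_amplifying",)
        return est

    # Search windows around the threshold crossing: the exponential phase a
    # quantification cycle can be read from.
    i0 = int(np.argmax(f >= threshold))
    cands = _window_candidates(
        f, plateau_frac, window_min, window_max, lo=i0 - 7, hi=i0 + 5
    )
    if not cands:  # crossing hugs the plateau; fall back to a global search
        cands = _window_candidates(f, plateau_frac, window_min, window_max)
    if not cands:
        est.reasons = ("no_linear_window",)
        return est
    # The threshold must lie inside the window span for a valid Cq read, so
    # windows containing it are preferred outright; R^2 decides among them.
    best = None
    logt = np.log(threshold)
    for lo, hi in cands:
        y = np.log(f[lo : hi + 1])
        x = c[lo : hi + 1]
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (intercept + slope * x)
        sst = np.sum((y - y.mean()) ** 2)
        r2 = 1.0 - np.sum(resid**2) / sst if sst > 0 else 0.0
        contains = bool(y[0] <= logt <= y[-1])
        key = (contains, round(r2, 9), hi - lo, -lo)
        if best is None or key > best[0]:
            best = (key, (lo, hi), slope)
    (contains_thr, _, _, _), (lo, hi), slope = best
    if slope <= 0:
        est.reasons = ("no_linear_window",)
        return est
    est.efficiency = float(np.exp(slope))
    est.window = (int(c[lo]), int(c[hi]))

    # Log-linear interpolation at the first upward threshold crossing.
    above = np.flatnonzero(f >= threshold)
    i = above[0]
    if i == 0 or f[i - 1] <= 0:
        est.cq = float(c[i])
    else:
        lf0, lf1 = np.log(f[i - 1]), np.log(f[i])
        est.cq = float(c[i - 1] + (c[i] - c[i - 1]) * (logt - lf0) / (lf1 - lf0))

    reasons = []
    if not contains_thr:
        reasons.append("threshold_outside_window")
    if not (1.0 < est.efficiency <= MAX_EFFICIENCY):
        reasons.append("efficiency_out_of_range")
    est.reasons = tuple(reasons)
    est.qc_pass = not reasons
    return est


def set_group_threshold(
    curves: Iterable[AmplificationCurve],
    amplicon: str,
    first_k_plates: int = DEFAULT_FIRST_K_PLATES,
    window_min: int = 4,
    window_max: int = 6,
    plateau_frac: float = 0.95,
) -> float:
    """Constant threshold for an amplicon group from its first plates.

    For every amplifying well of ``amplicon`` on the first ``first_k_plates``
    plates (sorted by plate id), the window of linearity is located and a
    provisional Cq taken at the window's midpoint fluorescence.  The returned
    threshold lies within the fluorescence span common to all windows and is
    chosen (by root finding) so that the group's average interpolated Cq at
    that threshold matches the average provisional Cq.
    """
    group = [cv for cv in curves if cv.amplicon == amplicon and cv.role != "NTC"]
    if not group:
        raise InputError(f"no curves for amplicon {amplicon!r}")
    plates = sorted({cv.plate_id for cv in group})[:first_k_plates]
    group = [cv for cv in group if cv.plate_id in plates]

    spans, prov_cqs, interps = [], [], []
    for cv in group:
        f, c = cv.fluorescence, cv.cycles
        cands = _window_candidates(
            f, plateau_frac, window_min, window_max, min_last=0.1 * np.max(f)
        )
        if not cands:
            continue
        best = None
        for lo, hi in cands:
            y = np.log(f[lo : hi + 1])
            x = c[lo : hi + 1]
            slope, intercept = np.polyfit(x, y, 1)
            sst = np.sum((y - y.mean()) ** 2)
            r2 = 1.0 - np.sum((y - (intercept + slope * x)) ** 2) / sst if sst > 0 else 0
            key = (round(r2, 9), hi - lo, -lo)
            if best is None or key > best[0]:
                best = (key, (lo, hi))
        lo, hi = best[1]
        lf = np.log(f[lo : hi + 1])
        spans.append((lf[0], lf[-1]))
        mid = 0.5 * (lf[0] + lf[-1])
        prov_cqs.append(np.interp(mid, lf, c[lo : hi + 1]))
        interps.append((lf, c[lo : hi + 1]))
    if not interps:
        raise EstimationError(f"no usable windows for amplicon {amplicon!r}")

    lo_common = max(s[0] for s in spans)
    hi_common = min(s[1] for s in spans)
    if lo_common >= hi_common:  # no common span; fall back to pooled quantiles
        lo_common = float(np.median([s[0] for s in spans]))
        hi_common = float(np.median([s[1] for s in spans]))
    target = float(np.mean(prov_cqs))

    def mean_cq(log_thr):
        return np.mean([np.interp(log_thr, lf, cc) for lf, cc in interps]) - target

    a, b = mean_cq(lo_common), mean_cq(hi_common)
    if a == 0:
        return float(np.exp(lo_common))
    if b == 0:
        return float(np.exp(hi_common))
    if a * b > 0:  # target unreachable inside span; clamp to nearest end
        return float(np.exp(lo_common if abs(a) < abs(b) else hi_common))
    return float(np.exp(brentq(mean_cq, lo_common, hi_common)))


def triplicate_cv_qc(cqs: Sequence[float], cv_limit: float = DEFAULT_CV_LIMIT) -> QCResult:
    """Coefficient of variation (sample SD / mean) across triplicate Cqs.

    Fails when CV exceeds ``cv_limit`` (default 5%) or when fewer than three
    finite Cq values are available (``missing_replicate``).
    """
    cqs = np.asarray(cqs, dtype=float)
    if cqs.size != 3 or not np.all(np.isfinite(cqs)):
        return QCResult(False, ("missing_replicate",))
    cv = float(np.std(cqs, ddof=1) / np.mean(cqs))
    return QCResult(cv <= cv_limit, () if cv <= cv_limit else ("cv",), cv)


def well_efficiency_qc(
    well_eff: float,
    plate_amplicon_mean_eff: float,
    limit: float = DEFAULT_EFF_DEV_LIMIT,
) -> QCResult:
    """Flag wells whose efficiency deviates more than ``limit`` (default 5%)
    from the plate x amplicon mean efficiency."""
    if well_eff <= 1 or plate_amplicon_mean_eff <= 1:
        raise DomainError("efficiencies must exceed 1")
    dev = abs(well_eff - plate_amplicon_mean_eff) / plate_amplicon_mean_eff
    return QCResult(dev <= limit, () if dev <= limit else ("efficiency",), dev)


def dna_sample_qc(
    record: DNASampleQC,
    min_yield: float = 20.0,
    a260_280_range: tuple[float, float] = (1.7, 2.0),
    a260_230_range: tuple[float, float] = (1.8, 2.2),
    max_integrity: int = 2,
) -> QCResult:
    """DNA-extraction QC: yield >= 20 ng/ul, absorbance ratios 1.7-2.0
    (260/280) and 1.8-2.2 (260/230), gel integrity score <= 2.

    Interval endpoints are inclusive; the yield and integrity cut-offs follow
    the strict "< 20" / "higher than 2" reading.
    """
    for name in ("yield_ng_per_ul", "a260_280", "a260_230", "integrity_score"):
        v = getattr(record, name)
        if v is None or (isinstance(v, float) and not np.isfinite(v)):
            raise InputError(f"DNA QC record {record.sample_id}: missing {name}")
    if record.integrity_score not in range(1, 6):
        raise InputError(f"integrity_score must be 1-5, got {record.integrity_score}")
    reasons = []
    if record.yield_ng_per_ul < min_yield:
        reasons.append("low_yield")
    if not (a260_280_range[0] <= record.a260_280 <= a260_280_range[1]):
        reasons.append("purity_260_280")
    if not (a260_230_range[0] <= record.a260_230 <= a260_230_range[1]):
        reasons.append("purity_260_230")
    if record.integrity_score > max_integrity:
        reasons.append("integrity")
    return QCResult(not reasons, tuple(reasons))


def apply_dna_qc(records: Sequence[DNASampleQC], max_attempts: int = 2, **kwargs):
    """Sample-level DNA QC with one re-extraction retry.

    ``records`` may contain up to ``max_attempts`` entries per sample (in
    extraction order).  A sample is accepted as soon as one attempt passes;
    a sample failing all supplied attempts is finally excluded only once it
    has exhausted ``max_attempts``, otherwise it is marked for re-extraction.
    Returns a DataFrame with sample_id, accepted, final, reason columns.
    """
    out = {}
    counts: dict[str, int] = {}
    for rec in records:
        n = counts.get(rec.sample_id, 0)
        if n >= max_attempts:
            continue  # extra attempts beyond the retry budget are ignored
        counts[rec.sample_id] = n + 1
        res = dna_sample_qc(rec, **kwargs)
        prev = out.get(rec.sample_id)
        if prev is not None and prev["accepted"]:
            continue
        out[rec.sample_id] = dict(
            sample_id=rec.sample_id,
            accepted=res.passed,
            final=res.passed or counts[rec.sample_id] >= max_attempts,
            reason="" if res.passed else ";".join(res.reasons),
        )
    return pd.DataFrame(out.values())


def compute_rtl(cq_tel: float, cq_b2m: float, plate: PlateSummary) -> float:
    """Calibrator- and efficiency-corrected relative telomere length.

    RTL = E_TEL^(CqTEL[cal] - CqTEL[sample]) / E_B2M^(CqB2M[cal] - CqB2M[sample])
    using the plate-mean efficiencies and plate calibrator mean Cqs.
    """
    if plate.mean_eff_tel <= 1 or plate.mean_eff_b2m <= 1:
        raise DomainError("plate mean efficiencies must exceed 1")
    if not (np.isfinite(plate.calib_cq_tel) and np.isfinite(plate.calib_cq_b2m)):
        raise InputError(f"plate {plate.plate_id}: missing calibrator Cq")
    return float(
        plate.mean_eff_tel ** (plate.calib_cq_tel - cq_tel)
        / plate.mean_eff_b2m ** (plate.calib_cq_b2m - cq_b2m)
    )


def _curves_from_long(wells: pd.DataFrame):
    required = {"plate", "well", "sample", "amplicon", "role", "cycle", "fluorescence"}
    missing = required - set(wells.columns)
    if missing:
        raise InputError(f"plate table missing columns: {sorted(missing)}")
    for (plate, well), grp in wells.groupby(["plate", "well"], sort=True):
        grp = grp.sort_values("cycle")
        yield AmplificationCurve(
            plate_id=plate,
            well_id=well,
            sample_id=grp["sample"].iloc[0],
            amplicon=grp["amplicon"].iloc[0],
            role=grp["role"].iloc[0],
            cycles=grp["cycle"].to_numpy(),
            fluorescence=grp["fluorescence"].to_numpy(),
        )


def plate_summary(estimates: pd.DataFrame, plate_id: str) -> PlateSummary:
    """Plate-level mean efficiencies and calibrator mean Cqs from a per-well
    estimate table (only QC-eligible wells of the right role contribute)."""
    p = estimates[(estimates["plate_id"] == plate_id) & estimates["qc_pass"]]
    out = {}
    for amp, key in (("TEL", "tel"), ("B2M", "b2m")):
        wells = p[p["amplicon"] == amp]
        out[f"mean_eff_{key}"] = float(wells["efficiency"].mean()) if len(wells) else np.nan
        cal = wells[wells["role"] == "calibrator"]
        out[f"calib_cq_{key}"] = float(cal["cq"].mean()) if len(cal) else np.nan
    return PlateSummary(plate_id=plate_id, **out)


def process_plates(
    wells: pd.DataFrame,
    thresholds: dict[str, float] | None = None,
    n_baseline_cycles: int = 6,
    baseline_negligible_frac: float = 0.02,
    cv_limit: float = DEFAULT_CV_LIMIT,
    eff_dev_limit: float = DEFAULT_EFF_DEV_LIMIT,
    window_min: int = 4,
    window_max: int = 6,
    plateau_frac: float = 0.95,
    qc_enabled: bool = True,
    plate_mean_after_sample_qc: bool = False,
):
    """Run the full measurement pipeline on a long-format plate table.

    Returns ``(rtl, well_qc, summaries, exclusions)``: the per-sample RTL
    table (with exclusion flags and a single primary reason each), the
    per-well estimate/QC table, the per-plate summaries, and a per-reason
    exclusion count.  ``plate_mean_after_sample_qc`` recomputes plate-mean
    efficiencies after sample-level exclusions instead of before (the two
    conventions are both defensible; the default excludes only well-level
    failures first).
    """
    thresholds = dict(DEFAULT_THRESHOLDS if thresholds is None else thresholds)

    est_rows = []
    for curve in _curves_from_long(wells):
        thr = thresholds[curve.amplicon]
        corrected = correct_baseline(
            curve, n_baseline_cycles, negligible_level=baseline_negligible_frac * thr
        )
        est = estimate_efficiency_and_cq(
            corrected, thr, window_min, window_max, plateau_frac
        )
        est_rows.append(vars(est).copy())
    well_qc = pd.DataFrame(est_rows)
    well_qc["reasons"] = well_qc["reasons"].map(lambda r: ";".join(r))

    # NTC wells must not amplify; amplifying NTCs are flagged, never used.
    ntc = well_qc["role"] == "NTC"
    well_qc.loc[ntc, "qc_pass"] = False
    well_qc.loc[ntc & well_qc["cq"].notna(), "reasons"] = "ntc_amplification"

    eligible = well_qc[~ntc]

    def plate_means(tbl):
        ok = tbl[tbl["qc_pass"]]
        return ok.groupby(["plate_id", "amplicon"])["efficiency"].mean()

    means = plate_means(eligible)

    # Per-well efficiency deviation QC against the plate x amplicon mean.
    if qc_enabled:
        devs = []
        for _, row in well_qc.iterrows():
            if row["role"] == "NTC" or not row["qc_pass"]:
                devs.append(False)
                continue
            m = means.get((row["plate_id"], row["amplicon"]), np.nan)
            res = well_efficiency_qc(row["efficiency"], m, eff_dev_limit)
            devs.append(not res.passed)
        well_qc["eff_dev_fail"] = devs
    else:
        well_qc["eff_dev_fail"] = False

    # Sample-level aggregation: triplicate means + QC exclusions.
    rtl_rows = []
    exclusions: dict[str, int] = {}
    sample_wells = well_qc[well_qc["role"].isin(["sample", "calibrator"])]
    summaries = {}
    for plate_id in sorted(well_qc["plate_id"].unique()):
        summaries[plate_id] = plate_summary(
            well_qc[~well_qc["eff_dev_fail"]] if plate_mean_after_sample_qc else well_qc,
            plate_id,
        )
    for (plate_id, sample_id), grp in sample_wells.groupby(
        ["plate_id", "sample_id"], sort=True
    ):
        role = grp["role"].iloc[0]
        reasons = []
        cq_mean = {}
        for amp in ("TEL", "B2M"):
            reps = grp[grp["amplicon"] == amp]
            cqs = reps["cq"].to_numpy()
            ok = reps["qc_pass"].to_numpy()
            if len(reps) < 3 or not ok.all() or not np.all(np.isfinite(cqs)):
                reasons.append("missing_replicate")
                continue
            if qc_enabled:
                cv = triplicate_cv_qc(cqs, cv_limit)
                if not cv.passed:
                    reasons.append(f"cv_{amp.lower()}" if cv.reasons == ("cv",) else cv.reasons[0])
                if reps["eff_dev_fail"].any():
                    reasons.append("efficiency")
            cq_mean[amp] = float(np.mean(cqs))
        summary = summaries[plate_id]
        excluded = bool(reasons)
        rtl = np.nan
        if not excluded:
            try:
                rtl = compute_rtl(cq_mean["TEL"], cq_mean["B2M"], summary)
            except (DomainError, InputError):
                excluded, reasons = True, ["no_calibrator"]
        if excluded and role == "sample":
            primary = reasons[0]
            exclusions[primary] = exclusions.get(primary, 0) + 1
        rtl_rows.append(
            dict(
                sample_id=sample_id,
                plate_id=plate_id,
                role=role,
                cq_tel=cq_mean.get("TEL", np.nan),
                cq_b2m=cq_mean.get("B2M", np.nan),
                rtl=rtl,
                excluded=excluded,
                reason=reasons[0] if reasons else "",
            )
        )
    rtl_df = pd.DataFrame(rtl_rows)
    return rtl_df, well_qc, summaries, exclusions
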