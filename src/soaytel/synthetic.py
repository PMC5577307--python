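"""Synthetic study generator: phenotypes, pedigree links and raw qPCR plates.

The generator emulates the structure of a two-year cross-sectional telomere
study in a wild sheep population: each observation is one relative telomere
length (RTL) measurement on an animal with known sample year, age, sex,
mother, father, maternal/paternal age at conception (MAC/PAC) and qPCR plate.
RTL is generated from a Gaussian linear mixed model with crossed random
intercepts for mother, father and plate:

    RTL = mu + beta_year*year + beta_age*age + beta_sex*sex
             + beta_agesex*age*sex
             + b_MAC*(MAC - E[MAC]) + b_PAC*(PAC - E[PAC])
             + u_mother + u_father + u_plate + eps

with u_* ~ N(0, sigma^2_*) and eps ~ N(0, sigma^2_resid).  MAC and PAC are
integer years (>= 1) drawn independently of one another from truncated
geometric distributions, so their expected correlation is zero.

A second stage inverts the calibrator/efficiency-corrected RTL formula to
produce raw per-well amplification curves (fluorescence by cycle) whose
processed read-out reproduces each record's RTL — exactly in the noiseless
limit, and up to well-to-well Cq noise otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import DomainError, ParameterError

__all__ = [
    "PopulationParams",
    "QPCRPlateSpec",
    "PlateSimulation",
    "study_design",
    "sample_population",
    "simulate_plates",
    "truncated_geometric_probs",
    "solve_truncated_geometric",
]

# Study-scale constants of the default design: 389 RTL measurements on 318
# animals (so 71 measured in both years), 208 mothers, 138 fathers, 9 plates,
# two August sampling years with 200 and 189 measurements.
DEFAULT_N_OBS = 389
DEFAULT_N_ANIMALS = 318
DEFAULT_N_MOTHERS = 208
DEFAULT_N_FATHERS = 138
DEFAULT_N_PLATES = 9
DEFAULT_YEARS = (2014, 2015)
DEFAULT_YEAR1_OBS = 200  # of which 134 female / 66 male; 2015: 140 / 49
DEFAULT_TOTAL_RTL_SD = 0.185
DEFAULT_PAC_SD = 2.121


def truncated_geometric_probs(lo: int, hi: int, p: float):
    """Probability mass of a geometric(p) distribution truncated to [lo, hi].

    Returns (support, probs).  Small p approaches the discrete uniform on the
    range; large p concentrates mass on ``lo``.
    """
    if not (0 < p < 1):
        raise ParameterError(f"geometric parameter must be in (0,1), got {p}")
    if hi < lo:
        raise ParameterError(f"empty support [{lo}, {hi}]")
    k = np.arange(lo, hi + 1)
    w = (1.0 - p) ** (k - lo)
    return k, w / w.sum()


def _trunc_geom_moments(lo, hi, p):
    k, probs = truncated_geometric_probs(lo, hi, p)
    mean = float(np.sum(k * probs))
    var = float(np.sum((k - mean) ** 2 * probs))
    return mean, np.sqrt(var)


def solve_truncated_geometric(lo: int, hi: int, target_sd: float) -> float:
    """Geometric parameter p whose [lo, hi]-truncated SD equals ``target_sd``.

    The SD is strictly decreasing in p; the maximum attainable SD is that of
    the discrete uniform on the range.
    """
    max_sd = _trunc_geom_moments(lo, hi, 1e-9)[1]
    if not (0 < target_sd < max_sd):
        raise ParameterError(
            f"target SD {target_sd} not attainable on [{lo}, {hi}] "
            f"(max {max_sd:.3f})"
        )
    return brentq(
        lambda p: _trunc_geom_moments(lo, hi, p)[1] - target_sd, 1e-9, 1 - 1e-9
    )


@dataclass(frozen=True)
class PopulationParams:
    """Parameters of the simulated study population.

    Variances are on the RTL^2 scale; slopes are RTL units per year of
    parental age.  ``mac_sd``/``pac_sd`` set the marginal dispersion of the
    truncated-geometric parental-age distributions over ``mac_range`` /
    ``pac_range`` (integer years, inclusive).
    """

    n_obs: int = DEFAULT_N_OBS
    n_animals: int = DEFAULT_N_ANIMALS
    n_mothers: int = DEFAULT_N_MOTHERS
    n_fathers: int = DEFAULT_N_FATHERS
    n_plates: int = DEFAULT_N_PLATES
    mac_range: tuple[int, int] = (1, 14)
    pac_range: tuple[int, int] = (1, 10)
    mac_sd: float = 2.6
    pac_sd: float = DEFAULT_PAC_SD
    fixed_effects: Mapping[str, float] = field(
        default_factory=lambda: {"year": 0.0, "age": 0.0, "sex": 0.0, "age:sex": 0.0}
    )
    mac_slope: float = 0.0
    pac_slope: float = 0.0
    var_mother: float = 0.0
    var_father: float = 0.0
    var_plate: float = 0.0
    var_resid: float = DEFAULT_TOTAL_RTL_SD**2
    rtl_mean: float = 1.0
    female_frac: float = 0.70
    lamb_frac: float = 164 / 389
    year1_frac: float = DEFAULT_YEAR1_OBS / DEFAULT_N_OBS
    years: tuple[int, int] = DEFAULT_YEARS
    replate_repeats: bool = True
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_obs", "n_animals", "n_mothers", "n_fathers", "n_plates"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be a positive count")
        if self.n_obs < self.n_animals:
            raise ParameterError("n_obs must be >= n_animals")
        if self.n_obs > 2 * self.n_animals:
            raise ParameterError(
                "n_obs > 2*n_animals: at most two sampling years per animal"
            )
        for name in ("var_mother", "var_father", "var_plate", "var_resid"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        for rng_name in ("mac_range", "pac_range"):
            lo, hi = getattr(self, rng_name)
            if lo < 1 or hi < lo:
                raise ParameterError(
                    f"{rng_name} must be an integer range with 1 <= lo <= hi"
                )
        for frac in ("female_frac", "lamb_frac", "year1_frac"):
            if not (0 <= getattr(self, frac) <= 1):
                raise ParameterError(f"{frac} must lie in [0, 1]")

    @property
    def mac_mean(self) -> float:
        p = solve_truncated_geometric(*self.mac_range, self.mac_sd)
        return _trunc_geom_moments(*self.mac_range, p)[0]

    @property
    def pac_mean(self) -> float:
        p = solve_truncated_geometric(*self.pac_range, self.pac_sd)
        return _trunc_geom_moments(*self.pac_range, p)[0]


def study_design(
    total_rtl_sd: float = DEFAULT_TOTAL_RTL_SD,
    random_frac: float = 1 / 3,
    intercept_shares: tuple[float, float, float] = (0.16, 0.02, 0.82),
    **overrides,
) -> PopulationParams:
    """Default parameters matching the study's design.

    389 observations on 318 animals, 208 mothers, 138 fathers, 9 plates; PAC
    dispersion targets SD 2.121 and the total RTL SD targets 0.185.  The
    random-intercept component (mother+father+plate) takes ``random_frac`` of
    the total RTL variance, split mother:father:plate per
    ``intercept_shares`` (default 16% / 2% / 82%, the mother/father shares of
    the random-effects component reported for this design); the residual
    absorbs the remainder.  Keyword overrides replace any
    :class:`PopulationParams` field.
    """
    shares = np.asarray(intercept_shares, dtype=float)
    if np.any(shares < 0) or not np.isclose(shares.sum(), 1.0):
        raise ParameterError("intercept_shares must be non-negative and sum to 1")
    if not (0 <= random_frac < 1):
        raise ParameterError("random_frac must lie in [0, 1)")
    total_var = total_rtl_sd**2
    vr = random_frac * total_var
    params = PopulationParams(
        var_mother=shares[0] * vr,
        var_father=shares[1] * vr,
        var_plate=shares[2] * vr,
        var_resid=total_var - vr,
    )
    if overrides:
        params = replace(params, **overrides)
    params.validate()
    return params


def _draw_trunc_geom(rng, lo, hi, sd, size):
    k, probs = truncated_geometric_probs(lo, hi, solve_truncated_geometric(lo, hi, sd))
    return rng.choice(k, size=size, p=probs)


def sample_population(
    params: PopulationParams, seed: int | np.random.SeedSequence | None = None
) -> pd.DataFrame:
    """Draw one study population as a phenotype table.

    Returns a DataFrame with one row per RTL observation and columns
    ``sample_id, animal_id, year, age, sex, mother_id, father_id, plate_id,
    mac, pac, rtl``.  Identical ``params`` and seed give identical tables.
    ``seed=None`` uses ``params.seed``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n_a = params.n_animals
    year1, year2 = params.years

    # Animal-level attributes.
    animal_id = np.array([f"A{i:04d}" for i in range(n_a)])
    sex = np.where(rng.random(n_a) < params.female_frac, "F", "M")
    mother = rng.integers(0, params.n_mothers, size=n_a)
    father = rng.integers(0, params.n_fathers, size=n_a)
    mac = _draw_trunc_geom(rng, *params.mac_range, params.mac_sd, n_a)
    pac = _draw_trunc_geom(rng, *params.pac_range, params.pac_sd, n_a)
    is_lamb = rng.random(n_a) < params.lamb_frac
    # Age at first capture: lambs are ~4 months old, adults 1-9 years.
    age0 = np.where(is_lamb, 0.33, rng.integers(1, 10, size=n_a) + 0.33)

    # 71 of 318 animals (n_obs - n_animals) are measured in both years; the
    # rest appear once, allocated to hit the two-year split of observations.
    n_rep = params.n_obs - n_a
    repeated = np.zeros(n_a, dtype=bool)
    repeated[rng.choice(n_a, size=n_rep, replace=False)] = True
    singles = np.flatnonzero(~repeated)
    n_single_y1 = int(np.clip(round(params.year1_frac * params.n_obs) - n_rep, 0, singles.size))
    single_year = np.full(singles.size, year2)
    single_year[rng.choice(singles.size, size=n_single_y1, replace=False)] = year1

    rows_animal, rows_year, rows_age = [], [], []
    for i in range(n_a):
        if repeated[i]:
            rows_animal += [i, i]
            rows_year += [year1, year2]
            rows_age += [age0[i], age0[i] + 1.0]
        else:
            yr = single_year[np.searchsorted(singles, i)]
            rows_animal.append(i)
            rows_year.append(yr)
            rows_age.append(age0[i] if yr == year1 else age0[i])
    idx = np.asarray(rows_animal)
    year = np.asarray(rows_year)
    age = np.asarray(rows_age)
    n = params.n_obs

    plate = rng.integers(0, params.n_plates, size=n)
    if not params.replate_repeats:
        # Repeated animals keep the plate of their first observation.
        first_plate: dict[int, int] = {}
        for j in range(n):
            plate[j] = first_plate.setdefault(idx[j], plate[j])

    u_mother = rng.normal(0.0, np.sqrt(params.var_mother), params.n_mothers)
    u_father = rng.normal(0.0, np.sqrt(params.var_father), params.n_fathers)
    u_plate = rng.normal(0.0, np.sqrt(params.var_plate), params.n_plates)

    fe = dict(params.fixed_effects)
    male = (sex[idx] == "M").astype(float)
    mean = (
        params.rtl_mean
        + fe.get("year", 0.0) * (year == year2)
        + fe.get("age", 0.0) * age
        + fe.get("sex", 0.0) * male
        + fe.get("age:sex", 0.0) * age * male
        + params.mac_slope * (mac[idx] - params.mac_mean)
        + params.pac_slope * (pac[idx] - params.pac_mean)
        + u_mother[mother[idx]]
        + u_father[father[idx]]
        + u_plate[plate]
    )
    resid = rng.normal(0.0, np.sqrt(params.var_resid), n)
    rtl = mean + resid
    # RTL must stay positive; redraw the (rare) offending residuals.
    for _ in range(100):
        bad = rtl <= 0
        if not bad.any():
            break
        rtl[bad] = mean[bad] + rng.normal(0.0, np.sqrt(params.var_resid), bad.sum())
    else:  # pragma: no cover - only reachable with absurd parameters
        raise ParameterError("could not generate positive RTL; check parameters")

    df = pd.DataFrame(
        {
            "sample_id": [f"{a}_{y}" for a, y in zip(animal_id[idx], year)],
            "animal_id": animal_id[idx],
            "year": year,
            "age": age,
            "sex": sex[idx],
            "mother_id": [f"M{m:03d}" for m in mother[idx]],
            "father_id": [f"F{f:03d}" for f in father[idx]],
            "plate_id": [f"P{p:02d}" for p in plate],
            "mac": mac[idx].astype(int),
            "pac": pac[idx].astype(int),
            "rtl": rtl,
        }
    )
    return df


# ---------------------------------------------------------------------------
# Raw qPCR plate simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QPCRPlateSpec:
    """True plate-level parameters for simulated amplification curves.

    Efficiencies are per-cycle fold changes in (1, 2]; thresholds are the
    fixed fluorescence levels at which Cq is read for each amplicon group.
    ``cq_noise_sd`` is well-to-well Cq noise in cycles; ``fluor_noise_sd`` is
    multiplicative (lognormal sigma) fluorescence noise.  The baseline is a
    per-well linear drift ``a + b*cycle`` with a, b drawn uniformly from the
    given ranges.  ``corrupt_cv_fraction`` deliberately shifts one TEL
    replicate of that fraction of samples by ``corrupt_shift`` cycles, to
    exercise the triplicate-CV QC filter downstream.
    """

    e_tel: float = 1.91
    e_b2m: float = 1.88
    threshold_tel: float = 0.222
    threshold_b2m: float = 0.193
    n_cycles: int = 50
    plateau: float = 2.0
    cal_cq_tel: float = 15.0
    cal_cq_b2m: float = 24.0
    b2m_spread_sd: float = 0.3  # true sample-to-sample DNA-input variation
    cq_noise_sd: float = 0.05
    fluor_noise_sd: float = 0.0
    baseline_intercept: tuple[float, float] = (0.0, 0.0)
    baseline_slope: tuple[float, float] = (0.0, 0.0)
    n_calibrators: int = 2
    n_replicates: int = 3
    corrupt_cv_fraction: float = 0.0
    corrupt_shift: float = 4.0
    calibrator_rtl: float = 1.0  # by construction

    def validate(self) -> None:
        for name in ("e_tel", "e_b2m"):
            e = getattr(self, name)
            if not (1.0 < e <= 2.0):
                raise ParameterError(f"{name} must be in (1, 2], got {e}")
        if self.n_cycles < 30:
            raise ParameterError("n_cycles must be >= 30")
        for name in ("threshold_tel", "threshold_b2m"):
            t = getattr(self, name)
            if not (0 < t < self.plateau):
                raise ParameterError(f"plateau > {name} > 0 violated")
        if self.cq_noise_sd < 0 or self.fluor_noise_sd < 0:
            raise ParameterError("noise SDs must be >= 0")

    def threshold(self, amplicon: str) -> float:
        return self.threshold_tel if amplicon == "TEL" else self.threshold_b2m

    def efficiency(self, amplicon: str) -> float:
        return self.e_tel if amplicon == "TEL" else self.e_b2m


@dataclass
class PlateSimulation:
    """Output of :func:`simulate_plates`.

    ``wells`` is the long-format raw table (one row per well per cycle);
    ``truth`` holds the generating per-well Cq and efficiency for testing.
    """

    wells: pd.DataFrame
    truth: pd.DataFrame


def _well_curve(rng, spec, cq, eff, cycles, amplifying=True):
    a = rng.uniform(*spec.baseline_intercept)
    b = rng.uniform(*spec.baseline_slope)
    baseline = a + b * cycles
    signal = 0.0
    if amplifying:
        # F0 chosen so the noiseless curve crosses the threshold exactly at cq.
        cq_val, thr = cq
        f0 = thr * eff ** (-cq_val)
        signal = np.minimum(f0 * eff**cycles, spec.plateau)
    fluor = baseline + signal
    if spec.fluor_noise_sd > 0:
        fluor = fluor * np.exp(rng.normal(0.0, spec.fluor_noise_sd, cycles.size))
    return np.maximum(fluor, 1e-9)


def simulate_plates(
    records: pd.DataFrame,
    spec: QPCRPlateSpec | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> PlateSimulation:
    """Emit raw amplification curves whose processed RTL matches ``records``.

    For each phenotype record, three TEL and three B2M sample wells are
    generated on the record's plate; each plate also carries calibrator
    triplicates for both amplicons and no-template-control (NTC) wells.  The
    true sample Cqs invert the RTL formula

        RTL = E_TEL^(CqTEL[cal] - CqTEL[sample]) / E_B2M^(CqB2M[cal] - CqB2M[sample])

    at the spec's efficiencies, so the noiseless round trip through qPCR
    processing is the identity.
    """
    spec = spec or QPCRPlateSpec()
    spec.validate()
    if (records["rtl"] <= 0).any():
        bad = records.loc[records["rtl"] <= 0, "sample_id"].iloc[0]
        raise DomainError(f"rtl must be > 0 (sample {bad})")
    rng = np.random.default_rng(seed)
    cycles = np.arange(1, spec.n_cycles + 1)
    ln_et, ln_eb = np.log(spec.e_tel), np.log(spec.e_b2m)

    well_rows = []
    truth_rows = []

    def emit(plate, sample, amplicon, role, cq_true, rep):
        thr = spec.threshold(amplicon)
        eff = spec.efficiency(amplicon)
        amplifying = role != "NTC"
        cq_well = np.nan
        if amplifying:
            cq_well = cq_true + (
                rng.normal(0.0, spec.cq_noise_sd) if spec.cq_noise_sd > 0 else 0.0
            )
        well = f"{sample}_{amplicon}_r{rep}"
        fl = _well_curve(rng, spec, (cq_well, thr), eff, cycles, amplifying)
        well_rows.append((plate, well, sample, amplicon, role, fl))
        truth_rows.append(
            dict(
                plate_id=plate,
                well_id=well,
                sample_id=sample,
                amplicon=amplicon,
                role=role,
                cq_nominal=cq_true,
                cq_true=cq_well,
                efficiency=eff,
            )
        )

    for plate_id, grp in records.groupby("plate_id", sort=True):
        for c in range(spec.n_calibrators):
            for rep in range(spec.n_replicates):
                emit(plate_id, f"{plate_id}_CAL{c+1}", "TEL", "calibrator",
                     spec.cal_cq_tel, rep)
                emit(plate_id, f"{plate_id}_CAL{c+1}", "B2M", "calibrator",
                     spec.cal_cq_b2m, rep)
        corrupt = rng.random(len(grp)) < spec.corrupt_cv_fraction
        for k, (_, rec) in enumerate(grp.iterrows()):
            # Invert the RTL formula for the true sample Cqs.
            cq_b2m = spec.cal_cq_b2m + rng.normal(0.0, spec.b2m_spread_sd)
            cq_tel = spec.cal_cq_tel - (
                np.log(rec["rtl"]) + (spec.cal_cq_b2m - cq_b2m) * ln_eb
            ) / ln_et
            for rep in range(spec.n_replicates):
                shift = spec.corrupt_shift if (corrupt[k] and rep == 0) else 0.0
                emit(plate_id, rec["sample_id"], "TEL", "sample", cq_tel + shift, rep)
            for rep in range(spec.n_replicates):
                emit(plate_id, rec["sample_id"], "B2M", "sample", cq_b2m, rep)
        for amplicon in ("TEL", "B2M"):
            for rep in range(spec.n_replicates):
                emit(plate_id, f"{plate_id}_NTC", amplicon, "NTC", np.nan, rep)

    n_wells = len(well_rows)
    wells = pd.DataFrame(
        {
            "plate": np.repeat([r[0] for r in well_rows], spec.n_cycles),
            "well": np.repeat([r[1] for r in well_rows], spec.n_cycles),
            "sample": np.repeat([r[2] for r in well_rows], spec.n_cycles),
            "amplicon": np.repeat([r[3] for r in well_rows], spec.n_cycles),
            "role": np.repeat([r[4] for r in well_rows], spec.n_cycles),
            "cycle": np.tile(cycles, n_wells),
            "fluorescence": np.concatenate([r[5] for r in well_rows]),
        }
    )
    return PlateSimulation(wells=wells, truth=pd.DataFrame(truth_rows))
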