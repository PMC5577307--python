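"""Monte-Carlo power analysis for parental-age effects, and slope <->
correlation effect-size conversion.

A qPCR RTL value is unitless and parental ages span different ranges in
different species, so slopes are made comparable across studies by
converting to a correlation coefficient:

    r = slope * SD_x / SD_y

with SD_x the parental-age SD and SD_y the RTL SD.  For this study's
design, SD_PAC = 2.121 and SD_RTL = 0.185, so a PAC slope of 0.012
corresponds to r ~ 0.14.

Power is estimated by simulation: each replicate draws a fresh study
(parents, plates, covariates and RTL) from the design structure with the
candidate slope injected, runs the 1-df linear likelihood-ratio test, and
the power is the fraction of replicates with p below alpha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DomainError, ParameterError, UsageError
from .lmm import test_parental_age
from .synthetic import PopulationParams, sample_population, study_design

__all__ = [
    "PowerRequest",
    "PowerEstimate",
    "slope_to_r",
    "r_to_slope",
    "estimate_power",
    "minimum_detectable_effect",
    "partition_sensitivity",
    "plot_power_curve",
    "SD_PAC",
    "SD_RTL",
]

SD_PAC = 2.121
SD_RTL = 0.185


def slope_to_r(slope: float, sd_x: float = SD_PAC, sd_y: float = SD_RTL) -> float:
    """Correlation coefficient implied by a regression slope."""
    if sd_x <= 0 or sd_y <= 0:
        raise DomainError("standard deviations must be positive")
    return slope * sd_x / sd_y


def r_to_slope(r: float, sd_x: float = SD_PAC, sd_y: float = SD_RTL) -> float:
    """Regression slope implied by a correlation coefficient (exact inverse
    of :func:`slope_to_r`)."""
    if sd_x <= 0 or sd_y <= 0:
        raise DomainError("standard deviations must be positive")
    return r * sd_y / sd_x


@dataclass(frozen=True)
class PowerRequest:
    """A power-analysis job: design structure, effect grid and test size."""

    structure: PopulationParams = field(default_factory=study_design)
    effect_grid: tuple[float, ...] = (0.0, 0.006, 0.012, 0.018)
    n_reps: int = 500
    alpha: float = 0.05
    which: str = "pac"
    seed: int = 0
    max_nonconverged_frac: float = 0.02

    def validate(self) -> None:
        if self.n_reps < 1:
            raise ParameterError("n_reps must be >= 1")
        if not (0 < self.alpha < 1):
            raise ParameterError("alpha must lie in (0, 1)")
        if not np.all(np.isfinite(self.effect_grid)):
            raise ParameterError("effect_grid must be finite")
        self.structure.validate()


@dataclass
class PowerEstimate:
    """Rejection fraction at one true slope, with Monte-Carlo error."""

    effect: float
    power: float
    n_reps: int
    n_nonconverged: int = 0

    @property
    def mc_se(self) -> float:
        return float(np.sqrt(self.power * (1.0 - self.power) / self.n_reps))


def estimate_power(req: PowerRequest, progress: bool = False) -> list[PowerEstimate]:
    """Monte-Carlo power curve over ``req.effect_grid``.

    One master seed spawns independent substreams per effect and per
    replicate, so results are reproducible and effects are independent.
    Non-converged replicates are dropped from the denominator with a
    warning; if more than ``max_nonconverged_frac`` of replicates drop, the
    run fails loudly.
    """
    req.validate()
    master = np.random.SeedSequence(req.seed)
    effect_streams = master.spawn(len(req.effect_grid))
    out = []
    for effect, stream in zip(req.effect_grid, effect_streams):
        params = replace(
            req.structure,
            **{f"{req.which.lower()}_slope": float(effect)},
        )
        rejections = 0
        nonconv = 0
        rep_streams = stream.spawn(req.n_reps)
        for i, rep_seed in enumerate(rep_streams):
            data = sample_population(params, seed=rep_seed)
            res = test_parental_age(data, which=req.which, order="linear")
            if not (res.full.converged and res.reduced.converged):
                nonconv += 1
                continue
            if res.p_value < req.alpha:
                rejections += 1
            if progress and (i + 1) % 50 == 0:
                print(f"  effect {effect:+.4f}: {i+1}/{req.n_reps} replicates")
        n_eff = req.n_reps - nonconv
        if nonconv:
            warnings.warn(
                f"effect {effect}: {nonconv} non-converged replicates dropped",
                RuntimeWarning,
            )
        if nonconv > req.max_nonconverged_frac * req.n_reps:
            raise RuntimeError(
                f"effect {effect}: {nonconv}/{req.n_reps} replicates failed to "
                "converge; power estimate unreliable"
            )
        out.append(PowerEstimate(float(effect), rejections / n_eff, n_eff, nonconv))
    return out


def _pava_increasing(y: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators: least-squares non-decreasing fit."""
    y = np.asarray(y, dtype=float)
    stack: list[list] = []
    for j in range(len(y)):
        stack.append([y[j], 1.0, [j]])
        while len(stack) > 1 and stack[-2][0] > stack[-1][0]:
            v1, w1, i1 = stack.pop()
            v0, w0, i0 = stack.pop()
            stack.append([(v0 * w0 + v1 * w1) / (w0 + w1), w0 + w1, i0 + i1])
    out = np.empty_like(y)
    for v, _, ids in stack:
        out[ids] = v
    return out


@dataclass
class MDEResult:
    slope: float
    target_power: float
    bracket: tuple[float, float]
    bracket_powers: tuple[float, float]
    mc_se_at_bracket: tuple[float, float]


def minimum_detectable_effect(
    estimates: list[PowerEstimate], target_power: float, alpha: float = 0.05
) -> MDEResult:
    """Smallest slope reaching ``target_power``, by monotone interpolation.

    The estimated power curve is first made non-decreasing in |effect|
    (pool-adjacent-violators, absorbing Monte-Carlo wiggle), then inverted
    linearly between the bracketing grid points.
    """
    if not (alpha < target_power < 1):
        raise UsageError("target_power must lie in (alpha, 1)")
    ests = sorted(estimates, key=lambda e: abs(e.effect))
    effects = np.array([abs(e.effect) for e in ests])
    powers = _pava_increasing(np.array([e.power for e in ests]))
    if powers[0] >= target_power or powers[-1] < target_power:
        raise UsageError(
            f"effect grid {effects.tolist()} does not bracket power {target_power}"
        )
    j = int(np.argmax(powers >= target_power))
    lo, hi = effects[j - 1], effects[j]
    plo, phi = powers[j - 1], powers[j]
    slope = lo + (hi - lo) * (target_power - plo) / (phi - plo)
    return MDEResult(
        float(slope),
        target_power,
        (float(lo), float(hi)),
        (float(plo), float(phi)),
        (ests[j - 1].mc_se, ests[j].mc_se),
    )


def partition_sensitivity(
    effect: float,
    random_fracs: tuple[float, ...] = (0.1, 1 / 3, 0.6),
    n_reps: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
    **design_kwargs,
) -> pd.DataFrame:
    """Power at one slope across variance partitions.

    The mother:father:plate split of the random-intercept component is held
    at its design values while the fraction of total RTL variance assigned
    to the random intercepts (vs the residual) varies — the partition the
    printed study summaries do not pin down.
    """
    rows = []
    for frac in random_fracs:
        req = PowerRequest(
            structure=study_design(random_frac=frac, **design_kwargs),
            effect_grid=(effect,),
            n_reps=n_reps,
            alpha=alpha,
            seed=seed,
        )
        est = estimate_power(req)[0]
        rows.append(
            dict(random_frac=frac, effect=effect, power=est.power,
                 mc_se=est.mc_se, n_reps=est.n_reps)
        )
    return pd.DataFrame(rows)


def plot_power_curve(estimates: list[PowerEstimate], target_power: float = 0.8, ax=None):
    """Plot the power curve with +-1 Monte-Carlo SE (requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    eff = [e.effect for e in estimates]
    pw = [e.power for e in estimates]
    se = [e.mc_se for e in estimates]
    ax.errorbar(eff, pw, yerr=se, marker="o", capsize=3)
    ax.axhline(target_power, ls="--", color="grey")
    ax.set_xlabel("true PAC slope (RTL per year)")
    ax.set_ylabel("power")
    ax.set_ylim(0, 1.02)
    return ax
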