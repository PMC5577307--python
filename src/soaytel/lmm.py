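"""Gaussian linear mixed models with crossed random intercepts, and
likelihood-ratio tests for parental-age effects on RTL.

The model for one RTL observation is

    y = X beta + Z_m u_m + Z_f u_f + Z_p u_p + eps,
    u_k ~ N(0, sigma_k^2 I),   eps ~ N(0, sigma_e^2 I),

with crossed (non-nested) grouping factors: maternal identity, paternal
identity and qPCR plate.  The base fixed-effect structure is sample year
(2-level factor), age, sex (2-level factor) and the age x sex interaction;
a lamb-only variant drops age and its interaction since all lambs are the
same age.  Parental age at conception (MAC or PAC) enters as a linear or
linear+quadratic term (mean-centred before squaring) and is tested against
the base model with a likelihood-ratio test, both models fitted by maximum
likelihood.

Fitting maximises the profiled log-likelihood over the variance ratios
gamma_k = sigma_k^2 / sigma_e^2 (beta and sigma_e^2 have closed forms given
gamma).  All linear algebra runs on the q x q random-effect cross-product
via the Woodbury identity, where q = total number of random-effect levels,
so the cost per likelihood evaluation is O(q^3) regardless of n.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize
from scipy.stats import chi2

from .errors import ParameterError, UsageError

__all__ = [
    "ModelSpec",
    "FitResult",
    "LRTResult",
    "fit_lmm",
    "lrt",
    "test_parental_age",
    "variance_proportions",
    "BASE_FIXED_TERMS",
    "LAMB_FIXED_TERMS",
]

BASE_FIXED_TERMS = ("year", "age", "sex", "age:sex")
LAMB_FIXED_TERMS = ("year", "sex")
DEFAULT_RANDOM_TERMS = ("mother_id", "father_id", "plate_id")
_KNOWN_FIXED = {"year", "age", "sex", "age:sex", "mac", "mac2", "pac", "pac2"}


@dataclass(frozen=True)
class ModelSpec:
    """Which terms enter the model and how it is estimated."""

    fixed: tuple[str, ...] = BASE_FIXED_TERMS
    random: tuple[str, ...] = DEFAULT_RANDOM_TERMS
    reml: bool = False
    lamb_mode: bool = False

    def validate(self) -> None:
        unknown = set(self.fixed) - _KNOWN_FIXED
        if unknown:
            raise ParameterError(f"unknown fixed terms: {sorted(unknown)}")
        f = set(self.fixed)
        if "age:sex" in f and not {"age", "sex"} <= f:
            raise ParameterError("age:sex requires age and sex main effects")
        for term in ("mac", "pac"):
            if f"{term}2" in f and term not in f:
                raise ParameterError(f"{term}2 requires the linear {term} term")
        if self.lamb_mode and ("age" in f or "age:sex" in f):
            raise ParameterError("lamb_mode models must not contain age terms")


@dataclass
class FitResult:
    """A fitted LMM: fixed effects, variance components and log-likelihood."""

    spec: ModelSpec
    coefficients: pd.Series
    se: pd.Series
    varcomps: dict[str, float]  # per random term, plus "resid"
    loglik: float
    n_obs: int
    converged: bool
    boundary: tuple[str, ...] = ()  # variance components estimated at 0
    _ratios: np.ndarray | None = None

    @property
    def n_fixed(self) -> int:
        return len(self.coefficients)


@dataclass
class LRTResult:
    chisq: float
    df: int
    p_value: float
    term_tested: str
    full: FitResult | None = None
    reduced: FitResult | None = None


def _design(data: pd.DataFrame, spec: ModelSpec):
    """Fixed-effect design matrix (treatment coding, second sorted level of
    each factor as the dummy) and random-effect factor codes."""
    n = len(data)
    cols = {"(Intercept)": np.ones(n)}
    levels = {}
    for fac in ("year", "sex"):
        if fac in spec.fixed:
            lv = np.sort(data[fac].unique())
            if len(lv) != 2:
                raise ParameterError(f"factor {fac!r} needs exactly 2 levels, got {len(lv)}")
            levels[fac] = lv
            cols[f"{fac}[{lv[1]}]"] = (data[fac].to_numpy() == lv[1]).astype(float)
    if "age" in spec.fixed:
        cols["age"] = data["age"].to_numpy(dtype=float)
    if "age:sex" in spec.fixed:
        lv = levels["sex"]
        cols[f"age:sex[{lv[1]}]"] = cols["age"] * cols[f"sex[{lv[1]}]"]
    for term in ("mac", "pac"):
        if term in spec.fixed:
            x = data[term].to_numpy(dtype=float)
            xc = x - x.mean()
            cols[term] = xc
            if f"{term}2" in spec.fixed:
                cols[f"{term}2"] = xc**2
    X = np.column_stack(list(cols.values()))
    factors = {}
    for name in spec.random:
        codes, lv = pd.factorize(data[name], sort=True)
        if len(lv) < 2:
            raise ParameterError(f"random term {name!r} needs >= 2 levels")
        factors[name] = (codes, len(lv))
    return np.asarray(data["rtl"], dtype=float), X, list(cols), factors


class _Profile:
    """Profiled (RE)ML negative log-likelihood over the variance ratios
    gamma_k = sigma_k^2 / sigma_e^2, with its analytic gradient.

    With V* = I + sum_k gamma_k Z_k Z_k', beta and sigma_e^2 have closed
    forms, and all solves go through M = I_q + D^(1/2) Z'Z D^(1/2)
    (D = diag of gamma per level), so the per-evaluation cost is O(q^3).
    """

    def __init__(self, y, X, factors, reml):
        self.n, self.p = X.shape
        self.reml = reml
        self.names = list(factors)
        self.nlev = np.array([factors[k][1] for k in self.names])
        offs = np.concatenate([[0], np.cumsum(self.nlev)])
        self.blocks = [slice(offs[i], offs[i + 1]) for i in range(len(self.names))]
        Z = sp.hstack(
            [
                sp.csr_matrix(
                    (np.ones(self.n), (np.arange(self.n), factors[k][0])),
                    shape=(self.n, factors[k][1]),
                )
                for k in self.names
            ],
            format="csr",
        )
        self.q = Z.shape[1]
        self.ZtZ = (Z.T @ Z).toarray()
        self.ZtX = Z.T @ X
        self.Zty = Z.T @ y
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)

    def _core(self, gamma):
        gam = np.repeat(np.maximum(np.asarray(gamma, dtype=float), 0.0), self.nlev)
        sq = np.sqrt(gam)
        M = self.ZtZ * np.outer(sq, sq)
        M[np.diag_indices_from(M)] += 1.0
        c = cho_factor(M, lower=True, check_finite=False)
        logdetM = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
        dZtX = sq[:, None] * self.ZtX
        dZty = sq * self.Zty
        wy = cho_solve(c, dZty, check_finite=False)
        XtViX = self.XtX - dZtX.T @ cho_solve(c, dZtX, check_finite=False)
        XtViy = self.Xty - dZtX.T @ wy
        ytViy = self.yty - dZty @ wy
        cb = cho_factor(XtViX, lower=True, check_finite=False)
        beta = cho_solve(cb, XtViy, check_finite=False)
        rss = ytViy - beta @ XtViy
        return sq, c, cb, logdetM, XtViX, beta, rss, dZtX

    def nll_grad(self, gamma):
        try:
            sq, c, cb, logdetM, XtViX, beta, rss, dZtX = self._core(gamma)
        except np.linalg.LinAlgError:
            return np.inf, np.zeros(len(self.names))
        if rss <= 0 or not np.isfinite(rss):
            return np.inf, np.zeros(len(self.names))
        n, p = self.n, self.p
        dof = n - p if self.reml else n

        # d log|V*| / dgamma_k = tr(V*^-1 Z_k Z_k')
        S = sq[:, None] * self.ZtZ
        W = cho_solve(c, S, check_finite=False)
        # d rss / dgamma_k = -|Z_k' e|^2 with e = V*^-1 (y - X beta)
        Zr = self.Zty - self.ZtX @ beta
        Ze = Zr - S.T @ cho_solve(c, sq * Zr, check_finite=False)
        grad = np.empty(len(self.names))
        if self.reml:
            G = self.ZtX.T - dZtX.T @ W  # X' V*^-1 Z, p x q
            H = cho_solve(cb, G, check_finite=False)
        for i, blk in enumerate(self.blocks):
            tr_k = float(np.sum(np.diag(self.ZtZ)[blk])) - float(
                np.sum(S[:, blk] * W[:, blk])
            )
            drss_k = -float(np.sum(Ze[blk] ** 2))
            g = dof * drss_k / rss + tr_k
            if self.reml:
                g -= float(np.sum(G[:, blk] * H[:, blk]))
            grad[i] = 0.5 * g

        sigma2 = rss / dof
        nll = 0.5 * (dof * np.log(2 * np.pi * sigma2) + logdetM + dof)
        if self.reml:
            nll += 0.5 * 2.0 * float(np.sum(np.log(np.diag(cb[0]))))
        return nll, grad

    def nll(self, gamma):
        return self.nll_grad(gamma)[0]

    def finish(self, gamma):
        _, _, cb, _, XtViX, beta, rss, _ = self._core(gamma)
        dof = self.n - self.p if self.reml else self.n
        sigma2 = float(rss / dof)
        cov = sigma2 * cho_solve(cb, np.eye(self.p), check_finite=False)
        se = np.sqrt(np.diag(cov))
        return beta, se, sigma2


def fit_lmm(
    data: pd.DataFrame,
    spec: ModelSpec,
    start: np.ndarray | None = None,
) -> FitResult:
    """Fit the LMM by profiled ML (or REML).

    Variance components may be estimated exactly at the zero boundary; such
    fits are kept and the affected terms reported in ``boundary``.
    Non-convergence is flagged on the result, never silent.  The fit is
    deterministic given data and spec.  ``start`` optionally warm-starts the
    optimizer with sigma_k/sigma_e ratios (e.g. from a nested fit).
    """
    spec.validate()
    y, X, names, factors = _design(data, spec)
    if not factors:
        beta, rss, *_ = np.linalg.lstsq(X, y, rcond=None)
        n, p = X.shape
        sigma2 = float(rss[0] / n) if len(rss) else float(np.sum((y - X @ beta) ** 2) / n)
        ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + n)
        se = np.sqrt(sigma2 * np.diag(np.linalg.inv(X.T @ X)))
        return FitResult(spec, pd.Series(beta, index=names), pd.Series(se, index=names),
                         {"resid": sigma2}, ll, n, True)

    prof = _Profile(y, X, factors, spec.reml)
    k = len(prof.names)
    x0 = np.full(k, 0.1) if start is None else np.maximum(np.asarray(start, float), 0.0)
    res = minimize(
        prof.nll_grad, x0, jac=True, method="L-BFGS-B",
        bounds=[(0.0, 2500.0)] * k,
        options={"ftol": 1e-13, "gtol": 1e-8, "maxiter": 500},
    )
    # L-BFGS-B can stop with an "abnormal" line search right at the optimum
    # (tight ftol); a small projected gradient still certifies convergence.
    def _ok(r):
        if not (np.isfinite(r.fun) and hasattr(r, "jac")):
            return False
        pg = np.where((r.x <= 1e-12) & (r.jac > 0), 0.0, r.jac)
        return r.success or float(np.max(np.abs(pg))) < 1e-3

    if not _ok(res):
        # Rescue with a simplex pass; the profiled surface can be flat near
        # zero-variance corners.
        res2 = minimize(prof.nll, res.x if np.isfinite(res.fun) else x0,
                        method="Nelder-Mead",
                        options={"xatol": 1e-9, "fatol": 1e-10, "maxiter": 1000})
        if res2.fun <= res.fun or not np.isfinite(res.fun):
            res = res2
        converged_flag = np.isfinite(res.fun)
    else:
        converged_flag = True
    gamma_hat = np.maximum(res.x, 0.0)
    converged = bool(converged_flag)
    beta, se, sigma2 = prof.finish(gamma_hat)
    varcomps = {nm: float(sigma2 * g) for nm, g in zip(prof.names, gamma_hat)}
    varcomps["resid"] = sigma2
    boundary = tuple(nm for nm, g in zip(prof.names, gamma_hat) if g < 1e-12)
    if not converged:
        warnings.warn("LMM fit did not converge", RuntimeWarning)
    return FitResult(
        spec,
        pd.Series(beta, index=names),
        pd.Series(se, index=names),
        varcomps,
        float(-res.fun),
        prof.n,
        converged,
        boundary,
        _ratios=gamma_hat,
    )


def lrt(full: FitResult, reduced: FitResult) -> LRTResult:
    """Likelihood-ratio test of nested fixed-effect structures.

    chisq = 2 (loglik_full - loglik_reduced) clipped at zero; df is the
    difference in fixed-effect parameter counts; p from the upper tail of
    chi-square(df).  Both fits must be ML on the same data with the same
    random terms.
    """
    if full.spec.reml or reduced.spec.reml:
        raise UsageError("LRT on fixed effects requires ML fits")
    if full.n_obs != reduced.n_obs:
        raise UsageError("LRT requires fits on the same data")
    if full.spec.random != reduced.spec.random:
        raise UsageError("LRT requires identical random-effect structures")
    if not set(reduced.spec.fixed) <= set(full.spec.fixed):
        raise UsageError("reduced model terms must nest within the full model")
    df = full.n_fixed - reduced.n_fixed
    tested = ",".join(sorted(set(full.spec.fixed) - set(reduced.spec.fixed))) or "(none)"
    if df == 0:
        return LRTResult(0.0, 0, 1.0, tested, full, reduced)
    chisq = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    return LRTResult(chisq, df, float(chi2.sf(chisq, df)), tested, full, reduced)


def test_parental_age(
    data: pd.DataFrame,
    which: str = "pac",
    order: str = "linear",
    lamb_mode: bool = False,
) -> LRTResult:
    """LRT for a MAC or PAC effect on RTL against the base model.

    ``order='linear'`` adds the centred parental-age covariate (1 df);
    ``order='quadratic'`` adds the centred term and its square jointly
    (2 df).  ``lamb_mode`` uses the reduced base model (year + sex) for
    same-age lamb subsets.  Both models are fitted by ML; the reduced fit's
    variance ratios warm-start the full fit.
    """
    which = which.lower()
    if which not in ("mac", "pac"):
        raise UsageError(f"which must be 'mac' or 'pac', got {which!r}")
    if order not in ("linear", "quadratic"):
        raise UsageError(f"order must be 'linear' or 'quadratic', got {order!r}")
    base_terms = LAMB_FIXED_TERMS if lamb_mode else BASE_FIXED_TERMS
    add = (which,) if order == "linear" else (which, f"{which}2")
    base = ModelSpec(fixed=base_terms, lamb_mode=lamb_mode)
    full = ModelSpec(fixed=base_terms + add, lamb_mode=lamb_mode)
    fit0 = fit_lmm(data, base)
    fit1 = fit_lmm(data, full, start=fit0._ratios)
    out = lrt(fit1, fit0)
    out.term_tested = f"{which}:{order}"
    return out


def variance_proportions(fit: FitResult, include_residual: bool = False) -> pd.Series:
    """Share of each random term in the random-effects variance component.

    By default the residual is excluded, i.e. each random intercept variance
    is divided by the sum over the random intercepts only; with
    ``include_residual=True`` shares of the total (random + residual)
    variance are reported instead.
    """
    if not fit.converged:
        raise UsageError("variance_proportions requires a converged fit")
    comps = {k: v for k, v in fit.varcomps.items() if include_residual or k != "resid"}
    total = sum(comps.values())
    if total <= 0:
        return pd.Series(dtype=float, name="proportion")
    return pd.Series({k: v / total for k, v in comps.items()}, name="proportion")
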