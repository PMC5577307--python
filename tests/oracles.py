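"""Independent oracles used by the tests.

These deliberately avoid the package's own linear-algebra shortcuts: the
mixed-model likelihood is evaluated through the dense n x n marginal
covariance matrix and maximised with a generic simplex optimizer, and the
variance components are alternatively estimated by one-way method-of-moments
ANOVA per grouping factor.
"""

import numpy as np
import pandas as pd
from scipy.optimize import minimize


def build_base_design(df: pd.DataFrame) -> np.ndarray:
    """Intercept + year dummy + age + sex dummy + age x sex, built from
    scratch (independently of the package's design-matrix code)."""
    year = np.sort(df["year"].unique())
    sexlv = np.sort(df["sex"].unique())
    yd = (df["year"].to_numpy() == year[-1]).astype(float)
    sd = (df["sex"].to_numpy() == sexlv[-1]).astype(float)
    age = df["age"].to_numpy(dtype=float)
    return np.column_stack([np.ones(len(df)), yd, age, sd, age * sd])


def dense_ml_loglik(df: pd.DataFrame, X: np.ndarray | None = None) -> float:
    """Maximised Gaussian ML log-likelihood of the crossed random-intercept
    model, via the explicit n x n covariance matrix.

    beta is profiled out by GLS; the four log-variances are maximised with
    Nelder-Mead.  Only feasible for small n.
    """
    y = df["rtl"].to_numpy(dtype=float)
    n = len(y)
    X = build_base_design(df) if X is None else X
    ZZt = []
    for col in ("mother_id", "father_id", "plate_id"):
        Z = pd.get_dummies(df[col]).to_numpy(dtype=float)
        ZZt.append(Z @ Z.T)

    def negll(logvar):
        v = np.exp(logvar)
        V = v[3] * np.eye(n)
        for k in range(3):
            V += v[k] * ZZt[k]
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return np.inf
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        Vi_y = np.linalg.solve(V, y)
        Vi_X = np.linalg.solve(V, X)
        beta = np.linalg.solve(X.T @ Vi_X, X.T @ Vi_y)
        r = y - X @ beta
        quad = float(r @ np.linalg.solve(V, r))
        return 0.5 * (n * np.log(2 * np.pi) + logdet + quad)

    s2 = np.var(y)
    best = None
    for start in ([s2 / 10, s2 / 10, s2 / 10, s2], [s2 / 3, s2 / 3, s2 / 3, s2 / 3]):
        res = minimize(
            negll,
            np.log(start),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 5000, "maxfev": 5000},
        )
        if best is None or res.fun < best:
            best = res.fun
    return -best


def mom_variance(df: pd.DataFrame, col: str, response: str = "rtl") -> float:
    """One-way ANOVA method-of-moments variance for one grouping factor.

    Other independently assigned crossed random effects inflate the between-
    and within-group mean squares equally in expectation, so they cancel in
    MS_between - MS_within.
    """
    g = df.groupby(col)[response]
    N, J = len(df), g.ngroups
    nj = g.size().to_numpy()
    grand = df[response].mean()
    msb = float((nj * (g.mean().to_numpy() - grand) ** 2).sum()) / (J - 1)
    msw = float(((df[response] - g.transform("mean")) ** 2).sum()) / (N - J)
    n0 = (N - (nj**2).sum() / N) / (J - 1)
    return (msb - msw) / n0
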