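"""Independent oracles used by the test suite.

These deliberately avoid the package's own fitting code paths: the
Poisson deviance oracle maximizes the likelihood with a generic
second-order optimizer, and the curvature oracle detrends generating
effect vectors with plain least squares.
"""
import numpy as np
from scipy.optimize import minimize


def brute_force_deviance(X, deaths, person_years):
    """Poisson GLM deviance via direct likelihood maximization."""
    d = np.asarray(deaths, float).ravel()
    off = np.log(np.asarray(person_years, float).ravel())

    def nll(b):
        eta = off + X @ b
        return np.exp(eta).sum() - d @ eta

    def grad(b):
        return X.T @ (np.exp(off + X @ b) - d)

    def hess(b):
        return (X * np.exp(off + X @ b)[:, None]).T @ X

    res = minimize(
        nll, np.zeros(X.shape[1]), jac=grad, hess=hess,
        method="trust-exact", tol=1e-14, options={"gtol": 1e-12},
    )
    mu = np.exp(off + X @ res.x)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(d > 0, d * np.log(d / mu), 0.0)
    return float(2.0 * np.sum(term - (d - mu)))


def generating_curvature(effects, ref_idx):
    """Estimable curvature of a generating effect vector.

    Remove the least-squares linear trend over the equally spaced level
    indices, then shift so the reference level is zero: the component of
    the effects that any trend reallocation leaves untouched.
    """
    v = np.asarray(effects, float)
    x = np.arange(len(v)) - (len(v) - 1) / 2.0
    slope = float(x @ v / (x @ x))
    c = v - slope * x
    return c - c[ref_idx]
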