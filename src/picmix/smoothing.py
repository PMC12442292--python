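"""Univariate smoothers: a penalized-spline GAM and a lowess wrapper.

The GAM contract used throughout the package is a Gaussian additive model
``y = beta0 + f(x) + eps`` with a cubic B-spline basis of dimension 10 and the
smoothing penalty chosen by generalized cross-validation.  Predictions outside
the training range of the predictor are clamped to the boundary fitted values
(the spline has no support there and linear extrapolation of a wiggly basis is
not meaningful for bias curves).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from statsmodels.gam.api import BSplines, GLMGam
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess


@dataclass
class GamFit:
    """A fitted univariate smooth: evaluate with :meth:`predict`.

    Attributes
    ----------
    grid, fitted
        Evaluation grid over the training range and the fitted values on it.
    x_min, x_max
        Training range; predictions are clamped to it.
    intercept
        The model's constant term.
    sigma
        Residual standard deviation.
    """

    grid: np.ndarray
    fitted: np.ndarray
    x_min: float
    x_max: float
    intercept: float
    sigma: float

    def predict(self, x) -> np.ndarray:
        x = np.clip(np.asarray(x, dtype=float), self.x_min, self.x_max)
        return np.interp(x, self.grid, self.fitted)

    @property
    def amplitude(self) -> float:
        """max - min of the fitted curve over the training range."""
        return float(np.max(self.fitted) - np.min(self.fitted))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"grid": self.grid, "fitted": self.fitted})


def fit_gam(
    x: np.ndarray,
    y: np.ndarray,
    basis_dim: int = 10,
    grid_size: int = 200,
) -> GamFit:
    """Fit ``y = beta0 + f(x) + eps`` with a penalized cubic B-spline.

    The smoothing parameter is selected by generalized cross-validation on a
    log-spaced candidate grid.  Degenerate inputs (fewer distinct x values
    than the basis needs) fall back to a smaller basis, and ultimately to the
    sample mean.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 5 or np.unique(x).size < 4:
        mean = float(np.mean(y)) if y.size else 0.0
        g = np.linspace(x.min() if x.size else 0.0, x.max() if x.size else 1.0, 2)
        return GamFit(g, np.full(2, mean), g[0], g[-1], mean, float(np.std(y)) if y.size else 0.0)

    df = min(basis_dim, max(4, np.unique(x).size - 1))
    spline = BSplines(x[:, None], df=[df], degree=[3])
    gam = GLMGam(y, exog=np.ones((x.size, 1)), smoother=spline, alpha=[1.0])
    # GCV over a log-spaced alpha grid
    alphas = np.logspace(-4, 6, 11)
    best_alpha, best_gcv = 1.0, np.inf
    for a in alphas:
        try:
            res = GLMGam(
                y, exog=np.ones((x.size, 1)), smoother=spline, alpha=[a]
            ).fit()
            edf = float(np.sum(res.edf)) if hasattr(res, "edf") else df
            rss = float(np.sum(res.resid_response**2))
            n = x.size
            denom = max(n - edf, 1e-8)
            gcv = n * rss / denom**2
            if np.isfinite(gcv) and gcv < best_gcv:
                best_gcv, best_alpha = gcv, a
        except Exception:  # singular fits at extreme alphas
            continue
    try:
        res = GLMGam(
            y, exog=np.ones((x.size, 1)), smoother=spline, alpha=[best_alpha]
        ).fit()
    except Exception:
        # degenerate response (e.g. constant y): fall back to the flat fit
        mean = float(np.mean(y))
        g = np.linspace(x.min(), x.max(), 2)
        return GamFit(g, np.full(2, mean), g[0], g[-1], mean,
                      float(np.std(y, ddof=1)) if y.size > 1 else 0.0)

    # evaluate strictly inside the knot range (the basis is undefined outside)
    span = float(x.max() - x.min())
    eps = 1e-9 * max(span, 1.0)
    grid = np.linspace(x.min() + eps, x.max() - eps, grid_size)
    basis_grid = spline.transform(grid[:, None])
    fitted = res.params[0] + basis_grid @ res.params[1:]
    sigma = float(np.std(res.resid_response, ddof=1))
    return GamFit(
        grid=grid,
        fitted=np.asarray(fitted),
        x_min=float(x.min()),
        x_max=float(x.max()),
        intercept=float(res.params[0]),
        sigma=sigma,
    )


def lowess_curve(
    x: np.ndarray,
    y: np.ndarray,
    frac: float = 2.0 / 3.0,
    it: int = 3,
    grid_size: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Local linear regression of y on x (span ``frac``, ``it`` robustness
    iterations), evaluated on an even grid over the training range."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    fitted = _sm_lowess(y, x, frac=frac, it=it, return_sorted=True)
    grid = np.linspace(x.min(), x.max(), grid_size)
    return grid, np.interp(grid, fitted[:, 0], fitted[:, 1])
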