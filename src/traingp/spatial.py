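"""Per-trial spatial adjustment with a separable AR1 x AR1 residual model.

The single-trial model is

    y = mu + u_line + s + n,    u ~ iid(0, sg2),  s ~ N(0, ss2 * R),  n ~ iid(0, sn2)

with R the Kronecker AR1(rho_row) x AR1(rho_col) correlation restricted to
the observed plots. Restricted maximum likelihood is maximized by a coarse
grid over (rho_row, rho_col) followed by Nelder-Mead refinement, with the
nugget scale profiled out analytically at every candidate. Adjusted plot
values are the raw values minus the predicted spatial component, so the
genetic signal stays in the data handed downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize, minimize_scalar

__all__ = ["SpatialFit", "fit_ar1ar1", "adjust_all_trials", "trial_summary"]

_RHO_BOUND = 0.95


@dataclass
class SpatialFit:
    trial: str
    rho_row: float
    rho_col: float
    spatial_var: float
    nugget_var: float
    genotype_var: float
    loglik: float
    converged: bool
    message: str
    adjusted: pd.DataFrame  # plot table plus 'trend' and 'adjusted' columns
    line_means: pd.Series  # adjusted mean per line
    raw_line_means: pd.Series

    def __post_init__(self) -> None:
        for name in ("spatial_var", "nugget_var", "genotype_var"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _ar1(n: int, rho: float) -> np.ndarray:
    return rho ** np.abs(np.subtract.outer(np.arange(n), np.arange(n)))


class _DenseREML:
    """REML pieces for arbitrary observed plots (missing cells, genotype effect)."""

    def __init__(self, rows, cols, line_idx, y, genotype_effect: bool):
        self.dr = np.abs(np.subtract.outer(rows, rows)).astype(float)
        self.dc = np.abs(np.subtract.outer(cols, cols)).astype(float)
        self.zz = (line_idx[:, None] == line_idx[None, :]).astype(float)
        self.y = y
        self.n = y.size
        self.genotype_effect = genotype_effect

    def corr(self, rho_r: float, rho_c: float) -> np.ndarray:
        return np.power(rho_r, self.dr) * np.power(rho_c, self.dc)

    def nll(self, rho_r, rho_c, g_s, g_g) -> float:
        c = g_s * self.corr(rho_r, rho_c) + np.eye(self.n)
        if self.genotype_effect:
            c += g_g * self.zz
        try:
            cf = cho_factor(c, lower=True)
        except np.linalg.LinAlgError:
            return np.inf
        logdet = 2.0 * np.log(np.diag(cf[0])).sum()
        ciy = cho_solve(cf, self.y)
        one = np.ones(self.n)
        cix = cho_solve(cf, one)
        xcx = one @ cix
        ypy = self.y @ ciy - (one @ ciy) ** 2 / xcx
        if ypy <= 0 or xcx <= 0:
            return np.inf
        s2 = ypy / (self.n - 1)
        return 0.5 * ((self.n - 1) * (np.log(s2) + 1.0) + logdet + np.log(xcx))

    def finish(self, rho_r, rho_c, g_s, g_g):
        """Variance estimates, log-REML and the spatial-trend BLUP at a point."""
        r = g_s * self.corr(rho_r, rho_c)
        c = r + np.eye(self.n)
        if self.genotype_effect:
            c += g_g * self.zz
        cf = cho_factor(c, lower=True)
        one = np.ones(self.n)
        mu = (one @ cho_solve(cf, self.y)) / (one @ cho_solve(cf, one))
        resid = self.y - mu
        trend = r @ cho_solve(cf, resid)
        ciy = cho_solve(cf, self.y)
        cix = cho_solve(cf, one)
        ypy = self.y @ ciy - (one @ ciy) ** 2 / (one @ cix)
        s2 = max(ypy / (self.n - 1), 0.0)
        return s2, trend, -self.nll(rho_r, rho_c, g_s, g_g)


class _GridREML:
    """Fast eigen-decomposition path: complete grid, no genotype effect."""

    def __init__(self, y_grid: np.ndarray):
        self.yg = y_grid
        self.n = y_grid.size

    def _pieces(self, rho_r, rho_c):
        nr, nc = self.yg.shape
        wr, qr = np.linalg.eigh(_ar1(nr, rho_r))
        wc, qc = np.linalg.eigh(_ar1(nc, rho_c))
        lam = np.outer(wr, wc)
        yt = qr.T @ self.yg @ qc
        xt = np.outer(qr.T @ np.ones(nr), qc.T @ np.ones(nc))
        return lam, yt, xt, qr, qc

    def profile_nll(self, rho_r, rho_c):
        """Profile the spatial-to-nugget ratio out with a 1-D bounded search."""
        lam, yt, xt, _, _ = self._pieces(rho_r, rho_c)

        def nll_of(log_gs):
            d = np.exp(log_gs) * lam + 1.0
            xcx = (xt**2 / d).sum()
            ypy = (yt**2 / d).sum() - ((xt * yt / d).sum()) ** 2 / xcx
            if ypy <= 0 or xcx <= 0:
                return np.inf
            s2 = ypy / (self.n - 1)
            return 0.5 * ((self.n - 1) * (np.log(s2) + 1.0) + np.log(d).sum() + np.log(xcx))

        res = minimize_scalar(nll_of, bounds=(-12.0, 12.0), method="bounded")
        return res.fun, float(np.exp(res.x))

    def nll_nospatial(self) -> float:
        lam, yt, xt, _, _ = self._pieces(0.0, 0.0)
        xcx = (xt**2).sum()
        ypy = (yt**2).sum() - ((xt * yt).sum()) ** 2 / xcx
        s2 = ypy / (self.n - 1)
        return 0.5 * ((self.n - 1) * (np.log(s2) + 1.0) + np.log(xcx))

    def finish(self, rho_r, rho_c, g_s):
        lam, yt, xt, qr, qc = self._pieces(rho_r, rho_c)
        d = g_s * lam + 1.0
        mu = ((xt * yt / d).sum()) / ((xt**2 / d).sum())
        rt = yt - mu * xt
        trend_grid = qr @ (g_s * lam * rt / d) @ qc.T
        xcx = (xt**2 / d).sum()
        ypy = (yt**2 / d).sum() - ((xt * yt / d).sum()) ** 2 / xcx
        s2 = max(ypy / (self.n - 1), 0.0)
        nll, _ = self.profile_nll(rho_r, rho_c)
        return s2, trend_grid, -nll


def fit_ar1ar1(
    plots: pd.DataFrame,
    value_col: str = "yield",
    genotype_effect: bool = True,
    include_checks: bool = True,
    max_iter: int = 200,
    tol: float = 1e-6,
    lrt_threshold: float = 5.0,
) -> SpatialFit:
    """Fit one trial's AR1 x AR1 spatial model and return adjusted values.

    ``plots`` holds one trial's records with columns ``trial``, ``row``,
    ``col``, ``line`` and ``value_col``. Non-convergence is flagged on the
    result rather than raised; a single observed row (or column) degrades to
    a one-dimensional AR1 fit with a warning. The spatial component is kept
    only when it improves the restricted log-likelihood over a pure-nugget
    model by more than ``lrt_threshold`` — near rho = 0 the two are not
    identifiable and "removing" the trend would strip iid noise (and genetic
    signal) from the data.
    """
    df = plots.copy()
    if df["trial"].nunique() != 1:
        raise ValueError("fit_ar1ar1 expects records for exactly one trial")
    if not include_checks and "is_check" in df.columns:
        df = df.loc[~df["is_check"]].copy()
    trial = str(df["trial"].iloc[0])
    rows = df["row"].to_numpy(int)
    cols = df["col"].to_numpy(int)
    y = df[value_col].to_numpy(float)
    n_rows = len(np.unique(rows))
    n_cols = len(np.unique(cols))
    fix_row = n_rows < 2
    fix_col = n_cols < 2
    if fix_row or fix_col:
        warnings.warn(
            f"trial {trial}: single observed {'row' if fix_row else 'column'}; "
            "fitting a one-dimensional AR1 only",
            stacklevel=2,
        )

    line_codes = pd.factorize(df["line"])[0]
    full_grid = (
        len(df) == (rows.max() + 1) * (cols.max() + 1)
        and len(df) == len(set(zip(rows, cols)))
    )

    coarse = np.array([-0.6, -0.3, 0.0, 0.3, 0.6])
    rr_cands = np.array([0.0]) if fix_row else coarse
    rc_cands = np.array([0.0]) if fix_col else coarse

    if full_grid and not genotype_effect:
        grid = np.zeros((rows.max() + 1, cols.max() + 1))
        grid[rows, cols] = y
        engine = _GridREML(grid)
        best = (np.inf, 0.0, 0.0)
        for rr in rr_cands:
            for rc in rc_cands:
                val, _ = engine.profile_nll(rr, rc)
                if val < best[0]:
                    best = (val, rr, rc)

        def unpack_rho(t):
            vals = iter(t)
            ar = _RHO_BOUND * np.tanh(next(vals)) if not fix_row else 0.0
            ac = _RHO_BOUND * np.tanh(next(vals)) if not fix_col else 0.0
            return ar, ac

        t0 = []
        if not fix_row:
            t0.append(np.arctanh(np.clip(best[1] / _RHO_BOUND, -0.999, 0.999)))
        if not fix_col:
            t0.append(np.arctanh(np.clip(best[2] / _RHO_BOUND, -0.999, 0.999)))
        converged = True
        if t0:
            res = minimize(
                lambda t: engine.profile_nll(*unpack_rho(t))[0],
                np.array(t0),
                method="Nelder-Mead",
                options={"maxiter": max_iter, "fatol": tol, "xatol": 1e-4},
            )
            converged = bool(res.success)
            if res.fun < best[0]:
                rr, rc = unpack_rho(res.x)
                best = (res.fun, rr, rc)
        _, rho_r, rho_c = best
        _, g_s = engine.profile_nll(rho_r, rho_c)
        # keep the spatial term only when it clearly beats a pure-nugget fit:
        # at rho ~ 0 the two are unidentifiable and trend removal would strip
        # shrunken iid noise (and genetic signal) from the data
        if engine.nll_nospatial() - best[0] < lrt_threshold:
            rho_r = rho_c = 0.0
            g_s = 0.0
            s2, trend_grid, loglik = engine.finish(0.0, 0.0, 0.0)
        else:
            s2, trend_grid, loglik = engine.finish(rho_r, rho_c, g_s)
        trend = trend_grid[rows, cols]
        g_g = 0.0
    else:
        engine = _DenseREML(rows, cols, line_codes, y, genotype_effect)
        g0 = (0.5, 0.5 if genotype_effect else 0.0)
        best = (np.inf, 0.0, 0.0)
        for rr in rr_cands:
            for rc in rc_cands:
                val = engine.nll(rr, rc, *g0)
                if val < best[0]:
                    best = (val, rr, rc)

        def unpack(t):
            i = 0
            ar = ac = 0.0
            if not fix_row:
                ar = _RHO_BOUND * np.tanh(t[i]); i += 1
            if not fix_col:
                ac = _RHO_BOUND * np.tanh(t[i]); i += 1
            gs = np.exp(t[i]); i += 1
            gg = np.exp(t[i]) if genotype_effect else 0.0
            return ar, ac, gs, gg

        t0 = []
        if not fix_row:
            t0.append(np.arctanh(np.clip(best[1] / _RHO_BOUND, -0.999, 0.999)))
        if not fix_col:
            t0.append(np.arctanh(np.clip(best[2] / _RHO_BOUND, -0.999, 0.999)))
        t0.append(np.log(g0[0]))
        if genotype_effect:
            t0.append(np.log(max(g0[1], 1e-3)))
        res = minimize(
            lambda t: engine.nll(*unpack(t)),
            np.array(t0),
            method="Nelder-Mead",
            options={"maxiter": max(max_iter, 100 * len(t0)), "fatol": tol, "xatol": 1e-4},
        )
        converged = bool(res.success)
        start_val = engine.nll(*unpack(np.array(t0)))
        if res.fun <= start_val:
            rho_r, rho_c, g_s, g_g = unpack(res.x)
            fit_val = res.fun
        else:  # keep the best coarse candidate
            rho_r, rho_c, g_s, g_g = best[1], best[2], g0[0], g0[1]
            fit_val = engine.nll(rho_r, rho_c, g_s, g_g)
        # same tie-break as the fast path: drop an unidentified spatial term
        if genotype_effect:
            res0 = minimize_scalar(
                lambda lg: engine.nll(0.0, 0.0, 0.0, np.exp(lg)), bounds=(-12, 12), method="bounded"
            )
            nll0, gg0 = res0.fun, float(np.exp(res0.x))
        else:
            nll0, gg0 = engine.nll(0.0, 0.0, 0.0, 0.0), 0.0
        if nll0 - fit_val < lrt_threshold:
            rho_r = rho_c = 0.0
            g_s, g_g = 0.0, gg0
        s2, trend, loglik = engine.finish(rho_r, rho_c, g_s, g_g)

    out = df.copy()
    out["trend"] = trend
    out["adjusted"] = out[value_col] - out["trend"]
    line_means = out.groupby("line")["adjusted"].mean()
    raw_means = out.groupby("line")[value_col].mean()
    return SpatialFit(
        trial=trial,
        rho_row=float(rho_r),
        rho_col=float(rho_c),
        spatial_var=float(g_s * s2),
        nugget_var=float(s2),
        genotype_var=float(g_g * s2),
        loglik=float(loglik),
        converged=converged,
        message="" if converged else "optimizer did not converge; best-found parameters returned",
        adjusted=out,
        line_means=line_means,
        raw_line_means=raw_means,
    )


def adjust_all_trials(plots: pd.DataFrame, value_col: str = "yield", **kwargs):
    """Fit every trial separately; returns (fits, combined adjusted table)."""
    fits = [
        fit_ar1ar1(plots.loc[plots["trial"] == t], value_col=value_col, **kwargs)
        for t in dict.fromkeys(plots["trial"])
    ]
    combined = pd.concat([f.adjusted for f in fits], ignore_index=True)
    return fits, combined


def trial_summary(fit: SpatialFit) -> pd.Series:
    """One Table-2-style summary row: n lines, mean, CV%, raw-vs-adjusted r."""
    m = fit.line_means
    mean = float(m.mean())
    cv = 100.0 * float(m.std(ddof=1)) / mean if mean != 0 else np.nan
    raw = fit.raw_line_means.loc[m.index]
    corr = float(np.corrcoef(raw, m)[0, 1]) if m.size > 1 and raw.std() > 0 and m.std() > 0 else np.nan
    return pd.Series(
        {
            "trial": fit.trial,
            "n_lines": int(m.size),
            "mean": mean,
            "cv_pct": cv,
            "corr_raw_adjusted": corr,
            "rho_row": fit.rho_row,
            "rho_col": fit.rho_col,
            "spatial_var": fit.spatial_var,
            "nugget_var": fit.nugget_var,
        }
    )
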