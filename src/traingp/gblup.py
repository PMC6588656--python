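"""GBLUP: AI-REML variance components, line predictions, heritability.

Model on the training lines' BLUEs:

    y = mu + g + e,   g ~ N(0, G sg2),   e ~ N(0, I se2)

Average-information updates with an EM-REML fallback whenever an AI step
would drive a component negative or lower the restricted likelihood.
Convergence follows the normalized-component rule: the algorithm stops when
the largest absolute change in sg2/(sg2+se2), se2/(sg2+se2) drops below
1e-5. Unphenotyped lines are predicted either through the mixed-model
equations or the equivalent conditional-mean formula.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .kinship import GRMatrix, stabilize

__all__ = [
    "VarComp",
    "fit_aireml",
    "reml_loglik",
    "predict_lines",
    "heritability",
    "plot_residual_variance",
]

_FLOOR_FRACTION = 1e-8


@dataclass
class VarComp:
    sigma_g2: float
    sigma_e2: float
    converged: bool
    n_iter: int
    loglik: float
    trace: list[tuple[float, float]] = field(default_factory=list)
    message: str = ""

    @property
    def theta(self) -> np.ndarray:
        """Components normalized to sum to one."""
        total = self.sigma_g2 + self.sigma_e2
        return np.array([self.sigma_g2, self.sigma_e2]) / total

    @property
    def total(self) -> float:
        return self.sigma_g2 + self.sigma_e2

    @property
    def h2(self) -> float:
        return self.sigma_g2 / self.total


def reml_loglik(y: np.ndarray, k: np.ndarray, sigma_g2: float, sigma_e2: float) -> float:
    """Restricted log-likelihood (constant dropped) for y = mu + g + e."""
    n = y.size
    v = sigma_g2 * k + sigma_e2 * np.eye(n)
    cf = cho_factor(v, lower=True)
    logdet = 2.0 * np.log(np.diag(cf[0])).sum()
    one = np.ones(n)
    vix = cho_solve(cf, one)
    viy = cho_solve(cf, y)
    xvx = one @ vix
    ypy = y @ viy - (one @ viy) ** 2 / xvx
    return -0.5 * (logdet + np.log(xvx) + ypy)


def _p_matrix(k: np.ndarray, sigma_g2: float, sigma_e2: float) -> np.ndarray:
    n = k.shape[0]
    v = sigma_g2 * k + sigma_e2 * np.eye(n)
    cf = cho_factor(v, lower=True)
    vi = cho_solve(cf, np.eye(n))
    vix = vi @ np.ones(n)
    return vi - np.outer(vix, vix) / vix.sum()


def fit_aireml(
    y: pd.Series,
    grm: GRMatrix,
    start: tuple[float, float] | None = None,
    max_iter: int = 100,
    tol: float = 1e-5,
) -> VarComp:
    """Estimate (sigma_g2, sigma_e2) by AI-REML on the training lines in ``y``.

    ``y`` is indexed by line id; the relationship matrix is subset to those
    rows. Components are floored at 1e-8 of the total variance instead of
    being allowed to go negative.
    """
    ids = list(y.index)
    if len(ids) < 3:
        raise ValueError("need at least 3 training lines")
    k = grm.submatrix(ids)
    yv = y.to_numpy(float)
    n = yv.size
    vary = float(np.var(yv, ddof=1))
    if vary == 0.0:
        warnings.warn("constant phenotype; returning the boundary sigma_g2 = 0", stacklevel=2)
        return VarComp(0.0, 0.0, True, 0, -np.inf, [], "constant phenotype")

    sg, se = start if start is not None else (vary / 2.0, vary / 2.0)
    floor = _FLOOR_FRACTION * (sg + se)
    ll = reml_loglik(yv, k, sg, se)
    trace = [(sg, se)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p = _p_matrix(k, sg, se)
        py = p @ yv
        kpy = k @ py
        # scores: dl/ds_i = -0.5 (tr(P V_i) - y'P V_i P y)
        score = np.array(
            [
                -0.5 * (np.sum(p * k) - py @ kpy),
                -0.5 * (np.trace(p) - py @ py),
            ]
        )
        pkpy = p @ kpy
        ppy = p @ py
        ai = 0.5 * np.array(
            [
                [kpy @ pkpy, kpy @ ppy],
                [kpy @ ppy, py @ ppy],
            ]
        )
        try:
            delta = np.linalg.solve(ai, score)
        except np.linalg.LinAlgError:
            delta = None

        took_em = False
        if delta is not None:
            cand = np.array([sg, se]) + delta
            if np.all(cand > floor):
                ll_cand = reml_loglik(yv, k, *cand)
                if np.isfinite(ll_cand) and ll_cand >= ll - 1e-10:
                    new_sg, new_se, new_ll = cand[0], cand[1], ll_cand
                else:
                    took_em = True
            else:
                took_em = True
        else:
            took_em = True
        if took_em:
            # EM-REML step: s_i += (s_i^2 / n)(y'P V_i P y - tr(P V_i))
            new_sg = sg + (sg**2 / n) * (py @ kpy - np.sum(p * k))
            new_se = se + (se**2 / n) * (py @ py - np.trace(p))
            new_sg = max(new_sg, floor)
            new_se = max(new_se, floor)
            new_ll = reml_loglik(yv, k, new_sg, new_se)

        theta_old = np.array([sg, se]) / (sg + se)
        theta_new = np.array([new_sg, new_se]) / (new_sg + new_se)
        sg, se, ll = float(new_sg), float(new_se), float(new_ll)
        floor = _FLOOR_FRACTION * (sg + se)
        trace.append((sg, se))
        if np.max(np.abs(theta_new - theta_old)) < tol:
            converged = True
            break

    return VarComp(
        sg,
        se,
        converged,
        it,
        ll,
        trace,
        "" if converged else f"no convergence in {max_iter} iterations; best-found returned",
    )


def predict_lines(
    vc: VarComp,
    y: pd.Series,
    grm: GRMatrix,
    method: str = "conditional",
    epsilon: float = 1e-6,
) -> pd.DataFrame:
    """Predicted genetic values for every line in the relationship matrix.

    ``method='conditional'`` uses g_hat = sg2 * G[:, t] V^-1 (y - mu_hat);
    ``method='mme'`` solves Henderson's mixed-model equations with G^-1.
    The two routes are algebraically identical on the same stabilized G.
    """
    if vc.sigma_g2 < 0 or vc.sigma_e2 < 0:
        raise ValueError("variance components must be non-negative")
    train_ids = list(y.index)
    gs = stabilize(grm, epsilon) if grm.epsilon == 0.0 else grm
    t_idx = gs.indexer(train_ids)
    yv = y.to_numpy(float)
    n, nl = yv.size, len(gs.ids)
    g_all = gs.matrix

    if method == "conditional":
        ktt = g_all[np.ix_(t_idx, t_idx)]
        v = vc.sigma_g2 * ktt + vc.sigma_e2 * np.eye(n)
        cf = cho_factor(v, lower=True)
        one = np.ones(n)
        mu = (one @ cho_solve(cf, yv)) / (one @ cho_solve(cf, one))
        ghat = vc.sigma_g2 * (g_all[:, t_idx] @ cho_solve(cf, yv - mu))
    elif method == "mme":
        if vc.sigma_g2 <= 0:
            mu = float(yv.mean())
            ghat = np.zeros(nl)
        else:
            lam = vc.sigma_e2 / vc.sigma_g2
            ginv = np.linalg.inv(g_all)
            z = np.zeros((n, nl))
            z[np.arange(n), t_idx] = 1.0
            lhs = np.zeros((1 + nl, 1 + nl))
            lhs[0, 0] = n
            lhs[0, 1:] = z.sum(axis=0)
            lhs[1:, 0] = z.sum(axis=0)
            lhs[1:, 1:] = z.T @ z + lam * ginv
            rhs = np.concatenate([[yv.sum()], z.T @ yv])
            sol = np.linalg.solve(lhs, rhs)
            mu, ghat = float(sol[0]), sol[1:]
    else:
        raise ValueError(f"unknown prediction method {method!r}")

    in_training = np.isin(np.arange(nl), t_idx)
    return pd.DataFrame(
        {"line": list(gs.ids), "ghat": ghat, "in_training": in_training, "mu": float(mu)}
    )


def line_scale_genetic_variance(vc: VarComp, grm: GRMatrix) -> float:
    """Genomic variance on the line scale: sigma_g2 times mean(diag(G)).

    The REML sigma_g2 is the variance of a hypothetical line with unit
    self-relationship; in inbred, family-structured panels the mean diagonal
    of the VanRaden G sits well above 1, so the average line's genetic
    variance is sigma_g2 scaled by it.
    """
    return vc.sigma_g2 * float(np.mean(np.diag(grm.matrix)) - grm.epsilon)


def heritability(sigma_g2: float, v: float, n) -> float:
    """Line heritability sg2 / (sg2 + v/n), v the per-plot residual variance.

    ``n`` may be a scalar or a per-line array of location counts, in which
    case the mean of the per-line ratios is returned.
    """
    if sigma_g2 < 0 or v < 0:
        raise ValueError("variance inputs must be non-negative")
    n_arr = np.asarray(n, dtype=float)
    if np.any(n_arr < 1):
        raise ValueError("location counts must be >= 1")
    if sigma_g2 == 0 and v == 0:
        return np.nan
    return float(np.mean(sigma_g2 / (sigma_g2 + v / n_arr)))


def plot_residual_variance(
    plots: pd.DataFrame | None = None,
    spatial_fits=None,
    value_col: str = "yield",
    method: str = "anova",
) -> float:
    """Per-plot residual variance v for the heritability formula.

    ``method='anova'``: pooled residual mean square of plot values after
    removing trial and line means (computed from the raw plot table).
    ``method='spatial_fits'``: plot-count-weighted sum of spatial + nugget
    variance across the per-trial spatial fits.
    """
    if method == "anova":
        if plots is None:
            raise ValueError("anova method needs the plot table")
        df = plots.copy()
        t_codes = pd.factorize(df["trial"])[0]
        l_codes = pd.factorize(df["line"])[0]
        nt = t_codes.max() + 1
        nl = l_codes.max() + 1
        y = df[value_col].to_numpy(float)
        # exact residual MSE of the two-way trial + line fixed-effects fit
        n_eff = nt + nl
        a = np.zeros((n_eff + 1, n_eff + 1))
        rhs = np.zeros(n_eff + 1)
        np.add.at(a, (t_codes, t_codes), 1.0)
        np.add.at(a, (nt + l_codes, nt + l_codes), 1.0)
        np.add.at(a, (t_codes, nt + l_codes), 1.0)
        np.add.at(a, (nt + l_codes, t_codes), 1.0)
        a[nt:n_eff, n_eff] = 1.0
        a[n_eff, nt:n_eff] = 1.0
        np.add.at(rhs, t_codes, y)
        np.add.at(rhs, nt + l_codes, y)
        sol = np.linalg.solve(a, rhs)
        fitted = sol[t_codes] + sol[nt + l_codes]
        dof = y.size - nt - nl + 1
        if dof <= 0:
            raise ValueError("not enough replication to estimate a plot residual variance")
        return float(((y - fitted) ** 2).sum() / dof)
    if method == "spatial_fits":
        if not spatial_fits:
            raise ValueError("spatial_fits method needs the per-trial fits")
        weights = np.array([len(f.adjusted) for f in spatial_fits], dtype=float)
        v = np.array([f.spatial_var + f.nugget_var for f in spatial_fits])
        return float(np.average(v, weights=weights))
    raise ValueError(f"unknown method {method!r}")
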