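"""Across-trial line BLUEs from spatially adjusted plot values.

Fixed-effects model: adjusted value = trial mean + line effect + residual,
with line effects constrained to sum to zero; reported BLUEs are the grand
mean plus the line effect, so differences between lines are estimable and
unaffected by per-trial constants.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["DisconnectedDesignError", "estimate_blues", "write_blues_csv"]


class DisconnectedDesignError(ValueError):
    """Trials fall into groups with no lines in common; BLUEs not comparable."""

    def __init__(self, groups: list[set[str]]):
        self.groups = groups
        desc = "; ".join("{" + ", ".join(sorted(g)) + "}" for g in groups)
        super().__init__(f"design is disconnected into trial groups: {desc}")


def _connected_components(plots: pd.DataFrame) -> list[set[str]]:
    """Components of the bipartite trial-line graph, reported as trial groups."""
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        parent.setdefault(a, a)
        parent.setdefault(b, b)
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for trial, line in zip(plots["trial"], plots["line"]):
        union(f"t:{trial}", f"l:{line}")
    groups: dict[str, set[str]] = {}
    for trial in plots["trial"].unique():
        groups.setdefault(find(f"t:{trial}"), set()).add(str(trial))
    return list(groups.values())


def estimate_blues(plots: pd.DataFrame, value_col: str = "adjusted") -> pd.DataFrame:
    """Solve the trial-mean + line-effect least-squares system exactly.

    ``plots`` needs columns ``trial``, ``line`` and ``value_col``. Returns a
    table with one row per line: ``line``, ``blue``, ``n_plots``, ``trials``.
    """
    if value_col not in plots.columns:
        raise KeyError(f"column {value_col!r} not present in the plot table")
    df = plots[["trial", "line", value_col]].dropna()
    if df.empty:
        raise ValueError("no plot records")
    groups = _connected_components(df)
    if len(groups) > 1:
        raise DisconnectedDesignError(groups)

    trials = sorted(df["trial"].astype(str).unique())
    lines = sorted(df["line"].astype(str).unique())
    t_idx = df["trial"].astype(str).map({t: i for i, t in enumerate(trials)}).to_numpy()
    l_idx = df["line"].astype(str).map({l: i for i, l in enumerate(lines)}).to_numpy()
    y = df[value_col].to_numpy(float)
    nt, nl = len(trials), len(lines)

    # bordered normal equations: [X'X  c; c' 0] [beta; lam] = [X'y; 0],
    # c the sum-to-zero constraint on line effects
    n = nt + nl
    a = np.zeros((n + 1, n + 1))
    rhs = np.zeros(n + 1)
    np.add.at(a, (t_idx, t_idx), 1.0)
    np.add.at(a, (nt + l_idx, nt + l_idx), 1.0)
    np.add.at(a, (t_idx, nt + l_idx), 1.0)
    np.add.at(a, (nt + l_idx, t_idx), 1.0)
    a[nt : nt + nl, n] = 1.0
    a[n, nt : nt + nl] = 1.0
    np.add.at(rhs, t_idx, y)
    np.add.at(rhs, nt + l_idx, y)

    try:
        sol = np.linalg.solve(a, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"normal equations singular beyond the handled confounding: {exc}")
    u = sol[nt : nt + nl]
    grand = float(y.mean())

    counts = df.groupby(df["line"].astype(str)).size()
    trial_lists = df.groupby(df["line"].astype(str))["trial"].agg(
        lambda s: ";".join(sorted(map(str, set(s))))
    )
    return pd.DataFrame(
        {
            "line": lines,
            "blue": grand + u,
            "n_plots": counts.loc[lines].to_numpy(),
            "trials": trial_lists.loc[lines].to_numpy(),
        }
    )


def write_blues_csv(blues: pd.DataFrame, path) -> None:
    blues.to_csv(path, index=False)
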