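"""Resampling designs and accuracy metrics for training-set evaluation.

Emits ``TrainingDesign`` records (disjoint training/validation line sets
with descriptors) from the generators below, runs the GBLUP machinery on
each, and scores predictions as Pearson correlations per validation cross
or pooled across all validation lines, with the accompanying Wald and
paired-t significance tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gblup import fit_aireml, predict_lines
from .kinship import GRMatrix
from .simdata import CrossDesign

__all__ = [
    "TrainingDesign",
    "accuracy",
    "tenfold_by_cross",
    "tenfold_random",
    "leave_one_cross_out",
    "mask_training_fraction",
    "crosses_by_lines_grid",
    "classify_relatedness",
    "relatedness_designs",
    "wald_significance",
    "increment_ttest",
    "top_fraction_accuracy",
    "evaluate_designs",
]


@dataclass(frozen=True)
class TrainingDesign:
    """One training/validation split plus descriptors of how it was built."""

    label: str
    replicate: int
    training: tuple[str, ...]
    validation: tuple[str, ...]
    descriptors: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.training) & set(self.validation)
        if overlap:
            raise ValueError(f"training and validation overlap: {sorted(overlap)[:5]}")
        if not self.validation:
            raise ValueError("validation set must be non-empty")


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.size < 2 or np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def accuracy(
    blues: pd.Series,
    preds: pd.Series,
    cross_of: Mapping[str, str] | None = None,
    grouping: str = "by-cross",
) -> pd.Series | float:
    """Pearson correlation of BLUEs vs predictions.

    ``grouping='by-cross'`` returns a Series indexed by cross (requires the
    line -> cross map); ``'across-all'`` pools every validation line into a
    single correlation. Zero-variance groups come back as NaN.
    """
    common = blues.index.intersection(preds.index)
    b = blues.loc[common].to_numpy(float)
    p = preds.loc[common].to_numpy(float)
    if grouping == "across-all":
        return _pearson(b, p)
    if grouping != "by-cross":
        raise ValueError(f"unknown grouping {grouping!r}")
    if cross_of is None:
        raise ValueError("by-cross accuracy needs the line -> cross map")
    crosses = pd.Series([cross_of[l] for l in common], index=common)
    out = {}
    for cid, ids in crosses.groupby(crosses).groups.items():
        out[cid] = _pearson(blues.loc[ids].to_numpy(float), preds.loc[ids].to_numpy(float))
    return pd.Series(out, name="accuracy")


def wald_significance(r: float, n: int) -> float:
    """One-sided p for H0: rho = 0 vs rho > 0 via t = r sqrt((n-2)/(1-r^2))."""
    if n < 4:
        raise ValueError("need at least 4 validation lines")
    if np.isnan(r):
        return np.nan
    if abs(r) >= 1.0:
        return 0.0 if r > 0 else 1.0
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    return float(stats.t.sf(t, df=n - 2))


def increment_ttest(acc_low: Sequence[float], acc_high: Sequence[float]) -> float:
    """Paired two-sided t test on replicate-level mean accuracies."""
    a = np.asarray(acc_low, float)
    b = np.asarray(acc_high, float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need >= 3 paired replicates")
    d = b - a
    if np.all(d == d[0]):
        if d[0] == 0:
            return 1.0
        # constant non-zero difference: zero variance, conventionally p = 0
        return 0.0
    return float(stats.ttest_rel(b, a).pvalue)


def top_fraction_accuracy(
    blues: pd.Series,
    preds: pd.Series,
    cross_of: Mapping[str, str],
    k: int = 15,
) -> pd.Series:
    """Per-cross Pearson restricted to the k highest-BLUE lines of each cross."""
    common = blues.index.intersection(preds.index)
    crosses = pd.Series([cross_of[l] for l in common], index=common)
    out = {}
    for cid, ids in crosses.groupby(crosses).groups.items():
        if len(ids) < k:
            raise ValueError(f"cross {cid} has {len(ids)} lines, fewer than k={k}")
        top = blues.loc[ids].nlargest(k).index
        out[cid] = _pearson(blues.loc[top].to_numpy(float), preds.loc[top].to_numpy(float))
    return pd.Series(out, name="topk_accuracy")


# ---------------------------------------------------------------------------
# design generators
# ---------------------------------------------------------------------------


def tenfold_by_cross(
    design: CrossDesign, k: int = 10, reps: int = 10, seed: int = 0
) -> Iterator[TrainingDesign]:
    """Crosses partitioned into k folds; each fold's lines validate in turn."""
    cids = design.cross_ids
    if k > len(cids):
        raise ValueError(f"k={k} exceeds the {len(cids)} available crosses")
    rng = np.random.default_rng(np.random.SeedSequence([0xF01D, seed]))
    for rep in range(reps):
        perm = list(rng.permutation(cids))
        folds = [perm[i::k] for i in range(k)]
        for f_idx, fold in enumerate(folds):
            val = tuple(l for c in fold for l in design.lines_of(c))
            train = tuple(l for c in cids if c not in fold for l in design.lines_of(c))
            yield TrainingDesign(
                "tenfold_by_cross",
                rep,
                train,
                val,
                {"fold": f_idx, "validation_crosses": tuple(sorted(fold)),
                 "n_training_lines": len(train), "n_training_crosses": len(cids) - len(fold)},
            )


def tenfold_random(
    design: CrossDesign, k: int = 10, reps: int = 10, seed: int = 0
) -> Iterator[TrainingDesign]:
    """Individual lines (not whole crosses) partitioned into k folds."""
    lines = design.line_ids()
    if k > len(lines):
        raise ValueError(f"k={k} exceeds the {len(lines)} available lines")
    rng = np.random.default_rng(np.random.SeedSequence([0xF01E, seed]))
    for rep in range(reps):
        perm = list(rng.permutation(lines))
        folds = [perm[i::k] for i in range(k)]
        for f_idx, fold in enumerate(folds):
            train = tuple(l for l in lines if l not in set(fold))
            yield TrainingDesign(
                "tenfold_random",
                rep,
                train,
                tuple(fold),
                {"fold": f_idx, "n_training_lines": len(train)},
            )


def leave_one_cross_out(design: CrossDesign) -> Iterator[TrainingDesign]:
    """One design per cross: validate the whole cross, train on all others."""
    cids = design.cross_ids
    if len(cids) < 2:
        raise ValueError("need at least two crosses")
    for cid in cids:
        val = tuple(design.lines_of(cid))
        train = tuple(l for c in cids if c != cid for l in design.lines_of(c))
        yield TrainingDesign(
            "leave_one_cross_out",
            0,
            train,
            val,
            {"validation_crosses": (cid,), "n_training_lines": len(train),
             "n_training_crosses": len(cids) - 1},
        )


def mask_training_fraction(
    base: TrainingDesign,
    fractions: Sequence[float],
    reps: int = 10,
    seed: int = 0,
) -> Iterator[TrainingDesign]:
    """Randomly drop a fraction of the training records; validation untouched."""
    if not base.training:
        raise ValueError("base design has an empty training set")
    rng = np.random.default_rng(np.random.SeedSequence([0x3A5C, seed]))
    train = np.array(base.training)
    for frac in fractions:
        if not (0.0 < frac < 1.0):
            raise ValueError(f"fraction {frac} outside (0, 1)")
        n_remove = int(round(frac * train.size))
        for rep in range(reps):
            keep = rng.permutation(train.size)[n_remove:]
            kept = tuple(train[np.sort(keep)])
            desc = dict(base.descriptors)
            desc.update({"masked_fraction": frac, "n_training_lines": len(kept)})
            yield TrainingDesign(f"{base.label}_masked", rep, kept, base.validation, desc)


def crosses_by_lines_grid(
    design: CrossDesign,
    n_crosses_list: Sequence[int] = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 15, 20, 30, 40),
    n_lines_list: Sequence[int] = (10, 20, 30, 40, 50, 60, 65),
    reps: int = 10,
    seed: int = 0,
    validation_crosses: Sequence[str] | None = None,
) -> Iterator[TrainingDesign]:
    """Sample n_lines from each of n_crosses non-validation crosses.

    For every validation cross and every feasible (n_crosses, n_lines) grid
    cell, ``reps`` random training sets are drawn; infeasible cells are
    skipped silently (their absence is visible in the emitted descriptors).
    """
    rng = np.random.default_rng(np.random.SeedSequence([0x62D, seed]))
    vcids = list(validation_crosses) if validation_crosses is not None else design.cross_ids
    lines_per = {c.cross_id: c.n_lines for c in design.crosses}
    for vcid in vcids:
        others = [c for c in design.cross_ids if c != vcid]
        val = tuple(design.lines_of(vcid))
        for nc in n_crosses_list:
            if nc > len(others):
                continue
            for nl in n_lines_list:
                if any(nl > lines_per[c] for c in others):
                    continue
                for rep in range(reps):
                    chosen = rng.choice(others, size=nc, replace=False)
                    train: list[str] = []
                    for c in chosen:
                        pool = design.lines_of(c)
                        train.extend(rng.choice(pool, size=nl, replace=False))
                    yield TrainingDesign(
                        "crosses_by_lines",
                        rep,
                        tuple(train),
                        val,
                        {
                            "validation_crosses": (vcid,),
                            "n_training_crosses": nc,
                            "lines_per_cross": nl,
                            "n_training_lines": nc * nl,
                        },
                    )


def classify_relatedness(design: CrossDesign, validation_cross: str) -> dict[str, str]:
    """'related' iff a cross shares >= 1 pedigree parent with the validation cross."""
    vparents = set(design.parents_of(validation_cross))
    out = {}
    for c in design.crosses:
        if c.cross_id == validation_cross:
            continue
        out[c.cross_id] = "related" if vparents & set(c.parents) else "unrelated"
    return out


def _quarters(lines: list[str], rng: np.random.Generator) -> list[list[str]]:
    perm = list(rng.permutation(lines))
    q = len(lines) // 4
    sizes = [q + (1 if i < len(lines) % 4 else 0) for i in range(4)]
    out, pos = [], 0
    for s in sizes:
        out.append(perm[pos : pos + s])
        pos += s
    return out


def relatedness_designs(
    design: CrossDesign,
    validation_cross: str,
    set_type: str,
    n_combinations: int = 5,
    quarters_in_training: Sequence[int] = (0, 1, 2, 3),
    n_crosses_list: Sequence[int] | None = None,
    reps: int = 10,
    seed: int = 0,
) -> Iterator[TrainingDesign]:
    """Relatedness-stratified training sets with partial validation-cross inclusion.

    ``set_type``: 'one-parent' (crosses sharing one chosen parent),
    'both-parents' (equal numbers through each validation parent),
    'unrelated' (no shared parent), or 'mixed' (equal related and unrelated).
    The validation cross is split once into four fixed quarters (frozen by
    the seed); for each requested number of quarters added to training, the
    evaluation quarter cycles through all four. Infeasible set sizes are
    skipped.
    """
    if set_type not in {"one-parent", "both-parents", "unrelated", "mixed"}:
        raise ValueError(f"unknown set_type {set_type!r}")
    rel = classify_relatedness(design, validation_cross)
    related = sorted(c for c, r in rel.items() if r == "related")
    unrelated = sorted(c for c, r in rel.items() if r == "unrelated")
    vparents = design.parents_of(validation_cross)
    by_parent = {
        p: sorted(
            c.cross_id
            for c in design.crosses
            if c.cross_id != validation_cross and p in c.parents
        )
        for p in vparents
    }
    rng = np.random.default_rng(np.random.SeedSequence([0x9E1A7, seed]))
    quarters = _quarters(design.lines_of(validation_cross), rng)

    def sample_sets(size: int) -> list[tuple[str, ...]]:
        """Up to n_combinations distinct cross combinations for one set size."""
        combos: set[tuple[str, ...]] = set()
        for _ in range(20 * n_combinations):
            if set_type == "one-parent":
                parent = rng.choice(np.array(vparents))
                pool = by_parent[str(parent)]
                if len(pool) < size:
                    continue
                pick = tuple(sorted(rng.choice(pool, size=size, replace=False)))
            elif set_type == "both-parents":
                per = size // len(vparents)
                if per == 0 or size % len(vparents):
                    return []
                pick_l: list[str] = []
                ok = True
                for p in vparents:
                    pool = [c for c in by_parent[p] if c not in pick_l]
                    if len(pool) < per:
                        ok = False
                        break
                    pick_l.extend(rng.choice(pool, size=per, replace=False))
                if not ok:
                    continue
                pick = tuple(sorted(pick_l))
            elif set_type == "unrelated":
                if len(unrelated) < size:
                    continue
                pick = tuple(sorted(rng.choice(unrelated, size=size, replace=False)))
            else:  # mixed
                half = size // 2
                if size % 2 or len(related) < half or len(unrelated) < half:
                    return []
                pick = tuple(
                    sorted(
                        list(rng.choice(related, size=half, replace=False))
                        + list(rng.choice(unrelated, size=half, replace=False))
                    )
                )
            combos.add(pick)
            if len(combos) >= n_combinations:
                break
        return sorted(combos)

    if n_crosses_list is None:
        n_crosses_list = range(1, len(design.cross_ids))
    for size in n_crosses_list:
        for rep in range(reps):
            combos = sample_sets(int(size))  # re-sampled every replicate
            for combo_idx, combo in enumerate(combos):
                base_train = [l for c in combo for l in design.lines_of(c)]
                for nq in quarters_in_training:
                    if nq not in (0, 1, 2, 3):
                        raise ValueError("quarters_in_training values must be in {0,1,2,3}")
                    for eval_q in range(4):
                        train_q = [q for q in range(4) if q != eval_q][:nq]
                        train = tuple(
                            base_train + [l for q in train_q for l in quarters[q]]
                        )
                        yield TrainingDesign(
                            f"relatedness_{set_type}",
                            rep,
                            train,
                            tuple(quarters[eval_q]),
                            {
                                "validation_crosses": (validation_cross,),
                                "set_type": set_type,
                                "n_training_crosses": len(combo),
                                "combination": combo_idx,
                                "crosses": combo,
                                "quarters_in_training": nq,
                                "eval_quarter": eval_q,
                                "n_training_lines": len(train),
                                "relatedness": tuple(rel[c] for c in combo),
                            },
                        )


# ---------------------------------------------------------------------------
# runner
# ---------------------------------------------------------------------------


def evaluate_designs(
    designs: Iterable[TrainingDesign],
    blues: pd.Series,
    grm: GRMatrix,
    cross_of: Mapping[str, str],
    min_lines: int = 3,
    include_pooled: bool = True,
    reml_kwargs: Mapping[str, object] | None = None,
) -> pd.DataFrame:
    """Refit GBLUP on every design and score the validation predictions.

    Variance components are re-estimated on each training set. Returns a
    tidy frame with one row per (design, replicate, validation cross) plus,
    when requested, an ``__all__`` pooled row per design.
    """
    rows = []
    kw = dict(reml_kwargs or {})
    for d in designs:
        y_train = blues.loc[list(d.training)]
        vc = fit_aireml(y_train, grm, **kw)
        preds = predict_lines(vc, y_train, grm).set_index("line")["ghat"]
        val = pd.Index(d.validation)
        acc = accuracy(blues.loc[val], preds.loc[val], cross_of, grouping="by-cross")
        base = {
            "label": d.label,
            "replicate": d.replicate,
            "n_training_lines": len(d.training),
            "sigma_g2": vc.sigma_g2,
            "sigma_e2": vc.sigma_e2,
            "reml_converged": vc.converged,
        }
        base.update(
            {
                k: v
                for k, v in d.descriptors.items()
                if isinstance(v, (int, float, str, bool, np.integer, np.floating))
            }
        )
        for cid, r in acc.items():
            n_val = sum(1 for l in val if cross_of[l] == cid)
            if n_val < min_lines:
                continue
            row = dict(base)
            row.update({"validation_cross": cid, "n_validation_lines": n_val, "accuracy": r})
            rows.append(row)
        if include_pooled:
            row = dict(base)
            row.update(
                {
                    "validation_cross": "__all__",
                    "n_validation_lines": len(val),
                    "accuracy": accuracy(
                        blues.loc[val], preds.loc[val], grouping="across-all"
                    ),
                }
            )
            rows.append(row)
    return pd.DataFrame(rows)
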