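"""Synthetic multi-parent breeding population and multi-trial yield data.

Generates, in order: a crossing design with a prescribed parent-usage
structure, fully inbred founder genomes, F2:4 line genotypes via simulated
meiosis and single-seed descent with a terminal family bulk, an additive
QTL trait, an unbalanced multi-trial plot allocation, and plot-level yields
carrying a separable AR1 x AR1 spatial field plus nugget noise.

All randomness flows from explicit integer seeds through
``numpy.random.SeedSequence`` children, so every artifact is
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "InfeasibleDesignError",
    "GeneticMap",
    "UsageBucket",
    "REFERENCE_USAGE_BUCKETS",
    "Cross",
    "CrossDesign",
    "Founders",
    "DosageMatrix",
    "TraitModel",
    "TrialSpec",
    "AllocationSpec",
    "design_crosses",
    "generate_founders",
    "simulate_cross",
    "generate_population",
    "simulate_trait",
    "allocate_trials",
    "simulate_trials",
    "ar1_field",
]


class InfeasibleDesignError(ValueError):
    """Raised when a requested design cannot satisfy its constraints."""


# ---------------------------------------------------------------------------
# genetic map
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneticMap:
    """Marker positions (centimorgans) on one or more chromosomes.

    ``chromosomes`` is a tuple of ``(name, positions)`` with positions
    strictly increasing and non-negative within each chromosome.
    """

    chromosomes: tuple[tuple[str, np.ndarray], ...]

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("genetic map must contain at least one chromosome")
        clean = []
        for name, pos in self.chromosomes:
            pos = np.asarray(pos, dtype=float)
            if pos.ndim != 1 or pos.size == 0:
                raise ValueError(f"chromosome {name!r}: need a 1-D non-empty position array")
            if np.any(pos < 0):
                raise ValueError(f"chromosome {name!r}: negative positions")
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"chromosome {name!r}: positions must be strictly increasing")
            clean.append((str(name), pos))
        object.__setattr__(self, "chromosomes", tuple(clean))

    @property
    def n_markers(self) -> int:
        return sum(pos.size for _, pos in self.chromosomes)

    @property
    def marker_ids(self) -> list[str]:
        return [f"{name}_M{i + 1:04d}" for name, pos in self.chromosomes for i in range(pos.size)]

    def spans(self) -> list[tuple[int, int]]:
        """Half-open column spans of each chromosome in the marker axis."""
        out, start = [], 0
        for _, pos in self.chromosomes:
            out.append((start, start + pos.size))
            start += pos.size
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (mid, name, p)
            for (name, pos) in self.chromosomes
            for mid, p in zip(
                (f"{name}_M{i + 1:04d}" for i in range(pos.size)), pos
            )
        ]
        return pd.DataFrame(rows, columns=["marker", "chromosome", "position_cm"])

    @classmethod
    def uniform(
        cls, n_chromosomes: int = 10, markers_per_chromosome: int = 200, length_cm: float = 150.0
    ) -> "GeneticMap":
        """Evenly spaced markers on equally long chromosomes."""
        chroms = tuple(
            (f"chr{c + 1:02d}", np.linspace(0.0, length_cm, markers_per_chromosome))
            for c in range(n_chromosomes)
        )
        return cls(chroms)


# ---------------------------------------------------------------------------
# crossing design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class UsageBucket:
    """``n_parents`` parents each appearing in [min_crosses, max_crosses] crosses.

    ``max_crosses=None`` means unbounded above.
    """

    n_parents: int
    min_crosses: int
    max_crosses: int | None = None

    def __post_init__(self) -> None:
        if self.n_parents <= 0 or self.min_crosses <= 0:
            raise ValueError("bucket sizes and minimum usage must be positive")
        if self.max_crosses is not None and self.max_crosses < self.min_crosses:
            raise ValueError("bucket max below min")

    def describe(self) -> str:
        hi = "inf" if self.max_crosses is None else str(self.max_crosses)
        return f"{self.n_parents} parents in [{self.min_crosses}, {hi}] crosses"


#: 27 parents: 5 heavily reused, 6 moderately, 1 twice, 15 once.
REFERENCE_USAGE_BUCKETS: tuple[UsageBucket, ...] = (
    UsageBucket(5, 6, None),
    UsageBucket(6, 3, 4),
    UsageBucket(1, 2, 2),
    UsageBucket(15, 1, 1),
)


@dataclass(frozen=True)
class Cross:
    cross_id: str
    parents: tuple[str, ...]
    n_lines: int

    def __post_init__(self) -> None:
        if len(self.parents) not in (2, 3):
            raise ValueError(f"cross {self.cross_id}: needs 2 or 3 parents")
        if len(set(self.parents)) != len(self.parents):
            raise ValueError(f"cross {self.cross_id}: parents must be distinct")
        if self.n_lines <= 0:
            raise ValueError(f"cross {self.cross_id}: n_lines must be positive")


@dataclass(frozen=True)
class CrossDesign:
    """Pedigree of bi-/tri-parental crosses and the lines derived from them."""

    parents: tuple[str, ...]
    crosses: tuple[Cross, ...]

    def __post_init__(self) -> None:
        used = {p for c in self.crosses for p in c.parents}
        missing = set(self.parents) - used
        if missing:
            raise ValueError(f"parents never used in any cross: {sorted(missing)}")

    @property
    def cross_ids(self) -> list[str]:
        return [c.cross_id for c in self.crosses]

    @property
    def n_lines(self) -> int:
        return sum(c.n_lines for c in self.crosses)

    def lines_of(self, cross_id: str) -> list[str]:
        for c in self.crosses:
            if c.cross_id == cross_id:
                return [f"{cross_id}-{i + 1:03d}" for i in range(c.n_lines)]
        raise KeyError(f"unknown cross id {cross_id!r}")

    def line_ids(self) -> list[str]:
        return [lid for c in self.crosses for lid in self.lines_of(c.cross_id)]

    def cross_of(self) -> dict[str, str]:
        return {lid: c.cross_id for c in self.crosses for lid in self.lines_of(c.cross_id)}

    def parents_of(self, cross_id: str) -> tuple[str, ...]:
        for c in self.crosses:
            if c.cross_id == cross_id:
                return c.parents
        raise KeyError(f"unknown cross id {cross_id!r}")

    def parent_usage(self) -> dict[str, int]:
        usage = {p: 0 for p in self.parents}
        for c in self.crosses:
            for p in c.parents:
                usage[p] += 1
        return usage


def design_crosses(
    n_parents: int,
    usage_spec: Sequence[UsageBucket] = REFERENCE_USAGE_BUCKETS,
    n_bi: int = 39,
    n_tri: int = 5,
    lines_per_cross: int = 68,
    seed: int = 0,
) -> CrossDesign:
    """Build a crossing design whose parent-usage counts satisfy every bucket.

    Parent slots (2 per bi-parental cross, 3 per tri-parental) are first
    distributed to parents so each bucket's bounds hold exactly, then crosses
    are formed greedily, always drawing the parents with the most unassigned
    slots, which keeps parents distinct within a cross.
    """
    if n_bi < 0 or n_tri < 0 or n_bi + n_tri == 0:
        raise InfeasibleDesignError("need at least one cross")
    n_crosses = n_bi + n_tri
    slots = 2 * n_bi + 3 * n_tri

    spec = tuple(usage_spec)
    if sum(b.n_parents for b in spec) != n_parents:
        raise InfeasibleDesignError(
            f"usage buckets cover {sum(b.n_parents for b in spec)} parents, expected {n_parents}"
        )
    for b in spec:
        if b.min_crosses > n_crosses:
            raise InfeasibleDesignError(
                f"bucket '{b.describe()}' infeasible: minimum exceeds {n_crosses} crosses"
            )
    min_total = sum(b.n_parents * b.min_crosses for b in spec)
    max_total = sum(
        b.n_parents * (min(b.max_crosses, n_crosses) if b.max_crosses is not None else n_crosses)
        for b in spec
    )
    if slots < min_total:
        worst = max(spec, key=lambda b: b.n_parents * b.min_crosses)
        raise InfeasibleDesignError(
            f"only {slots} parent slots but bucket minimums need {min_total} "
            f"(largest demand: {worst.describe()})"
        )
    if slots > max_total:
        raise InfeasibleDesignError(
            f"{slots} parent slots exceed the bucket maximums' capacity {max_total}"
        )

    rng = np.random.default_rng(np.random.SeedSequence([0x5EED, seed]))
    parents = [f"P{i + 1:02d}" for i in range(n_parents)]

    # per-parent usage targets: bucket minimum, then leftovers wherever headroom remains
    counts = np.zeros(n_parents, dtype=int)
    caps = np.zeros(n_parents, dtype=int)
    idx = 0
    bucket_of = np.zeros(n_parents, dtype=int)
    for bi_, b in enumerate(spec):
        for _ in range(b.n_parents):
            counts[idx] = b.min_crosses
            caps[idx] = min(b.max_crosses, n_crosses) if b.max_crosses is not None else n_crosses
            bucket_of[idx] = bi_
            idx += 1
    leftover = slots - int(counts.sum())
    while leftover > 0:
        room = np.flatnonzero(counts < caps)
        pick = rng.choice(room)
        counts[pick] += 1
        leftover -= 1

    # greedy construction: tri-parental crosses first, always the fullest parents
    remaining = counts.astype(float).copy()
    crosses: list[Cross] = []
    arities = [3] * n_tri + [2] * n_bi
    for k, arity in enumerate(arities):
        jitter = rng.random(n_parents) * 1e-6  # random tie-breaking
        order = np.argsort(-(remaining + jitter))
        chosen = [int(i) for i in order[:arity] if remaining[i] > 0]
        if len(chosen) < arity:
            raise InfeasibleDesignError(
                "cannot form a cross with distinct parents from the remaining usage counts"
            )
        remaining[chosen] -= 1
        cid = f"X{k + 1:02d}"
        crosses.append(Cross(cid, tuple(parents[i] for i in chosen), lines_per_cross))
    assert np.all(remaining == 0)

    design = CrossDesign(tuple(parents), tuple(crosses))
    usage = design.parent_usage()
    for b, cnt in zip(spec, _bucket_slices(spec)):
        for p in cnt:
            u = usage[parents[p]]
            hi = b.max_crosses if b.max_crosses is not None else n_crosses
            if not (b.min_crosses <= u <= hi):
                raise InfeasibleDesignError(
                    f"bucket '{b.describe()}' violated by parent {parents[p]} (used {u} times)"
                )
    return design


def _bucket_slices(spec: Sequence[UsageBucket]) -> list[range]:
    out, start = [], 0
    for b in spec:
        out.append(range(start, start + b.n_parents))
        start += b.n_parents
    return out


# ---------------------------------------------------------------------------
# founders and meiosis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Founders:
    """Fully homozygous founder lines; one haplotype per founder (doubled)."""

    ids: tuple[str, ...]
    haplotypes: np.ndarray  # (n_founders, n_markers) in {0,1}
    gmap: GeneticMap

    def haplotype(self, founder_id: str) -> np.ndarray:
        return self.haplotypes[self.ids.index(founder_id)]

    def dosages(self) -> np.ndarray:
        return 2.0 * self.haplotypes.astype(float)


def generate_founders(
    n_parents: int,
    gmap: GeneticMap,
    founder_diversity: tuple[float, float] | float | np.ndarray = (0.1, 0.9),
    seed: int = 0,
) -> Founders:
    """Draw inbred founder haplotypes from a per-marker allele-frequency spectrum.

    ``founder_diversity`` is either a ``(low, high)`` uniform range for the
    per-marker frequency, a single fixed frequency, or an explicit array of
    per-marker frequencies.
    """
    if n_parents <= 0:
        raise ValueError("n_parents must be positive")
    m = gmap.n_markers
    rng = np.random.default_rng(np.random.SeedSequence([0xF0, seed]))
    if isinstance(founder_diversity, tuple):
        lo, hi = founder_diversity
        p = rng.uniform(lo, hi, size=m)
    elif np.isscalar(founder_diversity):
        p = np.full(m, float(founder_diversity))
    else:
        p = np.asarray(founder_diversity, dtype=float)
        if p.shape != (m,):
            raise ValueError("frequency array length must equal marker count")
    haps = (rng.random((n_parents, m)) < p).astype(np.int8)
    ids = tuple(f"P{i + 1:02d}" for i in range(n_parents))
    return Founders(ids, haps, gmap)


def _meiosis(hap_a: np.ndarray, hap_b: np.ndarray, gmap: GeneticMap, rng: np.random.Generator) -> np.ndarray:
    """One gamete per row of ``hap_a``/``hap_b`` under the Haldane model.

    Crossover counts are Poisson in map length with uniform positions, which
    is equivalent to independent Poisson counts in each inter-marker gap; the
    gamete tracks the parental haplotype whose switch parity is current.
    """
    n = hap_a.shape[0]
    out = np.empty_like(hap_a)
    start_hap = rng.integers(0, 2, size=n)
    for (lo, hi), (_, pos) in zip(gmap.spans(), gmap.chromosomes):
        gaps_m = np.diff(pos) / 100.0  # Morgans between adjacent markers
        if gaps_m.size:
            xovers = rng.poisson(gaps_m, size=(n, gaps_m.size))
            parity = np.concatenate([start_hap[:, None], xovers], axis=1).cumsum(axis=1) % 2
        else:
            parity = start_hap[:, None]
        out[:, lo:hi] = np.where(parity == 0, hap_a[:, lo:hi], hap_b[:, lo:hi])
        # chromosomes assort independently
        start_hap = rng.integers(0, 2, size=n)
    return out


def simulate_cross(
    parent_haplotypes: Sequence[np.ndarray],
    n_lines: int,
    gmap: GeneticMap,
    bulk_size: int = 6,
    seed: int = 0,
    round_dosage: bool = False,
) -> np.ndarray:
    """F2:4 line dosages for one bi- or tri-parental cross.

    Bi-parental: the (single, uniform) F1 is selfed to give each line's F2,
    then single-seed descent F2 -> F3, and the line dosage is the mean of
    ``bulk_size`` F4 plants grown from that line's F3 (the family bulk).
    Tri-parental: a (P1 x P2) F1 gamete is combined with a P3 haplotype to
    form each line's three-way F1, which is then selfed down the same chain.
    """
    if len(parent_haplotypes) not in (2, 3):
        raise ValueError("a cross requires 2 or 3 parents")
    if n_lines <= 0:
        raise ValueError("n_lines must be positive")
    haps = [np.asarray(h, dtype=np.int8) for h in parent_haplotypes]
    m = gmap.n_markers
    for h in haps:
        if h.shape != (m,):
            raise ValueError("parent haplotype length must equal marker count")
    rng = np.random.default_rng(np.random.SeedSequence([0xC0, seed]))

    tile = lambda h: np.broadcast_to(h, (n_lines, m)).copy()
    if len(haps) == 2:
        f1a, f1b = tile(haps[0]), tile(haps[1])
    else:
        f1a = _meiosis(tile(haps[0]), tile(haps[1]), gmap, rng)  # gamete of (P1 x P2) F1
        f1b = tile(haps[2])
    # three generations of selfing: F1 -> F2 -> F3, then the F4 bulk
    f2a = _meiosis(f1a, f1b, gmap, rng)
    f2b = _meiosis(f1a, f1b, gmap, rng)
    f3a = _meiosis(f2a, f2b, gmap, rng)
    f3b = _meiosis(f2a, f2b, gmap, rng)
    rep = lambda h: np.repeat(h, bulk_size, axis=0)
    f4 = _meiosis(rep(f3a), rep(f3b), gmap, rng).astype(np.int16) + _meiosis(
        rep(f3a), rep(f3b), gmap, rng
    )
    dos = f4.reshape(n_lines, bulk_size, m).mean(axis=1)
    if round_dosage:
        dos = np.rint(dos)
    return dos


@dataclass(frozen=True)
class DosageMatrix:
    """Lines x markers allele dosages in [0, 2]."""

    line_ids: tuple[str, ...]
    marker_ids: tuple[str, ...]
    values: np.ndarray  # float (n_lines, n_markers)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.line_ids), len(self.marker_ids)):
            raise ValueError("dosage matrix shape does not match id lists")
        if np.any(~np.isfinite(v)) or v.min(initial=0) < 0 or v.max(initial=0) > 2:
            raise ValueError("dosages must be finite and within [0, 2]")
        object.__setattr__(self, "values", v)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.line_ids), columns=list(self.marker_ids))

    def to_csv(self, path) -> None:
        self.to_frame().rename_axis("line").to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "DosageMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(tuple(df.index.astype(str)), tuple(df.columns.astype(str)), df.to_numpy(float))


def generate_population(
    design: CrossDesign,
    gmap: GeneticMap,
    founders: Founders | None = None,
    founder_diversity: tuple[float, float] | float | np.ndarray = (0.1, 0.9),
    bulk_size: int = 6,
    seed: int = 0,
) -> DosageMatrix:
    """Genotype every line of every cross in the design."""
    if founders is None:
        founders = generate_founders(len(design.parents), gmap, founder_diversity, seed=seed)
    ss = np.random.SeedSequence([0xB10C, seed])
    child_seeds = ss.generate_state(len(design.crosses))
    blocks, line_ids = [], []
    for c, cseed in zip(design.crosses, child_seeds):
        haps = [founders.haplotype(p) for p in c.parents]
        blocks.append(simulate_cross(haps, c.n_lines, gmap, bulk_size=bulk_size, seed=int(cseed)))
        line_ids.extend(design.lines_of(c.cross_id))
    return DosageMatrix(tuple(line_ids), tuple(gmap.marker_ids), np.vstack(blocks))


# ---------------------------------------------------------------------------
# trait model and trial simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TraitModel:
    """Additive QTL trait plus trial/noise parameters for yield simulation.

    ``h2_plot`` targets the plot-level ratio var(g)/(var(g)+noise); when set,
    ``spatial_weight``/``nugget_weight`` act as relative shares of the noise
    budget. When ``h2_plot`` is None the weights are absolute variances.
    """

    qtl_indices: np.ndarray
    effects: np.ndarray
    h2_plot: float | None = 0.65
    site_means: tuple[float, ...] = (8.6, 10.8, 8.2, 4.6)
    rho_row: float = 0.4
    rho_col: float = 0.4
    spatial_weight: float = 1.0
    nugget_weight: float = 1.0

    def __post_init__(self) -> None:
        q = np.asarray(self.qtl_indices, dtype=int)
        e = np.asarray(self.effects, dtype=float)
        if q.shape != e.shape or q.ndim != 1:
            raise ValueError("qtl_indices and effects must be matching 1-D arrays")
        if self.h2_plot is not None and not (0.0 < self.h2_plot < 1.0):
            raise ValueError("target plot-level heritability must lie strictly in (0, 1)")
        for rho in (self.rho_row, self.rho_col):
            if not (-1.0 < rho < 1.0):
                raise ValueError("autocorrelations must lie strictly inside (-1, 1)")
        if self.spatial_weight < 0 or self.nugget_weight < 0:
            raise ValueError("variance weights must be non-negative")
        object.__setattr__(self, "qtl_indices", q)
        object.__setattr__(self, "effects", e)

    @classmethod
    def random(
        cls, n_markers: int, n_qtl: int, seed: int = 0, effect_sd: float = 1.0, **kwargs
    ) -> "TraitModel":
        rng = np.random.default_rng(np.random.SeedSequence([0x7A17, seed]))
        idx = rng.choice(n_markers, size=min(n_qtl, n_markers), replace=False)
        eff = rng.normal(0.0, effect_sd, size=idx.size)
        return cls(np.sort(idx), eff, **kwargs)

    @staticmethod
    def plot_h2_for_line_h2(line_h2: float, n_plots: int) -> float:
        """Plot-level ratio that yields a given line-mean heritability at n plots."""
        if not (0.0 < line_h2 < 1.0):
            raise ValueError("line-level heritability must lie in (0, 1)")
        return line_h2 / (line_h2 + n_plots * (1.0 - line_h2))


def simulate_trait(genotypes: DosageMatrix, model: TraitModel, seed: int = 0) -> pd.Series:
    """Centered true genetic values per line (sum of dosage x effect at QTL)."""
    m = len(genotypes.marker_ids)
    if model.qtl_indices.size and (model.qtl_indices.min() < 0 or model.qtl_indices.max() >= m):
        raise ValueError("QTL indices outside the marker range")
    g = genotypes.values[:, model.qtl_indices] @ model.effects
    g = g - g.mean()
    if model.h2_plot is not None and model.h2_plot > 0 and np.var(g) == 0:
        raise ValueError("trait has zero genetic variance but a positive heritability target")
    return pd.Series(g, index=list(genotypes.line_ids), name="genetic_value")


@dataclass(frozen=True)
class TrialSpec:
    trial_id: str
    site: str
    year: int
    n_cols: int


_DEFAULT_TRIALS: tuple[TrialSpec, ...] = (
    TrialSpec("T1", "Cambridge", 2016, 60),
    TrialSpec("T2", "Duxford", 2016, 60),
    TrialSpec("T3", "Duxford", 2017, 60),
    TrialSpec("T4", "Hinxton", 2017, 60),
)

#: season-1-present lines split across five plot-count patterns (per-trial plot
#: counts over T1..T4, each summing to 4), in the reference proportions; absent
#: populations take (0, 0, 2, 2).
_REFERENCE_PATTERN_WEIGHTS: tuple[tuple[int, tuple[int, int, int, int]], ...] = (
    (367, (2, 1, 1, 0)),
    (381, (2, 1, 0, 1)),
    (381, (1, 2, 1, 0)),
    (367, (1, 2, 0, 1)),
    (748, (1, 1, 1, 1)),
)
_ABSENT_PATTERN: tuple[int, int, int, int] = (0, 0, 2, 2)


@dataclass(frozen=True)
class AllocationSpec:
    """How lines are spread over trials: which crosses miss season 1 and the
    per-line plot-count patterns for the rest; sub-block size emulates the
    lattice grouping; checks are replicated entries added to every trial."""

    trials: tuple[TrialSpec, ...] = _DEFAULT_TRIALS
    absent_crosses: tuple[str, ...] = ()
    patterns: tuple[tuple[int, tuple[int, ...]], ...] = ()
    absent_pattern: tuple[int, ...] = _ABSENT_PATTERN
    plots_per_line: int = 4
    sub_block_size: int = 10
    n_checks: int = 0
    check_reps: int = 2

    @classmethod
    def reference(
        cls,
        design: CrossDesign,
        trials: tuple[TrialSpec, ...] = _DEFAULT_TRIALS,
        absent_fraction: float = 11 / 44,
        n_checks: int = 4,
        check_reps: int = 2,
        n_cols: int | None = None,
        seed: int = 0,
    ) -> "AllocationSpec":
        """Scale the reference unbalanced scheme to an arbitrary design size."""
        rng = np.random.default_rng(np.random.SeedSequence([0xA110, seed]))
        cids = list(design.cross_ids)
        n_absent = int(round(absent_fraction * len(cids)))
        n_absent = min(n_absent, len(cids) - 1)
        absent = tuple(sorted(rng.choice(cids, size=n_absent, replace=False))) if n_absent else ()
        n_present_lines = sum(c.n_lines for c in design.crosses if c.cross_id not in absent)
        weights = np.array([w for w, _ in _REFERENCE_PATTERN_WEIGHTS], dtype=float)
        sizes = np.floor(weights / weights.sum() * n_present_lines).astype(int)
        sizes[-1] += n_present_lines - sizes.sum()  # remainder into the balanced pattern
        patterns = tuple(
            (int(s), pat) for s, (_, pat) in zip(sizes, _REFERENCE_PATTERN_WEIGHTS) if s > 0
        )
        if n_cols is not None:
            trials = tuple(dataclasses.replace(t, n_cols=n_cols) for t in trials)
        return cls(trials, absent, patterns, _ABSENT_PATTERN, 4, 10, n_checks, check_reps)

    @classmethod
    def balanced(
        cls,
        design: CrossDesign,
        trials: tuple[TrialSpec, ...] = _DEFAULT_TRIALS,
        n_checks: int = 0,
        check_reps: int = 2,
        n_cols: int | None = None,
    ) -> "AllocationSpec":
        """Every line once per trial (one plot in each of the four trials)."""
        pat = tuple(1 for _ in trials)
        if n_cols is not None:
            trials = tuple(dataclasses.replace(t, n_cols=n_cols) for t in trials)
        return cls(trials, (), ((design.n_lines, pat),), pat, len(trials), 10, n_checks, check_reps)


def check_ids(spec: AllocationSpec) -> list[str]:
    return [f"CHK{i + 1:02d}" for i in range(spec.n_checks)]


def allocate_trials(design: CrossDesign, spec: AllocationSpec, seed: int = 0) -> pd.DataFrame:
    """Assign every line to plots on each trial's row x column grid.

    Returns one row per plot: trial, site, year, row, col, line, is_check.
    Every non-check line receives exactly ``spec.plots_per_line`` plots in
    total; entries are shuffled into contiguous sub-blocks before being laid
    on the grid, emulating lattice-style randomization.
    """
    rng = np.random.default_rng(np.random.SeedSequence([0xA5516, seed]))
    for cid in spec.absent_crosses:
        design.parents_of(cid)  # raises on unknown id
    present_lines = [
        lid for c in design.crosses if c.cross_id not in spec.absent_crosses
        for lid in design.lines_of(c.cross_id)
    ]
    absent_lines = [
        lid for c in design.crosses if c.cross_id in spec.absent_crosses
        for lid in design.lines_of(c.cross_id)
    ]
    n_trials = len(spec.trials)
    for _, pat in spec.patterns:
        if len(pat) != n_trials or sum(pat) != spec.plots_per_line:
            raise InfeasibleDesignError(
                f"pattern {pat} does not sum to {spec.plots_per_line} over {n_trials} trials"
            )
    if absent_lines and (
        len(spec.absent_pattern) != n_trials or sum(spec.absent_pattern) != spec.plots_per_line
    ):
        raise InfeasibleDesignError("absent-cross pattern does not sum to the per-line plot count")
    if sum(n for n, _ in spec.patterns) != len(present_lines):
        raise InfeasibleDesignError(
            f"patterns cover {sum(n for n, _ in spec.patterns)} lines, "
            f"but {len(present_lines)} lines are present in season 1"
        )

    order = rng.permutation(len(present_lines))
    pattern_of: dict[str, tuple[int, ...]] = {}
    pos = 0
    for n, pat in spec.patterns:
        for k in order[pos : pos + n]:
            pattern_of[present_lines[k]] = pat
        pos += n
    for lid in absent_lines:
        pattern_of[lid] = spec.absent_pattern

    checks = check_ids(spec)
    records = []
    for t_idx, tspec in enumerate(spec.trials):
        entries = [lid for lid, pat in pattern_of.items() for _ in range(pat[t_idx])]
        entries += [c for c in checks for _ in range(spec.check_reps)]
        entries = list(rng.permutation(entries))
        # contiguous sub-blocks on a row-major grid
        n_plots = len(entries)
        n_rows = -(-n_plots // tspec.n_cols)
        if n_rows < 1:
            raise InfeasibleDesignError(f"trial {tspec.trial_id}: empty grid")
        for i, lid in enumerate(entries):
            records.append(
                (
                    tspec.trial_id,
                    tspec.site,
                    tspec.year,
                    i // tspec.n_cols,
                    i % tspec.n_cols,
                    i // (spec.sub_block_size * 1),
                    lid,
                    lid in checks,
                )
            )
    df = pd.DataFrame(
        records, columns=["trial", "site", "year", "row", "col", "sub_block", "line", "is_check"]
    )
    return df


def ar1_ar1_covariance(n_rows: int, n_cols: int, rho_row: float, rho_col: float) -> np.ndarray:
    """Dense separable AR1 x AR1 correlation over a full grid (row-major)."""
    r = rho_row ** np.abs(np.subtract.outer(np.arange(n_rows), np.arange(n_rows)))
    c = rho_col ** np.abs(np.subtract.outer(np.arange(n_cols), np.arange(n_cols)))
    return np.kron(r, c)


def ar1_field(
    n_rows: int, n_cols: int, rho_row: float, rho_col: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-marginal-variance stationary AR1 x AR1 Gaussian field."""
    if abs(rho_row) >= 1 or abs(rho_col) >= 1:
        raise ValueError("autocorrelations must lie strictly inside (-1, 1)")
    lr = np.linalg.cholesky(
        rho_row ** np.abs(np.subtract.outer(np.arange(n_rows), np.arange(n_rows)))
    )
    lc = np.linalg.cholesky(
        rho_col ** np.abs(np.subtract.outer(np.arange(n_cols), np.arange(n_cols)))
    )
    z = rng.standard_normal((n_rows, n_cols))
    return lr @ z @ lc.T


def simulate_trials(
    assignments: pd.DataFrame,
    genetic_values: Mapping[str, float] | pd.Series,
    model: TraitModel,
    seed: int = 0,
) -> pd.DataFrame:
    """Plot yields = site-year mean + genetic value + AR1 x AR1 field + nugget.

    When the model carries a target plot-level heritability, the total noise
    variance is scaled against the realized genetic variance of the assigned
    non-check lines so the ratio is met by construction.
    """
    gv = pd.Series(genetic_values, dtype=float)
    missing = set(assignments["line"]) - set(gv.index)
    if missing:
        raise ValueError(f"no genetic value for assigned lines: {sorted(missing)[:5]}")
    if abs(model.rho_row) >= 1 or abs(model.rho_col) >= 1:
        raise ValueError("autocorrelations must lie strictly inside (-1, 1)")

    lines_only = assignments.loc[~assignments["is_check"], "line"].unique()
    var_g = float(np.var(gv.loc[lines_only])) if len(lines_only) else float(np.var(gv))
    wsum = model.spatial_weight + model.nugget_weight
    if model.h2_plot is not None and wsum > 0:
        v_total = var_g * (1.0 - model.h2_plot) / model.h2_plot
        var_s = v_total * model.spatial_weight / wsum
        var_n = v_total * model.nugget_weight / wsum
    else:
        var_s, var_n = model.spatial_weight, model.nugget_weight

    rng = np.random.default_rng(np.random.SeedSequence([0x7121A15, seed]))
    trial_ids = list(dict.fromkeys(assignments["trial"]))
    site_means = dict(zip(trial_ids, model.site_means))
    if len(trial_ids) > len(model.site_means):
        raise ValueError("fewer site means than trials")
    out = assignments.copy()
    out["yield"] = 0.0
    for tid in trial_ids:
        mask = out["trial"] == tid
        rows = out.loc[mask, "row"].to_numpy()
        cols = out.loc[mask, "col"].to_numpy()
        n_rows, n_cols = rows.max() + 1, cols.max() + 1
        field = (
            np.sqrt(var_s) * ar1_field(n_rows, n_cols, model.rho_row, model.rho_col, rng)
            if var_s > 0
            else np.zeros((n_rows, n_cols))
        )
        nug = np.sqrt(var_n) * rng.standard_normal(mask.sum()) if var_n > 0 else 0.0
        out.loc[mask, "yield"] = (
            site_means[tid] + gv.loc[out.loc[mask, "line"]].to_numpy() + field[rows, cols] + nug
        )
    return out
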