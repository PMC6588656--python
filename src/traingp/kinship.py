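"""VanRaden (method 1) genomic relationship matrix from allele dosages."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .simdata import DosageMatrix

__all__ = ["GRMatrix", "compute_grm", "stabilize", "filter_segregating", "write_grm_csv", "write_grm_triplets"]


@dataclass(frozen=True)
class GRMatrix:
    """Symmetric genomic relationship matrix with build provenance."""

    ids: tuple[str, ...]
    matrix: np.ndarray
    freqs: np.ndarray  # allele frequencies of the markers actually used
    denominator: float
    n_markers: int
    epsilon: float = 0.0  # diagonal stabilization already applied

    def __post_init__(self) -> None:
        g = np.asarray(self.matrix, dtype=float)
        n = len(self.ids)
        if g.shape != (n, n):
            raise ValueError("matrix shape does not match id count")
        if not np.allclose(g, g.T, atol=1e-10):
            raise ValueError("relationship matrix must be symmetric")
        if self.denominator <= 0:
            raise ValueError("denominator must be positive")
        object.__setattr__(self, "matrix", g)

    def submatrix(self, ids: list[str]) -> np.ndarray:
        idx = self.indexer(ids)
        return self.matrix[np.ix_(idx, idx)]

    def indexer(self, ids) -> np.ndarray:
        lookup = {lid: i for i, lid in enumerate(self.ids)}
        try:
            return np.array([lookup[i] for i in ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"line {exc.args[0]!r} absent from the relationship matrix") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.ids), columns=list(self.ids))


def compute_grm(genotypes: DosageMatrix, freqs: np.ndarray | None = None) -> GRMatrix:
    """G = W W' / (2 * sum p_i (1 - p_i)), W the column-centred dosages.

    Allele frequencies default to estimation from the supplied genotypes
    (mean dosage / 2 over the full set). Markers that are monomorphic in the
    data, or whose frequency is 0 or 1, drop out of numerator, denominator
    and the reported marker count.
    """
    x = genotypes.values
    if freqs is None:
        p = x.mean(axis=0) / 2.0
    else:
        p = np.asarray(freqs, dtype=float)
        if p.shape != (x.shape[1],):
            raise ValueError("frequency vector length must equal marker count")
    keep = (x.var(axis=0) > 0) & (p > 0) & (p < 1)
    if not keep.any():
        raise ValueError("all markers are monomorphic; the GRM denominator is zero")
    w = x[:, keep] - 2.0 * p[keep]
    denom = float(2.0 * np.sum(p[keep] * (1.0 - p[keep])))
    g = w @ w.T / denom
    g = (g + g.T) / 2.0
    return GRMatrix(genotypes.line_ids, g, p[keep], denom, int(keep.sum()))


def stabilize(grm: GRMatrix, epsilon: float = 1e-6) -> GRMatrix:
    """Add ``epsilon`` to the diagonal so downstream solves stay well posed."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    return replace(
        grm,
        matrix=grm.matrix + epsilon * np.eye(len(grm.ids)),
        epsilon=grm.epsilon + epsilon,
    )


def filter_segregating(genotypes: DosageMatrix) -> tuple[DosageMatrix, int, int]:
    """Drop markers with zero dosage variance; returns (filtered, kept, dropped)."""
    keep = genotypes.values.var(axis=0) > 0
    kept = int(keep.sum())
    filtered = DosageMatrix(
        genotypes.line_ids,
        tuple(m for m, k in zip(genotypes.marker_ids, keep) if k),
        genotypes.values[:, keep],
    )
    return filtered, kept, len(genotypes.marker_ids) - kept


def write_grm_csv(grm: GRMatrix, path) -> None:
    grm.to_frame().rename_axis("line").to_csv(path)


def write_grm_triplets(grm: GRMatrix, path) -> None:
    """Lower triangle (including diagonal) as id1, id2, value text."""
    with open(path, "w") as fh:
        fh.write("id1,id2,value\n")
        for i, a in enumerate(grm.ids):
            for j in range(i + 1):
                fh.write(f"{a},{grm.ids[j]},{grm.matrix[i, j]:.10g}\n")
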