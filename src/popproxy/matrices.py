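"""Labelled distance matrices — the pipeline's universal currency.

Every stage of the analysis (trait distances, proxy distances, regression on
distance matrices, prioritisation) consumes and produces instances of
:class:`DistanceMatrix`: a square, symmetric, hollow (zero-diagonal),
non-negative, finite matrix whose rows are either study *replicates*
(population x tank) or *populations*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REPLICATE = "replicate"
POPULATION = "population"

_SYMMETRY_TOL = 1e-9


@dataclass
class DistanceMatrix:
    """A labelled symmetric distance matrix at replicate or population level.

    Parameters
    ----------
    labels:
        Ordered unit names (one per row/column).
    values:
        Square array of pairwise distances.
    level:
        ``"replicate"`` or ``"population"``.
    """

    labels: list[str]
    values: np.ndarray
    level: str = POPULATION

    def __post_init__(self) -> None:
        self.labels = [str(x) for x in self.labels]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels in distance matrix")
        if self.level not in (REPLICATE, POPULATION):
            raise ValueError(f"unknown level {self.level!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite entries in distance matrix")
        if not np.allclose(self.values, self.values.T, atol=_SYMMETRY_TOL):
            raise ValueError("matrix is not symmetric")
        if np.any(np.abs(np.diag(self.values)) > _SYMMETRY_TOL):
            raise ValueError("matrix diagonal is not zero")
        if np.any(self.values < -_SYMMETRY_TOL):
            raise ValueError("negative distances")
        # exact hygiene after tolerance checks
        self.values = np.clip((self.values + self.values.T) / 2.0, 0.0, None)
        np.fill_diagonal(self.values, 0.0)

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Strict lower triangle in row-major order: (1,0),(2,0),(2,1),..."""
        i, j = np.tril_indices(self.n, k=-1)
        return self.values[i, j]

    def offdiag(self) -> np.ndarray:
        return self.condensed()

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path, config_hash: str | None = None) -> None:
        """Write as a labelled square CSV (12 significant digits)."""
        with open(path, "w") as fh:
            if config_hash is not None:
                fh.write(f"# config_hash={config_hash}\n")
            fh.write(f"# level={self.level}\n")
            self.to_dataframe().to_csv(fh, float_format="%.12g")

    @classmethod
    def from_csv(cls, path, level: str | None = None) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0, comment=None, skiprows=_count_comment_rows(path))
        lvl = level if level is not None else _level_from_header(path)
        return cls(list(df.index), df.to_numpy(dtype=float), level=lvl)

    # ----- level conversion ------------------------------------------------

    def expand(self, replicate_map: Mapping[str, str]) -> "DistanceMatrix":
        """Expand a population-level matrix to replicate level.

        ``replicate_map`` maps replicate label -> population label; its key
        order fixes the replicate ordering.  Cross-population blocks copy the
        population distance; within-population blocks are zero.
        """
        if self.level != POPULATION:
            raise ValueError("expand() only applies to population-level matrices")
        pops = set(replicate_map.values())
        missing = pops - set(self.labels)
        if missing:
            raise KeyError(f"replicate_map references unknown populations: {sorted(missing)}")
        rep_labels = list(replicate_map)
        idx = {p: k for k, p in enumerate(self.labels)}
        pop_idx = np.array([idx[replicate_map[r]] for r in rep_labels])
        vals = self.values[np.ix_(pop_idx, pop_idx)].copy()
        same = pop_idx[:, None] == pop_idx[None, :]
        vals[same] = 0.0
        return DistanceMatrix(rep_labels, vals, level=REPLICATE)

    def collapse(self, replicate_map: Mapping[str, str]) -> "DistanceMatrix":
        """Average cross-replicate blocks down to population level.

        Inverse of :meth:`expand` on matrices whose within-population blocks
        are zero (expand-then-collapse is the identity).
        """
        if self.level != POPULATION and set(replicate_map) != set(self.labels):
            raise KeyError("replicate_map keys must equal the matrix labels")
        pops = list(dict.fromkeys(replicate_map.values()))
        groups = {p: [i for i, r in enumerate(self.labels) if replicate_map[r] == p] for p in pops}
        out = np.zeros((len(pops), len(pops)))
        for a, pa in enumerate(pops):
            for b in range(a):
                block = self.values[np.ix_(groups[pa], groups[pops[b]])]
                out[a, b] = out[b, a] = block.mean()
        return DistanceMatrix(pops, out, level=POPULATION)


def _count_comment_rows(path) -> int:
    n = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                n += 1
            else:
                break
    return n


def _level_from_header(path) -> str:
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith("# level="):
                return line.strip().split("=", 1)[1]
    return POPULATION


def condensed_index_pairs(n: int) -> list[tuple[int, int]]:
    """(row, col) pairs matching :meth:`DistanceMatrix.condensed` order."""
    return [(i, j) for i in range(n) for j in range(i)]


def check_same_labels(*matrices: DistanceMatrix) -> None:
    ref = matrices[0].labels
    for m in matrices[1:]:
        if m.labels != ref:
            extra = sorted(set(m.labels) ^ set(ref))
            raise ValueError(f"distance matrices have mismatched labels: {extra or 'ordering differs'}")
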