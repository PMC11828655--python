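"""Simple (square) lattice designs.

A simple lattice accommodates ``g = k**2`` genotypes in two replications,
each resolved into ``k`` incomplete blocks of ``k`` plots.  Writing the
genotypes on a k x k square, replication 1 blocks are the rows of the square
and replication 2 blocks are the columns, so any two genotypes meet in at
most one block — a partially balanced incomplete block (PBIB) design with
concurrence 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DesignError

__all__ = ["TrialDesign", "make_design"]


@dataclass(frozen=True)
class TrialDesign:
    """Layout of a simple lattice trial.

    Attributes
    ----------
    k : int
        Block size (plots per incomplete block).
    r : int
        Number of replications (2 for a simple lattice).
    layout : dict[tuple[int, int], tuple[int, ...]]
        Mapping ``(replication, block) -> ordered genotype ids`` (1-based).
    """

    k: int
    r: int
    layout: dict[tuple[int, int], tuple[int, ...]] = field(repr=False)

    @property
    def g(self) -> int:
        """Number of genotypes, ``k**2``."""
        return self.k * self.k

    @property
    def n_plots(self) -> int:
        return self.g * self.r

    def validate(self) -> None:
        """Check all structural invariants; raise :class:`DesignError` if violated."""
        full = set(range(1, self.g + 1))
        for rep in range(1, self.r + 1):
            blocks = [self.layout.get((rep, b)) for b in range(1, self.k + 1)]
            if any(b is None for b in blocks):
                raise DesignError(f"replication {rep} does not have {self.k} blocks")
            seen: list[int] = []
            for b in blocks:
                if len(set(b)) != self.k:
                    raise DesignError(
                        f"a block in replication {rep} does not hold {self.k} distinct genotypes"
                    )
                seen.extend(b)
            if set(seen) != full or len(seen) != self.g:
                raise DesignError(
                    f"replication {rep} is not a permutation of genotypes 1..{self.g}"
                )
        # pairwise concurrence at most one shared block across replications
        pair_count: dict[tuple[int, int], int] = {}
        for members in self.layout.values():
            s = sorted(members)
            for i in range(len(s)):
                for j in range(i + 1, len(s)):
                    key = (s[i], s[j])
                    pair_count[key] = pair_count.get(key, 0) + 1
                    if pair_count[key] > 1:
                        raise DesignError(
                            f"genotypes {key} co-occur in more than one block"
                        )

    def block_of(self, accession: int, rep: int) -> int:
        """Block index holding ``accession`` in replication ``rep``."""
        for (rp, blk), members in self.layout.items():
            if rp == rep and accession in members:
                return blk
        raise DesignError(f"accession {accession} absent from replication {rep}")

    def to_frame(self) -> pd.DataFrame:
        """Plot list as a tidy frame with columns accession, replication, block."""
        rows = [
            (acc, rep, blk)
            for (rep, blk), members in sorted(self.layout.items())
            for acc in members
        ]
        return pd.DataFrame(rows, columns=["accession", "replication", "block"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TrialDesign":
        """Rebuild a design from a tidy accession/replication/block table."""
        r = int(frame["replication"].max())
        k = int(frame["block"].max())
        layout: dict[tuple[int, int], tuple[int, ...]] = {}
        for (rep, blk), grp in frame.groupby(["replication", "block"]):
            layout[(int(rep), int(blk))] = tuple(int(a) for a in grp["accession"])
        design = cls(k=k, r=r, layout=layout)
        design.validate()
        return design


def make_design(k: int, r: int = 2, seed: int | None = None) -> TrialDesign:
    """Construct a simple lattice: rows of the k x k square in replication 1,
    columns in replication 2.

    Parameters
    ----------
    k : int
        Block size; the design has ``k**2`` genotypes. Must be >= 2.
    r : int
        Replications; a simple lattice requires exactly 2.
    seed : int, optional
        When given, genotype labels are randomly permuted over the square
        (reproducibly).  The incomplete-block structure is unchanged, so all
        downstream estimators are invariant to this randomization.
    """
    if k < 2:
        raise DesignError(f"block size k must be >= 2, got {k}")
    if r != 2:
        raise DesignError(f"a simple lattice has exactly 2 replications, got r={r}")
    g = k * k
    labels = np.arange(1, g + 1)
    if seed is not None:
        labels = np.random.default_rng(seed).permutation(labels)
    square = labels.reshape(k, k)
    layout: dict[tuple[int, int], tuple[int, ...]] = {}
    for i in range(k):
        layout[(1, i + 1)] = tuple(int(x) for x in square[i, :])
    for j in range(k):
        layout[(2, j + 1)] = tuple(int(x) for x in square[:, j])
    design = TrialDesign(k=k, r=r, layout=layout)
    design.validate()
    return design
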