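"""Per-cell, per-locus, per-base allele count tensor.

The tensor holds raw read counts ``n[x, i, j]`` for each base
``x in {A, C, G, T}``, cell ``i`` and mitochondrial locus ``j``.  It is the
sole input of the statistical core: every downstream quantity (sequencing
depth, wild-type allele, heteroplasmy proxy) is derived from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BASES = ("A", "C", "G", "T")
BASE_INDEX = {b: k for k, b in enumerate(BASES)}


@dataclass
class AlleleCountTensor:
    """Dense allele count tensor of shape (4 bases, n_cells, n_loci).

    Parameters
    ----------
    cells : list of str
        Unique cell barcodes, in column order.
    loci : list of (str, int)
        Unique ``(contig, 1-based position)`` pairs, sorted.
    counts : ndarray, shape (4, n_cells, n_loci)
        Non-negative integer read counts, bases ordered A, C, G, T
        (forward and reverse strand reads already summed).
    """

    cells: list[str]
    loci: list[tuple[str, int]]
    counts: np.ndarray
    zero_loci: np.ndarray = field(default=None)  # loci with zero total count

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (4, len(self.cells), len(self.loci)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"(4, {len(self.cells)} cells, {len(self.loci)} loci)"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.round(self.counts)):
                raise ValueError("counts must be integer-valued")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if len(set(self.cells)) != len(self.cells):
            raise ValueError("cell barcodes must be unique")
        if len(set(self.loci)) != len(self.loci):
            raise ValueError("loci must be unique")
        if list(self.loci) != sorted(self.loci):
            # re-sort loci (and count columns) by (contig, position)
            idx = np.lexsort(
                ([p for _, p in self.loci], [c for c, _ in self.loci])
            )
            self.loci = [self.loci[k] for k in idx]
            self.counts = self.counts[:, :, idx]
        if self.zero_loci is None:
            self.zero_loci = self.counts.sum(axis=(0, 1)) == 0

    # ------------------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_names(self) -> list[str]:
        """Labels like ``chrM.310`` used throughout exports."""
        return [f"{contig}.{pos}" for contig, pos in self.loci]

    def depth(self) -> np.ndarray:
        """Sequencing depth N(i,j) = sum of the four base counts."""
        return self.counts.sum(axis=0)

    def base_counts(self, base: str) -> np.ndarray:
        return self.counts[BASE_INDEX[base]]

    def subset_cells(self, keep: np.ndarray | list) -> "AlleleCountTensor":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return AlleleCountTensor(
            cells=[self.cells[k] for k in idx],
            loci=list(self.loci),
            counts=self.counts[:, idx, :],
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame (cell, locus, base, count); mostly for debugging."""
        b, i, j = np.nonzero(self.counts)
        return pd.DataFrame(
            {
                "cell": [self.cells[k] for k in i],
                "locus": [self.locus_names[k] for k in j],
                "base": [BASES[k] for k in b],
                "count": self.counts[b, i, j],
            }
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AlleleCountTensor):
            return NotImplemented
        return (
            self.cells == other.cells
            and list(self.loci) == list(other.loci)
            and np.array_equal(self.counts, other.counts)
        )
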