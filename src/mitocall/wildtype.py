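"""Reference-free wild-type allele definition.

For each locus the wild-type (WT) allele is the base with the highest
*median raw count* across all cells — no reference genome is consulted,
so private germline polymorphisms become the WT by construction.  From the
WT allele we derive, per cell and locus, the WT read count ``m`` and the
WT allele frequency ``wAF = m / N``, the working proxy for the WT
heteroplasmy level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .tensor import BASES, AlleleCountTensor


@dataclass
class WildtypeProfile:
    """Per-locus WT allele and per-base median counts.

    Attributes
    ----------
    wt_base : ndarray of int, shape (n_loci,)
        Index into A,C,G,T of the WT allele W_j.
    medians : ndarray, shape (4, n_loci)
        Median count M(x, j) of each base across cells.
    tie : ndarray of bool
        True where two or more bases attain the maximal median; the tie is
        broken by the fixed base order A < C < G < T.
    """

    wt_base: np.ndarray
    medians: np.ndarray
    tie: np.ndarray

    @property
    def wt_allele(self) -> list[str]:
        return [BASES[k] for k in self.wt_base]


def call_wildtype(tensor: AlleleCountTensor) -> WildtypeProfile:
    """Identify the WT allele per locus as the base with maximal median count.

    The median over an even number of cells is the midpoint of the two
    central order statistics.  Ties between bases are broken in favour of
    the earlier base in A < C < G < T and flagged.
    """
    if tensor.n_cells < 1:
        raise ValueError("at least one cell is required")
    medians = np.median(tensor.counts, axis=1)  # (4, n_loci)
    wt = np.argmax(medians, axis=0)  # argmax takes the first max: A<C<G<T order
    tie = (medians == medians.max(axis=0, keepdims=True)).sum(axis=0) > 1
    return WildtypeProfile(wt_base=wt, medians=medians, tie=tie)


def wt_reads(
    tensor: AlleleCountTensor, profile: WildtypeProfile
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per cell x locus WT read count m, depth N and WT allele frequency.

    Returns ``(m, N, wAF)``; ``wAF`` is NaN where the depth is zero (missing,
    neither 0 nor 1).
    """
    if len(profile.wt_base) != tensor.n_loci:
        raise ValueError("profile was computed on a different locus set")
    m = np.take_along_axis(
        tensor.counts, profile.wt_base[None, None, :], axis=0
    )[0]
    depth = tensor.depth()
    with np.errstate(divide="ignore", invalid="ignore"):
        waf = np.where(depth > 0, m / np.maximum(depth, 1), np.nan)
    return m, depth, waf


def filter_cells_by_depth(
    tensor: AlleleCountTensor,
    min_depth: float = 5.0,
    stat: str = "mean",
) -> np.ndarray:
    """Boolean mask of cells whose per-cell depth statistic exceeds ``min_depth``.

    ``stat`` is ``"mean"`` (default) or ``"median"`` of the per-locus depths.
    """
    depth = tensor.depth()
    if stat == "mean":
        per_cell = depth.mean(axis=1)
    elif stat == "median":
        per_cell = np.median(depth, axis=1)
    else:
        raise ValueError(f"unknown depth statistic {stat!r}")
    keep = per_cell > min_depth
    if not keep.any():
        warnings.warn(
            f"no cell passes the depth filter ({stat} > {min_depth})",
            stacklevel=2,
        )
    return keep
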