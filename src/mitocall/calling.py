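"""Whole-dataset mutation-calling pipeline and precision metrics.

``MitoMutationModel`` wires the stages together for every locus of an
allele count tensor:

1. wild-type allele per locus (median rule, reference-free);
2. binomial-mixture EM classifier -> preselected WT reference cells;
3. beta-binomial null fitted by MLE on the reference cells;
4. per-cell inclusive lower-tail probability under the null,
   Benjamini-Hochberg adjusted *within each locus* across cells ->
   mutation q-value.

``fit()`` returns a ``MitoMutationResults`` holding the q-value table;
``call()`` on the results applies the reporting filters (q-value
threshold and minimum number of mutant cells per locus).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from statsmodels.stats.multitest import multipletests

from .betabinom import BetaBinomialModel, BetaBinomialResults
from .mixture import BinomialMixtureModel, select_wt_cells
from .tensor import AlleleCountTensor
from .wildtype import WildtypeProfile, call_wildtype, filter_cells_by_depth, wt_reads


@dataclass
class CallingConfig:
    """Default reporting thresholds for lineage-informative mutations."""

    q_threshold: float = 0.01
    min_mutant_cells: int = 5
    min_mean_depth: float = 5.0
    depth_stat: str = "mean"
    classifier_fdr: float = 0.05
    preselection: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.q_threshold <= 1):
            raise ValueError("q_threshold must be in (0, 1]")
        if self.min_mutant_cells < 1:
            raise ValueError("min_mutant_cells must be >= 1")
        if not (0 <= self.classifier_fdr <= 1):
            raise ValueError("classifier_fdr must be in [0, 1]")


def compute_qvalues(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up across cells of one locus.

    NaN entries (zero-depth or depth-filtered cells) are excluded from the
    adjustment and stay NaN.  q-values preserve the p-value ordering.
    """
    pvals = np.asarray(pvals, dtype=float)
    q = np.full_like(pvals, np.nan)
    finite = np.isfinite(pvals)
    if finite.any():
        q[finite] = multipletests(pvals[finite], method="fdr_bh")[1]
    return q


@dataclass
class LocusFit:
    """Per-locus fitting record kept alongside the p/q tables."""

    mixture_params: dict | None
    selection: np.ndarray | None  # WT reference-cell mask over all cells
    null: BetaBinomialResults | None
    ok: bool
    message: str = ""


def _fit_one_locus(
    m: np.ndarray,
    depth: np.ndarray,
    cell_mask: np.ndarray,
    config: CallingConfig,
) -> tuple[LocusFit, np.ndarray, np.ndarray]:
    """Fit classifier + null at one locus; returns (fit, pvals, qvals)."""
    n_cells = m.size
    pvals = np.full(n_cells, np.nan)
    usable = cell_mask & (depth > 0)
    if usable.sum() < 2:
        return (
            LocusFit(None, None, None, ok=False, message="fewer than 2 usable cells"),
            pvals,
            np.full(n_cells, np.nan),
        )
    try:
        mix = BinomialMixtureModel(m[usable], depth[usable]).fit()
        class_p = np.full(n_cells, np.nan)
        class_p[usable] = mix.tail_prob(m[usable], depth[usable])
        sel_usable, _ = select_wt_cells(
            class_p[usable],
            fdr_threshold=config.classifier_fdr,
            enabled=config.preselection,
        )
        selection = np.zeros(n_cells, dtype=bool)
        selection[np.flatnonzero(usable)[sel_usable]] = True

        null = BetaBinomialModel(m[selection], depth[selection]).fit()
        pvals[usable] = null.lower_tail(m[usable], depth[usable])
    except Exception as exc:  # a failed locus must not kill the pipeline
        return (
            LocusFit(None, None, None, ok=False, message=str(exc)),
            np.full(n_cells, np.nan),
            np.full(n_cells, np.nan),
        )
    qvals = compute_qvalues(pvals)
    return (
        LocusFit(mix.params, selection, null, ok=True),
        pvals,
        qvals,
    )


class MitoMutationModel:
    """Mutation-calling model over a full allele count tensor.

    Parameters
    ----------
    tensor : AlleleCountTensor
        Raw per-base counts.
    config : CallingConfig, optional
        Depth filter, classifier FDR and reporting thresholds.
    """

    def __init__(self, tensor: AlleleCountTensor, config: CallingConfig | None = None):
        self.tensor = tensor
        self.config = config or CallingConfig()

    def fit(self, n_jobs: int = 1) -> "MitoMutationResults":
        """Fit every locus; results are identical for any ``n_jobs``."""
        tensor = self.tensor
        config = self.config
        profile = call_wildtype(tensor)
        m, depth, _ = wt_reads(tensor, profile)
        cell_mask = filter_cells_by_depth(
            tensor, min_depth=config.min_mean_depth, stat=config.depth_stat
        )
        cols = [
            delayed(_fit_one_locus)(m[:, j], depth[:, j], cell_mask, config)
            for j in range(tensor.n_loci)
        ]
        fitted = Parallel(n_jobs=n_jobs)(cols)
        fits = [f for f, _, _ in fitted]
        pmat = np.column_stack([p for _, p, _ in fitted]) if fitted else np.empty((tensor.n_cells, 0))
        qmat = np.column_stack([q for _, _, q in fitted]) if fitted else np.empty((tensor.n_cells, 0))
        return MitoMutationResults(
            model=self,
            profile=profile,
            cell_mask=cell_mask,
            wt_counts=m,
            depth=depth,
            locus_fits=fits,
            pvalues=pmat,
            qvalues=qmat,
        )


@dataclass
class MitoMutationResults:
    """Fitted pipeline: per-locus nulls plus the per-cell p/q tables."""

    model: MitoMutationModel
    profile: WildtypeProfile
    cell_mask: np.ndarray
    wt_counts: np.ndarray
    depth: np.ndarray
    locus_fits: list[LocusFit]
    pvalues: np.ndarray  # (n_cells, n_loci), NaN = missing
    qvalues: np.ndarray

    @property
    def tensor(self) -> AlleleCountTensor:
        return self.model.tensor

    def qvalue_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.qvalues, index=self.tensor.cells, columns=self.tensor.locus_names
        )

    def af_frame(self) -> pd.DataFrame:
        with np.errstate(divide="ignore", invalid="ignore"):
            waf = np.where(self.depth > 0, self.wt_counts / np.maximum(self.depth, 1), np.nan)
        return pd.DataFrame(waf, index=self.tensor.cells, columns=self.tensor.locus_names)

    def call(self, config: CallingConfig | None = None) -> "MutationCalls":
        """Apply the reporting filters to the q-value table.

        A locus is reported as a mutation iff the number of cells with
        ``q < q_threshold`` is at least ``min_mutant_cells``.
        """
        config = config or self.model.config
        flags = np.zeros(self.qvalues.shape, dtype=bool)
        with np.errstate(invalid="ignore"):
            below = self.qvalues < config.q_threshold
        n_mutant = below.sum(axis=0)
        reported = n_mutant >= config.min_mutant_cells
        flags[:, reported] = below[:, reported]
        return MutationCalls(
            results=self,
            config=config,
            reported_loci=np.flatnonzero(reported),
            mutant_flags=flags,
        )

    def summary(self) -> str:
        ok = sum(f.ok for f in self.locus_fits)
        with np.errstate(invalid="ignore"):
            n_sig = int((self.qvalues < self.model.config.q_threshold).sum())
        lines = [
            "Mitochondrial mutation calling",
            "=" * 40,
            f"cells                 {self.tensor.n_cells}",
            f"cells passing depth   {int(self.cell_mask.sum())}"
            f" ({self.model.config.depth_stat} depth > {self.model.config.min_mean_depth})",
            f"loci                  {self.tensor.n_loci} ({ok} fitted)",
            f"cell x locus q < {self.model.config.q_threshold}: {n_sig}",
        ]
        return "\n".join(lines)


@dataclass
class MutationCalls:
    """Reported mutations and per-cell mutant flags after filtering."""

    results: MitoMutationResults
    config: CallingConfig
    reported_loci: np.ndarray
    mutant_flags: np.ndarray  # (n_cells, n_loci); True only at reported loci

    @property
    def mutations(self) -> list[str]:
        names = self.results.tensor.locus_names
        return [names[j] for j in self.reported_loci]

    def clone_sizes(self) -> pd.Series:
        """Number of flagged mutant cells per reported mutation."""
        return pd.Series(
            self.mutant_flags[:, self.reported_loci].sum(axis=0),
            index=self.mutations,
            name="clone_size",
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format calls table: (cell, locus, p, q, mutant)."""
        rows = []
        tensor = self.results.tensor
        for j in self.reported_loci:
            cells = np.flatnonzero(self.mutant_flags[:, j])
            for i in cells:
                rows.append(
                    (
                        tensor.cells[i],
                        tensor.locus_names[j],
                        self.results.pvalues[i, j],
                        self.results.qvalues[i, j],
                        True,
                    )
                )
        return pd.DataFrame(rows, columns=["cell", "locus", "p", "q", "mutant"])

    def binary_matrix(self) -> pd.DataFrame:
        """Mutations x cells 0/1 matrix of flagged mutant cells."""
        return pd.DataFrame(
            self.mutant_flags[:, self.reported_loci].T.astype(int),
            index=self.mutations,
            columns=self.results.tensor.cells,
        )


# ----------------------------------------------------------------------
# precision metrics against external cell labels
# ----------------------------------------------------------------------

def mutation_precision(calls: MutationCalls, in_target: dict | pd.Series) -> pd.DataFrame:
    """Per-mutation precision against a ground-truth cell subset.

    For mutation *i* with ``n_i`` mutant cells inside the target subset and
    ``m_i`` mutant cells in total, the precision is ``y_i = n_i / m_i``;
    mutations with no mutant cell in the target subset (n_i = 0) are
    excluded, as are mutations with ``m_i = 0``.  The overall precision is
    the pooled ratio ``sum(n_i) / sum(m_i)`` (not the mean of the y_i);
    it is attached as frame attribute ``overall``.
    """
    member = pd.Series(in_target).astype(bool)
    tensor = calls.results.tensor
    mask = member.reindex(tensor.cells).fillna(False).to_numpy()
    rows = []
    for j in calls.reported_loci:
        flags = calls.mutant_flags[:, j]
        m_i = int(flags.sum())
        if m_i == 0:
            continue
        n_i = int((flags & mask).sum())
        if n_i == 0:
            continue
        rows.append((tensor.locus_names[j], n_i, m_i, n_i / m_i))
    out = pd.DataFrame(rows, columns=["mutation", "n_target", "n_mutant", "precision"])
    out.attrs["overall"] = (
        out["n_target"].sum() / out["n_mutant"].sum() if len(out) else np.nan
    )
    return out


def lineage_precision(calls: MutationCalls, lineage: dict | pd.Series) -> pd.DataFrame:
    """Dominant-lineage precision for binary lineage labels.

    With ``n_i`` and ``m_i`` mutant cells in the two lineages, the
    precision is ``max(n_i, m_i) / (n_i + m_i)``, a rational number in
    [0.5, 1]; mutations with no called cells are excluded.
    """
    lab = pd.Series(lineage)
    levels = sorted(lab.unique())
    if len(levels) != 2:
        raise ValueError(f"lineage labels must be binary, got {levels}")
    tensor = calls.results.tensor
    side = lab.reindex(tensor.cells).to_numpy()
    rows = []
    for j in calls.reported_loci:
        flags = calls.mutant_flags[:, j]
        n_i = int((flags & (side == levels[0])).sum())
        m_i = int((flags & (side == levels[1])).sum())
        if n_i + m_i == 0:
            continue
        rows.append(
            (tensor.locus_names[j], n_i, m_i, max(n_i, m_i) / (n_i + m_i))
        )
    return pd.DataFrame(
        rows, columns=["mutation", f"n_{levels[0]}", f"n_{levels[1]}", "precision"]
    )
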