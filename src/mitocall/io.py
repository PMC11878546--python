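"""Count-matrix dialect readers, the HDF5 working store, and exports.

Two upstream dialects are supported:

* mgatk-style per-base tables: one gzipped CSV per base with
  (position, barcode, forward count, reverse count) rows plus an optional
  coverage table; forward and reverse strands are summed on import.
* cellSNP-lite-style sparse matrices: AD/DP Matrix Market pairs with a
  VCF-style variant list and a barcode list; per variant the REF base
  receives DP - AD reads and the ALT base receives AD.

All raw and intermediate results can be persisted in one hierarchical
HDF5 file per dataset (groups /counts, /wildtype, /bm_fit, /bb_fit,
/pvals, /calls), so reruns with new thresholds reuse the fits.
"""

from __future__ import annotations

import gzip
import logging
import os
import warnings
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .betabinom import BetaBinomialResults
from .tensor import BASE_INDEX, BASES, AlleleCountTensor

logger = logging.getLogger(__name__)

MGATK_COLUMNS = ("position", "barcode", "fwd", "rev")


# ----------------------------------------------------------------------
# mgatk dialect
# ----------------------------------------------------------------------

def _read_base_table(path: Path, columns: tuple[str, ...]) -> pd.DataFrame:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"no records in {path}")
    rows = []
    for lineno, ln in enumerate(lines, start=1):
        parts = ln.split(",")
        if len(parts) != len(columns):
            raise ValueError(
                f"{path}: malformed row at line {lineno}: "
                f"expected {len(columns)} fields, got {len(parts)}"
            )
        rec = dict(zip(columns, parts))
        try:
            rec["position"] = int(rec["position"])
            rec["fwd"] = int(rec["fwd"])
            rec["rev"] = int(rec["rev"])
        except ValueError as exc:
            raise ValueError(f"{path}: malformed row at line {lineno}: {exc}") from exc
        rows.append(rec)
    return pd.DataFrame(rows)


def read_mgatk(
    directory: str | os.PathLike,
    whitelist: list[str] | None = None,
    columns: tuple[str, ...] = MGATK_COLUMNS,
    contig: str = "chrM",
) -> AlleleCountTensor:
    """Read mgatk-style per-base count tables into an allele count tensor.

    ``columns`` gives the CSV column order (upstream versions differ);
    it must contain "position", "barcode", "fwd" and "rev".  Barcodes not
    in the whitelist are dropped (count logged); loci with zero total
    count remain but are flagged on the tensor.
    """
    directory = Path(directory)
    if set(columns) != set(MGATK_COLUMNS):
        raise ValueError(f"columns must be a permutation of {MGATK_COLUMNS}")
    tables = {}
    for base in BASES:
        candidates = [directory / f"{base}.txt.gz", directory / f"{base}.txt"]
        path = next((p for p in candidates if p.exists()), None)
        if path is None:
            raise FileNotFoundError(
                f"missing per-base count file for base {base}: expected {candidates[0]}"
            )
        tables[base] = _read_base_table(path, columns)

    positions = sorted({int(p) for t in tables.values() for p in t["position"]})
    seen_barcodes = sorted({b for t in tables.values() for b in t["barcode"]})
    if whitelist is not None:
        dropped = [b for b in seen_barcodes if b not in set(whitelist)]
        if dropped:
            logger.info("dropping %d barcodes absent from whitelist", len(dropped))
        cells = list(whitelist)
    else:
        cells = seen_barcodes

    pos_idx = {p: j for j, p in enumerate(positions)}
    cell_idx = {b: i for i, b in enumerate(cells)}
    counts = np.zeros((4, len(cells), len(positions)), dtype=np.int64)
    for base, table in tables.items():
        x = BASE_INDEX[base]
        for _, row in table.iterrows():
            i = cell_idx.get(row["barcode"])
            if i is None:
                continue
            counts[x, i, pos_idx[row["position"]]] += row["fwd"] + row["rev"]
    return AlleleCountTensor(
        cells=cells,
        loci=[(contig, p) for p in positions],
        counts=counts,
    )


# ----------------------------------------------------------------------
# cellSNP-lite dialect
# ----------------------------------------------------------------------

def _read_variant_list(path: str | os.PathLike) -> pd.DataFrame:
    rows = []
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for ln in fh:
            if not ln.strip() or ln.startswith("#"):
                continue
            parts = ln.split()
            if len(parts) < 4:
                raise ValueError(f"variant row needs >= 4 fields: {ln!r}")
            # VCF layout CHROM POS [ID] REF ALT: detect the optional ID column
            if len(parts) >= 5 and len(parts[3]) == 1 and parts[3] in "ACGTN." and parts[2] == ".":
                chrom, pos, ref, alt = parts[0], parts[1], parts[3], parts[4]
            else:
                chrom, pos, ref, alt = parts[0], parts[1], parts[2], parts[3]
            rows.append((chrom, int(pos), ref.upper(), alt.upper()))
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])


def read_cellsnp(
    ad_matrix: str | os.PathLike,
    dp_matrix: str | os.PathLike,
    variants: str | os.PathLike,
    barcodes: str | os.PathLike,
) -> AlleleCountTensor:
    """Read cellSNP-lite AD/DP sparse matrices into an allele count tensor.

    AD and DP are variants x cells Matrix Market files of identical shape;
    per variant row, the REF base gets DP - AD reads and the ALT base
    gets AD.  Variants with non-ACGT ref or alt are skipped with a
    warning; AD > DP anywhere is a hard error.
    """
    ad = sparse.csr_matrix(spio.mmread(str(ad_matrix)))
    dp = sparse.csr_matrix(spio.mmread(str(dp_matrix)))
    if ad.shape != dp.shape:
        raise ValueError(f"AD shape {ad.shape} != DP shape {dp.shape}")
    if (ad > dp).nnz > 0:
        raise ValueError("AD exceeds DP for at least one (variant, cell)")
    var = _read_variant_list(variants)
    if len(var) != ad.shape[0]:
        raise ValueError(
            f"variant list has {len(var)} rows but matrices have {ad.shape[0]}"
        )
    with open(barcodes) as fh:
        cells = [ln.strip() for ln in fh if ln.strip()]
    if len(cells) != ad.shape[1]:
        raise ValueError(
            f"barcode list has {len(cells)} entries but matrices have {ad.shape[1]} columns"
        )

    keep = []
    for r, row in var.iterrows():
        if row["ref"] in BASE_INDEX and row["alt"] in BASE_INDEX:
            keep.append(r)
        else:
            warnings.warn(
                f"skipping variant {row['chrom']}:{row['pos']} with non-ACGT alleles "
                f"{row['ref']}>{row['alt']}",
                stacklevel=2,
            )
    var = var.loc[keep]
    if var.duplicated(subset=["chrom", "pos"]).any():
        raise ValueError("duplicate positions in variant list (dialect is biallelic)")

    loci = [(c, int(p)) for c, p in zip(var["chrom"], var["pos"])]
    counts = np.zeros((4, len(cells), len(var)), dtype=np.int64)
    ad_d = np.asarray(ad.todense()).astype(np.int64)
    dp_d = np.asarray(dp.todense()).astype(np.int64)
    for j, r in enumerate(var.index):
        ref_x = BASE_INDEX[var.at[r, "ref"]]
        alt_x = BASE_INDEX[var.at[r, "alt"]]
        counts[ref_x, :, j] = dp_d[r] - ad_d[r]
        counts[alt_x, :, j] += ad_d[r]
    return AlleleCountTensor(cells=cells, loci=loci, counts=counts)


# ----------------------------------------------------------------------
# fixture writers (inverse of the readers)
# ----------------------------------------------------------------------

def write_mgatk(
    tensor: AlleleCountTensor, out_dir: str | os.PathLike, gzipped: bool = True
) -> None:
    """Write a tensor in the mgatk per-base dialect.

    Strand counts are split 50/50 with the remainder on the forward strand.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    depth = tensor.depth()
    for base in BASES:
        x = BASE_INDEX[base]
        suffix = ".txt.gz" if gzipped else ".txt"
        opener = gzip.open if gzipped else open
        with opener(out / f"{base}{suffix}", "wt") as fh:
            for i, cell in enumerate(tensor.cells):
                for j, (_, pos) in enumerate(tensor.loci):
                    c = int(tensor.counts[x, i, j])
                    if c == 0:
                        continue
                    rev = c // 2
                    fwd = c - rev
                    fh.write(f"{pos},{cell},{fwd},{rev}\n")
    opener = gzip.open if gzipped else open
    suffix = ".txt.gz" if gzipped else ".txt"
    with opener(out / f"coverage{suffix}", "wt") as fh:
        for i, cell in enumerate(tensor.cells):
            for j, (_, pos) in enumerate(tensor.loci):
                if depth[i, j] > 0:
                    fh.write(f"{pos},{cell},{int(depth[i, j])}\n")


def write_cellsnp(tensor: AlleleCountTensor, out_dir: str | os.PathLike) -> None:
    """Write a biallelic tensor in the cellSNP-lite AD/DP dialect.

    The REF base per locus is the one with the largest total count; exactly
    one other base may carry reads (the dialect is biallelic), otherwise
    this raises.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    totals = tensor.counts.sum(axis=1)  # (4, n_loci)
    depth = tensor.depth()
    n_cells, n_loci = tensor.n_cells, tensor.n_loci
    ad = np.zeros((n_loci, n_cells), dtype=np.int64)
    refs, alts = [], []
    for j in range(n_loci):
        nonzero = np.flatnonzero(totals[:, j] > 0)
        if len(nonzero) > 2:
            raise ValueError(
                f"locus {tensor.locus_names[j]} carries {len(nonzero)} bases; "
                "the cellSNP dialect is biallelic"
            )
        ref_x = int(np.argmax(totals[:, j]))
        alt_candidates = [x for x in nonzero if x != ref_x]
        alt_x = alt_candidates[0] if alt_candidates else (ref_x + 1) % 4
        refs.append(BASES[ref_x])
        alts.append(BASES[alt_x])
        ad[j] = tensor.counts[alt_x, :, j]
    spio.mmwrite(str(out / "cellSNP.tag.AD.mtx"), sparse.coo_matrix(ad))
    spio.mmwrite(str(out / "cellSNP.tag.DP.mtx"), sparse.coo_matrix(depth.T))
    with open(out / "cellSNP.base.vcf", "w") as fh:
        fh.write("#CHROM\tPOS\tID\tREF\tALT\n")
        for j, (contig, pos) in enumerate(tensor.loci):
            fh.write(f"{contig}\t{pos}\t.\t{refs[j]}\t{alts[j]}\n")
    with open(out / "cellSNP.samples.tsv", "w") as fh:
        fh.write("\n".join(tensor.cells) + "\n")


def write_fixture(
    tensor: AlleleCountTensor, dialect: str, out_dir: str | os.PathLike
) -> None:
    """Write ``tensor`` in the requested upstream dialect (mgatk or cellsnp)."""
    if dialect == "mgatk":
        write_mgatk(tensor, out_dir)
    elif dialect == "cellsnp":
        write_cellsnp(tensor, out_dir)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ----------------------------------------------------------------------
# hierarchical working store
# ----------------------------------------------------------------------

_STR = h5py.string_dtype(encoding="utf-8")


class MitoStore:
    """One HDF5 file per dataset; each pipeline stage writes its own group.

    Groups: /counts (raw tensor), /wildtype, /bm_fit, /bb_fit, /pvals,
    /calls.  Stage parameters are stored as group attributes so reruns
    with new thresholds can reuse persisted fits.
    """

    def __init__(self, path: str | os.PathLike):
        self.path = Path(path)

    # -- raw counts ----------------------------------------------------
    def write_tensor(self, tensor: AlleleCountTensor) -> None:
        with h5py.File(self.path, "a") as f:
            if "counts" in f:
                del f["counts"]
            g = f.create_group("counts")
            g.create_dataset("cells", data=np.array(tensor.cells, dtype=_STR))
            g.create_dataset(
                "contigs", data=np.array([c for c, _ in tensor.loci], dtype=_STR)
            )
            g.create_dataset(
                "positions", data=np.array([p for _, p in tensor.loci], dtype=np.int64)
            )
            g.create_dataset("counts", data=tensor.counts, compression="gzip")

    def read_tensor(self) -> AlleleCountTensor:
        with h5py.File(self.path, "r") as f:
            self._require(f, "counts", "import")
            g = f["counts"]
            cells = [c.decode() for c in g["cells"][...]]
            contigs = [c.decode() for c in g["contigs"][...]]
            positions = g["positions"][...]
            counts = g["counts"][...]
        return AlleleCountTensor(
            cells=cells,
            loci=list(zip(contigs, (int(p) for p in positions))),
            counts=counts,
        )

    # -- fitted pipeline -----------------------------------------------
    def write_results(self, results) -> None:
        """Persist wildtype profile, per-locus fits and the p/q tables."""
        from .calling import MitoMutationResults  # local import avoids cycle

        assert isinstance(results, MitoMutationResults)
        with h5py.File(self.path, "a") as f:
            for name in ("wildtype", "bm_fit", "bb_fit", "pvals"):
                if name in f:
                    del f[name]
            g = f.create_group("wildtype")
            g.create_dataset("wt_base", data=results.profile.wt_base)
            g.create_dataset("medians", data=results.profile.medians)
            g.create_dataset("tie", data=results.profile.tie)

            n_loci = len(results.locus_fits)
            gm = f.create_group("bm_fit")
            params = np.full((n_loci, 4), np.nan)
            sel = np.zeros((results.tensor.n_cells, n_loci), dtype=bool)
            for j, fit in enumerate(results.locus_fits):
                if fit.ok and fit.mixture_params is not None:
                    params[j] = [
                        fit.mixture_params[k]
                        for k in ("pi_wt", "pi_mut", "theta_wt", "theta_mut")
                    ]
                    sel[:, j] = fit.selection
            gm.create_dataset("params", data=params)
            gm.attrs["param_names"] = ["pi_wt", "pi_mut", "theta_wt", "theta_mut"]
            gm.create_dataset("selection", data=sel, compression="gzip")
            gm.attrs["classifier_fdr"] = results.model.config.classifier_fdr
            gm.attrs["preselection"] = results.model.config.preselection

            gb = f.create_group("bb_fit")
            ab = np.full((n_loci, 3), np.nan)
            ok = np.zeros(n_loci, dtype=bool)
            for j, fit in enumerate(results.locus_fits):
                if fit.ok and fit.null is not None:
                    ab[j] = [fit.null.alpha, fit.null.beta, fit.null.loglike_]
                    ok[j] = True
            gb.create_dataset("alpha_beta_loglik", data=ab)
            gb.create_dataset("ok", data=ok)

            gp = f.create_group("pvals")
            gp.create_dataset("p", data=results.pvalues, compression="gzip")
            gp.create_dataset("q", data=results.qvalues, compression="gzip")
            gp.create_dataset("cell_mask", data=results.cell_mask)
            gp.attrs["min_mean_depth"] = results.model.config.min_mean_depth
            gp.attrs["depth_stat"] = results.model.config.depth_stat

    def read_fits(self) -> list[BetaBinomialResults | None]:
        """Per-locus beta-binomial fits, without refitting."""
        with h5py.File(self.path, "r") as f:
            self._require(f, "bb_fit", "fit")
            ab = f["bb_fit/alpha_beta_loglik"][...]
            ok = f["bb_fit/ok"][...]
        fits: list[BetaBinomialResults | None] = []
        for j in range(len(ok)):
            if ok[j]:
                fits.append(
                    BetaBinomialResults(
                        model=None,
                        alpha=float(ab[j, 0]),
                        beta=float(ab[j, 1]),
                        loglike_=float(ab[j, 2]),
                        converged=True,
                        n_cells_used=0,
                    )
                )
            else:
                fits.append(None)
        return fits

    def read_qvalues(self) -> pd.DataFrame:
        tensor = self.read_tensor()
        with h5py.File(self.path, "r") as f:
            self._require(f, "pvals", "fit")
            q = f["pvals/q"][...]
        return pd.DataFrame(q, index=tensor.cells, columns=tensor.locus_names)

    def write_calls(self, calls) -> None:
        table = calls.to_frame()
        with h5py.File(self.path, "a") as f:
            if "calls" in f:
                del f["calls"]
            g = f.create_group("calls")
            g.create_dataset("cell", data=np.array(list(table["cell"]), dtype=_STR))
            g.create_dataset("locus", data=np.array(list(table["locus"]), dtype=_STR))
            g.create_dataset("p", data=table["p"].to_numpy(dtype=float))
            g.create_dataset("q", data=table["q"].to_numpy(dtype=float))
            g.attrs["q_threshold"] = calls.config.q_threshold
            g.attrs["min_mutant_cells"] = calls.config.min_mutant_cells

    def read_calls(self) -> pd.DataFrame:
        with h5py.File(self.path, "r") as f:
            self._require(f, "calls", "call")
            g = f["calls"]
            table = pd.DataFrame(
                {
                    "cell": [c.decode() for c in g["cell"][...]],
                    "locus": [c.decode() for c in g["locus"][...]],
                    "p": g["p"][...],
                    "q": g["q"][...],
                }
            )
        table["mutant"] = True
        return table

    @staticmethod
    def _require(f: h5py.File, group: str, stage: str) -> None:
        if group not in f:
            raise KeyError(
                f"store has no /{group} group; run the '{stage}' pipeline step first"
            )


def export_results(store: MitoStore, what: str, out: str | os.PathLike) -> None:
    """Export a store stage as TSV (loci as rows, cells as columns).

    ``what`` is one of ``qvalues``, ``af`` or ``calls``.  Missing values
    are emitted as empty fields.
    """
    if what == "qvalues":
        q = store.read_qvalues()
        q.T.to_csv(out, sep="\t", na_rep="")
    elif what == "af":
        tensor = store.read_tensor()
        from .wildtype import call_wildtype, wt_reads

        profile = call_wildtype(tensor)
        _, depth, waf = wt_reads(tensor, profile)
        pd.DataFrame(
            waf.T, index=tensor.locus_names, columns=tensor.cells
        ).to_csv(out, sep="\t", na_rep="")
    elif what == "calls":
        store.read_calls().to_csv(out, sep="\t", index=False)
    else:
        raise ValueError(f"unknown export {what!r} (use qvalues, af or calls)")
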