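"""Synthetic data generation and the multi-allele collision simulation.

Two generators live here:

* ``collision_probability`` — Monte-Carlo estimate of the chance that a
  locus on a 16-kb mitochondrial genome receives two or more distinct
  mutant alleles when a handful of mutations are drawn uniformly from the
  48,000 possible single-nucleotide events (16,000 loci x 3 alternative
  bases).  A small value justifies the single-mutation-per-locus
  assumption of the calling model.

* ``simulate_dataset`` — allele count tensors with the statistical
  structure the calling model assumes: per cell and locus a WT
  heteroplasmy drawn from Beta(theta*s, (1-theta)*s), a depth drawn from a
  rounded log-normal, a WT read count drawn binomially, and the remaining
  reads assigned to one fixed alternative base.  Clones of planted mutant
  cells carry a lower WT heteroplasmy at their planted locus.  Ground
  truth is returned alongside the counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tensor import BASES, AlleleCountTensor

MT_GENOME_LENGTH = 16_000
ALT_BASES_PER_LOCUS = 3


@dataclass
class CollisionSpec:
    """Design of the multi-allele collision simulation."""

    n_mutations: int = 50
    repetitions: int = 100_000
    genome_length: int = MT_GENOME_LENGTH
    alt_bases_per_locus: int = ALT_BASES_PER_LOCUS
    seed: int = 0

    @property
    def event_count(self) -> int:
        """All possible single-nucleotide mutation events."""
        return self.genome_length * self.alt_bases_per_locus


def _sample_distinct(rng: np.random.Generator, n_rows: int, k: int, n_events: int) -> np.ndarray:
    """(n_rows, k) events, each row uniform without replacement.

    Rows are drawn iid and rows containing duplicates are redrawn, which is
    exact rejection sampling of the without-replacement distribution and
    avoids an O(n_events) shuffle per row.
    """
    out = rng.integers(0, n_events, size=(n_rows, k))
    while True:
        s = np.sort(out, axis=1)
        bad = (s[:, 1:] == s[:, :-1]).any(axis=1)
        if not bad.any():
            return out
        out[bad] = rng.integers(0, n_events, size=(int(bad.sum()), k))


def collision_probability(spec: CollisionSpec) -> float:
    """Probability that a locus carries >= 2 distinct sampled mutant alleles.

    Per repetition, ``n_mutations`` events are sampled without replacement
    from all ``genome_length * alt_bases_per_locus`` events; a collision is
    a locus receiving two or more (necessarily distinct) alternative
    alleles.  The estimate is the total number of collision loci across
    repetitions divided by the total number of sampled mutations — the
    aggregate and per-repetition ratios coincide since every repetition
    samples the same number of mutations.

    The closed-form pair-collision expectation is (k - 1) / (E - 1).
    """
    k, R, E = spec.n_mutations, spec.repetitions, spec.event_count
    if k > E:
        raise ValueError(f"cannot sample {k} events from {E} without replacement")
    if k < 2:
        return 0.0
    rng = np.random.default_rng(spec.seed)
    total = 0
    # chunked so the event matrix stays small
    chunk = 20_000
    done = 0
    while done < R:
        rows = min(chunk, R - done)
        events = _sample_distinct(rng, rows, k, E)
        loci = np.sort(events // spec.alt_bases_per_locus, axis=1)
        eq = loci[:, 1:] == loci[:, :-1]
        # count loci with multiplicity >= 2: run starts among equal-adjacent pairs
        run_start = eq & ~np.pad(eq[:, :-1], ((0, 0), (1, 0)), constant_values=False)
        total += int(run_start.sum())
        done += rows
    return total / (k * R)


@dataclass
class CloneSimSpec:
    """Design of a synthetic single-cell mtDNA allele count dataset.

    Defaults reflect a clean scATAC-style locus: WT heteroplasmy 0.999
    with precision s = alpha + beta = 1000 (dispersion phi ~ 1e-3, i.e.
    sequencing noise dominates cell-to-cell heteroplasmy variation),
    depths log-normal(log-mean 2, log-sd 1) rounded to the nearest
    integer (zeros permitted and treated as missing downstream).
    """

    n_cells: int = 200
    n_loci: int = 10
    wt_theta: float = 0.999
    precision: float = 1000.0
    depth_log_mean: float = 2.0
    depth_log_sd: float = 1.0
    # planted mutations: locus index -> (list of mutant cell indices,
    #                                    mutant-allele heteroplasmy)
    planted: dict[int, tuple[list[int], float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.wt_theta <= 1.0):
            raise ValueError("wt_theta must be in (0, 1]")
        if self.precision <= 0:
            raise ValueError("precision must be positive")
        for j, (cells, h) in self.planted.items():
            if not (0 <= j < self.n_loci):
                raise ValueError(f"planted locus {j} out of range")
            if not (0.0 <= h <= 1.0):
                raise ValueError("mutant heteroplasmy must be in [0, 1]")
            if any(c < 0 or c >= self.n_cells for c in cells):
                raise ValueError("planted cell index out of range")


def simulate_dataset(
    spec: CloneSimSpec,
) -> tuple[AlleleCountTensor, dict]:
    """Generate an allele count tensor plus ground-truth tables.

    Per cell x locus: heteroplasmy Pi ~ Beta(theta*s, (1-theta)*s) with the
    cell's effective theta (lowered to 1 - h at a planted locus for planted
    mutant cells), depth N ~ round(logNormal), WT count ~ Binomial(N, Pi),
    remainder assigned to one fixed alternative base per locus.  WT bases
    cycle A,C,G,T over loci; the alternative base is the next base over.
    """
    rng = np.random.default_rng(spec.seed)
    S, K = spec.n_cells, spec.n_loci
    s = spec.precision

    theta = np.full((S, K), spec.wt_theta)
    truth_mutant = np.zeros((S, K), dtype=bool)
    for j, (cells, h) in spec.planted.items():
        idx = np.asarray(cells, dtype=int)
        theta[idx, j] = 1.0 - h
        truth_mutant[idx, j] = True

    depth = np.rint(rng.lognormal(spec.depth_log_mean, spec.depth_log_sd, size=(S, K))).astype(
        np.int64
    )
    depth = np.maximum(depth, 0)
    # Beta(theta*s, (1-theta)*s); theta=1 would give Beta(s, 0) -> point mass at 1
    pi = np.where(
        theta >= 1.0,
        1.0,
        rng.beta(np.maximum(theta * s, 1e-12), np.maximum((1.0 - theta) * s, 1e-12)),
    )
    m = rng.binomial(depth, pi)

    wt_base = np.arange(K) % 4
    alt_base = (wt_base + 1) % 4
    counts = np.zeros((4, S, K), dtype=np.int64)
    for j in range(K):
        counts[wt_base[j], :, j] = m[:, j]
        counts[alt_base[j], :, j] += depth[:, j] - m[:, j]

    cells = [f"BC{i:05d}" for i in range(S)]
    loci = [("chrM", 100 + j) for j in range(K)]
    tensor = AlleleCountTensor(cells=cells, loci=loci, counts=counts)
    truth = {
        "mutant": truth_mutant,
        "wt_base": np.array([BASES[b] for b in wt_base]),
        "alt_base": np.array([BASES[b] for b in alt_base]),
        "theta": theta,
        "depth": depth,
        "planted_loci": sorted(spec.planted),
    }
    return tensor, truth


# fixture writers live with the dialect readers; re-exported here because
# generating a dataset and serializing it are used together
from .io import write_fixture  # noqa: E402,F401
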