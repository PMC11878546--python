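"""Shared builders for call-table tests."""

import numpy as np

from mitocall import AlleleCountTensor
from mitocall.calling import (
    CallingConfig,
    MitoMutationModel,
    MitoMutationResults,
    MutationCalls,
)


def make_calls(cells, flag_spec):
    """MutationCalls with given per-mutation flagged cell index tuples."""
    n = len(cells)
    loci = [("chrM", 100 + j) for j in range(len(flag_spec))]
    counts = np.ones((4, n, len(loci)), dtype=int)
    tensor = AlleleCountTensor(list(cells), loci, counts)
    flags = np.zeros((n, len(loci)), dtype=bool)
    for j, members in enumerate(flag_spec):
        flags[list(members), j] = True
    results = MitoMutationResults(
        model=MitoMutationModel(tensor),
        profile=None,
        cell_mask=np.ones(n, bool),
        wt_counts=np.ones((n, len(loci))),
        depth=np.ones((n, len(loci))),
        locus_fits=[],
        pvalues=np.zeros((n, len(loci))),
        qvalues=np.zeros((n, len(loci))),
    )
    return MutationCalls(
        results=results,
        config=CallingConfig(),
        reported_loci=np.arange(len(loci)),
        mutant_flags=flags,
    )
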