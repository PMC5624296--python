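"""Independent brute-force oracles shared across test modules.

Deliberately naive: all-pairs scans and exhaustive enumeration, kept free of
any hgtenrich internals so they can disagree with the implementation.
"""
import itertools

import numpy as np
from scipy.stats import rankdata


def brute_force_rbh(rows, max_evalue=1e-10, min_query_cov=0.5):
    """Reciprocal best hits by scanning every hit: filter, best-by-tuple, mutual."""
    kept = [r for r in rows
            if r["evalue"] <= max_evalue
            and r["align_len"] > min_query_cov * r["query_len"]
            and r["query_genome"] != r["subject_genome"]]
    best = {}
    for r in kept:
        key = (r["query_id"], r["subject_genome"])
        rank = (-r["bitscore"], r["evalue"], r["subject_id"])
        if key not in best or rank < best[key][0]:
            best[key] = (rank, r)
    pairs = set()
    for (q, sg), (_, r) in best.items():
        back = best.get((r["subject_id"], r["query_genome"]))
        if back is not None and back[1]["subject_id"] == q:
            pairs.add(frozenset((q, r["subject_id"])))
    return pairs


def exhaustive_anosim(values, labels):
    """ANOSIM R plus the exact p over every distinct label permutation."""
    labels = np.asarray(labels)
    n = len(labels)
    iu = np.triu_indices(n, 1)
    ranks = rankdata(values[iu])
    denom = len(ranks) / 2

    def r_of(lab):
        lab = np.asarray(lab)
        same = lab[iu[0]] == lab[iu[1]]
        return (ranks[~same].mean() - ranks[same].mean()) / denom

    observed = r_of(labels)
    stats = [r_of(p) for p in set(itertools.permutations(labels))]
    p = float(np.mean([s >= observed - 1e-12 for s in stats]))
    return observed, p
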