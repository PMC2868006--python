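"""Independent oracles shared by the test modules."""

import numpy as np
from sympy.utilities.iterables import multiset_permutations

from triadsig.encoding import N_TRIADS, count_triads, map_to_groups


def exact_significance(sequence: str) -> np.ndarray:
    """Exact Pr(X_i < o_i) by enumerating all distinct permutations.

    Under a uniform shuffle every distinct arrangement of the residue
    multiset is equally likely, so the exact probability is the fraction
    of distinct arrangements with a strictly smaller triad count.
    """
    gs = map_to_groups(sequence)
    o = count_triads(gs)
    counts = enumerate_null_counts(tuple(gs.symbols))
    return (counts < o).mean(axis=0)


def enumerate_null_counts(symbols: tuple[int, ...]) -> np.ndarray:
    """(n_arrangements, 343) triad counts over all distinct arrangements."""
    rows = [count_triads(np.array(perm, dtype=np.int8))
            for perm in multiset_permutations(list(symbols))]
    return np.array(rows)


def naive_kde_density(samples, bandwidths, v, kt=None) -> float:
    """Double-loop Gaussian KDE evaluation, optionally kt-truncated."""
    samples = np.asarray(samples, float)
    v = np.asarray(v, float)
    n, m = samples.shape
    d = np.array([np.sqrt(np.sum((v - s) ** 2)) for s in samples])
    order = np.argsort(d, kind="stable")
    keep = order if kt is None else order[:kt]
    total = 0.0
    for i in keep:
        sigma = bandwidths[i]
        total += (
            (2 * np.pi) ** (-m / 2)
            * sigma ** (-m)
            * np.exp(-d[i] ** 2 / (2 * sigma**2))
        )
    return total / n
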