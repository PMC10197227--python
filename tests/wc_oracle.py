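"""Independent scalar implementation of the Weir-Cockerham (1984) theta.

Written directly from the per-locus variance-component definitions with
plain Python loops, as a cross-check oracle for the vectorised estimator.
Dosages are 0/1/2 with None for missing.
"""

from __future__ import annotations

import math


def locus_components(pop_dosages: list[list[int | None]]):
    """Return (a, b, c) for one locus, or None if not computable."""
    r = len(pop_dosages)
    n = []
    p = []
    h = []
    for dos in pop_dosages:
        called = [d for d in dos if d is not None]
        if not called:
            return None
        n_i = len(called)
        p_i = sum(called) / (2.0 * n_i)
        h_i = sum(1 for d in called if d == 1) / n_i
        n.append(n_i)
        p.append(p_i)
        h.append(h_i)
    nbar = sum(n) / r
    if nbar <= 1:
        return None
    nc = (r * nbar - sum(x * x for x in n) / (r * nbar)) / (r - 1)
    if nc <= 0:
        return None
    pbar = sum(n[i] * p[i] for i in range(r)) / (r * nbar)
    s2 = sum(n[i] * (p[i] - pbar) ** 2 for i in range(r)) / ((r - 1) * nbar)
    hbar = sum(n[i] * h[i] for i in range(r)) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2.0
    return a, b, c


def multilocus_theta_bruteforce(pop_dosages_by_locus):
    """Ratio-of-sums theta over loci.

    ``pop_dosages_by_locus``: per locus, a list (one entry per population)
    of per-individual dosage lists.
    """
    num = 0.0
    den = 0.0
    for locus in pop_dosages_by_locus:
        comp = locus_components(locus)
        if comp is None:
            continue
        a, b, c = comp
        if a + b + c == 0 or not math.isfinite(a + b + c):
            continue
        num += a
        den += a + b + c
    if den == 0:
        raise ValueError("no usable loci")
    return num / den
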