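"""Independent brute-force oracles used across the test suite.

These deliberately avoid the package's interval algebra and statistics code
paths: interval operations are checked against per-base boolean masks on toy
chromosomes, enhancer assignment against an all-pairs scan, and the Fisher
test against exact fixed-margin enumeration with Fraction arithmetic.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np

from odontoprio.genomic_core import GenomicInterval

TOY_CHROMS = ("chrA", "chrB")
TOY_LEN = 10_000


def masks_of(ivs, chroms=TOY_CHROMS, length=TOY_LEN):
    masks = {c: np.zeros(length, dtype=bool) for c in chroms}
    for iv in ivs:
        masks[iv.chrom][iv.start : iv.end] = True
    return masks


def intervals_of(masks):
    out = []
    for chrom in sorted(masks):
        m = masks[chrom]
        if not m.any():
            continue
        padded = np.concatenate(([False], m, [False]))
        diff = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)
        out.extend(GenomicInterval(chrom, int(s), int(e)) for s, e in zip(starts, ends))
    return out


def random_intervals(rng, n, chroms=TOY_CHROMS, length=TOY_LEN, max_len=500):
    ivs = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, length - 1))
        end = start + 1 + int(rng.integers(0, min(max_len, length - start - 1) + 1))
        ivs.append(GenomicInterval(chrom, start, min(end, length)))
    return ivs


def allpairs_assignment_counts(enh_ivs, domains):
    """O(n*m) overlap scan of enhancers against extended domains."""
    counts: dict[str, int] = {}
    for iv in enh_ivs:
        for dom in domains:
            e = dom.extended
            if e.chrom == iv.chrom and min(e.end, iv.end) - max(e.start, iv.start) >= 1:
                counts[dom.gene_id] = counts.get(dom.gene_id, 0) + 1
    return counts


_FACT = [math.factorial(i) for i in range(121)]


def fisher_exact_enumeration(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-tailed Fisher p by exhaustive fixed-margin enumeration with exact
    rational arithmetic (factorial formula, independent of math.comb)."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    kmin, kmax = max(0, c1 - r2), min(r1, c1)
    pmf = [
        Fraction(
            _FACT[r1] * _FACT[r2] * _FACT[c1] * _FACT[n - c1],
            _FACT[n] * _FACT[k] * _FACT[c1 - k] * _FACT[r1 - k] * _FACT[r2 - (c1 - k)],
        )
        for k in range(kmin, kmax + 1)
    ]
    p_obs = pmf[a - kmin]
    return sum(q for q in pmf if q <= p_obs)
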