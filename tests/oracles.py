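"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's code paths: the Fisher oracle
enumerates hypergeometric point masses with exact integer arithmetic, and
the shared-region oracle evaluates every unit interval between consecutive
breakpoints directly.
"""

import math

from coacnv.model import Status, direction_of


def oracle_fisher_greater(a, b, c, d):
    """P(X >= a) with the 2x2 margins fixed, by integer enumeration."""
    n, row1, col1 = a + b + c + d, a + b, a + c
    if n == 0:
        return 1.0
    hi = min(row1, col1)
    num = sum(math.comb(row1, k) * math.comb(n - row1, col1 - k) for k in range(a, hi + 1))
    return num / math.comb(n, col1)


def oracle_fisher_tails(row1, row2, col1):
    """Suffix tail P(X >= a) for every a in 0..min(row1, col1), exact."""
    n = row1 + row2
    hi = min(row1, col1)
    masses = [math.comb(row1, k) * math.comb(row2, col1 - k) for k in range(0, hi + 1)]
    denom = math.comb(n, col1)
    tails = []
    acc = 0
    for m in reversed(masses):
        acc += m
        tails.append(acc / denom)
    tails.reverse()
    return tails


def brute_force_shared_regions(segments, samples, genome, min_affected, direction,
                               max_unaffected=0, min_size=10_000):
    """Evaluate every atomic interval between consecutive breakpoints, then
    stitch runs with an identical affected carrier set."""
    affected = {s.sample_id for s in samples if s.status is Status.affected}
    unaffected = {s.sample_id for s in samples if s.status is Status.unaffected}
    index = {s.sample_id: s for s in samples}
    out = []
    for chrom in sorted({s.chrom for s in segments}):
        segs = [
            s for s in segments
            if s.chrom == chrom and s.length > min_size
            and direction_of(s, index[s.sample_id].sex, genome) is direction
        ]
        pts = sorted({s.start for s in segs} | {s.end for s in segs})
        atoms = []
        for lo, hi in zip(pts[:-1], pts[1:]):
            aff = frozenset(s.sample_id for s in segs
                            if s.sample_id in affected and s.start <= lo and s.end >= hi)
            atoms.append((lo, hi, aff))
        i = 0
        while i < len(atoms):
            lo, hi, aff = atoms[i]
            if len(aff) < min_affected:
                i += 1
                continue
            j = i
            while (j + 1 < len(atoms) and atoms[j + 1][0] == atoms[j][1]
                   and atoms[j + 1][2] == aff):
                j += 1
            start, end = atoms[i][0], atoms[j][1]
            n_unaff = len({s.sample_id for s in segs
                           if s.sample_id in unaffected and s.start < end and s.end > start})
            if n_unaff <= max_unaffected:
                out.append((chrom, start, end, aff, n_unaff))
            i = j + 1
    return out
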