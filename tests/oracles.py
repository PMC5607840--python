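"""Independent brute-force oracles used only by the test suite.

These re-derive expected results by direct enumeration, deliberately
sharing no code with the implementation under test.
"""

from __future__ import annotations

import numpy as np


def scan_runs(chroms, pos, log2, del_log2=-0.6, gain_log2=0.4, min_probes=3):
    """Enumerate all maximal threshold runs by stepping probe by probe.

    Returns a set of (chrom, start, end, type, n_probes, mean_log2
    rounded to 9 decimals) tuples.
    """
    n = len(pos)
    out = set()
    for kind, pred in (
        ("loss", lambda v: v < del_log2),
        ("gain", lambda v: v > gain_log2),
    ):
        i = 0
        while i < n:
            if pred(log2[i]):
                j = i
                while j + 1 < n and chroms[j + 1] == chroms[i] and pred(log2[j + 1]):
                    j += 1
                if j - i + 1 >= min_probes:
                    mean = float(np.mean(log2[i : j + 1]))
                    out.add((chroms[i], int(pos[i]), int(pos[j]), kind, j - i + 1, round(mean, 9)))
                i = j + 1
            else:
                i += 1
    return out


def random_profile(rng, n_probes=10_000):
    """A log2 profile with noise plus implanted segments that straddle
    both caller thresholds."""
    log2 = rng.normal(0.0, 0.25, size=n_probes)
    levels = [-1.5, -1.0, -0.7, -0.6, -0.5, 0.4, 0.45, 0.6, 1.0]
    for _ in range(rng.integers(5, 15)):
        length = int(rng.integers(1, 12))
        start = int(rng.integers(0, n_probes - length))
        log2[start : start + length] = levels[int(rng.integers(len(levels)))]
    chroms = np.where(np.arange(n_probes) < n_probes // 2, "chr1", "chr2")
    pos = np.concatenate(
        [np.arange(n_probes // 2) * 100 + 1, np.arange(n_probes - n_probes // 2) * 100 + 1]
    )
    return chroms, pos, log2


def all_pairs_gene_overlap(call, genes):
    """Quadratic interval-intersection annotation oracle."""
    hits = []
    for g in genes:
        gs, ge = g.span
        if g.chrom == call.chrom and call.start <= ge and gs <= call.end:
            n_aff = sum(
                1 for (es, ee) in g.exons if call.start <= ee and es <= call.end
            )
            hits.append((g.symbol, n_aff))
    return sorted(hits)
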