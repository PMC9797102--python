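"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's internals: translation goes through
Bio.Seq, nothing is cached, pathways are enumerated with itertools, and the
binomial tail is a direct pmf summation.
"""

from __future__ import annotations

import math
from itertools import permutations

from Bio.Seq import Seq

BASES = "ACGT"

# the oracle derives its own genetic-code lookup by translating every codon
# with Bio.Seq ('*' marks a stop); independent of the package's CodonTable
_CODE = {
    a + b + c: str(Seq(a + b + c).translate())
    for a in BASES
    for b in BASES
    for c in BASES
}


def _aa(codon: str) -> str:
    return _CODE[codon]


def oracle_site_fractions(codon: str) -> tuple[float, float]:
    aa = _aa(codon)
    syn = 0
    for pos in range(3):
        for base in BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            mutant_aa = _aa(mutant)
            if mutant_aa == "*":
                continue  # mutation to a stop counts as nonsynonymous
            if mutant_aa == aa:
                syn += 1
    return 3.0 - syn / 3.0, syn / 3.0


def oracle_pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        return 0.0, 0.0

    def enumerate_paths(allow_stops: bool):
        tallies = []
        for order in permutations(diff_positions):
            codons = [codon_a]
            for pos in order:
                prev = codons[-1]
                codons.append(prev[:pos] + codon_b[pos] + prev[pos + 1 :])
            if not allow_stops and any(_aa(c) == "*" for c in codons[1:-1]):
                continue
            n = s = 0
            for prev, nxt in zip(codons, codons[1:]):
                if _aa(prev) == "*" or _aa(nxt) == "*":
                    n += 1
                elif _aa(prev) == _aa(nxt):
                    s += 1
                else:
                    n += 1
            tallies.append((n, s))
        return tallies

    tallies = enumerate_paths(allow_stops=False)
    if not tallies:
        tallies = enumerate_paths(allow_stops=True)
    n = sum(t[0] for t in tallies) / len(tallies)
    s = sum(t[1] for t in tallies) / len(tallies)
    return n, s


def oracle_kaks(seq_a: str, seq_b: str) -> dict:
    """Codon-by-codon NG86 with the same skipping conventions as the package."""
    n_sites = s_sites = n_diff = s_diff = 0.0
    used = 0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        if any(base not in BASES for base in ca + cb):
            continue
        if _aa(ca) == "*" or _aa(cb) == "*":
            continue
        na, sa = oracle_site_fractions(ca)
        nb, sb = oracle_site_fractions(cb)
        n_sites += (na + nb) / 2.0
        s_sites += (sa + sb) / 2.0
        nd, sd = oracle_pathway_differences(ca, cb)
        n_diff += nd
        s_diff += sd
        used += 1
    pn = n_diff / n_sites
    ps = s_diff / s_sites

    def jc(p):
        if p >= 0.75:
            return None
        return -0.75 * math.log(1.0 - 4.0 * p / 3.0)

    ka, ks = jc(pn), jc(ps)
    omega = ka / ks if (ka is not None and ks is not None and ks > 0) else None
    return {
        "n_sites": n_sites,
        "s_sites": s_sites,
        "n_diff": n_diff,
        "s_diff": s_diff,
        "pn": pn,
        "ps": ps,
        "ka": ka,
        "ks": ks,
        "omega": omega,
        "codons_used": used,
    }


def oracle_binomial_tail(a: int, n: int, p: float) -> float:
    """Pr[X >= a] for X ~ Binomial(n, p) by direct pmf summation."""
    total = 0.0
    for x in range(a, n + 1):
        total += math.comb(n, x) * p**x * (1.0 - p) ** (n - x)
    return min(total, 1.0)


def oracle_nearest_distances(genes: list[tuple[str, int, int]], tes: list[tuple[str, int, int]]):
    """All-pairs nearest-gene scan; None when the chromosome has no gene."""
    out = []
    for chrom, ts, te in tes:
        best = None
        for gchrom, gs, ge in genes:
            if gchrom != chrom:
                continue
            if gs < te and ge > ts:
                gap = 0
            else:
                gap = max(gs - te, ts - ge)
            best = gap if best is None else min(best, gap)
        out.append(best)
    return out
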