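"""Nei–Gojobori (NG86) Ka/Ks estimation for codon-aligned sequence pairs.

The NG86 method counts, for each codon, the expected numbers of synonymous
and nonsynonymous *sites* (each of the nine single-base mutants contributes
1/3 of a site to one class) and, for each differing codon pair, averages the
numbers of synonymous and nonsynonymous *differences* over all minimal
mutational pathways between the two codons. Proportions pn = Nd/N and
ps = Sd/S are then corrected for multiple hits with the Jukes–Cantor
formula, giving Ka and Ks and their ratio omega = Ka/Ks.

Conventions (standard NG86, matching the YN00 "NG" output on clean
alignments):

* mutations that create a stop codon count as nonsynonymous in site
  counting;
* mutational pathways that pass through a stop codon are excluded from
  difference counting (all pathways blocked -> fall back to including them,
  flagged);
* multi-step pathways are equally weighted (no ts/tv weighting);
* codon pairs containing a gap, an ambiguous base or a stop codon are
  skipped pairwise;
* a proportion >= 3/4 saturates the Jukes–Cantor correction and the
  corresponding rate is reported as missing with a ``saturated_*`` flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

__all__ = [
    "CodonAlignment",
    "KaKsEstimate",
    "SaturationError",
    "EmptyAlignmentError",
    "RejectedCodonError",
    "count_sites",
    "count_differences",
    "jukes_cantor",
    "kaks_pair",
    "kaks_table",
    "read_paired_fasta",
    "read_pairs_tsv",
    "write_kaks_table",
]

_BASES = "ACGT"

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_STANDARD.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))


class SaturationError(ValueError):
    """Observed proportion is at or beyond the Jukes–Cantor domain (p >= 3/4)."""


class EmptyAlignmentError(ValueError):
    """No scorable codon pair remains after skipping gaps/ambiguity/stops."""


class RejectedCodonError(ValueError):
    """Codon is ambiguous or a stop codon and cannot be scored."""


@dataclass(frozen=True)
class CodonAlignment:
    """A gap-aware pair of codon-aligned coding sequences.

    Both sequences must have equal length divisible by three, use the
    alphabet ``{A, C, G, T, N, -}`` and contain no internal stop codon once
    gaps are removed.
    """

    id_a: str
    id_b: str
    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq_a", self.seq_a.upper())
        object.__setattr__(self, "seq_b", self.seq_b.upper())
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError(
                f"aligned sequences differ in length for pair "
                f"({self.id_a}, {self.id_b}): {len(self.seq_a)} vs {len(self.seq_b)}"
            )
        if len(self.seq_a) % 3 != 0:
            raise ValueError(
                f"alignment length {len(self.seq_a)} is not a multiple of 3 "
                f"for pair ({self.id_a}, {self.id_b})"
            )
        allowed = set("ACGTN-")
        for name, seq in ((self.id_a, self.seq_a), (self.id_b, self.seq_b)):
            bad = set(seq) - allowed
            if bad:
                raise ValueError(f"illegal characters {sorted(bad)} in sequence {name}")
            _check_no_internal_stop(name, seq)

    def __len__(self) -> int:
        return len(self.seq_a) // 3


def _check_no_internal_stop(name: str, seq: str) -> None:
    ungapped = seq.replace("-", "")
    # trailing partial codons (possible after gap removal) are ignored;
    # a terminal stop is tolerated, internal ones are not
    n_codons = len(ungapped) // 3
    for i in range(n_codons - 1):
        codon = ungapped[3 * i : 3 * i + 3]
        if codon in STOP_CODONS:
            raise ValueError(
                f"internal stop codon {codon} at ungapped codon {i} in sequence {name}"
            )


@dataclass
class KaKsEstimate:
    """NG86 site/difference counts and Jukes–Cantor-corrected rates.

    ``ka``/``ks`` are ``None`` when the corresponding proportion is
    saturated; ``omega`` is ``None`` whenever ``ks`` is missing or zero.
    """

    id_a: str
    id_b: str
    n_sites: float
    s_sites: float
    n_diff: float
    s_diff: float
    pn: float
    ps: float
    ka: Optional[float]
    ks: Optional[float]
    omega: Optional[float]
    codons_used: int
    flags: frozenset[str] = field(default_factory=frozenset)


def _enumerate_site_fractions(codon: str) -> tuple[float, float]:
    aa = CODON_TO_AA[codon]
    syn = 0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if mutant in STOP_CODONS:
                continue  # counts as nonsynonymous
            if CODON_TO_AA[mutant] == aa:
                syn += 1
    s = syn / 3.0
    return 3.0 - s, s


_SITE_FRACTIONS: dict[str, tuple[float, float]] = {
    codon: _enumerate_site_fractions(codon) for codon in SENSE_CODONS
}


def count_sites(codon: str) -> tuple[float, float]:
    """Expected (nonsynonymous, synonymous) site fractions of one codon.

    Each of the nine single-base mutants contributes 1/3 of a site; mutants
    that are stop codons count as nonsynonymous. The fractions always sum
    to 3.
    """
    codon = codon.upper()
    try:
        return _SITE_FRACTIONS[codon]
    except KeyError:
        raise RejectedCodonError(f"cannot count sites of codon {codon!r}") from None


@lru_cache(maxsize=None)
def _pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float, bool]:
    positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not positions:
        return 0.0, 0.0, False

    def walk(include_stop_transit: bool) -> list[tuple[float, float]]:
        tallies = []
        for order in permutations(positions):
            current = codon_a
            n = s = 0.0
            blocked = False
            for pos in order:
                nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
                if nxt in STOP_CODONS and nxt != codon_b:
                    if not include_stop_transit:
                        blocked = True
                        break
                    n += 1.0  # a step into/out of a stop is nonsynonymous
                elif current in STOP_CODONS:
                    n += 1.0
                elif CODON_TO_AA[current] == CODON_TO_AA[nxt]:
                    s += 1.0
                else:
                    n += 1.0
                current = nxt
            if not blocked:
                tallies.append((n, s))
        return tallies

    tallies = walk(include_stop_transit=False)
    via_stop = False
    if not tallies:
        tallies = walk(include_stop_transit=True)
        via_stop = True
    n = sum(t[0] for t in tallies) / len(tallies)
    s = sum(t[1] for t in tallies) / len(tallies)
    return n, s, via_stop


def count_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged (nonsynonymous, synonymous) differences of a codon pair.

    All minimal mutational pathways (1, 2 or 6 orderings of the differing
    positions) are enumerated; pathways through stop codons are excluded and
    the rest equally weighted. ``n + s`` equals the Hamming distance.
    """
    codon_a, codon_b = codon_a.upper(), codon_b.upper()
    for codon in (codon_a, codon_b):
        if codon not in _SITE_FRACTIONS:
            raise RejectedCodonError(f"cannot count differences of codon {codon!r}")
    n, s, _ = _pathway_differences(codon_a, codon_b)
    return n, s


def jukes_cantor(p: float) -> float:
    """Jukes–Cantor multiple-hit correction d = -(3/4) ln(1 - 4p/3)."""
    if not 0.0 <= p < 0.75:
        raise SaturationError(f"proportion {p} outside the Jukes-Cantor domain [0, 0.75)")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def kaks_pair(aln: CodonAlignment) -> KaKsEstimate:
    """NG86 Ka/Ks estimate for one codon alignment.

    Site counts are averaged over the two sequences; codon pairs with a gap,
    an N or a stop codon are skipped pairwise.
    """
    n_sites = s_sites = n_diff = s_diff = 0.0
    used = 0
    flags: set[str] = set()
    acgt = set(_BASES)
    for i in range(0, len(aln.seq_a), 3):
        ca = aln.seq_a[i : i + 3]
        cb = aln.seq_b[i : i + 3]
        if set(ca) - acgt or set(cb) - acgt:
            continue
        if ca in STOP_CODONS or cb in STOP_CODONS:
            flags.add("stop_codon_skipped")
            continue
        na, sa = _SITE_FRACTIONS[ca]
        nb, sb = _SITE_FRACTIONS[cb]
        n_sites += (na + nb) / 2.0
        s_sites += (sa + sb) / 2.0
        nd, sd, via_stop = _pathway_differences(ca, cb)
        if via_stop:
            flags.add("stop_transit_pathway")
        n_diff += nd
        s_diff += sd
        used += 1
    if used == 0:
        raise EmptyAlignmentError(
            f"no scorable codon pair in alignment ({aln.id_a}, {aln.id_b})"
        )

    pn = n_diff / n_sites
    ps = s_diff / s_sites
    try:
        ka: Optional[float] = jukes_cantor(pn)
    except SaturationError:
        ka = None
        flags.add("saturated_nonsynonymous")
    try:
        ks: Optional[float] = jukes_cantor(ps)
    except SaturationError:
        ks = None
        flags.add("saturated_synonymous")

    omega: Optional[float] = None
    if ks is None:
        pass
    elif ks == 0.0:
        flags.add("ks_zero")
    elif ka is not None:
        omega = ka / ks
    return KaKsEstimate(
        id_a=aln.id_a,
        id_b=aln.id_b,
        n_sites=n_sites,
        s_sites=s_sites,
        n_diff=n_diff,
        s_diff=s_diff,
        pn=pn,
        ps=ps,
        ka=ka,
        ks=ks,
        omega=omega,
        codons_used=used,
        flags=frozenset(flags),
    )


# ---------------------------------------------------------------------------
# I/O


def read_paired_fasta(path: str | Path) -> list[CodonAlignment]:
    """Read alignments from a FASTA holding two consecutive records per pair."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) % 2 != 0:
        raise ValueError(f"{path}: odd number of records ({len(records)}); expected pairs")
    alignments = []
    for a, b in zip(records[0::2], records[1::2]):
        alignments.append(CodonAlignment(a.id, b.id, str(a.seq), str(b.seq)))
    return alignments


def read_pairs_tsv(pairs_path: str | Path, fasta_path: str | Path) -> list[CodonAlignment]:
    """Read (id_a, id_b) pairs from a TSV and their sequences from one multi-FASTA."""
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    pairs = pd.read_csv(pairs_path, sep="\t", comment="#")
    if not {"id_a", "id_b"} <= set(pairs.columns):
        raise ValueError(f"{pairs_path}: expected columns id_a and id_b")
    alignments = []
    for row in pairs.itertuples(index=False):
        for gid in (row.id_a, row.id_b):
            if gid not in seqs:
                raise KeyError(f"{pairs_path}: sequence {gid!r} absent from {fasta_path}")
        alignments.append(CodonAlignment(row.id_a, row.id_b, seqs[row.id_a], seqs[row.id_b]))
    return alignments


def kaks_table(estimates: Iterable[KaKsEstimate]) -> pd.DataFrame:
    """Tabulate estimates (one row per pair) in the exchange-TSV column order."""
    rows = []
    for est in estimates:
        rows.append(
            {
                "id_a": est.id_a,
                "id_b": est.id_b,
                "ka": est.ka,
                "ks": est.ks,
                "omega": est.omega,
                "n_sites": est.n_sites,
                "s_sites": est.s_sites,
                "n_diff": est.n_diff,
                "s_diff": est.s_diff,
                "codons_used": est.codons_used,
                "flags": ";".join(sorted(est.flags)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "id_a",
            "id_b",
            "ka",
            "ks",
            "omega",
            "n_sites",
            "s_sites",
            "n_diff",
            "s_diff",
            "codons_used",
            "flags",
        ],
    )


def write_kaks_table(estimates: Iterable[KaKsEstimate], path: str | Path) -> pd.DataFrame:
    table = kaks_table(estimates)
    table.to_csv(path, sep="\t", index=False)
    return table
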