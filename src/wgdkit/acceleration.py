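"""Per-GO-category binomial test for lineage-accelerated protein evolution.

Two lineages (a focal and a contrast species) are each compared with a
common outgroup, yielding pathway-averaged nonsynonymous and synonymous
difference counts per ortholog. Pooling all orthologs of one lineage gives
the genome-wide fraction of differences that are nonsynonymous,

    p_expect = sum(n_diff) / sum(n_diff + s_diff),

which serves as the null for every GO category: a category with orthologs
contributing ``a`` nonsynonymous and ``s`` synonymous differences is tested
one-sided for an excess of nonsynonymous changes,

    P = Pr[X >= a],  X ~ Binomial(a + s, p_expect).

Only categories with more than 20 orthologs are tested; a category is
called accelerated in a lineage when P < alpha there and not in the other
lineage. NG86 counts are pathway-averaged and hence may be fractional; the
tail is therefore evaluated through the regularized incomplete beta
function, which coincides with the exact binomial survival function at
integer counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special

__all__ = [
    "DiffCounts",
    "OrthologTriple",
    "GOCategoryResult",
    "binomial_tail",
    "genome_wide_expectation",
    "category_test",
    "test_categories",
    "two_lineage_contrast",
    "read_triples",
    "read_gene2go",
    "propagate_gene2go",
    "MIN_ORTHOLOGS",
]

#: categories need MORE than 20 orthologs to be tested
MIN_ORTHOLOGS = 21


@dataclass(frozen=True)
class DiffCounts:
    """NG86 difference and site counts for one gene-vs-outgroup comparison."""

    n_diff: float
    s_diff: float
    n_sites: float
    s_sites: float

    def __post_init__(self) -> None:
        if min(self.n_diff, self.s_diff) < 0 or min(self.n_sites, self.s_sites) <= 0:
            raise ValueError("differences must be nonnegative and sites positive")


@dataclass(frozen=True)
class OrthologTriple:
    gene_focal: str
    gene_other: str
    gene_outgroup: str
    counts_focal: DiffCounts
    counts_other: DiffCounts


@dataclass
class GOCategoryResult:
    go_id: str
    lineage: str
    n_orthologs: int
    a_obs: float
    s_obs: float
    p_expect: float
    p_value: Optional[float]
    status: str  # tested | skipped | untestable


class UndefinedNullError(ValueError):
    """No differences at all: the genome-wide expectation is undefined."""


def binomial_tail(a: float, total: float, p: float) -> float:
    """One-sided upper tail Pr[X >= a] for X ~ Binomial(total, p).

    Implemented as the regularized incomplete beta I_p(a, total - a + 1);
    for integer ``a`` this equals the exact pmf sum. Fractional counts
    (pathway-averaged NG86 output) interpolate smoothly.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p_expect {p} outside [0, 1]")
    if a <= 0:
        return 1.0
    if a > total:
        return 0.0
    return float(special.betainc(a, total - a + 1.0, p))


def _counts(triple: OrthologTriple, lineage: str) -> DiffCounts:
    if lineage == "focal":
        return triple.counts_focal
    if lineage == "other":
        return triple.counts_other
    raise ValueError(f"lineage must be 'focal' or 'other', not {lineage!r}")


def genome_wide_expectation(triples: Sequence[OrthologTriple], lineage: str = "focal") -> float:
    """Pooled nonsynonymous fraction of differences over all orthologs."""
    n = sum(_counts(t, lineage).n_diff for t in triples)
    s = sum(_counts(t, lineage).s_diff for t in triples)
    if n + s == 0:
        raise UndefinedNullError(f"no substitutions observed in the {lineage} lineage")
    return n / (n + s)


def category_test(
    go_id: str,
    member_counts: Sequence[tuple[float, float]],
    p_expect: float,
    lineage: str = "focal",
    min_orthologs: int = MIN_ORTHOLOGS,
    two_sided: bool = False,
) -> GOCategoryResult:
    """Binomial excess-nonsynonymous test for one GO category.

    ``member_counts`` holds (n_diff, s_diff) per member ortholog. A
    category with fewer than ``min_orthologs`` members is reported
    ``skipped``; one with zero pooled differences is ``untestable``.
    """
    a = float(sum(c[0] for c in member_counts))
    s = float(sum(c[1] for c in member_counts))
    n_orth = len(member_counts)
    if n_orth < min_orthologs:
        status, p_value = "skipped", None
    elif a + s == 0:
        status, p_value = "untestable", None
    else:
        status = "tested"
        p_value = binomial_tail(a, a + s, p_expect)
        if two_sided:
            lower = 1.0 - binomial_tail(a + 1.0, a + s, p_expect)
            p_value = min(1.0, 2.0 * min(p_value, lower))
    return GOCategoryResult(
        go_id=go_id,
        lineage=lineage,
        n_orthologs=n_orth,
        a_obs=a,
        s_obs=s,
        p_expect=p_expect,
        p_value=p_value,
        status=status,
    )


def test_categories(
    triples: Sequence[OrthologTriple],
    gene2go: Mapping[str, Sequence[str]],
    lineage: str = "focal",
    min_orthologs: int = MIN_ORTHOLOGS,
    two_sided: bool = False,
) -> pd.DataFrame:
    """Run the category test for every GO term in the annotation universe.

    ``gene2go`` maps the *focal* gene identifier of each triple to its GO
    terms; both lineages share this grouping so their GO universes match.
    """
    p_expect = genome_wide_expectation(triples, lineage)
    by_go: dict[str, list[tuple[float, float]]] = {}
    for triple in triples:
        counts = _counts(triple, lineage)
        for go_id in gene2go.get(triple.gene_focal, ()):
            by_go.setdefault(go_id, []).append((counts.n_diff, counts.s_diff))
    results = [
        category_test(go_id, members, p_expect, lineage, min_orthologs, two_sided)
        for go_id, members in sorted(by_go.items())
    ]
    return pd.DataFrame(
        {
            "go_id": [r.go_id for r in results],
            "lineage": [r.lineage for r in results],
            "n_orthologs": [r.n_orthologs for r in results],
            "a_obs": [r.a_obs for r in results],
            "s_obs": [r.s_obs for r in results],
            "p_expect": [r.p_expect for r in results],
            "p_value": [r.p_value for r in results],
            "status": [r.status for r in results],
        }
    )


def _bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (NaN-aware)."""
    out = np.full(p_values.shape, np.nan)
    mask = ~np.isnan(p_values)
    p = p_values[mask]
    m = p.size
    if m == 0:
        return out
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    result = np.empty(m)
    result[order] = np.minimum(adjusted, 1.0)
    out[mask] = result
    return out


def two_lineage_contrast(
    results_focal: pd.DataFrame,
    results_other: pd.DataFrame,
    alpha: float = 0.05,
    bh: bool = False,
) -> pd.DataFrame:
    """Label every GO category by which lineage shows accelerated evolution.

    Categories significant (raw P < alpha) in exactly one lineage are
    labelled with that lineage; both/neither otherwise. A Benjamini–
    Hochberg column is always attached; with ``bh=True`` the labels use the
    adjusted values instead of raw ones. Output sorted by min p-value.
    """
    universe_focal = set(results_focal["go_id"])
    universe_other = set(results_other["go_id"])
    if universe_focal != universe_other:
        diff = sorted(universe_focal ^ universe_other)
        raise ValueError(f"GO universes differ between lineages: {diff[:10]}")
    merged = results_focal.merge(
        results_other, on="go_id", suffixes=("_focal", "_other"), validate="1:1"
    )
    for side in ("focal", "other"):
        merged[f"bh_fdr_{side}"] = _bh_fdr(merged[f"p_value_{side}"].to_numpy(dtype=float))
    p_col = "bh_fdr" if bh else "p_value"
    sig_focal = merged[f"{p_col}_focal"] < alpha
    sig_other = merged[f"{p_col}_other"] < alpha
    label = np.select(
        [sig_focal & sig_other, sig_focal, sig_other],
        ["both", "focal", "other"],
        default="neither",
    )
    # untested categories are never called
    tested = (merged["status_focal"] == "tested") & (merged["status_other"] == "tested")
    merged["label"] = np.where(tested, label, "untested")
    merged["min_p"] = merged[["p_value_focal", "p_value_other"]].min(axis=1)
    return merged.sort_values("min_p", na_position="last").reset_index(drop=True)


# ---------------------------------------------------------------------------
# I/O


def read_triples(
    path: str | Path,
    kaks_focal: pd.DataFrame,
    kaks_other: pd.DataFrame,
) -> list[OrthologTriple]:
    """Assemble ortholog triples from a TSV and the two lineages' Ka/Ks tables.

    The TSV needs columns gene_focal, gene_other, gene_outgroup; counts are
    looked up as (gene, outgroup) rows of the corresponding Ka/Ks table.
    """

    def index(table: pd.DataFrame) -> dict[tuple[str, str], DiffCounts]:
        out = {}
        for row in table.itertuples(index=False):
            counts = DiffCounts(row.n_diff, row.s_diff, row.n_sites, row.s_sites)
            out[(row.id_a, row.id_b)] = counts
            out[(row.id_b, row.id_a)] = counts
        return out

    focal_idx = index(kaks_focal)
    other_idx = index(kaks_other)
    table = pd.read_csv(path, sep="\t", comment="#")
    triples = []
    for row in table.itertuples(index=False):
        key_f = (row.gene_focal, row.gene_outgroup)
        key_o = (row.gene_other, row.gene_outgroup)
        if key_f not in focal_idx:
            raise KeyError(f"no focal Ka/Ks row for pair {key_f}")
        if key_o not in other_idx:
            raise KeyError(f"no contrast Ka/Ks row for pair {key_o}")
        triples.append(
            OrthologTriple(
                gene_focal=row.gene_focal,
                gene_other=row.gene_other,
                gene_outgroup=row.gene_outgroup,
                counts_focal=focal_idx[key_f],
                counts_other=other_idx[key_o],
            )
        )
    return triples


def propagate_gene2go(
    gene2go: Mapping[str, Sequence[str]], obo_path: str | Path
) -> dict[str, list[str]]:
    """Propagate annotations up the GO graph from an OBO ontology file.

    Each gene additionally receives every ancestor (via is_a/part_of) of
    its directly annotated terms. Terms absent from the ontology are kept
    as-is.
    """
    import networkx as nx
    import obonet

    graph = obonet.read_obo(str(obo_path))
    out: dict[str, list[str]] = {}
    for gene, terms in gene2go.items():
        expanded = set(terms)
        for term in terms:
            if term in graph:
                # obonet edges point child -> parent, so graph-descendants
                # of a term are its ontology ancestors
                expanded |= nx.descendants(graph, term)
        out[gene] = sorted(expanded)
    return out


def read_gene2go(path: str | Path) -> dict[str, list[str]]:
    """Read a two-column (gene id, GO id) TSV into a mapping."""
    table = pd.read_csv(path, sep="\t", comment="#", names=["gene", "go"], header=None)
    if table.iloc[0].tolist() == ["gene", "go"]:
        table = table.iloc[1:]
    mapping: dict[str, list[str]] = {}
    for row in table.itertuples(index=False):
        mapping.setdefault(str(row.gene), []).append(str(row.go))
    return mapping
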