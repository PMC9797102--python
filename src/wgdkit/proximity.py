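"""Distance from transposable elements to the nearest gene, and the
intact-versus-fragmentary proximity contrast.

Intact TE copies inserting near genes (and into regulatory regions) is one
route by which bursts of transposition feed adaptive variation; the test
here asks whether intact elements lie closer to genes than fragmentary
remnants. Distances are boundary gaps in bp on half-open 0-based intervals
(overlap = 0). The primary test is a chi-square on the 2x2 table of status
by near/far (default edge 1 kb, no continuity correction); a Mann–Whitney
rank-sum comparison of the full distance distributions accompanies it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnnotatedGenomeModel",
    "read_gff3_genes",
    "read_te_table",
    "nearest_gene_distance",
    "proximity_test",
    "group_summaries",
    "DEFAULT_BIN_EDGE_BP",
]

DEFAULT_BIN_EDGE_BP = 1000

_GENE_COLUMNS = ["chrom", "start", "end", "strand", "id"]
_TE_COLUMNS = ["chrom", "start", "end", "id", "superfamily", "status"]


@dataclass
class AnnotatedGenomeModel:
    """Chromosome sizes plus gene and TE interval tables (0-based half-open)."""

    chromosomes: dict[str, int]
    genes: pd.DataFrame
    tes: pd.DataFrame

    def __post_init__(self) -> None:
        self.genes = self.genes[_GENE_COLUMNS].copy()
        self.tes = self.tes[_TE_COLUMNS].copy()
        self.validate()

    def validate(self) -> None:
        for kind, table in (("gene", self.genes), ("TE", self.tes)):
            for row in table.itertuples(index=False):
                if row.chrom not in self.chromosomes:
                    raise ValueError(f"{kind} {row.id}: undeclared chromosome {row.chrom!r}")
                length = self.chromosomes[row.chrom]
                if not 0 <= row.start < row.end <= length:
                    raise ValueError(
                        f"{kind} {row.id}: interval [{row.start}, {row.end}) outside "
                        f"chromosome {row.chrom} of length {length}"
                    )


def read_gff3_genes(path: str | Path, feature: str = "gene") -> pd.DataFrame:
    """Extract gene intervals from a GFF3 file (coordinates converted to
    0-based half-open)."""
    rows = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}: line {lineno} has {len(fields)} columns, expected 9")
            if fields[2] != feature:
                continue
            attrs = dict(
                item.split("=", 1) for item in fields[8].split(";") if "=" in item
            )
            rows.append(
                {
                    "chrom": fields[0],
                    "start": int(fields[3]) - 1,
                    "end": int(fields[4]),
                    "strand": fields[6],
                    "id": attrs.get("ID", f"{feature}_{lineno}"),
                }
            )
    return pd.DataFrame(rows, columns=_GENE_COLUMNS)


def read_te_table(path: str | Path) -> pd.DataFrame:
    """Read the BED-like TE TSV (chrom, start, end, id, superfamily, status)."""
    table = pd.read_csv(path, sep="\t", comment="#")
    missing = set(_TE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing TE columns {sorted(missing)}")
    bad = set(table["status"]) - {"intact", "fragmentary"}
    if bad:
        raise ValueError(f"{path}: unknown TE status values {sorted(bad)}")
    return table


def _merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    merged_s, merged_e = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= merged_e[-1]:
            merged_e[-1] = max(merged_e[-1], e)
        else:
            merged_s.append(s)
            merged_e.append(e)
    return np.asarray(merged_s), np.asarray(merged_e)


def nearest_gene_distance(model: AnnotatedGenomeModel) -> pd.DataFrame:
    """Per-TE distance in bp to the nearest gene on the same chromosome.

    Overlapping a gene gives 0; TEs on chromosomes without genes get NaN
    and a ``no_gene_on_chromosome`` flag. Strand is ignored. The scan is a
    sorted sweep: gene intervals are merged per chromosome and each TE is
    located between its flanking gene boundaries with a binary search.
    """
    model.validate()
    out = model.tes.copy()
    distances = np.full(len(out), np.nan)
    flags = np.array([""] * len(out), dtype=object)
    for chrom, te_idx in out.groupby("chrom").groups.items():
        genes = model.genes[model.genes["chrom"] == chrom]
        te_rows = out.loc[te_idx]
        if genes.empty:
            flags[out.index.get_indexer(te_idx)] = "no_gene_on_chromosome"
            continue
        gstart, gend = _merge_intervals(
            genes["start"].to_numpy(), genes["end"].to_numpy()
        )
        ts = te_rows["start"].to_numpy()
        te = te_rows["end"].to_numpy()
        # first merged gene starting at or beyond the TE end
        right = np.searchsorted(gstart, te, side="left")
        dist = np.full(ts.size, np.inf)
        has_right = right < gstart.size
        dist[has_right] = gstart[right[has_right]] - te[has_right]
        left = right - 1
        has_left = left >= 0
        overlap = has_left & (gend[np.clip(left, 0, None)] > ts)
        left_gap = np.where(has_left, ts - gend[np.clip(left, 0, None)], np.inf)
        dist = np.minimum(dist, left_gap)
        dist[overlap] = 0.0
        distances[out.index.get_indexer(te_idx)] = np.maximum(dist, 0.0)
    out["distance_bp"] = distances
    out["flags"] = flags
    return out


def group_summaries(distances: pd.DataFrame) -> pd.DataFrame:
    """n / median / mean distance for each status x superfamily cell."""
    usable = distances.dropna(subset=["distance_bp"])
    rows = []
    for (status, fam), group in usable.groupby(["status", "superfamily"]):
        rows.append(
            {
                "status": status,
                "superfamily": fam,
                "n": len(group),
                "median_bp": float(group["distance_bp"].median()),
                "mean_bp": float(group["distance_bp"].mean()),
            }
        )
    return pd.DataFrame(rows, columns=["status", "superfamily", "n", "median_bp", "mean_bp"])


def _one_test(
    intact: np.ndarray, fragmentary: np.ndarray, scope: str, bin_edge_bp: float
) -> dict:
    table = np.array(
        [
            [(intact <= bin_edge_bp).sum(), (intact > bin_edge_bp).sum()],
            [(fragmentary <= bin_edge_bp).sum(), (fragmentary > bin_edge_bp).sum()],
        ]
    )
    if table.sum(axis=1).min() == 0 or table.sum(axis=0).min() == 0:
        chi2_p = np.nan
        chi2_stat = np.nan
    else:
        chi2_stat, chi2_p, _, _ = stats.chi2_contingency(table, correction=False)
    rank = stats.mannwhitneyu(intact, fragmentary, alternative="two-sided")
    med_i, med_f = float(np.median(intact)), float(np.median(fragmentary))
    closer = "intact" if med_i < med_f else ("fragmentary" if med_f < med_i else "tie")
    return {
        "scope": scope,
        "n_intact": int(intact.size),
        "n_fragmentary": int(fragmentary.size),
        "median_intact_bp": med_i,
        "median_fragmentary_bp": med_f,
        "near_intact": int(table[0, 0]),
        "near_fragmentary": int(table[1, 0]),
        "chi2_stat": float(chi2_stat),
        "chi2_p": float(chi2_p),
        "ranksum_p": float(rank.pvalue),
        "closer_group": closer,
    }


def proximity_test(
    distances: pd.DataFrame,
    bin_edge_bp: float = DEFAULT_BIN_EDGE_BP,
    min_group: int = 20,
    per_superfamily: bool = True,
) -> pd.DataFrame:
    """Intact-vs-fragmentary proximity tests, overall and per superfamily.

    Primary statistic: chi-square on status x (<= edge / > edge) without
    continuity correction; secondary: two-sided Mann–Whitney on the raw
    distances. The ``closer_group`` column gives the direction by median.
    """
    usable = distances.dropna(subset=["distance_bp"])
    scopes: list[tuple[str, pd.DataFrame]] = [("all", usable)]
    if per_superfamily:
        scopes += [(fam, g) for fam, g in usable.groupby("superfamily")]
    rows = []
    for scope, group in scopes:
        intact = group.loc[group["status"] == "intact", "distance_bp"].to_numpy()
        frag = group.loc[group["status"] == "fragmentary", "distance_bp"].to_numpy()
        for name, values in (("intact", intact), ("fragmentary", frag)):
            if values.size == 0:
                raise ValueError(f"empty group: {name} TEs in scope {scope!r}")
        if min(intact.size, frag.size) < min_group:
            continue
        rows.append(_one_test(intact, frag, scope, bin_edge_bp))
    return pd.DataFrame(rows)
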