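"""Syntenic-block handling: anchor tables, block-median Ks, Ks distributions.

Collinearity anchors (produced upstream by MCscan-class tools) are grouped
into blocks; each anchor pair carries, or is assigned from a Ka/Ks table, a
synonymous divergence Ks. Blocks with at least ``min_pairs`` usable anchors
(default 10 collinear gene pairs) are summarised by their median Ks, and the
block medians of one comparison form a :class:`KsDistribution` — the raw
material for mixture-model peak detection of whole-genome duplications.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AnchorPair",
    "SyntenicBlock",
    "KsDistribution",
    "load_anchors",
    "load_collinearity",
    "attach_ks",
    "block_median_ks",
    "build_distribution",
    "write_block_table",
    "write_distribution",
    "read_distribution",
    "DEFAULT_MIN_PAIRS",
    "DEFAULT_KS_CEILING",
]

#: minimum collinear gene pairs for a block to enter a distribution
DEFAULT_MIN_PAIRS = 10
#: Ks ceiling for inclusion in distributions (saturation guard)
DEFAULT_KS_CEILING = 5.0


@dataclass
class AnchorPair:
    block_id: str
    gene_a: str
    gene_b: str
    ks: Optional[float] = None


@dataclass
class SyntenicBlock:
    block_id: str
    pairs: list[AnchorPair] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)

    def usable_ks(self, ks_ceiling: float = DEFAULT_KS_CEILING) -> list[float]:
        """Ks values that are present, finite, positive and below the ceiling."""
        out = []
        for pair in self.pairs:
            ks = pair.ks
            if ks is None or not math.isfinite(ks):
                continue
            if ks <= 0 or ks > ks_ceiling:
                continue
            out.append(ks)
        return out


@dataclass
class KsDistribution:
    """Block-median Ks values for one within- or between-genome comparison."""

    label: str
    values: np.ndarray
    threshold: int = DEFAULT_MIN_PAIRS

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.size and (not np.all(np.isfinite(values)) or np.any(values <= 0)):
            raise ValueError(f"{self.label}: Ks values must be finite and > 0")
        self.values = values

    def __len__(self) -> int:
        return self.values.size


def load_anchors(path: str | Path) -> list[SyntenicBlock]:
    """Load an anchor TSV (block_id, gene_a, gene_b[, ks]) into blocks.

    Rows are grouped by ``block_id`` preserving file order; duplicate
    (gene_a, gene_b) rows within a block are collapsed to the first
    occurrence. An empty file yields an empty list.
    """
    path = Path(path)
    try:
        table = pd.read_csv(path, sep="\t", comment="#", dtype={"block_id": str})
    except pd.errors.EmptyDataError:
        return []
    required = {"block_id", "gene_a", "gene_b"}
    if not required <= set(table.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}, got {list(table.columns)}")
    for col in ("gene_a", "gene_b"):
        bad = table.index[table[col].isna()]
        if len(bad):
            # +2: header line plus 1-based numbering
            raise ValueError(f"{path}: malformed row at line {bad[0] + 2} (missing {col})")
    has_ks = "ks" in table.columns

    blocks: dict[str, SyntenicBlock] = {}
    seen: set[tuple[str, str, str]] = set()
    for row in table.itertuples(index=False):
        key = (row.block_id, row.gene_a, row.gene_b)
        if key in seen:
            continue
        seen.add(key)
        block = blocks.setdefault(row.block_id, SyntenicBlock(row.block_id))
        ks = None
        if has_ks and pd.notna(row.ks):
            ks = float(row.ks)
        block.pairs.append(AnchorPair(row.block_id, row.gene_a, row.gene_b, ks))
    return list(blocks.values())


def load_collinearity(path: str | Path) -> list[SyntenicBlock]:
    """Load an MCScanX-style ``.collinearity`` file.

    ``## Alignment n`` headers open blocks (``n`` becomes the block id);
    anchor lines contribute their first two gene columns.
    """
    blocks: list[SyntenicBlock] = []
    current: Optional[SyntenicBlock] = None
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if line.startswith("## Alignment"):
                parts = line[2:].replace(":", " ").split()
                block_id = parts[1] if len(parts) > 1 else str(len(blocks))
                current = SyntenicBlock(block_id)
                blocks.append(current)
                continue
            if not line or line.startswith("#"):
                continue
            if current is None:
                raise ValueError(f"{path}: anchor line {lineno} before any '## Alignment' header")
            fields = line.replace(":", "\t").split()
            genes = [f for f in fields if not f.endswith("-")]
            if len(genes) < 2:
                raise ValueError(f"{path}: malformed anchor line {lineno}: {line!r}")
            # MCScanX rows are "idx-idx: geneA geneB e-value"
            gene_a, gene_b = genes[-3:-1] if len(genes) >= 3 else genes[:2]
            current.pairs.append(AnchorPair(current.block_id, gene_a, gene_b))
    return blocks


def attach_ks(blocks: Iterable[SyntenicBlock], kaks: pd.DataFrame) -> list[SyntenicBlock]:
    """Fill each anchor's Ks from a Ka/Ks table (orientation-insensitive)."""
    lookup: dict[tuple[str, str], Optional[float]] = {}
    for row in kaks.itertuples(index=False):
        ks = None if pd.isna(row.ks) else float(row.ks)
        lookup[(row.id_a, row.id_b)] = ks
        lookup[(row.id_b, row.id_a)] = ks
    out = list(blocks)
    for block in out:
        for pair in block.pairs:
            key = (pair.gene_a, pair.gene_b)
            if key in lookup:
                pair.ks = lookup[key]
    return out


def block_median_ks(
    block: SyntenicBlock,
    min_pairs: int = DEFAULT_MIN_PAIRS,
    ks_ceiling: float = DEFAULT_KS_CEILING,
) -> Optional[float]:
    """Median Ks over a block's usable anchors, or ``None`` if too thin.

    Missing and saturated Ks are dropped *before* the size filter, so the
    ``min_pairs`` threshold counts usable pairs only. Even counts use the
    midpoint of the two central order statistics.
    """
    usable = block.usable_ks(ks_ceiling)
    if len(usable) < min_pairs:
        return None
    return float(np.median(usable))


def build_distribution(
    blocks: Iterable[SyntenicBlock],
    label: str,
    min_pairs: int = DEFAULT_MIN_PAIRS,
    ks_ceiling: float = DEFAULT_KS_CEILING,
) -> KsDistribution:
    """Collect block medians passing the size filter into a distribution."""
    medians = []
    for block in blocks:
        median = block_median_ks(block, min_pairs=min_pairs, ks_ceiling=ks_ceiling)
        if median is not None:
            medians.append(median)
    return KsDistribution(label=label, values=np.asarray(medians), threshold=min_pairs)


def write_block_table(
    blocks: Sequence[SyntenicBlock],
    path: str | Path,
    min_pairs: int = DEFAULT_MIN_PAIRS,
    ks_ceiling: float = DEFAULT_KS_CEILING,
) -> pd.DataFrame:
    rows = []
    for block in blocks:
        usable = block.usable_ks(ks_ceiling)
        rows.append(
            {
                "block_id": block.block_id,
                "n_pairs": len(block),
                "n_usable": len(usable),
                "median_ks": block_median_ks(block, min_pairs, ks_ceiling),
            }
        )
    table = pd.DataFrame(rows, columns=["block_id", "n_pairs", "n_usable", "median_ks"])
    table.to_csv(path, sep="\t", index=False)
    return table


def write_distribution(dist: KsDistribution, path: str | Path) -> None:
    """One value per line, preceded by '#'-metadata naming the comparison."""
    with open(path, "w") as handle:
        handle.write(f"# label={dist.label}\n")
        handle.write(f"# min_pairs={dist.threshold}\n")
        handle.write("median_ks\n")
        for value in dist.values:
            handle.write(f"{value:.10g}\n")


def read_distribution(path: str | Path) -> KsDistribution:
    label = Path(path).stem
    threshold = DEFAULT_MIN_PAIRS
    values = []
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if line.startswith("#"):
                if "=" in line:
                    key, _, val = line.lstrip("# ").partition("=")
                    if key.strip() == "label":
                        label = val.strip()
                    elif key.strip() == "min_pairs":
                        threshold = int(val)
                continue
            if not line or line == "median_ks":
                continue
            values.append(float(line))
    return KsDistribution(label=label, values=np.asarray(values), threshold=threshold)
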