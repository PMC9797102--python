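"""Seeded generator of synthetic pipeline inputs.

Every analysis stage can be exercised without any genome download: this
module emits codon-aligned gene pairs diverging under a chosen dN/dS,
syntenic anchor tables whose block medians cluster around configured WGD
peaks, 5'/3' LTR pairs diverged under a Jukes–Cantor clock, gene/TE genome
annotations with a controllable intact-near-gene bias, gene-to-GO maps with
planted accelerated categories, and per-ortholog substitution-count tables
for the binomial-test calibration. All outputs are deterministic functions
of the configuration seed (independent numbered substreams per product, so
generation order never matters), and every emitted record is traceable
through the accompanying truth object.

Default parameters mirror the study conditions the pipeline targets: three
within-genome Ks peaks at 0.329 / 0.502 / 2.019, a per-site per-year rate
of 7.06e-9, an LTR burst near 1 Ma, background dN/dS 0.2, and syntenic
blocks around 10-20 anchor pairs.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .kaks import CODON_TO_AA, SENSE_CODONS, STOP_CODONS, CodonAlignment, count_sites
from .ltr import MU_H_TIBETANA, LTRPair
from .proximity import AnnotatedGenomeModel
from .synteny import AnchorPair, SyntenicBlock

__all__ = [
    "WGDEvent",
    "LTRCohort",
    "TELayout",
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_gene_pairs",
    "simulate_ks_mixture",
    "simulate_synteny",
    "simulate_ltr_pairs",
    "simulate_annotations",
    "simulate_ortholog_counts",
    "simulate_dataset",
]

_BASES = "ACGT"

# fixed substream labels so each product is independent of generation order
_STREAM_GENES = 1
_STREAM_GENES_OTHER = 2
_STREAM_SYNTENY = 3
_STREAM_LTR = 4
_STREAM_ANNOT = 5
_STREAM_GO = 6


@dataclass(frozen=True)
class WGDEvent:
    """One polyploidization cohort in the block-median Ks mixture."""

    name: str
    mean_ks: float
    sd: float
    weight: float


@dataclass(frozen=True)
class LTRCohort:
    age_ma: float
    n_elements: int
    ltr_length: int = 1000


@dataclass(frozen=True)
class TELayout:
    n_intact: int = 300
    n_fragmentary: int = 300
    near_gene_fraction: float = 0.8
    near_gene_bp: int = 500
    chromosome_lengths: tuple[int, ...] = (2_000_000, 2_000_000, 2_000_000, 2_000_000)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic genome; defaults encode the study conditions."""

    seed: int = 20221214
    n_genes: int = 300
    codon_length: int = 150
    pair_ks_range: tuple[float, float] = (0.1, 0.4)
    omega_default: float = 0.2
    omega_profile: dict[str, float] = field(default_factory=dict)
    n_go_categories: int = 10
    genes_per_category: int = 30
    accelerated_categories: tuple[str, ...] = ("GO:0000001", "GO:0000002", "GO:0000003")
    accelerated_omega_factor: float = 3.0
    wgd_events: tuple[WGDEvent, ...] = (
        WGDEvent("HRT", 0.329, 0.04, 0.35),
        WGDEvent("HAT", 0.502, 0.06, 0.35),
        WGDEvent("ECH", 2.019, 0.25, 0.30),
    )
    n_blocks: int = 120
    pairs_per_block: int = 15
    thin_block_fraction: float = 0.1
    pair_ks_noise: float = 0.02
    ltr_cohorts: tuple[LTRCohort, ...] = (LTRCohort(age_ma=1.0, n_elements=500, ltr_length=1000),)
    mu: float = MU_H_TIBETANA
    te_layout: TELayout = field(default_factory=TELayout)
    gene_length_bp: int = 1500

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.codon_length <= 0 or self.n_blocks <= 0:
            raise ValueError("counts must be positive")
        if any(event.mean_ks <= 0 for event in self.wgd_events):
            raise ValueError("WGD target Ks must be positive")
        if not 0.0 <= self.te_layout.near_gene_fraction <= 1.0:
            raise ValueError("near_gene_fraction must lie in [0, 1]")
        for event in self.wgd_events:
            if event.mean_ks >= 3.0:
                import warnings

                warnings.warn(
                    f"WGD cohort {event.name} at Ks {event.mean_ks} approaches "
                    "saturation; NG86 recovery will be biased low",
                    stacklevel=2,
                )

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass
class SyntheticTruth:
    """Ground truth for every emitted record."""

    gene_omega: dict[str, float] = field(default_factory=dict)
    gene_realized_ks: dict[str, float] = field(default_factory=dict)
    gene_realized_counts: dict[str, tuple[int, int]] = field(default_factory=dict)
    block_event: dict[str, str] = field(default_factory=dict)
    ltr_age: dict[str, float] = field(default_factory=dict)
    accelerated_categories: list[str] = field(default_factory=list)
    gene2go: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = dataclasses.asdict(self)
        return json.dumps(payload, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# gene pairs


def _assign_go(cfg: SimulationConfig) -> dict[str, list[str]]:
    """Deterministic gene -> GO assignment (round-robin with extra draws)."""
    rng = cfg.rng(_STREAM_GO)
    categories = [f"GO:{i + 1:07d}" for i in range(cfg.n_go_categories)]
    mapping: dict[str, list[str]] = {}
    for i in range(cfg.n_genes):
        gene = f"g{i:05d}"
        primary = categories[i % cfg.n_go_categories]
        terms = [primary]
        if rng.random() < 0.3:  # some genes carry a second annotation
            extra = categories[int(rng.integers(cfg.n_go_categories))]
            if extra not in terms:
                terms.append(extra)
        mapping[gene] = terms
    return mapping


def _gene_omega(cfg: SimulationConfig, gene2go: dict[str, list[str]], gene: str) -> float:
    omega = cfg.omega_default
    for go_id in gene2go.get(gene, ()):
        if go_id in cfg.omega_profile:
            omega = max(omega, cfg.omega_profile[go_id])
        elif go_id in cfg.accelerated_categories:
            omega = max(omega, cfg.omega_default * cfg.accelerated_omega_factor)
    return omega


def _random_cds(rng: np.random.Generator, n_codons: int) -> list[str]:
    idx = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    return [SENSE_CODONS[i] for i in idx]


def _synonymous_sites(codons: Sequence[str]) -> float:
    return sum(count_sites(c)[1] for c in codons)


def _evolve_pair(
    rng: np.random.Generator,
    ancestor: list[str],
    target_ks: float,
    omega: float,
) -> tuple[list[str], int, int]:
    """Evolve one copy until the drawn number of synonymous hits accrued.

    Substitutions are proposed uniformly over positions and alternative
    bases; proposals creating stops are rejected, synonymous proposals are
    always accepted and nonsynonymous ones with probability omega — a
    neutral-proposal filter whose realized Ka/Ks approximates omega.
    """
    derived = list(ancestor)
    s_sites = _synonymous_sites(ancestor)
    n_syn_target = int(rng.poisson(target_ks * s_sites))
    syn = nonsyn = 0
    n_codons = len(derived)
    while syn < n_syn_target:
        codon_idx = int(rng.integers(n_codons))
        pos = int(rng.integers(3))
        codon = derived[codon_idx]
        base = _BASES[int(rng.integers(4))]
        if base == codon[pos]:
            continue
        mutant = codon[:pos] + base + codon[pos + 1 :]
        if mutant in STOP_CODONS:
            continue
        if CODON_TO_AA[mutant] == CODON_TO_AA[codon]:
            derived[codon_idx] = mutant
            syn += 1
        elif rng.random() < omega:
            derived[codon_idx] = mutant
            nonsyn += 1
    return derived, syn, nonsyn


def simulate_gene_pairs(
    cfg: SimulationConfig,
    truth: Optional[SyntheticTruth] = None,
    lineage: str = "focal",
) -> tuple[list[CodonAlignment], SyntheticTruth]:
    """Codon-aligned gene pairs (gene vs outgroup ortholog) with known omega.

    Pair i aligns ``g{i}`` with outgroup ortholog ``og{i}``; the focal and
    contrast lineages share outgroup ids so they can be joined into
    ortholog triples.
    """
    truth = truth or SyntheticTruth()
    if not truth.gene2go:
        truth.gene2go = _assign_go(cfg)
        truth.accelerated_categories = list(cfg.accelerated_categories)
    rng = cfg.rng(_STREAM_GENES if lineage == "focal" else _STREAM_GENES_OTHER)
    prefix = "g" if lineage == "focal" else "h"
    alignments = []
    for i in range(cfg.n_genes):
        focal_key = f"g{i:05d}"
        gene = f"{prefix}{i:05d}"
        ancestor = _random_cds(rng, cfg.codon_length)
        target_ks = float(rng.uniform(*cfg.pair_ks_range))
        omega = _gene_omega(cfg, truth.gene2go, focal_key) if lineage == "focal" else cfg.omega_default
        derived, syn, nonsyn = _evolve_pair(rng, ancestor, target_ks, omega)
        alignments.append(
            CodonAlignment(
                id_a=gene,
                id_b=f"og{i:05d}",
                seq_a="".join(derived),
                seq_b="".join(ancestor),
            )
        )
        if lineage == "focal":
            truth.gene_omega[gene] = omega
            truth.gene_realized_ks[gene] = syn / _synonymous_sites(ancestor)
            truth.gene_realized_counts[gene] = (nonsyn, syn)
    return alignments, truth


# ---------------------------------------------------------------------------
# synteny / Ks mixtures


def simulate_ks_mixture(
    n: int,
    means: Sequence[float],
    sds: Sequence[float],
    weights: Sequence[float],
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Draw n positive values from a Gaussian mixture (redraw any <= 0)."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()
    comp = rng.choice(means.size, size=n, p=weights)
    values = rng.normal(means[comp], sds[comp])
    while np.any(values <= 0):
        redraw = values <= 0
        values[redraw] = rng.normal(means[comp[redraw]], sds[comp[redraw]])
    return values


def simulate_synteny(
    cfg: SimulationConfig, truth: Optional[SyntheticTruth] = None
) -> tuple[list[SyntenicBlock], SyntheticTruth]:
    """Syntenic blocks whose pair Ks values cluster around the WGD cohorts.

    Each block draws a centre from its cohort's Normal(mean, sd) and adds
    small within-block noise, so block medians follow the configured
    mixture. A ``thin_block_fraction`` of blocks is emitted below the
    10-pair filter threshold to exercise it.
    """
    truth = truth or SyntheticTruth()
    rng = cfg.rng(_STREAM_SYNTENY)
    weights = np.array([event.weight for event in cfg.wgd_events], dtype=float)
    weights /= weights.sum()
    blocks = []
    for b in range(cfg.n_blocks):
        event = cfg.wgd_events[int(rng.choice(len(cfg.wgd_events), p=weights))]
        block_id = f"block{b:04d}"
        truth.block_event[block_id] = event.name
        if rng.random() < cfg.thin_block_fraction:
            size = int(rng.integers(3, 10))  # deliberately below the >= 10 filter
        else:
            size = int(rng.integers(10, 2 * cfg.pairs_per_block - 9))
        center = -1.0
        while center <= 0:
            center = rng.normal(event.mean_ks, event.sd)
        block = SyntenicBlock(block_id)
        for p in range(size):
            ks = -1.0
            while ks <= 0:
                ks = center + rng.normal(0.0, cfg.pair_ks_noise)
            block.pairs.append(
                AnchorPair(block_id, f"sa{b:04d}_{p:03d}", f"sb{b:04d}_{p:03d}", float(ks))
            )
        blocks.append(block)
    return blocks, truth


def write_anchor_tsv(blocks: Sequence[SyntenicBlock], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("block_id\tgene_a\tgene_b\tks\n")
        for block in blocks:
            for pair in block.pairs:
                ks = "" if pair.ks is None else f"{pair.ks:.10g}"
                handle.write(f"{block.block_id}\t{pair.gene_a}\t{pair.gene_b}\t{ks}\n")


# ---------------------------------------------------------------------------
# LTR pairs


def simulate_ltr_pairs(
    cfg: SimulationConfig, truth: Optional[SyntheticTruth] = None
) -> tuple[list[LTRPair], SyntheticTruth]:
    """5'/3' LTR pairs identical at birth, diverged by 2*mu*age under JC69.

    Each aligned column of the 3' copy differs from the 5' copy with the
    Jukes–Cantor mismatch probability p = 3/4 (1 - exp(-4k/3)) at
    k = 2 mu T; a mismatching column takes one of the three other bases
    uniformly.
    """
    truth = truth or SyntheticTruth()
    rng = cfg.rng(_STREAM_LTR)
    pairs = []
    counter = 0
    for cohort in cfg.ltr_cohorts:
        k_true = 2.0 * cfg.mu * cohort.age_ma * 1e6
        p_mismatch = 0.75 * (1.0 - math.exp(-4.0 * k_true / 3.0))
        for _ in range(cohort.n_elements):
            element_id = f"ltr{counter:05d}"
            counter += 1
            seq5 = rng.integers(0, 4, size=cohort.ltr_length)
            offsets = rng.integers(1, 4, size=cohort.ltr_length)
            mutate = rng.random(cohort.ltr_length) < p_mismatch
            seq3 = np.where(mutate, (seq5 + offsets) % 4, seq5)
            superfamily = "Gypsy" if rng.random() < 0.55 else "Copia"
            pairs.append(
                LTRPair(
                    element_id=element_id,
                    seq5="".join(_BASES[b] for b in seq5),
                    seq3="".join(_BASES[b] for b in seq3),
                    superfamily=superfamily,
                )
            )
            truth.ltr_age[element_id] = cohort.age_ma
    return pairs, truth


def write_ltr_fasta(pairs: Sequence[LTRPair], path: str | Path) -> None:
    with open(path, "w") as handle:
        for pair in pairs:
            handle.write(f">{pair.element_id}:5ltr superfamily={pair.superfamily}\n{pair.seq5}\n")
            handle.write(f">{pair.element_id}:3ltr superfamily={pair.superfamily}\n{pair.seq3}\n")


# ---------------------------------------------------------------------------
# genome annotations


def simulate_annotations(
    cfg: SimulationConfig, truth: Optional[SyntheticTruth] = None
) -> tuple[AnnotatedGenomeModel, SyntheticTruth]:
    """Gene and TE intervals with a controllable intact-near-gene bias.

    Genes are placed one per evenly sized slot (guaranteed non-overlap);
    intact TEs land within ``near_gene_bp`` of a random gene with
    probability ``near_gene_fraction`` and uniformly otherwise, and
    fragmentary TEs always uniformly.
    """
    import pandas as pd

    truth = truth or SyntheticTruth()
    if not truth.gene2go:
        truth.gene2go = _assign_go(cfg)
        truth.accelerated_categories = list(cfg.accelerated_categories)
    rng = cfg.rng(_STREAM_ANNOT)
    layout = cfg.te_layout
    chroms = {f"chr{i + 1}": length for i, length in enumerate(layout.chromosome_lengths)}
    chrom_names = list(chroms)

    genes_per_chrom = int(np.ceil(cfg.n_genes / len(chrom_names)))
    gene_rows = []
    gene_index = 0
    for chrom in chrom_names:
        length = chroms[chrom]
        slot = length // genes_per_chrom
        if slot <= cfg.gene_length_bp:
            raise ValueError(
                f"chromosome {chrom} ({length} bp) too short for {genes_per_chrom} genes "
                f"of {cfg.gene_length_bp} bp"
            )
        for s in range(genes_per_chrom):
            if gene_index >= cfg.n_genes:
                break
            start = s * slot + int(rng.integers(0, slot - cfg.gene_length_bp))
            gene_rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": start + cfg.gene_length_bp,
                    "strand": "+" if rng.random() < 0.5 else "-",
                    "id": f"g{gene_index:05d}",
                }
            )
            gene_index += 1
    genes = pd.DataFrame(gene_rows)

    te_rows = []

    def place_uniform(length_bp: int) -> tuple[str, int, int]:
        chrom = chrom_names[int(rng.integers(len(chrom_names)))]
        start = int(rng.integers(0, chroms[chrom] - length_bp))
        return chrom, start, start + length_bp

    def place_near_gene(length_bp: int) -> tuple[str, int, int]:
        gene = gene_rows[int(rng.integers(len(gene_rows)))]
        gap = int(rng.integers(0, layout.near_gene_bp + 1))
        if rng.random() < 0.5:
            start = gene["end"] + gap
        else:
            start = gene["start"] - gap - length_bp
        chrom_len = chroms[gene["chrom"]]
        start = max(0, min(start, chrom_len - length_bp))
        return gene["chrom"], start, start + length_bp

    for i in range(layout.n_intact + layout.n_fragmentary):
        status = "intact" if i < layout.n_intact else "fragmentary"
        length_bp = int(rng.integers(300, 3000))
        if status == "intact" and rng.random() < layout.near_gene_fraction:
            chrom, start, end = place_near_gene(length_bp)
        else:
            chrom, start, end = place_uniform(length_bp)
        te_rows.append(
            {
                "chrom": chrom,
                "start": start,
                "end": end,
                "id": f"te{i:05d}",
                "superfamily": "Gypsy" if rng.random() < 0.55 else "Copia",
                "status": status,
            }
        )
    tes = pd.DataFrame(te_rows)
    model = AnnotatedGenomeModel(chromosomes=chroms, genes=genes, tes=tes)
    return model, truth


def write_gff3(model: AnnotatedGenomeModel, path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for chrom, length in model.chromosomes.items():
            handle.write(f"##sequence-region {chrom} 1 {length}\n")
        for row in model.genes.itertuples(index=False):
            handle.write(
                f"{row.chrom}\twgdkit_sim\tgene\t{row.start + 1}\t{row.end}\t.\t"
                f"{row.strand}\t.\tID={row.id}\n"
            )


def write_te_table(model: AnnotatedGenomeModel, path: str | Path) -> None:
    model.tes.to_csv(path, sep="\t", index=False)


def write_gene2go(gene2go: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("gene\tgo\n")
        for gene in sorted(gene2go):
            for go_id in gene2go[gene]:
                handle.write(f"{gene}\t{go_id}\n")


# ---------------------------------------------------------------------------
# ortholog count tables (binomial-test calibration)


def simulate_ortholog_counts(
    n_categories: int,
    orthologs_per_category: int,
    p_null: float,
    rng: np.random.Generator | int,
    enriched: Optional[dict[str, float]] = None,
    mean_diffs_per_ortholog: float = 20.0,
) -> dict[str, list[tuple[int, int]]]:
    """Per-category (n_diff, s_diff) count lists under a binomial model.

    Each ortholog draws a Poisson total number of differences and splits it
    binomially with the category's nonsynonymous fraction. ``enriched``
    maps category ids to an odds multiplier on ``p_null`` (a 3x odds
    enrichment models a threefold dN/dS increase at fixed sites).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    enriched = enriched or {}
    odds_null = p_null / (1.0 - p_null)
    categories: dict[str, list[tuple[int, int]]] = {}
    for c in range(n_categories):
        go_id = f"GO:{c + 1:07d}"
        factor = enriched.get(go_id, 1.0)
        odds = odds_null * factor
        p = odds / (1.0 + odds)
        members = []
        for _ in range(orthologs_per_category):
            total = int(rng.poisson(mean_diffs_per_ortholog))
            n_diff = int(rng.binomial(total, p)) if total else 0
            members.append((n_diff, total - n_diff))
        categories[go_id] = members
    return categories


# ---------------------------------------------------------------------------
# full dataset


def _write_pairs_fasta(alignments: Sequence[CodonAlignment], path: str | Path) -> None:
    with open(path, "w") as handle:
        for aln in alignments:
            handle.write(f">{aln.id_a}\n{aln.seq_a}\n>{aln.id_b}\n{aln.seq_b}\n")


def simulate_dataset(cfg: SimulationConfig, outdir: str | Path) -> SyntheticTruth:
    """Emit the complete synthetic input directory.

    Files: genes.fasta / genes_other.fasta (codon-aligned pairs for the
    focal and contrast lineages vs the shared outgroup), triples.tsv,
    anchors.tsv, ltr_pairs.fasta, genes.gff3, tes.bed, gene2go.tsv,
    truth.json and config.json (verbatim configuration echo).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = SyntheticTruth()

    focal, truth = simulate_gene_pairs(cfg, truth, lineage="focal")
    other, truth = simulate_gene_pairs(cfg, truth, lineage="other")
    _write_pairs_fasta(focal, outdir / "genes.fasta")
    _write_pairs_fasta(other, outdir / "genes_other.fasta")
    with open(outdir / "triples.tsv", "w") as handle:
        handle.write("gene_focal\tgene_other\tgene_outgroup\n")
        for i in range(cfg.n_genes):
            handle.write(f"g{i:05d}\th{i:05d}\tog{i:05d}\n")

    blocks, truth = simulate_synteny(cfg, truth)
    write_anchor_tsv(blocks, outdir / "anchors.tsv")

    ltr_pairs, truth = simulate_ltr_pairs(cfg, truth)
    write_ltr_fasta(ltr_pairs, outdir / "ltr_pairs.fasta")

    model, truth = simulate_annotations(cfg, truth)
    write_gff3(model, outdir / "genes.gff3")
    write_te_table(model, outdir / "tes.bed")
    write_gene2go(truth.gene2go, outdir / "gene2go.tsv")

    (outdir / "truth.json").write_text(truth.to_json())
    config_payload = dataclasses.asdict(cfg)
    (outdir / "config.json").write_text(json.dumps(config_payload, indent=1, sort_keys=True))
    return truth
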