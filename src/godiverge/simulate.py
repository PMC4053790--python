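"""Synthetic ortholog datasets with known selection structure.

Generates genome-scale sets of pairwise codon alignments by evolving two
lineages from a random ancestral coding sequence under a proposal–acceptance
scheme: single-base proposals with transition/transversion bias κ, synonymous
changes always accepted, non-synonymous changes accepted with probability
min(1, ω), stop-creating proposals rejected.  Each lineage accumulates a
Poisson(dS_target · S₀) number of accepted synonymous substitutions (S₀ the
ancestor's equal-weight synonymous site count), so realized per-lineage
synonymous divergence concentrates at dS_target and pairwise ks at about
2·dS_target.

Categories are planted by assigning genes to GO-like terms and multiplying
their ω by a per-category factor (>1 rapid, <1 slow, =1 null); genes carrying
several terms multiply all their factors.  Unannotated filler genes are
included so permutation over the full universe is exercised.  The generator
emits exactly the file formats the pipeline consumes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.Data import CodonTable

from .annotation import GoAnnotation
from .codon_counts import (
    CodonAlignment,
    SENSE_CODONS,
    STOP_CODONS,
    count_sites,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CategorySpec",
    "SimulationConfig",
    "TruthTable",
    "simulate_gene_pair",
    "simulate_dataset",
    "null_config",
    "planted_config",
    "write_dataset",
]

_BASES = "ACGT"
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_AA = dict(CodonTable.unambiguous_dna_by_id[1].forward_table)


@dataclass(frozen=True)
class CategorySpec:
    """A planted category: term id, member count, and the ω multiplier applied
    to its member genes (1.0 = null)."""

    term_id: str
    n_genes: int
    omega_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.omega_multiplier <= 0:
            raise ValueError("omega multiplier must be positive")
        if self.n_genes < 1:
            raise ValueError("category needs at least one gene")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a synthetic ortholog set.

    Defaults emulate a scaled-down passerine ortholog comparison: a few
    thousand gene pairs of 100-300 codons, per-lineage synonymous divergence
    0.1 (pairwise ks ≈ 0.2), baseline ω = 0.2 (typical genome-wide
    purifying selection), transition bias κ = 2.
    """

    n_genes: int = 2000
    gene_length_codons: tuple[int, int] = (100, 300)
    dS_target: float = 0.1
    omega0: float = 0.2
    kappa: float = 2.0
    categories: tuple[CategorySpec, ...] = ()
    overlap: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.gene_length_codons
        if not (1 <= lo <= hi):
            raise ValueError("invalid gene length range")
        if not 0 <= self.dS_target < 0.75:
            raise ValueError("dS_target must be in [0, 0.75)")
        if self.omega0 <= 0 or self.kappa <= 0:
            raise ValueError("omega0 and kappa must be positive")
        total = sum(c.n_genes for c in self.categories)
        if any(c.n_genes > self.n_genes for c in self.categories):
            raise ValueError("category larger than the gene set")
        if not self.overlap and total > self.n_genes:
            raise ValueError(
                f"disjoint categories need {total} genes but n_genes={self.n_genes}"
            )


@dataclass(frozen=True)
class TruthTable:
    """Ground truth of a simulated dataset: per-gene ω and per-category direction."""

    gene_omega: dict[str, float]
    category_direction: dict[str, str]  # rapid | slow | null

    @staticmethod
    def direction(multiplier: float) -> str:
        if multiplier > 1.0:
            return "rapid"
        if multiplier < 1.0:
            return "slow"
        return "null"


def _evolve(
    codons: list[str],
    omega: float,
    n_syn_target: int,
    kappa: float,
    rng: np.random.Generator,
) -> tuple[list[str], int]:
    """Evolve one lineage until n_syn_target synonymous substitutions are fixed.

    Returns the sequence and the number of non-synonymous events fixed.
    """
    seq = list(codons)
    L = len(seq)
    accepted_syn = 0
    accepted_nonsyn = 0
    guard = 0
    max_iter = 10_000 + 2_000 * max(1, n_syn_target)
    p_trans = kappa / (kappa + 2.0)
    while accepted_syn < n_syn_target:
        guard += 1
        if guard > max_iter:
            raise RuntimeError("evolution stalled; config likely degenerate")
        site = int(rng.integers(3 * L))
        ci, pos = divmod(site, 3)
        codon = seq[ci]
        old = codon[pos]
        u = rng.random()
        if u < p_trans:
            new = _TRANSITION[old]
        else:
            tv = [b for b in _BASES if b != old and b != _TRANSITION[old]]
            new = tv[0] if u < p_trans + (1 - p_trans) / 2 else tv[1]
        mutant = codon[:pos] + new + codon[pos + 1 :]
        if mutant in STOP_CODONS:
            continue
        if _AA[mutant] == _AA[codon]:
            seq[ci] = mutant
            accepted_syn += 1
        elif omega > 0 and (omega >= 1.0 or rng.random() < omega):
            seq[ci] = mutant
            accepted_nonsyn += 1
    return seq, accepted_nonsyn


def simulate_gene_pair(
    gene_id: str,
    length: int,
    omega: float,
    dS_target: float,
    kappa: float,
    rng: np.random.Generator,
    return_events: bool = False,
) -> CodonAlignment | tuple[CodonAlignment, dict[str, int]]:
    """Simulate one orthologous gene pair of ``length`` codons.

    Both lineages descend independently from a uniform-sense-codon ancestor;
    each fixes Poisson(dS_target · S₀) synonymous substitutions.  ω = 0 fixes
    zero non-synonymous events (pairwise counting may still attribute small
    fractional non-synonymous counts to codons hit more than once, a known
    property of pathway averaging); dS_target = 0 gives identical sequences.
    With ``return_events`` the realized event totals are returned alongside.
    """
    if omega < 0:
        raise ValueError("omega must be non-negative")
    if not 0 <= dS_target < 0.75:
        raise ValueError("dS_target must be in [0, 0.75)")
    anc = [SENSE_CODONS[i] for i in rng.integers(len(SENSE_CODONS), size=length)]
    S0 = sum(count_sites(c)[0] for c in anc)
    seqs = []
    syn_events = 0
    nonsyn_events = 0
    for _ in range(2):
        n_target = int(rng.poisson(dS_target * S0)) if dS_target > 0 else 0
        seq, n_nonsyn = _evolve(anc, omega, n_target, kappa, rng)
        seqs.append("".join(seq))
        syn_events += n_target
        nonsyn_events += n_nonsyn
    aln = CodonAlignment(gene_id, seqs[0], seqs[1])
    if return_events:
        return aln, {"syn_events": syn_events, "nonsyn_events": nonsyn_events}
    return aln


def _assign_members(
    config: SimulationConfig, gene_ids: Sequence[str], rng: np.random.Generator
) -> dict[str, list[str]]:
    members: dict[str, list[str]] = {}
    if config.overlap:
        for spec in config.categories:
            idx = rng.choice(len(gene_ids), size=spec.n_genes, replace=False)
            members[spec.term_id] = [gene_ids[i] for i in sorted(idx)]
    else:
        cursor = 0
        for spec in config.categories:
            members[spec.term_id] = list(gene_ids[cursor : cursor + spec.n_genes])
            cursor += spec.n_genes
    return members


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[list[CodonAlignment], GoAnnotation, TruthTable]:
    """Simulate a full dataset: alignments, annotation and ground truth.

    Per-gene ω is ω₀ times the product of the multipliers of every category
    the gene belongs to.  Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    width = max(4, len(str(config.n_genes - 1)))
    gene_ids = [f"g{i:0{width}d}" for i in range(config.n_genes)]
    members = _assign_members(config, gene_ids, rng)

    multiplier = {g: 1.0 for g in gene_ids}
    mapping: dict[str, set[str]] = {}
    for spec in config.categories:
        for g in members[spec.term_id]:
            multiplier[g] *= spec.omega_multiplier
            mapping.setdefault(g, set()).add(spec.term_id)

    lengths = rng.integers(
        config.gene_length_codons[0], config.gene_length_codons[1] + 1, size=config.n_genes
    )
    alignments = []
    gene_omega = {}
    for g, L in zip(gene_ids, lengths):
        w = config.omega0 * multiplier[g]
        gene_omega[g] = w
        alignments.append(
            simulate_gene_pair(g, int(L), w, config.dS_target, config.kappa, rng)
        )
    annotation = GoAnnotation(mapping, gene_ids)
    truth = TruthTable(
        gene_omega=gene_omega,
        category_direction={
            c.term_id: TruthTable.direction(c.omega_multiplier) for c in config.categories
        },
    )
    return alignments, annotation, truth


def null_config(
    n_genes: int = 2000,
    n_categories: int = 100,
    category_size: int = 20,
    seed: int = 0,
    **kw,
) -> SimulationConfig:
    """All-null conditions: uniform ω, disjoint categories of equal size."""
    cats = tuple(
        CategorySpec(f"GO:{i:07d}", category_size, 1.0) for i in range(n_categories)
    )
    return SimulationConfig(n_genes=n_genes, categories=cats, seed=seed, **kw)


def planted_config(
    n_rapid: int = 5,
    rapid_multiplier: float = 3.0,
    n_categories: int = 50,
    category_size: int = 20,
    n_filler_genes: int = 1000,
    seed: int = 0,
    **kw,
) -> SimulationConfig:
    """Planted-effect conditions: n_rapid accelerated categories among
    n_categories total, plus unannotated filler genes."""
    cats = [
        CategorySpec(f"GO:{i:07d}", category_size, rapid_multiplier if i < n_rapid else 1.0)
        for i in range(n_categories)
    ]
    n_genes = n_categories * category_size + n_filler_genes
    return SimulationConfig(n_genes=n_genes, categories=tuple(cats), seed=seed, **kw)


def write_dataset(
    alignments: Sequence[CodonAlignment],
    annotation: GoAnnotation,
    truth: TruthTable,
    config: SimulationConfig,
    outdir: str | Path,
) -> dict[str, Path]:
    """Emit alignments FASTA, annotation TSV, truth TSVs and a config snapshot."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "alignments": outdir / "alignments.fasta",
        "annotation": outdir / "annotation.tsv",
        "truth_genes": outdir / "truth_genes.tsv",
        "truth_categories": outdir / "truth_categories.tsv",
        "config": outdir / "config.json",
    }
    with open(paths["alignments"], "w") as fh:
        for aln in alignments:
            fh.write(f">{aln.gene_id}|A\n{aln.seq_a}\n>{aln.gene_id}|B\n{aln.seq_b}\n")
    with open(paths["annotation"], "w") as fh:
        for gene, terms in annotation.items():
            for t in sorted(terms):
                fh.write(f"{gene}\t{t}\n")
    with open(paths["truth_genes"], "w") as fh:
        fh.write("gene_id\tomega\n")
        for g, w in truth.gene_omega.items():
            fh.write(f"{g}\t{w:.6g}\n")
    with open(paths["truth_categories"], "w") as fh:
        fh.write("term_id\tdirection\n")
        for t, d in truth.category_direction.items():
            fh.write(f"{t}\t{d}\n")
    cfg = asdict(config)
    cfg["categories"] = [asdict(c) for c in config.categories]
    paths["config"].write_text(json.dumps(cfg, indent=2) + "\n")
    return paths
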