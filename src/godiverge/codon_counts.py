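"""Synonymous/non-synonymous site and substitution counting on pairwise codon alignments.

Implements equal-weight (Nei–Gojobori-style) counting: each codon position is
apportioned into synonymous and non-synonymous *sites* by the fraction of the
three possible single-base changes that are synonymous, and codon pairs
differing at more than one position have their substitutions averaged over all
minimal single-step mutational pathways, excluding pathways that pass through a
stop codon.  The per-gene outputs (a_i, A_i, s_i, S_i) are what the
category-level divergence test consumes; counts estimated externally with a
codon maximum-likelihood model can be imported verbatim through
:func:`read_counts_table` and are interchangeable downstream.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

logger = logging.getLogger(__name__)

__all__ = [
    "CodonAlignment",
    "SubstitutionCounts",
    "GeneRates",
    "count_sites",
    "count_substitutions_pair",
    "count_gene",
    "count_alignments",
    "jukes_cantor",
    "read_alignments",
    "read_counts_table",
    "write_counts_table",
    "SENSE_CODONS",
    "STOP_CODONS",
]

_BASES = "ACGT"
_STANDARD = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_STANDARD.stop_codons)
SENSE_CODONS = tuple(sorted(_STANDARD.forward_table))
_AA = dict(_STANDARD.forward_table)


class CodonCountError(ValueError):
    """Invalid codon or alignment passed to a counting routine."""


@dataclass(frozen=True)
class CodonAlignment:
    """A gene's pairwise in-frame aligned coding sequences.

    Both sequences must have equal length, a multiple of 3, over the
    alphabet ``A C G T N -``; gaps must fill whole codons (the alignment is
    codon-structured).
    """

    gene_id: str
    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        a, b = self.seq_a.upper(), self.seq_b.upper()
        object.__setattr__(self, "seq_a", a)
        object.__setattr__(self, "seq_b", b)
        if len(a) != len(b):
            raise CodonCountError(
                f"{self.gene_id}: aligned sequences differ in length ({len(a)} vs {len(b)})"
            )
        if len(a) % 3 != 0:
            raise CodonCountError(
                f"{self.gene_id}: alignment length {len(a)} is not a multiple of 3"
            )
        allowed = set("ACGTN-")
        for name, s in (("seq_a", a), ("seq_b", b)):
            bad = set(s) - allowed
            if bad:
                raise CodonCountError(f"{self.gene_id}/{name}: invalid characters {sorted(bad)}")
            for i in range(0, len(s), 3):
                codon = s[i : i + 3]
                if "-" in codon and codon != "---":
                    raise CodonCountError(
                        f"{self.gene_id}/{name}: partial-codon gap {codon!r} at codon {i // 3}"
                    )

    @property
    def n_codons(self) -> int:
        return len(self.seq_a) // 3

    def codon_pairs(self) -> Iterator[tuple[str, str]]:
        for i in range(0, len(self.seq_a), 3):
            yield self.seq_a[i : i + 3], self.seq_b[i : i + 3]


@dataclass(frozen=True)
class SubstitutionCounts:
    """Per-gene substitution/site counts: a (non-syn subs), A (non-syn sites),
    s (syn subs), S (syn sites), over ``codons_used`` retained codon columns.

    Counts may be fractional (pathway averages); A + S == 3 * codons_used when
    codons were actually counted.  ``codons_used`` is None for counts imported
    from an external estimator that does not report it (site totals then need
    not be 3 per codon).
    """

    gene_id: str
    a: float
    A: float
    s: float
    S: float
    codons_used: int | None = None

    def __post_init__(self) -> None:
        if min(self.a, self.A, self.s, self.S) < 0:
            raise CodonCountError(f"{self.gene_id}: negative count")
        if (
            self.codons_used is not None
            and self.codons_used > 0
            and abs(self.A + self.S - 3 * self.codons_used) > 1e-9
        ):
            raise CodonCountError(
                f"{self.gene_id}: site counts A+S={self.A + self.S} != 3*codons_used"
            )

    @property
    def usable(self) -> bool:
        return self.codons_used != 0 and self.A > 0 and self.S > 0

    def rates(self) -> "GeneRates":
        if not self.usable:
            raise CodonCountError(f"{self.gene_id}: no usable codons, rates undefined")
        ka = self.a / self.A
        ks = self.s / self.S
        return GeneRates(self.gene_id, ka, ks, ka / ks if ks > 0 else None)


@dataclass(frozen=True)
class GeneRates:
    """Per-gene ka = a/A, ks = s/S and their ratio (None when ks == 0)."""

    gene_id: str
    ka: float
    ks: float
    ka_ks: float | None


def _check_sense(codon: str) -> str:
    codon = codon.upper()
    if len(codon) != 3 or any(b not in _BASES for b in codon):
        raise CodonCountError(f"not an unambiguous codon: {codon!r}")
    if codon in STOP_CODONS:
        raise CodonCountError(f"stop codon: {codon}")
    return codon


def count_sites(codon: str) -> tuple[float, float]:
    """Apportion a sense codon's 3 positions into (synonymous, non-synonymous) sites.

    Each position contributes (number of synonymous single-base alternatives)/3
    to the synonymous total; changes to stop codons count as non-synonymous.
    The two components always sum to 3.
    """
    codon = _check_sense(codon)
    syn = 0.0
    aa = _AA[codon]
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if mutant not in STOP_CODONS and _AA[mutant] == aa:
                syn += 1.0
    syn /= 3.0
    return syn, 3.0 - syn


def _step_class(c1: str, c2: str) -> float:
    """1.0 if the single-base step c1->c2 is synonymous, else 0.0.

    Steps touching a stop codon are classified non-synonymous; they only occur
    on the all-pathways-blocked fallback.
    """
    if c1 in STOP_CODONS or c2 in STOP_CODONS:
        return 0.0
    return 1.0 if _AA[c1] == _AA[c2] else 0.0


def count_substitutions_pair(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Average (synonymous, non-synonymous) substitution counts between two sense codons.

    For codons differing at d positions, every ordering of the d single-base
    steps is a pathway; pathways whose intermediate codons are stops are
    excluded (if every pathway is blocked, the average is over all pathways,
    with stop-touching steps counted non-synonymous).  Returns fractions that
    sum exactly to d.
    """
    codon_a, codon_b = _check_sense(codon_a), _check_sense(codon_b)
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return 0.0, 0.0
    clean: list[float] = []
    blocked: list[float] = []
    for order in itertools.permutations(diff):
        cur = codon_a
        syn = 0.0
        hits_stop = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            syn += _step_class(cur, nxt)
            if nxt in STOP_CODONS:
                hits_stop = True
            cur = nxt
        (blocked if hits_stop else clean).append(syn)
    pool = clean if clean else blocked
    syn_avg = sum(pool) / len(pool)
    return syn_avg, len(diff) - syn_avg


# Lazily built lookup tables: per-codon sites and per-pair substitution averages.
_SITE_TABLE: dict[str, tuple[float, float]] = {}
_PAIR_TABLE: dict[tuple[str, str], tuple[float, float]] = {}


def _tables() -> tuple[dict, dict]:
    if not _SITE_TABLE:
        for c in SENSE_CODONS:
            _SITE_TABLE[c] = count_sites(c)
        for c1 in SENSE_CODONS:
            for c2 in SENSE_CODONS:
                if c1 <= c2:
                    v = count_substitutions_pair(c1, c2)
                    _PAIR_TABLE[(c1, c2)] = v
                    _PAIR_TABLE[(c2, c1)] = v
    return _SITE_TABLE, _PAIR_TABLE


def count_gene(alignment: CodonAlignment) -> SubstitutionCounts:
    """Aggregate site and substitution counts over an aligned gene pair.

    Codon columns containing a gap, an N, or a stop codon in either sequence
    are skipped entirely and excluded from ``codons_used``.  Site counts are
    averaged over the two sequences; substitution counts are pathway averages
    summed over retained columns.  A gene with zero retained codons is
    returned with codons_used == 0 and must be excluded downstream.
    """
    sites, pairs = _tables()
    a = s = A = S = 0.0
    used = 0
    for ca, cb in alignment.codon_pairs():
        if ca not in sites or cb not in sites:  # gap, N or stop in either
            continue
        used += 1
        sa, na = sites[ca]
        sb, nb = sites[cb]
        S += (sa + sb) / 2.0
        A += (na + nb) / 2.0
        syn, nonsyn = pairs[(ca, cb)]
        s += syn
        a += nonsyn
    if used == 0:
        logger.warning("%s: no usable codon columns; gene flagged unusable", alignment.gene_id)
    # pin the A+S invariant against float drift from the half-site averaging
    if used and abs(A + S - 3 * used) < 1e-9:
        S = 3 * used - A
    return SubstitutionCounts(alignment.gene_id, a, A, s, S, used)


def count_alignments(alignments: Iterable[CodonAlignment]) -> list[SubstitutionCounts]:
    """count_gene over a collection, dropping unusable genes with a logged count."""
    out, dropped = [], 0
    for aln in alignments:
        c = count_gene(aln)
        if c.usable:
            out.append(c)
        else:
            dropped += 1
    if dropped:
        logger.info("dropped %d gene(s) with no usable codon columns", dropped)
    return out


def jukes_cantor(p: float) -> float:
    """Jukes–Cantor correction −(3/4)·ln(1 − 4p/3) of an observed proportion p.

    Defined for 0 ≤ p < 3/4; the category test itself uses raw counts, this is
    only for reporting corrected per-gene distances.
    """
    if not 0 <= p < 0.75:
        raise ValueError(f"Jukes-Cantor distance undefined for p={p} (need 0 <= p < 0.75)")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def read_alignments(path: str | Path) -> list[CodonAlignment]:
    """Read pairwise codon alignments from an aligned multi-FASTA.

    Records are paired by gene: either exactly two consecutive records share a
    gene id given as ``geneID|species``, or the file holds exactly two records
    (one gene, ids taken verbatim).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        return []
    if all("|" in r.id for r in records):
        groups: dict[str, list[str]] = {}
        for r in records:
            gene = r.id.split("|", 1)[0]
            groups.setdefault(gene, []).append(str(r.seq))
        out = []
        for gene, seqs in groups.items():
            if len(seqs) != 2:
                raise CodonCountError(f"{path}: gene {gene} has {len(seqs)} records, expected 2")
            out.append(CodonAlignment(gene, seqs[0], seqs[1]))
        return out
    if len(records) == 2:
        return [CodonAlignment(records[0].id, str(records[0].seq), str(records[1].seq))]
    raise CodonCountError(
        f"{path}: expected 'gene|species' ids or exactly two records, got {len(records)}"
    )


def read_counts_table(path: str | Path) -> list[SubstitutionCounts]:
    """Read a per-gene counts TSV (gene_id, a, A, s, S [, codons_used]).

    Rows violating the count invariants (negative counts, zero sites) are
    rejected individually with a logged diagnostic; valid rows are returned.
    Use this to import externally estimated (e.g. codon-ML) counts.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    required = {"gene_id", "a", "A", "s", "S"}
    missing = required - set(df.columns)
    if missing:
        raise CodonCountError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        logger.warning("%s: empty counts table", path)
        return []
    out: list[SubstitutionCounts] = []
    for idx, row in df.iterrows():
        a, A, s, S = (float(row[c]) for c in ("a", "A", "s", "S"))
        cu = int(row["codons_used"]) if "codons_used" in df.columns else None
        if cu is not None and cu < 0:  # -1 sentinel: unknown (external counts)
            cu = None
        if min(a, A, s, S) < 0 or A <= 0 or S <= 0:
            logger.warning("%s row %d (%s): invalid counts, rejected", path, idx, row["gene_id"])
            continue
        try:
            out.append(SubstitutionCounts(str(row["gene_id"]), a, A, s, S, cu))
        except CodonCountError as exc:
            logger.warning("%s row %d: %s; rejected", path, idx, exc)
    return out


def counts_to_frame(counts: Iterable[SubstitutionCounts]) -> pd.DataFrame:
    """Per-gene counts with derived ka, ks, ka_ks columns (NaN where undefined)."""
    rows = []
    for c in counts:
        ka = c.a / c.A if c.A > 0 else float("nan")
        ks = c.s / c.S if c.S > 0 else float("nan")
        rows.append(
            {
                "gene_id": c.gene_id,
                "a": c.a,
                "A": c.A,
                "s": c.s,
                "S": c.S,
                "ka": ka,
                "ks": ks,
                "ka_ks": ka / ks if ks and ks > 0 else float("nan"),
                "codons_used": c.codons_used if c.codons_used is not None else -1,
            }
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "a", "A", "s", "S", "ka", "ks", "ka_ks", "codons_used"]
    )


def write_counts_table(counts: Iterable[SubstitutionCounts], path: str | Path) -> None:
    # full precision so the A+S == 3·codons_used invariant survives a round-trip
    counts_to_frame(counts).to_csv(path, sep="\t", index=False, float_format="%.17g")
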