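"""Gene→GO-term annotation handling: parsing, category building, and the
set-preserving permutation.

The permutation contract is the one the category-level null requires: each
gene's *entire* term set moves as a unit, so every term's gene count — and
hence the size filter and the per-gene co-annotation structure that encodes
the GO hierarchy — is invariant; only which genes carry which sets is
randomized.  Terms are assumed ancestor-propagated upstream; the DAG itself is
never consumed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["GoAnnotation", "GoCategory", "read_annotation", "build_categories", "permute_annotation"]


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class GoCategory:
    """A GO term with its annotated gene set (post size-filter)."""

    term_id: str
    gene_ids: frozenset[str]

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


class GoAnnotation:
    """Mapping gene_id → frozenset of term ids over a fixed gene universe.

    Genes in the universe without any term carry an (explicit) empty set; they
    participate in permutation but never in any category.
    """

    def __init__(self, mapping: Mapping[str, Iterable[str]], universe: Iterable[str]):
        self.universe: tuple[str, ...] = tuple(sorted(set(universe)))
        uni = set(self.universe)
        extra = set(mapping) - uni
        if extra:
            raise AnnotationError(f"{len(extra)} annotated gene(s) outside the universe")
        self._sets: dict[str, frozenset[str]] = {
            g: frozenset(mapping.get(g, ())) for g in self.universe
        }

    def __getitem__(self, gene_id: str) -> frozenset[str]:
        return self._sets[gene_id]

    def __len__(self) -> int:
        return len(self.universe)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GoAnnotation) and self._sets == other._sets

    def items(self):
        return self._sets.items()

    @property
    def n_annotated(self) -> int:
        return sum(1 for s in self._sets.values() if s)

    def term_sets(self) -> list[frozenset[str]]:
        """Per-gene term sets in universe order (the permuted multiset)."""
        return [self._sets[g] for g in self.universe]


def read_annotation(
    path: str | Path,
    universe: Iterable[str],
    namespace: str | None = None,
) -> GoAnnotation:
    """Read a two-column TSV (gene_id, term_id[, namespace]) restricted to a universe.

    Duplicate pairs are deduplicated; lines for genes outside the universe are
    dropped with a logged count.  With ``namespace`` given (e.g.
    ``molecular_function``) only rows in that namespace are kept, requiring a
    third column.
    """
    universe = set(universe)
    mapping: dict[str, set[str]] = {}
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise AnnotationError(f"{path}:{lineno}: malformed line {line!r}")
            gene, term = fields[0], fields[1]
            if namespace is not None:
                if len(fields) < 3:
                    raise AnnotationError(
                        f"{path}:{lineno}: namespace filtering requires a third column"
                    )
                if fields[2] != namespace:
                    continue
            if gene not in universe:
                dropped += 1
                continue
            mapping.setdefault(gene, set()).add(term)
    if dropped:
        logger.info("%s: dropped %d line(s) for genes outside the universe", path, dropped)
    return GoAnnotation(mapping, universe)


def build_categories(annotation: GoAnnotation, min_genes: int = 20) -> list[GoCategory]:
    """One GoCategory per term annotated to at least ``min_genes`` universe genes.

    The default of 20 is the size filter under which category-level counts are
    large enough for the binomial tail to be meaningful.
    """
    by_term: dict[str, set[str]] = {}
    for gene, terms in annotation.items():
        for t in terms:
            by_term.setdefault(t, set()).add(gene)
    return [
        GoCategory(t, frozenset(genes))
        for t, genes in sorted(by_term.items())
        if len(genes) >= min_genes
    ]


def permute_annotation(annotation: GoAnnotation, rng: np.random.Generator) -> GoAnnotation:
    """Uniformly re-assign whole per-gene term sets to genes.

    The multiset of term sets is preserved exactly; only the gene ↔ set
    assignment is drawn uniformly at random over all permutations of the
    universe, so every term's gene count is invariant.
    """
    genes = annotation.universe
    sets = annotation.term_sets()
    perm = rng.permutation(len(genes))
    return GoAnnotation({genes[i]: sets[perm[i]] for i in range(len(genes))}, genes)


def write_categories(categories: Iterable[GoCategory], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("term_id\tn_genes\tgene_ids\n")
        for c in categories:
            fh.write(f"{c.term_id}\t{c.n_genes}\t{','.join(sorted(c.gene_ids))}\n")
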