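"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the package's lookup tables and pathway machinery:
codons are translated with Bio.Seq, pathways enumerated recursively, and
binomial tails computed by direct summation.
"""

import itertools
from math import comb

from Bio.Seq import Seq

BASES = "ACGT"
ALL_CODONS = ["".join(p) for p in itertools.product(BASES, repeat=3)]
STOPS = {c for c in ALL_CODONS if str(Seq(c).translate()) == "*"}
SENSE = [c for c in ALL_CODONS if c not in STOPS]


def translate(codon: str) -> str:
    return str(Seq(codon).translate())


def oracle_sites(codon: str):
    """(syn, nonsyn) site fractions by enumerating all 9 single-base mutants."""
    syn = 0
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if mut not in STOPS and translate(mut) == translate(codon):
                syn += 1
    return syn / 3, 3 - syn / 3


def _pathways(c1: str, c2: str):
    """All orderings of single-base steps c1 -> c2 as lists of codon states."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    for order in itertools.permutations(diff):
        states = [c1]
        for pos in order:
            cur = states[-1]
            states.append(cur[:pos] + c2[pos] + cur[pos + 1 :])
        yield states


def oracle_substitutions(c1: str, c2: str):
    """Pathway-averaged (syn, nonsyn) substitution counts between sense codons."""
    scores = {"clean": [], "blocked": []}
    for states in _pathways(c1, c2):
        syn = 0
        blocked = any(s in STOPS for s in states[1:-1]) or c2 in STOPS
        for a, b in zip(states, states[1:]):
            if a not in STOPS and b not in STOPS and translate(a) == translate(b):
                syn += 1
        scores["blocked" if blocked else "clean"].append(syn)
    pool = scores["clean"] or scores["blocked"]
    if not pool:  # identical codons
        return 0.0, 0.0
    nd = sum(1 for i in range(3) if c1[i] != c2[i])
    syn = sum(pool) / len(pool)
    return syn, nd - syn


def oracle_binomial_upper(a: int, s: int, p: float) -> float:
    """P(j >= a), j ~ Binomial(a + s, p), by direct summation."""
    n = a + s
    return sum(comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(a, n + 1))


def oracle_binomial_lower(a: int, s: int, p: float) -> float:
    """P(j <= a) by direct summation."""
    n = a + s
    return sum(comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(0, a + 1))
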