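"""Ortholog coding-sequence QC: the four mapping filters and longest-transcript selection.

A transcript mapped onto another species' genome passes QC iff
(a) the mapped regions cover at least 80% of the coding region,
(b) at most 10% of the coding region lies in sequence gaps or low-quality sequence,
(c) it has no frame-shift indels unless they are compensated within 15 bases
    (operationalized as: indels clustered transitively by start-to-start
    distance ≤ 15 bases must have net length ≡ 0 mod 3 per cluster), and
(d) it has no in-frame stop codon and all splice sites are conserved.

Coverage/low-quality fractions and the splice/stop flags are upstream-computed
fields of the mapping record; this module only applies the filter logic.
Coordinates are 0-based half-open internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Indel",
    "TranscriptMapping",
    "QcVerdict",
    "cluster_indels",
    "check_mapping",
    "select_longest_transcript",
    "require_species",
    "read_mappings",
    "write_verdicts",
]


@dataclass(frozen=True)
class Indel:
    """An indel in CDS coordinates: 0-based base offset, signed length (+insert/−delete)."""

    position: int
    length: int

    def __post_init__(self) -> None:
        if self.length == 0:
            raise ValueError("indel length must be non-zero")


@dataclass(frozen=True)
class TranscriptMapping:
    transcript_id: str
    gene_id: str
    coding_length: int
    coverage_fraction: float
    lowqual_fraction: float
    indels: tuple[Indel, ...] = ()
    in_frame_stop: bool = False
    splice_sites_conserved: bool = True

    def __post_init__(self) -> None:
        if self.coding_length <= 0:
            raise ValueError(f"{self.transcript_id}: coding_length must be positive")
        for name in ("coverage_fraction", "lowqual_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{self.transcript_id}: {name}={v} outside [0, 1]")
        for ind in self.indels:
            if not 0 <= ind.position < self.coding_length:
                raise ValueError(
                    f"{self.transcript_id}: indel position {ind.position} outside CDS"
                )


@dataclass(frozen=True)
class QcVerdict:
    transcript_id: str
    passed: bool
    failed_criteria: tuple[str, ...]
    reasons: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        assert self.passed == (not self.failed_criteria)


def cluster_indels(
    indels: Sequence[Indel], window: int = 15
) -> list[tuple[list[Indel], int]]:
    """Group indels transitively by start-to-start distance ≤ window.

    Returns (members, net signed length) per cluster, in positional order.
    window=0 makes every indel its own cluster; input order is irrelevant.
    """
    if not indels:
        return []
    srt = sorted(indels, key=lambda i: (i.position, i.length))
    clusters: list[list[Indel]] = [[srt[0]]]
    for ind in srt[1:]:
        if ind.position - clusters[-1][-1].position <= window:
            clusters[-1].append(ind)
        else:
            clusters.append([ind])
    return [(c, sum(i.length for i in c)) for c in clusters]


def check_mapping(
    m: TranscriptMapping,
    min_coverage: float = 0.80,
    max_lowqual: float = 0.10,
    window: int = 15,
) -> QcVerdict:
    """Apply criteria (a)-(d); boundaries are inclusive (≥ 80% coverage, ≤ 10% low quality)."""
    failed: list[str] = []
    reasons: list[str] = []
    if m.coverage_fraction < min_coverage:
        failed.append("a")
        reasons.append(f"coverage {m.coverage_fraction:.3f} < {min_coverage}")
    if m.lowqual_fraction > max_lowqual:
        failed.append("b")
        reasons.append(f"low-quality fraction {m.lowqual_fraction:.3f} > {max_lowqual}")
    bad = [
        (c, net) for c, net in cluster_indels(m.indels, window=window) if net % 3 != 0
    ]
    if bad:
        failed.append("c")
        reasons.append(
            "uncompensated frame-shift cluster(s) at "
            + ", ".join(f"{c[0].position} (net {net:+d})" for c, net in bad)
        )
    if m.in_frame_stop or not m.splice_sites_conserved:
        failed.append("d")
        if m.in_frame_stop:
            reasons.append("in-frame stop codon")
        if not m.splice_sites_conserved:
            reasons.append("splice site not conserved")
    return QcVerdict(m.transcript_id, not failed, tuple(failed), tuple(reasons))


def select_longest_transcript(
    mappings: Iterable[TranscriptMapping],
) -> dict[str, TranscriptMapping]:
    """Keep one mapping per gene: maximal coding_length, ties to the
    lexicographically smallest transcript_id."""
    best: dict[str, TranscriptMapping] = {}
    for m in mappings:
        cur = best.get(m.gene_id)
        if (
            cur is None
            or m.coding_length > cur.coding_length
            or (m.coding_length == cur.coding_length and m.transcript_id < cur.transcript_id)
        ):
            best[m.gene_id] = m
    return best


def require_species(record: dict[str, object], required: Iterable[str]) -> bool:
    """True iff an ortholog record (species → mapping) covers every required species."""
    return set(required) <= set(record)


def _parse_indels(text: str) -> tuple[Indel, ...]:
    text = text.strip()
    if not text or text == ".":
        return ()
    out = []
    for tok in text.split(","):
        pos, length = tok.split(":")
        out.append(Indel(int(pos), int(length)))
    return tuple(out)


def read_mappings(path: str | Path) -> list[TranscriptMapping]:
    """Read a mappings TSV: transcript_id, gene_id, coding_length,
    coverage_fraction, lowqual_fraction, indels (comma-joined pos:len or '.'),
    in_frame_stop, splice_sites_conserved."""
    df = pd.read_csv(
        path, sep="\t", dtype={"transcript_id": str, "gene_id": str, "indels": str}
    )
    df["indels"] = df["indels"].fillna(".")
    out = []
    for _, row in df.iterrows():
        out.append(
            TranscriptMapping(
                transcript_id=row["transcript_id"],
                gene_id=row["gene_id"],
                coding_length=int(row["coding_length"]),
                coverage_fraction=float(row["coverage_fraction"]),
                lowqual_fraction=float(row["lowqual_fraction"]),
                indels=_parse_indels(str(row["indels"])),
                in_frame_stop=_as_bool(row["in_frame_stop"]),
                splice_sites_conserved=_as_bool(row["splice_sites_conserved"]),
            )
        )
    return out


def _as_bool(v) -> bool:
    if isinstance(v, str):
        return v.strip().lower() in ("1", "true", "yes")
    return bool(v)


def write_verdicts(verdicts: Iterable[QcVerdict], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tpassed\tfailed_criteria\treasons\n")
        for v in verdicts:
            fh.write(
                f"{v.transcript_id}\t{int(v.passed)}\t"
                f"{','.join(v.failed_criteria) or '.'}\t{'; '.join(v.reasons) or '.'}\n"
            )
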