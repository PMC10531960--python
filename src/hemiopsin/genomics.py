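"""Locus coordinate arithmetic for tandem-duplicate linkage analysis.

Coordinates are 1-based inclusive (NCBI gene-range style). Two
distances are exposed side by side because published interlocus
distances mix conventions: the between-gene *gap* (space separating
the two gene bodies) and the outer *span* (distance from the leftmost
start to the rightmost end).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd


class LinkageError(ValueError):
    """Raised when two loci on different linkage groups are compared."""


@dataclass(frozen=True)
class LocusRecord:
    protein_id: str
    locus_id: str
    linkage_group: str
    start: int
    end: int
    species: str = ""
    intervening_genes: int | None = None

    def __post_init__(self):
        if self.start <= 0 or self.end <= 0:
            raise ValueError("coordinates must be positive integers")
        if self.start > self.end:
            raise ValueError(f"start > end for {self.protein_id}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _check_same_group(r1: LocusRecord, r2: LocusRecord) -> None:
    if r1.linkage_group != r2.linkage_group:
        raise LinkageError(
            f"loci on different linkage groups: {r1.linkage_group!r} vs {r2.linkage_group!r}"
        )


def interlocus_gap(r1: LocusRecord, r2: LocusRecord) -> tuple[int, bool]:
    """Base pairs separating two gene bodies on one linkage group.

    Returns ``(gap, overlapping)``; overlapping records give gap 0
    with the flag set. Adjacent records (end 100, start 101) have a
    gap of 1 under the inclusive-coordinate convention: the printed
    distances this reproduces are start-minus-end differences.
    """
    _check_same_group(r1, r2)
    upstream, downstream = sorted((r1, r2), key=lambda r: (r.start, r.end))
    gap = downstream.start - upstream.end
    if gap < 0 or (upstream is not downstream and downstream.start <= upstream.end):
        return 0, True
    return gap, False


def locus_pair_span(r1: LocusRecord, r2: LocusRecord) -> int:
    """Outer span: max end minus min start."""
    _check_same_group(r1, r2)
    return max(r1.end, r2.end) - min(r1.start, r2.start)


def find_tandem_pairs(
    records: Sequence[LocusRecord],
    max_gap: int,
    max_intervening: int | None = None,
) -> list[tuple[LocusRecord, LocusRecord]]:
    """All same-linkage-group pairs with gap <= max_gap.

    When ``max_intervening`` is given, pairs also require that the
    known intervening gene count (taken from whichever record carries
    one) does not exceed it; pairs with no recorded count pass.
    """
    pairs = []
    for i, r1 in enumerate(records):
        for r2 in records[i + 1:]:
            if r1.linkage_group != r2.linkage_group:
                continue
            gap, _ = interlocus_gap(r1, r2)
            if gap > max_gap:
                continue
            if max_intervening is not None:
                counts = [
                    r.intervening_genes
                    for r in (r1, r2)
                    if r.intervening_genes is not None
                ]
                if counts and min(counts) > max_intervening:
                    continue
            pairs.append((r1, r2))
    return pairs


def read_locus_table(path: str | Path) -> list[LocusRecord]:
    """Read a locus coordinate TSV.

    Expected columns: species, protein_id, locus_id, linkage_group,
    start, end, intervening_genes (blank allowed). Lines starting with
    ``#`` are comments.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    records = []
    for _, row in df.iterrows():
        iv = row.get("intervening_genes")
        records.append(
            LocusRecord(
                protein_id=row["protein_id"],
                locus_id=row["locus_id"],
                linkage_group=row["linkage_group"],
                start=int(str(row["start"]).replace(",", "")),
                end=int(str(row["end"]).replace(",", "")),
                species=row.get("species", "") or "",
                intervening_genes=int(iv) if pd.notna(iv) and str(iv).strip() else None,
            )
        )
    return records


def to_bed(records: Sequence[LocusRecord]) -> pd.DataFrame:
    """Convert to BED-style 0-based half-open coordinates."""
    return pd.DataFrame(
        {
            "chrom": [r.linkage_group for r in records],
            "chromStart": [r.start - 1 for r in records],
            "chromEnd": [r.end for r in records],
            "name": [r.protein_id for r in records],
        }
    )
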