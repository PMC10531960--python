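"""Protein alignment I/O, gap-column trimming, and reference-site mapping.

Alignment columns are 1-based throughout, as are reference site numbers
(so that positions can be quoted in the conventional bovine-Rhodopsin
coordinate system without off-by-one gymnastics).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._jtt_data import AMINO_ACIDS

GAP = "-"
AMBIGUOUS = "X"
VALID_CHARS = set(AMINO_ACIDS) | {GAP, AMBIGUOUS}


class AlignmentError(ValueError):
    """Raised for ragged, empty, or otherwise malformed alignments."""


class EmptyAlignmentWarning(UserWarning):
    """Emitted when an operation leaves an alignment with no columns."""


@dataclass(frozen=True)
class Alignment:
    """An ordered, gapped protein multiple sequence alignment.

    ``records`` is a tuple of ``(id, sequence)`` pairs; sequences are
    upper-case strings over the 20 amino acids plus ``-`` (gap) and
    ``X`` (ambiguous residue). All sequences have equal length and ids
    are unique.
    """

    records: tuple[tuple[str, str], ...]

    def __post_init__(self):
        if not self.records:
            raise AlignmentError("alignment has no sequences")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            raise AlignmentError(f"ragged alignment: sequence lengths {sorted(lengths)}")
        ids = [rid for rid, _ in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise AlignmentError(f"duplicate sequence ids: {dupes}")
        for rid, seq in self.records:
            bad = set(seq) - VALID_CHARS
            if bad:
                raise AlignmentError(f"invalid characters {sorted(bad)} in sequence {rid!r}")

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(rid for rid, _ in self.records)

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    @property
    def nseq(self) -> int:
        return len(self.records)

    def sequence(self, seq_id: str) -> str:
        for rid, seq in self.records:
            if rid == seq_id:
                return seq
        raise KeyError(f"no sequence with id {seq_id!r}")

    def column(self, col: int) -> str:
        """Residues of 1-based column ``col``, in record order."""
        if not 1 <= col <= self.length:
            raise IndexError(f"column {col} outside 1..{self.length}")
        return "".join(seq[col - 1] for _, seq in self.records)

    def subset(self, ids: Iterable[str]) -> "Alignment":
        wanted = list(ids)
        return Alignment(tuple((rid, self.sequence(rid)) for rid in wanted))

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "Alignment":
        return cls(tuple((rid, seq.upper().replace(".", GAP)) for rid, seq in pairs))


def read_fasta_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA file.

    Sequences are upper-cased and ``.`` gap characters normalized to
    ``-``. Ragged records raise :class:`AlignmentError`; an empty file
    is a format error.
    """
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    return Alignment.from_pairs(records)


def write_fasta_alignment(aln: Alignment, path: str | Path) -> None:
    recs = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in aln.records]
    SeqIO.write(recs, str(path), "fasta")


def trim_gappy_columns(
    aln: Alignment, max_gap_fraction: float = 0.5
) -> tuple[Alignment, list[int]]:
    """Remove columns whose gap fraction exceeds ``max_gap_fraction``.

    This is a plain per-column gap-fraction filter (``X`` counts as a
    residue, not a gap). Returns the trimmed alignment and the list of
    kept 1-based column indices of the input so downstream site maps
    stay traceable. If every column is removed, an
    :class:`EmptyAlignmentWarning` is emitted and the kept list is
    empty (the returned alignment then has zero-length sequences,
    bypassing normal validation).
    """
    if not 0.0 <= max_gap_fraction <= 1.0:
        raise ValueError("max_gap_fraction must be within [0, 1]")
    n = aln.nseq
    kept = [
        col
        for col in range(1, aln.length + 1)
        if aln.column(col).count(GAP) / n <= max_gap_fraction
    ]
    if not kept:
        warnings.warn(
            "all columns exceeded the gap-fraction threshold; alignment is empty",
            EmptyAlignmentWarning,
        )
        empty = object.__new__(Alignment)
        object.__setattr__(empty, "records", tuple((rid, "") for rid in aln.ids))
        return empty, []
    trimmed = Alignment(
        tuple(
            (rid, "".join(seq[c - 1] for c in kept)) for rid, seq in aln.records
        )
    )
    return trimmed, kept


@dataclass(frozen=True)
class SiteMap:
    """Partial mapping of alignment columns to reference site numbers.

    ``scheme`` names the coordinate system (e.g. ``"Rhodopsin"`` for
    bovine Rhodopsin numbering or ``"CrUVop2"`` for jewel-beetle
    UV-opsin-2 numbering). Columns where the reference sequence has a
    gap are unmapped; the mapping is strictly increasing and therefore
    injective over mapped columns.
    """

    reference_id: str
    scheme: str
    column_to_site: dict[int, int] = field(default_factory=dict)

    def __post_init__(self):
        cols = sorted(self.column_to_site)
        sites = [self.column_to_site[c] for c in cols]
        if any(b <= a for a, b in zip(sites, sites[1:])):
            raise ValueError("site numbering must be strictly increasing over mapped columns")

    @property
    def site_to_column(self) -> dict[int, int]:
        return {s: c for c, s in self.column_to_site.items()}

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("column\tsite\n")
            for col in sorted(self.column_to_site):
                fh.write(f"{col}\t{self.column_to_site[col]}\n")


def map_sites_to_reference(
    aln: Alignment, reference_id: str, offset: int = 0, scheme: str = "Rhodopsin"
) -> SiteMap:
    """Map alignment columns to the residue numbering of one sequence.

    The k-th non-gap residue of ``reference_id`` (k counted from 1)
    maps its column to site ``k + offset``; gap columns of the
    reference are left unmapped. ``offset`` lets a partial reference
    start mid-protein (e.g. offset 89 makes its second residue site 91).
    """
    ref = aln.sequence(reference_id)  # KeyError if unknown
    mapping: dict[int, int] = {}
    k = 0
    for col, ch in enumerate(ref, start=1):
        if ch != GAP:
            k += 1
            mapping[col] = k + offset
    return SiteMap(reference_id=reference_id, scheme=scheme, column_to_site=mapping)
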