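"""Domain types and I/O for protein alignments, group assignments and
publication-style signature excerpts.

Coordinate conventions: internally all column indices are 0-based half-open;
every user-facing report and every window argument documented as "1-based
inclusive" follows the residue-numbering convention of the literature
(e.g. "F567-N569").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
UNKNOWN = "X"
ALPHABET = frozenset(AMINO_ACIDS + GAP + UNKNOWN)

#: glyph used for a source gap inside an encoded signature excerpt, so that
#: '-' is unambiguous as the identity-with-top-line mark
EXCERPT_GAP = "."


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned protein sequence.

    ``residues`` is drawn from the 20 canonical amino-acid letters plus
    ``-`` (gap) and ``X`` (unknown; never counts toward column majorities).
    """

    id: str
    residues: str
    taxon: str = ""

    def __post_init__(self):
        if not self.id:
            raise ValueError("record id must be non-empty")
        bad = set(self.residues) - ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r} contains illegal symbols: {sorted(bad)}"
            )
        if not self.taxon:
            object.__setattr__(self, "taxon", self.id)


class Alignment:
    """An ordered collection of equal-length :class:`SequenceRecord`.

    Invariants enforced on construction: at least one record, unique ids,
    equal lengths, no all-gap column (such columns are dropped with a
    logged warning).
    """

    def __init__(self, records: Sequence[SequenceRecord]):
        records = list(records)
        if not records:
            raise ValueError("alignment must contain at least one record")
        ids = [r.id for r in records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate record ids: {dup}")
        ncols = len(records[0].residues)
        for i, r in enumerate(records):
            if len(r.residues) != ncols:
                raise ValueError(
                    f"ragged alignment: record {i + 1} ({r.id!r}) has length "
                    f"{len(r.residues)}, expected {ncols}"
                )
        if ncols < 1:
            raise ValueError("alignment must have at least one column")
        # drop all-gap columns
        keep = [
            c for c in range(ncols)
            if any(r.residues[c] != GAP for r in records)
        ]
        if len(keep) < ncols:
            logger.warning(
                "dropped %d all-gap column(s) on load", ncols - len(keep)
            )
            records = [
                SequenceRecord(
                    r.id, "".join(r.residues[c] for c in keep), r.taxon
                )
                for r in records
            ]
        if not keep:
            raise ValueError("alignment consists entirely of gap columns")
        self.records: list[SequenceRecord] = records
        self.ncols: int = len(keep)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Alignment)
            and self.ncols == other.ncols
            and self.records == other.records
        )

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def record(self, rec_id: str) -> SequenceRecord:
        for r in self.records:
            if r.id == rec_id:
                return r
        raise KeyError(f"no record with id {rec_id!r}")

    def column(self, c: int) -> str:
        """Residues of 0-based column ``c``, in record order."""
        return "".join(r.residues[c] for r in self.records)

    def slice_columns(self, start: int, stop: int) -> "Alignment":
        """Sub-alignment over 0-based half-open column range [start, stop)."""
        if not (0 <= start < stop <= self.ncols):
            raise ValueError(f"bad column range [{start}, {stop})")
        recs = [
            SequenceRecord(r.id, r.residues[start:stop], r.taxon)
            for r in self.records
        ]
        return Alignment(recs)

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for r in self.records:
                fh.write(f">{r.id}\n{r.residues}\n")


@dataclass
class GroupAssignment:
    """Taxon-to-group mapping with designated target and outgroup labels.

    ``target_groups`` are the lineages whose shared derived indels are of
    interest (e.g. Bifidobacteriales and Coriobacteriales); every other
    label is an outgroup unless ``outgroups`` is given explicitly.
    """

    mapping: dict[str, str]
    target_groups: tuple[str, ...]
    outgroups: tuple[str, ...] = ()

    def __post_init__(self):
        self.target_groups = tuple(self.target_groups)
        labels = set(self.mapping.values())
        missing = [g for g in self.target_groups if g not in labels]
        if missing:
            raise ValueError(f"target group(s) with no members: {missing}")
        if not self.outgroups:
            self.outgroups = tuple(
                sorted(labels - set(self.target_groups))
            )
        if not self.target_groups:
            raise ValueError("at least one target group is required")
        if not self.outgroups:
            raise ValueError("at least one outgroup label is required")

    def group_of(self, taxon: str) -> str:
        try:
            return self.mapping[taxon]
        except KeyError:
            raise KeyError(f"taxon {taxon!r} has no group assignment") from None

    def is_target(self, taxon: str) -> bool:
        return self.group_of(taxon) in self.target_groups

    def members(self, group: str) -> list[str]:
        return [t for t, g in self.mapping.items() if g == group]

    def validate_against(self, aln: Alignment) -> None:
        missing = [r.taxon for r in aln if r.taxon not in self.mapping]
        if missing:
            raise ValueError(f"taxa without group assignment: {missing}")

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        target_groups: Iterable[str],
        outgroups: Iterable[str] = (),
    ) -> "GroupAssignment":
        """Read a two-column TSV (taxon <tab> group)."""
        mapping: dict[str, str] = {}
        for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln}: expected 'taxon<TAB>group'")
            taxon, group = parts
            if taxon in mapping:
                raise ValueError(f"{path}:{ln}: duplicate taxon {taxon!r}")
            mapping[taxon] = group
        return cls(mapping, tuple(target_groups), tuple(outgroups))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for taxon, group in self.mapping.items():
                fh.write(f"{taxon}\t{group}\n")


def read_alignment(path: str | Path, format: str = "aligned-fasta") -> Alignment:
    """Read an alignment from disk.

    Parameters
    ----------
    path:
        File in the given dialect.
    format:
        ``"aligned-fasta"`` or ``"clustal"``.

    Raises a :class:`ValueError` naming the offending record for ragged
    input, and for empty files.
    """
    fmt = {"aligned-fasta": "fasta", "fasta": "fasta", "clustal": "clustal"}.get(
        format
    )
    if fmt is None:
        raise ValueError(f"unknown alignment format {format!r}")
    seqs = list(SeqIO.parse(str(path), fmt))
    if not seqs:
        raise ValueError(f"{path}: no sequences found")
    records = []
    ncols = len(seqs[0].seq)
    for i, s in enumerate(seqs):
        residues = str(s.seq).upper()
        if len(residues) != ncols:
            raise ValueError(
                f"{path}: ragged alignment: record {i + 1} ({s.id!r}) has "
                f"length {len(residues)}, expected {ncols}"
            )
        records.append(SequenceRecord(s.id, residues))
    return Alignment(records)


def column_profile(aln: Alignment) -> pd.DataFrame:
    """Per-column conservation table.

    Returns a DataFrame indexed by 0-based column with columns
    ``majority_residue`` (alphabetically smallest on ties; '' when a column
    holds only gaps/X), ``majority_fraction`` (majority count over non-gap,
    non-X symbols) and ``gap_fraction`` (gaps over all records).
    """
    n = len(aln.records)
    rows = []
    for c in range(aln.ncols):
        col = aln.column(c)
        counts: dict[str, int] = {}
        gaps = 0
        for ch in col:
            if ch == GAP:
                gaps += 1
            elif ch != UNKNOWN:
                counts[ch] = counts.get(ch, 0) + 1
        if counts:
            # alphabetical tie-break: sort by (-count, residue)
            residue, cnt = min(counts.items(), key=lambda kv: (-kv[1], kv[0]))
            denom = sum(counts.values())
            frac = cnt / denom
        else:
            residue, frac = "", 0.0
        rows.append((residue, frac, gaps / n))
    return pd.DataFrame(
        rows,
        columns=["majority_residue", "majority_fraction", "gap_fraction"],
    )


@dataclass
class SignatureExcerpt:
    """A publication-style alignment excerpt.

    The top record is shown in full; in every other record a residue equal
    to the top-line residue at that column is rendered as the identity mark
    ``-`` and a source gap as ``.`` (so the encoding is lossless).
    ``window`` is 1-based inclusive in alignment coordinates.
    """

    top_id: str
    top_residues: str
    window: tuple[int, int]
    rows: list[tuple[str, str, str]] = field(default_factory=list)
    #: rows: (record id, group label, encoded residues)

    def to_tsv(self) -> str:
        lines = [f"{self.top_id}\t{_top_group(self)}\t{self.top_residues}"]
        for rec_id, group, enc in self.rows:
            lines.append(f"{rec_id}\t{group}\t{enc}")
        return "\n".join(lines) + "\n"

    def render(self) -> str:
        """Fixed-width plain-text rendering, grouped by group label."""
        width = max(
            [len(self.top_id)] + [len(r[0]) for r in self.rows], default=0
        )
        start, end = self.window
        out = [f"# columns {start}-{end} (1-based, alignment coordinates)"]
        out.append(f"{self.top_id:<{width}}  {self.top_residues}")
        last_group = _top_group(self)
        for rec_id, group, enc in self.rows:
            if group != last_group:
                out.append("")
                last_group = group
            out.append(f"{rec_id:<{width}}  {enc}")
        return "\n".join(out) + "\n"


def _top_group(ex: SignatureExcerpt) -> str:
    return ex.rows[0][1] if ex.rows else ""


def write_signature_excerpt(
    aln: Alignment,
    top_id: str,
    window: tuple[int, int],
    groups: GroupAssignment,
) -> SignatureExcerpt:
    """Encode a column window in the identity-dash convention.

    ``window`` is 1-based inclusive. Records are ordered by group: target
    groups first (in their designated order), then the remaining labels
    alphabetically; original record order is kept within a group. The top
    record must be gap-free over the window, otherwise the identity mark
    would be ambiguous.
    """
    start1, end1 = window
    if start1 > end1:
        raise ValueError(f"empty window {window}")
    if not (1 <= start1 and end1 <= aln.ncols):
        raise ValueError(f"window {window} outside [1, {aln.ncols}]")
    top = aln.record(top_id)  # KeyError for unknown id
    lo, hi = start1 - 1, end1  # 0-based half-open
    top_res = top.residues[lo:hi]
    if GAP in top_res:
        raise ValueError(
            f"top record {top_id!r} has gaps in window {window}; choose a "
            "record that spans the excerpt"
        )
    order = list(groups.target_groups) + [
        g
        for g in sorted(set(groups.mapping.values()))
        if g not in groups.target_groups
    ]
    rows: list[tuple[str, str, str]] = []
    for g in order:
        for r in aln.records:
            if r.id == top_id or groups.group_of(r.taxon) != g:
                continue
            enc = []
            for ch, t in zip(r.residues[lo:hi], top_res):
                if ch == GAP:
                    enc.append(EXCERPT_GAP)
                elif ch == t:
                    enc.append(GAP)  # identity mark
                else:
                    enc.append(ch)
            rows.append((r.id, g, "".join(enc)))
    return SignatureExcerpt(top_id, top_res, (start1, end1), rows)


def decode_signature_excerpt(ex: SignatureExcerpt) -> Alignment:
    """Invert :func:`write_signature_excerpt` over its window."""
    if GAP in ex.top_residues:
        raise ValueError("identity mark '-' present in the top line itself")
    recs = [SequenceRecord(ex.top_id, ex.top_residues)]
    for rec_id, _group, enc in ex.rows:
        if len(enc) != len(ex.top_residues):
            raise ValueError(f"row {rec_id!r} has wrong width")
        dec = []
        for ch, t in zip(enc, ex.top_residues):
            if ch == GAP:
                dec.append(t)
            elif ch == EXCERPT_GAP:
                dec.append(GAP)
            else:
                dec.append(ch)
        recs.append(SequenceRecord(rec_id, "".join(dec)))
    return Alignment(recs)
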