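"""Detection and classification of conserved signature indels (CSIs).

A CSI is a contiguous insertion or deletion in a protein alignment that is
(1) flanked on both sides by conserved residues — evidence that the indel is
positionally homologous rather than an alignment artifact — and (2) present
in a phylogenetically coherent set of taxa. The pipeline here is:

    find_indel_loci -> flank_conservation -> polarize_indel
                    -> classify_specificity -> resolve_locus_variants

All user-facing column coordinates are 1-based inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

from csikit.seqdata import (
    GAP,
    Alignment,
    GroupAssignment,
    column_profile,
)

logger = logging.getLogger(__name__)

State = Literal["present", "absent", "partial"]
Polarity = Literal["insertion", "deletion"]
Specificity = Literal[
    "exclusive", "shared_two_groups", "mainly_specific", "non_specific"
]


@dataclass
class IndelLocus:
    """A maximal gap-block locus.

    ``start``/``end`` are 1-based inclusive alignment columns. Each record
    is classified by its occupancy of the block: ``present`` (residues at
    every column), ``absent`` (gaps at every column) or ``partial``
    (anything in between). A partial record whose residues inside the block
    are non-contiguous is additionally flagged ``fragmented`` and excluded
    from length statistics.
    """

    start: int
    end: int
    states: dict[str, State]
    occupied: dict[str, int]
    fragmented: set[str] = field(default_factory=set)

    @property
    def width(self) -> int:
        return self.end - self.start + 1

    def records_with_state(self, state: State) -> list[str]:
        return [r for r, s in self.states.items() if s == state]

    def occupying(self) -> list[str]:
        """Record ids with at least one residue in the block, excluding
        fragmented records."""
        return [
            r
            for r, n in self.occupied.items()
            if n > 0 and r not in self.fragmented
        ]


@dataclass
class FlankEvidence:
    """Outcome of the flanking-conservation test for one locus."""

    window: int
    min_conserved: int
    cons_threshold: float
    left_conserved: int
    right_conserved: int
    left_pass: bool
    right_pass: bool
    edge_truncated: bool = False

    @property
    def passed(self) -> bool:
        return self.left_pass and self.right_pass


@dataclass
class CsiCall:
    """One called conserved signature indel."""

    locus: IndelLocus
    polarity: Polarity
    flank: FlankEvidence
    specificity: Specificity
    #: group label -> modal occupied length among the group's records
    group_lengths: dict[str, int]
    #: group label -> fraction of the group's records deviating from the
    #: group's modal state/length
    group_exceptions: dict[str, float]
    #: fraction of non-target records sharing the targets' derived state
    exception_fraction: float
    #: occupied length -> sorted group labels carrying that length
    variants: dict[int, list[str]]
    #: groups whose members disagree on occupied length
    mixed_groups: set[str] = field(default_factory=set)

    @property
    def start(self) -> int:
        return self.locus.start

    @property
    def end(self) -> int:
        return self.locus.end


@dataclass
class CsiParams:
    """Tunable thresholds of the detection pipeline.

    Defaults follow common CSI practice: an indel must be flanked on each
    side by at least ``min_conserved`` conserved columns within ``window``
    neighbouring columns; a column is conserved when its non-gap majority
    fraction reaches ``cons_threshold``; up to ``tol`` of unrelated records
    may share an indel for it to remain "mainly specific".
    """

    min_len: int = 1
    max_len: int = 50
    window: int = 30
    min_conserved: int = 5
    cons_threshold: float = 0.8
    tol: float = 0.05
    within_target_tol: float = 0.05


def _block_states(
    aln: Alignment, lo: int, hi: int
) -> tuple[dict[str, State], dict[str, int], set[str]]:
    """Classify every record over 0-based half-open columns [lo, hi)."""
    states: dict[str, State] = {}
    occupied: dict[str, int] = {}
    fragmented: set[str] = set()
    for r in aln.records:
        seg = r.residues[lo:hi]
        n_res = sum(1 for ch in seg if ch != GAP)
        occupied[r.id] = n_res
        if n_res == 0:
            states[r.id] = "absent"
        elif n_res == len(seg):
            states[r.id] = "present"
        else:
            states[r.id] = "partial"
            idx = [i for i, ch in enumerate(seg) if ch != GAP]
            if idx[-1] - idx[0] + 1 != len(idx):
                fragmented.add(r.id)
    return states, occupied, fragmented


def find_indel_loci(
    aln: Alignment, min_len: int = 1, max_len: int = 50
) -> list[IndelLocus]:
    """Locate maximal gap-block loci.

    A column is an indel column when it holds at least one gap and at least
    one residue. Each maximal run of indel columns is a candidate locus; it
    is kept when its length lies within [min_len, max_len] and at least one
    record spans it entirely with gaps while another spans it entirely with
    residues. Loci are returned sorted by start column.
    """
    if not (1 <= min_len <= max_len):
        raise ValueError(
            f"need 1 <= min_len <= max_len, got ({min_len}, {max_len})"
        )
    max_len = min(max_len, aln.ncols)
    is_indel_col = []
    for c in range(aln.ncols):
        col = aln.column(c)
        is_indel_col.append(GAP in col and any(ch != GAP for ch in col))
    loci: list[IndelLocus] = []
    c = 0
    while c < aln.ncols:
        if not is_indel_col[c]:
            c += 1
            continue
        start = c
        while c < aln.ncols and is_indel_col[c]:
            c += 1
        end = c  # half-open
        if not (min_len <= end - start <= max_len):
            continue
        states, occupied, fragmented = _block_states(aln, start, end)
        if "absent" in states.values() and "present" in states.values():
            loci.append(
                IndelLocus(start + 1, end, states, occupied, fragmented)
            )
    return loci


def flank_conservation(
    aln: Alignment,
    locus: IndelLocus,
    window: int = 30,
    min_conserved: int = 5,
    cons_threshold: float = 0.8,
    profile=None,
) -> FlankEvidence:
    """Test the conserved-flank criterion for one locus.

    A column counts as conserved iff its non-gap majority fraction is at
    least ``cons_threshold``. The test passes when both the ``window``
    columns left of the locus and the ``window`` columns right of it contain
    at least ``min_conserved`` conserved columns. Windows truncated by the
    alignment edge are used as-is and flagged.
    """
    if window < min_conserved:
        raise ValueError("window must be >= min_conserved")
    if not (0.5 < cons_threshold <= 1.0):
        raise ValueError("cons_threshold must lie in (0.5, 1]")
    if profile is None:
        profile = column_profile(aln)
    frac = profile["majority_fraction"].to_numpy()
    lo, hi = locus.start - 1, locus.end  # 0-based half-open
    left_cols = range(max(0, lo - window), lo)
    right_cols = range(hi, min(aln.ncols, hi + window))
    truncated = len(left_cols) < window or len(right_cols) < window
    left = int(sum(frac[c] >= cons_threshold for c in left_cols))
    right = int(sum(frac[c] >= cons_threshold for c in right_cols))
    return FlankEvidence(
        window=window,
        min_conserved=min_conserved,
        cons_threshold=cons_threshold,
        left_conserved=left,
        right_conserved=right,
        left_pass=left >= min_conserved,
        right_pass=right >= min_conserved,
        edge_truncated=truncated,
    )


def _record_taxon(aln: Alignment, rec_id: str) -> str:
    return aln.record(rec_id).taxon


def polarize_indel(
    locus: IndelLocus, groups: GroupAssignment, aln: Alignment
) -> Polarity:
    """Polarize the locus from the outgroup's modal state.

    Outgroup records mostly lacking residues at the locus mean the target
    groups gained them (insertion); outgroups mostly occupying the locus
    mean the target groups lost them (deletion). A 50/50 split resolves to
    insertion with a logged warning.
    """
    occupied = absent = 0
    for rec_id, n in locus.occupied.items():
        taxon = _record_taxon(aln, rec_id)
        if groups.is_target(taxon):
            continue
        if n > 0:
            occupied += 1
        else:
            absent += 1
    if occupied + absent == 0:
        raise ValueError("no outgroup records at locus: polarity undefined")
    if occupied == absent:
        logger.warning(
            "outgroup state tied at locus %d-%d; polarity set to insertion",
            locus.start,
            locus.end,
        )
        return "insertion"
    return "insertion" if absent > occupied else "deletion"


def classify_specificity(
    locus: IndelLocus,
    groups: GroupAssignment,
    aln: Alignment,
    tol: float = 0.05,
) -> tuple[Specificity, float, dict[str, float]]:
    """Classify how specific the targets' derived state is.

    The derived state is the modal occupancy state (occupied vs absent) of
    the target-group records. Returns the category, the fraction of
    non-target records sharing that state, and the per-target-group
    within-group exception fraction (members lacking the modal state).
    """
    if not (0 <= tol < 0.5):
        raise ValueError("tol must lie in [0, 0.5)")
    target_states: list[bool] = []  # True = occupied
    per_group: dict[str, list[bool]] = {g: [] for g in groups.target_groups}
    nontarget_states: list[bool] = []
    for rec_id, n in locus.occupied.items():
        taxon = _record_taxon(aln, rec_id)
        g = groups.group_of(taxon)
        occ = n > 0
        if g in groups.target_groups:
            target_states.append(occ)
            per_group[g].append(occ)
        else:
            nontarget_states.append(occ)
    if not target_states:
        raise ValueError("no target-group records at locus")
    derived = sum(target_states) * 2 >= len(target_states)  # modal, tie->occupied
    group_exceptions = {
        g: (sum(1 for s in states if s != derived) / len(states))
        if states
        else 1.0
        for g, states in per_group.items()
    }
    n_out = len(nontarget_states)
    share = (
        sum(1 for s in nontarget_states if s == derived) / n_out
        if n_out
        else 0.0
    )
    all_targets_share = all(target_states) if derived else not any(target_states)
    if all_targets_share and share == 0.0:
        cat: Specificity = (
            "shared_two_groups" if len(groups.target_groups) == 2 else "exclusive"
        )
    elif share <= tol:
        cat = "mainly_specific"
    else:
        cat = "non_specific"
    return cat, share, group_exceptions


def resolve_locus_variants(
    locus: IndelLocus, groups: GroupAssignment, aln: Alignment
) -> tuple[dict[int, list[str]], dict[str, int], set[str]]:
    """Partition occupying records by occupied length.

    Same-locus inserts of different lengths in different subclades (nested
    CSI variants) show up as distinct occupied lengths within one gap-block
    locus. Returns (length -> sorted group labels), the per-group modal
    length, and the set of groups whose members disagree on length (mixed).
    Fragmented records are excluded.
    """
    by_group: dict[str, list[int]] = {}
    for rec_id in locus.occupying():
        g = groups.group_of(_record_taxon(aln, rec_id))
        by_group.setdefault(g, []).append(locus.occupied[rec_id])
    modal: dict[str, int] = {}
    mixed: set[str] = set()
    for g, lengths in by_group.items():
        counts: dict[int, int] = {}
        for n in lengths:
            counts[n] = counts.get(n, 0) + 1
        best = min(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0]
        modal[g] = best
        if len(counts) > 1:
            mixed.add(g)
    partition: dict[int, list[str]] = {}
    for g, n in modal.items():
        partition.setdefault(n, []).append(g)
    for n in partition:
        partition[n].sort()
    return partition, modal, mixed


def detect_csis(
    aln: Alignment,
    groups: GroupAssignment,
    params: CsiParams | None = None,
) -> list[CsiCall]:
    """Run the full CSI detection pipeline.

    Loci failing the flanking-conservation criterion are discarded; all
    surviving loci are reported with their polarity, specificity category
    and nested-variant partition, sorted by start column. Deterministic for
    fixed inputs and parameters.
    """
    if params is None:
        params = CsiParams()
    groups.validate_against(aln)
    profile = column_profile(aln)
    calls: list[CsiCall] = []
    for locus in find_indel_loci(aln, params.min_len, params.max_len):
        ev = flank_conservation(
            aln,
            locus,
            window=params.window,
            min_conserved=params.min_conserved,
            cons_threshold=params.cons_threshold,
            profile=profile,
        )
        if not ev.passed:
            continue
        polarity = polarize_indel(locus, groups, aln)
        cat, share, group_exc = classify_specificity(
            locus, groups, aln, tol=params.tol
        )
        partition, modal, mixed = resolve_locus_variants(locus, groups, aln)
        all_lengths = {
            g: modal.get(g, 0) for g in sorted(set(groups.mapping.values()))
        }
        calls.append(
            CsiCall(
                locus=locus,
                polarity=polarity,
                flank=ev,
                specificity=cat,
                group_lengths=all_lengths,
                group_exceptions=group_exc,
                exception_fraction=share,
                variants=partition,
                mixed_groups=mixed,
            )
        )
    return calls


def csis_to_table(calls: list[CsiCall]) -> "pd.DataFrame":
    """Flatten calls into a report table (one row per CSI)."""
    import pandas as pd

    rows = []
    for i, c in enumerate(calls, 1):
        rows.append(
            {
                "csi": i,
                "start": c.start,
                "end": c.end,
                "width": c.locus.width,
                "polarity": c.polarity,
                "specificity": c.specificity,
                "exception_fraction": round(c.exception_fraction, 4),
                "group_lengths": ";".join(
                    f"{g}={n}" for g, n in sorted(c.group_lengths.items())
                ),
                "variants": ";".join(
                    f"{n}:{','.join(gs)}" for n, gs in sorted(c.variants.items())
                ),
                "mixed_groups": ",".join(sorted(c.mixed_groups)),
                "flank_left": c.flank.left_conserved,
                "flank_right": c.flank.right_conserved,
                "edge_truncated": c.flank.edge_truncated,
            }
        )
    return pd.DataFrame(rows)
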