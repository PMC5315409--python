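"""Tree building and character-origin analysis for CSI interpretation.

Covers: conservation-based block filtering of the alignment, pairwise
distances (p / Poisson-corrected), deterministic neighbor-joining with
column-bootstrap support, outgroup rooting and monophyly tests, the
gene-tree / reference-tree incongruence test for horizontal gene transfer,
Dollo parsimony mapping of CSI gains and losses onto branches, and
inference of the donor lineage of a transferred gene from CSI state vectors.

Trees are :class:`dendropy.Tree` objects throughout; leaf labels are taxon
labels of the alignment records.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Hashable, Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

from csikit.seqdata import GAP, UNKNOWN, Alignment, SequenceRecord, column_profile

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# alignment trimming


def filter_blocks(
    aln: Alignment,
    max_gap_fraction: float = 0.2,
    min_majority: float = 0.5,
    min_block: int = 5,
) -> tuple[Alignment, list[int]]:
    """Remove poorly conserved regions before tree building.

    Keeps maximal runs (length >= ``min_block``) of columns whose gap
    fraction is at most ``max_gap_fraction`` and whose non-gap majority
    fraction is at least ``min_majority``. Returns the trimmed alignment and
    the list mapping trimmed column index -> original 0-based column index.
    """
    if not (0 < max_gap_fraction <= 1 and 0 < min_majority <= 1):
        raise ValueError("thresholds must lie in (0, 1]")
    if min_block < 1:
        raise ValueError("min_block must be >= 1")
    prof = column_profile(aln)
    good = (
        (prof["gap_fraction"] <= max_gap_fraction)
        & (prof["majority_fraction"] >= min_majority)
    ).to_numpy()
    keep: list[int] = []
    c = 0
    n = aln.ncols
    while c < n:
        if not good[c]:
            c += 1
            continue
        start = c
        while c < n and good[c]:
            c += 1
        if c - start >= min_block:
            keep.extend(range(start, c))
    if not keep:
        raise ValueError(
            "all columns filtered out; relax max_gap_fraction/min_majority/"
            "min_block"
        )
    recs = [
        SequenceRecord(r.id, "".join(r.residues[c] for c in keep), r.taxon)
        for r in aln.records
    ]
    return Alignment(recs), keep


# ---------------------------------------------------------------------------
# distances and neighbor joining


def distance_matrix(aln: Alignment, correction: str = "poisson") -> pd.DataFrame:
    """Pairwise distances between records.

    Comparisons use only columns where both records carry a residue (gaps
    and 'X' are treated as missing). ``correction``: ``"p"`` gives the
    mismatch fraction, ``"poisson"`` gives -ln(1 - p).
    """
    if correction not in ("p", "poisson"):
        raise ValueError(f"unknown correction {correction!r}")
    seqs = [r.residues for r in aln.records]
    labels = [r.taxon for r in aln.records]
    if len(set(labels)) != len(labels):
        labels = aln.ids
    arr = np.frombuffer(
        "".join(seqs).encode("ascii"), dtype="S1"
    ).reshape(len(seqs), aln.ncols)
    valid = (arr != GAP.encode()) & (arr != UNKNOWN.encode())
    n = len(seqs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            m = int(both.sum())
            if m == 0:
                raise ValueError(
                    f"no shared non-gap columns between {labels[i]!r} and "
                    f"{labels[j]!r}"
                )
            p = float((arr[i][both] != arr[j][both]).sum()) / m
            if correction == "poisson":
                if p >= 1.0:
                    raise ValueError(
                        f"p-distance 1.0 between {labels[i]!r} and "
                        f"{labels[j]!r}: Poisson correction undefined"
                    )
                d = -math.log(1.0 - p)
            else:
                d = p
            D[i, j] = D[j, i] = d
    return pd.DataFrame(D, index=labels, columns=labels)


def nj_tree(D: pd.DataFrame) -> dendropy.Tree:
    """Neighbor-joining tree from a symmetric distance matrix.

    Deterministic: at every agglomeration step ties in the Q criterion are
    broken toward the lowest-index pair (row-major scan order of the current
    matrix). Negative branch-length estimates are clamped to zero with a log
    entry. The returned tree is unrooted (trifurcating seed node).
    """
    labels = list(D.index)
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = D.to_numpy(dtype=float).copy()
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix is not symmetric")
    if (d < 0).any():
        raise ValueError("distance matrix has negative entries")

    tns = dendropy.TaxonNamespace()
    nodes: list[dendropy.Node] = []
    for lab in labels:
        taxon = tns.new_taxon(lab)
        node = dendropy.Node(taxon=taxon)
        nodes.append(node)

    def clamp(x: float, what: str) -> float:
        if x < 0:
            logger.info("negative %s %.4g clamped to 0", what, x)
            return 0.0
        return x

    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest-index tie-break: argmin of flattened array scans row-major
        k = int(np.argmin(q))
        ai, aj = divmod(k, m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = dij - li
        li = clamp(li, "branch length")
        lj = clamp(lj, "branch length")
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        # distances from the new node to the remaining ones
        new_row = np.zeros(d.shape[0] + 1)
        for ak in active:
            if ak in (i, j):
                continue
            duk = 0.5 * (d[i, ak] + d[j, ak] - dij)
            new_row[ak] = clamp(duk, "distance")
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row[:-1]
        d[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]

    # resolve the final three nodes around an unrooted central node
    a, b, c = active
    root = dendropy.Node()
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    for idx, ln in ((a, la), (b, lb), (c, lc)):
        root.add_child(nodes[idx])
        nodes[idx].edge.length = clamp(ln, "branch length")
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# bipartitions, bootstrap


def _leafsets(tree: dendropy.Tree) -> dict[dendropy.Node, frozenset[str]]:
    out: dict[dendropy.Node, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            out[node] = frozenset([node.taxon.label])
        else:
            s: set = set()
            for ch in node.child_nodes():
                s |= out[ch]
            out[node] = frozenset(s)
    return out


def bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions as canonical leaf-label sets.

    Each split is represented by the side that does *not* contain the
    alphabetically smallest leaf label, making the representation
    independent of rooting.
    """
    leafsets = _leafsets(tree)
    all_leaves = leafsets[tree.seed_node]
    anchor = min(all_leaves)
    out: set[frozenset[str]] = set()
    for node, ls in leafsets.items():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = ls if anchor not in ls else all_leaves - ls
        if len(side) >= 2 and len(all_leaves - side) >= 2:
            out.add(side)
    return out


def bootstrap_support(
    aln: Alignment,
    n_reps: int = 100,
    seed: int = 0,
    correction: str = "poisson",
    builder: Callable[[pd.DataFrame], dendropy.Tree] = nj_tree,
) -> dendropy.Tree:
    """Column bootstrap: resample columns with replacement, rebuild, and
    annotate the original tree's internal nodes with the fraction of
    replicates containing each bipartition (``node.support`` in [0, 1]).

    Replicates on which the distance matrix is undefined (e.g. a pair with
    no shared columns) are skipped with a warning and still count toward the
    denominator ``n_reps``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    base = builder(distance_matrix(aln, correction))
    target = bipartitions(base)
    counts: dict[frozenset[str], int] = {bp: 0 for bp in target}
    skipped = 0
    mat = [r.residues for r in aln.records]
    for _ in range(n_reps):
        cols = rng.integers(0, aln.ncols, size=aln.ncols)
        recs = [
            SequenceRecord(r.id, "".join(s[c] for c in cols), r.taxon)
            for r, s in zip(aln.records, mat)
        ]
        rep_aln = Alignment(recs)
        try:
            rep_tree = builder(distance_matrix(rep_aln, correction))
        except ValueError as e:
            skipped += 1
            logger.warning("bootstrap replicate skipped: %s", e)
            continue
        rep_bps = bipartitions(rep_tree)
        for bp in target:
            if bp in rep_bps:
                counts[bp] += 1
    if skipped:
        logger.warning("%d/%d bootstrap replicates skipped", skipped, n_reps)
    leafsets = _leafsets(base)
    all_leaves = leafsets[base.seed_node]
    anchor = min(all_leaves)
    for node, ls in leafsets.items():
        if node is base.seed_node or node.is_leaf():
            continue
        side = ls if anchor not in ls else all_leaves - ls
        if side in counts:
            node.support = counts[side] / n_reps
            node.label = f"{node.support:.2f}"
    return base


# ---------------------------------------------------------------------------
# rooting, monophyly, HGT incongruence


def _check_labels(tree: dendropy.Tree, labels: Iterable[str]) -> None:
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    unknown = sorted(set(labels) - leaves)
    if unknown:
        raise ValueError(f"labels not in tree: {unknown}")


def root_on_outgroup(
    tree: dendropy.Tree, outgroup: Iterable[str]
) -> dendropy.Tree:
    """Return a rooted clone of ``tree`` with the outgroup basal.

    The tree is rerooted on the edge above one outgroup leaf, then — if the
    full outgroup forms a clade from that rooting — on the edge above the
    outgroup's common ancestor.
    """
    outgroup = sorted(set(outgroup))
    if not outgroup:
        raise ValueError("outgroup must be non-empty")
    _check_labels(tree, outgroup)
    t = tree.clone(depth=1)
    first = [
        lf for lf in t.leaf_node_iter() if lf.taxon.label == outgroup[0]
    ][0]
    t.reroot_at_edge(first.edge, update_bipartitions=False)
    if len(outgroup) > 1:
        leafsets = _leafsets(t)
        candidates = [
            nd
            for nd, ls in leafsets.items()
            if ls == frozenset(outgroup) and nd is not t.seed_node
        ]
        if candidates:
            t.reroot_at_edge(candidates[0].edge, update_bipartitions=False)
    t.is_rooted = True
    return t


def is_monophyletic(
    tree: dendropy.Tree, taxa: Iterable[str], outgroup: Iterable[str]
) -> bool:
    """True iff ``taxa`` form a clade once the tree is rooted on ``outgroup``.

    ``taxa`` and ``outgroup`` must be disjoint leaf-label sets.
    """
    taxa = frozenset(taxa)
    out = frozenset(outgroup)
    if taxa & out:
        raise ValueError("taxa and outgroup overlap")
    _check_labels(tree, taxa | out)
    rooted = root_on_outgroup(tree, out)
    leafsets = _leafsets(rooted)
    return any(ls == taxa for ls in leafsets.values())


@dataclass
class HgtReport:
    """Outcome of the gene-tree / reference-tree incongruence test."""

    gene_monophyly: bool
    reference_monophyly: bool
    incongruent: bool
    joint_clade_support: float | None = None


def congruence_test(
    gene_tree: dendropy.Tree,
    reference_tree: dendropy.Tree,
    group1: Iterable[str],
    group2: Iterable[str],
    outgroup: Iterable[str],
) -> HgtReport:
    """Horizontal-gene-transfer signal from topological incongruence.

    The HGT flag is raised iff the two groups are jointly monophyletic in
    the gene tree but not in the reference (species) tree — the situation
    where a gene unites lineages that the organismal phylogeny separates.
    Both trees must cover group1 + group2 + outgroup; taxa present in only
    one tree are an error.
    """
    joint = frozenset(group1) | frozenset(group2)
    out = frozenset(outgroup)
    for t in (gene_tree, reference_tree):
        _check_labels(t, joint | out)
    gene_mono = is_monophyletic(gene_tree, joint, out)
    ref_mono = is_monophyletic(reference_tree, joint, out)
    support = None
    if gene_mono:
        rooted = root_on_outgroup(gene_tree, out)
        leafsets = _leafsets(rooted)
        for node, ls in leafsets.items():
            if ls == joint:
                support = getattr(node, "support", None)
                if support is None and node.label:
                    try:
                        support = float(node.label)
                    except ValueError:
                        support = None
                break
    return HgtReport(
        gene_monophyly=gene_mono,
        reference_monophyly=ref_mono,
        incongruent=gene_mono and not ref_mono,
        joint_clade_support=support,
    )


# ---------------------------------------------------------------------------
# presence matrix, Dollo origins, donor inference


@dataclass
class PresenceMatrix:
    """Taxa x CSI binary character states with optional occupied lengths.

    ``states``: DataFrame of {0, 1, NaN} (NaN = missing/unknown), indexed by
    taxon, one column per CSI id. ``lengths``: same shape, occupied residue
    count at the locus (for multi-state loci), optional.
    """

    states: pd.DataFrame
    lengths: pd.DataFrame | None = None

    def __post_init__(self):
        vals = self.states.to_numpy(dtype=float)
        ok = np.isnan(vals) | (vals == 0) | (vals == 1)
        if not ok.all():
            raise ValueError("states must be 0, 1 or missing")
        if self.lengths is not None and not self.lengths.index.equals(
            self.states.index
        ):
            raise ValueError("lengths index must match states index")

    @classmethod
    def from_csi_calls(cls, aln, calls) -> "PresenceMatrix":
        """Binary state = record occupies the locus; length = occupied count."""
        taxa = [r.taxon for r in aln.records]
        states = {}
        lengths = {}
        for i, call in enumerate(calls, 1):
            cid = f"CSI{i}"
            col_s, col_l = [], []
            for r in aln.records:
                n = call.locus.occupied[r.id]
                col_s.append(1.0 if n > 0 else 0.0)
                col_l.append(float(n))
            states[cid] = col_s
            lengths[cid] = col_l
        return cls(
            pd.DataFrame(states, index=taxa),
            pd.DataFrame(lengths, index=taxa),
        )

    def to_tsv(self, path) -> None:
        self.states.to_csv(path, sep="\t", index_label="taxon")

    @classmethod
    def from_tsv(cls, path) -> "PresenceMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col="taxon"))


@dataclass
class OriginMap:
    """Dollo placements: one gain per character, losses below it.

    Branches are identified by the leaf-label set of the clade below them.
    """

    gains: dict[str, frozenset[str]]
    losses: dict[str, list[frozenset[str]]] = field(default_factory=dict)

    def loss_count(self, csi: str) -> int:
        return len(self.losses.get(csi, []))


def dollo_origins(
    tree: dendropy.Tree,
    M: PresenceMatrix,
    outgroup: Iterable[str] | None = None,
) -> OriginMap:
    """Map each CSI's origin onto the tree under Dollo parsimony.

    The single gain is placed on the branch above the most recent common
    ancestor of all taxa carrying the derived state; losses are the minimal
    set of branches below it whose subtrees contain no carrier (missing
    states are uninformative and demand no loss). Identical multi-residue
    indels arising twice are considered implausible, hence single-gain.
    """
    t = root_on_outgroup(tree, outgroup) if outgroup else tree
    leafsets = _leafsets(t)
    _check_labels(t, M.states.index)
    gains: dict[str, frozenset[str]] = {}
    losses: dict[str, list[frozenset[str]]] = {}
    for csi in M.states.columns:
        col = M.states[csi]
        present = frozenset(col[col == 1].index)
        absent = frozenset(col[col == 0].index)
        if not present:
            raise ValueError(f"character {csi!r} present in zero taxa")
        # gain node: smallest clade containing all carriers
        gain_node = min(
            (nd for nd, ls in leafsets.items() if present <= ls),
            key=lambda nd: len(leafsets[nd]),
        )
        gains[csi] = leafsets[gain_node]
        loss_list: list[frozenset[str]] = []

        def collect(node):
            ls = leafsets[node]
            if ls & present:
                for ch in node.child_nodes():
                    collect(ch)
            elif ls & absent:
                loss_list.append(ls)
            # subtree of only-missing taxa: uninformative, no event

        for ch in gain_node.child_nodes():
            collect(ch)
        losses[csi] = loss_list
    return OriginMap(gains=gains, losses=losses)


def ancestral_state_vector(
    tree: dendropy.Tree,
    M: PresenceMatrix,
    recipient_taxa: Iterable[str],
    outgroup: Iterable[str] | None = None,
) -> dict[str, float]:
    """Dollo-inferred character states of the recipient clade's ancestor.

    A CSI is ancestrally present (state 1) iff its gain branch subtends the
    whole recipient clade; when lengths are available the ancestral value is
    the modal occupied length among recipient carriers, so that same-locus
    length variants (e.g. a 3- vs 2-residue insert) are distinguishable.
    """
    recipient = frozenset(recipient_taxa)
    origins = dollo_origins(tree, M, outgroup)
    vec: dict[str, float] = {}
    for csi in M.states.columns:
        gain_clade = origins.gains[csi]
        col = M.states[csi]
        carriers = set(col[col == 1].index) & recipient
        if recipient <= gain_clade and carriers:
            if M.lengths is not None:
                lens = M.lengths.loc[sorted(carriers), csi].dropna()
                counts = lens.value_counts()
                vec[csi] = float(
                    min(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0]
                )
            else:
                vec[csi] = 1.0
        else:
            vec[csi] = 0.0
    return vec


@dataclass
class DonorReport:
    """Donor-lineage compatibility from CSI state vectors."""

    compatible: list[str]
    excluded: dict[str, list[str]]  # subclade -> loci that exclude it
    uninformative_loci: list[str] = field(default_factory=list)


def subclade_state_vector(
    M: PresenceMatrix, taxa: Iterable[str]
) -> dict[str, float]:
    """Modal character state (length-aware when lengths exist) of a subclade."""
    taxa = sorted(set(taxa))
    vec: dict[str, float] = {}
    for csi in M.states.columns:
        if M.lengths is not None:
            vals = M.lengths.loc[taxa, csi].dropna()
        else:
            vals = M.states.loc[taxa, csi].dropna()
        if vals.empty:
            continue
        counts = vals.value_counts()
        vec[csi] = float(min(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0])
    return vec


def donor_inference(
    recipient_ancestral: dict[str, float],
    subclade_states: dict[str, dict[str, float]],
    drop_unmatched_loci: bool = True,
) -> DonorReport:
    """Rank candidate donor subclades of a horizontally transferred gene.

    A subclade is compatible iff its state vector matches the recipient
    clade's inferred ancestral state at every shared locus. Loci at which no
    subclade matches the ancestral state are, by default, set aside as
    uninformative: such a universal mismatch indicates the recipient state
    postdates the transfer (a later modification), so the locus cannot
    discriminate among donors.
    """
    loci = sorted(recipient_ancestral)
    uninformative: list[str] = []
    if drop_unmatched_loci:
        for locus in loci:
            shared = [
                sv for sv in subclade_states.values() if locus in sv
            ]
            if shared and not any(
                sv[locus] == recipient_ancestral[locus] for sv in shared
            ):
                uninformative.append(locus)
    informative = [l for l in loci if l not in uninformative]
    compatible: list[str] = []
    excluded: dict[str, list[str]] = {}
    for name in sorted(subclade_states):
        sv = subclade_states[name]
        bad = [
            locus
            for locus in informative
            if locus in sv and sv[locus] != recipient_ancestral[locus]
        ]
        if bad:
            excluded[name] = bad
        else:
            compatible.append(name)
    return DonorReport(
        compatible=compatible,
        excluded=excluded,
        uninformative_loci=uninformative,
    )


# ---------------------------------------------------------------------------
# newick I/O


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(
        path=str(path),
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )
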