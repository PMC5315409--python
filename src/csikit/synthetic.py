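"""Truth-tagged synthetic inputs for every pipeline stage.

Two generators live here:

* :func:`simulate_msa` evolves a clade-structured protein alignment along a
  known tree under a Poisson substitution process (uniform replacement over
  the 19 alternative residues) and plants indel events on chosen branches,
  including same-locus inserts of different lengths in different subclades.
  Flanking columns of every planted locus are held invariant by masking, so
  the conserved-flank criterion is met by construction when intended.
  Planted indel residues themselves are held invariant across the carrying
  clade (a conserved indel by construction).

* :func:`make_toy_dimer` builds an idealized two-chain structure whose
  designed loop residues, hydrogen-bond pairs and salt-bridge pairs are the
  only cross-chain features; every other inter-chain atom pair sits at or
  beyond a background separation. Geometry is idealized, not a real fold:
  the structure stage's claims under test are geometric.

Every dataset is emitted together with a :class:`SyntheticTruth` record
sufficient to score recovery exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import dendropy
import numpy as np

from csikit.seqdata import AMINO_ACIDS, Alignment, GroupAssignment, SequenceRecord

# ---------------------------------------------------------------------------
# MSA simulation


@dataclass(frozen=True)
class PlantedIndel:
    """One indel event planted on the stem branch of a clade.

    ``clade`` lists the leaf labels below the branch; ``pos`` is the 0-based
    root-coordinate column the event anchors to (insertions are placed
    before that column; deletions remove ``length`` root columns starting
    there). Insertion events at the same position in nested clades model
    same-locus length variants: the most specific event wins in its clade.
    """

    clade: tuple[str, ...]
    pos: int
    length: int
    kind: Literal["insertion", "deletion"]


@dataclass
class MsaSimConfig:
    tree_newick: str
    root_length: int
    seed: int
    rate: float = 1.0
    events: tuple[PlantedIndel, ...] = ()
    #: 0-based half-open root-coordinate ranges held free of substitutions
    invariant_ranges: tuple[tuple[int, int], ...] = ()
    #: columns of invariant flank added automatically around each event
    auto_flank: int = 8
    groups: dict[str, str] = field(default_factory=dict)
    target_groups: tuple[str, ...] = ()


@dataclass
class TruthCsi:
    start: int  # 1-based inclusive, final alignment coordinates
    end: int
    kind: str
    gain_clade: list[str]
    group_lengths: dict[str, int]
    #: occupied length -> leaves carrying it (same-locus variants)
    variant_leaves: dict[int, list[str]]


@dataclass
class SyntheticTruth:
    tree_newick: str
    csis: list[TruthCsi] = field(default_factory=list)
    reference_newick: str | None = None
    groups: dict[str, str] = field(default_factory=dict)
    interface_residues: list = field(default_factory=list)
    hbonds: list = field(default_factory=list)
    salt_bridges: list = field(default_factory=list)
    designed_contacts: int = 0
    background_contacts: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, default=list))


def _leaf_sets(tree: dendropy.Tree) -> dict[dendropy.Node, frozenset[str]]:
    out = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            out[node] = frozenset([node.taxon.label])
        else:
            out[node] = frozenset().union(*(out[c] for c in node.child_nodes()))
    return out


def simulate_msa(
    cfg: MsaSimConfig,
) -> tuple[Alignment, GroupAssignment, SyntheticTruth]:
    """Evolve sequences root-to-leaves and plant the configured indels.

    Per-branch substitution probability per site is 1 - exp(-b * rate).
    Deterministic for a fixed config (the seed is mandatory).
    """
    rng = np.random.default_rng(cfg.seed)
    tree = dendropy.Tree.get(
        data=cfg.tree_newick, schema="newick", preserve_underscores=True
    )
    leafsets = _leaf_sets(tree)
    all_leaves = sorted(leafsets[tree.seed_node])
    L = cfg.root_length

    # resolve each event to its leaf set and validate
    ev_leaves: list[frozenset[str]] = []
    for ev in cfg.events:
        want = frozenset(ev.clade)
        if not want <= frozenset(all_leaves):
            raise ValueError(f"event clade has unknown leaves: {ev.clade}")
        if not (0 <= ev.pos <= L):
            raise ValueError(f"event position {ev.pos} outside root length {L}")
        if ev.kind == "deletion" and ev.pos + ev.length > L:
            raise ValueError("deletion runs past the root sequence")
        ev_leaves.append(want)
    # overlapping deletions on a shared lineage are ambiguous
    dels = [
        (ev, lv) for ev, lv in zip(cfg.events, ev_leaves) if ev.kind == "deletion"
    ]
    for i in range(len(dels)):
        for j in range(i + 1, len(dels)):
            (e1, l1), (e2, l2) = dels[i], dels[j]
            if l1 & l2 and not (
                e1.pos + e1.length <= e2.pos or e2.pos + e2.length <= e1.pos
            ):
                raise ValueError("overlapping planted deletions on one lineage")

    # invariant mask over root coordinates
    invariant = np.zeros(L, dtype=bool)
    for lo, hi in cfg.invariant_ranges:
        invariant[max(0, lo):min(L, hi)] = True
    f = cfg.auto_flank
    for ev in cfg.events:
        right0 = ev.pos + (ev.length if ev.kind == "deletion" else 0)
        invariant[max(0, ev.pos - f):ev.pos] = True
        invariant[right0:min(L, right0 + f)] = True

    # evolve root-coordinate residues down the tree
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1")
    root_seq = rng.integers(0, 20, size=L)
    seqs: dict[dendropy.Node, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            seqs[node] = root_seq.copy()
            continue
        parent = seqs[node.parent_node]
        b = node.edge.length or 0.0
        p = 1.0 - math.exp(-b * cfg.rate)
        child = parent.copy()
        hit = (rng.random(L) < p) & ~invariant
        if hit.any():
            # uniform over the 19 alternatives
            shift = rng.integers(1, 20, size=int(hit.sum()))
            child[hit] = (child[hit] + shift) % 20
        seqs[node] = child
    leaf_root_seq = {
        n.taxon.label: seqs[n] for n in tree.leaf_node_iter()
    }

    # insertion loci: group insertion events by anchor position
    ins_by_pos: dict[int, list[int]] = {}
    for idx, ev in enumerate(cfg.events):
        if ev.kind == "insertion":
            ins_by_pos.setdefault(ev.pos, []).append(idx)
    loci: list[dict] = []
    for pos in sorted(ins_by_pos):
        idxs = ins_by_pos[pos]
        width = max(cfg.events[i].length for i in idxs)
        # most specific event (smallest clade) wins for a leaf in several
        idxs_sorted = sorted(idxs, key=lambda i: len(ev_leaves[i]))
        content: dict[str, str] = {}
        per_leaf_len: dict[str, int] = {lf: 0 for lf in all_leaves}
        residues = {
            i: "".join(
                AMINO_ACIDS[k]
                for k in rng.integers(0, 20, size=cfg.events[i].length)
            )
            for i in sorted(idxs)
        }
        for lf in all_leaves:
            chosen = None
            for i in idxs_sorted:
                if lf in ev_leaves[i]:
                    chosen = i
                    break
            if chosen is None:
                content[lf] = "-" * width
            else:
                seg = residues[chosen]
                content[lf] = seg + "-" * (width - len(seg))
                per_leaf_len[lf] = len(seg)
        outer = max(idxs, key=lambda i: len(ev_leaves[i]))
        loci.append(
            dict(pos=pos, width=width, kind="insertion", content=content,
                 per_leaf_len=per_leaf_len, gain=sorted(ev_leaves[outer]))
        )

    # deletion masks over root coordinates
    del_mask: dict[str, np.ndarray] = {
        lf: np.zeros(L, dtype=bool) for lf in all_leaves
    }
    for ev, lv in zip(cfg.events, ev_leaves):
        if ev.kind == "deletion":
            for lf in lv:
                del_mask[lf][ev.pos:ev.pos + ev.length] = True

    # assemble final alignment: root columns with insertion blocks spliced in
    blocks = {b["pos"]: b for b in loci}
    records = []
    for lf in all_leaves:
        parts = []
        root_chars = aa[leaf_root_seq[lf]].tobytes().decode()
        for c in range(L + 1):
            if c in blocks:
                parts.append(blocks[c]["content"][lf])
            if c < L:
                parts.append("-" if del_mask[lf][c] else root_chars[c])
        records.append(SequenceRecord(lf, "".join(parts)))
    aln = Alignment(records)

    # final-coordinate ranges of every planted locus
    def final_col(root_pos: int) -> int:
        """0-based final column of root column root_pos."""
        return root_pos + sum(
            b["width"] for p, b in blocks.items() if p <= root_pos
        )

    def group_of(leaf: str) -> str:
        return cfg.groups.get(leaf, "ungrouped")

    truth_csis: list[TruthCsi] = []
    for b in loci:
        start0 = b["pos"] + sum(
            bb["width"] for p, bb in blocks.items() if p < b["pos"]
        )
        variant: dict[int, list[str]] = {}
        per_group: dict[str, dict[int, int]] = {}
        for lf, n in b["per_leaf_len"].items():
            if n > 0:
                variant.setdefault(n, []).append(lf)
            per_group.setdefault(group_of(lf), {}).setdefault(n, 0)
            per_group[group_of(lf)][n] += 1
        group_lengths = {
            g: min(cnt.items(), key=lambda kv: (-kv[1], kv[0]))[0]
            for g, cnt in per_group.items()
        }
        truth_csis.append(
            TruthCsi(
                start=start0 + 1,
                end=start0 + b["width"],
                kind="insertion",
                gain_clade=b["gain"],
                group_lengths=group_lengths,
                variant_leaves={n: sorted(v) for n, v in variant.items()},
            )
        )
    for ev, lv in zip(cfg.events, ev_leaves):
        if ev.kind != "deletion":
            continue
        start0 = final_col(ev.pos)
        width = ev.length
        per_group: dict[str, dict[int, int]] = {}
        variant: dict[int, list[str]] = {}
        for lf in all_leaves:
            n = 0 if lf in lv else width
            if n > 0:
                variant.setdefault(n, []).append(lf)
            per_group.setdefault(group_of(lf), {}).setdefault(n, 0)
            per_group[group_of(lf)][n] += 1
        group_lengths = {
            g: min(cnt.items(), key=lambda kv: (-kv[1], kv[0]))[0]
            for g, cnt in per_group.items()
        }
        truth_csis.append(
            TruthCsi(
                start=start0 + 1,
                end=start0 + width,
                kind="deletion",
                gain_clade=sorted(lv),
                group_lengths=group_lengths,
                variant_leaves={n: sorted(v) for n, v in variant.items()},
            )
        )
    truth_csis.sort(key=lambda t: t.start)

    if cfg.groups:
        groups = GroupAssignment(dict(cfg.groups), cfg.target_groups)
    else:
        groups = GroupAssignment(
            {lf: "ingroup" for lf in all_leaves[:-1]}
            | {all_leaves[-1]: "outgroup"},
            ("ingroup",),
        )
    truth = SyntheticTruth(
        tree_newick=cfg.tree_newick,
        csis=truth_csis,
        groups=dict(cfg.groups),
    )
    return aln, groups, truth


# ---------------------------------------------------------------------------
# presets


def _preset_tree() -> tuple[str, dict[str, str]]:
    """30-taxon tree: 12 bifid-like, 8 corio-like (4 genera), 10 outgroup.

    The gene-tree topology joins the two target orders, mirroring the
    transferred-gene scenario.
    """
    bifido = [f"Bifido{i:02d}" for i in range(1, 13)]
    atopo = ["Atopobium1", "Atopobium2", "Atopobium3"]
    olsen = ["Olsenella1", "Olsenella2"]
    colli = ["Collinsella1", "Collinsella2"]
    corio_g = ["Coriobacterium1"]
    outg = [f"Firmicutes{i:02d}" for i in range(1, 11)]

    def ladder(names: list[str], bl: float) -> str:
        t = names[0] + f":{bl}"
        for nm in names[1:]:
            t = f"({t},{nm}:{bl}):{bl}"
        return t

    bif = ladder(bifido, 0.03)
    cor = (
        f"((({colli[0]}:0.03,{colli[1]}:0.03):0.03,{corio_g[0]}:0.05):0.04,"
        f"(({atopo[0]}:0.03,{atopo[1]}:0.03):0.02,{atopo[2]}:0.04):0.03,"
        f"({olsen[0]}:0.03,{olsen[1]}:0.03):0.04):0.05"
    )
    out = ladder(outg, 0.04)
    newick = f"(({bif}:0.10,{cor}:0.08):0.20,{out}:0.10);"
    groups = (
        {t: "Bifidobacteriales" for t in bifido}
        | {t: "Coriobacteriales" for t in atopo + olsen + colli + corio_g}
        | {t: "Firmicutes" for t in outg}
    )
    return newick, groups


#: subclades of the corio-like order, used for donor inference
PRESET_SUBCLADES = {
    "Atopobium": ["Atopobium1", "Atopobium2", "Atopobium3"],
    "Olsenella": ["Olsenella1", "Olsenella2"],
    "Collinsella_Coriobacterium": [
        "Collinsella1", "Collinsella2", "Coriobacterium1"
    ],
}

PRESETS = ("fig1_like", "fig2_like", "hgt_like", "clean_negative")


def make_preset(
    preset: str, seed: int
) -> tuple[Alignment, GroupAssignment, SyntheticTruth]:
    """Build one of the standard synthetic datasets.

    * ``fig1_like``: a shared two-order 3-residue insertion with a nested
      2-residue variant in one subclade, plus a shared 2-residue deletion.
    * ``fig2_like``: same-locus inserts of length 2 (order 1) and 3 (order 2).
    * ``hgt_like``: gene alignment whose true tree joins the two orders
      while the emitted reference tree separates them.
    * ``clean_negative``: no planted events.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")
    newick, groups = _preset_tree()
    bifido = sorted(t for t, g in groups.items() if g == "Bifidobacteriales")
    corio = sorted(t for t, g in groups.items() if g == "Coriobacteriales")
    both = tuple(bifido + corio)
    colli_cor = tuple(PRESET_SUBCLADES["Collinsella_Coriobacterium"])
    events: tuple[PlantedIndel, ...] = ()
    if preset == "fig1_like":
        events = (
            PlantedIndel(both, 120, 3, "insertion"),
            PlantedIndel(colli_cor, 120, 2, "insertion"),
            PlantedIndel(both, 240, 2, "deletion"),
        )
    elif preset == "fig2_like":
        events = (
            PlantedIndel(tuple(bifido), 180, 2, "insertion"),
            PlantedIndel(tuple(corio), 180, 3, "insertion"),
        )
    elif preset == "hgt_like":
        events = (
            PlantedIndel(both, 150, 3, "insertion"),
        )
    cfg = MsaSimConfig(
        tree_newick=newick,
        root_length=360,
        seed=seed,
        rate=1.0,
        events=events,
        groups=groups,
        target_groups=("Bifidobacteriales", "Coriobacteriales"),
    )
    aln, ga, truth = simulate_msa(cfg)
    if preset == "hgt_like":
        # reference (species-like) tree: the two target orders branch apart
        truth.reference_newick = _reference_tree(groups)
    return aln, ga, truth


def _reference_tree(groups: dict[str, str]) -> str:
    bif = sorted(t for t, g in groups.items() if g == "Bifidobacteriales")
    cor = sorted(t for t, g in groups.items() if g == "Coriobacteriales")
    out = sorted(t for t, g in groups.items() if g == "Firmicutes")

    def comb(names):
        return "(" + ",".join(f"{n}:0.05" for n in names) + ")"

    # corio-like order is the deepest actinobacterial branch; bifid-like
    # order branches with the remaining outgroup taxa instead
    half = len(out) // 2
    return (
        f"(({comb(bif)}:0.1,{comb(out[:half])}:0.1):0.1,"
        f"({comb(cor)}:0.1,{comb(out[half:])}:0.1):0.1);"
    )


def make_standard_dataset(preset: str, seed: int, outdir: str | Path) -> dict:
    """Write a preset dataset to disk; returns the file manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    aln, groups, truth = make_preset(preset, seed)
    paths = {
        "alignment": outdir / "alignment.fasta",
        "groups": outdir / "groups.tsv",
        "tree": outdir / "true_tree.nwk",
        "truth": outdir / "truth.json",
    }
    aln.to_fasta(paths["alignment"])
    groups.to_tsv(paths["groups"])
    Path(paths["tree"]).write_text(truth.tree_newick + "\n")
    if truth.reference_newick:
        paths["reference"] = outdir / "reference.nwk"
        Path(paths["reference"]).write_text(truth.reference_newick + "\n")
    truth.to_json(paths["truth"])
    return {k: str(v) for k, v in paths.items()}


# ---------------------------------------------------------------------------
# toy dimer


@dataclass
class ToyDimerConfig:
    """Designed two-chain structure.

    ``loop`` residues carry a protruding carbon tip making a cross-chain
    contact at ``contact_distance``; ``hbond_pairs`` and ``bridge_pairs``
    are (residue index, distance) designs realized with Asn O/N tips and
    Arg/Asp tips respectively. All indices are 1-based and apply to both
    chains symmetrically. Everything else sits at ``background`` separation.
    """

    seed: int
    n_res: int = 30
    loop: tuple[int, ...] = (14, 15, 16)
    contact_distance: float = 3.0
    hbond_pairs: tuple[tuple[int, float], ...] = ((8, 2.8),)
    bridge_pairs: tuple[tuple[int, float], ...] = ((22, 3.8),)
    background: float = 12.0

    def __post_init__(self):
        designed = list(self.loop) + [i for i, _ in self.hbond_pairs] + [
            i for i, _ in self.bridge_pairs
        ]
        if len(set(designed)) != len(designed):
            raise ValueError("designed residue indices must be distinct")
        if max(designed, default=0) > self.n_res:
            raise ValueError("designed residue index beyond chain length")
        if self.contact_distance >= self.background / 2:
            raise ValueError("contact distance unsatisfiable at this background")
        for _, d in self.hbond_pairs:
            if not (2.5 <= d <= 3.5):
                raise ValueError("designed H-bond distance outside [2.5, 3.5]")
        for _, d in self.bridge_pairs:
            if not (3.5 < d <= 4.0):
                raise ValueError(
                    "designed salt-bridge distance must lie in (3.5, 4.0] so "
                    "it does not double as a hydrogen bond"
                )


_PDB_LINE = (
    "ATOM  {serial:>5d} {name:<4s}{alt:1s}{res:<3s} {chain:1s}{resseq:>4d}"
    "{icode:1s}   {x:>8.3f}{y:>8.3f}{z:>8.3f}{occ:>6.2f}{b:>6.2f}"
    "          {element:>2s}"
)


def make_toy_dimer(cfg: ToyDimerConfig) -> tuple[str, SyntheticTruth]:
    """Build the designed dimer; returns (PDB text, truth).

    Chain A runs along x at y=0, chain B parallel at y=``background``.
    Designed residues carry a two-atom stalk whose tip meets the partner
    chain's tip at the designed distance; tips are the only inter-chain
    atoms closer than the background separation. Deterministic given the
    config (the seed only draws the filler residue types).
    """
    rng = np.random.default_rng(cfg.seed)
    filler = ["ALA", "GLY", "SER", "VAL", "LEU", "THR"]
    spacing = 3.8
    D = cfg.background

    special: dict[int, tuple[str, str, str, float]] = {}
    # residue -> (resname, tipA atom, tipB atom, tip-tip distance)
    for i in cfg.loop:
        special[i] = ("LEU", "CG", "CG", cfg.contact_distance)
    for i, d in cfg.hbond_pairs:
        special[i] = ("ASN", "OD1", "ND2", d)
    for i, d in cfg.bridge_pairs:
        special[i] = ("ARG", "NH1", "NH1", d)  # chain B gets ASP/OD1 below

    res_names_a = {}
    res_names_b = {}
    for i in range(1, cfg.n_res + 1):
        if i in special:
            rn = special[i][0]
            res_names_a[i] = rn
            res_names_b[i] = "ASP" if rn == "ARG" else rn
        else:
            rn = filler[rng.integers(0, len(filler))]
            res_names_a[i] = rn
            res_names_b[i] = rn

    def element_of(name: str) -> str:
        return name[0]

    lines: list[str] = []
    serial = 1

    def emit(chain: str, resseq: int, resname: str, name: str, xyz):
        nonlocal serial
        lines.append(
            _PDB_LINE.format(
                serial=serial, name=f" {name:<3s}"[:4], alt=" ", res=resname,
                chain=chain, resseq=resseq, icode=" ", x=xyz[0], y=xyz[1],
                z=xyz[2], occ=1.00, b=0.00, element=element_of(name),
            )
        )
        serial += 1

    truth_iface: list[list] = []
    truth_hb: list[list] = []
    truth_sb: list[list] = []
    tip_coords: dict[tuple[str, int], tuple[float, float, float]] = {}

    for chain, base_y in (("A", 0.0), ("B", D)):
        sgn = 1.0 if chain == "A" else -1.0
        names = res_names_a if chain == "A" else res_names_b
        for i in range(1, cfg.n_res + 1):
            x = spacing * i
            rn = names[i]
            emit(chain, i, rn, "N", (x - 0.7, base_y, 0.6))
            emit(chain, i, rn, "CA", (x, base_y, 0.0))
            emit(chain, i, rn, "C", (x + 0.7, base_y, -0.6))
            emit(chain, i, rn, "O", (x + 0.7, base_y, -1.8))
            if i in special:
                _, tip_a, tip_b, d = special[i]
                tip_name = tip_a if chain == "A" else (
                    "OD1" if names[i] == "ASP" else tip_b
                )
                tip_y = base_y + sgn * (D - d) / 2.0
                emit(chain, i, rn, "CB", (x, base_y + sgn * 1.5, 0.0))
                emit(chain, i, rn, tip_name, (x, tip_y, 0.0))
                tip_coords[(chain, i)] = (x, tip_y, 0.0)
        lines.append("TER")
    lines.append("END")

    for i in sorted(special):
        truth_iface.append(["A", i, ""])
        truth_iface.append(["B", i, ""])
    for i, d in cfg.hbond_pairs:
        truth_hb.append(["A", i, "OD1", "B", i, "ND2", d])
    for i, d in cfg.bridge_pairs:
        truth_sb.append(["A", i, "NH1", "B", i, "OD1", d])

    # designed cross-chain contacts (< 4.5 A), computed from the designed
    # coordinates themselves: only aligned tip pairs can qualify
    contacts = 0
    for (ca, ia), pa in tip_coords.items():
        for (cb, ib), pb in tip_coords.items():
            if ca == "A" and cb == "B":
                dd = math.dist(pa, pb)
                if dd < 4.5:
                    contacts += 1
    background_contacts = sum(
        1
        for (ca, ia), pa in tip_coords.items()
        for (cb, ib), pb in tip_coords.items()
        if ca == "A" and cb == "B" and ia not in cfg.loop and ib not in cfg.loop
        and math.dist(pa, pb) < 4.5
    )
    truth = SyntheticTruth(
        tree_newick="",
        interface_residues=truth_iface,
        hbonds=truth_hb,
        salt_bridges=truth_sb,
        designed_contacts=contacts,
        background_contacts=background_contacts,
    )
    return "\n".join(lines) + "\n", truth
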