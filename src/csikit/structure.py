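"""Dimer-interface analysis: solvent accessibility, interface residues,
hydrogen bonds, salt bridges, and the geometric effect of excising CSI
residues from a two-chain complex.

Solvent-accessible surface areas are computed with the Shrake-Rupley
rolling-probe quadrature on a deterministic golden-section spiral. Hydrogen
bonds use a heavy-atom distance criterion (structures are assumed
hydrogen-free), salt bridges pair side-chain charged groups across chains.
All geometric thresholds are parameters echoed into every report.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

#: van der Waals radii (Angstrom) by element
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}
DEFAULT_RADIUS = 1.70

#: per-residue maximum accessible surface area (Gly-X-Gly tripeptide
#: reference, Angstrom^2) used for relative SASA
MAX_SASA_GXG = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

#: hydrogen-bond-capable heavy atoms (N/O only; no angle term without H)
HB_DONORS = {
    ("*", "N"),
    ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
    ("ASN", "ND2"), ("GLN", "NE2"),
    ("HIS", "ND1"), ("HIS", "NE2"),
    ("LYS", "NZ"), ("SER", "OG"), ("THR", "OG1"),
    ("TRP", "NE1"), ("TYR", "OH"),
}
HB_ACCEPTORS = {
    ("*", "O"), ("*", "OXT"),
    ("ASN", "OD1"), ("ASP", "OD1"), ("ASP", "OD2"),
    ("GLN", "OE1"), ("GLU", "OE1"), ("GLU", "OE2"),
    ("HIS", "ND1"), ("HIS", "NE2"),
    ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"),
}

#: salt-bridge groups: His counted as potentially protonated
SB_POSITIVE = {
    ("LYS", "NZ"),
    ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
    ("HIS", "ND1"), ("HIS", "NE2"),
}
SB_NEGATIVE = {
    ("ASP", "OD1"), ("ASP", "OD2"),
    ("GLU", "OE1"), ("GLU", "OE2"),
    ("*", "OXT"),
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray
    radius: float

    def __post_init__(self):
        self.coord = np.asarray(self.coord, dtype=float)
        if not np.isfinite(self.coord).all():
            raise ValueError(f"atom {self.name}: non-finite coordinates")
        if self.radius <= 0:
            raise ValueError(f"atom {self.name}: radius must be positive")


@dataclass
class Residue:
    name: str
    resseq: int
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[int, str]:
        return (self.resseq, self.icode)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.name}{self.resseq}: no atom {name!r}")


class Structure:
    """Chains of residues of heavy atoms, with coordinates in Angstrom."""

    def __init__(self, chains: dict[str, list[Residue]]):
        for cid, residues in chains.items():
            keys = [r.key for r in residues]
            if len(set(keys)) != len(keys):
                raise ValueError(f"chain {cid}: duplicate residue numbers")
        self.chains = chains

    def chain(self, cid: str) -> list[Residue]:
        try:
            return self.chains[cid]
        except KeyError:
            raise ValueError(f"no chain {cid!r} in structure") from None

    def subset(self, chain_ids: Sequence[str]) -> "Structure":
        return Structure({c: self.chain(c) for c in chain_ids})

    def excise(
        self, ranges: Sequence[tuple[int, int]], chain_ids: Sequence[str]
    ) -> "Structure":
        """Remove residues whose number falls in any 1-based inclusive range
        from each of ``chain_ids`` (no remodeling of the remainder)."""

        def keep(res: Residue) -> bool:
            return not any(lo <= res.resseq <= hi for lo, hi in ranges)

        new = {}
        for cid, residues in self.chains.items():
            if cid in chain_ids:
                kept = [r for r in residues if keep(r)]
                if not kept:
                    raise ValueError(f"excision empties chain {cid}")
                new[cid] = kept
            else:
                new[cid] = residues
        return Structure(new)

    def one_letter(self, cid: str) -> str:
        return "".join(
            THREE_TO_ONE.get(r.name, "X") for r in self.chain(cid)
        )

    def atom_table(
        self, chain_ids: Sequence[str] | None = None
    ) -> tuple[np.ndarray, np.ndarray, list[tuple[str, int, str, str, str]]]:
        """Flatten to (coords, radii, meta); meta rows are
        (chain, resseq, icode, resname, atomname)."""
        if chain_ids is None:
            chain_ids = list(self.chains)
        coords, radii, meta = [], [], []
        for cid in chain_ids:
            for res in self.chain(cid):
                for a in res.atoms:
                    coords.append(a.coord)
                    radii.append(a.radius)
                    meta.append((cid, res.resseq, res.icode, res.name, a.name))
        return np.asarray(coords, dtype=float), np.asarray(radii), meta


def read_structure(path: str | Path) -> Structure:
    """Parse a PDB file into a :class:`Structure`.

    Hydrogens and waters are dropped; alternate locations resolve to the
    highest-occupancy conformer (ties to altloc 'A'); van der Waals radii
    come from a fixed element table with a warned default of 1.70 A for
    elements outside it.
    """
    from Bio.PDB import PDBParser

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = PDBParser(QUIET=True).get_structure("s", str(path))
    chains: dict[str, list[Residue]] = {}
    n_waters = 0
    n_atoms = 0
    models = list(model.get_models())
    if not models:
        raise ValueError(f"{path}: no ATOM records")
    for chain in models[0]:
        residues: list[Residue] = []
        for res in chain:
            hetflag, resseq, icode = res.id
            if res.get_resname().strip() in ("HOH", "WAT", "DOD"):
                n_waters += 1
                continue
            atoms: list[Atom] = []
            for atom in res:
                if atom.is_disordered():
                    alts = sorted(
                        atom.disordered_get_list(),
                        key=lambda a: (-(a.get_occupancy() or 0.0),
                                       a.get_altloc()),
                    )
                    atom = alts[0]
                element = (atom.element or "").strip().upper()
                if element in ("H", "D"):
                    continue
                radius = VDW_RADII.get(element)
                if radius is None:
                    logger.warning(
                        "unknown element %r at %s%d:%s; default radius %.2f",
                        element, chain.id, resseq, atom.get_name(),
                        DEFAULT_RADIUS,
                    )
                    radius = DEFAULT_RADIUS
                atoms.append(
                    Atom(atom.get_name(), element, atom.coord, radius)
                )
            if atoms:
                residues.append(
                    Residue(res.get_resname().strip(), resseq,
                            icode.strip(), atoms)
                )
                n_atoms += len(atoms)
        if residues:
            chains[chain.id] = residues
    if n_atoms == 0:
        raise ValueError(f"{path}: no ATOM records")
    if n_waters:
        logger.info("excluded %d water residues", n_waters)
    return Structure(chains)


# ---------------------------------------------------------------------------
# Shrake-Rupley SASA


def _spiral_points(n: int) -> np.ndarray:
    """Deterministic golden-section spiral on the unit sphere."""
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    phi = i * math.pi * (3.0 - math.sqrt(5.0))
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


@dataclass
class SasaResult:
    """Per-atom and per-residue accessible surface areas (Angstrom^2)."""

    atom_areas: np.ndarray
    meta: list[tuple[str, int, str, str, str]]
    probe: float
    n_points: int

    @property
    def total(self) -> float:
        return float(self.atom_areas.sum())

    def residue_areas(self) -> dict[tuple[str, int, str], float]:
        out: dict[tuple[str, int, str], float] = {}
        for area, (cid, resseq, icode, _rn, _an) in zip(
            self.atom_areas, self.meta
        ):
            key = (cid, resseq, icode)
            out[key] = out.get(key, 0.0) + float(area)
        return out


def shrake_rupley(
    s: Structure,
    probe: float = 1.4,
    n_points: int = 960,
    chain_ids: Sequence[str] | None = None,
) -> SasaResult:
    """Shrake-Rupley solvent-accessible surface area.

    Each atom's sphere of radius r+probe is sampled at ``n_points`` spiral
    points; the accessible area is the exposed-point fraction times
    4*pi*(r+probe)^2. Neighbor search is restricted to atoms within
    r_i + r_j + 2*probe.
    """
    if probe < 0:
        raise ValueError("probe radius must be >= 0")
    if n_points < 92:
        raise ValueError("n_points must be >= 92")
    coords, radii, meta = s.atom_table(chain_ids)
    n = len(coords)
    pts = _spiral_points(n_points)
    areas = np.zeros(n)
    if n == 0:
        return SasaResult(areas, meta, probe, n_points)
    tree = cKDTree(coords)
    rmax = radii.max()
    for i in range(n):
        ri = radii[i] + probe
        cand = tree.query_ball_point(coords[i], radii[i] + rmax + 2 * probe)
        neigh = [
            j
            for j in cand
            if j != i
            and np.dot(coords[i] - coords[j], coords[i] - coords[j])
            < (radii[i] + radii[j] + 2 * probe) ** 2
        ]
        sphere = coords[i] + ri * pts
        exposed = np.ones(n_points, dtype=bool)
        for j in neigh:
            rj = radii[j] + probe
            d2 = np.einsum(
                "ij,ij->i", sphere - coords[j], sphere - coords[j]
            )
            exposed &= d2 >= rj * rj
            if not exposed.any():
                break
        areas[i] = exposed.mean() * 4.0 * math.pi * ri * ri
    return SasaResult(areas, meta, probe, n_points)


def relative_sasa(
    s: Structure, chain_id: str, probe: float = 1.4, n_points: int = 960
) -> dict[tuple[int, str], float]:
    """Residue SASA relative to the Gly-X-Gly reference value (surface-loop
    localization: values near 1 are fully exposed)."""
    res_area = shrake_rupley(s.subset([chain_id]), probe, n_points).residue_areas()
    out = {}
    for res in s.chain(chain_id):
        ref = MAX_SASA_GXG.get(res.name)
        if ref:
            out[res.key] = res_area.get((chain_id, *res.key), 0.0) / ref
    return out


# ---------------------------------------------------------------------------
# interface analysis


def _pairs_within(
    s: Structure, chain_a: str, chain_b: str, d_max: float
) -> list[tuple[int, int, float]]:
    """Indices (into each chain's atom table) of inter-chain atom pairs
    within d_max, with distances."""
    ca, _, _ = s.atom_table([chain_a])
    cb, _, _ = s.atom_table([chain_b])
    ta, tb = cKDTree(ca), cKDTree(cb)
    out = []
    for i, js in enumerate(ta.query_ball_tree(tb, d_max)):
        for j in js:
            d = float(np.linalg.norm(ca[i] - cb[j]))
            if d <= d_max:
                out.append((i, j, d))
    return out


def contact_count(
    s: Structure, chain_a: str, chain_b: str, d_max: float = 4.5
) -> int:
    """Number of inter-chain heavy-atom pairs within ``d_max`` Angstrom."""
    return len(_pairs_within(s, chain_a, chain_b, d_max))


@dataclass
class BondRecord:
    chain_a: str
    res_a: tuple[int, str, str]  # (resseq, icode, resname)
    atom_a: str
    chain_b: str
    res_b: tuple[int, str, str]
    atom_b: str
    distance: float


def _capable(resname: str, atomname: str, table) -> bool:
    return (resname, atomname) in table or ("*", atomname) in table


def hydrogen_bonds(
    s: Structure, chain_a: str, chain_b: str, d_max: float = 3.5
) -> list[BondRecord]:
    """Inter-chain hydrogen bonds by the heavy-atom criterion.

    A donor-capable N/O of one chain within ``d_max`` of an acceptor-capable
    N/O of the other counts as one bond; an atom pair capable in both
    directions is reported once. No angle term is applied (hydrogens are
    absent from the model).
    """
    if not (2.5 <= d_max <= 4.0):
        raise ValueError("hydrogen-bond cutoff must lie in [2.5, 4.0]")
    _, _, meta_a = s.atom_table([chain_a])
    _, _, meta_b = s.atom_table([chain_b])
    seen: set[tuple] = set()
    bonds: list[BondRecord] = []
    for i, j, d in _pairs_within(s, chain_a, chain_b, d_max):
        _, rs_a, ic_a, rn_a, an_a = meta_a[i]
        _, rs_b, ic_b, rn_b, an_b = meta_b[j]
        ab = _capable(rn_a, an_a, HB_DONORS) and _capable(rn_b, an_b, HB_ACCEPTORS)
        ba = _capable(rn_b, an_b, HB_DONORS) and _capable(rn_a, an_a, HB_ACCEPTORS)
        if not (ab or ba):
            continue
        key = (rs_a, ic_a, an_a, rs_b, ic_b, an_b)
        if key in seen:
            continue
        seen.add(key)
        bonds.append(
            BondRecord(chain_a, (rs_a, ic_a, rn_a), an_a,
                       chain_b, (rs_b, ic_b, rn_b), an_b, d)
        )
    return sorted(bonds, key=lambda b: (b.res_a[0], b.atom_a, b.res_b[0]))


def salt_bridges(
    s: Structure, chain_a: str, chain_b: str, d_max: float = 4.0
) -> list[BondRecord]:
    """Inter-chain salt bridges: a Lys/Arg/His positive-group nitrogen of
    one chain within ``d_max`` of an Asp/Glu carboxylate oxygen (or
    C-terminal OXT) of the other. His is treated as potentially protonated.
    """
    if not (3.0 <= d_max <= 5.0):
        raise ValueError("salt-bridge cutoff must lie in [3.0, 5.0]")
    _, _, meta_a = s.atom_table([chain_a])
    _, _, meta_b = s.atom_table([chain_b])
    bonds: list[BondRecord] = []
    for i, j, d in _pairs_within(s, chain_a, chain_b, d_max):
        _, rs_a, ic_a, rn_a, an_a = meta_a[i]
        _, rs_b, ic_b, rn_b, an_b = meta_b[j]
        pos_neg = _capable(rn_a, an_a, SB_POSITIVE) and _capable(
            rn_b, an_b, SB_NEGATIVE
        )
        neg_pos = _capable(rn_a, an_a, SB_NEGATIVE) and _capable(
            rn_b, an_b, SB_POSITIVE
        )
        if pos_neg or neg_pos:
            bonds.append(
                BondRecord(chain_a, (rs_a, ic_a, rn_a), an_a,
                           chain_b, (rs_b, ic_b, rn_b), an_b, d)
            )
    return sorted(bonds, key=lambda b: (b.res_a[0], b.atom_a, b.res_b[0]))


@dataclass
class InterfaceReport:
    """Per-residue interface evidence for a two-chain complex."""

    dsasa: dict[tuple[str, int, str], float]
    interface_residues: set[tuple[str, int, str]]
    hbonds: list[BondRecord]
    bridges: list[BondRecord]
    buried_area: float
    contacts: int
    params: dict


def interface_report(
    complex: Structure,
    chain_a: str,
    chain_b: str,
    probe: float = 1.4,
    n_points: int = 960,
    dsasa_min: float = 0.1,
    hbond_max: float = 3.5,
    bridge_max: float = 4.0,
    contact_max: float = 4.5,
) -> InterfaceReport:
    """Full interface characterization of the chain_a/chain_b complex.

    Delta-SASA of a residue is its SASA in the isolated chain minus its SASA
    in the complex; residues with Delta-SASA above ``dsasa_min`` form the
    interface set. Total buried area is the sum of Delta-SASA over both
    chains (equal to SASA_A + SASA_B - SASA_AB up to quadrature noise).
    """
    for cid in (chain_a, chain_b):
        if cid not in complex.chains or not complex.chains[cid]:
            raise ValueError(f"chain {cid!r} missing or empty")
    sasa_a = shrake_rupley(complex.subset([chain_a]), probe, n_points)
    sasa_b = shrake_rupley(complex.subset([chain_b]), probe, n_points)
    sasa_ab = shrake_rupley(complex.subset([chain_a, chain_b]), probe, n_points)
    mono = {**sasa_a.residue_areas(), **sasa_b.residue_areas()}
    comp = sasa_ab.residue_areas()
    dsasa = {k: mono[k] - comp.get(k, 0.0) for k in mono}
    iface = {k for k, v in dsasa.items() if v > dsasa_min}
    return InterfaceReport(
        dsasa=dsasa,
        interface_residues=iface,
        hbonds=hydrogen_bonds(complex, chain_a, chain_b, hbond_max),
        bridges=salt_bridges(complex, chain_a, chain_b, bridge_max),
        buried_area=float(sum(dsasa.values())),
        contacts=contact_count(complex, chain_a, chain_b, contact_max),
        params=dict(
            probe=probe, n_points=n_points, dsasa_min=dsasa_min,
            hbond_max=hbond_max, bridge_max=bridge_max,
            contact_max=contact_max, chain_a=chain_a, chain_b=chain_b,
        ),
    )


# backwards-compatible name mirroring the operation it implements
interface_residues = interface_report


@dataclass
class InterfaceDelta:
    """Interface metrics before and after residue excision."""

    before: InterfaceReport
    after: InterfaceReport
    excised_ranges: list[tuple[int, int]]

    @property
    def buried_area_loss(self) -> float:
        return self.before.buried_area - self.after.buried_area

    @property
    def contact_loss(self) -> int:
        return self.before.contacts - self.after.contacts


def interface_delta(
    complex: Structure,
    ranges: Sequence[tuple[int, int]],
    chain_a: str,
    chain_b: str,
    **params,
) -> InterfaceDelta:
    """Recompute the interface after excising residue ranges (1-based
    inclusive author numbering) from both chains — pure removal, no
    remodeling — and report before/after buried area, contact, hydrogen-bond
    and salt-bridge counts."""
    before = interface_report(complex, chain_a, chain_b, **params)
    cut = complex.excise(list(ranges), [chain_a, chain_b])
    after = interface_report(cut, chain_a, chain_b, **params)
    return InterfaceDelta(before, after, list(ranges))


# ---------------------------------------------------------------------------
# sequence-to-structure mapping


def map_alignment_to_structure(
    record, residues: list[Residue], min_identity: float = 0.9
) -> dict[int, tuple[int, str]]:
    """Map alignment columns of a record onto chain residue numbers.

    The record's ungapped sequence is globally aligned to the chain's
    one-letter sequence (match +1, mismatch -1, gap open -5, extend -1);
    each non-gap alignment column then maps to at most one residue number.
    Raises when identity over the aligned region falls below
    ``min_identity`` (wrong chain or sequence).
    """
    from Bio import Align

    seq = record.residues.replace("-", "")
    cols = [i for i, ch in enumerate(record.residues) if ch != "-"]
    chain_seq = "".join(THREE_TO_ONE.get(r.name, "X") for r in residues)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    alignment = aligner.align(seq, chain_seq)[0]
    mapping: dict[int, tuple[int, str]] = {}
    matches = aligned_pairs = 0
    for (qs, qe), (ts, te) in zip(*alignment.aligned):
        for q, t in zip(range(qs, qe), range(ts, te)):
            aligned_pairs += 1
            if seq[q] == chain_seq[t]:
                matches += 1
            mapping[cols[q]] = (residues[t].resseq, residues[t].icode)
    if aligned_pairs == 0 or matches / aligned_pairs < min_identity:
        ident = matches / aligned_pairs if aligned_pairs else 0.0
        raise ValueError(
            f"sequence/chain identity {ident:.2f} below {min_identity}: "
            "wrong chain or sequence"
        )
    return mapping


@dataclass
class CsiLocation:
    """A CSI projected onto structure residue numbering."""

    ranges: list[tuple[int, int]]
    partial: bool
    unmapped_columns: list[int]


def locate_csi(
    csi, mapping: dict[int, tuple[int, str]]
) -> CsiLocation:
    """Residue-number ranges (author numbering) occupied by a CSI.

    ``mapping`` is 0-based alignment column -> (resseq, icode) for the
    record carrying the CSI. Unmodeled columns are flagged; a CSI that is
    wholly unmodeled yields an empty range list.
    """
    cols0 = range(csi.start - 1, csi.end)
    mapped = [(c, mapping[c]) for c in cols0 if c in mapping]
    unmapped = [c + 1 for c in cols0 if c not in mapping]
    ranges: list[tuple[int, int]] = []
    for _c, (resseq, _ic) in mapped:
        if ranges and resseq == ranges[-1][1] + 1:
            ranges[-1] = (ranges[-1][0], resseq)
        else:
            ranges.append((resseq, resseq))
    return CsiLocation(
        ranges=ranges,
        partial=bool(unmapped) and bool(ranges) or len(ranges) > 1,
        unmapped_columns=unmapped,
    )
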