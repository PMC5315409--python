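"""End-to-end orchestration: detect -> phylogenetics -> structure.

A :class:`RunConfig` collects every stage parameter (all module defaults
overridable), is fully serializable, and is echoed into the output directory
so that rerunning with the archived config reproduces all outputs. Stage
failures abort with a stage-named error; outputs of completed stages are
retained together with a MANIFEST of what finished.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from csikit import csi_detection, phylogenetics, seqdata, structure

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    alignment: str
    groups: str
    target_groups: list[str]
    outdir: str
    seed: int = 42
    alignment_format: str = "aligned-fasta"
    # detection
    min_len: int = 1
    max_len: int = 50
    window: int = 30
    min_conserved: int = 5
    cons_threshold: float = 0.8
    tol: float = 0.05
    # phylogenetics
    reference: str | None = None
    outgroup_label: str | None = None
    bootstrap_reps: int = 100
    correction: str = "poisson"
    max_gap_fraction: float = 0.2
    min_majority: float = 0.5
    min_block: int = 5
    donor_subclades: dict[str, list[str]] = field(default_factory=dict)
    # structure (optional stage: runs only when a PDB is supplied)
    pdb: str | None = None
    chains: list[str] = field(default_factory=lambda: ["A", "B"])
    map_record: str | None = None
    excise_csis: list[int] = field(default_factory=list)
    probe: float = 1.4
    n_points: int = 960
    dsasa_min: float = 0.1
    hbond_max: float = 3.5
    bridge_max: float = 4.0
    contact_max: float = 4.5
    verbosity: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )

    def csi_params(self) -> csi_detection.CsiParams:
        return csi_detection.CsiParams(
            min_len=self.min_len,
            max_len=self.max_len,
            window=self.window,
            min_conserved=self.min_conserved,
            cons_threshold=self.cons_threshold,
            tol=self.tol,
        )


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_full(cfg: RunConfig) -> dict:
    """Run every applicable stage; returns the output manifest."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    logging.getLogger("csikit").setLevel(cfg.verbosity)
    cfg.to_yaml(out / "effective_config.yaml")
    manifest: dict[str, list[str]] = {"completed": [], "outputs": []}

    def done(stage: str, *paths: Path):
        manifest["completed"].append(stage)
        manifest["outputs"].extend(str(p) for p in paths)
        (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=1))

    # ---- detect ----
    try:
        aln = seqdata.read_alignment(cfg.alignment, cfg.alignment_format)
        groups = seqdata.GroupAssignment.from_tsv(
            cfg.groups, cfg.target_groups
        )
        groups.validate_against(aln)
        calls = csi_detection.detect_csis(aln, groups, cfg.csi_params())
        logger.info("detect: %d CSI(s) called", len(calls))
        table = csi_detection.csis_to_table(calls)
        csis_tsv = out / "csis.tsv"
        table.to_csv(csis_tsv, sep="\t", index=False)
        exc_path = out / "excerpts.txt"
        with open(exc_path, "w") as fh:
            for i, call in enumerate(calls, 1):
                ex = _excerpt_for(aln, groups, call)
                fh.write(f"## CSI {i}\n")
                fh.write(ex.render() if ex else "(no gap-free top record)\n")
                fh.write("\n")
        done("detect", csis_tsv, exc_path)
    except Exception as e:  # noqa: BLE001 - stage boundary
        raise StageError("detect", e) from e

    # ---- phylogenetics ----
    try:
        trimmed, colmap = phylogenetics.filter_blocks(
            aln, cfg.max_gap_fraction, cfg.min_majority, cfg.min_block
        )
        trimmed_path = out / "trimmed.fasta"
        trimmed.to_fasta(trimmed_path)
        tree = phylogenetics.bootstrap_support(
            trimmed, n_reps=cfg.bootstrap_reps, seed=cfg.seed,
            correction=cfg.correction,
        )
        tree_path = out / "gene_tree.nwk"
        phylogenetics.write_newick(tree, tree_path)
        logger.info(
            "phylo: tree on %d taxa, %d bootstrap replicates",
            len(trimmed), cfg.bootstrap_reps,
        )
        outg_label = cfg.outgroup_label or groups.outgroups[0]
        outg = groups.members(outg_label)
        paths = [trimmed_path, tree_path]
        hgt = None
        if cfg.reference:
            ref = phylogenetics.read_newick(cfg.reference)
            g1 = groups.members(cfg.target_groups[0])
            g2 = (
                groups.members(cfg.target_groups[1])
                if len(cfg.target_groups) > 1
                else []
            )
            hgt = phylogenetics.congruence_test(tree, ref, g1, g2, outg)
            hgt_path = out / "hgt.json"
            hgt_path.write_text(json.dumps(dataclasses.asdict(hgt), indent=1))
            paths.append(hgt_path)
        origins_path = out / "origins.json"
        M = phylogenetics.PresenceMatrix.from_csi_calls(aln, calls)
        if calls:
            origins = phylogenetics.dollo_origins(tree, M, outgroup=outg)
            origins_path.write_text(
                json.dumps(
                    {
                        c: {
                            "gain_clade": sorted(origins.gains[c]),
                            "losses": [sorted(l) for l in origins.losses[c]],
                        }
                        for c in origins.gains
                    },
                    indent=1,
                )
            )
            paths.append(origins_path)
            if cfg.donor_subclades:
                recipient = groups.members(cfg.target_groups[0])
                anc = phylogenetics.ancestral_state_vector(
                    tree, M, recipient, outgroup=outg
                )
                subs = {
                    name: phylogenetics.subclade_state_vector(M, taxa)
                    for name, taxa in cfg.donor_subclades.items()
                }
                donor = phylogenetics.donor_inference(anc, subs)
                donor_path = out / "donor.json"
                donor_path.write_text(
                    json.dumps(dataclasses.asdict(donor), indent=1)
                )
                paths.append(donor_path)
        done("phylo", *paths)
    except Exception as e:  # noqa: BLE001
        raise StageError("phylo", e) from e

    # ---- structure (optional) ----
    if cfg.pdb:
        try:
            st = structure.read_structure(cfg.pdb)
            ca, cb = cfg.chains[0], cfg.chains[1]
            rep = structure.interface_report(
                st, ca, cb, probe=cfg.probe, n_points=cfg.n_points,
                dsasa_min=cfg.dsasa_min, hbond_max=cfg.hbond_max,
                bridge_max=cfg.bridge_max, contact_max=cfg.contact_max,
            )
            iface_path = out / "interface.json"
            iface_path.write_text(json.dumps(_iface_json(rep), indent=1))
            paths = [iface_path]
            if cfg.excise_csis and cfg.map_record:
                rec = aln.record(cfg.map_record)
                mapping = structure.map_alignment_to_structure(
                    rec, st.chain(ca)
                )
                ranges = []
                for k in cfg.excise_csis:
                    loc = structure.locate_csi(calls[k - 1], mapping)
                    ranges.extend(loc.ranges)
                delta = structure.interface_delta(
                    st, ranges, ca, cb, probe=cfg.probe,
                    n_points=cfg.n_points, dsasa_min=cfg.dsasa_min,
                    hbond_max=cfg.hbond_max, bridge_max=cfg.bridge_max,
                    contact_max=cfg.contact_max,
                )
                delta_path = out / "interface_delta.json"
                delta_path.write_text(
                    json.dumps(
                        {
                            "excised_ranges": delta.excised_ranges,
                            "before": _iface_json(delta.before),
                            "after": _iface_json(delta.after),
                            "buried_area_loss": delta.buried_area_loss,
                            "contact_loss": delta.contact_loss,
                        },
                        indent=1,
                    )
                )
                paths.append(delta_path)
            done("structure", *paths)
        except Exception as e:  # noqa: BLE001
            raise StageError("structure", e) from e
    return manifest


def _excerpt_for(aln, groups, call):
    """Signature excerpt around a CSI; top record must span it gap-free."""
    lo = max(1, call.start - 15)
    hi = min(aln.ncols, call.end + 15)
    for r in aln.records:
        if "-" not in r.residues[lo - 1:hi]:
            return seqdata.write_signature_excerpt(aln, r.id, (lo, hi), groups)
    return None


def _iface_json(rep: structure.InterfaceReport) -> dict:
    return {
        "params": rep.params,
        "buried_area": rep.buried_area,
        "contacts": rep.contacts,
        "interface_residues": sorted(
            [list(k) for k in rep.interface_residues]
        ),
        "hbonds": [
            [b.chain_a, *b.res_a, b.atom_a, b.chain_b, *b.res_b, b.atom_b,
             round(b.distance, 3)]
            for b in rep.hbonds
        ],
        "salt_bridges": [
            [b.chain_a, *b.res_a, b.atom_a, b.chain_b, *b.res_b, b.atom_b,
             round(b.distance, 3)]
            for b in rep.bridges
        ],
    }
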