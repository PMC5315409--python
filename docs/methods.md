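# Methods

This note records the models, conventions, and design choices behind
`csikit`, and what the synthetic benchmarks do and do not establish.

## CSI model and detection criteria

A conserved signature indel (CSI) is modeled as a contiguous gap-block locus
in a protein multiple sequence alignment: a maximal run of columns in which
at least one sequence carries gaps at every column and at least one carries
residues at every column. Detection is a pipeline of independent criteria,
each reported with its evidence:

* **Flanking conservation.** A locus is retained only if both flanks contain
  at least `min_conserved` conserved columns within `window` columns of the
  block. A column is conserved when its majority residue (computed over
  non-gap, non-`X` symbols) reaches `cons_threshold` of the informative
  symbols. Defaults: `window = 30`, `min_conserved = 5`,
  `cons_threshold = 0.8`. The window/minimum defaults sit at the lenient end
  of common CSI practice (5–6 conserved residues in the neighbouring 30–40);
  the minimum is applied *per side*, the stricter of the two possible
  readings of "flanked on both sides". The conservation cutoff of 0.8 is a
  package choice — "conserved" has no canonical numeric definition — and is
  configurable. Windows truncated by the alignment edge are used as-is and
  flagged `edge-truncated`.
* **Occupancy states.** Within a block, a sequence is `absent` (all gaps),
  `present` (all residues), or `partial`. A partial sequence whose residues
  inside the block are *contiguous* is a genuine length variant (the way a
  2-residue insert sits inside a 3-column locus) and counts toward length
  statistics with its occupied length; a partial sequence with interleaved
  gaps and residues is flagged `fragmented` and excluded from length
  statistics, since its occupancy is more plausibly an alignment artifact.
* **Polarity.** Insertion vs deletion is read from the modal outgroup state:
  outgroups absent ⇒ the targets gained residues (insertion); outgroups
  present ⇒ deletion. A 50/50 outgroup split resolves to insertion with a
  logged warning.
* **Specificity.** The derived state is the modal occupancy of the target
  groups. With zero non-target carriers and no within-target exceptions the
  call is `exclusive` (one target group) or `shared_two_groups` (two);
  with a non-target sharing fraction ≤ `tol` it is `mainly_specific`
  (default `tol = 0.05`, the conventional "≈5 % of unrelated taxa may carry
  a similar indel" allowance); otherwise `non_specific`. The specificity
  screen operates only on the sequences supplied in the alignment — there is
  no database search; a BLAST-style "top N hits" screen is re-expressed as
  this fraction over the supplied non-target records. Within-target
  exception fractions are reported per group, so a CSI carried by "most" of
  a group remains callable and auditable.
* **Nested variants.** Sequences occupying a locus are partitioned by
  occupied length; groups whose members disagree on length are flagged
  `mixed`. Group-level modal lengths break ties toward the smaller length,
  deterministically.

`min_len`/`max_len` default to 1 and 50 columns. All detection output is a
pure function of the alignment, the group table, and the parameters.

## Signature excerpts

Publication-style excerpts print the top sequence in full and every other
sequence with `-` marking identity to the top line. Because source
alignments also use `-` for gaps, excerpts here render source gaps as `.`
so decoding is lossless (a round-trip invariant enforced by property tests);
the figures this format imitates overload `-` and are not losslessly
decodable. The top record must span the excerpt window without gaps.

## Phylogenetics

* **Block filtering.** Before tree building, columns failing a gap-fraction
  or majority-conservation threshold are removed, and only runs of at least
  `min_block` surviving columns are kept (defaults 0.2 / 0.5 / 5) — a simple
  stand-in for the conserved-block trimming tools commonly used upstream of
  tree inference. The trimmed→original column map is returned.
* **Distances and NJ.** Pairwise p-distances use only columns where both
  sequences carry a residue; the Poisson correction is `−ln(1−p)`. Neighbor
  joining is implemented in-package so that tie-breaking (lowest-index pair
  in scan order) and negative-branch clamping (to zero, logged) are
  deterministic and documented; tests cross-check the topology against an
  independent NJ implementation and against the additive-matrix recovery
  guarantee. Likelihood-based tree estimation is deliberately out of scope:
  the questions the pipeline answers (monophyly, incongruence) are
  topological, and an externally estimated tree can be imported as newick.
* **Bootstrap.** Column resampling with replacement, rebuild per replicate,
  support = fraction of replicates containing each original bipartition;
  reproducible under a fixed seed. Default 100 replicates. Replicates with
  undefined distances are skipped with a warning but still count in the
  denominator (support is then conservative).
* **Monophyly and HGT.** Monophyly of a taxon set is evaluated after
  rooting on the user-specified outgroup (no midpoint rooting). The HGT
  incongruence flag is raised iff the union of the two target groups is
  monophyletic in the gene tree but not in the reference tree. This is a
  deliberate one-directional test — it detects a gene uniting lineages the
  organismal phylogeny separates, and does not attempt reconciliation-based
  transfer inference.
* **Dollo origins.** Indel characters are mapped with single-gain/
  multiple-loss parsimony: the gain sits on the branch above the MRCA of all
  carriers; losses are the maximal carrier-free subtrees below it that
  contain at least one determinate absence (missing states demand no
  event). Dollo rather than unordered parsimony is used because an
  identical multi-residue indel arising twice is far less plausible than a
  secondary loss. Tests verify minimality against exhaustive search over
  all gain placements and loss subsets.
* **Donor inference.** The recipient clade's ancestral CSI vector is
  inferred under Dollo (length-aware where same-locus variants exist); a
  candidate donor subclade is compatible iff it matches that vector at every
  informative shared locus. A locus where *no* candidate matches the
  recipient state is set aside as uninformative: a universal mismatch
  indicates the recipient's state postdates the transfer (a later
  modification in the recipient lineage), so the locus cannot discriminate
  among donors. This mirrors the reasoning used for loci where the
  transferred gene was subsequently edited in the recipient.

## Structure stage

* **Input.** PDB files via Biopython; hydrogens and waters dropped;
  alternate locations resolved to the highest occupancy (ties → altloc A);
  van der Waals radii C 1.70, N 1.55, O 1.52, S 1.80 Å, default 1.70 Å with
  a warning for other elements. The input must already contain both chains
  of the complex; no crystallographic-symmetry reconstruction is attempted.
* **SASA.** Shrake–Rupley with a deterministic golden-section spiral
  (default 960 points, probe 1.4 Å); per-atom area is the exposed-point
  fraction times `4π(r+probe)²`; neighbor search is cut off at
  `r_i + r_j + 2·probe`. Accuracy anchors: the isolated-sphere and
  two-sphere spherical-cap closed forms agree within 2 % at 960 points, and
  per-residue sums equal per-atom sums exactly.
* **Interface.** ΔSASA(residue) = SASA in the isolated chain − SASA in the
  complex; interface residues have ΔSASA > 0.1 Ų. Total buried area equals
  `SASA_A + SASA_B − SASA_AB` up to quadrature noise (verified within 1 %).
  Hydrogen bonds use a heavy-atom criterion — donor-capable N/O within
  3.5 Å of acceptor-capable N/O on the other chain, from fixed per-residue
  atom tables — with no angle term, since crystallographic models carry no
  hydrogens. Salt bridges pair Lys NZ / Arg NE,NH1,NH2 / His ND1,NE2
  (histidine treated as potentially protonated) with Asp OD1,OD2 /
  Glu OE1,OE2 / C-terminal OXT within 4.0 Å. Contacts are inter-chain
  heavy-atom pairs within 4.5 Å. Every report echoes its parameters.
* **Sequence→structure mapping.** Global alignment of the ungapped record
  against the chain's one-letter sequence (match +1, mismatch −1, gap open
  −5, extend −1); identity below 0.9 over the aligned region is an error
  (wrong chain). CSIs project to author-numbered residue ranges, with
  partial/unmodeled coverage flagged.
* **Excision.** The CSI-removal analysis deletes the homologous residue
  ranges from both chains and recomputes the interface — pure excision, no
  remodeling or minimization. This replaces irreproducible docking-server
  scoring with a directly testable geometric statement: CSI residues
  provide buried surface and cross-chain contacts, and their removal cannot
  create new surviving-atom contacts (a monotonicity property tested over
  random excisions). Surface-loop localization of CSIs is reported as
  relative SASA against Gly-X-Gly reference maxima rather than by
  secondary-structure assignment.

## Synthetic data: what it emulates, and what it does not

The MSA simulator evolves sequences root-to-leaves with per-branch
substitution probability `1 − e^(−b·rate)` per site, uniform over the 19
alternative residues — a Poisson model chosen because the claims under test
concern indel placement and topology, not rate-matrix realism. Planted
indels are applied on chosen branches and inherited by all descendants;
insertion residues are held identical across the carrying clade, and the
flanking columns of every planted locus are held invariant by masking, so
the flank criterion is met by construction when intended. Same-locus length
variants are planted as nested events (the most specific event wins within
its clade). Standard presets use a 30-taxon, three-group tree (12 + 8 + 10)
with a 360-column root sequence:

* `fig1_like` — a 3-residue insertion shared by both target orders with a
  nested 2-residue variant in one subclade, plus a shared 2-residue
  deletion;
* `fig2_like` — same-locus inserts of length 2 and 3 in the two orders;
* `hgt_like` — a gene alignment whose true tree joins the orders while the
  emitted reference tree separates them;
* `clean_negative` — no planted events.

The toy dimer is two idealized extended chains at 12 Å background
separation whose designed residues carry protruding stalks meeting at the
designed distances (contact loop: carbon tips; hydrogen bond: Asn
OD1↔ND2; salt bridge: Arg NH1↔Asp OD1). Designed salt-bridge distances are
constrained to (3.5, 4.0] Å so they cannot double as hydrogen bonds under
the default cutoffs, keeping the designed truth unambiguous.

**Limitations.** Passing these benchmarks shows the machinery is correct on
data satisfying its assumptions; it does not certify performance on real
alignments, where alignment error, fragmentary sequences, compositional
heterogeneity, and non-contiguous indel placement can violate the planted
structure. The toy dimer validates geometry, not biophysics: no packing,
electrostatics, or conformational response to excision is modeled. Residue
calls on real crystal structures additionally depend on the thresholds
chosen here, which need not reproduce any particular interface server's
residue lists.

## Numerical and reproducibility choices

Seeds are mandatory for every stochastic component (simulation, bootstrap,
toy-dimer filler residues), and identical configurations produce
byte-identical outputs. Majority tie-breaks are alphabetical; NJ tie-breaks
are lowest-index; modal-length tie-breaks favor the smaller length; all are
platform-independent. Internal column coordinates are 0-based half-open;
everything user-facing is 1-based inclusive, matching residue-numbering
conventions (e.g. "F567–N569"). The acceptance script scales its problem
sizes to run in seconds (20 negative-control seeds, 20 random 8–12-leaf
trees, 15 Dollo cases on 5–10-leaf trees, 100 random excisions), sizes at
which the brute-force oracles remain exact.
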