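# Methods

## Scope and model

`contactprof` profiles noncovalent interactions between one small-molecule
ligand and a macromolecular receptor over an MD trajectory supplied as PDB
frames, and computes the standard binding-stability metrics. The receptor is
the union of protein and DNA; waters can only mediate bridges and ions are
ignored as interaction partners. Detection is purely geometric: no force
field, partial charges or pKa model is involved, which mirrors the
rule-based interaction profilers used in practice.

## Input handling

Frames come from one multi-model PDB file (MODEL order) or a directory of
per-frame PDBs (lexicographic order). Parsing is backed by gemmi; columns
follow wwPDB v3.3, both ATOM and HETATM are accepted, altLoc 'A'/blank is
kept and others dropped, and elements come from columns 77–78 with
name-based inference when blank. Residue identity is
(chain, res_seq, icode) with numbering taken verbatim from the file
(DA113 means res_seq 113). Every frame must present the identical
(name, res_name, res_seq, chain) sequence; the first deviation is a hard
error naming frame and atom. Times are `index × stride_ps` with
`stride_ps = 10 ps` by default, the usual save interval of long production
runs. Binary trajectory formats and mmCIF are out of scope.

Because extracted PDB frames carry no connectivity, covalent bonds are
inferred: two heavy atoms of one residue bond when their distance is at most
the sum of Cordero covalent radii + 0.45 Å; between residues only the
peptide C–N and nucleic O3'–P links are eligible (same distance rule), so
spurious ligand–receptor "covalent" edges cannot arise; each hydrogen bonds
to its nearest in-range heavy atom only. An isolated heavy atom or a
detached hydrogen is a warning, not an error.

## Perception rules

* **Hydrophobic atoms**: carbons whose bonded neighbours are all C or H.
* **Donors**: N/O (and S–H by default) carrying ≥ 1 explicit hydrogen.
* **Acceptors**: O with ≤ 1 heavy neighbour (hydroxyl, carbonyl,
  carboxylate, water) and N with ≤ 2 heavy neighbours; bridging ether/ester
  oxygens and amide-like/quaternary nitrogens are excluded. Sulfur is not
  an acceptor unless enabled in the config.
* **Rings**: template atom sets for Phe/Tyr/Trp/His and the purine /
  pyrimidine rings of DA/DG/DC/DT; for the ligand, 5/6-membered C/N/O/S
  cycles (cycle basis of the ligand bond graph) whose best-fit-plane RMS is
  ≤ 0.25 Å. Ring center, SVD plane normal and planarity RMS are stored.
* **Charge centers**: Arg guanidinium (CZ, NH1, NH2, NE) and Lys NZ are
  positive; His counts as positive only when both ring nitrogens carry
  hydrogens (a deterministic, testable protonation rule — a neutral His
  ring still counts as aromatic); Asp/Glu carboxylates, C-terminal
  carboxylates and DNA phosphates (P, OP1, OP2) are negative. Ligand
  charges are conservative pattern matches (carboxylate by default,
  ammonium optional). The basic side chains are modelled as their
  nitrogenous cationic groups (guanidinium/imidazolium/ammonium).

## Detection criteria (defaults, all config-overridable)

| class        | rule |
|--------------|------|
| hydrogen bond | d(D···A) ≤ 4.1 Å and best ∠(D–H···A) ≥ 100° |
| hydrophobic  | shortest ligand-atom↔residue pair distance ≤ 4.0 Å (one record per pair) |
| π-stacking   | center distance ≤ 5.5 Å; normal–normal angle ≤ 30° (parallel) or 60–90° (T-shaped); in-plane offset of projected centers ≤ 2.0 Å (minimum over both ring planes) |
| salt bridge  | opposite-sign centroid distance ≤ 5.5 Å |
| water bridge | both heavy-atom legs within 2.5–4.1 Å, each leg H-bond-compatible (donor angle ≥ 100° on whichever side donates), water-centered angle 75–140° |

The motivating study reports only that geometric angle/distance criteria
were applied, not the numbers; these defaults follow the published defaults
of the reference profiler family and are exposed in the config so a user
can match any specific version.

**No-hydrogen fallback.** If no polar atom in the structure carries a
hydrogen (typical for crystal inputs), donors cannot be oriented: the angle
gate is waived, the distance gate tightens to 3.5 Å, protonatable N/O act
as donor candidates, and each polar–polar pair yields at most one record
flagged `no-h-fallback`. This keeps crystal-structure worked examples
usable while MD frames (which carry hydrogens) always use the angle test.

**Filtering.** Hydrogen bonds whose donor and acceptor atoms belong to a
detected salt bridge between the same residue pair are dropped, as are
hydrophobic contacts whose two atoms both lie in π-stacked rings; at most
one hydrogen bond survives per (donor, acceptor) pair. Surviving records are
ordered by (type, chain, residue, atom names) so outputs are byte-stable.

Distances use no periodic-boundary imaging; frames are assumed whole and
imaged upstream. Candidate pairs come from k-d trees; an intentionally
naive all-pairs implementation of the same criteria
(`contactprof.bruteforce`) is kept as an independent oracle and is asserted
record-for-record equal in the tests and in the acceptance run.

## Ledger and persistence semantics

Records accumulate into a map key → sorted frame list. Keys are
`type|ligand-atoms|residue|receptor-atom`; hydrogen bonds and water bridges
keep the receptor atom (atom-tuple identification), hydrophobic, π-stacking
and salt-bridge keys are residue-level because their closest receptor atom
legitimately varies frame to frame. Water identity is never part of a key:
waters exchange, and identity-free keys are what make bridge persistence
well-defined.

* **Per type** (one decimal): percentage of frames containing ≥ 1
  interaction of the class — the only reading under which a ligand can
  simultaneously show ~100% hydrogen bonding and ~98% hydrophobic contact.
* **Per (ligand atom, residue)** (nearest integer, ties away from zero):
  union over interaction types and receptor atoms, because such tables mix
  hydrogen-bond partners and hydrophobic partners for one atom. Multi-atom
  ligand groups (ring, carboxylate) attribute their occupancy to each
  member atom. Rows under `min_percent` (default 10, the smallest value
  such tables usually print) are omitted.
* **Per atom per type**: the ligand-atom × class occupancy matrix behind
  "which atom does what" plots; all-zero rows are dropped.
* **Durations**: maximal consecutive-frame runs per key; run lengths sum to
  the frames present.

## Stability metrics

Superposition is the Kabsch least-squares fit (via
`scipy.spatial.transform.Rotation.align_vectors`; proper rotation
guaranteed, exact identity short-circuit when mobile equals reference so a
static series is identically zero). RMSD series fit every frame on the fit
mask — receptor Cα when ≥ 3 are present, receptor heavy atoms otherwise —
then measure over the selection; the ligand and its moieties are therefore
measured *within the pocket*, which is the reading that lets moiety series
be compared meaningfully. The reference is frame 0 by default
(configurable). RMSF fits frames to frame 0, forms the mean structure,
re-fits once to that mean and reports per-atom fluctuations. Values are
reported in nm (converted from Å at the boundary); moiety masks are
user-supplied ligand atom-name lists; RMSD is unweighted (no mass
weighting).

## Synthetic data: what it emulates and what it does not

`make_toy_complex` builds a ≤ 150-atom complex: Arg/Lys/Tyr/Asp side-chain
groups, one adenine nucleotide with phosphate and one thymine, eight
waters, a sodium ion, and a ligand with hydroxyls, an ester carbonyl, a
carboxylate, a phenyl ring and an aliphatic tail. Six interactions — two
hydrogen bonds (ester O6←Arg364, hydroxyl O1→Tyr426), a water bridge
(O2–water–Asp533), a π-stack (phenyl on the DA113 six-ring), a hydrophobic
contact (C13 to the DT9 methyl) and a salt bridge (carboxylate–Lys425) —
sit at stations ~16 Å apart. Bound geometry satisfies its criterion with
≥ 0.3 Å / ≥ 15° to spare; "broken" geometry displaces only the mobile
fragment of that one interaction and violates the tested criterion by at
least the same margin, so floating-point noise (including the 3-decimal
PDB round trip) can never flip a detection: recovery of a planted schedule
is exact, not statistical. `validate_independence` toggles every
interaction alone in both directions and asserts that exactly its key
appears/disappears. The default schedule plants occupancy fractions
{1.00, 0.98, 0.93, 0.778, 0.56, 0.10} over 1000 frames — the magnitudes a
real long-trajectory persistence table spans, from essentially permanent
contacts down to the relevance threshold; frame sets are drawn without
replacement by a seeded generator, `round(fraction × n_frames)` frames per
key.

The ligand's functional groups share one residue but are deliberately not
covalently linked to each other, and nothing here is energetically
plausible — the generator's purpose is exact planted ground truth, an
explicit non-goal being physical realism. Consequently, passing the
recovery tests demonstrates correctness of perception, geometry, filtering
and bookkeeping under controlled conditions; it does not demonstrate
agreement with any particular profiler version on crowded, thermally
distorted real frames, where borderline geometries near the cutoffs
dominate the differences between tools.

`make_crystal_site_synthetic` is a constructed stand-in (named and
documented as such) for the camptothecin ternary-complex binding site: a
hydrogen-free CPT-like lactone/hydroxyl fragment with the two published
contact distances — 2.9 Å to the Arg364 guanidinium and 3.4 Å to the
Asp533 carboxylate — built into its geometry. It exercises the
no-hydrogen fallback path end to end; since the distances are inputs, the
check validates the profiling machinery, not the crystallography.

`make_jitter_trajectory` applies an optional rigid transform per frame plus
i.i.d. Gaussian atomic noise, giving closed-form expectations (fitted rigid
motion → RMSD 0; one jittered atom → RMSF → σ√3).

## Numerical and design choices

* Tie-breaks everywhere are lexicographic on (chain, res_seq, atom name);
  floats are written with fixed formats; JSON keys are sorted — two
  identical runs produce byte-identical CSV/JSON.
* Rounding: per-type one decimal, per-pair nearest integer, both ties away
  from zero; the `min_percent` filter applies to the exact value before
  rounding (9.6% is omitted at a 10% threshold).
* The Kabsch fit needs ≥ 3 fit atoms; RMSF needs ≥ 2 frames; zero-frame
  ledgers and empty measure masks are errors, empty record lists are not.
* Seeds: every stochastic operation takes an explicit seed and uses
  numpy `default_rng` with derived stream keys; nothing reads global state.
* Problem sizes used by the test and acceptance runs — 1000-frame recovery,
  50 oracle frames, 10,000-frame RMSF sampling — were chosen as the
  smallest sizes at which the statistical checks are meaningful for this
  package's validation design.

## Known limitations

* No periodic-boundary imaging, no halogen bonds, cation–π or metal
  coordination; no pKa or partial-charge model (His protonation is read
  from explicit hydrogens).
* Ligand ring perception uses a cycle basis, which is sufficient for
  isolated and simple fused rings but does not enumerate every ring of a
  complex fused polycycle.
* Persistence semantics (any-type union per pair) are one defensible
  reading of the usual table format; the per-atom-per-type matrix is
  provided so the per-type decomposition is always available.
* The crystal worked example runs on constructed geometry, not a
  downloaded crystal structure; point `profile-frame` at a real PDB file
  to profile actual crystallographic sites.
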