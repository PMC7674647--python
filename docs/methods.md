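# Methods

## Scope and model

The package analyzes (p)ppGpp nucleotides — guanosine 3′,5′-bis(diphosphate)
(ppGpp, PDB chemical component `G4P`) and its 5′-triphosphate homolog
(pppGpp, `C1Z`/`0O2`) — in isolation and in complex with proteins. Two
layers of description are implemented.

### Nucleotide conformation

A furanose ring's conformation is captured by the Altona–Sundaralingam
pseudorotation model. From the five endocyclic torsions ν₀ (C4′-O4′-C1′-C2′)
through ν₄ (C3′-C4′-O4′-C1′):

    tan P = [(ν₄ + ν₁) − (ν₃ + ν₀)] / [2 ν₂ (sin 36° + sin 72°)]
    ν_max = ν₂ / cos P

with 180° added to P when ν₂ < 0, then P wrapped to [0°, 360°). The ten
pucker classes are 36° bins of P starting with C3′-endo at [0°, 36°), in
order C4′-exo, O4′-endo, C1′-exo, C2′-endo, C3′-exo, C4′-endo, O4′-exo,
C1′-endo, C2′-exo; bins are half-open [lo, hi). The hemisphere label follows
the standard convention: north for P ∈ [270°, 360°) ∪ [0°, 90°), south
otherwise. Near P = 90°/270° the divisor cos P vanishes; there ν_max is
recovered by a least-squares fit of the ideal cosine model
ν_j = ν_max·cos(P + 144°(j − 2)), and the quadrant is chosen by the sign of
the numerator. An all-zero torsion set (planar ring) is rejected.

The glycosidic state is *anti* iff χ mod 360° ∈ [90°, 270°), otherwise
*syn*; the boundaries are assigned so that exactly 90° is anti and exactly
270° is syn. Torsion angles follow the IUPAC sign convention (clockwise
positive looking down the central bond) and live in (−180°, 180°]. Note the
torsion angle is invariant under reversal of the atom order — dihedral(p₁…p₄)
equals dihedral(p₄…p₁) — and is negated by mirror reflection; the property
tests assert both.

### Interaction fingerprinting

Contacts are typed between a ligand and every non-ligand atom within a 5 Å
radial cutoff. Geometric criteria, all overridable through
`InteractionCriteria` / a YAML config:

| category     | rule (defaults) |
|--------------|-----------------|
| hbond        | donor–acceptor pair, D···A 2.8–3.5 Å, donor angle 120–180° |
| weak_hbond   | D···A < 2.8 Å **and** donor angle < 120° |
| polar        | donor–acceptor pair ≤ 3.5 Å, no angle test, not already an hbond |
| weak_polar   | donor–acceptor pair in (3.5, 4.0] Å |
| ionic        | cationic–anionic pair ≤ 4.0 Å |
| metal        | metal to ligand N/O ≤ 3.0 Å; protein N/O partners of the same metal reported as a bridge |
| aromatic     | ring-centroid distance ≤ 4.5 Å; inter-normal angle ≤ 30° parallel, ≥ 60° T-shaped, else inclined |
| vdw          | distance ≤ r_A + r_B + 0.1 Å (Bondi radii) |
| vdw_clash    | distance < r_A + r_B − 0.4 Å |

Only the hydrogen-bond windows and the 5 Å cutoff are fixed by the protocol
being reproduced; the ionic, metal, aromatic and polar cutoffs follow common
structural-database (CREDO/Arpeggio-style) conventions and are explicit
configuration. The weak-hydrogen-bond definition is the conjunctive one
(short **and** bent); a short pair with a good angle is not discarded but
falls through to the polar category. Whether the protocol measured the
angle at the hydrogen or at the donor is not derivable from its description;
crystal structures mostly lack hydrogens, so the default is the
**antecedent proxy**: the angle X-D···A maximized over the donor's heavy
covalent neighbors X. When explicit hydrogens are present the D-H···A angle
at the hydrogen is used instead, and a donor with no resolvable antecedent
(e.g. water oxygen) is classified on distance alone.

Double counting is resolved hierarchically so the nine per-category counts
partition the contact list exactly: metal coordination is assigned first;
cation–anion pairs within the ionic cutoff are ionic only; remaining
donor–acceptor pairs go to hbond > weak_hbond > polar > weak_polar; van der
Waals contacts are then computed between atoms **not** engaged in a
hydrogen bond (the fingerprint excludes both partners of every
hbond/weak_hbond from vdW pairing, matching the definition of vdW contacts
as interactions between non-hydrogen-bonding atoms). Water-mediated bridges
(a water hydrogen-bonded to ligand and protein simultaneously) are reported
in a separate list and never enter the nine marginals. Clash detection is
implemented and included in the nine counts by default; the aggregation
layer works from the contact list, so a consumer can drop any category.

### Atom typing

Typing is a pure function of (residue name, atom name, element), backed by a
bundled template table (`data/residue_templates.tsv`): donors, acceptors,
aromatic ring members, cationic (Arg NE/NH1/NH2, Lys NZ), anionic
(Asp/Glu carboxylates, terminal phosphate oxygens), metals (Mg, Mn, Zn, Na,
K, Ca) and hydrophobic carbons. Unknown residues fall back to an element
heuristic (N/O → donor+acceptor) with a logged warning. One census
convention is deliberate: all five guanine nitrogens — including the
glycosylated N9 — are flagged hydrogen-bond capable, so a complete ppGpp
ligand counts 5 N and 17 O hydrogen-bonding atoms (20 O for pppGpp). This
matches the published census of the ligand's polar atoms; functionally N9
of the intact nucleotide cannot donate, and the flag matters only for the
census, never for contact detection at N9 (which has no hydrogen and a
near-planar environment).

## Synthetic data: what it emulates and what it does not

The generator produces the study conditions end-to-end:

* **Ligands** at prescribed (P, ν_max, χ, γ). The ribose ring is built by
  solving the inverse pseudorotation problem: a planar pentagon with an
  out-of-plane displacement wave is refined by least squares against the
  ideal torsions ν_j = ν_max·cos(P + 144°(j−2)) with bond-length targets
  (C-C 1.525–1.527 Å, C-O 1.415–1.452 Å) and soft ring-angle restraints.
  The measured pucker of the result is within 2° of the request (declared
  tolerance, checked at build time). The guanine base is an idealized
  planar fused pentagon/hexagon (uniform 1.38 Å sides) mapped rigidly onto
  the sp² N9 frame so that χ is honoured to 0.5°; phosphate chains are
  placed from ideal internal coordinates (P-O ester 1.60–1.61 Å, terminal
  1.48 Å) with torsions chosen once to be clash-free across the published
  conformer range. Geometry targets are recorded in each PDB header.
* **Binding sites** with one planted partner fragment per interaction
  category. Planted geometries sit strictly inside their windows
  (≥ 0.1 Å / 5° margins) and placement directions are optimized
  deterministically so that no *unplanned* ligand–environment pair falls
  inside any category window; a margin audit runs at build time and raises
  on violation. Decoy atoms are placed beyond the environment cutoff.
* **χ ensembles** from a two-component von Mises mixture (syn center 45°,
  anti center −135°, κ = 12, syn fraction 0.7 by default — a sharply
  bimodal, mostly-syn free-nucleotide distribution as enhanced-sampling
  simulations of free (p)ppGpp report). With κ = 12 the leakage of a mode
  across the syn/anti boundary is ≈ 0.3%, so classification recovers the
  mixture weight to well within the ±2% acceptance band at n = 10000.
* **An annotated corpus** whose class recipes encode published signatures:
  synthetases and nucleotide-metabolic enzymes get tyrosine stacking,
  arginine salt bridges and Mg²⁺; GTPases get hydrogen bonds/vdW only (no
  stacking, no metals, no guanidinium); RNA polymerase engages the
  phosphates with basic residues and Mg²⁺. Ligand conformers per class
  follow the published bound conformers (C3′-endo for synthetase-bound,
  C2′-endo elsewhere, syn for the nucleotide-metabolic class) with ±4°
  jitter.

What passing these tests shows: the detectors implement their geometric
definitions exactly (brute-force all-pairs equivalence), the
generator/analyzer pair is adjoint (every planted truth is recovered), and
aggregation conserves counts. What it does not show: performance on real
crystal structures, which add missing atoms, alternate conformations beyond
the altloc policy, protonation ambiguity, crystallographic water networks
and genuinely ambiguous borderline geometry; and the synthetic sites are
sparse fragments, not packed binding pockets, so absolute contact counts are
not comparable to real complexes. Ensemble descriptors are validated on
closed-form cases (isolated-sphere SASA, two-point radius of gyration,
alternating-displacement RMSF), not against any simulation engine's
magnitudes.

## Numerical choices

* PDB parsing is delegated to gemmi with a validation pre-pass so malformed
  coordinate fields fail loudly with a line number. Alternate locations
  collapse to the highest occupancy, ties to altloc `A`. Hydrogens are used
  when present, never required. Incomplete ligands are returned flagged,
  not dropped (low-resolution entries remain analyzable).
* SASA uses Shrake–Rupley sampling with a fixed golden-section-spiral point
  set (default 960 points), so results are deterministic; the isolated-atom
  error at 960 points is below 1%.
* RMSF is computed on the supplied coordinates without superposition by
  default (ligand-only trajectories are typically pre-centered); an optional
  flag superposes every frame on frame 0 first. Kabsch superposition
  guarantees a proper rotation (det = +1) and refuses fewer than three or
  collinear points.
* Covalent bonds, where needed (antecedent search, intramolecular H-bond
  exclusion of pairs separated by fewer than three bonds), are inferred from
  distance (≤ 1.85 Å, ≤ 1.95 Å when P or S is involved).
* The torsion histogram uses left-open/right-closed bins covering
  (−180°, 180°], so percentages sum to exactly 100.
* All randomness flows through `numpy.random.default_rng` seeds; corpus
  generation spawns child seeds with `SeedSequence`, and PDB output is
  byte-identical for a fixed seed.

## Design decisions taken where the protocol is silent

* Ligand-code matching is case-insensitive (`0o2` ≡ `0O2`).
* Copies: every ligand copy in a model is extracted and fingerprinted
  per-copy; aggregation decides whether to merge.
* Counts are raw occurrences; a per-complex-normalized mode exists because
  real corpora mix class sizes (e.g. eight RNA polymerase entries against
  three synthetases). Riboswitch complexes (RNA receptors) carry their own
  class label and are excluded from protein-class profiles by default.
* The bundled class map covers the 38 published complexes; corpus
  membership is configuration (an editable TSV), not code.
* The package reports the convention-derived hemisphere for every conformer
  even where published prose describes south-phase rings as "north"; the
  numbers (P, ν_max) and the pucker class are the authoritative output.
* A rotatable-bond count is not pinned to any published bond tally, since
  no counting convention is stated with it.

## Known limitations

* No mmCIF, crystallographic symmetry, assemblies or PDB fetching; the
  multi-model PDB is the only ensemble format.
* The idealized guanine template has uniform ring bonds (1.38 Å); fine
  base-geometry effects (propeller, exocyclic angle asymmetry) are absent.
* The weak-hydrogen-bond class excludes C-H donors; only template donors
  count.
* Aromatic detection considers guanine and Phe/Tyr/Trp/His side-chain rings
  only (no cation-π, no backbone amide stacking).
* Descriptor operations (RMSF/rGyr/SASA/intraHB) are analysis-side only:
  the package neither runs nor re-weights molecular dynamics.
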