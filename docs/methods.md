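# Methods

## The geometric model

`kjunction` treats double-helical RNA as a set of rigid *helix
segments*. A segment is any two base pairs that stack (pair-midpoint
separation ≤ 5.5 Å, inter-pair twist within 10–60°; the pairs need not
be sequence-adjacent, so stacking across a strand exchange — the
situation at a three-way junction — is allowed). Each segment is
abstracted to four vectors:

1. an **origin** at the C1′–C1′ midpoint of its first pair,
2. a unit **axis** from that midpoint to the second pair's midpoint,
3. an **hbond direction**, the first pair's C1′(strand 1) → C1′(strand 2)
   vector projected perpendicular to the axis,
4. a **normal** completing the right-handed orthonormal triad.

The pose of one segment expressed in another's frame — a translation in
the reference triad's coordinates plus a proper rotation — is invariant
under any global rigid motion of the structure. A *search pattern* is a
set of such reference transforms (canonical-helix segment → noncanonical-
helix segment, measured on known kink-turn structures) with a
translation tolerance (default 4 Å) and a rotation tolerance (default
25°, angle of the composed rotation). Scanning tests every ordered
segment pair in all four strand orientations against every entry;
overlapping raw matches (sharing a base pair on both sides) are merged
into one reported hit.

### Base-pair detection

Watson–Crick pairs (A-U, G-C) and the G•U wobble are detected from
geometry alone: complementary bases, C1′–C1′ distance 8.9–11.9 Å, at
least two canonical donor–acceptor contacts within 2.4–3.5 Å (both
wobble contacts for G•U — the lower bound rejects steric clashes
masquerading as bonds), base-plane normals within 65°. Conflicts are
resolved greedily by summed hydrogen-bond quality, one pair per
nucleotide. All thresholds live in one config object.

### A screw-motion degeneracy worth knowing about

Re-anchoring a segment one base-pair step along its own helix is a
screw motion (≈32.7° twist + 2.81 Å rise about that helix's axis).
Consequently, two relative transforms that differ by a rotation about
either helix axis can describe the *same* pair of helices at shifted
anchors, and the scan will legitimately match either form. The quantity
invariant across all anchor shifts and flips is the inter-axis angle
(modulo the 0/180° flip ambiguity), exposed as
`search.interaxis_angle_deg`. Tests that need guaranteed negatives
sample transforms whose inter-axis angle is at least twice the rotation
tolerance away from the pattern's.

### The shipped pattern

`data/kturn_pattern_synthetic.json` is a synthetic canonical kink
geometry (rotation vector (30, 15, 115)° in the axis/hbond/normal
triad, translation (7, 3, 2) Å), chosen to approximate the tight
~60° included inter-axis angle of the kink-turn while avoiding the
helix-reversal self-symmetry that a pure rotation about the normal
would have. It exists so scanning works offline; patterns measured on
real reference structures are built with `pattern_from_reference` (or
the `pattern` subcommand) and are the recommended route for real
searches.

## Annotation

Role labels follow the standard kink-turn nomenclature (−2b…−1b, loop
L1/L1.1/L2/L3, 1b•1n, 2b•2n, …), assigned by 3D position rather than
sequence so that insertions between 1b and 2b are tolerated. The
heuristic looks for non-WC purine•purine pairs near the NC-segment end
facing the C segment (loose criteria: C1′–C1′ 8.5–13 Å, ≥1 base-edge
N/O contact ≤ 3.5 Å, near-parallel planes); an explicit role map always
wins, and failures produce a diagnostic listing the candidates
considered. The standard contact table (L1 O2′→1n N1/N3, −1n O2′→2b
N1/N3, 2b N6↔2n N3/N7, −2n O2′↔3b O2′, L3 O2′→loop phosphate pro-S
oxygen) is always reported in full, with absent atoms flagged rather
than dropped. Distances ≤ 3.5 Å are labelled "bonded", 3.5–4.0 Å
"borderline". The N1/N3 class is whichever of 2b N1/N3 is nearer the
−1n O2′ donor.

Superposition is a direct SVD Kabsch (proper rotation enforced by sign
correction; RMSD evaluated on the transformed coordinates, which keeps
the self-superposition at machine zero). Two named atom sets are
offered: `backbone` (phosphate + full ribose, 11 atoms) and `trace`
(phosphate + sugar trace, 6 atoms), since published core RMSDs depend
on that choice.

## ITC one-site model

The standard Wiseman/ORIGIN single-site isotherm: bound complex from
the mass-action quadratic, cumulative heat `Q = V0·ΔH·[XM]`,
per-injection heats as differences with the displaced-volume correction
`ΔQᵢ = Qᵢ − Qᵢ₋₁ + (vᵢ/V0)(Qᵢ + Qᵢ₋₁)/2`, and matching second-order
dilution bookkeeping for the total concentrations. The correction terms
do not telescope, so exact heat conservation
(`ΣΔQ = V0·ΔH·[bound]_final`) holds with the correction disabled —
which is how the conservation test runs it.

Default protocol: 1 µL initial injection then 29 × 8 µL of 150 µM
ligand into 1.4 mL of 15 µM RNA at 303.15 K. The injection count is not
part of the published protocol text; 29 brings the final molar ratio to
≈1.8, past saturation at these conditions (Wiseman c ≈ 65), which is
what a practitioner would run.

Fitting is unweighted nonlinear least squares over (ln n, ΔH, ln Ka)
(log-parametrisation enforces positivity), initialised at n = 1,
ΔH = first large heat per mole injected, Ka = 1/[cell]; the 1 µL
initial injection is excluded by default. Non-convergence and all-zero
data return flagged results, not exceptions. Standard errors come from
the Jacobian at the optimum.

Energies carry a declared unit label and are never silently converted.
`audit_gibbs_helmholtz` checks ΔG = ΔH − TΔS for the published E. coli
TPP riboswitch variant table (all six rows agree within 0.006 kJ/mol)
and also reports −RT·ln Ka, which matches the tabulated ΔG magnitudes
only on a kcal scale (−9.21 vs −9.20 for the natural sequence) — an
internal inconsistency of the published unit headers that the audit
exposes and deliberately does not resolve.

## Alignment statistics

Per-column composition and the sequence-logo information content
IC = 2 + Σ f·log₂f (bits) over gap-excluded frequencies; T is
normalised to U and IUPAC ambiguity codes count as gaps (simplest
defensible choice, flagged in output). Joint tables at two columns run
over co-ungapped sequences, so their marginals equal the column
statistics restricted to that subset — an exact identity, tested. No
small-sample correction by default (intended for family alignments with
thousands of sequences). Gap fractions are reported separately so both
raw and gap-excluded percentages are recoverable.

## Synthetic fixtures

`fixtures` builds regular duplexes from idealized ribonucleotide
templates (biotite's bundled chemical component dictionary). The two
bases of each pair are posed against each other by a small
deterministic least-squares refinement driving the canonical
donor–acceptor distances to standard values (2.8–3.0 Å) with the base
planes antiparallel (parallel for the trans sugar•Hoogsteen G•A pair,
which can be grafted into a duplex to exercise annotation). Pairs stack
with rise 2.81 Å and twist 32.7°/bp about +z with the C1′ midpoint *on*
the axis — that last choice is deliberately non-physical (real A-form
keeps C1′ midpoints ~7–8 Å off-axis) because it makes the segment-frame
axis exactly the construction axis, which is what the geometric tests
need. Fixture helices are therefore geometrically ideal but not
chemically refined: per-residue geometry is correct, pairing and
stacking are regular, but inter-residue backbone connectivity is not
energy-minimised and planted two-helix scenes may interpenetrate (a
clash flag is returned). Passing tests on these scenes validates the
*geometry pipeline* — detection thresholds, frames, transform algebra,
scanning, superposition — not the chemical realism of any particular
kink-turn; conclusions about real structures require real coordinate
files, for which `scripts/validate_with_pdb.py` runs the identical
pipeline and prints the published core distances alongside the measured
ones.

## Numerical choices and limitations

* Tolerances and thresholds are config values, not constants; defaults
  are listed above and in `config.py`.
* Degenerate frames (pair origins < 0.5 Å apart, C1′ vector within 1°
  of the axis) raise a dedicated error rather than returning garbage.
* Hit deduplication is union-find over base-pair sharing; deterministic
  ordering by combined deviation (translation + rotation/10).
* Alternate locations resolve to highest occupancy (ties → label 'A');
  only the first model of multi-model files is read; unknown residues
  drop with a warning during RNA filtering; completeness exempts the
  5′ phosphate of chain-start residues and OP3 always.
* Problem sizes in the test suite and acceptance script (12-bp helices,
  50 planted scenes, 200 random poses, 100 noise seeds) were chosen as
  the smallest sizes at which the studied effects are unambiguous.
* The role-assignment heuristic is validated offline only on grafted
  G•A scenes and failure diagnostics; complex topologies (S-turn
  "out-of-sequence" strands) need explicit role overrides by design.
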