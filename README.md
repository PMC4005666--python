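# kjunction

Geometric search and annotation of **kink-turn (k-turn) and k-junction
motifs** in RNA 3D structures, plus one-site isothermal titration
calorimetry (ITC) analysis and structure-guided alignment conservation
statistics.

The k-turn is a widespread RNA motif: a tight kink between a canonical
(C) helix and a non-canonical (NC) helix carrying tandem G•A/A•G pairs,
stabilised by two conserved cross-strand hydrogen bonds (L1 O2′ → A1n,
−1n O2′ → A2b N1 or N3, defining the N1/N3 classes). A *k-junction* is
a three-way helical junction built on the same architecture, with a
third (T) helix coaxially stacked on the C helix — the core of the TPP
riboswitch ligand pocket. Because such motifs are assigned by 3D
position rather than sequence, they are easy to miss by sequence
analysis; this package finds them geometrically.

## What it computes

* **Helix-segment frames.** Every stacked pair of detected Watson–Crick
  / G•U wobble base pairs becomes a rigid frame: origin **o** at the
  first pair's C1′–C1′ midpoint and a right-handed orthonormal triad
  (helix axis **a**, in-plane hydrogen-bond direction **h** ⊥ **a**,
  normal **n** = **a** × **h**).
* **Motif scanning.** The pose of an NC-helix segment in a C-helix
  segment's frame, (**t**, **R**) with **t** = Rᵣₑfᵀ(o_NC − o_C) and
  **R** = RᵣₑfᵀR_NC, is rigid-motion invariant. A search pattern is a
  set of reference transforms with tolerances (defaults 4 Å, 25°);
  matches are deduplicated and scored by deviation.
* **Annotation.** Standard role nomenclature (−1b/−1n, L1–L3, 1b•1n,
  2b•2n, …), the canonical core contact table, N1-vs-N3 classification
  (whichever of 2b N1/N3 is nearer the −1n O2′), and Kabsch
  superposition RMSD over chosen roles and backbone atom sets.
* **ITC.** The single-site (Wiseman) isotherm: simulation with the
  displaced-volume bookkeeping, nonlinear least-squares fitting of
  (n, ΔH, K_a), and the thermodynamic audit ΔG = ΔH − TΔS vs
  −RT ln K_a.
* **Alignment statistics.** Per-column base frequencies and sequence-
  logo information content (2 + Σ f log₂ f bits), and joint
  base-combination tables at designated role columns (e.g. 1b•1n).
* **Fixtures.** Deterministic ideal A-form duplexes and two-helix
  scenes planted at prescribed relative transforms, so the entire
  pipeline is testable offline.

## Worked example

Plant a two-helix scene at the shipped kink geometry and scan it:

```sh
$ kjunction fixtures scene --anchor-a 5 --anchor-b 5 --out scene.pdb
scene -> scene.pdb (clash warning)
$ kjunction scan scene.pdb --out hits.csv
1 hit(s) -> hits.csv
$ cat hits.csv
hit,c_segment,nc_segment,translation_dev_A,rotation_dev_deg,matched_entry
0,A6+A7+B6+B7,C6+C7+D6+D7,0.0,0.006,0
```

One deduplicated hit: the segment built on pairs A6•B7/A7•B6 (the
planted anchor of helix 1) matches the NC segment of helix 2 with zero
translation deviation and 0.006° rotation deviation (the residual is
PDB coordinate rounding). A straight duplex scanned the same way
returns no hits.

Simulate and refit a TPP-riboswitch-like titration (n = 1.07,
ΔH = −18.29 kJ/mol, K_d = 0.23 µM; 1 µL + 29 × 8 µL of 150 µM ligand
into 1.4 mL of 15 µM RNA at 303.15 K):

```sh
$ echo '{"n": 1.07, "dH": -18.29, "Kd_uM": 0.23}' > params.json
$ kjunction itc-sim --params params.json --out heats.csv
30 injections -> heats.csv
$ kjunction itc-fit heats.csv --out fit.json
n=1.070 dH=-18.29 Kd=0.230 uM -> fit.json
```

The fit recovers all three parameters of the noiseless simulation to
machine precision (`fit.json` also reports standard errors, the
convergence flag, and ΔG/ΔS derived from K_a). With 1 % Gaussian noise
the median K_d recovery error over 100 seeds is ≈2.6 %.

As a library:

```python
from kjunction import (HelixSpec, build_ideal_duplex, detect_base_pairs,
                       enumerate_helix_segments, relative_transform)

duplex = build_ideal_duplex(HelixSpec("GGCAUCGAUGCU"))
pairs = detect_base_pairs(duplex)            # 12 WC pairs
segs = enumerate_helix_segments(pairs)       # 11 two-pair segments
step = relative_transform(segs[0], segs[1])
print(round(step.rotation_angle_deg(), 1))   # 32.7 (helical twist/bp)
```

## Working with real structures

Scanning deposited coordinate files (PDB or mmCIF) uses the same
commands — `kjunction scan`, `annotate`, `superpose` — and
`scripts/validate_with_pdb.py` chains them for the TPP riboswitch
entries, printing the measured core hydrogen-bond distances next to
the published values. Patterns measured on real reference k-turns are
built with `kjunction pattern <coords> --c-sel A:20-24,B:40-44
--nc-sel ...`; the shipped pattern is a synthetic stand-in so that
everything runs offline.

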