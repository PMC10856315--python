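# Methods

This note documents the models, decision rules, numerical choices and
limitations of `btbcul3`. It states nothing that the test suite or
`scripts/acceptance.py` does not itself compute.

## Confidence-based stability classification

A structure predictor attaches two confidence signals to a multi-chain
model: the per-residue pLDDT (0–100; local reliability) and the N×N PAE
matrix, whose entry (i, j) is the expected positional error (Å) of residue
j when the model is aligned on residue i. When two chains genuinely form a
complex, the off-diagonal blocks that couple them are low (a few Å); when
the predictor has merely juxtaposed them, those blocks saturate near the
PAE ceiling (~30 Å). Practitioners usually judge this by eye from the PAE
plot. `btbcul3` replaces the visual judgment with an explicit,
reproducible rule:

* For every (adaptor chain, scaffold chain) pair, the two directional
  cross-blocks are pooled (PAE is directional, but the binder/non-binder
  contrast is symmetric in practice and no analysis here distinguishes
  direction) and summarized by mean, median, min and size.
* The global statistic is the size-weighted mean over pairs.
* Verdict: `stable` if global mean ≤ `stable_pae_max` **and** interface
  pLDDT mean ≥ `plddt_min`; `no_stable` if global mean ≥
  `unstable_pae_min`; otherwise `ambiguous`.

Defaults: `stable_pae_max = 10 Å`, `unstable_pae_min = 20 Å`,
`plddt_min = 70`. The 10/20 pair brackets the bimodal separation between
confident interfaces (typically < 10 Å cross-block means) and saturated
ones (> 20 Å, the "red" regime of PAE plots, whose scale tops near 30 Å);
the deliberate gap yields an `ambiguous` band rather than a knife-edge.
The pLDDT gate of 70 is the conventional lower edge of the "confident"
band. All three are configurable; the rule is monotone (raising every
cross-block entry can never rescue a non-stable verdict), a property the
test suite checks.

Interface pLDDT is averaged over residues whose representative atom (CA)
lies within `interface_distance` (default 8 Å) of the partner when
coordinates are available, else over all residues. An optional
adaptor–adaptor (inter-subunit) PAE statistic can be attached as a flag
for loose oligomers; it never changes the verdict.

The binder/non-binder labels of the 27 family constructs (16 binders, 11
non-binders, including the three separately-scored BTB domains of KCTD19)
are curated experimental metadata carried in `btbcul3.metadata`, not
computed; the classification benchmark asks whether confidence statistics
patterned on those two classes are separated perfectly by the default
thresholds.

## Surface areas and interfaces

SASA uses the Shrake–Rupley algorithm: each atom's solvent-expanded sphere
(van der Waals radius + probe, default probe 1.4 Å) is sampled on a
deterministic golden-spiral lattice (default 960 points) and a point is
accessible when it lies outside every neighbor's expanded sphere. Radii
are a fixed Bondi-style table; unknown elements raise unless a fallback
radius is supplied. The lattice is expressed in a body frame built from
the first non-degenerate atom triple of the model, so it rotates with the
molecule and areas are bit-exactly invariant under proper rigid motion —
essential because buried areas are small differences of large numbers.
Single-sphere and two-sphere closed forms bound the quadrature error
(≈ 0.05 % at 960 points); an independent SASA implementation (biotite) is
cross-checked in the tests at the few-percent level expected from
different lattices.

Buried area between chain groups A and B is ½·(SASA_A + SASA_B −
SASA_AB). The implementation evaluates only atoms that have at least one
cross-group neighbor within the sum of expanded radii: for all other atoms
the alone/complexed terms cancel exactly under the shared lattice, so the
restriction is lossless and ~15× faster. The lattice frame is taken from
the union in canonical (sorted) chain order, making buried(A,B) ==
buried(B,A) bit-exact.

Per scaffold chain, the buried area against each adaptor chain is computed
individually; the largest patch defines the **main** interface, the second
largest defines the **minor** one if it exceeds `min_minor_area`
(default 25 Å² — a floor below which a "patch" is quadrature-level grazing
contact, not an interface). In 1:1 assemblies only a main interface can
exist. A scaffold chain that buries nothing is reported with a
`no_interface` flag: that is the expected non-binder geometry, not an
error.

## Contact typing

Predicted models carry no hydrogens, so all criteria are heavy-atom
distance rules:

* **H-bond**: donor (N/O/S bearing at least one polar hydrogen in standard
  amino-acid chemistry; backbone N except proline, plus the usual
  side-chain donors) to any N/O acceptor at ≤ 3.5 Å. An optional
  donor-antecedent angle filter exists but is off by default — without
  hydrogens an angle term mostly adds parameters, not information.
* **Salt bridge**: side-chain N of Lys/Arg/His to side-chain O of Asp/Glu
  at ≤ 4.0 Å. Histidine is included among the bases because His–Asp/Glu
  pairs at these interfaces behave as electrostatic interactions.
* **Hydrophobic**: side-chain carbon to side-chain carbon at ≤ 4.5 Å
  between apolar residues (Ala, Val, Leu, Ile, Met, Phe, Trp, Pro, and the
  Tyr ring carbons only).

Each residue pair is reported once per kind at its minimal qualifying atom
pair (keeps contact tables readable); the full atom-pair dump is available
behind a flag. A `backbone_involved` flag marks contacts using backbone
N/O. Detection runs on a k-d tree and is checked for exact set equality
against a brute-force all-pairs scan on random fixtures.

## Superposition and cyclic symmetry

Superposition is the Kabsch least-squares fit (SVD with the determinant
correction, so reflections are never returned); it fails loudly on fewer
than three pairs or collinear references. The Cn symmetry score superposes
the assembly onto itself under the one-step cyclic permutation of its
chains (or chain groups, for n:n assemblies) and reports that RMSD — zero
for ideal Cn, with no axis fitting needed; the rotation axis falls out of
the fitted rotation's unit eigenvector. This choice is exact for ideal
rings and degrades smoothly (the tests verify monotone growth with an
injected subunit displacement).

## Trajectory statistics

Trajectories are multi-model PDB (every MD package exports it; binary
formats would buy speed the analyses do not need) against a fixed
topology. RMSD: each frame is Kabsch-fitted to the reference on a fit
selection and measured on a measure selection; separating the two supports
per-domain dissection (fit on the complex to see a domain move; fit on the
domain to see its internal deformation — both modes are exposed because
either convention is defensible). RMSF: frames in the stated window are
superposed to their mean structure (two mean-fit iterations, a standard
convention when the reference is not otherwise specified), then per-residue
RMSF is the RMS deviation of the CA atom about its mean position. For
isotropic per-coordinate Gaussian jitter of amplitude σ the closed form is
RMSF = √3·σ; fitting on ~40 CA atoms removes 6 rigid degrees of freedom
and biases recovery low by ≈ 6/(3·N_CA) in variance (~2 % here), well
inside the 5 % recovery tolerance the tests assert at 2000 frames.

Plateau detection formalizes "a stable plateau within X Å": the onset is
the earliest time t such that *every* sliding window of the requested span
starting at or after t has max − min ≤ tol (defaults 10 ns, 1.0 Å);
`None` if never satisfied. The rule is monotone in tol. Note the onset is
where the series *stays* within the band, which on a shallow ramp can
precede the ramp's end; the acceptance check therefore constructs its
ramp-then-flat series with coarse sampling and a tolerance below the last
ramp increment so the rule's answer is exactly the ramp end.

Atom pairs for distance traces use the mini-language
`chain:resnum:atom-chain:resnum:atom` (e.g. `A:84:NH2-B:121:OD2`); no
fitting is applied to distances.

## Alignment mapping and loop diagnostics

Interface residues are projected onto family-alignment columns through a
gap-aware residue-number→column map anchored at each construct's first
residue number. Categories per (sequence, column): `main_hbond`,
`main_hydrophobic`, `main_both` (dominates when both kinds hit the same
residue), `minor_hbond`; salt bridges pool with H-bonds. Minor-interface
hydrophobic contacts are kept in the contact tables but given no display
category of their own. Scaffold-side conservation is a presence count —
in how many complexes a Cul3 residue appears in ≥1 contact of each kind —
not an information score; complexes flagged low-reliability (KCTD11 by
default) are excluded from tallies unless requested.

The α2β3-loop diagnostics report, per protein: ungapped loop length,
insertion length relative to a reference binder (default KCTD2), proline
count inside the loop, and a helix-in-loop flag when the segment
annotations provide secondary structure there. Long insertions, embedded
helices, or a rigidifying proline in this loop are the structural
signatures distinguishing non-binders. Segment boundaries are supplied as
annotations (BED-like TSV, 1-based inclusive) rather than computed — DSSP-
style assignment is out of scope and boundaries are part of the input
definition.

## Synthetic data: what it emulates, and what it does not

The generators (numpy PCG64 throughout; byte-identical outputs for a given
seed) produce:

* **Cn complexes** — idealized helical-hairpin subunits (poly-Ala,
  backbone + CB in a local frame along an ideal helix: radius 2.3 Å, rise
  1.5 Å, 100°/residue) placed on a ring by rotation of 2π/n, plus an
  optional poly-Gly partner helix positioned by bisection so its closest
  approach is ~4.9 Å to subunit A and ~5.4 Å to subunit B — straddling two
  subunits the way Cul3 straddles a BTB pentamer. Engineered contacts
  (defaults: main salt bridge at 2.8 Å, main H-bond 3.0 Å, main
  hydrophobic 4.0 Å, minor H-bond 3.2 Å) are realized by mutating one
  residue per side to an extended rotamer laid along the inter-CA axis
  with the designated atom pair at the target distance exactly; candidate
  residue pairs are chosen clearance-aware so no *unintended* pair
  qualifies, and the generator re-runs contact detection on its own output
  and refuses to emit a fixture whose realized contact set differs from
  the manifest ("infeasible contact set"). Gap values were calibrated once
  at design time so the main patch buries ~115 Å² and the minor ~30 Å²
  (above the 25 Å² minor floor) across seeds.
* **Confidence bundles** — PAE blocks drawn uniformly: within-chain and
  adaptor–adaptor blocks from U[2, 6] Å; adaptor–scaffold cross-blocks
  from U[3, 8] Å (binder pattern) or U[22, 30] Å (non-binder pattern);
  zero diagonal; pLDDT from N(85, 5) for binders and N(75, 8) for
  non-binders, clamped to [0, 100]. The ranges place the two classes on
  the two sides of the red/blue cross-block contrast with realistic
  magnitudes; the 27-bundle benchmark follows the curated family table
  row-for-row (16/11).
* **Trajectories** — frame k = topology + i.i.d. per-coordinate Gaussian
  noise with per-residue σ, optionally composed with a linear rigid drift
  (rotation about z + translation per frame), so fitting must remove the
  drift and RMSF must recover √3·σ.

These fixtures emulate the *inputs* and their ground-truth statistics, not
the physics that generates real ones: the subunits are not folded
proteins, side chains have no rotamer energetics, confidence values carry
none of a real predictor's spatial error correlations, and jitter
trajectories have no kinetics. Passing tests therefore certify that the
*measurements* (areas, contacts, symmetry, block statistics, fluctuation
amplitudes) are computed correctly and that the decision rule separates
the stated confidence patterns — they do not certify predictor accuracy on
real complexes, and the paper-scale magnitudes (e.g. ~720/230 Å²
main/minor areas on a real pentamer interface, RMSF bounds of 100-ns MD
runs) require the real predicted models and trajectories as inputs.

## Problem sizes

The test suite and acceptance script run at desk scale by choice: 24-
residue subunits and a 16-residue partner (≈ 700 atoms per fixture), 30
residues per chain in confidence bundles (300×300 PAE for a 5:5 job), 100
seeds for the partition and classification benchmarks, 2000 frames for
RMSF recovery. Each quantity's estimator is size-consistent, so these
sizes exercise the same code paths as full-size inputs.

## Known limitations

* Minimal mmCIF support (atom_site loop only); no crystallographic
  symmetry expansion, connectivity records, or full mmCIF semantics.
* H-bond detection without hydrogens cannot distinguish donor/acceptor
  ambiguity in His/Asn/Gln flips; the distance criterion over-calls
  slightly relative to geometry-aware methods.
* The classifier consumes predictor confidence; it does not re-rank
  multiple predictor models or recompute pLDDT/PAE from coordinates.
* Alignments are consumed, not computed; cluster labels and binder status
  are metadata.
* PDB fixed-column output limits chain ids to one character and
  coordinates to 3 decimals; symmetry scores measured after a file round
  trip are floored at quantization level (~10⁻³ Å), not the in-memory
  10⁻¹⁴ Å.
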