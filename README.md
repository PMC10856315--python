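# btbcul3

Structural assessment of predicted complexes between BTB-domain adaptors
(the KCTD protein family) and the N-terminal helices of Cullin 3, the
scaffold of CRL3 ubiquitin ligases.

Structure predictors now produce candidate complexes for an entire protein
family in one sweep, and the practical question becomes *which of those
complexes are real*. For the KCTD family the answer is encoded in two
places: in the predictor's own confidence output — the per-residue pLDDT
vector and the predicted-aligned-error (PAE) matrix, whose adaptor–scaffold
cross-blocks are low (a few Å) only when the predictor is confident about
the relative placement of the two chains — and in the geometry of the
predicted interface itself (buried surface area, hydrogen bonds, salt
bridges, hydrophobic packing, five-fold symmetry of the pentameric
assemblies). `btbcul3` implements both halves as a tested, reusable
pipeline, together with the downstream comparative analyses: mapping
interface residues onto a family alignment, tallying conserved Cul3-side
hot spots, diagnosing the α2β3 binding loop of non-binders, and computing
RMSD/RMSF statistics of MD trajectories run on the complexes.

## What it computes

* **Stability call** — for each complex, the size-weighted mean of the
  inter-chain PAE cross-blocks (both directions pooled) drives a
  two-threshold rule: `stable` if mean ≤ 10 Å and interface pLDDT ≥ 70,
  `no_stable` if mean ≥ 20 Å, `ambiguous` between. All thresholds are
  configurable.
* **Interfaces** — buried area between chain groups as
  ½·(SASA_A + SASA_B − SASA_AB) with a deterministic Shrake–Rupley sampler;
  per Cul3 chain, the largest patch against the pentamer is the *main*
  interface and the second largest (if > 25 Å²) the *minor* one.
* **Contacts** — heavy-atom criteria: H-bond (donor→N/O acceptor ≤ 3.5 Å),
  salt bridge (Lys/Arg/His side-chain N to Asp/Glu side-chain O ≤ 4.0 Å),
  hydrophobic (apolar side-chain C–C ≤ 4.5 Å); one record per residue pair
  per kind at the minimal atom pair.
* **Symmetry & superposition** — Kabsch least-squares fits, and a Cn score
  defined as the RMSD of the assembly superposed onto itself under the
  one-step cyclic chain permutation (0 for ideal Cn).
* **Trajectory statistics** — RMSD time series with a sliding-window
  plateau detector, per-residue CA RMSF about the window-mean structure,
  and named atom-pair distance traces from multi-model PDB trajectories.
* **Synthetic ground truth** — seeded generators for Cn ring + partner
  complexes with engineered contacts, binder/non-binder confidence bundles,
  and Gaussian-jitter trajectories, so every stage is testable end-to-end
  without external data.

## Worked example

```python
from btbcul3.synthetic_data import (SyntheticComplexSpec, make_cn_complex,
                                    make_benchmark_bundles)
from btbcul3.geometry import partition_interfaces, cn_symmetry_score
from btbcul3.confidence import classify_complex, stability_report

ring, _ = make_cn_complex(SyntheticComplexSpec(n_fold=5, partner=False, seed=1))
score, axis = cn_symmetry_score(ring, 5)
print(f"C5 permutation RMSD: {score:.2e} A")

model, manifest = make_cn_complex(SyntheticComplexSpec(n_fold=5, partner=True, seed=1))
(summary,) = partition_interfaces(model, manifest.assembly)
print(f"main interface: chain {summary.main_kctd_chain}, {summary.area_main:.0f} A^2")
print(f"minor interface: chain {summary.minor_kctd_chain}, {summary.area_minor:.0f} A^2")
```

prints

```
C5 permutation RMSD: 9.59e-15 A
main interface: chain A, 114 A^2
minor interface: chain B, 32 A^2
```

i.e. the partner-free ring is five-fold symmetric to machine precision, and
the partner helix of the engineered fixture buries most of its surface
against subunit A (main) and a smaller patch against the adjacent subunit B
(minor) — the same two-subunit anchoring geometry seen in pentamer–Cul3
complexes. The contact table below the areas recovers exactly the
engineered interactions, e.g.

```
salt_bridge  A:ASP19 OD2 -- X:ARG5 NH2  2.80 A  (main)
hbond        B:GLN5 OE1  -- X:LYS8 NZ   3.20 A  (minor)
```

Classifying the 27-complex family benchmark (16 binder-patterned and 11
non-binder-patterned confidence bundles):

```python
rows = make_benchmark_bundles(seed=1)
calls = [classify_complex(b) for _, b, _ in rows]
df = stability_report(calls, [{"complex": e.complex_name} for e, _, _ in rows])
print(dict(df["verdict"].value_counts()))
# {'Stable complex detected': 16, 'No stable complex detected': 11}
```

binder bundles show cross-block PAE means near 5.5 Å and are called stable;
non-binder bundles sit near 26 Å and are called non-stable — a perfect
16/11 split.

The same stages are available from the shell via the `btbcul3` CLI
(`simulate`, `classify`, `interface`, `symmetry`, `superpose`, `mdstats`,
`annotate`, `report`); run `btbcul3 --help`.

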