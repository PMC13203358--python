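# ppikit

Tooling for characterising the binding interface of a two-partner protein
complex from replica molecular-dynamics ensembles, and for testing whether
short peptides cut from that interface block complex formation.

The motivating system is the TDP1–PARP1 complex: PARP1 recruits
tyrosyl-DNA phosphodiesterase 1 to trapped topoisomerase I–DNA cleavage
complexes, so peptides that block TDP1–PARP1 binding are candidate
sensitisers for existing TOP1 inhibitors. The package implements the full
computational workflow around that idea for any two-chain complex:

1. **Trajectory stability metrics** — superposition RMSD (Kabsch),
   partner–partner centre-of-mass distance and radius of gyration
   R\_g = √(Σ m\_i |r\_i − r\_com|² / Σ m\_i), per replica plus the
   cross-replica mean trace.
2. **Interface geometry** — frame-wise detection of interfacial contacts
   (any cross-interface heavy-atom pair ≤ 3.5 Å), hydrogen bonds
   (donor–acceptor ≤ 3.5 Å and ∠(D→H, D→A) ≤ 30°) and salt bridges
   (anionic O to cationic N ≤ 3.5 Å), with per-replica occupancies.
3. **Replica consensus** — an interaction is accepted only when present
   (occupancy ≥ 10%) in at least k of n independent replicas (default
   3 of 4), then kept partner-B residues are clustered into candidate
   pockets and blocking peptides are cut around the specific-bond anchors.
4. **MM/GBSA scoring** — single-trajectory
   ΔG\_bind = ⟨G(complex) − G(A) − G(B)⟩ with
   G = E\_coul + E\_vdW + ΔG\_GB + γ·SASA, HCT effective Born radii and a
   deterministic Shrake–Rupley surface.
5. **SPR 1:1 kinetics** — simulation and global fitting of Langmuir
   sensorgrams (dR/dt = k\_a·C·(R\_max − R) − k\_d·R, K\_D = k\_d/k\_a),
   double referencing, peptide-only subtraction and percent-binding
   inhibition against a no-peptide control.

Because production MD trajectories are neither small nor redistributable,
the `synthetic_data` module generates every input with known ground
truth: toy two-chain complexes with planted interactions that persist in
configurable replica subsets, multi-model replica PDBs, a matching
per-atom parameter table, and noisy sensorgram sets with a
competitive-inhibitor series. All generators are pure functions of their
recipe plus seed.

## Worked example

The numbered scripts under `analysis/` run the whole study on the
packaged synthetic ensemble (4 replicas × 50 frames, 0.1 Å jitter).
`python analysis/03_interface_consensus.py` prints:

```
consensus verdicts (>=3 of 4 replicas at >=10% occupancy):
  contact    ASP115 -> LYS940  present 3/4  KEPT
  contact    ASP115 -> LYS943  present 2/4  dropped
  contact    ARG137 -> GLU883  present 4/4  KEPT
  hbond      ARG137 -> GLU883  present 4/4  KEPT
  saltbridge ASP115 -> LYS940  present 3/4  KEPT
  saltbridge ASP115 -> LYS943  present 2/4  dropped
  saltbridge ARG137 -> GLU883  present 4/4  KEPT
vs manifest ground truth: 5/5 kept are planted, 5/5 planted recovered
designed 2 blocking peptides from anchors [883, 940]:
  PT-BLK-1: residues 879-887 (GGGGEGGGG)
  PT-BLK-2: residues 936-944 (GGGGKGGKG)
```

The Arg137→Glu883 hydrogen bond/salt bridge recurs in all four replicas
and survives consensus; the Asp115→Lys943 alternative partner is seen in
only two replicas and is dropped (an optional pooling rule can merge it
with the nearby Lys940 record before counting). Two separate peptides are
designed because the glutamate anchor sits far in sequence from the
lysine pair — one peptide covering both would exceed the 20-residue cap.

`python analysis/05_spr_kinetics.py` fits the simulated sensorgram set
globally and quantifies peptide inhibition:

```
global 1:1 fit over 10 curves: ka = 3.56e+05 /M/s, kd = 0.001 /s,
KD = 2.81 nM (generating 2.78 nM), Rmax = 100.6 RU
percent binding vs no-peptide control (100%):
  [peptide] =     25 uM ->  44.6 +/- 0.4 %
  ...
  [peptide] =    400 uM ->   3.8 +/- 1.1 %
```

i.e. the fit recovers the generating low-nanomolar affinity from 1%-noise
duplicate injections, and percent binding falls monotonically with
peptide concentration, as expected for competitive sequestration of the
analyte.

A `ppikit` CLI wraps the same stages (`simulate-fixtures`, `metrics`,
`interface`, `consensus`, `peptides`, `mmgbsa`, `spr-fit`,
`spr-inhibition`, `run-all`); `ppikit run-all --outdir out --seed 1`
writes all CSV/JSON artifacts plus a summary, byte-reproducibly for a
given seed.

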