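# Methods

## Scope and data model

The package analyses a two-partner protein complex carried as multi-model
PDB files, one file per independent MD replica, one MODEL per frame, all
MODELs sharing one topology. Chains are mapped to the two binding
partners ("A"/"B") in the run configuration. Coordinates are Å, atom
indices 0-based internally, residue ids 1-based as in the PDB format.
Covalent bonds are inferred from distances (hydrogen to its nearest heavy
atom within 1.2 Å; heavy–heavy pairs within 2.0 Å); no topology/PSF file
is read. Histidine protonation is taken from CHARMM-style residue names
(HSD/HSE/HSP); a plain `HIS` is treated as neutral and NE2-protonated.
Binary trajectory formats are out of scope — convert with standard tools
to multi-model PDB first.

## Stability metrics

RMSD uses Kabsch superposition (SVD of the weighted covariance, with the
determinant correction that keeps the rotation proper) of each frame onto
a reference frame of the same replica before the deviation is taken. The
fit selection defaults to the Cα trace with uniform weights and the
reference defaults to frame 0; both are configurable and are recorded in
the outputs, since different choices give different absolute values.
COM distance is the Euclidean distance between the mass-weighted partner
centroids; R_g is the mass-weighted radius of gyration of a selection.
Each metric is reported per replica plus a pointwise cross-replica mean
series. A small "stable" flag (tail drift below 1.0 Å over the last 20%
of frames) is a reporting heuristic only, not a statistical test.

## Interface geometry

Detection criteria (defaults, all configurable):

| interaction | criterion |
|---|---|
| contact | any cross-interface heavy-atom pair ≤ 3.5 Å; one record per residue pair with the minimum distance |
| hydrogen bond | donor-heavy→acceptor distance ≤ 3.5 Å AND deviation angle ∠(D→H, D→A) ≤ 30° |
| salt bridge | anionic side-chain O (Asp/Glu carboxylates, C-terminal O/OXT) to cationic side-chain N (Lys NZ, Arg NE/NH1/NH2, HSP ring N) ≤ 3.5 Å |

The angle convention measures how far the acceptor lies off the D–H axis
at the donor; a perfectly linear D–H···A geometry scores 0°. "Contact"
considers heavy atoms of any kind by default; a side-chain-only switch
exists. Candidate pairs come from a scipy KD-tree purely as an
optimisation — correctness is defined by, and tested as set equality
against, the all-pairs brute-force evaluation of the same criteria.
Occupancy is the fraction of analysed frames (default: all frames; an
analysis window can exclude equilibration) in which a keyed interaction
is present. Contacts and salt bridges are keyed by residue pair;
hydrogen bonds additionally by donor/acceptor atom names.

## Replica consensus, clusters, peptides

An interaction is "present in a replica" when its occupancy there reaches
`presence_occupancy_min` (default 10% — the presence notion needs a
threshold and run-to-run support, not raw occupancy, is what the k-of-n
rule counts; the value is recorded in every output). It is kept when
present in at least `min_replicas_present` of `n_replicas` (default 3 of
4). The rule is deterministic, order-independent and monotone in both
thresholds.

An optional pre-consensus pooling rule handles alternative partners: salt
bridges from one partner-A residue to several partner-B residues whose
side-chain centroids lie within 8 Å may be merged into one record whose
per-replica occupancy is the member-wise maximum. This models the
situation where a charged residue bridges to either of two adjacent
partners in different runs; it is off by default because it weakens the
plain k-of-n guarantee.

Kept partner-B residues are clustered by single linkage (within 4
residues in sequence OR side-chain centroids within 8 Å). Peptide
design partitions the specific-bond anchor residues greedily
left-to-right so that each group's span plus two flanks (default 4) fits
the maximum length (default 20); each group yields one peptide clipped to
the chain termini, with its sequence read from the topology. Anchors far
apart in sequence therefore produce separate short peptides instead of
one long one.

## MM/GBSA

Single-trajectory protocol: partner coordinates are extracted from the
complex frames, so bonded/internal terms cancel identically in
ΔG = G(complex) − G(A) − G(B) and are omitted. Per species:

* E_coul = Σ k_e q_i q_j / (ε_in r_ij), k_e = 332.0636 kcal·Å/(mol·e²),
  ε_in = 1; E_vdW in the ε/r_min form with geometric-mean ε and summed
  r_min halves. Bonded 1-2/1-3 pairs are excluded; 1-4 pairs enter at
  full strength (they cancel in the single-trajectory difference); no
  distance cutoff, no periodicity/PME.
* ΔG_GB = −(k_e/2)(1/ε_in − 1/ε_out) Σ_ij q_i q_j / f_GB with
  f_GB = √(r² + R_i R_j exp(−r²/(4 R_i R_j))), the i=j term giving the
  Born self energy. Effective radii come from HCT pairwise descreening
  with unit scaling factors — the simplest form with the exact Born-ion
  limit (an isolated atom keeps its intrinsic radius). Swapping in an
  OBC-style correction would only touch `hct_born_radii`.
* Nonpolar term γ·SASA + b with γ = 0.00542 kcal/(mol·Å²), b = 0;
  SASA by Shrake–Rupley with a deterministic golden-spiral point set
  (960 points/atom, probe 1.4 Å), GB radii doubling as vdW radii.

Defaults: ε_out = 78.5, frame stride 10 (25 in the demo pipeline to keep
the end-to-end run light); the stride and every constant are echoed in
the outputs. No entropy term is computed. Known numerical behaviour: the
point-set SASA is deterministic but not rotation-invariant, so ΔG is
rigid-motion invariant only to ≈0.01 kcal/mol on small fixtures
(doubling the point count moves totals by < 0.5%); overlapping atoms
(< 0.1 Å) and descreening failures raise named errors rather than
returning garbage. These energies are a scoring model, not a replacement
for a simulation engine's force field, and the toy-complex ΔG numbers
are not comparable to values computed from real all-atom ensembles.

## SPR kinetics

The 1:1 Langmuir model is used in closed form: association
R(t) = R_eq (1 − e^{−(k_a C + k_d)(t−t₀)}) with
R_eq = R_max C/(C + K_D), dissociation R(t_end) e^{−k_d (t−t_end)},
K_D = k_d/k_a. The numerically integrated ODE is retained as a test
oracle only. Double referencing subtracts the reference-surface and
buffer-blank curves on aligned grids; peptide-only subtraction removes
the inhibitor's bulk response from mixture curves before quantification.

Global fitting shares k_a, k_d, R_max across all concentrations,
minimising summed squared residuals over both phases with
Levenberg–Marquardt in log-parameters (positivity built in) and
multi-start initialisation on a log grid (k_a ∈ [10³, 10⁷] M⁻¹s⁻¹,
k_d ∈ [10⁻⁵, 10⁻¹] s⁻¹, 3×3 starts; best residual wins). A single
concentration triggers a weak-identifiability warning. Mass transport,
heterogeneous ligands and bivalent analytes are not modelled.

Percent binding reads the response at the end of association:
100 × R_mix/R_control, with the no-peptide control defined as 100%;
duplicate injections aggregate to mean ± s.d. The readout is
scale-invariant by construction.

## Synthetic data: what it emulates and what it does not

The generator builds two zig-zag backbones along x with side chains
pointing toward the partner chain, from simplified residue templates
(only the atoms the detectors and energies need, at idealised internal
geometry; no rotamers). A planted interaction is realised exactly: the
partner-B side chain is translated so its tip atom sits at the target
distance (hydrogen bonds on the donor's D–H axis, so the planted angle is
0°), with a required margin of 0.2 Å to the cutoff. Thermal motion is
isotropic Gaussian jitter per atom per frame; an interaction is "broken"
(outside its persistence window or its replica subset) by displacing the
side chain 4.5 Å further, keeping frame counts balanced. The default
recipe mirrors the emulated study design: 4 replicas, 50 frames, 0.1 Å
jitter, an Arg→Glu hydrogen bond + salt bridge present in all four
replicas (90% persistence) and an Asp bridging to either of two nearby
lysines in overlapping replica subsets (3-of-4 and 2-of-4, 80%
persistence). Sensorgram defaults emulate a low-nanomolar assay:
k_a = 3.6×10⁵ M⁻¹s⁻¹, k_d = 10⁻³ s⁻¹ (K_D = 2.78 nM), R_max = 100 RU,
five concentrations spanning 0.1–10×K_D injected in duplicate, 1 RU
noise; the inhibition series uses 100 nM analyte with peptide at
25–400 µM, competitive sequestration C_eff = C/(1 + [pep]/K_i) with
K_i = 4 µM, and a peptide bulk-response pulse that the subtraction step
must remove.

Passing tests on these ensembles demonstrates the correctness of the
geometric criteria, the occupancy/consensus bookkeeping, the energy
expressions and the fitting machinery. It does not demonstrate force-field
realism, conformational sampling, or that any particular real residue
pair is a hotspot — those depend on real trajectories, which users supply
as replica PDBs.

## Problem sizes in the shipped runs

The packaged demo and test runs use the default 4 × 50-frame ensemble
(~550 atoms), strided MM/GBSA frames, and 10–20 seeds for the recovery
statistics; these sizes were chosen so the full study re-runs in about a
minute on one core while leaving every statistical margin wide (e.g. the
tests require K_D recovery within ±10%, and the fits land within ~1–2%).
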