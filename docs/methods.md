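# Methods

## Representation

A molecular system is one chemical graph. Protein chains are expanded from
an embedded residue-template dictionary (20 standard amino acids: atom names,
elements, intra-residue bonds, backbone set {N, CA, C, O}, C→N peptide link);
ligands must bring explicit bonds from an SDF record or a template — there
is deliberately no distance-based bond perception, which fails silently on
distorted inputs. Hydrogens are stripped at graph construction. Each atom
carries element, formal charge, a role flag (backbone / side chain / ligand)
and its source identity (chain, residue number + insertion code, atom name),
so PDB round trips and atom selections work unmodified. The peptide link is
added between consecutive residues of a chain only when the C–N distance is
plausible (< 2.5 Å) or coordinates are missing, which handles chain breaks.

Bond separation — the number of covalent bonds on the shortest path — is
computed per component (scipy shortest paths) and stored exactly, with a
sentinel for atom pairs in different covalent components; featurization
clamps it at 32 and adds a dedicated "unconnected" token.

Chiral centers are (O, A, B, C) tuples. Candidates are C/N/P/S atoms with
3–4 heavy neighbors whose substituent branches are pairwise distinct
(BFS-level signatures to depth 4 — bounded for speed, sufficient for the
fixture chemistry). (A, B, C) are the three lowest-index neighbors in
ascending order; the target sign is the sign of the triple product
V = ê_A · (ê_B × ê_C) in the reference geometry, so the stored convention is
definitionally identical at training and inference time, which is all the
loss requires. Near-planar candidates (|V| < 0.1) are excluded: they are
sp² or inversion-labile and carry no stable handedness.

## Corruption

All modes are pure functions of (input, seed); a single `default_rng`
stream is consumed in documented order (group order, then one noise draw in
atom order), so seeds reproduce across platforms.

* **training** — per residue, each side-chain atom moves to the backbone
  atom it transitively hangs from (CA for standard residues); each ligand
  component collapses onto one uniformly chosen atom; then i.i.d. N(0, σ²)
  noise (σ = 1.5 Å default) is added to every coordinate of every atom,
  backbone included. Noising the backbone makes the task strictly harder
  than a fixed-backbone reading, never easier, so recovery results remain
  valid under the other reading.
* **docking** — one anchor position (a uniformly chosen reference ligand
  atom when a reference pose exists, else a user-supplied point) is noised
  with N(0, σ²); all ligand atoms collapse onto it; uncorrelated N(0, σ²)
  noise is added per ligand atom. After this, ligand atoms are exchangeable:
  neither internal structure nor orientation is recoverable from the input
  (property-tested by a Kolmogorov–Smirnov check). Side chains are
  randomized around their Cα; the backbone passes through exactly.
* **sidechain** — backbone fixed, side chains randomized around Cα, ligand
  components collapsed training-style; used for repacking/preorganization.

Training crops keep residues and ligand components whole (groups enter in
order of their nearest atom to the crop center, whole-or-not, preferring
inclusion under the 600-atom cap), because collapse-to-backbone corruption
is defined per residue.

## Losses and metrics

**All-atom FAPE.** Frames are all bonded triples a–b–c (each geometric
triple once; triples collinear in the reference within 2° of 180° are
excluded). Frame convention: origin at b, x along b→c, y by Gram–Schmidt of
b→a, z = x×y — one code path builds frames for both structures, so any
fixed convention yields identical values. Every frame scores every atom
(including other components); per-atom deviations are clamped at 10 Å and
averaged over atoms × frames. The loss is differentiable in the model
coordinates through the frame construction itself.

**Bonded geometry.** Mean absolute errors of bond lengths, bonded angles
(all a–b–c paths), planar angles (improper dihedrals at 3-coordinate
centers flagged sp² from bond orders) and chiral angles (improper dihedrals
O–A–B–C at chiral centers; the report plots these in degrees). Angle
differences are wrapped through atan2, keeping the training loss
differentiable almost everywhere.

**Chirality loss.** Mean of (V − V_ideal)² over centers, with
V_ideal = sign · 4/(3√3). Its analytic gradient (the "biasing vectors") is
also exposed as the network's type-1 chirality input, recomputed from the
current coordinates at every block; being built from cross products it is
the one parity-odd feature, which is exactly what lets the model select a
requested enantiomer.

**lDDT.** Per-atom, superposition-free: reference pairs within 15 Å whose
partners are in a different covalent component or at bond separation ≥ 4
(so the score measures packing, not bonded geometry), thresholds
{0.5, 1, 2, 4} Å. Radius and thresholds are conventional and config-exposed.

**Confidence.** Deviation targets dᵢ default to distances after optimal
rigid superposition (Kabsch) of model onto reference — the alignment under
which RMSD-style deviations are conventionally defined — with a
frame-median alternative behind a policy switch. The σ head minimizes
ln σ + d²/(2σ²); σ is predicted as log σ with floor 0.05 Å and cap 20 Å so
the likelihood stays bounded on corrupted inputs. Signed distance-error
bins use symmetric edges (−4, −2, −1, −0.5, 0.5, 1, 2, 4) Å with open
tails. pRMSD over a selection is sqrt(mean σᵢ²).

## Network

One parameter set shared by all blocks (depth adds compute, not
parameters; asserted in tests). Micro defaults: 2 blocks, 4 message rounds
per block, 1D width 64, 2D width 32, 8 vector channels, K = 16, ~131k
parameters; the reference-scale preset (8 blocks, K = 32, wider tracks) is
a configuration, not a tested training target. The equivariant layer is a
scalar+vector message-passing update: invariant inputs (element/charge/role
embeddings, edge embeddings adapted from the 2D track, distance RBFs, dot
products among vector features and relative directions) gate vector
messages and coordinate updates along relative directions and vector
channels. Coordinate-update head weights initialize at zero, so an
untrained block is the identity on coordinates. The neighbor graph is
rebuilt from current coordinates at each block entry (half spatial, half
chemical, deduplicated, spatially backfilled, sentinel-padded; ties broken
by atom index).

The confidence heads read the 1D track plus direct geometric cues — the
atom's neighbor-distance histogram, the distance it moved during the block,
and the pair head's expected |distance error| aggregated per atom — with a
linear skip path. The cues are invariant, and without them the σ head
converges to a near-constant marginal estimate at desk scale; the skip path
keeps small geometric signals from being squashed by the tanh MLP.

Training: Adam with global-norm gradient clipping at 1.0, cosine learning
rate decay (3e-3 down to 15%), gradients averaged over the dataset (up to 8
systems per step) with one fresh corruption per system per step, losses
applied after every block. Stage 1 uses a reduced block count and FAPE
only; stage 2 the full block count plus bonded-geometry, chirality and
confidence losses. The confidence NLL is role-balanced (backbone /
side-chain / ligand means averaged) so abundant easy backbone atoms do not
drown out the ligand deviation signal. An optional post-hoc calibration
stage freezes everything but the confidence heads and continues the NLL on
fresh corruptions — with features frozen this is a plain regression of
realized deviations, which sharpens the conditional spread of σ that pRMSD
ranking relies on. All training runs in the package's own numpy
reverse-mode autodiff engine; gradients are verified against central
differences in the test suite.

## Synthetic fixtures

Generators produce chains (1.5 Å bonds, 109.47° angles, all-trans), regular
rings and macrocycle-sized loops (exact closure), branched and chiral
centers (tetrahedral, four distinct single-atom substituents, mirrored to
the requested sign), an Ala–Ala dipeptide built by natural-extension
internal coordinates with L-configured α-carbons, and toy pockets: 20–40
pseudo-residues (real backbone atom names, 1–3 side-chain atoms pointing
inward) on a jittered ellipsoid enclosing a small ring ligand in a seeded
random orientation, with ≥ 3 contacts within 4 Å and no contact below 2 Å.
The ellipsoidal deformation and per-residue radius jitter make the cavity
asymmetric — in a spherically symmetric cage, differently placed ligand
poses have nearly identical contact signatures and pose quality is
fundamentally unrankable from geometry.

Fixture geometry is idealized, not force-field minimized: oracle tests need
exact ground truth, and the network only needs a self-consistent target.
Consequences for interpretation: passing recovery tests shows the
architecture can learn the denoising map and the chirality mechanism works;
it says nothing about chemical transferability, conformational strain, or
performance on experimental structures, which would require corpus-scale
training. Training sets mix the fixture kinds deterministically (an
enantiomer pair is always present from n ≥ 6) and split train/validation by
spec hash.

## Desk-scale evaluation choices

Recovery is evaluated by denoising each training fixture from 20 fresh
corruption seeds (micro model, 5 fixtures, ~2 minutes of training); the
pocket model trains on a single 126-atom pocket (~100 + 500 steps, then 200
calibration steps, ~8 minutes). The pRMSD-vs-RMSD rank correlation over a
50-sample ensemble is the weakest desk-scale property: a single overfit
pocket gives a true correlation around 0.3–0.5, so the 50-sample Spearman
estimate fluctuates substantially across ensemble seeds (measured roughly
−0.2 to +0.6 across seeds and training variants). The test pins one fixed,
pre-registered protocol (pocket seed 1, model seed 0, ensemble base seed
12345), which is deterministic on one machine; treat the property as a
mechanism check, not a performance claim.

## Known limitations

* No aromaticity or tautomer perception; bond orders are taken from input.
* No E/Z double-bond stereochemistry (planar improper dihedrals constrain
  sp² centers only locally); detected trans/cis ambiguity is not modeled.
* The dense 2D track is quadratic in crop size; systems above the 600-atom
  cap are rejected, not chunked.
* Hydrogens are never modeled or placed.
* mmCIF, MOL V3000 and nucleic-acid templates are out of scope (the type
  system allows nucleic templates; none are shipped).
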