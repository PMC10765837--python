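# Methods

This note documents the models and procedures implemented in `pharmadual`,
the conventions chosen where the underlying methodology left them open, and
what the synthetic benchmarks do and do not demonstrate.

## The pharmacophore model

A pharmacophore query is a set of typed feature spheres — here drawn from
the closed set {acceptor, donor, aromatic, hydrophobic} — each with a 3D
center (Å), a tolerance radius, and an *essential* flag, plus an optional
set of excluded-volume spheres marking receptor-occupied space and a
minimum-match count. The packaged dual ROCK1/ASK1 query (`model11`) has
three acceptors (F1–F3) and two aromatic centers (F4–F5); F1, F4 and F5
are essential, and any accepted hit must map at least four features in
total. F1 targets the catalytic lysine (Lys105 in ROCK1, Lys709 in ASK1);
F2 and F3 the hinge residues (Tyr155/Met156 and Gln756/Val757); F4/F5 the
aromatic stacking region near the catalytic domain.

### Geometry from distances

Only the inter-feature distance matrix of the selected model is published,
not coordinates, so the 3D configuration is reconstructed by classical
multidimensional scaling: double-center the squared distances into a Gram
matrix, eigendecompose, clamp negative eigenvalues to zero, keep the top
three components. Because the printed distances are rounded to two
decimals the matrix is not exactly 3D-Euclidean; the residual of the
reconstruction is 0.0089 Å (maximum over the ten pairs), and the embedding
routine treats 0.05 Å — the worst case consistent with two-decimal
rounding — as the acceptance tolerance. Orientation ambiguity is resolved
deterministically: eigenvalues sorted descending, each axis flipped so the
first feature with a non-negligible coordinate on it is positive, the
configuration centered at its centroid. Rigid motions of the input leave
all recomputed distances unchanged, and exact distance matrices round-trip
to 1e-9, both verified by property tests.

### Radii and excluded volumes

Feature radii for the published model are not printed. The defaults are
1.0 Å for acceptors/donors and 1.4 Å for aromatic features — conventional
modeling-suite values — and are configurable per feature in the JSON model
format. Excluded volumes for the original receptor are likewise not
published; the packaged model ships without them, and
`add_excluded_volumes` derives them from any supplied PDB structure (one
1.2 Å sphere per heavy atom within an 8 Å shell of the binding site, both
configurable). PDB input is read from ATOM/HETATM records only, with
author residue numbering preserved as text.

## Feature perception

The original work used a commercial modeling suite whose perception rules
are not published, so `pharmadual` ships an explicit, editable SMARTS
pattern list. Acceptors: pyridine/azole-type aromatic nitrogen, nitrile
nitrogen, non-amide amines, carbonyl/sulfoxide/N-oxide oxygen, hydroxyl
and ether oxygen; pyrrole-type N–H and amide nitrogen are excluded
(donor-only treatment). These patterns cover every mapped group reported
for the reference actives (pyridine N, indazole/triazole ring N, amide
carbonyl O, sulfoxide O). A sulfoxide emits one acceptor point per oxygen
atom. Aromatic features are the unweighted centroid of each smallest
aromatic ring, one per ring of a fused system. Donor perception exists but
is off by default (the packaged query has no donor feature); hydrophobic
perception is likewise disabled. Perception is equivariant under rigid
motion and deterministic (features ordered by first source-atom index).

## Matching

Per conformer:

1. **Correspondence enumeration.** All injective, type-consistent mappings
   of query features to perceived features that include every essential
   feature and reach the minimum-match count, pruned by pairwise distance
   compatibility: a pair (i, j) may be mapped only if
   |d_ligand − d_query| ≤ r_i + r_j. The radius-sum bound is a necessary
   condition for simultaneous sphere containment under any rigid motion,
   so pruning never removes a true match; this soundness is verified
   against exhaustive enumeration without pruning.
2. **Alignment.** Kabsch least-squares superposition (SVD with the
   reflection-correction determinant, so always a proper rotation) of the
   mapped ligand points onto the query centers. Two-point and collinear
   sets are permitted; the SVD solution is still RMSD-optimal and the
   rotation about the degenerate axis follows the deterministic SVD
   convention, with the transform flagged degenerate.
3. **Acceptance.** A correspondence is accepted iff every mapped ligand
   point lies inside its query sphere (≤ radius, boundary inclusive) after
   alignment and no heavy atom falls strictly inside an excluded volume.
   Acceptance is deliberately containment-based rather than an RMSD
   cutoff: the spheres define the model's semantics, while the minimized
   RMSD is reported as the alignment-quality score. Among accepted
   correspondences, larger mappings beat lower RMSD; remaining ties break
   on lexicographic feature-label order.

At the compound level, a molecule is a hit if **any** conformer of its
ensemble is accepted — the only reading consistent with counting hits per
compound while screening conformers.

## Validation statistics

With A actives, D decoys, N = A + D, and compound-level counts TP/FP/FN/TN:
Se = TP/(TP+FN), Sp = TN/(TN+FP), Ya = TP/(TP+FP), E = Ya/(A/N),
Acc = (TP+TN)/N, DR = Se/Sp, F1 = 2TP/(2TP+FP+FN), and the Matthews
correlation coefficient. DR = Se/Sp reproduces all thirteen printed
discrimination-ratio values of the reference table; a narrative occurrence
of 0.899 for the selected model conflicts with the table's 0.889 (= Se/Sp)
and is treated as a typo. Any statistic with a vanishing denominator is
reported as 0 with a flag rather than raising. Display rounding is
half-up to three decimals, with raw values retained. In the packaged
13-row reference table, the printed hit count n disagrees with TP + FP by
one for four models; TP/FP/FN/TN are treated as authoritative and
n ≡ TP + FP, which is the convention the printed Ya values follow.
Best-model selection is by MCC, ties broken by F1.

## Filtration cascade

Stage order: duplicate removal (canonical isomeric SMILES key, first
occurrence kept, stereoisomers distinct) → Oprea lead-likeness (MW < 450
strict, logP ≤ 4.5, HBA ≤ 8, HBD ≤ 5) → mutagenicity alerts → Veber
(TPSA < 140 Å², strict; rotatable bonds are gated by the inclusive
0–10 prefilter and not re-checked) → solubility (logS ≥ −5, inclusive) →
PAINS (RDKit's A/B/C catalogs) → pharmacokinetic gate. The library
prefilter (350 ≤ MW ≤ 500, 0 ≤ RotB ≤ 10, both inclusive) is available as
an optional leading stage. Each stage records its removals and reasons;
conservation (removed ∪ survivors = inputs), idempotence and the
commutativity of independent predicate filters are property-tested.

Descriptor choices: MW and TPSA from RDKit; Wildman–Crippen logP serves
both as the lead-like logP and as the WLOGP axis of the pharmacokinetic
plot. logS uses the ESOL linear estimator
(0.16 − 0.63·logP − 0.0062·MW + 0.066·RotB − 0.74·AromaticProportion), a
documented stand-in selected by configuration. The mutagenicity alert set
is a curated, editable subset of the classic toxicophore families
(nitroaromatic, aromatic amine, epoxide, aziridine, aliphatic halide, azo,
N-oxide, polycyclic planar); the cascade contract, not the exact alert
census, is the reproducible object. GI absorption and BBB permeation are
classified by point-in-ellipse membership in the two published BOILED-Egg
ellipses in (TPSA, WLOGP) space, shipped as overridable constants. The
P-glycoprotein call is a machine-learned prediction in the original
workflow and is deliberately not re-implemented: it is read from an
annotation field, with a configurable policy (default: keep and flag) for
missing annotations.

## Clustering

Tanimoto similarity on 2048-bit radius-2 Morgan fingerprints;
agglomerative merging of the most-similar cluster pair until the maximum
inter-cluster similarity falls below the 0.60 threshold. The threshold is
on **similarity**, not distance. Complete linkage is the default because
it guarantees that in the final partition every cross-cluster compound
pair is below threshold — the natural reading of "highest similarity set
to fall below 60%"; single and average linkage are available. Merge ties
break on the lexicographically smallest pair of cluster minimum indices,
so the partition is order-independent; only representative sampling uses
the seed. Cluster counts depend on the fingerprint, so no specific count
is asserted — the stop-criterion postcondition is what is tested, against
brute-force partition enumeration at small n.

## Synthetic benchmarks

`synthetic_data` builds molecules as *formal mixtures* of rigid fragments:
benzene or pyridine rings realize aromatic features, acetone or DMSO
oxygens realize acceptors, cyclohexane is the inert stand-in. Fragments
are complete valence-legal molecules, so no linker atoms are needed, and
keeping them disconnected keeps the feature geometry fully analytic — a
perceived feature sits exactly at its planted anchor. A matcher places one
fragment anchor at each query feature center plus Gaussian jitter σ·z; the
planted truth is the containment rule evaluated on the raw offsets (every
essential offset within its radius, at least min-match offsets within
radius overall). At σ = 0 this truth is exact and screening must recover
it perfectly; at σ > 0 the matcher's rigid realignment can recover
compounds whose raw offsets exceed the radii, so the planted label is an
approximation there and only the monotone decline of sensitivity with σ is
asserted. Non-matching conformers and decoys place fragment anchors ≥ 16 Å
apart, provably beyond the distance-pruning reach of a query whose
pairwise distances are ≤ 10.1 Å and radius sums ≤ 2.8 Å. Decoys
additionally contain at most zero aromatic rings, so they cannot cover the
two essential aromatic features regardless of geometry — rejection is
guaranteed by construction, not by statistics. Decoys copy the fragment
multiset of a randomly chosen active with aromatic rings swapped for
cyclohexane, which matches the property distributions (MW within ~6 Da per
ring, identical acceptor counts) as the emitted composition audit records.

The default benchmark reproduces the study's test-set design: 39 actives
versus 1198 decoys (ratio > 1:30), three conformers per compound, one
planted matching conformer per active. What passing these benchmarks shows
is that the matching engine, aggregation, statistics and cascade behave
exactly as specified on inputs with known truth. What it does not show:
performance on real medicinal-chemistry conformers (flexible molecules,
correlated feature geometry, tautomers), real decoy difficulty
(property-matched but pharmacophore-plausible molecules), or the original
absolute screening counts, which depended on a live 35M-compound vendor
database and are out of scope.

## Problem sizes and tolerances

The test suite and the acceptance script use: the full 13-row reference
table; the full-size 39/1198 planted benchmark once at σ = 0; 39-active
mini-benchmarks for the jitter sweep (sensitivity does not depend on
decoys); 200 random matcher instances against exhaustive search with 100
random-transform probes; ~25-compound filter panels; and n ≤ 8 clustering
problems against brute-force partition enumeration (Bell(8) = 4140).
Statistical reproduction tolerance is ±0.0015 against three-decimal
printed values; geometric tolerances are 0.05 Å (embedding, bounded by
print rounding) and 1e-9 (exact round trips and equivariance).
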