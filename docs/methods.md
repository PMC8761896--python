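# Methods

This note records the models, conventions, and numerical choices behind
fabkit, and what its synthetic fixtures do and do not establish about real
antibody structures.

## Scope and data model

fabkit analyses antibody Fab (VH, VL, CH1, CL) or Fv (VH, VL) fragments given
as single- or multi-model PDB files (mmCIF read is supported behind the same
interface), where the models of a multi-model file play the role of
trajectory snapshots.  A domain map — chain plus inclusive Chothia residue
range per domain, supplied as YAML — partitions the structure.  Residue
numbering is taken verbatim from the file and assumed to be Chothia with
insertion codes; fabkit never renumbers, and germline numbering assignment
from raw sequence is out of scope.  Insertion-coded residues sort after their
parent number (103 < 103a < 103b < 104) and an insertion at the top of a
range is inside the range (a map ending at 107 includes 107a).

Altloc groups are resolved to the highest-occupancy conformer, ties broken by
file order.  Waters and hetero compounds are excluded by default and can be
retained by flags.  Hydrogens are used when present (MD snapshots) and never
required (crystal structures).  Van der Waals radii come from a small
packaged element table (Bondi-style values, version tag
`fabkit-tables-1`); unknown elements fall back to 1.8 A with a warning.

## VH-VL orientation

Each variable domain carries a frame (origin `o`, orthonormal vectors `v1`,
`v2`) obtained by least-squares superposition (Kabsch, SVD with reflection
correction) of a packaged reference coreset onto the observed coreset
C-alpha positions.  Coreset positions missing from the structure are dropped
pairwise; below 80% coverage the fit refuses with the list of missing
positions.  With `C = o_L - o_H`:

- `dc = |C|` (Angstrom),
- `HL` = signed torsion of `(o_H + H1, o_H, o_L, o_L + L1)` in (-180, 180],
  with the standard atan2 dihedral sign convention,
- `HC1 = angle(H1, C)`, `HC2 = angle(H2, C)`,
- `LC1 = angle(L1, -C)`, `LC2 = angle(L2, -C)`.

The packaged reference is an idealized two-layer beta-sandwich C-alpha set
generated once by the fixture module (seed frozen, serialized in
`fabkit/data/reference_domain.json`, consistency-tested against the
generator).  This is *a* fixed convention, not a reproduction of any
published consensus frame: absolute angle values are convention-dependent,
and differences between variants or ensembles are the meaningful output.
Users with a preferred convention can pass their own reference (coreset
coordinates plus embedded frame) to every geometry entry point.

## Elbow angle

The elbow angle is the angle between the VH<->VL and CH1<->CL pseudo-twofold
axes.  Each axis is the rotation axis (via rotation-vector extraction) of the
Kabsch superposition of one domain onto its partner over paired C-alpha
positions; by default positions pair by identical Chothia number and
insertion code, and an explicit pairing table can be given.  A rotation
magnitude below 90 degrees sets a warning flag (the pairing is probably
wrong); a true pseudo-dyad gives close to 180 degrees.

Sign conventions, chosen so the angle is well-defined above 180 degrees and
continuous through it: with `u` the unit vector from the variable-module
C-alpha centroid to the constant-module centroid and
`r = u x (o_VL - o_VH)`, the V axis is oriented so `v . r >= 0`, the C axis
so `c . (-r) >= 0`; then `theta = arccos(v . c)` is reported as-is when
`(v x c) . u >= 0` and as `360 - theta` otherwise.  On the idealized
straight assembly (parallel dyad axes perpendicular to `u`) this reads
exactly 180 degrees, and rotating the constant module about `u` by `delta`
reads `180 - delta`.  The convention degenerates when the VH->VL axis is
parallel to `u`, which is flagged as an error rather than guessed.

## Surface area and interfaces

SASA uses a native Shrake-Rupley implementation: each atom's expanded sphere
(r + probe, probe default 1.4 A) is sampled at `n_points` (default 960)
golden-spiral quadrature points; a point is buried if inside any neighbour's
expanded sphere (KD-tree neighbour search).  The quadrature is deterministic,
so results are bit-reproducible at fixed `n_points`.  The sphere points are
expressed in a canonical frame derived from the input cloud (principal axes,
signs fixed by the third moment of the data along each axis) so areas are
invariant under global rigid motions; for burial computations one canonical
frame derived from the union of both sides is shared by all three SASA calls,
which makes buried ASA exactly zero for non-interacting sides.  The sign rule
is deterministic but arbitrary for clouds with vanishing skewness or
degenerate inertia (e.g. two identical spheres) — areas are still correct
there, only the exact quadrature orientation is unspecified.

Buried ASA for an interface (two disjoint domain-label sets) is reported as
the total `ASA(A) + ASA(B) - ASA(A+B)`; half of that is emitted as the
interface area for comparability with tools that report one side.  Interface
residues are those whose ASA drops by more than `min_delta` (default 0.1 A^2)
upon complexation.

Hydrogen bonds: donor/acceptor heavy atoms from a packaged per-residue table
(backbone N donates except proline, carbonyl O accepts; conventional polar
side-chain assignments; His N atoms both ways).  Criteria: donor-acceptor
heavy-atom distance <= 3.5 A, plus D-H...A angle >= 120 degrees whenever the
donor carries a resolvable hydrogen; donors without hydrogens are accepted on
distance alone.  Salt bridges: Asp/Glu carboxylate oxygens versus
Lys/Arg/His basic nitrogens within 4.0 A.  All cutoffs are configurable;
the defaults are conventional values and deliberately not a reimplementation
of any specific server's internals.  Contact occupancy over a trajectory is
the fraction of analyzed snapshots in which an atom pair satisfies its
criteria; pairs never observed are absent rather than listed at zero, and
reports carry both atom-pair and residue-pair granularity.

## Ensemble statistics

Snapshots are aligned to a reference snapshot (default the first) by Kabsch
superposition on selection C-alphas, yielding an RMSD series.  A sliding
window drift diagnostic flags non-plateaued series; data are never dropped
automatically — convergence screening is the user's decision.  RMSF is the
per-residue C-alpha root-mean-square deviation from the window-mean position.
PCA is an eigendecomposition of the 3N C-alpha coordinate covariance
(population normalization, so the eigenvalue sum equals the total coordinate
variance identically); it operates on coordinates, not internal angles.

The analysis window is given as trajectory fractions with default
(0.5, 1.0): equilibrium statistics are taken over the second half of a run
unless the caller chooses otherwise.  Feature series (orientation
parameters, elbow, buried ASA, or custom callables) are extracted
per-snapshot over the same windows.

## Variant comparison

Distributions are compared feature-by-feature with the two-sample
Kolmogorov-Smirnov test on right-continuous ECDFs.  When the label
enumeration `C(n+m, n)` is at most 1e5 the p-value is permutation-exact
(every assignment enumerated, ties handled naturally by the ECDF
definition); otherwise the classical asymptotic Kolmogorov tail at
`sqrt(nm/(n+m)) * D` is used, which agrees with the exact two-sample
distribution to within ~1% at n = m = 50.

Multiple testing is controlled with Bonferroni across the features of one
comparison call (`m` overridable); Bonferroni controls the family-wise error
rate, not the false-discovery rate, and a Benjamini-Hochberg mode is
available for users who want literal FDR.  Star coding in reports: `**` for
corrected significance at alpha (default 0.01), `*` for uncorrected
p < 0.05, `ns` otherwise.

## Dataset construction

Structures are annotated one record each (model 0): sequences and positions,
orientation parameters, elbow (only when CH1/CL are mapped — Fv-only entries
get partial records), interface burial, contact counts, and interface
positions; per-field failures are recorded as nulls with warnings rather
than aborting a batch.  Deduplication groups records by exact,
case-normalized VH+VL concatenated sequence identity (equivalent to
clustering at identity 1.0 without an external binary); the representative
is the lexicographically smallest identifier, making the operation
deterministic, idempotent and order-insensitive.  Position frequency
profiles report, per Chothia position, the fraction of records in which the
position is an interface residue, computed over the non-redundant set by
default; positions under the reporting threshold (default 1%) are omitted
from the table but kept in the raw profile.  Gene origin and
somatic-hypermutation level are pass-through metadata, never computed.
Stratification partitions records by light-chain isotype or by arbitrary
predicates such as "Gln at heavy 39 and Gln at light 38", feeding the
comparison machinery.

## Synthetic fixtures

The generator builds idealized Fab-like assemblies: per domain, two
antiparallel layers of C-alpha strands (3.8 A spacing along the strand,
4.8 A between strands, layers 10 A apart, a small frozen shape jitter to
remove exact symmetries) with rigid N/C/O backbone stubs; VL is VH rotated
180 degrees about an axis perpendicular to the module axis, and the constant
module repeats the arrangement displaced along the module axis, so the
unperturbed elbow is exactly 180 degrees and domain faces are in light
contact (closest heavy-atom gap 4.5 A by default).  Per-frame perturbations
are rigid: an HL twist rotates VL about the axis through both variable-domain
frame origins, a dc offset translates VL along it, an elbow rotation turns
the whole constant module about the module-connecting axis; programs can be
constant, linear ramps, Gaussian draws, or explicit per-frame arrays, with
optional isotropic Gaussian jitter on every atom.  One pseudo-random stream
is derived per purpose (residue identities, each program, per-frame jitter),
so adding frames never changes earlier frames and identical specs give
byte-identical PDB output.

These fixtures are geometric idealizations, not physical proteins.  They
establish that the estimators are exact on rigid-body ground truth, unbiased
under isotropic noise, invariant under global motion, and statistically
calibrated — they do not establish force-field realism, side-chain packing,
or the absolute angle conventions of other software.  Conclusions about real
antibodies should rest on relative comparisons computed consistently within
this toolkit.

Simulation-scale choices used by the test suite and the acceptance script
(500-frame ensembles, 100 replicates for power and error-rate checks,
10,000 frames for the RMSF closed form, 960-point quadrature) are the
package's own verification sizes: large enough that Monte-Carlo error is
well below the asserted tolerances, small enough to run routinely on one
CPU.

## Known limitations

- Absolute orientation/elbow values follow fabkit's packaged convention and
  are not comparable number-for-number with other tools; differences are.
- Default position pairing for pseudo-dyads (identical Chothia positions)
  is a heuristic for real Fabs; supply curated pairing tables for careful
  elbow work on deposited structures.
- Hydrogen-bond typing ignores protonation states and does not include
  pi-stacking or cation-pi interactions.
- Binary trajectory formats (DCD/XTC) are not read; convert to multi-model
  PDB first.
- The KS exact mode enumerates label assignments and is therefore limited to
  small samples; beyond the bound the asymptotic tail is used.
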