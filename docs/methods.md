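# Methods

`pbsfret` analyses the geometry of excitation-energy transfer in
phycobilisomes (PBS) — the giant light-harvesting antennae of cyanobacteria —
directly from atomic models, and quantifies linker-protein-induced
rearrangement of phycocyanin (PC) rods. This note records the models,
conventions, parameters and numerical choices behind each stage, and what the
synthetic test conditions do and do not establish about real structures.

## Chromophore model

A phycocyanobilin (PCB; PDB chemical component `CYC`) is an open-chain
tetrapyrrole bound to a conserved cysteine through a thioether link. The
package represents each PCB by

* a **centroid**: the unweighted mean of a configured set of conjugated
  atoms. The default set is the C4A–C1D conjugation path through rings B and
  C and the methine bridges (`C4A CHB C1B C2B C3B C4B NB CHC C1C C2C C3C C4C
  NC CHD C1D`). "Center-to-center" distance conventions differ across the
  literature, so the atom list is configuration, not code.
* a **transition dipole direction**: the principal axis (leading eigenvector
  of the 3×3 covariance) of those conjugated atoms, sign-oriented so its
  projection on the vector from a ring-A-side reference atom to a
  ring-D-side reference atom (default `C4A → C1D`) is positive. The
  lowest-energy transition of a bilin is polarized along the long axis of
  the conjugated system, which the principal axis tracks; published
  atom-pair conventions for the exact dipole vary, so the reference atoms
  are also configuration. Dipole magnitudes default to 1: all couplings and
  rates in this package are *relative*, never absolute.
* an **identity** following the field's nomenclature: core cylinder plus
  trimer index, subunit type (α/β rendered `a`/`b`) plus a monomer index or
  role tag (`LCM`, `ApcD`, `ApcF`), and the author number of the attachment
  cysteine — e.g. `A3bApcF-82`. The cysteine is located as the nearest SG
  atom within 2.5 Å of the ligand (a typical S–C bond is ~1.8 Å); if none is
  found the ligand's own author number is used and the ID flagged uncertain.
  ApcD assignments are always flagged tentative, mirroring the uncertainty
  of that subunit's placement in deposited core models.

A ligand presenting fewer than 4 of the configured conjugated atoms is
excluded from pair analysis with a warning — partial ligands would otherwise
produce meaningless axes.

## Förster geometry

For a donor/acceptor pair with unit dipoles **μ**_D, **μ**_A and
center-to-center vector **r**, the point-dipole coupling is

V ∝ μ_D μ_A (cos θ_T − 3 cos θ_D cos θ_A) / r³,  κ² = (cos θ_T − 3 cos θ_D cos θ_A)² ∈ [0, 4]

with θ_T the inter-dipole angle and θ_D, θ_A the angles to **r**. The
transfer-rate proxy stored on each pair is κ²/r⁶; the spectral overlap
factor is a fixed constant (1.0) because no spectra are modelled. The
orientation average over isotropic dipoles is 2/3, which the Monte-Carlo
routine reproduces by drawing directions as normalized 3-D Gaussians
(unbiased on the sphere, seedable).

Angles are stored as cosines throughout — degree/radian convention drift is
a classic source of silent error in κ² code.

Pair enumeration gates on centroid distance with a default cutoff of
**35 Å**: inter-cylinder hops in the PBS core all fall at or below this
distance, and κ²/r⁶ suppresses anything beyond it by orders of magnitude.
The enumeration is a plain O(n²) pass — n ≤ a few hundred chromophores makes
anything cleverer pointless — with deterministic ordering (donor before
acceptor lexicographically; rows sorted by descending weight).

## Transfer network and pathways

Chromophores become nodes of an undirected graph, gated pairs its edges,
with the κ²/r⁶ proxy as edge weight. Terminal emitters — by default the
ApcE α-LCM chromophore at Cys198 and the ApcD chromophore at Cys81 — are
designated sinks. A candidate pathway from a source is defined as the simple
path maximizing the product of edge weights, i.e. minimizing Σ −log(weight).
This is a deliberate formalization choice: the underlying structural
literature argues pathways qualitatively from distances and orientations,
and excitonic coherence (which the point-dipole picture cannot represent) is
known to contribute in both allophycocyanin and phycocyanin. The ranked path
is therefore a structure-derived hypothesis generator, not a kinetic claim;
no master-equation or excitonic Hamiltonian is computed.

Numerics: with physical weights (κ²/r⁶ at Å distances, always ≪ 1) the
−log lengths are positive and Dijkstra is exact. Synthetic toys can carry
weights > 1, where log-space shortest paths are ill-defined on an undirected
graph; the search then falls back to exhaustive simple-path enumeration,
acceptable at fixture sizes. Ties between co-optimal paths resolve to the
lexicographically smallest node sequence, implemented by a greedy
distance-consistent reconstruction from the source (float comparisons at
1e-9 relative tolerance).

## Anchored superposition

To expose rearrangement of a PC rod rather than deformation of its monomers,
the Cα backbone of one designated αβ monomer is fitted (Kabsch, proper
rotation enforced by correcting the SVD reflection branch) and that single
transform is applied to the whole mobile assembly; each monomer is then
scored against its reference counterpart with **no refitting**. The anchor's
score equals its own minimal RMSD; every other unit's anchored score is
bounded below by its dedicated best-fit RMSD, and the gap between the two is
precisely the placement shift the comparison is designed to measure.

Residue correspondence uses global sequence alignment (match +1, mismatch 0,
linear gap −1) of one-letter sequences, pairing aligned non-gap positions
that have Cα on both sides — robust to the numbering offsets common between
crystal and cryo-EM depositions. Traceback ties prefer diagonal, then
gap-in-the-second-sequence, making the pairing deterministic. RMSDs are
Cα-only and unweighted with no outlier trimming: the comparison is meant to
*show* large shifts, not suppress them.

Degenerate fits (fewer than 3 pairs, collinear coordinates) raise rather
than return an arbitrary rotation; collinearity is detected as a second
singular value below 1e-9 of the first.

## Synthetic study conditions

The generators provide every geometry the tests need, with analytic ground
truth:

* **Rings** (n pseudo-chromophores on a circle) mimic the bilin arrangement
  of an (αβ)₃ trimer viewed down the cylinder axis; chord distances
  2R·sin(kπ/n) are recorded exactly. Default test ring: n = 3, R = 20 Å —
  adjacent distance 34.64 Å, the same scale as the longest inter-cylinder
  hops in the core.
* **Stacked rings** (default spacing 30 Å, the trimer–trimer scale) mimic a
  core cylinder; each ring carries its own cylinder label so inter-ring
  edges register as bridging pairs.
* **Rods** are 4–5 units of identical 30-residue Cα helices. Planted
  per-unit rigid motions give exact anchored RMSDs, computed inside the
  generator directly from the planted coordinates (the anchored alignment is
  the inverse of the anchor's own motion; a pure translation of a unit gives
  RMSD = |t|). This value never passes through the fitting code it is used
  to test.

Pseudo-chromophores are 5-atom collinear runs reusing the configured atom
names, so principal-axis dipole assignment is exact and the fixtures survive
PDB/mmCIF round trips; manifests reproduce bit-for-bit under a fixed seed.
What these fixtures do **not** emulate: real bilin chemistry and geometry
(bent conjugation paths, propionate arms), density-limited coordinate error,
alternative conformers, sequence heterogeneity between α and β subunits, or
the actual chain-ID conventions of deposited entries. Passing tests
establish the correctness of the geometry, graph and superposition machinery
— not the biological conclusions one would draw from a particular deposited
model.

Problem sizes used by the default suite and the acceptance script — 10⁶
Monte-Carlo orientation draws, 10⁴ random coupling pairs, 20-chromophore
pair enumeration, 15-node path graphs, 30-mer alignments, 5-unit rods —
were chosen as the smallest sizes at which each check is sharp (Monte-Carlo
standard error ~0.001; oracle enumerations still exhaustive).

## Deposited-structure use

`scripts/regression_deposited.py` documents the full recipe for running the
pipeline on the deposited core (7VEA), rod (7VEB) and the crystal-packing
rod derived from 3O2C. It requires network access and two user-supplied
inputs the package cannot fabricate: the chain-ID → cylinder/subunit
correspondence of each deposition (the packaged
`configs/core_inventory_synthetic.cfg` carries the published 38/40/6/2/2/2
subunit inventory but deliberately synthetic placeholder chain IDs, and says
so in its header), and the pre-assembled crystal rod (crystal-symmetry
expansion is out of scope for the library; `gemmi convert --assembly` does
it in one line).

## Known limitations

* The principal-axis dipole is a declared stand-in for literature atom-pair
  conventions; both the atom list and sign reference are configurable so a
  specific convention can be reproduced exactly once adopted.
* Relative weights only; no refractive index, quantum yield, or spectral
  overlap — two pairs can be compared, a rate cannot be predicted.
* The max-product pathway is a ranking heuristic; excitonic coupling at
  20–30 Å separations is documented in this family of antennae and is
  outside the model.
* Multi-model files use model 1 only; alt-locs collapse to the
  highest-occupancy conformer (ties → alphabetically first ID); hydrogens
  and waters are dropped.
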