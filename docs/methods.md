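# Methods

This note records the models and procedures `capsfit` implements, the
choices made where the design was genuinely open, and what the synthetic
benchmarks do and do not demonstrate.

## Density model and scoring

An atomic model is rendered as a sum of isotropic Gaussians, one per atom,
with standard deviation σ = 0.225 × nominal resolution and amplitude
proportional to atomic number, truncated at 4σ. This is a common generator
convention for intermediate-resolution work; no attempt is made to model
element-specific scattering factors or B-factor broadening, which do not
matter for rigid-body discrimination at 6–8 Å.

Map-to-model agreement is the Pearson correlation between experimental and
simulated density over the voxels the model occupies (simulated density
above 10 % of its own maximum). This "model-mask" convention scores how
well the model explains *its own* footprint; a sub-map-mask variant (score
over the whole blob) is available. When the experimental map has been
band-limited, the simulated template is low-pass filtered identically
(`lowpass_template=True` in the pipeline); an unfiltered template caps the
achievable CC near 0.86 through spectral mismatch alone, a filtered one
near √(SNR/(1+SNR)).

The low-pass filter is a raised-cosine edge in the radial spatial
frequency, full width 0.2 × cutoff and centred on the cutoff 1/resolution;
the zero frequency is always in the pass band, so map means are preserved.

## Exhaustive docking

Rotations are enumerated on a deterministic grid uniform in
(α, cos β, γ) of ZYZ Euler angles — the Haar-measure factorisation of
SO(3) — with degenerate poles collapsed. For each rotation the template is
rendered once and the best translation found by circular FFT
cross-correlation; this is numerically identical to scanning all voxel
shifts in real space (the brute-force scan is kept as an oracle and both
routes are compared in the tests).

Coarse-grid scores select candidate basins; each surviving basin is then
polished by Nelder–Mead over a 6-parameter local pose (rotation-vector
increment about the placed centroid plus a translation), with the initial
simplex spanning a third of the grid's angular step. This matters: with a
45° search grid the correct basin is regularly *not* the best-scoring
coarse pose, and a narrow simplex cannot cross the gap. Poses are
deduplicated by symmetric chamfer RMS between placed point clouds
(nearest-neighbour matching), so placements related by an internal
symmetry of the model — e.g. the two orientations of a C2 dimer — collapse
to one. Ties in the final CC ranking break by smaller translation norm,
then grid index, making "top N" reproducible.

Default knobs: 12° angular step for standalone docking; the pipeline uses
45° plus local fill-in and basin refinement, which on the benchmark scenes
recovers planted poses to ~0.1–0.2 Å while costing an order of magnitude
less than a fine grid.

## The screening pipeline

Rounds follow the fragment ladder: whole trimmed models → N/C half-models
→ 150-residue windows (125 overlap) → 75-residue windows (60 overlap).
Confidence trimming removes residues strictly below pLDDT 70 (stored in
the B-factor field, the convention for predicted models). Fragments are
cut from the existing predicted coordinates rather than re-predicted;
re-running structure prediction per fragment is outside this package's
scope, and coordinate-cut fragments are the conservative rigid-body
choice.

Sub-maps come from thresholded 26-connected components (default threshold
0.25 × map maximum, minimum volume 800 Å³), optionally refined by a
watershed split at density saddles. The manual "check the fit by eye"
step of interactive workflows is replaced by an explicit three-part rule:
minimum CC 0.6, minimum CC lead of 0.05 over the best *viable* competitor
of a different source, and minimum model-in-density coverage of 0.6.
Two refinements of the obvious rule proved necessary:

* **Coverage.** A whole model docked into one half of a split protein
  density scores CC ≈ 1/√2 ≈ 0.71 over its own mask — above any sane CC
  threshold — so CC alone would happily accept a model hanging half out
  of the blob. Requiring 60 % of atoms inside the blob rejects it, and the
  half-model round then assigns each domain correctly (this is the
  split-protein rescue the tests exercise).
* **Viable competitors only.** The ambiguity rule exists to prevent
  accepting one of two near-equal explanations. A rival that itself fails
  the coverage rule could never be accepted, so it does not block the
  winner.

Accepted density is removed by masking voxels within 3 Å of placed atoms
to zero with a 3 Å cosine edge — masking rather than subtracting a scaled
simulation, which is robust to amplitude mismatch. Sub-maps whose residual
above-threshold density exceeds 25 % of the original continue to the next
round. Multiple copies of one source may be accepted in different
sub-maps; the no-double-assignment rule applies to density regions, not to
sources.

## Helical and cyclic symmetry

A lattice is parametrised by rise (Å) and signed twist (degrees) per
asymmetric unit, a start number, and optional cyclic point symmetry.
Handedness convention: positive twist advances counter-clockwise viewed
down the +axis while rising along +axis (a right-handed screw).

Estimation superposes designated adjacent units (Kabsch least squares;
RMSD > 2 Å raises an ambiguous-lattice error) and decomposes the resulting
transform into screw parameters: axis from the rotation's fixed direction,
twist from its angle, rise as the translation component along the axis.
The start number is `round(360/ring angle)` from an in-ring neighbour.
When a series of consecutive axial copies is supplied the parameters are
averaged over pairs; with 0.3 Å coordinate noise this brings the rise
error comfortably under 0.1 Å, where single-pair estimation sits at the
edge of that bound (axis error couples to the in-plane chord of the screw).

Rotational order of a map is detected by angular self-correlation: for
each candidate order n the map is rotated by k·360/n (k ≤ 3) about the
symmetry axis and correlated with itself over significant voxels; the
reported order is the **largest** order within 0.05 of the best score,
because a Cn-symmetric map also self-correlates at every divisor of n.
If all tested orders score alike the map is rotationally degenerate and a
no-signal error is raised. The default axis is the inertia eigenvector
whose eigenvalue is most separated from the other two — a Cn object has
two near-degenerate moments, and this picks the symmetry axis for both
prolate (cylinder) and oblate (ring) shapes.

## Geometric screens

Disulfides: cysteine Sγ–Sγ pairs within 2.5 Å (detection cutoff, wider
than an ideal 2.05 Å bond to tolerate intermediate-resolution
coordinates). Cross-links: lysine side-chain amine (NZ) pairs — and
protein N-terminal amines, reflecting amine-reactive chemistry such as
BS³ (11.4 Å spacer) — classified against a 10–15 Å reactive range;
distances are measured between the amine nitrogens, not Cα atoms. An
optional burial filter (neighbour-count proxy) drops occluded amines.
Polar contacts: donor–acceptor pairs within 3.5 Å (with a 120° D–H···A
angle check when hydrogens exist, distance-only otherwise) and
opposite-charge side-chain group pairs within 4.0 Å as salt bridges.

## Capsid morphometrics

The internal cavity is modelled as a cylinder, V = πr²h, reported in
10⁴ nm³; with the 21 nm internal radius, the 210 nm and 310 nm particle
lengths give 29.1 and 42.9 × 10⁴ nm³. Genome packing is an ordinary
least-squares line of genome size (kbp) on internal volume for reference
capsids of known content; the reference table is caller-supplied input —
the package does not bundle literature values — so the benchmark
regenerates a synthetic table around the ~4.87 kbp per 10⁴ nm³ ratio and
recovers the slope. Particle lengths are binned into half-open 5 nm bins.

## Synthetic scenes: what they are and are not

Toy proteins are idealised backbone + Cβ traces (Cα spacing 3.8 Å):
up-down helix bundles, two-sheet β-sandwiches and compact self-avoiding
coils, with packing spacings, segment lengths and an inter-sheet twist
drawn from the seed so two same-kind, same-length proteins are still
distinct folds (median pairwise Cα RMSD ≈ 6 Å after superposition). Scenes
render placed models, low-pass to the nominal resolution, and add white
Gaussian real-space noise scaled so in-mask signal variance over noise
variance equals the requested SNR. Everything is deterministic given the
seed, and ground-truth records carry all poses and identities.

Benchmark conditions: 3 true proteins (32–40 residues) plus 10 decoy
models per scene, 6 Å resolution, 2.5 Å voxels, SNR 10; the assignment
benchmark runs 12 such scenes (36 source identifications) plus the
split-protein fixture. These scenes emulate one segmented asymmetric unit
of an end-cap, not a whole capsid; passing them shows the screening logic
discriminates distinct folds under realistic noise and band-limits, **not**
that real homologous folds are distinguishable at 6 Å (they often are
not — at these resolutions CC separates secondary-structure architectures,
and two proteins with near-identical architecture remain ambiguous; the
gap rule then correctly reports the blob unassigned rather than guessing).
Real maps additionally contain non-protein density, anisotropic
resolution, and segmentation ambiguity that the generator does not
emulate.

## Numerical choices and degenerate inputs

* Grids are float32 on disk, float64 in computation; FFTs via `numpy.fft`.
* Circular FFT correlation requires the template to fit the search grid;
  grids are zero-padded when a candidate is larger than the sub-map box.
* A pose with no map overlap scores the sentinel −1 (with a warning) so
  rankings stay total; empty trims, zero acceptances, and empty maps are
  legal outcomes that propagate as empty results plus warnings, never
  crashes.
* Map origin follows the MRC2014 ORIGIN field, falling back to
  `nstart × voxel` when zero; on-disk axis order is normalised on read.
* PDB output is refused (with advice to use mmCIF) for models exceeding
  the fixed-width format: > 99,999 atoms, > 62 chains, multi-character
  chain ids, or residue numbers above 9999.

## Known limitations

* Rigid-body only: no flexible fitting or refinement of accepted models.
* The acceptance rule's thresholds are engineering defaults, echoed into
  every report; they are not calibrated against curated real-map decisions.
* `detect_rotational_order` assumes a single dominant symmetry axis;
  nested symmetries must be separated by masking (as the shell/plug
  benchmark does).
* The cross-link screen is geometric; it does not model reactivity,
  solvent accessibility beyond a neighbour-count proxy, or spectra.
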