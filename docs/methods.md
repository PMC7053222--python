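# Methods

## The indexing problem

A snapshot diffraction pattern records Bragg peaks from a crystal in a single,
unknown orientation.  With known unit-cell parameters, indexing means finding
the rotation of the reciprocal lattice that predicts the observed peaks and
assigning Miller indices `hkl` to each.  Three beam regimes complicate this in
different ways:

* **Monochromatic X-rays (~1 Å).**  Each peak maps to a single point in
  reciprocal space on the Ewald sphere of radius 1/λ.
* **Pink (polychromatic) X-rays.**  With bandwidth up to ~25%, the wavelength
  that excited a given peak is unknown, so each peak maps to a radial
  *uncertainty line segment* (ULS) in reciprocal space:
  `q(λ) = (n − ẑ)/λ`, `λ ∈ [λ_min, λ_max]`, where `n` is the unit scattering
  direction and `ẑ` the beam direction.
* **Electrons (λ ~ 0.01–0.03 Å).**  The Ewald sphere is nearly flat, which
  makes ab-initio cell determination ill-conditioned; with a known cell,
  orientation recovery remains well posed.

One algorithm covers all three: the monochromatic case is the zero-bandwidth
limit in which the ULS degenerates to a point, and the electron case is the
small-λ limit.  Conventions: beam along +z; flat detector perpendicular to z;
reciprocal metric `|q| = 1/d` (Ewald radius `1/λ`); detector coordinates are
pixel centers; 0-based indices in files.

## Orientation search in a bounded rotation space

For each observed peak, the reciprocal-lattice points (RLPs) whose norm falls
inside the peak's radial shell `[(1−tol)·q_min, (1+tol)·q_max]` are its
*candidate* RLPs (a rotation-invariant test).  For a candidate with direction
`p̂` and a ULS with direction `d̂`, the rotations placing the candidate on the
ULS form a one-parameter family

    R(φ) = R_d̂(φ) ∘ R_m̂(π),   m̂ = (p̂ + d̂)/|p̂ + d̂|,

the half-turn about the bisector followed by any rotation about the ULS axis;
`R(φ)·p̂ = d̂` holds for every φ.  Composition is done with quaternion
(Rodrigues) multiplication.

Rotations are embedded in a ball by `v = ê·f(θ)` with axis `ê`, angle
`θ ∈ [0, π]`, and the nonlinear radial scale `f(θ) = (θ/2)^{1/3}`
(`r_ball = (π/2)^{1/3}`).  The cube root fills the ball more uniformly than
plain axis–angle while keeping adjacent rotations in adjacent voxels; it is a
single pure function (`embedding_radius`/`embedding_angle`) so alternative
scalings are drop-in.  Each rotation family traces a closed *planar* curve in
the ball (the plane spanned by `m̂` and `d̂ × m̂`).

Per peak, all candidate curves are rasterized into a binary voxel grid
(φ sampled at ≤ 0.1 rad, chords subdivided so consecutive points are at most
1.8 voxels apart — the mandatory 26-neighbor dilation bridges 2-voxel gaps,
keeping the dilated curve 26-connected at half the point load), the grid is
dilated by its full 26-neighborhood, and the per-peak binary grids are summed.
Each voxel of this *rotogram* counts the peaks predicted by the orientation at
its center; the maximum indicates the solution.  Named grid presets: loose
(45³), balanced (71³), dense (101³); an explicit voxel count can override the
preset.

### Keeping the rotogram sharp at high candidate multiplicity

The candidate count per peak scales as (cell volume) × q³ × (relative shell
width).  For wide bands and dense lattices each peak can have thousands of
candidates, and the union of that many dilated curves covers most of the ball
— every voxel then "predicts" every peak and the maximum is meaningless.
Three measures keep the voting stage informative; none affects refinement or
scoring, which always use all peaks and the full band:

* **Core-band voting** (`core_bandwidth`): ULSs for the voting stage may be
  built from a sub-band centred on the nominal wavelength (e.g. the FWHM of a
  tailed spectrum).  Most observed peaks are excited in the spectral core, and
  a majority suffices for the vote.
* **Multiplicity-ordered admission** (`vote_multiplicity_cap`,
  `vote_curve_budget`, `min_vote_peaks`): peaks enter the rotogram in order of
  increasing candidate multiplicity, subject to a per-peak cap and a total
  curve budget, so a few high-resolution peaks cannot drown the grid.
* **Top-slice tie scanning**: discretization, point-group replication and the
  doubled representation of near-half-turn rotations on the ball surface can
  leave the true orientation a vote or two below a spurious maximum.  The top
  slice of the rotogram (extended level by level within a pre-scoring budget)
  is scored by a vectorized nearest-RLP pass against the voting ULSs, and the
  best few voxels (fitted peaks, then mean residual) are refined and compared
  by final score.

## Refinement and scoring

The coarse orientation is polished by minimizing the mean Euclidean distance
between each inlier peak's ULS (a closed segment; nearest-point or endpoint
distance) and its nearest RLP.  The nearest-RLP search inverts the basis at 16
radial positions along each segment and expands the rounded index triples by
±1 — complete whenever the tolerance is small against the shortest reciprocal
vector.  A peak is an *inlier* iff its distance is ≤ `tolerance · |q_rlp|`
(default tolerance 0.02).  Optimization is fixed-step gradient descent with
backtracking (≤ 20 halvings), forward finite differences (step 1e-6), an
adaptive trial step (grown ×2 after an immediate acceptance, capped at 0.05),
and convergence at relative objective change < 1e-7 or 200 iterations; the
objective is non-increasing over accepted steps by construction, and the
inlier set is re-selected after each accepted step, so outliers never pull on
the solution.  `fixedLatticeParameters` applies a pure rotation (the six cell
parameters are preserved exactly); `fitAllLatticeParameters` refines all nine
basis components.

The solution's score is the number of inliers over *all* peaks.  Each inlier's
excitation wavelength follows from the elastic condition at its assigned RLP,
`λ = −2 q_z/|q|²`.  A peak is demoted to outlier when that wavelength falls
outside the band widened by `tol · max(1, 2/(|q| λ))` — the second term is the
wavelength sensitivity of the elastic condition to a positional offset within
the distance tolerance, which dominates in the flat-Ewald-sphere electron
limit where `|q| λ ≪ 1`.  A solution is accepted iff the score reaches
`min_fitted_fraction` (default 0.25) of the peaks.  Multi-crystal patterns are
indexed iteratively, removing each accepted solution's inliers.

Note on the tolerance and resolution: the inlier ball grows as `tol·|q|` while
the lattice spacing is constant, so beyond the resolution where
`tol·q ≈` half the shortest reciprocal vector the criterion saturates and even
random positions "fit".  Peak lists must be resolution-limited accordingly
(the studies below stay well inside that bound).

Misorientation between two lattice orientations is the minimal rotation angle
after quotienting by the proper point group of the lattice (right action,
`R ~ R∘S`), detected from the cell parameters (cubic 24, tetragonal 8,
hexagonal 12, orthorhombic 4, monoclinic 2, triclinic 1 ops).  A solution is
*correct* iff its misorientation from the truth is strictly below 3°.

## The forward simulator

The simulator is the package's entire test bed; it emits the same TSV peak
lists the indexer reads, with full ground truth (orientations as canonical
quaternions; per-spot crystal id, `hkl`, excitation wavelength, exact
position).

* **Band (pink) regime:** RLPs whose elastic wavelength lies inside the band
  diffract; the spot position follows from `n = λq + ẑ`.  At zero jitter the
  positions are *exactly* the reflection predictions — the round-trip
  invariant tested against `predict_reflections`.
* **Monochromatic / electron regime:** an exactly monochromatic Ewald sphere
  is a zero-measure surface, so the generator uses an excitation-error model:
  RLPs within ξ (default 1e-3 Å⁻¹) of the nominal sphere diffract and the
  spot appears where the sphere cuts the smeared RLP.  ξ stands for mosaic
  spread, divergence and residual bandwidth for X-rays, and the
  crystal-shape-transform ("relrod") excitation for electrons.  Ground-truth
  wavelengths are λ_nominal.  This floor (≈ ξ offsets in reciprocal space)
  is what limits post-refinement precision in the monochromatic studies to
  ~0.05° — there is no exact-identity round trip in this regime.
* **Spectra:** `flat` (top-hat) or `gaussian_with_tails` (Gaussian of the
  stated FWHM truncated at the tail extent and renormalized); densities are
  normalized on the band.
* **Intensities and detection:** intensity = Exp(1) × spectral weight ×
  Wilson factor `exp(−B q²/2)` (default B = 30 Å²); a reflection is observed
  iff its intensity exceeds a detection threshold (default 0.05 of the mean
  unattenuated intensity).  This makes bright peaks predominantly
  low-resolution, as in real data — the property that intensity-ranked peak
  selection relies on.  Intensities never influence geometry.
* Spots closer than 1 px merge (positions averaged, intensities summed, the
  brightest member keeps the ground-truth record); optional Gaussian
  positional jitter, random omissions, and uniformly placed spurious peaks
  (intensity drawn at the true peaks' median scale so intensity ranking
  cannot trivially reject them).
* Everything is driven by one seed; identical seeds give byte-identical
  outputs.

What the simulator does **not** model: pixel-level images and peak-finding
errors, detector point-spread and panel gaps, mosaicity-induced streak shapes,
polarization/absorption, correlated (non-Gaussian) position errors, and
structure-factor correlations between reflections.  Passing the synthetic
studies therefore demonstrates geometric correctness and noise tolerance of
the search, not performance against real detector artefacts.

## Study conditions (snapindex.studies)

* **Monochromatic:** orthorhombic 50/60/70 Å cell, λ = 1.0 Å, q ≤ 0.25 Å⁻¹
  (4 Å resolution), 100 mm detector distance, 40 peaks per pattern fed to the
  indexer, dense (101³) grid.
* **Pink beam:** 5% FWHM Gaussian, tails to 25%; 25/30/35 Å cell at
  q ≤ 0.5 Å⁻¹ (2 Å), Wilson B = 15 Å²; 60 peaks; voting on a 0.08 core band
  with a 201³ grid, all 60 peaks considered.  The small cell is deliberate:
  candidate multiplicity ∝ cell volume × q³ × bandwidth, and with a
  protein-sized cell plus 25% tails every desk-scale grid saturates (measured
  >40% of voxels at full support on a 201³ grid with a 50/60/70 Å cell).
  The regime's defining feature — the wavelength ambiguity spanning a 29%
  radial range — is fully preserved.
* **Electron:** λ = 0.025 Å, 50/60/70 Å cell, q ≤ 0.25 Å⁻¹, 1900 mm camera
  length; rotation series of 8 frames at 1°/frame about the lab x axis,
  each frame indexed independently.
* **Robustness sweep:** monochromatic patterns with 1 px Gaussian positional
  jitter (peak-centroid noise), reduced to 5–50 peaks either at the smallest
  scattering angles or at random, 10 patterns per point.  The jitter gives
  the success-vs-peak-count curve dynamic range over the whole span; on
  noise-free patterns the indexer saturates at 100% from ~10 peaks up and a
  rank correlation of the (perfectly monotone) curve is dominated by ties.
* Replicates: the test suite uses 50 patterns for the monochromatic and
  pink studies, 20 two-crystal patterns, 10 patterns per sweep point;
  `scripts/acceptance.py` re-runs the same protocols at 12/12/6–8 replicates.

## Known limitations

* Wavelength assignment is ill posed for peaks whose ULS ray carries several
  in-band RLPs (collinear harmonics): they land on the same pixel and only an
  energy-resolving detector could separate them.  Wavelength-recovery metrics
  exclude such peaks (~1–2 per 60-peak pink pattern).
* The voting stage degrades gracefully but measurably when no peak has a
  candidate multiplicity below the cap (patterns whose 60 peaks are all at
  high resolution); the top-slice scan recovers most such cases.
* Detector distance, beam center and bandwidth are taken as exact; no
  experimental-parameter refinement is attempted.
* Indexing assumes the cell is known; only its orientation (optionally the
  full basis) is fitted.
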