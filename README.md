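# snapindex

Indexing of snapshot crystal diffraction patterns — monochromatic X-ray,
broad-bandwidth ("pink") X-ray, and electron — given known unit-cell
parameters, together with a forward simulator that provides ground truth for
every stage.

## Who this is for

Serial crystallography records one still diffraction pattern per crystal,
each in an unknown random orientation.  Indexing — determining that
orientation and assigning Miller indices *hkl* to the observed Bragg peaks —
is the step everything downstream depends on.  It is hardest exactly where
this package aims: polychromatic ("pink") beams, where the wavelength that
excited each peak is unknown, and electron diffraction, where the Ewald
sphere is nearly flat.

## The algorithm

With a known cell, each observed peak at scattering direction **n** maps to a
radial *uncertainty line segment* (ULS) in reciprocal space,

> **q**(λ) = (**n** − **ẑ**)/λ,  λ ∈ [λ_min, λ_max],

containing every reciprocal-lattice point (RLP) that could have produced it.
For each peak, the RLPs whose norm falls in the segment's radial shell are its
*candidates*; each candidate **p̂** defines a one-parameter family of lattice
rotations placing it on the ULS,

> R(φ) = R_**d̂**(φ) ∘ R_**m̂**(π),  **m̂** = (**p̂** + **d̂**)/|**p̂** + **d̂**|,

(half-turn about the bisector, then any rotation about the ULS axis).  Each
family is embedded as a closed planar curve in a bounded rotation ball via
**v** = **ê**·(θ/2)^⅓ (axis **ê**, angle θ).  Rasterizing all curves of each
peak into a binary voxel grid, dilating by the 26-neighborhood, and summing
over peaks yields the *rotogram*: each voxel counts the peaks predicted by the
orientation at its center.  The best-supported orientation is refined by
gradient descent on the mean ULS-to-nearest-RLP distance (inliers only,
re-selected every step), scored by the number of fitted peaks, and each fitted
peak receives its excitation wavelength from the elastic condition
λ = −2·q_z/|**q**|².  Monochromatic and electron patterns run through the same
code path as the zero-bandwidth and small-λ limits.

See `docs/methods.md` for conventions, parameter defaults, the voting-stage
workload controls for wide bands, and what the simulator does and does not
model.

## Worked example

Simulate a monochromatic snapshot (orthorhombic 50/60/70 Å cell, λ = 1 Å),
index it, and compare with the ground truth:

```sh
snapindex simulate --cell-params 50 60 70 90 90 90 --q-cutoff 0.25 \
    --seed 5 --out-prefix demo
snapindex index --peaks demo.peaks.tsv --geom demo.experiment.json \
    --cell demo.experiment.json --angle-resolution dense --out demo.sol.json
snapindex evaluate --solution demo.sol.json --truth demo.truth.json \
    --cell demo.experiment.json --out demo.report.json
```

The run logs (standard error) end with

```
INFO ... index peaks=demo.peaks.tsv n=76 tolerance=0.02 considered=30 resolution=dense ...
INFO ... indexed 1 lattice(s); best score 74
INFO ... success rate 1.000 over 1 lattices
```

and `demo.report.json` contains

```json
"per_pattern": [
  {"lattice": 0, "misorientation_deg": 0.0267, "pattern": 0, "success": true}
],
"success_rate": 1.0
```

i.e. 74 of the 76 simulated peaks were fitted and the recovered orientation
is 0.027° from the true one — far inside the strict 3° correctness
criterion.
The solution JSON holds the oriented reciprocal basis (Å⁻¹, lab frame) and,
per peak, the assigned *hkl*, fitted wavelength, residual distance and inlier
flag.

The same `index` command handles pink-beam and electron peak lists; only the
wavelength band in the experiment JSON differs.

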