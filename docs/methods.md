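# Methods

## Model

The simulator implements an extended two-angle (E2A) description of the
chromatin fiber. The state between two nucleosomes is an orthonormal
chain frame (exit point, outgoing tangent, transported normal). One step
advances along a straight effective linker, then places a nucleosome:
the outgoing strand leaves so that the in/out strands subtend the
opening angle α (α = π is straight-through), with the bending plane
rotated by the dihedral β about the incoming tangent; entry and exit
points are offset by the nucleosomal-DNA pitch d along the nucleosome
axis (the normal of the in/out plane), and the nucleosome center sits
midway between them. The construction is deterministic and
frame-covariant; a chain with constant (α, β) is a regular helix, which
the tests verify against a closed-form chord fit.

No interaction potentials are used. Each position draws (α, β, linker
length) from parameter distributions; excluded volume is the only
interaction. Nucleosomes are spheres of radius 5.5 nm (one sphere per
11 × 5.5 nm cylinder — the sphere keeps the center–center contact
distance at the 11 nm nucleosome diameter, which is what bounds the 3D
pair distribution from below); naked-DNA vertices are spheres of radius
1.2 nm. Overlap queries run on a uniform-grid cell list and are exactly
equivalent to brute force. Pairs closer than one NRL along the genome
are never counted as self-clashes.

## Sampling

Conformations are generated by unbiased chain growth with rejection: a
clashing position is locally redrawn, and because a clash at position k
is usually baked in by the draw at k−1, exhausted retries trigger a
one-position backtrack (bounded; then a full regrow). Every clash-free
chain is therefore a draw from the parameter distributions restricted
to the self-avoiding set — the athermal target ensemble. On top of
growth, `mc_equilibrate` applies independence-resampling pivot moves:
one position's variates are redrawn from their priors and the chain
downstream is rebuilt rigidly; the move is accepted iff clash-free.
Proposals are state-independent, so detailed balance w.r.t. the growth
ensemble holds; the test-suite checks that long MC runs and independent
regrowth agree on ⟨R²ₑₑ⟩ within statistical error. An ensemble-level
diagnostic compares half-ensemble means of R²ₑₑ (block check). Local
retry resampling introduces a weak Rosenbluth-type bias at positions
with high clash pressure; at the default parameters clash rates are a
few percent and the MC/regrowth cross-check resolves no bias.

Seeding: `simulate_ensemble` derives one generator per fiber from
`(rng_seed, fiber_index)`; identical config + seed reproduce ensembles
bit-for-bit.

## Defects

Defects are i.i.d. per 196 bp repeat, mutually exclusive at a position
(a nucleosome skip implies no histone at all): nucleosome skip with
probability 0.08, linker-histone skip with 0.06 (the shipped default
rates of the disturbed case; `params.regular()` zeroes both). Runs of k
nucleosome skips leave naked DNA of k·NRL + linker bp, discretized in
~10 bp segments as a worm-like chain with persistence length 50 nm at
the B-DNA rise 0.34 nm/bp. The bend scale per segment is solved
numerically so the discrete update has ⟨cos θ⟩ = e^(−s/Lp) exactly; the
tests recover the input Lp within 10% from generated stretches. The
chain frame is transported through the stretch, so a straight stretch
would continue the fiber direction. A linker-histone skip releases the
entry–exit constraint: α is drawn uniformly between the regular mean
opening and π, the dihedral uniformly on (−π, π], and up to 80 bp of
nucleosomal DNA may unwrap (uniform), extending that linker at the
model's effective rise. These three choices are fixed model defaults,
set on physical grounds (H1 loss opens the stalk and permits breathing),
not fitted.

## Calibrated defaults and the effective geometry

The source angle distributions of the E2A family are not publicly
tabulated, so the defaults are calibration constants
(`calibrate_defaults`), frozen in `data/default_params.cfg`:

| constant | value | anchored to |
|---|---|---|
| effective linker | 51.13 nm | ⟨r₁⟩ = 51.00 nm |
| mean opening α₀ | 0.6908 rad (39.6°) | ⟨r₂⟩ = 37.55 nm (with β₀, r₁₀) |
| mean dihedral β₀ | 2.2420 rad (128.5°) | ⟨r₁₀⟩ = 125.06 nm |
| linker jitter σ_b | 0.63 nm | σ₁ = 0.63 nm |
| angle noise (σ_α, σ_β) | (0.2427, 0.4854) rad | Lp(regular) = 280 nm |
| pitch d | 2.7 nm | nucleosomal-DNA gyre spacing (fixed, not fitted) |

The rigid chain with these angles reproduces the full Δ = 1…10 mean
distance ladder to ~1%. Calibration is staged and deterministic:
(1) a multistart least-squares fit of (linker, α₀, β₀) on the rigid
chain (chord lengths are invariant under discrete dihedral symmetries;
near-equal optima are resolved toward the current defaults); (2) the
linker jitter is set directly from the target σ₁; (3) a bisection on a
single noise scale (σ_β = 2σ_α) against simulated ensembles matches the
target persistence length. Parameter recovery (simulate → recalibrate)
is tested to 5%.

A deliberate consequence of anchoring to the distance ladder: the
51 nm effective linker corresponds to ~1.04 nm/bp over the 49 bp linker,
far above the B-DNA rise. The model treats the anchored distances as
authoritative and keeps `rise_nm_per_bp = 0.34` for actual DNA (naked
stretches); the inter-nucleosome linker is an *effective* rod whose
per-segment rise is recorded in `linker_segments()`. Related, the
geometry advances ~12.5 nm of fiber axis per repeat, i.e. a linear
compaction of ~15.7 bp/nm. A fiber with Lp = 280 nm then has a genomic
persistence length Lp·c ≈ 4.4 kbp. Quotes of ~13.5 kbp for the same
quantity presuppose ~48 bp/nm (≈4 nm axis advance per repeat), which is
incompatible with the anchored distance ladder (it would cap ⟨r₁₀⟩ near
68 nm); the two cannot hold simultaneously and this package follows the
distance anchors.

## Observables

- `pair_distances` streams (Δ, r) for all unordered nucleosome pairs;
  Δ is the genomic separation in NRL units from the genomic indices, so
  pairs spanning a nucleosome skip carry their true separation. A
  KD-tree accelerates the finite-cutoff mode; equivalence with the
  O(N²) oracle is tested exactly.
- `conditional_probability` bins distances at Δr = 0.2 nm (default) and
  normalizes to unit mass over [0, cutoff]; per-Δ component histograms
  sum to the total bin-by-bin, exactly.
- `pair_distribution_3d`: g(r) = (2·counts/N)/(4πr²Δr·ρ̄), ρ̄ = mean
  neighbour count within the cutoff sphere per reference, divided by the
  sphere volume; `pair_distribution_2d` is the disk analogue. With this
  bounded normalization a boundary-free Poisson process gives exactly
  g ≡ 1 (tested on a torus); uniform points *inside* the analysis sphere
  do not, because edge references see partial spheres.
- `scattering_function` evaluates the isotropic transform
  S(q) = 1 + 4πρ̄∫₀ᴿ (g−1) r² sinc(qr) dr by trapezoidal quadrature;
  validated against a closed-form Gaussian transform and a direct Debye
  sum with analytic background.
- `project_fiber` performs an orthogonal projection (fixed or random
  axis). The analytic single-pair law r′/(r√(r²−r′²)) and pairwise
  shortening are tested.
- `detect_peaks` finds prominence-filtered maxima and assigns each
  genomic separation to the peak whose half-prominence width contains
  its component mode (fallback: nearest peak within twice the
  half-width, at least 4 nm). With the Gaussian default distributions
  the Δ=2 component is symmetric and broad, so it forms the left flank
  of the dominant ~51 nm peak rather than a separate maximum; a distinct
  first peak requires skewed component shapes that the Gaussian family
  cannot produce. Allocation semantics are validated on constructed
  mixtures.
- Contacts: all path sites (nucleosome centers + naked-DNA vertices)
  within 35 nm, counted once per site pair per conformation, at genomic
  separation ≥ 2 kbp by default. The exclusion window is deliberately
  larger than one NRL: in this geometry Δ = 2…5 neighbours of the
  *regular* zigzag sit at 31–64 nm, so a 1-NRL window floods the loop
  statistics with same-segment pairs and erases the central gap that
  the observable is about; 2 kbp equals the default map bin (first-
  diagonal masking, as common for 3C-type maps) and ~2.5 fiber diameters
  of contour. `interaction_map` bins contacts per fiber (per-contact
  normalization via flag), `center_cut`/`gap_width` quantify the central
  depletion zone, `loop_size_distribution` the loop spectrum.
- Stiffness: the fiber axis is the 5-nucleosome running mean of centers;
  Lp comes from a weighted log-linear fit of the axis tangent
  correlation (an end-to-end WLC inversion is provided as a cross-check
  estimator), compaction from genomic span over axis contour, CIs from
  a fiber-level bootstrap. Rod-like non-decaying correlations raise a
  diagnostic error instead of extrapolating.

## What the generator emulates, and what it does not

Simulated ensembles are dilute single fibers (a mean-field view of
sub-Mbp chromatin pieces): no inter-fiber interactions, confinement,
supercoiling, nucleosome repositioning dynamics, sequence-dependent
positioning, or electrostatics. Defects are spatially uncorrelated;
real nucleosome-free regions cluster at regulatory elements. The angle
distributions are Gaussian by construction, so heavy-tailed features of
real fibers enter only through the defect channel. Passing tests
therefore demonstrate internal consistency of the model and estimators
at calibrated anchors — not that real chromatin has these statistics.

## Reduced scales and numerical choices

Distance statistics converge fast in the number of pairs, so the
acceptance script and test-suite use 50 fibers × 160 kbp (~4 × 10⁴
pairs per Δ) for r_Δ and 100 fibers × 400 kbp for stiffness; these
choices reproduce the same means as larger runs to well under a
percent. Histogram bin 0.2 nm (mode estimation: argmax with ties toward
smaller r); tangent-correlation fit uses 10 nm contour bins and stops
at the first bin below a 0.15 correlation floor; growth uses bounded
local retries (max//10) plus one-position backtracking; the WLC bend
scale is solved by Brent iteration to 1e-12. Coordinates are nm,
float64, right-handed; genomic coordinates 0-based bp.

## Known limitations

- The depleted-fiber persistence length saturates near ~110 nm at the
  default skip rates: each naked stretch (245 bp ≈ 83 nm of 50 nm-Lp
  DNA, ~1.7 persistence lengths) is a near-free hinge, and at the
  anchored compaction the hinge density caps Lp from above. Values of
  ~140 nm for the same skip rates are only reachable together with a
  much denser fiber (see the compaction conflict above).
- Regular ensembles show rare (≈0.3 per 160 kbp fiber) loops at
  2–6 kbp from heavy-tail kink events of the Gaussian angle noise;
  "strictly zero loops below the genomic persistence length" holds only
  as a strong suppression, not as a literal zero at ensemble scale.
- Archived ensembles (HDF5) do not carry the growth variates, so fibers
  read back from disk can be analyzed but not further MC-moved.
- The calibration treats the reference distance anchors as exact; the
  component spreads σ_Δ for Δ ≥ 2 are not calibration targets and come
  out broader here (the noise scale is set by the stiffness anchor
  instead).
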