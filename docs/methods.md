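# Methods

This note documents the models implemented in aqpflux, the assumptions they
make, the defaults and why they were chosen, what the synthetic validation
systems do and do not emulate, and the numerical decisions that shape the
results.

## Collective coordinate and channel bookkeeping

The channel is a finite cylinder aligned with +z: axis position
`center_xy`, extent `[z_min, z_max]` (length L = z_max − z_min) and radius
(default 4 Å, roughly an aquaporin pore radius; L is a required user input,
typically 20–28 Å for an AQPZ monomer pore). A water — represented by its
oxygen atom — is inside when its minimum-image lateral distance to the axis
is ≤ radius and its z lies within the extent, boundaries inclusive.

The collective coordinate accumulates per frame interval

    n(t_{k+1}) = n(t_k) + Σ_{i ∈ s(t_k) ∩ s(t_{k+1})} dz_i / L,

with dz the minimum-image-unwrapped z-displacement over the interval (the
interval uses the box height of its starting frame; for the NPT-like box
fluctuations this package targets, the difference from any other convention
is far below coordinate precision). Counting an interval only when the water
is inside at *both* endpoints is time-symmetric, never double-counts an
entry/exit displacement, and makes a water that enters and leaves through
the same channel end contribute exactly zero net — these properties are
asserted in the test suite. A water carried from z_min to z_max while inside
contributes exactly +1, the defining identity of the coordinate.

Entry/exit bookkeeping discards the partial displacement of the frame in
which a water crosses the channel boundary; at realistic frame intervals
this truncation is far smaller than the statistical error of the diffusivity
fit.

## Diffusivity and permeability

Each channel's n(t) is cut into **non-overlapping** windows of 200 ps
(default), each re-based to start at zero; consecutive windows share their
boundary frame, and a trailing remainder is discarded. Non-overlapping
rather than sliding windows keep the pooled segments approximately
independent, which the ~1/√N error scaling (asserted in tests) relies on.
Windows from all channels are pooled into one MSD before fitting — with four
channels and 50-ns series this yields the canonical 1,000 pooled random
walks.

D_n is half the slope of an ordinary least-squares line through MSD(τ) over
the whole window with a **free intercept**: a forced zero intercept would
bias the slope whenever the first lag carries any short-time artifact, while
for an ideal random walk the fitted intercept is statistically zero (tested).
The reported uncertainty is the OLS slope standard error; note that MSD
values at different lags are correlated, so this stderr is an optimistic
within-run number — comparisons across conditions should use the spread over
repeated runs.

Unit conversion uses v_w = 29.9 Å³ per water (bulk molar volume
18.07 cm³/mol ÷ Avogadro; configurable), p_u,mon = v_w·D_n with
1 Å³/ps = 10⁻¹² cm³/s, and p_u,tet = 4·p_u,mon exactly. A negative fitted
slope is clamped to zero permeability with a warning, retaining the raw
slope in the estimate object.

## Hydrophobic thickness and Δd_P−P,adj

Thickness is the difference of leaflet-mean phosphorus z, with leaflets
assigned by sign against the midplane (mean z of the full P selection, per
frame). Leaflet-mean was chosen over nearest-neighbour P–P pairing because
the protein-adjacent shell can hold only a handful of lipids, where pairing
is noisy and ill-defined.

"Adjacent to the protein" is realized as the P atoms whose minimum lateral
(xy, minimum-image) distance to any protein atom is ≤ 5 Å (default,
configurable and echoed in the output). The reference thickness d_origin
comes from a protein-free reference trajectory by default; a stated constant
is accepted as an alternative (a distal-shell mode within the same system
would also be defensible — the separate reference was preferred because it
is unambiguous and the synthetic harness can provide one exactly).

The averaging schedule evaluates thickness as five 1-ns block averages over
the first 5 ns and reports their mean; blocks are the half-open intervals
[k, k+1) ns so no frame is counted twice. Block averages rather than five
instantaneous frames were chosen because they are strictly lower-variance
and the schedule is configurable anyway (n_points, spacing). The spread of
the five per-block Δd values yields the reported standard error.

Sign convention: compression of the adjacent bilayer (deformed thinner than
reference) gives Δd > 0.

## Selectivity-filter central area

Per frame: the centre point is the mean of the four residues' all-atom
centroids (an all-atom rather than Cα centroid; a Cα mode can be obtained by
selecting Cα atoms only); each residue contributes its atom closest to that
centre, ties broken deterministically by lowest atom index; the four picks
are projected onto the plane perpendicular to the channel axis (default +z,
the membrane normal); vertices are ordered by polar angle about their
projected centroid — guaranteeing a simple quadrilateral regardless of input
order — and the shoelace formula gives the area. Re-picking every frame is
the default (the filter's flexibility is exactly what the observable is
for); a fixed-atom mode exists for stability comparisons. Histograms are
relative-frequency with bin edges starting at 0 and 0.5 Å² bins.

## System metrics

ρ_prot = n_proteins / box xy-area, converted to proteins/cm² (1 Å² =
10⁻¹⁶ cm²), with the area taken as a time average over analysed frames.
The trend value ρ_prot/Δd is reported per condition and ranked; Δd ≤ 0 is
flagged NaN and excluded from ranking, since the inverse-mismatch
proportionality is only claimed for compressive deformation. The Pearson
test uses the exact two-sided t convention, t = r√(n−2)/√(1−r²) with n−2
degrees of freedom (delegated to `scipy.stats.pearsonr`, which implements
precisely this); an independent permutation p-value is provided as a
cross-check utility and the test suite additionally verifies the p-value
against a hand-written quadrature of the t density and a uniformity (KS)
calibration under the null.

## Synthetic validation systems

The generators produce the *study conditions* used throughout the test
suite and the acceptance script; their defaults are fixed and are not
tuning knobs.

**Channel water** (default: 4 channels × 8 waters, L = 20 Å, radius 4 Å,
D_w = 0.2 Å²/ps, dt = 1 ps, 200,000 frames, seed 42): independent waters
performing 1D Brownian motion along z with increments Normal(0, 2·D_w·dt),
plus small lateral jitter capped well inside the radius so occupancy never
flickers. Independent (non-interacting) waters admit the exact closed form
D_n = N_w·D_w/L² by variance additivity. In the default **periodic** mode
the channel spans the full periodic box height: the occupancy set is
constant *and* each water remains a free random walk, so the closed form is
exact at every lag. A **reflective** mode confines waters between hard
channel ends instead; reflected Brownian motion has a saturating MSD
(equilibrating on the scale L²/D ≈ 200 ps at the defaults), so in that mode
the closed form holds only for lags ≪ L²/D and the mode serves qualitative
boundary-bookkeeping checks, not parameter recovery. This is why periodic is
the default. The 200,000-frame default gives ~4,000 pooled windows and a
diffusivity recovery well inside 10 % across seeds.

**Bilayer** (default: 256 lipids/leaflet on an 8-Å square lattice ≈ 64 Å²
per lipid, d0 = 38 Å, protein radius 10 Å, amplitude A = 4 Å, decay σ = 3 Å,
z-noise 0.5 Å, 50 frames at 100 ps so the 5-ns schedule is exactly tiled,
seed 42): both leaflets displaced inward by (A/2)·exp(−(r−r_prot)²/(2σ²)),
r the lateral distance to the surface of a dense dummy-atom protein cylinder
(180 atoms per ring, keeping the discretized surface distance accurate to
<0.01 Å). The planted truth Δd_expected(cutoff) is the average of the
analytic profile over the noise-free lattice sites in the shell — a numeric
integration over the shell as the bilayer actually samples it, which is what
any estimator on this lattice can recover; the test suite separately checks
that this site average approximates the continuum annulus integral. The
pipeline path (noisy frames → leaflet assignment → shell detection → block
schedule) shares no code with the truth computation.

**Filter** (default: modes 5 and 9 Å², symmetric switch probability
0.02/frame, vertex jitter 0.1 Å, 5,000 frames, seed 42): four marker atoms
on square corners, two-state Markov area switching with emitted state
labels; the stationary distribution is (½, ½) and is verified empirically.

What the generators deliberately do **not** emulate: single-file water
correlation (real channel water is strongly correlated; the independence
assumption is what buys a closed-form target), protein structure and
flexibility, lipid tails and lateral diffusion, box-size fluctuations, and
force-field physics in general. Passing the recovery tests therefore
demonstrates the correctness of the *estimators and bookkeeping*, not the
physical realism of any simulation.

## Numerical choices

- Coordinates are stored in float32 (DCD native); every statistic
  accumulates in float64. Format round-trip tolerances: 10⁻³ Å for PDB
  (fixed-column %8.3f), exact for DCD.
- Only orthorhombic boxes are supported; triclinic DCD unit cells are
  rejected with a clear error. Both the angle (90°) and cosine (0.0)
  conventions for the DCD cell record are accepted on read.
- The frame interval dt is always a user input; time fields in DCD headers
  are written but never trusted on read.
- Degenerate inputs error early with named exceptions: empty selections,
  single frames, windows longer than the series, constant input to the
  correlation, collapsed bilayers, non-positive bin widths.
- Tie-breaks are deterministic everywhere (lowest atom index for filter-atom
  picking; numpy argmin order).

## Problem sizes

The validation suite runs the permeability chain at 200,000 frames × 32
waters (seconds on one CPU), the bilayer chain at 480 lipids × 50 frames,
and the filter chain at 5,000 frames; the permutation and null-calibration
statistics use 10,000 permutations and 1,000 replicates respectively. These
sizes give planted-truth recovery comfortably inside the asserted
tolerances while keeping the whole suite fast.

## Known limitations

- The OLS slope stderr understates the true run-to-run uncertainty (lag
  correlation); use repeated runs for error bars.
- The channel model assumes a straight, z-aligned pore of fixed radius; no
  curved-axis or pore-profile (HOLE-style) support.
- Thickness is a z-projection quantity; strongly undulating membranes would
  need a local-normal treatment the package does not attempt.
- `pf_trend` is a proportional ranking, not an absolute permeability; no
  attempt is made to calibrate p_f in physical units.
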