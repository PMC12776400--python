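# Methods

## The compartment model

`wellmix` models solute homogenization in one round well of a standard
96-well plate (radius R = 3.2 mm, working fluid height H = 8.0 mm for
~200–250 µL; H is pinned at the lower end of the realistic 8–10 mm range
for determinism). The fluid is represented by a 2-D vertical slice through
the well diameter — x ∈ [−R, R] lateral, z ∈ [0, H] depth, z increasing
upward — tiled by a regular `n_x × n_z` grid of macrocells (default 16 × 16
= 256 cells). The vertical-slice reading is a deliberate design choice: the
biphasic initial condition (solute in the top half of the well, diluent in
the bottom half) and a pipette axis that penetrates the fluid at an angle
are only meaningful in a section that resolves depth. Cylinder curvature is
ignored and all macrocell volumes are equal, which makes the exchange
matrix symmetric and the variance metric an unweighted average; cells are
indexed row-major with row 0 at the bottom.

Neighboring cells exchange solute at dimensionless rate 1 (the baseline
rate k₀ after nondimensionalizing time as τ = k₀t), representing combined
local advection and diffusion. The rate matrix K is the negated weighted
graph Laplacian of the grid: symmetric, off-diagonals ≥ 0 and supported on
the face-neighbor edges, columns summing to zero, so total solute is
conserved exactly and the dynamics dc/dτ = Kc relaxes toward the uniform
state.

## The pipette jet

The pipette axis is the infinite line through the tip point
(x = tip_offset·R, z = 0.3·H), tilted by the pipette angle θ ∈ [0°, 60°]
from vertical toward +x (the same side as the offset; the tilt azimuth is
otherwise arbitrary by symmetry). The *jet footprint* is the set of
macrocells whose centers lie within perpendicular distance r_f·R of this
line. Anchoring the axis at a mid-depth tip point rather than at the
surface entry keeps the swept band comparable across angles; an axis hinged
at the rim would collapse the footprint into a corner at large tilt, which
contradicts the observation that moderate tilt mildly *helps* mixing. Edges
with **both** endpoints inside the footprint carry the enhanced rate 1 + S,
keeping the enhanced subgraph interior to the jet band. The cycled volume
fraction φ (fraction of the well volume aspirated per stroke) is carried as
protocol metadata only: the model does not remove and re-inject fluid
parcels, the footprint size acting as its proxy.

## Cycles, recirculation, and the mixing metric

One aspirate–dispense stroke is a single application of the linear mixing
operator M = exp(τ_c K): the square-wave jet schedule (enhanced exchange
during dispense, baseline during aspiration and rest) is aggregated into
one jet-on exponential per cycle, with the effective per-stroke duration
τ_c absorbing the off phases. M is computed through the eigendecomposition
of the symmetric K, which keeps it exactly symmetric; it is entrywise
non-negative and doubly stochastic, so it contracts the spatial variance
every cycle. After the exchange step, a global recirculation relaxation
c ← (1−γ)c + γ·mean(c) mimics the bulk three-dimensional recirculating
flow the 2-D slice cannot resolve, with

    γ = min(γ_max, γ₀ · S · f),    γ_max = 0.5 (pinned),

f the footprint fraction — a stronger, broader jet drives more bulk
recirculation. The functional form is the simplest one increasing in both
S and f; its scale γ₀ is calibrated, not asserted. Operator order within a
cycle (exchange first, recirculation second) is a convention; on the
zero-mean component the two steps commute, so the order only relabels the
calibrated constants.

Mixedness is the normalized concentration variance
Φ(τ) = Var cᵢ(τ)/Var cᵢ(0), using population (divide-by-N) variances;
Φ = 1 is the unmixed start, Φ → 0 perfectly mixed, with operational
thresholds Φ ≤ 0.05 and Φ ≤ 0.01 and an inclusive (≤) crossing convention.
The initial condition places c = 1 in the upper n_z/2 rows and c = 0 below
(for odd n_z the middle row joins the lower block). Simulations run 12
cycles by default, recording the field and Φ after each full cycle;
thresholds not reached in the window are reported as ">12".

## Calibration

The model has exactly two free constants, τ_c and γ₀. They are pinned by a
grid search — τ_c logarithmic, 60 points in [0.01, 2.0]; γ₀ linear, 41
points in [0, 0.2] — against two anchor protocols (vertical, centered,
large footprint r_f = 0.55): the aggressive jet S = 8 must reach Φ ≤ 0.05
at exactly cycle 4 and the gentle jet S = 2 at exactly cycle 9. Among the
constant pairs that reproduce both counts (14 in the default search), the
tie is broken by the summed |log Φ(12) − log Φ_anchor(12)| against the
anchors' published 12-cycle variances, used only as tie-breakers, never as
exact targets. The selected constants are τ_c ≈ 1.528 and γ₀ = 0.045. All
other sweep cells — angles, offsets, the S = 4 midpoint, the small
footprint — are then predictions. The search exploits the fact that the
recirculation step scales the zero-mean component by the scalar (1−γ), so
Φ(n) = (1−γ)^{2n}·‖Mⁿd₀‖²/‖d₀‖² can be evaluated for all γ₀ at once; this
identity is exact, and a round-trip test re-simulates the anchors through
the ordinary cycle loop.

No quantity is tied to absolute physical time: τ_c rescales the mixing rate
per stroke, and only relative changes across cycle counts and parameters
are interpreted.

## Scenarios and sweeps

Four named scenarios span the gentle/aggressive strength extremes (S = 2,
8) crossed with small/large footprints (r_f = 0.25, 0.55), all vertical and
centered; S = 4 appears in sweeps unnamed. The default sweep is the full
Cartesian product θ ∈ {0°, 30°, 60°} × offset ∈ {0, 0.25, 0.5} × S ∈
{2, 4, 8} × r_f ∈ {0.25, 0.55} (54 rows). The heat-map view pivots a sweep
slice into a strength × radius matrix of cycles-to-threshold, encoding
censored cells as n_cycles + 1 with a flag.

## The survey dataset

The packaged fixture (`wellmix/data/survey_strokes.csv`) transcribes
explicit 96-well pipette-mixing stroke counts from lab-forum threads,
vendor kit documents and peer-reviewed protocols. Curation rules: an entry
listing two counts is split into two records; entries giving only a
pipetting volume are excluded; one protocol served at two URLs (an English
and a Chinese mirror of the same vendor document) is counted once; the one
"couple of times" instruction is read as 2 strokes. Ranges are reduced to
their midpoint ("2 – 3" → 2.5), so normalized counts may be half-integers;
the quoted raw range of 2–20 strokes refers to the raw texts, while
normalized counts span [1.5, 20]. The curated dataset holds 42 protocol
instances, 4 of which also specify a pipetting volume (as % of well
volume). Summaries report min/max/mode (mode ties break toward the smaller
count) and a frequency histogram over the distinct half-integer-resolved
values — unit-width bins cannot separate values 0.5 apart (1.5 vs 2,
2.5 vs 3), so the histogram is per-value, matching the distinct peaks at
2.5, 10 and 15 that the data show. The survey is descriptive; no inference
is attempted.

## Numerical choices and verification

- Matrix exponentials via `numpy.linalg.eigh` of the symmetric K (exactly
  symmetric M, double stochasticity to ~1e−13).
- The operator is verified against an independent forward-Euler integration
  of dc/dτ = Kc. Forward Euler's own global error is ≈ 2e⁻²/n per mode
  (n = substep count), i.e. ~5e−6 at n = 10⁴, so the oracle uses n = 2×10⁵
  substeps to push its own error (~2.5e−7) below the 1e−6 comparison
  tolerance.
- The footprint filter is verified against a brute-force per-cell
  point-to-line distance check over random configurations.
- Problem sizes in the tests and acceptance script are the model's working
  defaults (16×16 grid, 12 cycles, 54-point sweep, 8×8/24×24 resolution
  checks); the whole suite runs in well under a minute of compute.
- The simulator is fully deterministic — no random number generation — so
  identical configurations produce byte-identical outputs.

## Limitations

The model resolves no velocity field: no Navier–Stokes dynamics, jet
momentum decay, spreading angle, depth-limited footprint, bubble formation
or shear stress. The 2-D slice cannot represent azimuthal structure, and
the global recirculation term is a one-parameter stand-in for 3-D flow.
Cycles-to-threshold values are meaningful relative to each other, not as
absolute stroke counts for a particular pipette; calibrating τ_c against
measured mixing times for a specific liquid handler is left to the user.
The survey fixture reflects protocols that chose to state stroke counts
explicitly and therefore undercounts the practice at large.
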