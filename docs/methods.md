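# Methods

`dbacsim` is a desk-scale simulation of a deep-bleeder acoustic coagulation
(DBAC) cuff: a wearable ring of high-intensity focused ultrasound (HIFU)
therapy tiles (Tx) and 3D imaging probes (Ix) that finds deep arterial
bleeders in a limb and cauterizes them automatically. The package replaces
the hardware with synthetic physics at every interface — phantoms instead of
limbs, geometric Doppler rendering instead of an imager, envelope beams and
a finite-difference bioheat solver instead of transducers and tissue — while
keeping the decision-making algorithms (detection, planning, closed-loop
control, registration) the real object of study.

## Coordinate and unit conventions

Right-handed coordinates, millimeters, limb axis = +z, origin at the
limb-axis midpoint. Voxels are 0-based with half-open extents. Sound speeds
in m/s, flow velocities in cm/s, acoustic powers in W, attenuation in Np/cm
at 1 MHz with linear frequency scaling, thermal quantities in SI.
Every random draw flows through an explicit integer seed; identical seeds
give bit-identical outputs.

## Synthetic phantoms

Limb phantoms are tissue cylinders, 7.5–25 cm in diameter, holding a
vascular tree, optional bone cylinders, and a 1-cm water-coupling jacket.
Tissue defaults describe a soft-tissue-mimicking gel: c = 1515 m/s,
α = 0.05 Np/cm/MHz, ρ = 1050 kg/m³, c_p = 3600 J/(kg·K),
k_t = 0.55 W/(m·K), perfusion 0 (phantom mode). The thermal values are
documented soft-tissue surrogates (the gel formulation's own constants are
not published) and are configuration-exposed.

Vessel trees grow by recursive binary branching off a main artery that runs
near the limb axis: child radii follow a Murray-like law with exponent 2.5
(floored at the 0.6-mm minimum structure resolution), branching half-angles
scale from ~15° in 7.5-cm limbs to ~35° in 25-cm limbs, and daughter
directions carry an outward bias so daughters separate from the parent
lumen rather than running alongside it. Bleeder branches are straight
vented stubs at least 31 mm long, so the thermocouple marker placed 20 mm
downstream of the bifurcation always fits on the branch.

Flow waveforms are built from a fixed systolic pulse shape so that the
resistive index RI = (V_sys − V_dia)/V_sys is pinned by construction:
`normal` draws RI in [0.82, 0.95], `bleeder` in [0.55, 0.70] (diastolic
run-off through the vent), and `irregular-slow` produces aperiodic traces
with mean velocity ≤ 4 cm/s whose RI is erratic — these reproduce the known
failure mode of RI-based classification at the minimum detectable velocity.

Power-Doppler rendering is geometric, not an RF simulation: the lumen is
rasterized, scaled by branch mean speed and by the best |cos θ| between any
probe's beam direction and the local flow direction (Doppler-angle dropout,
removed by compounding when at least one probe sees the flow at
|cos θ| ≥ 0.3), plus additive Gaussian noise clipped at zero. Spectral
gates return the branch waveform under multiplicative noise, or a no-signal
sentinel beyond a 2-mm capture radius. Rendering covers the vessel-tree
bounding box (plus 3 mm) rather than the whole limb; full-limb rendering at
sub-0.3-mm voxels adds nothing to the detection logic. What the renderer
does **not** emulate — speckle statistics, beamforming artifacts, shadowing,
wall filters — bounds what passing tests show about real data: they validate
the decision chain, not image formation.

## Detection and localization

Segmentation thresholds the nonzero intensities (Otsu) and drops components
under 20 voxels. Centerlines come from 3D thinning; because arterial trees
are acyclic, the skeleton's 26-connectivity graph is reduced to its
Euclidean minimum spanning tree, which removes the diagonal braids a
digital curve generates. Two robustness measures deal with thinning
artifacts: spurs shorter than max(2 mm, 2 × local lumen radius) are pruned
(blunt tube ends skeletonize into crow's-foot twigs about one radius long),
and skeleton fragments that leave mask voxels uncovered are re-skeletonized
at 2× resolution and re-bridged (the Lee-style thinning in use erases bars
with certain even voxel cross-sections). Junction nodes closer than
max(1.5 mm, 1.2 × the sum of local lumen radii) merge into one bifurcation
— at working voxel sizes a thick vessel otherwise yields several skeleton
junctions inside a single lumen.

Bifurcation localization inherits a genuine physical bias: where a daughter
leaves its parent at angle θ, the two lumens overlap for roughly
(r_parent + r_child)/sin θ, and the skeleton junction sits where the lumens
separate, several millimeters downstream of the geometric branch point.
The effect worsens as branching angles narrow, i.e. in the smallest limbs —
the same trend the hardware exhibited.

Three spectral gates per bifurcation sit 5 mm along each incident branch
(branch midpoint, flagged, when shorter); the 5-mm default is a choice, not
a published value. Roles (proximal / distal / in-the-bleeder) come from
ground-truth flow direction. Each outgoing branch is classified bleeder iff
RI < 0.75, strictly. Reported targets are the in-the-bleeder gate
locations; duplicates per branch are collapsed. Phase wall-clock times are
recorded but never gated — simulation timing says nothing about the
hardware's acquisition budget.

## Cuff geometry and planning

The cuff is a regular polygon of 4–7 rigid panels tangent to the limb plus
standoff (1 cm default), three 52 × 52 mm tiles per panel laid axially with
a 2-mm gap, and up to six probes (one per panel, 30 mm above the panel
center, 70° × 70° sectors to 250 mm). Each tile is 4 acoustic modules of
96 × 12 elements — 4608 elements, 27.04 cm² of aperture — steerable ±60°
azimuth, ±45° elevation. The per-tile acoustic cap is the 6 W/cm² skin
intensity limit times the full aperture area: 162.24 W, i.e. 163 W to three
significant figures.

For a target, tiles are available if within steering limits and the
10–160 mm focal range with a bone-free path. Transport efficiency is
η_m = 0.5 (electroacoustic) × cos-power steering directivity × e^(−2αf d_t).
Achievable absorbed power in the 8-mm minimum therapeutic volume (MTV)
follows Q_m = Q_0 η_m (1 − e^(−2αd_0)). Tiles rank by Q_m; for each group
size k in [minTx, maxTx] (defaults 2 and 6) the top-k group is equalized to
its k-th largest member, total k·Q_(k); the maximizing k wins, ties to more
tiles (more equalized beams heat more spherically). "Equalized" means every
recruited tile contributes the same absorbed power at the target — the only
reading consistent with weights 0 < w ≤ 1 and with comparing group totals.
Dither patterns: 12-point double ring (radii 3.2/1.6 mm) at focal depths
≤ 7 cm, 9-point 3 × 3 grid (±2.8 mm) deeper, interpreted in each beam's
lateral frame; pattern geometry is a stated design choice — only the counts
and the depth split are normative.

## Acoustic fields

Two beam models serve different scales. Diffraction quantities (focal
widths ≈ f#·λ, −13.3 dB rectangular-aperture side lobes) come from
monochromatic far-field element summation over the 96 × 48 grid with a
baffled-cosine element factor and uniform apodization. Deposition maps for
the thermal solver use an energy-conserving envelope: Gaussian lateral
profile with hyperbolic waist w(s) = w_f √(1 + ((s − s_f)/z_R)²) reaching
the aperture radius at the tile face, power attenuated along the in-tissue
path, heating q = 2αI, dither applied as 1/n time-averaged weights.
Propagation is linear and monochromatic throughout — the dosing regime is
deliberately constrained to linear thermal mechanisms.

One bookkeeping subtlety: the planning value Q_m treats all arriving power
as absorbed while crossing the 8-mm sphere, but the physical beams put
their lateral and axial Gaussian tails just outside it, so the deposition
integral strictly inside the MTV is a sub-unity fraction (≈ 0.5–0.8
depending on f-number and pattern) of the plan value, with the remainder
deposited in the immediately surrounding shell. Both numbers are computed
and reported wherever "absorbed power" matters; the benchmark experiment
bisects on the planning quantity, matching how the power requirement is
defined.

## Bioheat solver and dose metrics

The Pennes equation ρc_p ∂ΔT/∂t = k_t∇²ΔT − ρ_b c_b w_b ΔT + q is solved
with an explicit 6-point stencil; time steps above the stability bound
h²ρc_p/(6k_t) × 0.9 are rejected with the computed bound. Boundaries are
Dirichlet ΔT = 0 (water jacket as heat sink) or insulated for conservation
tests. An optional lumen sink (5 × 10⁶ W/(m³·K) in vessel voxels) stands in
for intraluminal advective cooling — enough to reproduce the cold-lumen
thermometry bias, explicitly not a CFD solve. Metrics: (min, mean, max)
end-of-dose ΔT over the MTV sphere; peak skin-surface ΔT over all times;
the lateral-confinement check (pass iff max ΔT beyond 1 cm lateral of the
beam axis is < 20 % of the MTV mean — "no significant heating" has no
published number, 20 % is this package's operationalization); and CEM43
with the Sapareto–Dewey convention (R = 0.5 above 43 °C, 0.25 below).

## Closed-loop targeting and dosing

Focus localization segments super-threshold strain (keeping the connected
component with the most integrated strain), fits a strain-weighted
total-least-squares line (the beam axis), and projects the peak-strain
voxel onto it. Iterative correction applies the full negative measured
offset each round (damping exposed, default 1); convergence requires the
measured offset to clear a guard band of tolerance − 3σ_loc (floored at
30 % of tolerance), because the goal is *true* focus overlap within 3 mm
and accepting a borderline noisy reading right at tolerance would leave the
actual focus outside it.

Echo features (apparent displacement, thermal strain, backscatter change,
inter-frame correlation) are simulated from the solver's ΔT history. The
strain response is linear at λ = 0.0012 °C⁻¹ up to 10 °C and logarithmic
above, calibrated so a linear readout underestimates a 30 °C rise by
~30 % — this constant is a calibration to the reported thermal-strain bias
magnitude, not derived physics. Two estimators: TSI (strain/λ with
cubic-polynomial temporal smoothing) and a recurrent estimator implemented
as an echo-state network — 32-unit fixed random reservoir (spectral radius
0.9), ridge-regression readout over reservoir states plus raw features —
trained on a synthetic corpus of 250 heating/cooling ramps (2–35 °C peaks),
deterministic under seed, with train/held-out MAE reported in the 0–10 and
11–30 °C bands. The dose controller steps the solver in 0.5-s frames,
estimates per-MTV-voxel temperatures, and powers off when the voxel-mean
estimate reaches the threshold or at the 30-s exposure limit, recording the
cause, the estimate, and the true solver temperatures at shutoff.

## Time-of-flight registration

Each array face carries five 3 × 3 mm sub-apertures (four inset corners +
center). Arrival times follow a two-segment straight ray: the chord inside
the limb cylinder at the tissue speed, the rest at the water speed, plus
Gaussian jitter (default one 2.5-MHz period, 0.4 µs — a stated choice, no
published noise figure). Pairs must be roughly facing (incidence ≤ 72°)
and bone-free. The solver fits all sub-aperture coordinates plus both layer
speeds jointly by sparse nonlinear least squares (trf/lsmr, residuals in
µs), initialized from the polygon prior — the known panel count standing in
for the calibration file, replacing the fiber-optic shape sensor the
hardware itself ended up not deploying. Poses come from the best-fit rigid
frame over each array's five points; panel count is re-identified by
clustering tile-normal azimuths. Because forward and inverse models share
the straight-ray assumption, Snell bending at the water/tissue interface
cancels out of the error metrics and is not modelled. Simulated cuffs are
perturbed per-panel (2 mm, 2°) so the solver genuinely recovers a deformed
geometry rather than echoing its initialization.

## Benchmark experiment sizes

The reference experiments (`dbacsim.experiments`) run on one CPU in well
under a minute each; sizes are the package's own choices:

* minimum absorbed power: 15-cm phantom, 3 equalized tiles, target at
  7.5-cm depth, deposition on a 4-cm box at 0.5-mm voxels, 30-s doses,
  10-step bisection on the planning absorbed power until min-over-MTV
  ΔT_eod = 33 °C;
* maximal-dose skin check: same geometry at 55 W/tile, full cross-section
  grid at 2-mm voxels including the skin surface, dt = 0.5 s;
* targeting: 50 seeded trials, offsets uniform in 3–10 mm, σ_loc = 0.5 mm,
  5-iteration cap;
* registration: 7-panel cuff on a 25-cm phantom, 0.4-µs jitter, full and
  degraded (20/21 tiles, 5/6 probes) measurement sets.

## Known limitations

Geometric Doppler rendering and envelope beams omit speckle, aberration,
nonlinearity, and cavitation; the bioheat solver ignores property changes
with coagulation and real perfusion fields; bifurcation localization
carries the lumen-overlap bias described above; D&L wall-clock times are
not comparable to hardware acquisition budgets; and the thermometry
estimator is trained and evaluated on the same synthetic feature generator
— its reported MAEs say nothing about performance on real echo data.
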