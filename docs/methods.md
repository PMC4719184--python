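# Methods

## Problem

EEG is a potential *difference*: every recorded channel is measured against
a reference, and no point on the body is electrically neutral. Linear
re-referencing operators try to recover the reference-free ("referenced at
infinity") topography from the recorded one. This package simulates the
whole measurement chain — dipolar brain sources, volume conduction to the
scalp, referencing — so that the distortion introduced by each operator
can be measured exactly, because the reference-free truth is known by
construction.

## Forward models

Potentials are computed for current dipoles inside spherical volume
conductors. Positions are in millimetres in a head frame (origin at the
sphere centre, +x right, +y anterior, +z vertex); conductivities enter only
as ratios, and dipole moments are in arbitrary units — every metric used
downstream is scale-invariant.

* **Homogeneous sphere.** The surface potential of an eccentric dipole in
  an insulated homogeneous sphere has a closed form, obtained by summing
  the Legendre series of the interior Neumann Green's function:

      V(r_e) = [ 2 (d·p)/d³ + ((r_e + R d/|d|)·p) / (R F) ] / (4πσ),

  with `d = r_e − r0` and `F = R² − r0·r_e + R|d|`. It reproduces the
  textbook central-dipole field `3 p cosθ / (4πσR²)` exactly and serves as
  the independent oracle for the layered solver.

* **Concentric shells (brain/skull/scalp).** Default relative radii
  (0.87, 0.92, 1.0) of a 92 mm scalp sphere and conductivity ratios
  (1, 0.0125, 1). For each spherical-harmonic degree *n* the interface
  conditions (continuity of potential and radial current; no current
  through the scalp) give a small linear system whose solution yields a
  surface transfer coefficient `t_n`; the potential is the `t_n`-weighted
  Legendre series of the source expansion. The series is truncated at
  `n_terms = 100`: with the default 10% depth margin the deepest-to-most-
  superficial sources all converge far below 1e-8 relative (checked by a
  60-vs-120-term test). With equal conductivities the solver reduces to the
  homogeneous closed form at machine precision.

* **Boundary elements (optional).** For triangulated nested surfaces a
  constant-collocation double-layer BEM is provided: van Oosterom–Strackee
  solid angles, per-row correction so each observation point's own surface
  subtends exactly 2π, deflation of the additive-constant null space, and
  smooth evaluation at electrodes pulled just inside the outer surface.
  Gain columns are returned zero-mean (noted in provenance) because the
  deflation fixes the free constant arbitrarily. Against the analytic
  shells at 642 vertices/layer the solution correlates > 0.999 per dipole
  with amplitudes within ~3%, and refinement reduces the error
  monotonically. The plain collocation BEM (no isolated-skull treatment)
  is accurate enough here because test sources keep a depth margin; very
  superficial sources under a 1:80 skull contrast would need finer meshes.

## Montages

All layouts live on the scalp sphere. The 10/20 (21-channel) and 10/10
(71-channel) systems follow the classical arc construction: vertex at the
pole, nasion/inion/preauricular points on the equator, outer ring at 72°
polar angle, inner electrodes by great-circle interpolation of the coronal
chains. The dense 128/256-channel layouts are Fibonacci lattices on a
spherical cap (geodesic-net-like equal-area coverage) plus an exact vertex
electrode and two mastoid channels.

Two geometric choices matter and were made deliberately: angular coverage
must grow with channel count across the whole family, because the
average-reference error is dominated by coverage, not density. Hence the
10/10 lower (9/10) chain sits on the below-ear mastoid ring (100° polar),
and the dense caps extend to 115° (128 channels) and 126° (256 channels),
mirroring how real high-density nets extend further down the head as the
count grows. Mastoid channels sit at (100°, ±108° azimuth) in every
layout.

**Position noise.** `random` mode displaces each electrode by an isotropic
Gaussian vector with expected norm equal to the requested magnitude;
`systematic` mode displaces all electrodes by one shared random vector of
that norm. Both re-project onto the scalp (electrodes physically sit
there); re-projection keeps the tangential part of the displacement, so
the net random displacement has expected norm (π/4)·magnitude. Rigid
(Kabsch) alignment against a headshape recovers pure rigid misplacements
exactly; for the re-projected shared shift the residual field is a
tangential gradient field, which rigid motions can only partly absorb
(~40% displacement reduction) — this partial correction is precisely what
the corrected-vs-uncorrected contrast in the shift study measures. A
consequence of modelling the systematic shift as one coherent vector is
that it perturbs the REST operator much less than random scrambling of the
same magnitude: the corrupted leadfield is close to that of a rigidly
moved head.

## Re-referencing operators

All four are N×N matrices `R = I − K` and annihilate constants (rows sum
to zero, asserted at construction): vertex reference (CzR), linked
mastoids (LMR, K has 0.5 in the two mastoid columns), average reference
(AR, K = 1/N), and REST,

    R_REST = G · pinv(G_AR) · R_AR,   G_AR = R_AR · G,

i.e. minimum-norm equivalent sources on a brain grid estimated from the
demeaned leadfield and re-projected through G to obtain an
infinity-referenced map. The pseudo-inverse zeroes singular values below
`pinv_tol = 1e-8` of the largest. The REST source grid defaults to a
10 mm lattice over the brain compartment (M ≈ 1500, 3M ≫ N), the
underdetermined regime of practical REST; the exact-recovery oracle
(gRE < 1e-8 for on-grid sources) instead uses a coarse grid with 3M < N
where the demeaned leadfield has full column rank.

With a near-full-rank `G_AR`, REST's response to a non-brain artifact
pattern is the demeaned pattern plus an estimated reference offset, so its
artifact attenuation tracks AR's for smooth patterns but can exceed 1 for
random ones; stronger pseudo-inverse truncation (as with ill-conditioned
realistic leadfields and aggressive default tolerances) makes REST more
suppressive. This sensitivity to `pinv_tol` is inherent to REST and the
reason the tolerance is exposed.

## Metrics

Global relative error `gRE = ‖V_reref − V‖ / ‖V‖` against the
reference-free truth map (Frobenius norms for multi-sample maps); signed
channel-based error `cRE(i) = (V_reref(i) − V(i)) / V(i)` with channels
below 1e-3 of the map maximum excluded (the ratio is meaningless near
nulls), averaged over geometric regions (frontal: y > 0.25R; occipital:
y < −0.25R and z < 0.5R; central-parietal: remaining superior channels).
Mean signed cRE is heavy-tailed across dipoles — regional means are stable
only for the central-parietal region in this geometry. The artifact
reduction index `ARI = mean((Ra)²)/mean(a²)` is computed on the spatial
pattern alone; linearity makes the artifact time course irrelevant. For AR
it has the closed form `1 − N·mean(a)²/Σa²`, used as an exact test.

Artifact patterns: a frontal-pole-centred Gaussian patch
`exp(−(Δ/σ)²)` of angular distance Δ with σ = 25° (ocular-like; its AR/REST
attenuation scales ≈ σ², about 11% at the default width), a homogeneous
pattern (power-line-like; eliminated exactly by any constant-annihilating
operator), and i.i.d. Gaussian channel noise (seeded).

## Experiments

Four seeded drivers return tidy long-format tables (one row per condition
× dipole × realization × metric) with mean ± standard error (sd/√n)
summaries. Study conditions follow the defaults: 100 dipoles uniform over
the brain ball minus a 10% depth margin, x/y/z unit orientations, one time
sample per map (the operators are time-invariant), the 256-channel montage
for single-montage studies, shifts of 1/2/4/8 mm with 10 realizations.
The shift study compares REST built from perturbed-montage leadfields
against truth maps at the *unperturbed* electrodes — position noise
corrupts the model, not the physical recording. Tests run the same drivers
at reduced size (30 dipoles, 15–25 mm REST grids, 3 realizations), chosen
so the qualitative contrasts are stable across seeds. The truth model
defaults to the concentric shells; a realistic-head truth or REST model is
used by importing an externally computed leadfield (`--import-leadfield`),
since no realistic subject geometry ships with the package.

## Synthetic oddball ERP

Rare-condition averages contain a P300-like component: a radial dipole at
(0, −0.45, 0.55)·brain radius (posterior parietal), forward-projected,
with a Gaussian time course (SD 60 ms) whose peak latency is drawn per
subject uniformly from 325–470 ms (snapped to the sample grid so the
sampled peak equals the nominal amplitude, 10 µV at the peak channel by
default); frequent averages contain only noise (i.i.d. Gaussian, 1 µV,
emulating residual noise of cleaned averages). Data are emitted in a
physical vertex reference by subtracting the Cz row of the
infinity-referenced signal-plus-noise, as a vertex-referenced amplifier
would. The generator omits real-data stages that standard tooling handles
(filtering, ICA cleaning, photogrammetric alignment) and contains no trial
count, overlapping components, or correlated noise — so passing tests
demonstrate the correctness of the measurement/statistics chain, not
robustness to real preprocessing.

Measurements: per-channel maximum amplitude and latency in 200–500 ms,
pre-stimulus RMS in −200–0 ms, ROI means over the parietal group
(y < 0, z > 0.4R; 47 channels on the 128-channel layout), across-subject
two-sided Wilcoxon signed-rank test reported as the plain normal
approximation z = (W⁺ − μ)/σ without tie correction (so the all-positive
extreme matches its closed form), plus the Spearman correlation of paired
values. Comparisons with fewer than five subjects are flagged.

## Numerical choices and degenerate inputs

Pseudo-inverse cutoff 1e-8 (relative); series truncation 100 terms; depth
margin 10% of the brain radius (keeps near-surface singularities out of
gRE averages and series convergence fast); zero-magnitude perturbations
return the montage unchanged; zero paired differences are dropped from the
signed-rank test and an all-zero case is reported as degenerate rather
than tested; channels with near-null truth potentials are excluded from
cRE with their count reported; all-zero truth maps or artifact patterns
raise an undefined-metric error.

## Known limitations

Spherical geometry only (no FEM/FDM, no skull anisotropy); idealized
montage families rather than vendor digitizations; plain collocation BEM
without the isolated-skull approach; artifact injection is purely spatial;
the ERP generator produces already-clean averages. Absolute error levels
therefore differ from realistic-geometry values (e.g. AR error on the
256-channel montage is ~15% here versus ~5% with a realistic head), while
orderings and trends — REST < AR < LMR/CzR, errors falling with montage
density, REST's dependence on head model and electrode-position accuracy,
and the artifact signatures — are reproduced.
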