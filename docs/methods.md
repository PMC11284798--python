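# Methods

`membuckle` analyzes *buckled* lipid bilayers: elongated membranes compressed
along one box axis until they adopt a periodic, nearly sinusoidal standing
wave.  Because the deformation is uniform along the short axis (`y`), a single
trajectory exposes a continuum of membrane curvatures, and every local
property can be resolved as a function of the signed local curvature `K`
instead of being averaged over the whole patch.

## Surface model

Every surface of interest — the bilayer midplane (traced by the terminal,
non-hydrogen acyl-chain centers), the two leaflet surfaces (traced by the
phosphorus markers), and any per-atom surface — is modeled per frame as a
periodic harmonic series in the `xz`-plane:

    Z(x) = A0 + Σ_{n=1..N} A_n sin(2πn (x − x_n) / L_x),      N = 6 by default.

The exact parameterization of this series (presence of the offset `A0` and of
per-harmonic phases `x_n`) is a reconstruction from the parameter set the
method is described with; it is fitted by re-expressing each harmonic as
`a_n sin + b_n cos`, which makes the problem linear with a unique global
optimum, and converting back under the gauge `A_n ≥ 0`, `x_n ∈ [0, L_x/n)`.
Signed curvature is analytic, `K = Z'' / (1 + Z'²)^{3/2}` — negative at a
crest, positive in a trough — and local unit normals are
`(−Z', 1)/√(1+Z'²)`.  Curves are discretized into points spaced by a constant
arc length `δs = 0.1 nm` (composite Simpson quadrature of `√(1+Z'²)` on an
8192-point grid, inverted by monotone interpolation with one Newton polish;
total length matches adaptive quadrature to ≲1e-10 relative, consecutive
chords to ≲1e-6 nm).

Per-leaflet quantities use a fixed sign convention: the leaflet curvature is
`−K_mid` for the upper leaflet and `+K_mid` for the lower, so `K > 0` wherever
the lipid–water interface is convex.  Opposite leaflets at the same position
carry curvatures of equal magnitude and opposite sign.

## Curvature-resolved observables

* **Thickness `D_PP`** — both leaflet discretizations are swept; for each arc
  point the closest point of the opposing leaflet curve is found (discrete
  scan refined by a bounded vectorized ternary search on the continuous
  curve).  The segment length is the local thickness, assigned to the
  midplane curvature at the arc point nearest the segment.  Segments more
  than 80° away from the local leaflet normal, or of vanishing length, are
  excluded and counted (the construction presumes quasi-parallel curves).
* **Bilayer / monolayer area density** — terminal tail centers are binned to
  their nearest midplane arc points; each arc bin covers `δS = L_y·δs` and
  counts are normalized by centers-per-lipid.  The bilayer profile pools both
  leaflets against `|K|`; monolayer profiles keep leaflets separate and pool
  after the leaflet sign transform.  Binning the core density at the midplane
  makes the pooled bilayer profile exactly flat for a laterally uniform
  membrane, while the per-leaflet response measures the pivotal height
  (see below).
* **Interface area per lipid** — phosphorus markers are binned to their own
  leaflet's arc points, `APL = δS / (mean markers per bin)`, the reciprocal
  taken per trajectory block so the mean and its error come from the same
  estimator; bin curvature is the midplane curvature at the midplane point
  nearest the bin center, leaflet-signed.
* **Hydration** — waters strictly within 0.3 nm (the first minimum of the
  water–lipid RDF; the boundary itself is measure-zero and excluded) of a
  lipid's head or terminal-tail heavy atoms, counted once per lipid using
  x/y-periodic minimum-image distances (periodic KD-tree with candidate
  re-checking).  Each lipid is labeled with the curvature at the midplane
  point nearest its phosphorus marker.
* **Order parameters** — `S = ⟨(3cos²θ − 1)/2⟩_K` of chain bond vectors
  (C–C or C–H, defined by the role map) against the local normal at the
  lipid's midplane point.  Two algebraically equivalent evaluation paths are
  implemented (direct dot product, and rotation of each lipid's frame about
  `y` by the angle between the local normal and `z`) and asserted to agree.
* **Lateral diffusion** — markers are projected per frame onto their
  leaflet's arc-length coordinate; signed displacements are accumulated
  incrementally with minimum-arc increments (immune to periodic wrap over a
  track).  Tracks of 10 ns are opened at a configurable origin stride, each
  labeled by the leaflet-signed curvature at its origin; `⟨δs²⟩ = 2Dt` is
  fitted over lag times 5–10 ns with a free intercept (which absorbs the
  `δs²/12`-scale projection quantization), per curvature bin and per block.
  `D` is reported in nm²/ns (×100 = 10⁻⁷ cm²/s).
* **Pivotal plane** — for each tracked center at reference height `z_A` above
  the midplane, a surface is fitted per frame to that center's positions, the
  center's area density along its own surface is binned by leaflet-signed
  curvature and normalized to its `K = 0` bin, and a slope `a_A` is fitted
  over `K ∈ [−0.15, 0.15] nm⁻¹`.  Parallel-curve geometry gives
  `ρ_A ∝ 1 + (z_p − z_A)K` exactly to first order, with the multiplicative
  higher-order corrections leaving the root unchanged, so the zero crossing
  of the ordinary least-squares line through `(z_A, a_A)` is the pivotal
  height `z_p`.  Its uncertainty comes from repeating the line fit per block.
  `2·z_p/D_PP` is ½ for a uniform elastic sheet and ≈0.67 for phospholipid
  monolayers.  `z_A` values are flat-geometry reference inputs, not inferred
  from the buckled run.
* **Curvature sorting** — for a two-component mixture, the enhancement ratio
  `ER(K) = ln[(ϕ_b^u/ϕ_a^u)/(ϕ_b^l/ϕ_a^l)]` compares the two leaflets at the
  same membrane location (leaflet curvatures `+K` and `−K`).  Under a
  Helfrich-type per-lipid energy `½ M_i (K − K0_i)²` with ideal mixing
  entropy, ER is exactly linear with slope `J_ab = 2(M_b K0_b − M_a K0_a)/kBT`
  — the normalizers cancel in the log odds ratio, which is why this form is
  preferred (a simple `ln(ϕ_b^u/ϕ_b^l)` variant is available).  ER is
  computed per block from species counts, fitted by inverse-variance weighted
  least squares, and inverted for the spontaneous curvature
  `K0_b = (J_ab/2 + M_a K0_a)/M_b` with per-lipid moduli `M = κ·S` (monolayer
  bending modulus κ in kBT, per-lipid area S in nm²).  κ is force-field and
  composition dependent and has no safe default; it is a required input.

## Statistics

All profiles share one estimator: samples `(K, value, t)` are histogrammed
into curvature bins (default width 0.02 nm⁻¹ over ±0.2 nm⁻¹), the trajectory
time range is split into four equal blocks, the reported mean is the mean of
per-block means and the SEM is the standard deviation of block means over
`√4` — robust to temporal correlation, unlike per-sample standard errors.
Bins with an empty block are flagged `sem_reliable = False`; empty bins are
NaN, never zero.  Profiles normalize to their `K = 0` bin by ratio (most
observables) or shift (thickness), with first-order SEM propagation; the
normalized profile retains its reference so denormalization is exact.

## The synthetic generator

Estimators are validated by parameter recovery on synthetic trajectories with
planted ground truth, not against molecular dynamics (whose headline numbers
require multi-microsecond simulations).  The generator emulates the study
conditions: a 24 × 7.5 nm box, a single dominant buckle harmonic of 3 nm
amplitude (|K| up to ≈0.21 nm⁻¹, arc excess ≈15% — between the plotted ±0.2
range and the ~0.2 compression factor of the simulated systems), thickness
3.9 nm, APL 0.65 nm², head hydration 7 waters/lipid, pivotal heights 1.31 nm
(AA-like, 0.67 of the monolayer) or 0.98 nm (CG-like elastic sheet), and
diffusion 6×10⁻³ (AA-like) or 5×10⁻² nm²/ns (CG-like) — a dynamic range
mirroring the ~5× gap between resolutions.

Lateral positions are placed on a chosen base surface (pivotal surface,
interface, or interface weighted by a prescribed `APL(K)`) by inverse-CDF
sampling of the arc measure, stratified on a jittered grid in the placement
coordinate × `y` (uniform marginals, suppressed close pairs).  All molecular
sites are offsets along the local midplane normal, so parallel-curve geometry
yields closed-form expectations for every density observable.  Chain vectors
are drawn from a Maier–Saupe axial distribution `p(cosθ) ∝ exp(λP2)` with λ
solved from the requested `S(K)` (numeric inverse CDF, quantized to 1e-3 in
S).  Composition is drawn per frame from the Gibbs weights
`P(b|K) ∝ ϕ̄_b exp(−M_b(K−K0_b)²/2)`, making the planted log-odds law exact.
Dynamics, when enabled, is Brownian motion in the placement coordinate
(periodic, as the arc has no boundary) with per-frame step `√(2D·dt)`.

First-shell waters are Poisson-placed around each lipid's own head (or
terminal-tail) atoms and rejection-resampled out of every *other* lipid's
cutoff shell, so the planted per-lipid counts are realized exactly.  Real
membranes do share shell waters between neighbors; the generator excludes
sharing deliberately so the planted count is the unambiguous ground truth.

What the generator does **not** emulate — and hence what passing tests do not
establish about real membranes: thermal undulations of the surface shape
(frozen per run; per-frame refitting is still exercised through placement and
jitter noise), lipid flip-flop, coupling between composition and mechanics,
atomistic packing correlations, explicit solvent structure, and any force
field's actual parameters.  The tests establish that *given* data with known
curvature dependences, the estimators recover them.

## Numerical choices and degenerate inputs

Closest-point and nearest-arc-point queries break ties to the lowest index;
curvature bin edges follow `numpy.digitize` (left-closed).  Surface fitting
requires ≥ `2N+1` points and rejects degenerate designs (all x equal).
Leaflet assignment falls back to the terminal-center offset when a marker
lies exactly on the midplane and errors if still ambiguous.  The ER fit
drops bins with zero counts in any block (with a warning) and requires three
usable bins.  The pivotal line fit errors when the slope of `a(z)` vanishes
(no crossing in range).  Diffusion requires ≥3 lag points in the fit window
and drops tracks whose lipid changes leaflet.

Problem sizes in the shipped tests (hundreds of lipids per leaflet, tens of
frames, 10 seeds per planted pivotal depth, 1000 diffusion walkers) were
chosen so each recovery sits several standard errors inside its tolerance
while the whole suite stays at desk scale; estimator uncertainties shrink as
`1/√N` and real analyses with longer trajectories will do better.

## Known limitations

* Surface-fit noise leaks into curvature labels: on very small systems the
  N = 6 fit overfits lateral density fluctuations, producing spurious |K| up
  to ~0.03 nm⁻¹ on a flat membrane and percent-level bin-assignment biases.
  This shrinks as 1/N_points and is negligible at MD system sizes.
* Because the generator's geometry is frozen, curvature bins capture a fixed
  set of arc points; profile values carry a reproducible ±1–2% bin
  quantization wobble that block SEMs (which measure temporal variance)
  cannot see.  Contrasts between runs on the same geometry are unaffected.
* The analysis is strictly 1D-periodic in x: no xy-dependent (2D) surface
  fitting, no reconstruction across the z boundary, no rotational or 2D
  diffusion tensors, and no stress-profile (neutral-plane) calculation.
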