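# Methods

`bonesim` simulates the adaptation of a small 2D patch of trabecular bone to
its mechanical environment.  The model couples three ingredients: a linear
plane-stress finite-element solve on a voxel grid, an osteocyte
mechanosensing field that turns local strain-energy density (SED) into a
remodeling stimulus at the trabecular surface, and a mechanostat rule set
that converts the stimulus into stochastic osteoclastic resorption and
deterministic osteoblastic formation.

## Mechanical model

The tissue occupies a 2 mm x 2 mm region (thickness 0.02 mm) meshed with
80 x 80 four-node bilinear plane-stress elements, framed by side plates two
elements thick on every edge.  The plates are held at full density, never
remodel, host no osteocytes, and serve only to even out edge deflections.
Each element carries a relative mineral density m in [0.01, 1.0] (0.01
encodes resorbed/void tissue) and a Young's modulus

    E(m) = E_max * m^r,      E_max = 500 MPa, r = 3,

with Poisson's ratio nu = 0.3 (not specified by the source model; 0.3 is the
standard choice for bone-tissue continuum models, and it is configurable).
The far-field load is a uniform stress with principal values +sigma
(tension) and -sigma (compression), the tensile axis at phi = 30 degrees to
the horizontal, applied as consistent edge tractions.  The cyclic 0-2 MPa
loading is represented by a single static solve (the stimulus is defined
through static FE analysis); rigid-body motion is removed by pinning one
corner node and holding an adjacent corner vertically, so the tractions, not
the supports, carry the load.  Per element the solver reports the centroid
strain tensor, the SED (1/2 sigma:eps, MPa), and the maximum absolute
principal strain, the scalar measure used for the reported "average bone
strain" (the source model never names its strain measure; ratio-based checks
are insensitive to this choice).

The element stiffness is exact for this discretization (2x2 Gauss on an
affine square element integrates the quadratic integrand exactly) and is
verified in the tests against a symbolic integration and an independently
coded dense assembly.

## Mechanosensing

One osteocyte sits at the center of every bone-filled element (m strictly
above the 0.01 floor), i.e. 1600 cells/mm^2 on a filled mesh.  The stimulus
at a surface element centroid x is

    P(x) = sum_i mu_i R_i exp(-d_i(x)/D),

with mu_i = 1 (mechanosensitivity is introduced by the model but given no
value), R_i the host-element SED, and D = 100 um (the influence decays to
0.36788 at d = D).  For performance the sum is truncated at 5D, where the
weight is below 0.7%; an exact-summation switch exists and the truncated
grid-convolution path is tested against an explicit double loop.  Near the
mesh edge the osteocyte neighborhood is geometrically truncated, so raw
stimuli are multiplied by a correction factor S_ref/S(x), where S(x) is the
total influence weight reaching x on a fully filled mesh and S_ref its value
at the mesh center.  The exact factor used by the original ANSYS
implementation is not documented; this normalization is a stand-in with the
right limits (1 at the center, largest at corners, ->1 as D->0).

## Remodeling rules

Four SED thresholds (MPa) bound the mechanostat zones: K_RD = 0.0357
(resorption drift), K_OB = 0.0714 (formation threshold), K_AD1 = 0.0918 and
K_AD2 = 0.1122 (adaptive/lazy zone; K_AD2 doubles as the formation-drift
threshold).  A surface site is a remodelable bone element with at least one
edge-sharing void neighbor (4-connectivity matches the quadrilateral faces);
side plates never count as void.

Osteoclast activation per surface site and iteration is a Bernoulli draw
with probability

    p(P) = p_max / (1 + exp(a (P - b)))   for P <  K_AD1   (disuse)
         = c                              for K_AD1 <= P <= K_AD2
         = d P^2 - g P + h  (clamped <=1) for P >  K_AD2    (overload)

with p_max = 0.2, a = 90, b = K_OB, c = 0.0275, d = 176.0, g = 19.506.  The
closed forms are reconstructed from the reference constants and continuity
conditions: the sigmoid meets c at K_AD1 (0.0275 exactly), and h (~4.37e-4)
is fixed so the quadratic equals c at K_AD2, which reproduces the reference
anchors 0.2505 at 0.122436 MPa and 1.0014 at 0.149 MPa within rounding, and
a mean probability over [0, 0.149] MPa of 0.2147 vs. the reference value 0.2148.

An activated site resorbs the fixed quantum r_oc = 0.38 (derived from a
1.42e-2 mm^2 BMU trench over a 60-day resorption period against the
6.25e-4 mm^2 element area; the period is folded into the quantum, not
simulated as a lag) and osteoblasts form

    r_ob(P) = 0                            P <= K_OB
            = tau1 (P - K_OB)              K_OB < P < K_AD1
            = r_oc                         K_AD1 <= P <= K_AD2
            = r_oc + tau2 (P - K_AD2)      P > K_AD2,

with tau1 = r_oc/(K_AD1 - K_OB) ~ 18.63 MPa^-1 from continuity and
tau2 = 1 MPa^-1.  Formation is coupled to activation (it refills the
activated site), which is the only reading that makes the adaptive zone
mass-neutral; the overload branch keeps r_ob continuous at K_AD2 and yields
net gain.  Sites not visited by osteoclasts change only through the
formation drift of modeling, tau2 (P - K_AD2) above K_AD2; no formation is
assumed for quiet sites between K_OB and K_AD2.  Density updates are clipped
to [0.01, 1.0] (a passage elsewhere in the source prints "0.01 and 0.1",
treated as a typo).  The menopause mechanism scales all thresholds by a
factor s (both curves are evaluated at P/s), moving the activation curve
rightward.

## Iteration loop and scenarios

One iteration = one activation/formation epoch (no calendar time claimed):
FE solve at the scheduled load -> refresh osteocyte SED -> detect surface
sites -> accumulate and edge-correct stimuli -> one uniform draw per site in
row-major order -> density update -> metrics row (bone mass, % change,
volume fraction = mean m over the remodelable region, average bone strain
over elements with m >= 0.5, site/activation counts).  A named seeded
generator (`numpy.random.default_rng`) makes runs bit-reproducible.

Scenario presets applied to a homeostatic start: disuse (load factor falling
linearly from 1 to B = 0.8; the reference implementation documents the schedule only as a figure,
so the shape is pluggable and linear by default), overload (1.2), artificial
strut disconnection (listed or auto-selected elements set to the density
floor), load rotation (phi 30 -> 0 degrees), physiological +/-8% (1.08 /
0.92), and menopause (threshold scale 1.2 combined with the 0.92 load).
Scenario length defaults to 500 iterations.

## Study conditions and calibration

Two conditions are fixed by the package itself rather than the source
model:

* **Reference load magnitude.**  The reference parameter set is not
  self-consistent with a 2 MPa far-field load: summing the influence
  function over the default osteocyte lattice gives a total center weight of
  ~100, so even a fully mineralized plate would carry an interior stimulus
  of ~1 MPa, an order of magnitude above K_AD2 - permanent overload in
  which no homeostasis can exist.  (The original homeostatic architecture
  was produced by a different, external remodeling model.)  The package
  instead applies the model's own stated calibration - the reference
  stimulus is the average of K_AD1 and K_AD2 - to its stated initial
  condition m(x, t0) = 0.7: `calibrate_load_magnitude` solves
  S_c sigma^2 (1 + nu) / E(m0) = (K_AD1 + K_AD2)/2 for sigma, giving
  ~0.37 MPa on the default mesh (the value adapts to mesh resolution
  through S_c).  The 2 MPa figure remains the `LoadSpec` default for pure
  FE work; the strain anchors are normalized by strain and insensitive to
  the magnitude.
* **Bootstrap porosity seed.**  Surface remodeling is inert on a void-free
  plate (no bone/void interface exists), so the bootstrap nucleates 5% of
  remodelable elements at the density floor (seeded RNG) before
  equilibrating under the reference load until the trailing 100-iteration
  relative mass change drops below 0.5% (max 2000 iterations).

Under these conditions the bootstrap settles at a volume fraction of ~0.67
(the reference architecture had 0.613) and an average bone strain of
~3100 ue (reference: 1041 ue; the discrepancy is inherited from the modulus
/ load calibration above and does not affect the ratio-based strain
anchors).  The 500-iteration scenario responses at the default scale are
overload +7.4%, disuse -11.8%, phys +/-8%: +2.8% / -1.8%, menopause -11.5%
(reference: +16.45%, -10.48%, +3.12%, -1.33%, -7.08%) - the right zones,
ordering and magnitudes, though not the reference point values, which
depend on the external bootstrap model and undocumented run lengths.

## Numerical choices

* Sparse Cholesky-like ordering: SuperLU with MMD-on-A^T+A ordering; the
  system retains the density floor 0.01 (modulus contrast 1e6), which the
  direct factorization handles without special casing.
* Stimulus convolution: FFT convolution with the truncated influence
  kernel; negatives from round-off are clipped at zero.
* Activation draws are consumed in deterministic row-major site order, so
  identical seeds yield bit-identical histories.
* Degenerate inputs: all-void fields have no surface sites and freeze; a
  zero reference mass, empty bone-element averages and invalid stimulus
  intervals raise errors rather than returning NaN.
* The quadrature mean of p(P) is cross-checked in-function against the
  piecewise closed form (sigmoid antiderivative via logaddexp; clamp root
  from the quadratic formula) and must agree to 1e-6.

## What the synthetic architectures do and do not show

Fixtures (uniform plate, struts, lattices, random porous fields) and the
self-bootstrapped homeostatic state exercise every code path offline, but
they are not micro-CT architectures: the bootstrapped state is a porous
plate that is nearly isotropic (its orientation tensor is degenerate), its
surface density is lower than real trabecular bone, and plate-rim shielding
by the stiff side frame depresses the stimulus of rim sites (visible as a
slow rim erosion in long runs, and dominant on meshes much coarser than the
default).  Passing tests therefore demonstrate the mechanostat feedback
logic - zone-dependent mass responses, error-correcting strain trends,
determinism - not morphological fidelity to real trabeculae.

## Known limitations

* Only bone elements remodel; void elements never re-mineralize, so the
  bone footprint cannot expand beyond its initial support.  Adaptation acts
  by densifying or resorbing existing bone, which bounds overload gains by
  the available surface headroom and makes load-rotation realignment weak.
* The +/- biaxial load makes the SED field exactly invariant under a
  90-degree rotation, so trabecular orientation is meaningful only modulo
  90 degrees (`fabric_angle_mod90`); "alignment with the tensile axis"
  cannot be distinguished from alignment with the compressive one.
* No pathologic-overload zone, microdamage field, BMU lag, cellular
  accommodation, 3D extension, or calendar-time calibration; the disuse
  schedule's exact shape and the reference iteration counts are
  unknown, so quantitative agreement with the reference simulation
  percentages is not claimed.
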