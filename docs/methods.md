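# Methods

## The model

`pihna` integrates a reaction–diffusion model of glioblastoma growth with
five coupled fields on a radial grid, assuming spherical symmetry:
normoxic tumour cells *c*, hypoxic tumour cells *h*, necrotic debris *n*,
vasculature *v* (treated as a cell population occupying carrying
capacity), and a generic diffusible angiogenic factor *a* (a VEGF-like
signal in arbitrary concentration units scaled so that the
vessel-proliferation half-saturation is ≈ 1).

With T = (c+h+n+v)/K the occupied fraction of the carrying capacity K and
V = v/(c+h+v) the *relative vascular density* (the nutrient-sufficiency
signal: ≈ 1 in normal tissue, small inside a packed tumour), the
equations are

    ∂c/∂t = ∇·(D_c (1−T) ∇c) + ρ c (1−T) − β g_ch(V) c + γ g_hc(V) h
    ∂h/∂t = ∇·(D_h (1−T) ∇h) + β g_ch(V) c − γ g_hc(V) h − α_n g_hn(V) h
    ∂n/∂t = α_n g_hn(V) h
    ∂v/∂t = ∇·(D_v (1−T) ∇v) + μ a/(a+a_m) v (1−T) − η a²/(a²+a_d²) v
    ∂a/∂t = ∇·(D_a ∇a) + ξ_h h/K + ξ_c c/K − λ a − ω (v/K) a
            − q μ a/(a+a_m) (v/K)(1−T)

Normoxic cells invade and divide; hypoxic cells only move; necrosis is
the terminal fate of hypoxia.  All conversions appear pairwise with
opposite signs, so the logistic term in the *c* equation is the only net
source of tumour cells — a bookkeeping invariant the test suite checks
numerically.

The oxygenation switches are logistic gates in V centred on the
vascular-sufficiency threshold V_ch with width w:
g_ch = 1/(1+e^{(V−V_ch)/w}) (conversion to hypoxia, on below threshold)
and its complement g_hc (recovery, on above threshold); necrosis ramps in
linearly below the lower threshold V_hn.  The smooth pair makes the
oxygenation *balance point* respond to the two conversion rates, which is
how anti-angiogenic therapy shifts the effective sufficiency threshold
(below).  Setting V_ch = 0 disables the hypoxia pathway entirely, which
reduces the model to proliferation–invasion growth — the Fisher–KPP
limit with asymptotic front speed 2√(Dρ), used as a structural test.

Vasculature proliferates where angiogenic factor and free room are
available, and regresses where the factor is persistently high (immature,
leaky vessels), with a cooperative (Hill-2) dependence so that the rim's
modest factor levels leave vessels intact while the core's high levels
collapse perfusion.  This closes the central feedback loop of the model:
packing → vessel loss → hypoxia → strong factor production (ξ_h ≫ ξ_c) →
further vessel destabilisation → necrotic core, with an angiogenic,
normoxic rim.

## Imaging observables

The T1Gd (contrast-enhancing) abnormality is the outermost radius where
total malignant density c+h+n ≥ 80% of K; the T2/FLAIR abnormality uses
16% of K.  Necrotic inclusion and vascular inclusion in the imaging total
are configurable flags (defaults: necrotic in, vasculature out).  Cell
counts are spherical integrals 4π∫u(r)r²dr computed by the composite
trapezoid rule applied to the integrand g(r)=u(r)r² sampled at the nodes;
because g is interpolated linearly, counts are exactly additive over
radial shells split at arbitrary radii — which makes resection
bookkeeping (pre = post + removed) exact rather than approximate.

## Therapy operators

**Anti-angiogenic therapy** (bevacizumab-like) is a pure parameter
transformation active during the treatment window (default 42 days):
every angiogenic-factor half-saturation ("action") constant — vessel
proliferation a_m and vessel destabilisation a_d — is multiplied by an
action factor (default 100: more factor is needed for the same action),
and the conversion pair is adjusted (h→c rate ×2, c→h rate ×0.5),
which shifts the effective sufficiency threshold down by w·ln 4: the
normalized vasculature supports normoxia at lower relative density.  The
identity effect (all multipliers 1) leaves the parameters bit-identical.

**Gross total resection** zeroes c, h and n at every node inside the
T1Gd radius, leaving vasculature, factor and everything outside
untouched.  A tumour that nowhere reaches 80% of K is a logged no-op.

**Radiotherapy** applies the whole fractionated linear-quadratic course
at one instant (no interfraction kinetics): per node, survival is
S = exp(−n(αd+βd²)/OER_e) with d = 2 Gy, n = 30, α/β = 10 Gy.  The
radiosensitivity α is a linear function of the patient's net
proliferation rate, α = slope·ρ + intercept; the coefficients are
*required configuration with no code default*.  The shipped configuration
uses slope 0.003 Gy⁻¹·yr and intercept 0.025 Gy⁻¹, which spans
α ≈ 0.05–0.27 Gy⁻¹ over the cohort's ρ axis, the patient-specific range
reported for glioblastoma.  The effective oxygen-enhancement ratio per
node is the viable-compartment-weighted mean
OER_e = (c + OER_max·h)/(c+h), exactly 1 in purely normoxic and
OER_max = 3 in purely hypoxic tissue; necrotic cells neither weight the
mean nor absorb kill (they are already dead).

## Virtual cohort and experiments

The cohort is a deterministic Cartesian grid of 11 net proliferation
rates ρ ∈ [8.3, 83] yr⁻¹ and 13 net invasion rates D ∈ [1.43, 143]
mm²·yr⁻¹, both log-spaced with endpoints included, evaluated at three
treatment-start sizes (T2 radius 1.5, 2.5, 3.5 cm).  The ρ axis spans one
decade (exact 10^0.1 steps) anchored at the aggressive preset
(D = 305 mm²·yr⁻¹, ρ = 83 yr⁻¹); the D axis spans two decades.  The axis
bounds are configurable and recorded in every run manifest.  The choice
of a one-decade ρ axis follows a travelling-wave argument: the 80%
contour trails the 16% contour by ≈ 3.5·√(D/ρ)·(fill-time factor) mm, so
kinetics with D/ρ ≳ 19 mm² cannot yet carry an enhancing core at a T2
radius of 1.5 cm, and resection of such tumours would be a universal
no-op; with ρ ≥ 8.3 yr⁻¹ every grid member retains a core (max
D/ρ = 17.2 mm²).

Experiments grow each patient from a 1-mm, 2%-of-K normoxic seed until
the T2 radius crosses the start size (event-detected; the returned state
matches the target within 0.1 mm), then:

* **Experiment 0** records composition time-series (counts, fractions,
  radii) for treated and untreated arms of one patient.
* **Experiment 1** computes R1 = H(t₁) − H(t₁+14 d) under therapy;
  negative R1 means hypoxia is still accumulating two weeks in.
* **Experiment 2** computes R2 = H_control(t₁+14 d) − H_treated(t₁+14 d);
  both arms fork from the identical state, so R2 isolates the therapy
  effect (the untreated virtual control).
* **Experiment 3** irradiates the treated arm at the 14-day state (the
  anti-angiogenic course still in force; only the instantaneous
  composition enters the kill) and the control arm after 14 untreated
  days, and reports the additional cell kill.
* **Experiment 4** resects at the start size and reports the percentage
  of the hypoxic burden removed.  Rows whose pre-resection burden is
  below one cubic millimetre of packed tumour (≈ 2.4×10⁵ cells, far
  below any imaging detectability) are flagged "no measurable hypoxia"
  rather than contributing percentages computed from numerical noise.

Per-patient growth timeouts or solver failures flag the row and never
abort a sweep.  Everything is deterministic: no randomness exists
anywhere in the study, and rerunning a sweep from the same configuration
reproduces every table cell bit-identically (asserted in the tests).

## Numerics

Method of lines on a uniform radial grid (default spacing 0.25 mm,
domain 100 mm).  Diffusion uses a finite-volume discretisation of the
symmetric spherical Laplacian ∇·(D(1−T)∇u) with zero flux at r = 0 and
r = r_max; the crowding factor at a cell face is the *smaller* of the two
neighbouring cells' free room, clipped at zero, so no flux ever pushes
cells into an already-full cell (a face-averaged factor lets the total
density overshoot K).  Time integration is LSODA with a banded Jacobian
(the five fields are interleaved per node; the widest coupling, a density
at node i against v or n at node i±1 through the shared crowding factor,
gives bandwidth 8).  Tolerances: rtol 10⁻⁵, atol 1 cell·mm⁻³ for the
densities and 10⁻⁶ for the factor.  Small undershoots are clipped at
output; anything below one cell·mm⁻³ negative is an error.  Radius
crossings are located by the integrator's event root-finding on the
interpolated threshold radius.

Internal units are millimetres and days; D and ρ are accepted in the
literature's units (mm²·yr⁻¹, yr⁻¹) and converted with 1 yr = 365 days.

Known resolution limitation: the travelling front is ≈ √(D/ρ) mm wide,
so the sharpest cohort corner (D = 1.43, ρ = 83: ≈ 0.13 mm) is not
resolved at the default step, and its absolute population counts carry a
few-percent discretisation error (counts change ≈ 12% when the step is
halved, versus < 1% for the aggressive preset).  Removal *percentages* —
ratios of hypoxic integrals over the same profile — are much less
sensitive.  The refinement test is therefore scoped to kinetics whose
front the default grid resolves.

## Default constants and what they encode

K = 2.39×10⁵ cells·mm⁻³ (packing density convention of this model
family).  D_h = D (hypoxic cells migrate at the normoxic rate);
D_v = 0.1·D (endothelial sprouts an order slower than the tumour
front); D_a = 3139 mm²·yr⁻¹ (≈ 8.6 mm²·day⁻¹, a VEGF-scale tissue
diffusivity; with clearance λ = 2 day⁻¹ the factor's reach is
√(D_a/λ) ≈ 2 mm, the width of the perivascular destabilisation halo).
Conversion rates: β = 0.02 day⁻¹ (hypoxic conversion; deliberately below
the slowest cohort proliferation rate of 8.3 yr⁻¹ ≈ 0.023 day⁻¹, so
conversion can never outrun core filling and every member forms an
enhancing core), γ = 0.1 day⁻¹ (recovery), α_n = 0.05 day⁻¹ (necrosis).
Thresholds: V_ch = 0.05 with width 0.01 and V_hn = 0.03; with the normal
vascular fraction v₀ = 0.05 (grey-matter blood-volume fraction) the
oxygenation balance pins viable density near v₀(1/V_ch − 1) ≈ 0.95 K,
comfortably above the 0.8 K imaging threshold — placing the pin *below*
that threshold stalls core formation for part of the kinetics grid, which
is how these three constants constrain each other.  Vessel kinetics:
μ = 0.1 day⁻¹ (sprouting), η = 0.12 day⁻¹ with a_d = 3 (destabilisation);
factor production ξ_h = 40, ξ_c = 0.4 a-units·day⁻¹ at full K (hypoxic
cells the dominant source), uptake ω = 1 day⁻¹·K⁻¹, consumption q = 10.

These constants are this package's own reconstruction of the model
family's behaviour, chosen once on the structural grounds above and then
frozen.  Quantities that depend on their exact values — absolute cell
counts, the grid extremum of a bimodal removal distribution — should be
read as model-family-typical rather than as transcriptions; quantities
protected by structure (conversion bookkeeping, OER endpoints, LQ
closed forms, shell additivity, determinism, the Fisher–KPP limit) are
exact or tolerance-controlled and are what the test suite pins down.

## What the virtual cohort does and does not emulate

The cohort is a noise-free grid sweep of two kinetic rates under
spherical symmetry.  It emulates the clinically observed spread of
glioma growth kinetics (two decades of invasiveness, one of
proliferation) and the size heterogeneity at presentation.  It does not
emulate anatomical geometry, patient-to-patient variation in any other
constant, imaging noise or segmentation error, interfraction radiation
kinetics, chemotherapy (absorbed implicitly in the radiosensitivity
map), oedema, or resection cavities' mass effects.  Passing tests
therefore demonstrate internal consistency of the model and operators
under the study's idealisations, not clinical predictive accuracy.
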