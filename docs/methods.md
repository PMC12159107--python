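# Methods

This note records the models behind each module, the defaults and why they
were chosen, the numerical choices that affect results, and what the
synthetic-data tests do and do not demonstrate about real data.

## Scattering profiles and units

A profile is (q, I(q), σ) with q in Å⁻¹ (files declaring nm⁻¹ are converted
on read), I in cm⁻¹ when on absolute scale, and σ a 1-standard-deviation
uncertainty. All analyses assume dilute, monodisperse solutions — the
interparticle structure factor S(q) ≡ 1 — and background-subtracted
intensities. Two-column files get σ imputed as 2% of I and are flagged
(`sigma_imputed`), so downstream fits can treat them as indicative only.
Merging multi-detector-range profiles rescales later segments to the first
by weighted least squares on the overlap window; duplicate q are combined
by inverse-variance weighting with the conservative minimum-σ rule, so a
merge never claims better precision than its best input.

## Scattering-length densities and contrast

Component SLDs are computed from residue-level atom inventories
(`data/residues.json`: 20 amino-acid and 4 deoxynucleotide residues, each
with explicit element counts and a labile-H count covering N–H, O–H and
S–H) and mass densities, ρ = Σb/V with V = MW/(d·N_A). Labile hydrogens
exchange with solvent deuterium at `exchange_fraction × fraction_D₂O`;
the default exchange fraction is 0.5, the value hydrogen–deuterium exchange
measurements support for folded histone complexes, and it is overridable.
Default mass densities are 1.35 g/cm³ (protein) and 1.69 g/cm³ (DNA).

The water endpoints are computed, not copied: H₂O at 1.000 g/cm³ gives
−0.56×10⁻⁶ Å⁻², D₂O at 1.105 g/cm³ gives +6.36×10⁻⁶ Å⁻². A widely quoted
D₂O figure of 6.67 is the deuteron scattering length (6.671 fm) rather
than an SLD; we use the Σb/V value. Solvent SLD is linear in the D₂O
volume fraction, hence every component contrast is linear in fraction D₂O
and match points are roots of a line. At these densities the computed
match points are ≈0.38 (histone octamer), ≈0.56 (DNA), ≈0.45 (nucleosome);
DNA match points near 0.65 quoted elsewhere correspond to higher effective
DNA densities (partial specific volume ≈0.55 cm³/g) and near-complete
exchange — with the densities fixed as above we report the
composition-consistent values rather than forcing agreement.

X-ray contrasts are electron counts per volume minus water's 334 e⁻/nm³:
≈102 e⁻/nm³ for the octamer and ≈193 e⁻/nm³ for DNA at the default
densities, consistent with the usual ~90/~220 figures at the ±20% level
that density/hydration conventions introduce.

Experimental match points come from signed `√(I₀/c)` vs fraction D₂O. The
square root loses the contrast sign, so every split of the
fraction-ordered sequence into a leading-positive/trailing-negative block
is tried and the best weighted line kept; the x-intercept and its
propagated uncertainty are reported, and a fit whose slope is under 2σ is
flagged ambiguous rather than trusted.

## Guinier analysis

Weighted least squares of ln I on q² with σ_ln I = σ/I. The automatic
window starts at the first positive-intensity point, spans roughly the
first half-decay of I(q) initially, and iterates: fit → R_g → largest
window with q·R_g ≤ 1.2 → refit, to 10⁻⁴ relative convergence. When two
adjacent windows alternate under noise the smaller (stricter) one is
taken. Up to three leading points with studentized residuals > 3 are
dropped (beamstop/aggregation guard). Negative intensities are excluded
from the log-space window.

One bias is worth knowing: for a homogeneous sphere the quartic term of
ln I makes a q·R_g ≤ 1.2 Guinier estimate systematically high by
√(1+3cT)−1 ≈ 1.7% (c = 0.00794, T = 1.44). This is a property of the
estimator at that window, not an implementation artefact; recovery on
exact Guinier-law data is at machine precision.

## Indirect Fourier transform P(r)

I(q) = 4π ∫₀^Dmax p(r) sinc(qr) dr is discretised on a ≥100-point r-grid
with p(0) = p(Dmax) = 0 enforced and solved by Tikhonov least squares with
a second-difference (smoothness) penalty. The regularisation weight is
chosen by the L-curve corner (maximum curvature of log-residual vs
log-seminorm over a 41-point α grid spanning 20 decades, α scaled by
trace(AᵀA)/trace(DᵀD)), guarded so a flat L-curve on very clean data can
never select an α that degrades χ² beyond 1.5× the best achievable.
R_g comes from the second moment of p, I₀ from its integral.

The 0–1 quality score is the geometric mean of a fit term,
1/(1 + max(0, χ²_red − 1)), and a smoothness term, exp(−max(0, n_extrema − 1))
with n_extrema the count of interior local extrema of p(r). It is a
documented surrogate for the perceptual quality figures of classical IFT
software; numeric equality with any of them is not claimed. A Dmax below
π/q_min (first Shannon channel unmeasured) sets a feasibility flag. The
Dmax scan recommends the smallest candidate within 2% of the best quality
— the tie-break prefers compactness on plateaus.

## Kratky transforms

Standard (q²I vs q) and dimensionless ((qR_g)² I/I₀ vs qR_g). Maxima are
detected on a 5-point moving average (noise robustness) and refined by a
parabola through the raw values. Reference points: exact Guinier-law data
peak at qR_g = √3 ≈ 1.73 with height 3/e; the analytic homogeneous sphere
peaks at qR_g = 1.61 (the root of x²sin x + 2x cos x − 2 sin x = 0 scaled
by √(3/5)); both sit in the ~1.7 region that signals a compact particle,
while flexible chains rise to a plateau with no return to baseline.

## Stuhrmann analysis

R_g² is regressed on (1, 1/Δρ, −1/Δρ²) by weighted least squares, weights
from σ_{R_g²} = 2R_g·σ_{R_g} (an unweighted mode mirrors plot-space manual
fitting). R_c is the infinite-contrast radius; α > 0 places the
higher-SLD component peripherally; β ≠ 0 means the component centres of
scattering mass are displaced. For two-phase bodies the closed forms
(used as test oracles) are R_c² = φ₁Rg₁² + φ₂Rg₂² + φ₁φ₂d²,
α = φ₁δ₁[(Rg₁² − Rg₂²) + (φ₂² − φ₁²)d²], β = (φ₁δ₁d)². Designs whose
1/Δρ values are too clustered to separate the three terms are flagged
ill-conditioned.

## Component masses and per-q decomposition

The absolute-scale relation √(I₀/n) = |Δρ_P|MW_P/(N_A d_P) +
|Δρ_D|MW_D/(N_A d_D) is solved across contrast points by weighted least
squares. The number density n = c·N_A/MW_total involves the unknown total
mass, so the solve is iterated to self-consistency by default (converges
in a few steps); a fixed-n mode exists and is exactly linear in √I₀.
Negative solved masses are reported with a flag, never clamped.

The per-q decomposition solves I(q) = Δρ_P²I_P + Δρ_PΔρ_D I_PD + Δρ_D²I_D
point-by-point across ≥3 distinct contrasts (the physically standard form,
with Δρ_D² on the DNA term), propagating covariances; an optional flat
per-profile nuisance term absorbs unsubtracted incoherent background. For
single-particle data the zero-angle cross term obeys
I_PD(0) = 2√(I_P(0)·I_D(0)) (amplitudes add in phase), which the tests
verify on generator output.

## Core–shell cylinder and global fitting

The nucleosome is idealised as a cylinder: core = histone octamer at the
protein SLD, shell = DNA wrap at the DNA SLD, with the fitted
shell thickness playing the "radius of the DNA wrap". The standard full
core–shell cylinder is used — the shell covers the end faces as well as
the sides (outer dimensions R+t and L+2t); a side-only variant is a
deliberate non-feature and the difference is an explicit test case
concern, not a hidden convention. Orientational averaging is
Gauss–Legendre over the tilt angle, 76 points by default (relative error
< 10⁻⁴ against a 10× oracle; orders below 16 are rejected). The
contrast-weighted R_g uses the closed form Σwᵢ(Rᵢ²/2 + Lᵢ²/12)/Σwᵢ with
the annulus second moment for the shell, and agrees with the Guinier R_g
of the model's own low-q curve within 1%.

Global fits share (core radius, shell thickness, length) across curves
with per-curve scale (log-parametrised) and flat background, by
trust-region least squares with bounds at start/3 to 3×start and a seeded
multi-start (default 3). Degeneracy — a single curve with everything
free, or a Jacobian whose normalised condition exceeds 10⁸ — raises a
flag on the result instead of failing silently.

Debye sums offer a direct O(N²·n_q) reference and a distance-histogram
acceleration whose bins store the weight-averaged pair distance
(first-moment matching), keeping the two within ~10⁻³ at 0.25 Å bins.

## Synthetic generator

The generator emulates the measured study conditions: dilute monodisperse
nucleosomes (R_g ≈ 36–45 Å, Dmax ≈ 110–155 Å regime) over
q = 0.009–0.3 Å⁻¹; neutron contrast series at 0/20/70/80/95% D₂O at
~1 mg/mL with 3% relative noise at I₀ and a flat incoherent background
proportional to the H fraction of the solvent; X-ray pressure series at
1.2 mg/mL from ambient (0.1013 MPa) through 100 MPa steps to 300 MPa with
return points.

Geometry defaults (superhelix radius 41.8 Å, pitch 25.9 Å, 1.65 wrap
turns, 147 bp, core radius 32 Å, height 55 Å, duplex half-width 10 Å) are
canonical nucleosome crystallography conventions, exposed in
`NucleosomeGeometry`. Each base pair contributes two beads at ±10 Å along
the local radial normal, giving the native particle its ~110 Å disc
diameter; unwrapped base pairs continue as straight tangents;
`extension_fraction` linearly morphs the DNA path to a straight rod
(147 bp → 500 Å) while shrinking the protein core weighting. Default
protein composition is the canonical human core histone octamer
(2×(H3.1, H4, H2A, H2B) sequences); DNA defaults to 147 bp at 50% GC,
with the Widom-601 and α-satellite 145-mer positioning sequences available
as explicit inputs. The extended state is modelled as a Gaussian coil at
the rigid-rod R_g (L/√12 ≈ 144 Å for 147 bp) for speed; a bead-rod
alternative (`extension_fraction = 1`) exists for cross-checks. Noise
follows counting statistics, σ = √((I+bg)/exposure), so quadrupling the
exposure halves σ. Every profile's seed, contrast, noise parameters and
state mixture are recorded in a ground-truth manifest, and regeneration
from the same master seed is bit-identical.

What passing these tests shows: the estimators recover known parameters
under realistic noise, contrast and q-range conditions. What it does not
show: robustness to instrument resolution smearing (the SANS wavelength
spread is not simulated), interparticle interference, radiation damage,
aggregation, compositional polydispersity, or imperfect background
subtraction beyond a flat term — real-data quirks that remain the
analyst's responsibility.

## Pressure-series analysis

`analyze_series` produces per-profile Guinier and IFT summaries with the
recommended Dmax from a per-profile scan of 1.5–4× the Guinier R_g (8
candidates by default). Any later profile at the baseline's pressure, or
labelled as a return, is a return point; hysteresis is its ΔR_g and
ΔDmax against the baseline with the joint Guinier uncertainty. In the
default synthetic schedule a 10% residual extended fraction at the return
point is detected at >3σ. Reference calculators: rigid rod
(L = n·3.4 Å, R_g = L/√12), Stokes–Einstein radius R_h = k_BT/(6πηD),
and centrifuge-cell pressure P = P_amb + ½ρω²(r_b² − r_m²) — cell
geometry is an explicit input because reported pressures depend on it.

## Problem sizes

Defaults keep every analysis interactive on one CPU: 100–150 point
profiles, ~1100-bead models, 101-point P(r) grids with a 41-point α scan,
76-point quadrature, and 5-curve global fits of ~40 points each; the full
test battery, including 20-replicate global-fit recovery and 500-replicate
match-point simulations, completes in well under a minute.
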