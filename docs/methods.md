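# Methods

## Physical model

All analyses assume the fast-exchange NMR regime: species interconverting
rapidly on the chemical-shift timescale give one population-weighted
resonance, so an observed shift is an exact linear reporter of species
mole fractions.  Three system classes are modelled:

* **Monoprotic site.**  Deprotonated fraction f = 1/(1 + 10^(pKa − pH));
  each probe moves affinely between its acid- and base-form shifts.
* **Coupled two-site tautomer.**  An intramolecular O···H···N bridge with
  two deprotonation paths, characterised by site constants K_HO and K_HN.
  The two reporter probes (H6 for the oxygen site, H9 for the nitrogen
  site) are treated as *pure* reporters: each follows the two-state
  response of its own site constant only.  Cross-response of a probe to
  the remote site is not modelled.  The prototropic constant is the
  quotient ΔK = K_HN/K_HO = 10^(pKa_HO − pKa_HN); ΔK > 1 places the labile
  proton on nitrogen (zwitterion ⁺N–H···O⁻), ΔK < 1 on oxygen (neutral
  N···H–O), ΔK ≈ 1 a centred proton.
* **Sequential polyprotic ladder.**  N stepwise dissociations with state
  weights 1 : K1/[H⁺] : K1K2/[H⁺]² : … (computed in log space); any probe
  may respond to every state.  N = 2 is the classical diprotic three-state
  system; N = 3 (four states) reproduces the phenomenology of compounds
  that rearrange before two deprotonations and show three slope changes in
  the paired-shift diagram.  A three-state system geometrically cannot
  show more than two linear branches — its trajectory is a convex
  combination x₀·A + x₁·B + x₂·C — which is why the two-kink fixture
  requires four states.

Activity corrections, ionic-strength effects, pD correction of the glass
electrode reading and slow-exchange lineshapes are all out of scope; pH is
used exactly as read.

## Estimators

### Semilog pKa fit

y = log10[(δ_max − δ_obs)/(δ_obs − δ_min)] is regressed on pH
(ordinary least squares); pKa = −intercept/slope is the zero crossing and
is invariant to which axis is regressed on which, but the chosen
orientation gives well-behaved error propagation.  The pKa standard error
comes from first-order propagation through the full slope/intercept
covariance.  Points whose log argument is not strictly positive (plateau
points at or beyond a limit) are excluded and counted, not errors.
Safeguards: |slope| < 0.1 is refused as "no transition"; |slope| outside
[0.8, 1.2] raises a deviation flag (non-two-state behaviour); all-equal pH
is a singular design.

Limiting shifts default to means of the first/last `n_plateau = 3`
observations.  A plateau whose internal spread exceeds 5 % of the shift
range flags the titration as truncated.  Endpoint contamination of a
plateau mean is ~0.5 % of the range on a grid stopping 2.5 units past the
pKa and < 0.1 % at 3.5 units; the closed-loop tests that assert 10⁻⁶
recovery therefore supply the exact limiting shifts, mirroring an analyst
fixing the limits from a fully developed plateau.

### Perrin bilinear slope

With anchors (δ_x°, δ_y°) and (δ_x^e, δ_y^e), the transform
u = (δ_x − δ_x°)(δ_y^e − δ_y), v = (δ_y − δ_y°)(δ_x^e − δ_x) satisfies
v = ΔK·u identically for the two-site model, with ΔK = K_y/K_x — this
follows from f_y(1 − f_x)/[f_x(1 − f_y)] = K_y/K_x at every pH.  The fit
is OLS with a free intercept (absorbing imperfect anchors; reported in
ppm²); the two anchor points themselves are excluded (u = v = 0 by
construction).  Exact algebraic properties, each verified to 10⁻⁹ or
better in the suite: swapping probe roles inverts the slope, as does
exchanging the anchor roles (titration direction); slopes within 0.005 of
unity raise a near-unity flag rather than an error.  Anchors default to
the first/last diagram points and can be overridden for truncated runs;
with the true endpoint shifts as anchors the recovery is exact to machine
precision, with data anchors on a ±2.5-unit grid it is accurate to ~0.3 %.

### Breakpoint classification

Piecewise-linear models with 0–2 interior vertices are fitted by
exhaustive search over vertex placements (vertices at data points, shared
between adjacent segments) minimising summed squared *orthogonal*
residuals; prefix-sum cumulants make each candidate segment an O(1)
eigenvalue problem.  Pure residual comparison cannot distinguish a smooth
arc from a kink (with noiseless data, more segments always fit a curve
better by a scale-free factor), so a vertex only counts as a breakpoint if
it is a genuine corner:

* the turning of the trajectory within ±2 points of the vertex must hold
  ≥ 80 % of all turning between the midpoints of its flanking segments
  (turning angles are measured on the polyline after merging plateau
  duplicates);
* adjacent fitted segments must differ in direction by ≥ 10°;
* total turning below 5° is collinear; vertices closer than the window
  width are unresolved.

Among corner-valid models, the smallest vertex count within a factor
1 + tol_model (tol_model = 0.05) of the best residual is selected.  On
25-point grids this classifies exactly-linear and smoothly curved
diagrams (coupled sites, or steps separated by ≲ 1 pK unit) as 0
breakpoints, and well-separated sequential steps (≳ 1.5 units) as kinks —
matching the qualitative split between "almost linear" two-site systems
and stepwise polyprotic ones.  The thresholds are sampling-relative: a
grid much finer than the transition width will spread a kink over more
points and eventually declassify it.

### Gibbs-triangle (Polster–Lachmann) analysis

The triangle is A = start anchor, C = end anchor, and B the
neutralization vertex.  B is initialised as the intersection of the first
and last branch lines (terminal segments re-fitted on their anchor-side
halves, where the other equilibrium contaminates least) and then refined
by *distance-ratio self-consistency*: for the true vertex the reading
x_B²/(x_A·x_C) — equivalently the product of the cevian ratios
(|A→Y|/|Y→B|)·(|X→C|/|B→X|) — is the same at every experimental point,
because [HA]²/([H₂A][A²⁻]) = K1/K2 is pH-free.  The refinement minimises
the variance of the log-reading over points well inside the triangle
(membership judged in a triangle enlarged 1.6× away from the A–C chord,
coordinates > 0.04; at least 4 such points, otherwise the branch
intersection is kept — which is exactly the regime, well-separated steps,
where it is unbiased).  ΔK is then read at the experimental point BC
(the data point at the breakpoint vertex); the single ratio |B→X|/|X→C| —
which equals x(A²⁻)/x(HA⁻) and is pH-dependent — is reported separately
as `distance_ratio`.

Degenerate configurations are refused: parallel branches (no B),
collinear A/B/C, BC coinciding with a triangle corner or lying outside
the triangle.  Accuracy: ≤ 1 % recovery of K1/K2 ∈ {2, 5, 10} at zero
noise on default grids.  For very separated steps (K1/K2 ≳ 100) the
reading becomes ill-conditioned — the experimental point approaches B and
the anchor contamination of A and C enters squared — and errors of tens
of percent are expected; such systems are better treated as two
independent monoprotic fits, which the pipeline's windowed pKa stage
provides.

### Windowed pKa fits for multi-step systems

With k ≥ 1 detected breakpoints the series is split at the vertex points
into k + 1 windows and the semilog fit runs per window.  A window end
shared with another transition takes the vertex estimate (intersection of
the flanking segment lines, consistency-refined for single-vertex models)
as its limiting shift — the intermediate species never develops a plateau
of its own.  On the reference two-step fixture (pKa 8 and 10) both
windows recover their pKa within 0.1.

## Thermodynamic layer

ΔpK = −log₁₀ ΔK and ΔΔG° = −RT ln ΔK / 1000 (kJ mol⁻¹; the per-kelvin
unit sometimes attached to this expression is dimensionally a slip).
Defaults R = 8.314 J mol⁻¹ K⁻¹, T = 296.15 K — the temperature at which
the tabulated reference ΔΔG° values reproduce to their printed three
decimals (a stated alternative of 295.15 K does not, and is selectable in
the configuration).  Exact identities, tested to 10⁻¹²:
ΔΔG°(ΔK) = −ΔΔG°(1/ΔK), ΔpK(ΔK) = −ΔpK(1/ΔK), and
ΔΔG° = (RT ln 10/1000)·ΔpK.  Classification near-unity band:
|ΔK − 1| ≤ max(0.005, 2·stderr).

## Synthetic generator defaults

25-point pH grids bracketing the transition(s) by 2.5 units; Gaussian
noise σ_shift = 0.002 ppm (digital resolution of a 500 MHz instrument)
and σ_pH = 0.02 (meter repeatability); a fixed seed reproduces the series
bit for bit.  Shifts are evaluated at the true pH and only the recording
is perturbed, i.e. pH error is treated as pure reading noise, not as a
solution-state error.  What the generator deliberately omits — probe
cross-response, baseline drift, referencing error, hydrolysis of the
analyte in the acid branch, activity effects — bounds what passing tests
demonstrate: they validate the estimators *under the model the methods
assume*, not the chemistry of any particular compound.

## Known limitations

* Perrin and Gibbs-triangle readings require the titration to reach (or
  the analyst to supply) both limiting states; anchor error enters the
  Perrin slope linearly and the triangle reading quadratically.
* The corner test is sampling-relative (see above); heavily overlapping
  steps (K1/K2 ≲ 10, i.e. ΔpK ≲ 1) never raise a corner and must be
  analysed as a posited two-step model (`linearity_check(d).models[1]`).
* The near-unity flag means the proton position is statistically
  undecidable at the reported precision, not that the system is proven
  centred.
* One breakpoint at most per window boundary; more than two breakpoints
  (≥ 5 states) are out of scope.
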