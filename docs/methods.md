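# Methods

## The measurement model

A whole-blood immunoassay reading of an analyte whose true plasma
concentration is $C$ in a sample of hematocrit $h$ (%) is modelled as

$$C_\text{wb} = C \cdot \underbrace{(1 - h/100)}_{\text{plasma volume}}
\cdot \underbrace{(1 - y(h)/100)}_{\text{residual binding bias}}
\cdot \varepsilon$$

where $y(h)$ is the four-parameter logistic (4PL)

$$y(h) = d - \frac{d-a}{1 + (h/c)^b}, \qquad a < d < 100,\; b, c > 0,$$

and $\varepsilon$ is unit-mean multiplicative noise. The first factor is exact
volume displacement by red cells; the second captures the empirical
observation that even after converting to plasma-equivalent units, recovery
falls with HCT — attributed to red cells and cell debris slowing immune
binding. $y$ is therefore interpreted as the percent under-recovery
*remaining after* the volume conversion. This reading is self-consistent: the
mean of $100 - y(h)$ over the eight panel levels (HCT 25–60%) under the
reference cTnI parameters is 89.2%, matching the recovery achievable by the
volume stage alone, and it makes the two-stage correction

$$C_\text{final} = \frac{C_\text{wb}}{(1 - h/100)(1 - y(h)/100)}$$

an exact inverse of the suppression: with all noise off, correction returns
$C$ to 1 part in 10⁹ for every $h \in [0, 65]$ (property-tested). The two
factors commute, so the order of the stages is immaterial; both stages are
applied with the HCT *measured at the same aspiration*, not a nominal tube
value, which is what removes sedimentation-induced imprecision (below).

The reference cTnI parameter set is $d = 34.145$, $d - a = 31.816$
(so $a = 2.329$), $c = 52.155$, $b = 9.175$. The package treats the bias
curve as per-assay configurable; nothing assumes these values transfer to
other analytes.

Note the corner case $h = 0$: the volume factor is 1 but $y(0) = a > 0$, so
even a plasma-like sample receives a ~2.4% uplift under the reference
parameters. This is a property of the fitted curve, not a bug; a laboratory
that wants identity at $h = 0$ should fit a model with $a = 0$.

## HCT quantification

The chemiluminescent photon yield of lysed blood is proportional to red-cell
content, so RLU is modelled as $s \cdot h + i$ with multiplicative noise. The
standard curve is fitted by OLS *with* an intercept — the blank signal of
plasma is not assumed to be zero — and inversion returns
$(RLU - i)/s$. Estimates more than 5 HCT points outside the calibrated span
are flagged as extrapolation (the method is claimed usable on 0–65% while
calibration covers 25–60%); negative estimates clamp to 0 with a flag.

Interference is evaluated on volumetric mixing series (blood : interferent
stock at 10/0 … 0/10). Because mixing dilutes red cells, the observed RLU is
compared against the dilution expectation
$RLU_\text{ref} \cdot p_\text{sample}/(p_\text{sample}+p_\text{stock})$
rather than the raw unspiked value; otherwise dilution would masquerade as
interference. This expectation presumes a background-free (blank-subtracted)
signal, and the interference scenario simulates it accordingly. A series is
flagged only when some mix deviates by strictly more than 10% — a deviation
of exactly 10% is acceptable. The 0/10 mix (no blood, expected signal 0) has
no defined relative deviation and is excluded.

## Method-comparison statistics

**Passing–Bablok.** All pairwise slopes $S_{ij}$ are enumerated; slopes equal
to −1 are excluded, tied $x$ with differing $y$ contribute signed infinite
slopes (placed at the ordering extremes by the sort), and fully tied pairs
carry no information. With $K$ slopes below −1, the estimate is the
order statistic at position $(N+1)/2 + K$ — the arithmetic mean of the two
middle shifted positions when $N$ is even. The intercept is
$\mathrm{median}(y - bx)$. Confidence intervals use the rank-based normal
approximation $C = w_{1-\alpha/2}\sqrt{n(n-1)(2n+5)/18}$; intercept bounds
reuse the slope bounds. The implementation is cross-checked against an
independent brute-force enumeration on 1,000 random instances with $n \le 8$,
including tied-integer designs. One consequence of the arithmetic-mean
convention: the swap identity slope$(y,x) = 1/$slope$(x,y)$ is exact only
when $N$ is odd, so the property test uses $n = 7$ ($N = 21$).

**Bland–Altman.** Differences $y_i - x_i$, or $100(y_i - x_i)/\bar{m}_i$ with
$\bar m_i$ the pairwise mean in relative mode (relative mode requires
positive pairwise means). Both the 1.96-SD limits of agreement and the
t-based CI of the mean bias are always reported, because published "95%
interval of the bias" phrasing is ambiguous between the two.

**Repeatability CV.** $cv = 100\,s/\bar x$ with the chi-square interval on
the SD propagated first-order to the CV:
$\left(cv\sqrt{(n-1)/\chi^2_{1-\alpha/2,n-1}},\;
cv\sqrt{(n-1)/\chi^2_{\alpha/2,n-1}}\right)$.

## The synthetic-data generator

The generator emulates the statistical structure of the laboratory designs:
full-factorial reconstituted panels (default calibration levels 25–60% in 5%
steps, with an HCT-0 sample as plasma reference in the effect panel; cTnI
spikes log-spaced over 0.1–50 ng/mL, five levels, 45 samples in the effect
design), interferent series (albumin 500, triglycerides 1000, bilirubin 50,
cholesterol 2000 mg/dL), repeatability tubes at cTnI 0.114/0.522/5.471 ng/mL
assayed 10 times, and paired cohorts of $n = 86$ (concentration) or $n = 58$
(HCT methods).

Distributional choices the underlying experiments do not pin down, chosen
once and documented here:

- **Measurement noise** is multiplicative log-normal parameterised by CV
  (positivity, CV-scaling match assay practice): `rlu_cv` default 0.02,
  `conc_cv` default 0.03.
- **Sedimentation heterogeneity** is additive Gaussian jitter on the
  effective HCT of each aspiration, truncated to [0, 99]; default SD 1.5 HCT
  points, which places uncorrected whole-blood CVs in the 2–4% band typical
  of repeatability studies on this kind of platform.
- **Cohort concentrations** are log-uniform, since clinical marker levels
  span more than two decades.
- **RNG**: a single master seed; each operation draws from an independent
  substream derived from it, so identical spec + seed reproduces
  byte-identical tables.

What the generator does *not* emulate: photon-count kinetics over time (only
integrated RLU is produced), hemoglobin chemistry, reagent-lot or master-curve
variation, matrix effects beyond the modelled suppression, and any
non-lognormal error structure of a real instrument. Passing tests therefore
demonstrate the correctness and internal consistency of the algorithms under
the stated model, not the clinical performance of a physical analyzer. In
particular, real uncorrected recovery ranges are wider than the deterministic
suppression model alone can produce; that extra scatter is instrument noise
the generator represents only through the declared CVs.

## Precision mechanism and its regime

Repeated aspiration of a settling whole-blood tube samples a different
effective HCT each time, inflating the CV of reported concentrations;
correcting each draw with its own measured HCT removes exactly that
component. The strict per-seed ordering "corrected CV < uncorrected CV"
is guaranteed only when the sedimentation component dominates the analytical
noise: with comparable components and only 10 draws, the empirical covariance
between the HCT factor and the analytical noise occasionally flips the
sample-CV ordering (about 5% of seeds at the defaults). The property test
therefore runs the sweep at sedimentation SD 3.0 (analytical CV at its 0.03
default), where the ordering holds for all 100 seeds with a worst-case margin
above one CV point, and a separate test asserts the mean-CV ordering across
100 seeds at the defaults.

## Numerical choices and edge cases

- 4PL fitting is bounded nonlinear least squares (`scipy.optimize.curve_fit`;
  hill in (0, 50], inflection in (0, 100], asymptotes in [−100, 100]) with
  automatic initialisation: asymptotes from the padded data range, inflection
  from the interpolated midpoint crossing, hill from a log-linearised slope.
  Flat deviations are rejected as unidentifiable (the $a < d$ invariant);
  solver non-convergence raises an error carrying the initial guess.
- Noiseless self-generated grids of ≥ 13 points recover all four parameters
  to 4 significant figures; with 2% multiplicative noise on $y$ the median
  inflection error over 100 replicates is under 2 HCT points (tested).
- $y(h)$ underflows to the lower asymptote for $h \lesssim 2$ at double
  precision (the term $(h/c)^b$ drops below machine epsilon for large $b$);
  monotonicity is strict wherever the term is representable.
- The plasma-equivalent conversion diverges as $h \to 100$; $h \ge 100$ and
  $h < 0$ raise domain errors, and the invariant $d < 100$ keeps the
  stage-two divisor positive for any valid parameter set.
- Corrections at HCT outside [0, 65] are returned flagged, not refused.
- Scenario problem sizes follow the study designs (45-sample effect panel,
  10-draw repeatability at three levels, $n = 86$/$n = 58$ cohorts); every
  scenario completes in well under a second, and the full test suite in a few
  seconds.

## Known limitations

- The residual-bias model is fitted to cTnI-style behaviour; applying the
  reference parameters to other analytes is a modelling decision the user
  must justify per assay.
- Passing–Bablok CIs use the large-sample normal approximation; for $n < 10$
  they are indicative only.
- The CV confidence interval treats the mean as fixed (first-order
  propagation); for CVs above ~20% the exact noncentral-t interval would
  differ noticeably.
- The interference rule evaluates RLU deviation only; it does not model
  chemical mechanisms of interference.
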