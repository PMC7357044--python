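# Methods

## The model

`ogttscan` simulates the plasma glucose response of a rat to an oral
glucose bolus (OGTT) with a four-state extension of Bergman's minimal
model (MINMOD). MINMOD was built for *intravenous* tests, where glucose
is maximal at t = 0; an oral test needs two additions: a glucose input
flux, and a representation of the fast first phase of insulin secretion.

States (units): `G` plasma glucose (mg/dL), `X` insulin-driven glucose
withdrawal rate (1/min), `I` plasma insulin (nU/dL), `Is` readily
releasable pool (RRP) of stored insulin (nU/dL).

```
dG/dt  = -p1 (G - Gb) - rCd X G + GRA(t)
dX/dt  = -p2 X + p3 (I - Ib)
dI/dt  = -n I + gamma (G - h) t + p4 Is
dIs/dt = -p4 Is
```

* `GRA(t) = K * N(t; mu, sigma)` is the glucose rate of appearance in
  plasma: a Gaussian density centred at `mu = 30` min (time of maximal
  absorption) with `sigma = 35` min, chosen so that the rate at gavage is
  ~70% of its maximum (exp(−900/2450) = 0.6926). `K` is not free: mass
  balance over [0, ∞) forces `K = (m_glc / V_blood) / Φ(mu/sigma)`, where
  `m_glc` is the ingested glucose mass (2 mg per g body mass), `V_blood`
  the blood volume, and `Φ` the standard normal CDF (the denominator
  restores the Gaussian mass that would fall before t = 0). For the
  packaged rat physiology this gives K ≈ 3730, 4041, 3982 mg/(dL·min) at
  post-natal days 21, 26 and 60.
* `rCd` scales the efficiency of insulin-dependent withdrawal; `rCd < 1`
  is insulin resistance. It is fixed at 1 for reference (control) animals.
* `p4 Is` injects the RRP into circulation with first-order kinetics;
  `Is(t) = Is0 exp(−p4 t)` exactly, which the test suite uses as an
  analytic oracle.
* The slow-phase secretion drive `gamma (G − h) t` is implemented exactly
  as written, **unclamped**: when `G < h` (which happens at the PND26
  fasting state, G(0) = 76 < h = 79) the term is negative. Classical
  minimal-model formulations clamp `(G − h)` at zero; an optional
  `clamp_threshold` flag provides that variant, default off. Simulations
  are not prevented from producing negative `G` or `I`; a
  `NegativeStateWarning` is emitted when an excursion exceeds solver
  tolerance, since the model is outside its intended regime there.

Not modelled (out of scope by design): gut/stomach compartments,
C-peptide, hepatic glucose production, non-insulin hormones, two-phase
granule trafficking beyond the single `Is` pool. Insulin time courses
are never fitted — only glucose enters the objective.

## Integration

Time is absolute minutes from gavage (the secretion drive carries an
explicit factor `t`, so the clock must never be restarted). The default
integrator is LSODA at rtol 1e−8 / atol 1e−10: the insulin degradation
scale (n ≈ 8–11 /min) is two decades faster than the glucose dynamics,
which step-limits explicit Runge–Kutta pairs over the 2-h window — on
the PND21 reference problem LSODA is ~6× faster than RK45 at equal
achieved accuracy (≈6e−6 mg/dL against a 1e−12-tolerance reference).
Any scipy `solve_ivp` method can be selected through
`SolverSettings.method`; the test suite cross-checks the adaptive
solution against an independent fixed-step RK4 at h = 0.01 min
(< 0.05 mg/dL) and against tolerance refinement (< 0.1 mg/dL under a
10× tightening). Scans and cohort sweeps in the test suite use
rtol 1e−6 / atol 1e−8, whose error (~1e−6 mg/dL) is far below every
threshold asserted there.

## The goodness-of-fit score

For a dataset of per-timepoint group means `x_i` with between-animal
sample variances `v_i`:

```
eps(k) = sqrt( sum_i W_i (x_i - G_sim(t_i; k))^2 ),   W_i = 1 / (v_i * sum_j x_j^2)
```

Tightly clustered timepoints carry the most weight; `eps = 0` iff the
simulated glucose passes through every mean. "Variance to the mean" is
interpreted as the between-animal **sample variance**, not the squared
standard error — group spread, not mean precision, is the dominant
uncertainty in these cohorts; the loader can rescale SEM²-convention
files (`variance_kind="sem2"`). Because the weights are built from one
dataset's means and variances, scores are comparable only within that
dataset; `ScanReport.merge` refuses to aggregate scores across datasets.
Reports display three significant figures; all comparisons use full
precision. Zero variances are rejected at load; the cohort generator
floors degenerate variances at 1e−6 (mg/dL)² and flags the dataset.

## Hypothesis scanning

The protocol: (1) fit a control parameter set to the control cohort;
(2) for each of seven mechanistic hypotheses, refit **one** parameter to
the perturbed cohort with the other nine frozen at control values;
(3) rank hypotheses by score. The hypothesis → parameter map is fixed:
H1.1→rCd, H1.2→p3, H1.3→p2 (tissue insulin sensitivity), H2→n (insulin
turnover), H3.1→gamma, H3.2→p4, H3.3→h (beta-cell secretion).

* **Search intervals.** One decade each way around the control value for
  rates and `rCd`; ±50% for the thresholds `h` and `Gb`, where a decade
  would leave the physiological range.
* **1-D refit.** Deterministic: a 64-point scan of the interval
  (log-spaced when positive), then bounded Brent polishing of the three
  best brackets — the score along one parameter can be near-flat or
  gently multimodal, and a single bracket occasionally misses the global
  basin by ~1e−8. The control value is always a candidate, so a refit
  can never score worse than the no-hypothesis entry; a refit that
  cannot beat it is flagged "no improvement" (rendered "-").
* **Control fit.** Nine free parameters (`rCd` fixed at 1 for control
  data); Latin-hypercube multi-start (default 64 starts, log-scaled for
  rate-like parameters) with Powell refinement of the best starts, under
  an evaluation budget (default 6000). Failed integrations score +inf.
  When a reference set is supplied it is included as a candidate and
  honoured exactly, so the fit matches-or-beats the reference score.
  Only the fitted trajectory is meaningful: a single glucose curve
  under-determines ten parameters (the fit is "sloppy"), so parameter
  values themselves are never asserted, only curve reproduction and
  single-perturbed-parameter recovery.
* **Ties** (scores equal within 1e−9) rank in hypothesis-id order.

## Synthetic cohorts

The group-level tables the pipeline consumes are emulated, not stored:
each animal is a model simulation with its six rate parameters jittered
by median-preserving multiplicative lognormal noise (default CV 0.1;
thresholds and `rCd` are not jittered — rates plausibly vary between
littermates, setpoints much less), plus additive Gaussian measurement
noise on sampled glucose (default sd 5 mg/dL, a typical glucometer-scale
error). Defaults give group CVs of roughly 5–15% — the narrow
within-group spread these rat cohorts show. Cohort sizes default to the
published group sizes (e.g. 48 control animals at PND21). The default
grid [10, 20, 30, 40, 60, 90, 120] min starts at the first measured
point (10 min) and ends at the 2-h mark. Paired control/perturbed
cohorts share all seed-derived draws and differ only in the perturbed
parameter's population value, so recovery experiments are exactly
matched. Not modelled: within-animal autocorrelated error, dropout.

What passing synthetic-data tests does and does not show: they validate
the machinery (simulation, scoring, optimization, ranking) under the
noise structure assumed above; they cannot validate that structure
against the real cohorts, whose raw per-timepoint spreads were never
published.

## Calibration of the scan

Two properties anchor trust in a ranking, both measured by the test
suite with the fit-then-scan protocol at published cohort sizes and
default noise:

* **Null**: on unperturbed cohort pairs, no hypothesis improves the
  score by more than 10% in ≥ 90% of 50 seeds. (Scanning against the
  *generating* parameters instead of a fitted control inflates apparent
  improvements badly — the cohort mean curve is systematically offset
  from the nominal-parameter curve by the nonlinear propagation of
  parameter spread, and any single refit absorbs that shared offset.
  Fitting the control first, as the protocol prescribes, removes it.)
* **Power**: a slow-phase reduction of the published effect size
  (gamma × 0.694) is ranked first in ≥ 80% of 25 seeds; a large store
  release increase (p4 × 9.35) is ranked first with the rate recovered
  within 25%. Noiseless single-parameter perturbations are recovered to
  < 0.1% with scores ~0.

## Numerical choices and degenerate inputs

* Grid times must be strictly increasing within [0, 120] min; dataset
  timepoints strictly positive (t = 0 is the known initial state).
* `X(0) = 0` is enforced: the withdrawal machinery is taken as
  unengaged after the overnight fast.
* K is always derived, never read: a `K` field in a physiology file is
  ignored and recomputed.
* Integration failures inside a scan score +inf and do not abort the
  scan; a control fit whose budget never yields a successful simulation
  raises instead of returning +inf.
* CSV round trips are exact (`%.17g` on write, round-trip float parsing
  on read), which is what makes fixed-seed CLI reruns byte-identical.

## Known limitations

The fitted parameter sets are qualitative instruments for ranking
mechanisms, not quantitative estimates: identifiability from a single
mean glucose curve is poor, and the appearance curve is a coarse
stand-in for intestinal absorption (its accuracy is weakest in the
first minutes and near 120 min). Scores never compare across datasets.
Joint multi-parameter hypotheses (e.g. gamma and p4 together) are out
of scope.
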