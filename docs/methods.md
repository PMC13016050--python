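# Methods

## Model and assumptions

`mihcost` estimates the per-visit operating cost of an acute-care
mobile integrated health (MIH) program by probabilistic (Monte Carlo)
cost analysis. The model assumes:

* the program's budget decomposes into a finite list of cost elements,
  each independently uncertain — no correlation between elements is
  modeled (a joint elicitation would require data no program publishes);
* every visit belongs to exactly one complexity stratum, *basic* or
  *advanced*, decided by a deterministic rule on service use (two or
  more diagnostic modalities and/or any IV therapy ⇒ advanced; multiple
  lab panels count as a single laboratory modality; a visit with no
  diagnostics and no IV is basic — the advanced triggers are an
  explicit enumeration, everything else is basic);
* fixed costs are a pool allocated across strata in proportion to
  weight × visit count. With the default unit weights the per-visit
  fixed share is identical for both strata, so the entire
  basic/advanced cost gap comes from variable costs. Published results
  for programs of this kind are also consistent with resource-weighted
  allocation (e.g. by visit duration); the `weight_basic` /
  `weight_advanced` configuration fields provide that reading without
  code changes;
* overhead, taxes, utilities, vehicle purchase and training costs are
  out of model scope, as is any cost-effectiveness comparison.

## Uncertainty: the PERT distribution

Each cost element carries a PERT triple (minimum, most-likely,
maximum). PERT is a beta distribution rescaled to `[a, b]` with
`alpha = 1 + lam*(m-a)/(b-a)`, `beta = 1 + lam*(b-m)/(b-a)`; relative
to a triangular distribution on the same triple it concentrates mass
near the mode and damps the extremes. The shape `lam` defaults to the
conventional 4 (mean `(a+4m+b)/6`) and is configurable per run
(`simulation.pert_shape`) and per element, since elicitation practice
varies. Degenerate triples (`a == b`) are point masses, which makes
deterministic cost lines and exact oracle tests expressible in the same
schema. Closed-form moments (`pert_mean`, `pert_variance`) are exposed
and serve as independent oracles for the sampler.

## Simulation and summaries

Default 1,000 iterations. Each iteration draws all element values and
the annual visit volume, rounds the volume to a whole encounter count,
splits it 60/40 (round-half-to-even on `total × prop_basic`, remainder
to advanced, so counts always sum), allocates, and records per-visit
costs. The central estimate reported is the **median**; the 90%
interval is the 5th–95th **percentile interval of the simulated
per-visit cost distribution** (not an interval on the median
estimator — the narrower of the two readings of a "probabilistic
confidence interval", chosen because it describes cost variability
across scenarios, which is the decision-relevant quantity). Quantiles
use linear interpolation between order statistics (the numpy default),
fixed and documented for reproducibility. The mean and SD are also
reported; the mean admits an exact linearity-of-expectation oracle when
the visit volume is degenerate.

### Random-number contract

Every element owns an independent RNG stream seeded by
`[master_seed, crc32(element_id)]`; iteration *i* uses position *i* of
the stream. Consequences: results are bit-reproducible across platforms
for a given (config, iterations, seed); and removing elements — the
unreimbursed scenario, which drops the payor-reimbursed laboratory and
radiology elements — leaves all other draws unchanged. The two
scenarios are therefore coupled by common random numbers and the full
cost dominates the unreimbursed cost in *every* iteration, which the
test suite checks exhaustively.

## Configuration

Structured text (YAML; JSON parses identically), machine-validated with
per-field errors. Monetary PERT triples are USD per program-period
(fixed, per-period variable) or USD per visit. Invariants: fixed
elements are `per_period`/`all`; stratum proportions sum to 1 (1e-9
tolerance); element ids unique; at least one fixed and one variable
element. Fuel and vehicle maintenance are modeled as *per-period
variable* costs: they scale with operations rather than with an
individual encounter, and are split across strata by the same
allocation rule as the fixed pool while remaining in the variable
totals. Visit volume is PERT-varied by default; a point-mass
`annual_visits` reproduces the fixed-volume reading. Currency is binary
floating point internally; rounding to whole dollars (tables) or cents
(CSV/JSON) happens only at the reporting boundary.

## Synthetic data

The generator emulates a single urban program performing ~800 annual
acute-care visits, 60% basic / 40% advanced.

* **Encounters** are generated constraint-first: the stratum is drawn
  (Bernoulli 0.60), then service usage is sampled within that stratum's
  defining constraints (basic: at most one diagnostic modality, no IV;
  advanced: both modalities forced whenever no IV therapy was drawn),
  so the classifier recovers the generating stratum by construction and
  the generator and classifier are mutually testable. Per-visit
  utilization rates (lab 45%, radiology 25% for basic; IV 70%, both
  modalities 80% for advanced; Poisson extras) are **placeholders** —
  no per-visit utilization data is published for this kind of program.
* **The configuration template** (`program_template`, also shipped as
  `data/program_template.yaml`) carries the full cost taxonomy —
  personnel at 6.5 FTE paramedics / 1.0 FTE administrator / 0.5 FTE
  physician medical direction, administrative costs, durable clinical
  equipment, fuel, vehicle maintenance, laboratory analysis and
  radiology (both flagged reimbursable), and medications/supplies —
  with placeholder dollar ranges at public salary/equipment orders of
  magnitude. It is a synthetic stand-in, not any program's ledger.
* **Calibration** (`calibrate_config`) rescales three multiplicative
  factors — the shared pool (fixed elements, per-period variable costs,
  and any all-visit per-visit elements, which all hit both strata
  equally under count-proportional allocation), basic-only variable
  costs, advanced-only variable costs — by deterministic staged
  bisection under common random numbers until the simulated medians hit
  user targets. Because the basic and advanced variable scales do not
  interact, one pass of monotone bisections converges; the fixed-pool
  scale is only engaged when the shared base alone exceeds 80% of the
  smaller target (the 80% headroom leaves room for stratum variable
  costs). Calibrating the template to medians of $550/$1,400 yields a
  fixed-pool scale ≈ 0.41 — interpretable as the acute-care share of a
  program whose staff also serve other service lines, since full
  personnel costs divided by 800 visits would alone exceed the basic
  target. The calibrated configuration is a labeled *reconstruction*
  whose medians match published totals; its element-level values are
  not data.

Passing tests on these synthetic inputs demonstrate the arithmetic,
the distributional machinery, the scenario coupling and the calibration
search — not the accuracy of any real program's elicited triples, the
independence assumption, or real utilization patterns.

## Numerical choices

* Quantiles: linear interpolation; medians of even-length vectors are
  midpoints.
* Visit split: round-half-to-even, remainder to advanced.
* Fixed allocation: advanced share computed by subtraction so shares
  sum to the pool exactly in floating point.
* Zero-visit strata report NaN per-visit cost (never a division by
  zero); both strata empty is an error.
* Conservation (`n_b·c_b + n_a·c_a` = total sampled cost) holds to
  1e-9 relative and is enforced by tests on randomized configurations.
* Problem sizes in the test suite — 10^6-draw moment checks, 10^5
  iteration convergence/linearity checks, 50-iteration randomized
  conservation sweeps — were chosen as the smallest sizes at which the
  4-standard-error statistical bounds are meaningfully tight; the whole
  suite runs in seconds.

## Known limitations

* Cost elements are sampled independently; correlated inputs (e.g.
  salary and certification costs moving together) would widen or
  narrow intervals in ways the model cannot express.
* The unreimbursed scenario removes reimbursable elements entirely; it
  does not model partial reimbursement rates.
* Single-period model: no discounting, inflation adjustment, or
  multi-year horizon.
* The benchmark unit costs (outpatient $160, ED $2,715, inpatient
  $24,680) are literature constants external to the model, overridable
  per report.
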