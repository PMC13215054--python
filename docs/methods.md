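# Methods

## Model and assumptions

The simulator represents one presynaptic terminal as a single well-mixed
compartment: all concentrations are volume averages, with no microdomains,
no pH state, no Mg²⁺ binding corrections and no diffusion.  Six metabolites
are tracked ([ATP], [ADP], [AMP], [Arg], [ArgP], [Pᵢ], mM) under three
processes — spike-driven consumption, energy-state-regulated production,
and instantaneous kinase equilibration.  Membrane excitability is not
modelled: action potentials are imposed timestamps, each carrying a fixed
energetic budget.

### Consumption

A spike at t_s adds, for each component j ∈ {Na, Ca, NT1, NT2, NT3}, an
instantaneous rate of height N_j/τ_j that decays exponentially; spikes
summate linearly, and a constant non-signalling base rate applies at all
times.  Molecule counts convert to concentrations through the terminal
volume (1 mM ≡ 6.02214×10⁵ molecules/µm³; equivalently 1 molecule/µm³ =
1/602.214 µM ≈ 1.66×10⁻⁶ mM).  Spike generation follows the duty-cycle
convention: within a full cycle, spikes fall at t_c + k/rate for
k = 0 … floor(duty·rate), i.e. both window edges fire when duty·rate is
integral (this is the only convention reproducing the worked counts of 7,
8160 and 6060 APs; a caption quoting "800 APs" for an 80 Hz × 10 s train
suggests the truncated convention, so `include_endpoint=False` is provided
— inclusive is the default).  `floor` is evaluated with a 1e-9 guard so the
terminal spike is never lost to round-off.

### Production

Production is driven by the energy state ES = [ATP]/([ADP][Pᵢ]) (1/mM)
through a mitochondrial turnover function pcc(ES).  Only turnover *ratios*
enter: production is calibrated to equal the terminal's rest consumption at
the resting ES, which absorbs the absolute respiratory-chain scale
(cytochrome c content never appears).  Two deliberate choices:

* **pcc decreases with ES.**  Production must rise as the terminal runs
  down (ADP and Pᵢ accumulate, ES falls); with an increasing pcc the rest
  state would be an unstable equilibrium and any perturbation would run
  away.  The shipped default is a Hill function of the inverse energy
  state, pcc = u^h/(K^h + u^h) with u = 1/ES, K = 0.5 mM⁻¹ (inverse-ES at
  half-maximal turnover) and h = 2.  At the default resting ES ≈ 23.7 mM⁻¹
  this puts rest at ~0.7 % of maximal turnover, leaving ample headroom
  before the capacity cap engages.  The exact turnover function of the
  underlying respiratory-chain model is not published with the model, so
  the interface accepts any strictly decreasing callable; the rest
  calibration makes all choices agree at rest.  Quantitative trajectory
  details (e.g. minimum free-energy values under load) depend on this
  choice and on the terminal parameters, and are not reproduction targets.
* **Soft cap with exact rest calibration.**  The uncapped rate is limited
  by max_rate = cap × mitochondrial density (caps of 0.079 and
  0.154 mM/s per 1 % density are the two published tissue estimates;
  densities near 6.3 % are typical of big-bouton terminals) through
  p_capped = (p⁻⁵ + max⁻⁵)^(−1/5), evaluated in a rescaled form that
  cannot overflow.  The cap exponent 5 is exposed as a parameter.  Because
  the cap strictly lowers every positive rate, a literal calibration would
  leave the rest state leaking at a relative ~(base/max)⁵/5 (~10⁻⁷).  The
  production prefactor is therefore set to the inverse cap of the base
  rate, so the *capped* rest production equals rest consumption exactly and
  the rest state is a true fixed point — a refinement of order 10⁻⁷ that is
  far below every other uncertainty.

### Equilibration

Adenylate kinase (AMP + ATP ⇌ 2 ADP, K_Ad = 1) and arginine kinase
(ADP + ArgP ⇌ ATP + Arg, K_Ph = 39.6) are treated as instantaneously
equilibrated — no kinetic rates.  The solver works in the two reaction
extents, which conserves the adenine pool, the guanidino pool and the
phosphoryl tally (3·ATP + 2·ADP + AMP + ArgP) by construction; Pᵢ is
untouched.  A damped 2×2 Newton iteration on the relative equilibrium
residuals (default tolerance 1e-10, 100 iterations) runs first; whenever it
stalls or would leave the feasible box (any species < 0) the solver falls
back to alternating exact single-reaction bisections, which are
unconditionally convergent because each residual is monotone in its own
extent.  Boundary cases (a species exactly zero) are handled naturally by
the extent bounds: e.g. AMP = 0 with ADP > 0 forces AK to create AMP.
Phosphagen "knock-down" runs skip the ArgK relation and return Arg/ArgP
bit-identical.  The iteration scheme and tolerance are this package's
choices, validated against an independent brute-force oracle in the tests
(final-state root bracketing over conserved pools).

### Time stepping

Operator splitting in the stated order: (1) update [ATP], [ADP], [Pᵢ] with
the net of capped production and consumption by one explicit-Euler step;
(2) equilibrate.  Defaults: dt = 1e-4 s (well under the shortest default
τ of 0.05 s and the 12.5 ms inter-spike interval at 80 Hz; a warning fires
if dt > min τ/10), recording every 10th step.  Spike costs are deposited
into per-component decay accumulators at the grid point nearest the spike
time; the accumulator evaluation equals the explicit sum over past spikes
to round-off, and the splitting scheme is verified first-order convergent
in dt, with dt-halving changing recorded [ATP] by < 0.1 %.  If a step
would drive a concentration negative it is subdivided locally (up to 10
halvings, re-evaluating production and equilibrating within sub-steps)
before an error is raised — exhaustion scenarios degrade gracefully
instead of producing negative concentrations.  The inner loop is
JIT-compiled (numba) for the default turnover; custom turnover callables
run through an equivalent pure-Python loop that matches the compiled path
exactly.  The 20-minute locomotion protocol (1200 cycles at 42 Hz,
dt = 1e-4 s, 12×10⁶ steps) completes in a few seconds on one CPU.

### Resting state and constants

Resting pools: [ATP] = 2.16, [ArgP] = 7.5, [Arg] = 3.3, [Pᵢ] = 3.8 mM
(the low end of the measured 3.8–17.8 mM range; a sweep over that range is
supported but not the default).  Free ADP and AMP follow from the two
equilibrium relations: [ADP] = [ATP][Arg]/(K_Ph[ArgP]) = 24.0 µM and
[AMP] = [ADP]²/(K_Ad[ATP]) = 0.27 µM.  Free energy uses ΔG = ΔG₀ +
RT ln([ADP][Pᵢ]/[ATP]) with concentrations in mM — the convention under
which the printed constants give the expected resting magnitude of
38 kJ/mol (|ΔG| ≈ 38.5); ΔG itself is negative and CSV output documents
the sign convention.  "Volatility" has no canonical formula, so two
summaries are always reported: the mean within-cycle peak-to-trough
excursion, and the standard deviation of the linearly detrended series.

## Trace processing

* **ΔR/R** — per frame, the mean of the background regions is subtracted
  from the bouton signal in each channel; the ratio is referenced to its
  pre-stimulus mean.  Invariant to common gain on both channels.
* **Bleach correction** — a monoexponential a·exp(−t/τ) (offset term
  optional, on by default; pure-exponential selectable) is least-squares
  fitted to the 20 s of pre-stimulus ratio estimates (log-linear
  initialisation), and divides the ratio between −10 and 40 s around
  stimulus onset, re-normalised to a pre-stimulus mean of 1.  Samples
  outside the correction window are returned as NaN — they are not
  corrected and must not be averaged with corrected ones; a
  non-convergent fit returns the input unchanged with a warning flag.
  Window bounds and the offset choice are parameters because the original
  procedure does not pin them down.
* **MAD screen** — outliers lie strictly beyond median ± 3×MAD with MAD
  unscaled (no 1.4826 consistency factor); bound values are kept; MAD = 0
  flags everything off-median and warns.
* **Quantal content** — corrected mean EJP over mean mEJP, with the
  Martin-type non-linear summation correction v/(1 − v/driving) (unit
  correction factor) applied to the evoked mean only.  The driving force
  is required input and never silently defaulted, since the original
  correction variant and driving force are not specified.

## Synthetic data

The generators exist because neither the terminals' energetic parameters
nor the raw traces are distributed with the model.  All are pure functions
of (spec, seed) using numpy's PCG64 (`default_rng`) with per-generator
streams, so outputs are bit-reproducible across platforms.

* **Terminal parameters** — uniform draws inside documented bounds whose
  magnitudes are anchored to the published context: mitochondrial density
  in 5–7 % (bracketing the published big-bouton densities of 6.29 % and
  6.42 %), production caps 0.079/0.154 mM/s/1 %, base rate 0.03–0.07 mM/s,
  volume 200–400 µm³, per-AP costs 10⁴–6×10⁵ molecules with decay
  constants from 50 ms (fast vesicle recycling) to 15 s (slow refilling).
  They are labelled synthetic in name and metadata and are NOT the real
  terminals' values; real values load through the YAML configuration.
* **Ratiometric traces** — 4 Hz ratio sampling (the acquisition cadence of
  the imaging protocols), numerator-channel monoexponential bleach (the
  denominator fluorophore is taken as photostable, so the ratio itself
  decays with τ_bleach — the regime the ratio correction addresses; a
  common-mode bleach would cancel in the ratio and exercise nothing),
  a stimulus-locked saturating-rise/exponential-decay response scaled to
  peak at exactly the programmed ΔR/R, two constant background regions,
  independent additive Gaussian noise per channel.  Ground truth
  (τ_bleach, peak ΔR/R) is returned alongside.
* **Amplitude samples** — mEJPs from a zero-truncated normal (selectable)
  with given mean and CV; EJPs drawn around the inverse-corrected value of
  (true QC)·(population mEJP mean), so the analysis-side correction
  recovers the truth exactly at CV = 0 and within sampling error
  otherwise.  Default sample sizes follow the protocol minima (10 EJPs,
  30 mEJPs).

What passing tests on these data do **not** show: recovery on real traces
with correlated noise, movement artefacts, saturation or non-exponential
bleaching; nor quantitative agreement with the real terminals' ATP
trajectories, which would require the unpublished parameter set.  The
qualitative model claims (buffering, cap effects, conservation) are
parameter-robust and are asserted as inequalities, not trajectories.

## Design notes and limitations

* Resting [ADP]: the printed equilibrium relation with the printed pools
  gives exactly 24.0 µM (7.128/297 mM), matching the 0.024 mM used for the
  simulations; a Methods sentence elsewhere quotes 24.2 µM, which is not
  reproducible from the stated inputs.  This package reports the
  relation-derived value.  The derived AMP (0.27 µM) and resting |ΔG|
  (38 kJ/mol) are insensitive to the difference.
* Single production pathway: no glycolytic ATP term, no oxygen/substrate
  limitation, no NADH or proton-motive-force state.
* Deterministic stimulation: no spike jitter, no per-spike variability in
  the energetic budgets.
* Group-comparison statistics (t tests, ANOVA) are out of scope; only the
  MAD screen is implemented on the analysis side.
* The CLI is a thin convenience layer; the library API and the
  `examples/` scripts are the primary interface.
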