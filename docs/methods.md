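# Methods

`sabre_kd` estimates protein–ligand dissociation constants from spin–spin
(R2) relaxation of a SABRE-hyperpolarized reporter ligand measured at
milli-Tesla field. This note describes the model, the estimation procedure,
the synthetic-data generator used for validation, and the numerical and
design choices that were genuinely open.

## Physical model

Three mass-action equilibria govern the speciation of the reporter ligand L
(3-amidinopyridine in the reference system):

* catalyst binding C + L ⇌ CL with association constant K_eq (mM⁻¹);
  the iridium polarization-transfer catalyst binds exactly one reporter
  ligand, with the deuterated coligand (DMSO-d6) occupying the remaining
  coordination sites. The coligand is carried in `SampleComposition` for
  bookkeeping but does not enter the equilibria.
* protein binding P + L ⇌ PL with dissociation constant K_D (μM);
* competitor binding P + S ⇌ PS with dissociation constant K_D,2 (μM).
  Competitor–catalyst binding is not modeled: competitors are added with
  the protein solution, after hyperpolarization.

All internal concentrations are mM; K_D and K_D,2 are accepted and reported
in μM with one explicit ÷1000 at the model boundary. Four conservation laws
close the system (total catalyst, ligand, protein, competitor).

Under fast exchange the observed relaxation rate is the population-weighted
average of the pool rates,

    R2,obs = ( [PL]·R2,PL + [CL]·R2,CL + [L]·R2,f ) / [L_tot],

with no exchange (R_ex) term: at ~0.85 mT chemical-shift differences vanish,
which is the simplification that makes the low-field experiment attractive.
R2,PL is large (the bound ligand tumbles with the protein), so a bound
fraction of a few percent dominates R2,obs.

The SABRE process converts parahydrogen into NMR-visible orthohydrogen,
which contributes a decaying component of opposite sign and roughly one
quarter of the ligand amplitude to the echo integrals. Its rate
(0.961 s⁻¹) and relative amplitude (1/4) are calibrated at high field and
assumed transferable to low field; `OrthohydrogenModel` makes that
assumption an explicit, overridable configuration.

## Equilibrium solver

The coupled system is reduced to one unknown, the free-ligand concentration
l: free catalyst follows in closed form from catalyst conservation, and
free protein p(l) is the positive root of the protein-conservation
quadratic (competitor saturation in closed form). The remaining ligand
conservation residual is strictly increasing in l, and is solved by damped
Newton iteration with the analytic derivative (cap 200 iterations,
convergence at 1e-12 absolute on residuals), falling back to bisection —
which is globally convergent here — if Newton stalls. Tests compare the
solver against an independent nested grid-refinement search (step refined
below 1e-9 mM) on random instances.

## Echo-train processing

The pulse sequence is p90–τ[2·p90–2·τ]×n with τ = 50 ms, p90 = 0.35 ms,
n = 100 at a ¹H frequency of 35,240 Hz. Processing choices:

* Echo times t_k = 2kτ at echo centers; the p90 durations (0.35 ms against
  100 ms spacing) are neglected, a sub-0.4% timing effect.
* Each echo is discrete-Fourier-transformed with the echo center as time
  zero; the spectrum is scaled by the dwell time so its full-axis integral
  equals the echo-center amplitude.
* Integration default is the real part after zero-order phasing on the
  first echo, with the phase held fixed across the train. Real-mode
  integration preserves sign, which matters because the orthohydrogen
  component has the opposite sign; magnitude mode is available by flag.
* The default window is ±3 linewidths (FWHM) around the tallest peak of the
  first echo's spectrum. For a Lorentzian line this captures ~90% of the
  peak area — a constant factor that cancels in rate estimation because the
  pipeline is linear in amplitude. Full-axis integration (`window=None`)
  recovers absolute amplitudes.
* No baseline correction by default; the decay model is A·exp(−R t) with no
  offset, since hyperpolarized signal decays to zero (offset and baseline
  flags exist for diagnostics).

The rate fit uses variable projection: for fixed R the amplitude is linear
and solved in closed form, leaving a 1-D problem in R that is minimized by
a 64-point grid bracket plus bounded Brent refinement, then polished on the
stationarity condition with the analytic derivative. The grid bracket
matters: once a decay has died inside the sampled window the RSS flattens
into a plateau where a bare Brent search can stall. Rate standard errors
come from the two-parameter Jacobian at the optimum.

## Orthohydrogen correction

The correction subtracts a simulated orthohydrogen integral series,
sign·(Â_L/ratio)·exp(−R2,o·t), from the measured integrals. The absolute
anchor Â_L (the ligand amplitude) is estimated by fitting the contaminated
series to a biexponential in which the orthohydrogen rate and relative
amplitude are fixed at their calibrated values and only (Â_L, ligand rate)
float. Â_L is constrained to the ligand's sign (nonnegative under the
default convention): without this constraint a negative-amplitude solution
at a large ligand rate can reproduce the data through the orthohydrogen
component alone whenever the two decay rates are similar.

## Estimation

All fits minimize a bounded residual sum of squares; equilibrium
concentrations can never exceed their totals by construction of the solver.

**Catalyst titration** (R2,f, R2,CL, K_eq from rates at several catalyst
levels): for fixed K_eq the model is linear in the two rates, so the fit
profiles the RSS over log₁₀K_eq — an 80-point scan with Brent refinement of
*every* local minimum — projects the rates out by weighted linear least
squares, and polishes the winner with bounded Levenberg–Marquardt. The
profile structure was chosen over plain multistart because the objective is
genuinely multimodal: with only three titration levels a strong-binding
branch (near-stoichiometric CL formation with a small R2,CL) reproduces the
same three observations *exactly* as a weak-binding branch. When two
profile minima tie within numerical precision the fit prefers the
weaker-binding (smaller K_eq) root and reports the choice implicitly
through the estimates; attaching measured [CL]/[L] bound-fraction ratios
(optional weighted residuals, default weight scaling ratio and rate
residuals to comparable size) removes the ambiguity — which is exactly why
the original experiment recorded those ratios at high field.

**Reporter-K_D calibration** (K_D, R2,PL from two observations: protein
only, and protein plus a competitor of known affinity): bounded least
squares in (log₁₀K_D, R2,PL) from ten spaced starts (or a caller-supplied
warm start for Monte Carlo refits). R2,PL is treated as a free nuisance
parameter — two observations, two unknowns; an exact fit is attainable for
consistent inputs, and bound-hitting solutions are flagged rather than
silently returned.

**Competitor K_D,2** (one observation, calibrated reporter held fixed): the
predicted rate is strictly increasing in K_D,2 (a weaker competitor
displaces less reporter), so the fit is bracketed root finding in
log₁₀K_D,2 over [10⁻³, 10⁷] μM. Observations outside the attainable range
return the nearest bound, flagged.

**Monte Carlo uncertainty**: observations are perturbed with independent
Gaussian noise — per-point replicate sd when available, else the rate-fit
standard error, else a fixed sd — and refit (default 10⁴ draws, seeded).
Each parameter is summarized by its mean and the narrowest contiguous
interval containing 90% of the draws (ties broken toward the lower window),
a highest-density-style summary chosen because the draw distributions are
typically skewed. Draws that end on a parameter bound are retained and
counted — they are what makes the mean occasionally fall outside the 90%
region, and that signature is reported, never clipped. More than 10%
failed draws is an error.

## Synthetic data

The generator produces the observables the pipeline consumes, from the
forward model down:

* integral series A·exp(−R2,obs·t_k) with R2,obs computed through the
  coupled equilibria from a ground-truth parameter set, plus the
  orthohydrogen term when configured, plus Gaussian noise of sd A/SNR
  (default SNR 16, the level of the dilution experiments);
* raw echo trains whose per-echo center amplitudes equal the simulated
  integrals, with a symmetric exponential envelope (T2* = 20 ms default)
  at a configurable offset (200 Hz default), so the full processing chain
  closes on the integral series;
* named scenarios with the published concentrations: catalyst titration at
  1/5/10 mM (ligand and coligand 10 mM), and the protein-injection
  conditions obtained by mixing 0.25 mL of stock with 1.25 mL of protein
  solution — final 0.167 mM catalyst, 1.67 mM ligand, 33.33 μM trypsin,
  14.40 mM competitor.

Ground-truth values not published anywhere had to be chosen once:
R2,PL = 40 s⁻¹, set so that a ~2% protein-bound fraction dominates the
observed rate, matching the qualitative behavior of the protein
experiments; and a benzamidine calibration constant of 18 μM, a nominal
literature-scale affinity for benzamidine–trypsin. The benzamidine constant
cancels out of every round-trip check because it is used identically in
generation and fitting. Optional log-normal shot-to-shot amplitude
variability (default sd 20% when enabled, off by default) mimics SABRE
polarization fluctuations.

What the generator does **not** emulate: cross-relaxation between ligand
and residual solvent protons, field drift, mixing transients after protein
injection, multi-peak spectra, or non-Gaussian noise. Passing round-trip
tests therefore demonstrates correctness of the estimation machinery under
the model's own assumptions, not robustness to every artifact of real
low-field data.

## Problem sizes and reproducibility

Validation runs use the experiment's native sizes: 100-echo trains, three
titration levels, two protein conditions plus one competition condition.
Monte Carlo summaries in the test pipeline use a few hundred draws; the
library default is 10⁴. Every stochastic component is seeded; pipeline
reports embed the config hash and seed, and rerunning with the same seed
reproduces the report byte for byte.

## Known limitations

* At SNR ≈ 16 with single-shot observations, K_D is weakly identified: the
  competition condition's protein-bound excess over the catalyst baseline
  is small, so its relative noise is large and the Monte Carlo intervals
  are wide. Replicate averaging (as in the real experiment) tightens them.
* The three-point titration degeneracy described above means titration-only
  data cannot distinguish weak-from strong-binding branches; use more
  levels or bound-fraction ratios.
* The orthohydrogen correction inherits the high-field-to-low-field
  transfer assumption for the contaminant's rate and relative amplitude.
* One-site, non-cooperative binding only; no ternary complexes, no
  activity-coefficient corrections.
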