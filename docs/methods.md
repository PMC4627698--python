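# Methods

## Model structure and conventions

The model is a deterministic mass-action ODE system over 32 state
variables: 20 early-signaling states (receptor engagement/trafficking, four
Syk forms, Lyn, SHP1/Csk/Cbp, BLNK/BTK/PLC2γ) and 12 downstream states
(DAG, PKC*, SOS_b, Ras*, Raf*, MEK_p, the two Erk phosphoforms, IKK*, IκB,
phospho-IκB, free NF-κB). Time is in minutes and concentrations in
arbitrary units; ligand (μg/mL) and orthogonal-inhibitor (μM) doses enter
through the conversion scalars `ligand_scale` and `oi_scale`. CD45 is a
constant input. Every reaction is first- or second-order mass action; each
"by phosphatases" dephosphorylation is a first-order background rate with
no explicit phosphatase species.

Free pools are eliminated by conservation (free Syk, Lyn, SHP1, Csk, Cbp,
clathrin, BLNK, BTK, PLC2γ, PIP2, PKC, SOS, Ras, Raf, MEK, Erk, IKK, and
the NF-κB:IκB complex). The implied free concentrations are clamped at
zero inside the right-hand side to guard against transient integrator
undershoot; the public `rhs` additionally raises when a conservation
residual is negative beyond tolerance.

Bookkeeping conventions worth stating explicitly:

* **Syk binding carries the receptor.** Syk binding consumes BCRp1/BCRp2
  and unbinding releases BCRp2, so a receptor occupied by bound Syk is
  accounted inside the Syk states. The reported BCR pool is therefore
  free + bound + p1 + p2 + internalized + Syk_b + Syk342 + Syk317; its only
  sinks are internalized-receptor degradation and, under AQL,
  orthogonal-inhibitor sequestration of receptor-bound Syk. With that
  definition the BCR pool is non-increasing along every trajectory.
* **Mass-balanced transcription.** Where one balance equation implies a
  partner term in another (Syk unbinding feeding BCRp2 from Syk_b; Y317
  dephosphorylation returning equally to Syk_b and Syk342 against its
  factor-2 loss; the Lyn de-autophosphorylation gain matching the full
  three-term loss; BTK_p and PLC2γ_p dephosphorylation returning to the
  bound forms, with the mirror losses on the bound forms), the partner term
  is included so that every pool closes exactly.
* **BLNK_p is a catalytic scaffold**: BTK, PLC2γ and SOS binding read its
  concentration without depleting it.
* **OI binding is irreversible** (association only), one reaction per Syk
  form, present only in the AQL scenario.
* **Downstream wiring.** PLC2γ_p converts the PIP2 pool to DAG
  (r13_kf/r13_kr); DAG activates PKC; PKC activates IKK; IKK*
  phosphorylates IκB both free and in the NF-κB complex (r38_kf),
  phospho-IκB degrades, freeing NF-κB; free NF-κB drives IκB resynthesis
  (negative feedback) and re-associates with new IκB. The MAPK branch runs
  SOS-on-BLNK_p (r19_kf) → Ras → Raf → MEK → two-step Erk phosphorylation
  (r18_kf), with reported Erkp = x_Erkp1 + x_Erkp2. Each activated species
  deactivates first order. "Non-degraded IκB" is free IκB plus IκB held in
  the complex, via NF-κB conservation.

The unstimulated model equilibrates with all receptor free and only the
Lyn/SHP1/Csk/Cbp module at nonzero levels, so downstream outputs are zero
at baseline by construction; `run_to_steady_state` verifies the residual
‖rhs‖∞ ≤ tol (default 1e−10 a.u./min).

## Surrogate nominal parameters

No fitted kinetic constants ship with the model; `bcrsignal.nominal`
provides a surrogate set of order-of-magnitude mass-action defaults (pool
totals of 1 a.u., rates 0.02–5 per minute, `ligand_scale` = 0.01 a.u. per
μg/mL so the 150 μg/mL maximum dose is near receptor saturation,
`r_oi_association` = 0.05 per μM·min so 1 μM inhibitor sequesters Syk
gradually and partially over 30 minutes). The set was chosen once so the
qualitative study phenotypes hold: a graded Erkp dose response at t = 5
over 5.5–150 μg/mL; response dynamics spread across the 30-minute window;
the MAPK cascade operating near saturation (so it buffers upstream
reductions) while the IKK/NF-κB branch stays in its linear regime (so
NF-κB tracks the DAG signal ~1:1 and is the more inhibitor-sensitive
readout). All quantitative screening tests generate synthetic data from
known vectors, so none of their conclusions depend on these defaults being
biologically calibrated.

## Numerical choices

* Integration: `scipy.integrate.solve_ivp` with the implicit BDF method;
  default tolerances rtol 1e−8 / atol 1e−10 (the screening and surface
  layers default to rtol 1e−6 / atol 1e−9 for throughput). Reporting grid:
  integer minutes 0..30.
* Steady state: chunked integration (100 min, growing ×10) until
  ‖rhs‖∞ ≤ tol, error with the final residual at t_max = 1e6 min.
* Basal normalization divides by max(basal, ε_basal) with ε_basal = 1e−6
  a.u., because downstream basals are structurally zero. Relative-to-basal
  values of downstream outputs therefore scale with 1/ε_basal; the
  objective J is insensitive to that scale because σ is proportional to
  the signal at these magnitudes.
* Readout times default to t = 5 min (Erkp) and t = 15 min (IκB/NF-κB).
* Wall-time budgets: response-surface points default to 30 s (config-
  selectable), screened candidates to 20 s; exceeding a budget flags the
  point halted / rejects the candidate with cause `"halted"` rather than
  stalling the sweep. Halted grid points are filled by linear interpolation
  on a triangulation of completed points (nearest-neighbor outside the
  hull) and flagged.

## Sensitivity estimator

First-order Sobol indices are estimated with a Saltelli-style pick-freeze
scheme (cost n·(d+2) model runs for d parameters; a vector-valued output —
the whole time course — costs the same as a scalar). Parameters are
sampled uniformly in log10 over ±1 decade by default. Two stabilizers
matter in practice and are part of the estimator's contract:

* outputs are centered by their grand mean before the pick-freeze products
  are formed (the raw estimator is dominated by the mean when it dwarfs
  the spread);
* when the output's coefficient of variation falls below `min_cv`
  (default 1e−4), the variance is integrator noise rather than signal and
  S is defined as 0. This also covers the exactly-constant case, including
  t = 0 where every trajectory starts at the same baseline.

The screening rule keeps a parameter when the median of S(t) over the 31
reporting times is ≥ 0.15 (exclusion is strict: only median < 0.15 drops a
parameter). Sensitivity of the regulatory-enzyme group is prone to
integration failures at wide ranges; failed sample rows are dropped, and
exceeding a configurable failure fraction raises a stiffness diagnostic
instead of returning silently censored indices.

The test suite validates the estimator against a brute-force double-loop
oracle (stratified outer grid, shared inner sample) on analytic functions,
against closed-form indices of additive models, and against
quadrature-derived indices of a linear ODE with a multiplicative
closed-form solution.

## Screening objective and noise model

Fitness is J = (y_obs − y_sim)/σ with boundary-inclusive acceptance
|J| ≤ η. For blot-style dose-response data, σ follows the linear model
σ = 0.0127 + 0.3084·y_obs, evaluated at the observed signal; replicate
time courses instead carry the sample SD of their replicates. Candidates
are Latin-hypercube samples in log10 space (±2 decades by default) over
the sensitive-parameter list only; the unstimulated baseline is shared
across candidates whenever no screened parameter touches the regulatory
module that sets it.

Because σ is evaluated at y_obs while the noise is generated at σ(y_true),
the band is asymmetric at the ~30% relative noise of the linear model: a
low draw shrinks σ and inflates |J|. Two consequences are quantified in
the tests rather than hidden: (i) band coverage is checked on the
single-observation Erkp screen, where the ±2σ band holds ~95% of noise
replicates — with k independent observations the joint coverage shrinks
like 0.954^k, so multi-observation datasets need larger η for the same
coverage; (ii) the selectivity Monte Carlo (random two-decade candidates
versus a 0.1-decade neighborhood of the generating vector) runs on
noise-free data, where |J| measures pure model distance and the
generating vector scores exactly 0.

## Synthetic data

Three dataset shapes mirror the screening pipeline's assumptions:
`healy_like` (Erkp at t = 5 under 20 μg/mL plus non-degraded IκB at t = 15
at doses 5.5/16.5/50/150 μg/mL, relative to basal, linear-σ uncertainty),
`inhouse_like` (triplicate Erkp time course at 10 μg/mL on t = 0..30,
normalized to the final time point, replicate-SD uncertainty), and
`oh_like` (wild-type and mutant NF-κB dose responses, both normalized by
the wild-type response at maximum dose; the mutant arm runs under AQL with
the Y317 phosphorylation rate scaled ×10 by default, mirroring the manual
mutant retuning route). Noise is Gaussian truncated at zero; at the
signal-to-noise ratios of the linear model the truncation bias is
negligible, and the generated tables are byte-identical under a fixed
seed. The generator emulates the statistical structure of blot
densitometry — not loading controls, censoring, or image artifacts — so
passing recovery tests demonstrates the screening machinery, not
instrument realism.

## Response surfaces and the collapse exponent

Surfaces sweep log10 k_f and log10 k_r over ±2 decades by default (the
literature-derived ranges are not pinned; both axes are config-driven) at
a 20 μg/mL dose. The metric is Erkp(t=5)/max_WT(Erkp) −
NF-κB(t=15)/max_WT(NF-κB), with the normalizers taken from the wild-type
zero-inhibitor surface. The region partition splits the k_r axis at
log10 k_r = −0.5. The collapse exponent α̂ maximizes, over a grid of
candidate α (default 0 to 1.5 in steps of 0.05), the variance explained by
the best monotone (isotonic, either direction) 1-D fit of the metric
against log10(k_f) − α·log10(k_r); a constant metric returns a degenerate
flag instead of an exponent. Isotonic regression was chosen over a
smoothing spline because the collapsed profiles are sigmoidal and a
monotone fit cannot manufacture spurious structure at small sample sizes;
the fit kind is recorded in the result.

Syk-allocation sweeps realize each power-law affinity with k_r held fixed
(k_f = K·k_r^α), read the Syk fractions at t = 30 of stimulation, and sum
to one by conservation. The amplification diagnostic compares wild type
against mutant+OI at one readout time: the fractional drop of an output
divided by the fractional drop of DAG, the last species feeding both
branches.

## Workflow and problem sizes

`run_workflow` executes synthesize → sensitivity → screen → dose_response
→ contour with per-stage seeds derived from the global seed by hashing the
stage name, and writes a manifest of artifact content hashes; a rerun with
the same config and seed reproduces the manifest exactly. The shipped
defaults are desk-scale — dozens-to-hundreds of LHS candidates, 6–8 grid
points per surface axis, a few dozen Sobol samples per group — chosen so a
full pipeline run completes in minutes on one core; all sizes scale up
through the config.

## Known limitations

* Ca²⁺/NFAT/ionomycin dynamics and dynamic CD45 are out of scope; CD45 is
  a constant input, so the regulatory module has a fixed basal operating
  point.
* The 22-species census of the biological system is not asserted; the
  package fixes the 32 model variables and documents its parameter
  inventory (88 symbols) rather than forcing a particular count.
* Whether "Syk bound to clathrin" is a distinct species is unresolved;
  the clathrin-localization reaction is catalytic in Syk342, so no such
  state is modeled.
* The receptor occupied by an OI-inhibited Syk is sequestered out of the
  BCR pool rather than recycled; this is the conservative reading of the
  irreversible-inhibition kinetics.
* Exact reproduction of any fitted time-course or dose-response figures is
  not claimed anywhere: without published parameter vectors those fits are
  not recomputable, and the package's claims are property-level
  (monotonicity, conservation, coverage, collapse) plus the printed
  noise-model coefficients.
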