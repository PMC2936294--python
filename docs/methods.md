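# Methods

## Scope

`pichia_mfa` validates a small constraint-based model of *Pichia pastoris*
central carbon metabolism against published extracellular-rate datasets.
Three complementary instruments are implemented: elementary-flux-mode
analysis with carbon yields, possibilistic metabolic flux analysis (MFA),
and a variance-weighted least-squares consistency residual. The package is
organised so that every step — model I/O, enumeration, the consistency LPs,
dataset handling, synthetic-data generation, and the orchestrated study —
is callable as a library function; the `pichia-mfa` CLI is a thin wrapper.

## The constraint-based model

The model is the polyhedral set

    M = { v : N·v = 0,  v_i >= 0 for irreversible i }

with `N` the stoichiometric matrix over the balanced internal metabolites.
No kinetics, thermodynamics or ATP/energy-cofactor balancing is included;
resources devoted to recombinant-protein production are likewise not
modelled, which is deliberate: the point of the study is to see how far such
a minimal description carries.

### The shipped network is a reconstruction

The original supplementary reaction list for this network is not publicly
archived, so `data/pichia_pastoris.tsv` was **reconstructed** from the
published description: EMP glycolysis, TCA cycle, pentose-phosphate pathway,
fermentative pathway, methanol oxidation plus XuMP assimilation, glycerol
uptake, with NAD, NADP, acetyl-CoA, oxaloacetate and pyruvate split into
cytosolic/mitochondrial pools and a lumped biomass equation. The published
structural facts are honoured exactly:

* 44 reactions, 45 compounds, 36 balanced internal metabolites;
* reversible reactions exactly {2–8, 15, 22–27, 29, 34, 41} (1-based);
* 8 degrees of freedom (rank(N) = 36).

Where the description under-determines the chemistry, choices were fixed
once: NAD-dependent mitochondrial isocitrate dehydrogenase, an NAD-coupled
acetaldehyde dehydrogenase in the pyruvate-dehydrogenase bypass, a
mitochondrial NADP-malic enzyme as the mitochondrial NADPH source, and a
glycerol dehydrogenase (DHA pathway) beside glycerol kinase — all documented
yeast biochemistry. Every reaction is written carbon- and redox-consistently
(electrons tracked through NADH/NADPH/FADH2 and O2).

The lumped biomass equation (per Cmol dry weight, ~25.9 g) draws G6P, R5P,
E4P, pyruvate, cytosolic and mitochondrial acetyl-CoA, oxaloacetate,
2-oxoglutarate, NADPH in both pools and ammonium. Its free coefficients —
the 2-oxoglutarate demand and the CO2 co-product — were calibrated so that
the maximal growth yields of the network reproduce the published values
(glucose 4.93, glycerol 2.46, methanol 0.82 Cmol DW mol⁻¹); the NADH
coefficient (which sets the biomass degree of reduction, here 4.02 electrons
per Cmol) was selected from a small physiological range for best agreement
with the published consistency degrees. Calibration used only quantities the
original study prints about its own model.

What the reconstruction does **not** reproduce: the elementary-mode census
is 115 modes (16 without biomass, 5 with ethanol) against the published
98/17/9 — mode counts are combinatorially sensitive to the exact lumping;
the glycerol+methanol maximal yield comes out 2.38 vs the printed 2.25; and
the seven measurable quantities add 5 (not 7) independent constraints,
because the reconstruction's exact carbon *and* electron conservation laws
both live on the measured exchange fluxes. The acceptance suite asserts the
published numbers and these tests fail, by design, until the original matrix
becomes available.

## Elementary-mode analysis

Enumeration uses the tableau double-description method on the flux cone:
reversible reactions are split into forward/backward pairs, one balance
constraint is processed at a time (cheapest first), candidate rays from
positive/negative combination are kept only if they pass the standard
adjacency/elementarity test (no third ray's support inside the union),
futile two-cycles from the splitting are discarded, and pairs are re-fused.
Correctness is cross-checked in the tests against an independent exhaustive
support-subset oracle (a support S is elementary iff null(N restricted to S)
is one-dimensional, fully supported and sign-feasible) on a library of
hand-verified toys and on randomly generated networks of up to 7 reactions.

Modes are scaled so total substrate consumption is 1 mol (fallback: largest
coefficient 1 for substrate-free modes). Yields per mode are Cmol biomass
per mol of substrate consumed (per-Cmol basis available; bounded by 1 via
carbon conservation). Coefficients below 1e-9 after scaling count as zero;
arg-max ties break to the lowest mode index.

## Possibilistic MFA

Each measurement w of a flux v is relaxed as

    w = v + eps1 - mu1 + eps2 - mu2,   0 <= eps2 <= eps2max, 0 <= mu2 <= mu2max

with cost J = alpha·eps1 + beta·mu1 and possibility pi = exp(-J) (natural
logarithm throughout). Default shaping assigns full possibility within ±5%
of the measured value and possibility 0.1 at ±20%, i.e.
eps2max = mu2max = 0.05·s and alpha = beta = ln(10)/(0.15·s) with
s = max(|w|, zero_floor). Zero-valued measurements (common for glucose and
ethanol in these datasets) use `zero_floor` = 0.05 mol kg⁻¹ h⁻¹ as the
reference scale, keeping the LP bounded while treating zeros as small but
uncertain.

All quantities are linear programs (HiGHS via `scipy.optimize.linprog`):

* **consistency degree**: min J subject to the model and measurement
  constraints; pi(v_mp) = exp(-J*);
* **gamma-intervals**: min/max v_i subject additionally to a cost budget.
  Two budget conventions are provided: *absolute* (J <= -ln gamma; empty and
  flagged when gamma exceeds pi(v_mp)) and *conditional*
  (J - J* <= -ln gamma). Prediction reports use the conditional form — that
  is the stated semantics of the interval definition, and it is the only
  form that yields intervals for datasets whose own consistency is below
  gamma;
* **minimal full-consistency band**: the smallest uniform relative band b
  such that some feasible v satisfies |v_i - w_i| <= b·max(|w_i|, floor) for
  every measurement, solved as a single LP in (v, b).

Monotonicity properties (widening bands or dropping measurements never
decreases pi; intervals are nested in gamma) are enforced as tests.

## Weighted-least-squares residual

phi = min (w - v_m)' F⁻¹ (w - v_m) over M, with F diagonal,
sd = 10% of the measured value (floored like the possibilistic scale). The
QP is solved in the 8-dimensional nullspace of N with the irreversibility
rows as linear inequality constraints (`trust-constr`, analytic gradient and
Hessian); an equality-only closed form (normal equations) serves as the test
oracle. Because of the inequality constraints phi is *not* chi-square
distributed; no p-value is emitted, and the chi-square reference threshold
is attached only when no inequality is active at the optimum.

## Datasets and units

The eleven literature datasets ship as a TSV fixture transcribed
digit-for-digit (checksum-tested). mu is used directly in Cmol kg⁻¹ h⁻¹ and
maps to the biomass efflux; substrate uptakes, ethanol production, OUR and
CPR map to their exchange reactions with uptakes positive. Specific protein
productivity q_p is carried but never mapped by default — the model has no
protein efflux. Ethanol values of 0.00 are included as measurements; they
actively constrain the fermentative fluxes.

## Synthetic data

* **Rejection batteries**: uniform independent draws per quantity. Battery 1
  draws every quantity in [0, 10]; battery 2 uses the physiological ranges
  spanned by the literature data (mu 1.5–6, glucose 0–2, glycerol 0–2.7,
  methanol 0–2.7, ethanol 0–0.1, OUR 2.1–7.2, CPR 1.5–4). The distribution
  and size are not specified in the original study; uniform draws with
  n = 1000 (CLI default) are the simplest reading, and the acceptance checks
  use n = 500 per battery with a fixed seed, which reproduces the reported
  rejection rates (≈99% and ≈95%) while keeping runtime in seconds.
* **Ground-truth flux vectors** are Dirichlet(1) mixtures of the elementary
  modes — exactly feasible by construction (exactness was preferred over
  uniform coverage of the cone, which parameter-recovery tests do not need).
* **Noisy read-outs** multiply each exchange flux by an independent uniform
  factor in [1±rel_noise] before shaping. The generator emulates random
  relative measurement error only — no drift, autocorrelation or systematic
  bias — so passing recovery tests demonstrate correctness of the machinery,
  not robustness to structured real-world error.
* **Toy networks** (chain, branch, reversible cycle, diamond with futile
  cycle, substrate choice) ship with oracle-enumerated mode sets.

## Numerical choices

LP feasibility/optimality are HiGHS defaults (~1e-9). The nullspace and rank
computations use SVD with tolerance max(m,n)·eps·sigma_max. J* is clipped at
0 before exponentiation. Steady-state verification of enumerated modes uses
tol 1e-7 after canonical scaling. The WLS QP polish runs to xtol 1e-14.
Battery seeds derive from the user seed; batteries 1 and 2 use consecutive
seeds.

## Known limitations

* The stoichiometric matrix is a calibrated reconstruction; combinatorial
  quantities (mode census, mixed-substrate yields, measurement-set rank) and
  roughly a quarter of the published consistency degrees differ from the
  original (documented above and visible as failing acceptance tests).
* With 7 measured quantities and two exact conservation laws the measured
  system retains 3 degrees of freedom, so flux intervals here are somewhat
  wider than those of the original model.
* The chi-square reference for phi is informational; with active
  irreversibility constraints no calibrated significance level exists.
* Elementary-mode enumeration is exact but not genome-scale: the
  double-description tableau is intended for networks of this size
  (tens of reactions); a configurable ray cap raises an explicit error
  rather than truncating.
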