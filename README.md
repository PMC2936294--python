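# pichia-mfa

Constraint-based validation of a small stoichiometric model of *Pichia
pastoris* central carbon metabolism — the methylotrophic yeast used as a
workhorse for heterologous protein expression — for researchers who need to
assess whether a medium-sized metabolic network is consistent with scarce,
imprecise extracellular measurements (growth rate, substrate uptake, gas
exchange) before trusting it for flux estimation, monitoring or control.

The model is the constraint set

```
N·v = 0,    D·v ≥ 0
```

over 44 reactions and 36 balanced internal metabolites (glycolysis, TCA,
pentose-phosphate, fermentative pathway, methanol oxidation/assimilation and
glycerol uptake, with compartmented NAD/NADP/AcCoA/OAA/pyruvate pools and a
lumped biomass equation; 8 degrees of freedom). Three instruments are built
on it:

1. **Elementary flux modes** — all support-minimal steady-state flux
   distributions, enumerated by double description, classified by substrate
   and product, with maximal carbon yields per substrate combination.
2. **Possibilistic MFA** — each measurement `w` of a flux `v` is relaxed as
   `w = v + ε₁ − μ₁ + ε₂ − μ₂` with a linear cost `J = α·ε₁ + β·μ₁`; a flux
   state has possibility `π = e^(−J)`. The consistency degree `π(v_mp)`,
   flux intervals at possibility level γ, and the smallest uniform
   measurement band achieving full consistency are all linear programs.
   Defaults: ±5% deviations fully possible, ±20% has possibility 0.1.
3. **Weighted least squares** — the classical residual
   `φ = min (w−v)' F⁻¹ (w−v)` over the feasible set with 10% relative
   standard deviations (reported as a raw index; the χ² test is invalid
   under inequality constraints).

Eleven published culture datasets (glucose, glycerol, methanol and mixed
feeds) ship as fixtures, together with generators for random rejection
batteries and noisy synthetic measurements.

The shipped network is a faithful **reconstruction** from the published
description of the original model (whose supplementary reaction list is not
publicly archived); structural counts, reversibilities and maximal yields
are reproduced exactly, while mode-census details differ — see
`docs/methods.md`.

## Worked example

Consistency of the eleven datasets with the model:

```
$ pichia-mfa consistency
id      phi     pi      band_to_full
D1      0.03    1.00    0.9%
A1      0.24    1.00    2.8%
A2      1.10    0.83    5.4%
A3      2.69    0.26    9.8%
A4      5.19    0.09    14.1%
B1      0.11    1.00    1.7%
B2      0.75    0.93    5.2%
B3      2.13    0.36    8.6%
C1      0.11    1.00    1.7%
C2      0.74    1.00    4.5%
C3      1.58    0.51    6.9%
```

`pi = 1.00` means some flux distribution satisfies the model within ±5% of
every measurement — the glucose chemostat D1 needs under 1% stretch. Low
values flag datasets that require large measurement errors to be feasible:
A4 (`pi = 0.09`, a 14% band needed) is the scenario with the highest
recombinant-protein productivity, a demand the model deliberately omits.
`phi` is the weighted-least-squares residual and ranks the datasets the
same way.

Predicting the growth rate after removing it from each dataset:

```
$ pichia-mfa predict --exclude biomass
id      measured  estimate  [0.8]         [0.5]         [0.1]
D1      3.86      3.56      [3.30, 4.24]  [3.12, 4.42]  [2.52, 5.03]
A1      1.88      1.57      [1.42, 2.02]  [1.32, 2.12]  [0.97, 2.46]
...
```

Every measured growth rate falls inside the γ = 0.1 interval of its
leave-one-out estimate — the under-determined model still has predictive
power thanks to the irreversibility constraints.

Elementary-mode census and maximal theoretical yields (Cmol DW per mol of
substrate):

```
$ pichia-mfa ems
elementary modes: 115
without biomass production: 16
producing ethanol: 5
max yield on glucose: 4.93 (mode 16)
max yield on glycerol: 2.46 (mode 18)
max yield on methanol: 0.82 (mode 21)
...
```

No experimental yield exceeds its theoretical maximum (e.g. D1 achieves
3.98 of the 4.93 possible on glucose); glucose is the most efficient
substrate and methanol the worst, also in mixtures.

The full study (consistency table, growth prediction, flux-sign report,
rejection batteries) runs with `pichia-mfa validate --out report/`.

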