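# clampeq

Thermodynamic analysis of complexin/SNARE assembly: binding equilibria,
isothermal titration calorimetry (ITC) thermogram simulation and fitting,
a dynamic-light-scattering (DLS) oligomerization model, and FRET
donor-quenching distance determination — with seeded synthetic-data
generators replacing the wet-lab instruments.

## Who this is for

Complexin clamps SNARE-mediated membrane fusion by inserting its accessory
helix (CPX_acc) into the t-SNARE groove of a neighbouring half-zippered
SNAREpin. Testing that model quantitatively requires (i) showing that a
blocking fragment saturates the competing central-helix site, (ii)
measuring micromolar CPX_acc–t-SNARE affinities by ITC, (iii) relating the
cross-linking equilibrium to the oligomer sizes seen by DLS, and (iv)
placing the accessory helix in space by FRET. `clampeq` packages each of
those calculations as a tested, reusable estimator, for anyone analysing
calorimetric titrations, self-associating complexes, or donor-quenching
FRET — with or without the SNARE biology.

## The models

- **1:1 equilibrium**: [RL] = 2RL/(S+√(S²−4RL)), S = R+L+K_d (the stable
  conjugate root); percent saturation 100·[RL]/R. ΔG = −RT ln K_a,
  TΔS = ΔH − ΔG (kcal/mol, R = 1.987×10⁻³ kcal mol⁻¹ K⁻¹).
- **ITC (Wiseman) isotherm**: Q = n·Mt·ΔH·V₀/2·[A − √(A² − 4Xt/(n·Mt))]
  with A = 1 + Xt/(n·Mt) + 1/(n·K_a·Mt), totals after the perfusion
  displacement correction; per-injection heats and NDH follow the
  calorimeter convention. A two-independent-site-classes variant solves
  the free-ligand mass balance numerically for bivalent titrants.
- **DLS oligomer model**: bound probability p from [free]² = K_d[bound],
  mean chain length N = 1/(1−p) = (1+√(1+4C/K_d))/2, radius r = √N·r₀.
- **FRET**: E = 1 − ∫F_DA/∫F_D over the donor band; r = R₀(1/E − 1)^(1/6).

See `docs/methods.md` for assumptions, parameterizations and limitations.

## Worked example

Simulate a realistic titration of complexin fragment into the half-zippered
SNARE complex (210 µM syringe, 14 µM cell, 20 × 2 µL injections, 2% noise),
then fit it back:

```python
from clampeq import (BindingParameters, OneSiteBindingModel,
                     TitrationExperiment, saturation_percent)
from clampeq.synthetic import GeneratorConfig, gen_itc

exp = TitrationExperiment.standard(cell_concentration=14e-6,
                                   syringe_concentration=210e-6,
                                   first_injection_volume=None)
truth = BindingParameters(dissociation_constant=457e-9, enthalpy=-10.0,
                          stoichiometry=1.0)
thermogram = gen_itc(exp, truth, GeneratorConfig(seed=42, noise_fraction=0.02))[0]
print(OneSiteBindingModel(thermogram, exp).fit().summary())
```

```
Calorimetric binding fit
==========================================================
Model:              OneSiteBindingModel
Injections fitted:  20
SSR (kcal/mol)^2:   0.472092
n  = 0.9985 +/- 0.0093
Kd = 4.502e-07 M +/- 4.4e-08
Ka = 2.221e+06 1/M
dH = -9.912 +/- 0.12 kcal/mol
dG = -8.657 kcal/mol
TdS = -1.255 kcal/mol
c-value = 31.05
```

The fit recovers the generating K_d = 457 nM within its standard error
(450 ± 44 nM), a stoichiometry of one site, and the binding enthalpy; ΔG
and TΔS are derived through the thermodynamic relations. The c-value of 31
sits comfortably in the identifiable range.

The same equilibrium layer answers the blocking question directly — a
1.5-fold excess of the central-helix fragment over 20 µM complex at
K_d = 457 nM occupies

```python
>>> saturation_percent(20e-6, 1.5, 457e-9)
95.94431617629958
```

i.e. ~96% of the central-helix sites, so heats measured on the blocked
complex report the accessory-helix interaction.

## Command line

```bash
clampeq itc simulate --cell-conc 14 --syringe-conc 210 --kd 457 --dh -10 \
    --noise 0.02 --seed 1 --out tg.csv
clampeq itc fit --cell-conc 14 --syringe-conc 210 --in tg.csv
clampeq dls fit --in radii.csv
clampeq fret efficiency --donor d.csv --donor-acceptor da.csv --r0 38
clampeq saturation --receptor 20 --kd 457
clampeq gen dls --kd 25 --r0 3.5 --noise 0.03 --seed 1 --out radii.csv
```

All inputs/outputs are plain CSV (schemas in `clampeq/io.py`); seeded runs
are byte-reproducible.

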