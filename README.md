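# scfkin

Quantitative analysis of SCF (Skp1–Cullin1–F-box) ubiquitin-ligase
poly-ubiquitylation pathways: pre-steady-state chain kinetics,
Michaelis–Menten enzyme characterisation, absolute protein
quantification, and differential CRISPR-screen scoring — with seeded
synthetic-data generators so every stage is testable without wet-lab
inputs.

## Who this is for

SCF ligases build poly-ubiquitin chains on substrates through a
division of labour between chain-*initiating* enzymes (the E3 ARIH1,
the E2 UBE2D3) and chain-*elongating* E2s (UBE2R1/2, UBE2G1). Deciding
which enzyme matters in a cell requires combining three quantitative
strands: per-step transfer rates from single-encounter quench-flow
experiments, Michaelis constants from multi-turnover titrations, and
the enzymes' actual intracellular concentrations. This package
implements that analysis chain for kineticists and systems biologists
working on cullin-RING ligase biochemistry.

## The models

**Single-encounter chain kinetics.** Under single-encounter conditions
(excess unlabelled competitor blocks rebinding) each substrate molecule
moves irreversibly through

```
S0 → S1 → S2 → … → S_{n−1} → S≥n        dS0/dt = −k1·S0
                                         dSi/dt = ki·S_{i−1} − k_{i+1}·Si
```

where `Si` is substrate carrying `i` ubiquitins, `ki` [s⁻¹] is the
observed rate of the *i*-th transfer, and `S≥n` aggregates chains too
long to resolve on a gel. The solution is the classical Bateman sum of
exponentials; coincident or nearly coincident rates are handled without
cancellation via confluent divided differences (see
`docs/methods.md`). `SingleEncounterModel` fits the rates to gel
densitometry fractions by multi-start nonlinear least squares and
reports Gauss–Newton standard errors and a χ² goodness-of-fit p-value.

**Multi-turnover saturation.** Titrating the E2/E3 against a fixed
ligase–substrate complex follows `v = kcat·[E]/(Km + [E])`;
`MichaelisMentenModel` estimates `Km` [nM] and `kcat` [min⁻¹].
Catalytic efficiency `kobs/Km` [M⁻¹s⁻¹] compares elongating enzymes.

**Copies per cell.** SILAC-heavy cells lysed in buffer spiked with
light recombinant standards give heavy:light SRM ratios, converted as
`copies/cell = ratio × spike × N_A / n_cells` and
`conc = copies/(N_A·V_cell)` with a spherical cell-volume model.

**Screen differentials.** Gene-level fitness scores of knockout
screens minus the mean of control screens expose synthetic-lethal
interactions; a Hamming-distance scan flags sgRNA off-target sites.

## Worked example

Simulate a duplicate quench-flow experiment from the published
ARIH1/Cyclin E transfer rates (0.5, 0.2, 0.08 s⁻¹) with realistic
densitometry noise, then re-estimate the rates:

```python
from scfkin import (RateSet, NoiseSpec, gen_quenchflow, fit_rates,
                    closed_form_fractions, distribution_summary)

tcs = gen_quenchflow(RateSet([0.5, 0.2, 0.08]),
                     noise=NoiseSpec(additive_sd=0.02, replicates=2, seed=42))
res = fit_rates(tcs)
print(res.summary())
```

```
Single-encounter chain fit
==============================================
Time courses (replicates): 2
Observations:              78
Residual df:               75
SSR:                       0.01977
Converged:                 True
GoF p-value (chi2):        0.369
----------------------------------------------
step      k (1/s)           SE
   1       0.5052      0.00679
   2       0.1978      0.00411
   3      0.08297      0.00487
----------------------------------------------
```

All three generating rates are recovered within ~1 standard error, and
the χ² p-value of 0.37 says the closed-form chain model is consistent
with the noise level of the duplicates. The fitted chain predicts the
product distribution at the 10 s quench point:

```python
d = distribution_summary(closed_form_fractions(res.rateset, [10.0]),
                         10.0, threshold_length=2)
print(round(d.mean_chain_length, 2), round(d.fraction_at_least, 3))
# 2.03 0.777
```

i.e. ~2 ubiquitins per substrate on average and 78% of molecules
carrying at least two — the modest-processivity signature of this
initiating E3. Efficiency comparison of the elongating E2s:

```python
from scfkin import catalytic_efficiency
print(f"{catalytic_efficiency(40.0, 317.0).rounded:.2g}")  # 1.3e+08 M^-1 s^-1
```

The same stages are scriptable from the shell (`scfkin simulate`,
`quenchfit`, `mmfit`, `srm`, `screendiff`, `report`, `fixtures`); run
`scfkin --help`.

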