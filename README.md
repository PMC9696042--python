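# radiokin

Mass-action kinetics of water radiolysis for radiation-crosslinked peptide
nanogels: pulse-radiolysis competition experiments, thiocyanate dosimetry,
and the dose-resolved crosslinking of histidine/glycine peptides under
γ-irradiation.

## The problem

Irradiating a dilute aqueous peptide solution produces the water-radiolysis
primaries — hydroxyl radicals (·OH), hydrated electrons (e⁻aq) and H atoms —
with radiation-chemical yields *G* = 0.287, 0.27 and 0.055 µmol L⁻¹ Gy⁻¹.
·OH attacks the imidazole ring of histidine residues to give OH-adduct
peptide radicals; pairwise recombination of those radicals forms covalent
crosslinks, which is how His/Gly peptides (HGHGH "H5", HGGGHGGGH "H9") gel
into sub-100 nm nanogels. Two quantitative questions drive the package:

1. **How fast does a peptide react with ·OH?** Measured by thiocyanate
   competition kinetics: in N₂O-saturated KSCN solution every ·OH (including
   e⁻aq converted by N₂O) ends up as the chromophore (SCN)₂⁻·
   (ε = 7100 L mol⁻¹ cm⁻¹ at 472 nm). A competing peptide suppresses the
   plateau absorbance according to

   Abs₀/Abs = 1 + (k_pep/k_SCN) · [peptide]/[SCN⁻],  k_SCN = 2.8 × 10¹⁰ M⁻¹ s⁻¹,

   so a straight-line fit of Abs₀/Abs − 1 against the concentration ratio
   yields k_pep.

2. **How does crosslink density grow with absorbed dose?** A mass-action
   network over oligomer size classes: Pₙ + OH → Rₙ (adduct radicals),
   Rₙ + Rₘ → Pₙ₊ₘ (one crosslink bond per event, k = 10⁴ M⁻¹ s⁻¹),
   OH-driven degradation of oligomers (10⁹ M⁻¹ s⁻¹), O₂ quenching of the
   monomer radical, and ring-opening of the OH-substituted product —
   integrated under a continuous dose rate with G-value source terms.

Both are built on a generic stiff mass-action ODE engine (`radiokin.core`)
with instantaneous-pulse and continuous irradiation protocols.

## Worked example

```python
import radiokin as rk

# competition experiment: full ODE pulse network for H5, then the fit
ds = rk.simulate_competition_experiment(rk.PEPTIDE_TABLE["H5"],
                                        conc_ratios=(0.25, 0.5, 1, 1.5, 2))
fit = rk.fit_competition(ds)
print(f"k(H5 + OH) = {fit.k_estimate:.3e} M^-1 s^-1")
# k(H5 + OH) = 4.204e+09 M^-1 s^-1        (table value 4.2e9)

# gamma crosslinking: 0.1 wt% aerated H5, 10 kGy/h to 15 kGy
tc, curve = rk.simulate_gamma(rk.PEPTIDE_TABLE["H5"])
print(f"crosslink density at 15 kGy: "
      f"{curve.crosslink_umol_per_l[-1]:.0f} umol/L")
# crosslink density at 15 kGy: 1445 umol/L
```

The first number is the OH rate constant recovered by fitting the simulated
competition data — it reproduces the constant the network was built with,
closing the loop between the forward model and the estimation procedure.
The second is the cumulative concentration of crosslink bonds after 15 kGy;
the dose curve rises steeply once the dissolved O₂ (250 µmol/L) is depleted
and flattens above ~10 kGy as the peptide is consumed (the rise over
10→15 kGy is 16%).

The numbered drivers under `analysis/` run the complete study:
`01_pulse_trace.py` (dosimeter transient + dose round trip),
`02_competition_fit.py` (H5/H9 rate constants), `03_gamma_crosslinking.py`
(dose–response curves), `04_noise_recovery.py` (Monte-Carlo recovery from
noisy synthetic data). Each writes its tables under `results/`.

There is also a CLI:

```bash
radiokin simulate-pulse --dose-gy 4.5 --out trace.csv
radiokin simulate-competition --peptide H9 --out ds.csv
radiokin fit-competition --data ds.csv --out fit.json
radiokin simulate-gamma --peptide H5 --out curve.csv
radiokin export-network --network crosslink --peptide H5 --out net.yaml
```

Every command writes a JSON manifest of its resolved parameters next to its
output, so any file is regenerable from its manifest.

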