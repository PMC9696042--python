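# Methods

## Model

The package simulates homogeneous aqueous radiation chemistry as a
mass-action reaction network with radiolytic source terms. For species
concentrations **c** (mol L⁻¹), reactions of overall order 1 or 2 with rate
constants k (s⁻¹ / M⁻¹ s⁻¹), and a dose rate r(t) (Gy s⁻¹),

d**c**/dt = S·v(**c**) + **g**·r(t),

where S is the net stoichiometry matrix, v the mass-action rates
(k[A][B] for A+B, k[A]² for 2A with a factor-2 consumption of A), and
**g** the G-value vector converted from µmol L⁻¹ Gy⁻¹ to mol L⁻¹ Gy⁻¹.
Primary yields: G(·OH) = 0.287, G(e⁻aq) = 0.27, G(H) = 0.055 µmol L⁻¹ Gy⁻¹.
Higher-order reactions are rejected: every reaction in scope is uni- or
bimolecular. The model is homogeneous — no spur/track structure, diffusion
kinetics, temperature or pH dependence.

Two conditioning regimes are built in:

* **aerated** — dissolved O₂ at 250 µmol/L scavenges e⁻aq (1.9 × 10¹⁰) and
  H (2.1 × 10¹⁰ M⁻¹ s⁻¹), leaving ·OH the reactive species;
* **N₂O-saturated** — ~25 mmol/L N₂O converts e⁻aq to ·OH
  (9.1 × 10⁹ M⁻¹ s⁻¹), so the effective OH yield is
  G(OH) + G(e⁻aq) = 0.557 µmol L⁻¹ Gy⁻¹. A literature value of 0.567 for
  this lumped yield circulates; the package computes the conversion
  explicitly from its own primaries and only exposes 0.567 as a named
  constant (`G_OH_N2O_LUMPED_PAPER`) for users who want it.

The three scavenging constants above are literature values for steps whose
rates the crosslinking analysis does not otherwise pin down; all are
overridable per `ConditionSpec`.

## Integration

`scipy.integrate.solve_ivp` with LSODA and an analytically assembled
Jacobian; the bimolecular constants reach 2.8 × 10¹⁰ M⁻¹ s⁻¹ while
irradiations last up to hours, so the system is very stiff and an explicit
solver is hopeless. Defaults rtol = 10⁻⁸, atol = 10⁻¹⁵ mol/L
(concentrations span ~10⁻¹³–10⁻² mol/L). The integration is split at every
source discontinuity (pulse edges, end of irradiation) so the solver never
steps across one. Instantaneous pulses are state jumps of G×dose at the
pulse time — the 10 ns electron pulse is three orders of magnitude below
the fastest chemistry observed (≈ 4 ns only for e⁻aq + N₂O, but the
observable chemistry is ≥ 100 ns), and a rectangular-delivery option exists
for sensitivity checks. Negative solver excursions are clipped to zero on
output; a clip exceeding 10× the per-species error scale (atol + rtol·|c|ₘₐₓ)
raises instead of being hidden. Accuracy is verified against closed forms
(first-order decay, equal-concentration second-order) to 10⁻⁶ relative, and
tag-weighted conservation (peptide monomer units) holds to 10⁻⁶ relative
across the γ simulations.

## Competition kinetics

The pulse experiment is simulated with the full network (N₂O water
chemistry + KSCN + peptide); the plateau is the maximum of the (SCN)₂⁻·
trace over a 10 µs window — robust because the minimal scheme gives the
chromophore no decay channel. Abs₀ always comes from a matched peptide-free
simulation in the same run. The analytic competition expression is
implemented as Abs₀/Abs = 1 + (k_pep/k_SCN)·ratio (the suppression form
consistent with the observed decrease of Abs with added peptide). The fit
regresses Abs₀/Abs − 1 on the ratio with the intercept fixed at zero
(free-intercept mode available); k = slope × k_SCN. When a dataset carries
a known per-point noise SD on the Abs/Abs₀ scale, it is propagated to the
regression scale by the delta method (sd(1/y) = σ/y²) and the slope SE is
the known-variance weighted-least-squares value; otherwise the SE is
residual-based. With five ratio points the residual-based ±2 SE interval
under-covers (t with 4 df), which is why known noise is used when stated.

Dosimetry inverts Beer–Lambert at 472 nm (ε = 7100 L mol⁻¹ cm⁻¹) with the
full-conversion yield 0.557 µmol L⁻¹ Gy⁻¹; path length defaults to 1 cm and
cancels in all ratio-based analyses. Traces are reported at 472 nm, the
only wavelength with a stated ε (experimental traces are often read at
500 nm to dodge product absorption, but ratio analyses are ε-independent).

## Crosslinking network

Oligomers are resolved into size classes P₁…P_nmax (closed-shell) and
R₁…R_nmax (OH-adduct radicals), n_max = 10 by default:

* Pₙ + OH → Rₙ, at the measured peptide constant for n = 1 (4.2 × 10⁹ for
  H5, 2.7 × 10⁹ for H9) and `k_oligomer_oh` (default: same as the monomer,
  within the literature 10⁹–10¹⁰ range for aromatic dimers) for n ≥ 2;
* Rₙ + Rₘ → Pₙ₊ₘ at 10⁴ M⁻¹ s⁻¹ (reported range 10³–10⁵ for peptide/protein
  radical dimerization), each event counting one crosslink bond via an
  auxiliary counter species. Recombination overflowing n_max is lumped into
  P_nmax with the excess monomer units booked to the degraded pool so unit
  totals are exactly conserved; at 5 kGy the crosslink density moves < 5%
  between n_max = 10 and 20, so lumping does not drive the observable.
  Chain growth is modelled through this recombination cascade; an optional
  radical + closed-shell addition channel exists (default off) because no
  rate constant is stated for it anywhere.
* Pₙ + OH → n degraded units (terminal pool) at 10⁹ M⁻¹ s⁻¹ for n ≥ 2 (the
  size threshold is configurable);
* R₁ + O₂ → OH-substituted peptide + HO₂ at 2 × 10⁹ M⁻¹ s⁻¹ — an assumed
  typical carbon-radical + O₂ constant, flagged configurable
  (`k_radical_o2`); an option extends the channel to all size classes;
* OH-substituted + OH → ring-opened products at 10⁹ M⁻¹ s⁻¹.

Degradation products are terminal (no further chemistry), matching the
minimal scheme. Extra water-spur recombinations (OH+OH, OH+e⁻aq, …) are
excluded by default to keep the scheme minimal.

Initial peptide concentration converts 0.1 wt.% (density 1 g/mL) through
the sequence average mass computed with Biopython: H5 (HGHGH) 543.5 g/mol →
1.84 mmol/L; H9 771.7 g/mol → 1.30 mmol/L. Oxygen depletion is modelled
(O₂ is consumed, no re-aeration): the aerated curve therefore shows an
induction region while O₂ quenches R₁, a steep rise after depletion
(~0.8 kGy at these yields), and a plateau once the peptide pool is
exhausted. The observable is the cumulative crosslink-bond concentration in
µmol/L — the curve's qualitative shape (monotone rise, < 20% growth over
10–15 kGy at default H5 parameters) is the checkable property; no absolute
experimental scale exists for it.

## Synthetic data

Generators wrap the package's own forward models and add seeded additive
Gaussian noise (`numpy.random.default_rng`, integer seeds, platform-stable):
competition datasets from the analytic curve (clipped to (0, 1.05]) and
pulse traces from the full ODE network. Noise-free output is bit-identical
to the forward model. Default sd = 0.01 absorbance-ratio units — no noise
characterization exists for the real traces (which were averaged over ≥ 20
shots), so this is a free parameter chosen to be of the order of the
scatter visible in such plots. What passing recovery tests show is that the
estimation pipeline is unbiased (< 2% at sd 0.01 over 200 replicates) and
its standard errors honest under this noise model; they do not validate the
noise model itself against real instrument traces, nor any wet-lab
observable (particle size, yield, zeta potential), which have no stated
mapping from crosslink density.

## Problem sizes and numerical choices

Pulse simulations use a 10 µs window with 400 output points; γ simulations
run to 15 kGy at 10 kGy/h (5400 s) sampled at 60 dose points — with the
analytic Jacobian each takes well under a second, so the whole analysis
suite runs in seconds. Ties/degenerates: a zero total dose returns an
identically zero curve; zero scavenger or zero rate constants leave the
corresponding channels present but fluxless; a competition fit requires at
least two distinct ratios and rejects a constant design. Network configs
round-trip losslessly through the YAML schema (`radiokin.io`); SBML export
is not provided.
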