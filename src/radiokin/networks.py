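"""Builders for the radiolysis networks used in the peptide-nanogel study.

Three building blocks:

* water-radiolysis conditioning — aerated (dissolved O2 scavenges e_aq and H)
  or N2O-saturated (N2O converts e_aq into additional OH),
* thiocyanate dosimetry chemistry (SCN- + OH -> SCN., SCN. + SCN- -> (SCN)2-.,
  the reference chromophore of the KSCN competition method),
* the histidine-peptide crosslinking scheme: OH-adduct radical formation,
  radical-radical dimerization (one crosslink bond per event), chain growth
  through size classes, OH-driven degradation, O2 quenching of the adduct
  radical, and ring opening of the OH-substituted product.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .core import (
    AERATED_G_VALUES,
    CROSSLINK_SPECIES,
    GYield,
    NetworkError,
    Reaction,
    ReactionNetwork,
    Species,
)

__all__ = [
    "ConditionSpec",
    "PeptideSpec",
    "CrosslinkRateSet",
    "AERATED",
    "N2O_SATURATED",
    "PEPTIDE_TABLE",
    "K_SCN_OH",
    "K_SCN_SCN",
    "EPS_SCN_DIMER_472",
    "G_OH_N2O_LUMPED_PAPER",
    "build_water_network",
    "add_kscn_chemistry",
    "add_peptide_scavenger",
    "build_crosslink_network",
    "peptide_molar_mass",
    "peptide_molar_conc",
]

# Printed rate constants of the thiocyanate method (mol^-1 L s^-1)
K_SCN_OH = 2.8e10   # SCN- + OH -> SCN. + OH-
K_SCN_SCN = 7.0e9   # SCN- + SCN. -> (SCN)2-.

#: molar extinction coefficient of (SCN)2-. at 472 nm, L mol^-1 cm^-1
EPS_SCN_DIMER_472 = 7100.0

#: Lumped N2O-condition OH yield as printed in the source study
#: (umol L^-1 Gy^-1).  The package never uses it implicitly: the N2O
#: conversion is simulated explicitly via the e_aq + N2O reaction, which
#: gives G(OH) + G(e_aq) = 0.557 at the default primary yields.
G_OH_N2O_LUMPED_PAPER = 0.567

# Scavenging rate constants (mol^-1 L s^-1); literature values, overridable.
K_EAQ_N2O = 9.1e9
K_EAQ_O2 = 1.9e10
K_H_O2 = 2.1e10


@dataclass(frozen=True)
class ConditionSpec:
    """Dissolved-gas conditioning of the irradiated solution.

    ``aerated``: 250 umol/L O2, which scavenges e_aq and H so OH is the only
    reactive primary.  ``n2o_saturated``: ~25 mmol/L N2O converts e_aq into
    OH, roughly doubling the OH yield (pulse-radiolysis condition).
    """

    name: str
    dissolved_o2: float = 0.0    # mol/L
    dissolved_n2o: float = 0.0   # mol/L
    k_eaq_n2o: float = K_EAQ_N2O
    k_eaq_o2: float = K_EAQ_O2
    k_h_o2: float = K_H_O2

    def __post_init__(self) -> None:
        if self.name not in ("aerated", "n2o_saturated"):
            raise ValueError(f"unknown condition {self.name!r}")
        if self.dissolved_o2 < 0 or self.dissolved_n2o < 0:
            raise ValueError("dissolved-gas concentrations must be >= 0")

    def with_(self, **kwargs) -> "ConditionSpec":
        return replace(self, **kwargs)


AERATED = ConditionSpec("aerated", dissolved_o2=2.5e-4)
N2O_SATURATED = ConditionSpec("n2o_saturated", dissolved_n2o=2.5e-2)


@dataclass(frozen=True)
class PeptideSpec:
    """A His/Gly peptide and its OH-radical rate constant.

    ``k_oh`` (mol^-1 L s^-1) is the bimolecular constant for
    peptide + OH -> OH-adduct radical, as measured by the KSCN competition
    method.
    """

    name: str
    sequence: str
    k_oh: float

    def __post_init__(self) -> None:
        if self.k_oh <= 0:
            raise ValueError("k_oh must be > 0")
        seq = self.sequence.upper()
        if seq and set(seq) - set("ACDEFGHIKLMNPQRSTVWY"):
            raise ValueError(f"invalid residues in sequence {self.sequence!r}")

    @property
    def n_his(self) -> int:
        return self.sequence.upper().count("H")

    @property
    def n_gly(self) -> int:
        return self.sequence.upper().count("G")


#: Default peptide/OH rate constants (mol^-1 L s^-1) from the KSCN method
#: (H and G single-residue values from the earlier literature).
PEPTIDE_TABLE: dict[str, PeptideSpec] = {
    "H": PeptideSpec("H", "H", 5.0e9),
    "H5": PeptideSpec("H5", "HGHGH", 4.2e9),
    "H9": PeptideSpec("H9", "HGGGHGGGH", 2.7e9),
    "G": PeptideSpec("G", "G", 1.7e7),
}


def peptide_molar_mass(spec: PeptideSpec) -> float:
    """Average molar mass of the peptide (g/mol) from its sequence."""
    from Bio.SeqUtils.ProtParam import ProteinAnalysis

    return float(ProteinAnalysis(spec.sequence.upper()).molecular_weight())


def peptide_molar_conc(spec: PeptideSpec, weight_percent: float = 0.1) -> float:
    """Molarity (mol/L) of a ``weight_percent`` wt.% aqueous solution.

    Dilute-solution density is taken as 1 g/mL, so 0.1 wt.% = 1 g/L.
    """
    if weight_percent < 0:
        raise ValueError("weight_percent must be >= 0")
    grams_per_litre = weight_percent * 10.0
    return grams_per_litre / peptide_molar_mass(spec)


@dataclass(frozen=True)
class CrosslinkRateSet:
    """Rate constants of the crosslinking/decomposition scheme (mol^-1 L s^-1).

    ``k_radical_dimerization`` is the peptide-radical recombination constant
    (literature range 1e3-1e5; 1e4 adopted).  ``k_oligomer_oh`` defaults to
    the monomer's k_oh when None (aromatic dimers react at 1e9-1e10).
    ``k_radical_o2`` is an assumed typical carbon-radical + O2 constant.
    ``n_max`` is the oligomer size cutoff; recombination overflowing it is
    lumped into the largest class.  ``degradation_min_size`` is the smallest
    oligomer subject to the OH-degradation channel.
    """

    k_radical_dimerization: float = 1e4
    k_oligomer_oh: float | None = None
    k_polymer_degradation_oh: float = 1e9
    k_radical_o2: float = 2e9
    k_ring_opening_oh: float = 1e9
    n_max: int = 10
    degradation_min_size: int = 2
    k_radical_monomer_addition: float = 0.0  # optional R + P addition channel
    o2_all_radicals: bool = False

    def __post_init__(self) -> None:
        for name in ("k_radical_dimerization", "k_polymer_degradation_oh",
                     "k_radical_o2", "k_ring_opening_oh",
                     "k_radical_monomer_addition"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.k_oligomer_oh is not None and self.k_oligomer_oh < 0:
            raise ValueError("k_oligomer_oh must be >= 0")
        if self.n_max < 2:
            raise ValueError("n_max must be >= 2")

    def with_(self, **kwargs) -> "CrosslinkRateSet":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------

def build_water_network(
    condition: ConditionSpec, g: GYield | None = None
) -> ReactionNetwork:
    """Water-radiolysis primaries plus the condition's scavenging chemistry."""
    net = ReactionNetwork(g_yield=g if g is not None else GYield())
    for name in ("OH", "e_aq", "H"):
        net.add_species(Species(name, role="radiolytic_primary"))
    if condition.name == "n2o_saturated":
        net.add_species(Species("N2O", condition.dissolved_n2o))
        net.add_species(Species("N2", role="product"))
        net.add_species(Species("OH-", role="product"))
        net.react("e_aq + N2O", "OH + N2 + OH-", condition.k_eaq_n2o,
                  "e_aq + N2O -> OH conversion")
    else:  # aerated
        net.add_species(Species("O2", condition.dissolved_o2))
        net.add_species(Species("HO2", role="product"))
        net.add_species(Species("O2-", role="product"))
        net.react("H + O2", "HO2", condition.k_h_o2, "H + O2 scavenging")
        net.react("e_aq + O2", "O2-", condition.k_eaq_o2, "e_aq + O2 scavenging")
    return net


def add_kscn_chemistry(net: ReactionNetwork, kscn_conc: float) -> ReactionNetwork:
    """Add the thiocyanate dosimetry chemistry (chromophore: (SCN)2-. at 472 nm)."""
    if kscn_conc < 0:
        raise ValueError("kscn_conc must be >= 0")
    net.add_species(Species("SCN-", kscn_conc))
    net.add_species(Species("SCN", role="radical"))
    net.add_species(
        Species("(SCN)2-", role="product", extinction={472.0: EPS_SCN_DIMER_472})
    )
    net.ensure_species("OH-", role="product")
    net.react("SCN- + OH", "SCN + OH-", K_SCN_OH, "thiocyanate oxidation")
    net.react("SCN- + SCN", "(SCN)2-", K_SCN_SCN, "dimer radical formation")
    return net


def add_peptide_scavenger(
    net: ReactionNetwork, peptide: PeptideSpec, conc: float
) -> ReactionNetwork:
    """Add a peptide as a simple OH scavenger (competition experiments)."""
    if conc < 0:
        raise ValueError("conc must be >= 0")
    if peptide.k_oh <= 0:
        raise ValueError("peptide k_oh must be > 0")
    # the single-residue specs ("H", "G") collide with the H atom etc.
    sp_name = peptide.name if peptide.name not in net.species \
        else f"{peptide.name}_peptide"
    adduct = f"{sp_name}-OH_adduct"
    net.add_species(Species(sp_name, conc))
    net.add_species(Species(adduct, role="radical"))
    net.react(f"{sp_name} + OH", adduct, peptide.k_oh,
              f"{peptide.name} + OH scavenging")
    return net


def build_crosslink_network(
    peptide: PeptideSpec,
    condition: ConditionSpec = AERATED,
    rates: CrosslinkRateSet | None = None,
    peptide_conc: float | None = None,
    weight_percent: float = 0.1,
    g: GYield | None = None,
) -> ReactionNetwork:
    """Full crosslinking/decomposition network over oligomer size classes.

    Species: ``P1..P{n_max}`` closed-shell n-mers, ``R1..R{n_max}`` OH-adduct
    radicals, ``P-OH`` (OH-substituted monomer from O2 quenching),
    ``ring_opened`` and ``degraded_unit`` terminal pools (counted in monomer
    units), plus the condition's water chemistry and a ``crosslink`` counter
    incremented once per recombination event.

    ``peptide_conc`` (mol/L of monomer) defaults to a ``weight_percent`` wt.%
    solution converted via the sequence molar mass.
    """
    rates = rates if rates is not None else CrosslinkRateSet()
    if peptide_conc is None:
        peptide_conc = peptide_molar_conc(peptide, weight_percent)

    net = build_water_network(condition, g)
    n_max = rates.n_max
    k_olig = rates.k_oligomer_oh if rates.k_oligomer_oh is not None else peptide.k_oh

    net.add_species(Species("P1", peptide_conc))
    for n in range(2, n_max + 1):
        net.add_species(Species(f"P{n}", role="product"))
    for n in range(1, n_max + 1):
        net.add_species(Species(f"R{n}", role="radical"))
    net.add_species(Species("P-OH", role="product"))
    net.add_species(Species("ring_opened", role="product"))
    net.add_species(Species("degraded_unit", role="product"))
    net.add_species(Species(CROSSLINK_SPECIES, role="auxiliary"))

    # (i) OH-adduct radical formation
    net.react("P1 + OH", "R1", peptide.k_oh, f"{peptide.name} + OH -> adduct radical")
    for n in range(2, n_max + 1):
        net.react(f"P{n} + OH", f"R{n}", k_olig, f"{n}-mer + OH -> adduct radical")

    # (ii) radical-radical dimerization: one crosslink bond per event,
    # overflow beyond n_max lumped into the largest class; excess monomer
    # units are booked to the degraded pool so unit totals stay conserved
    k_dim = rates.k_radical_dimerization
    for n in range(1, n_max + 1):
        for m in range(n, n_max + 1):
            size = min(n + m, n_max)
            excess = n + m - size
            lhs = f"2 R{n}" if n == m else f"R{n} + R{m}"
            rhs = f"P{size} + {CROSSLINK_SPECIES}"
            if excess:
                rhs += f" + {excess} degraded_unit"
            net.react(lhs, rhs, k_dim, f"R{n} + R{m} recombination")

    # optional chain growth by radical + closed-shell monomer addition
    if rates.k_radical_monomer_addition > 0:
        for n in range(1, n_max):
            net.react(f"R{n} + P1", f"R{min(n + 1, n_max)}",
                      rates.k_radical_monomer_addition, f"R{n} + monomer addition")

    # (iii) OH degradation of oligomers into a terminal low-MW pool
    for n in range(max(2, rates.degradation_min_size), n_max + 1):
        net.react(f"P{n} + OH", f"{n} degraded_unit",
                  rates.k_polymer_degradation_oh, f"{n}-mer OH degradation")

    # (iv) O2 quenching of the adduct radical -> OH-substituted peptide
    if condition.name == "aerated" or "O2" in net.species:
        net.ensure_species("O2", role="solute")
        net.ensure_species("HO2", role="product")
        radical_sizes = range(1, n_max + 1) if rates.o2_all_radicals else (1,)
        for n in radical_sizes:
            pool = "P-OH" if n == 1 else f"{n} degraded_unit"
            net.react(f"R{n} + O2", f"{pool} + HO2", rates.k_radical_o2,
                      f"R{n} + O2 quenching")

    # (v) ring opening of the OH-substituted product
    net.react("P-OH + OH", "ring_opened", rates.k_ring_opening_oh,
              "OH-substituted + OH ring opening")

    # peptide-monomer-unit bookkeeping for conservation checks
    units: dict[str, float] = {"P-OH": 1.0, "ring_opened": 1.0, "degraded_unit": 1.0}
    for n in range(1, n_max + 1):
        units[f"P{n}"] = float(n)
        units[f"R{n}"] = float(n)
    net.tags["peptide_units"] = units
    return net
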