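"""Pulse-radiolysis observables and competition-kinetics rate-constant fits.

The thiocyanate (KSCN) method: a nanosecond electron pulse deposits a few Gy
in N2O-saturated KSCN solution; essentially every OH radical (including those
converted from e_aq by N2O) ends up as the chromophore (SCN)2-. whose
transient absorbance is read by Beer-Lambert.  Adding a peptide that competes
for OH suppresses the plateau absorbance; the suppression as a function of
[peptide]/[SCN-] gives the peptide's OH rate constant through

    Abs0 / Abs = 1 + (k_pep / k_SCN) * [peptide] / [SCN-]

fitted by least squares (intercept fixed at 1 by default).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core import (
    IrradiationProtocol,
    ReactionNetwork,
    TimeCourse,
    integrate,
)
from .networks import (
    EPS_SCN_DIMER_472,
    K_SCN_OH,
    N2O_SATURATED,
    ConditionSpec,
    PeptideSpec,
    add_kscn_chemistry,
    add_peptide_scavenger,
    build_water_network,
)

__all__ = [
    "CompetitionDataset",
    "RateConstantFit",
    "absorbance_trace",
    "dose_from_dosimetry",
    "competition_ratio",
    "fit_competition",
    "simulate_pulse",
    "simulate_competition_experiment",
    "G_DIMER_DEFAULT",
]

#: Default G-value for (SCN)2-. under N2O (full conversion of OH + e_aq),
#: umol L^-1 Gy^-1: G(OH) + G(e_aq) = 0.287 + 0.27.
G_DIMER_DEFAULT = 0.557

DEFAULT_PULSE_WINDOW = 10e-6  # s
DEFAULT_KSCN_CONC = 1e-3      # mol/L
DEFAULT_PULSE_DOSE = 4.5      # Gy, within the 4-4.9 Gy/pulse dosimetry range


@dataclass
class CompetitionDataset:
    """([peptide]/[SCN-], Abs/Abs0) pairs for the competition fit."""

    conc_ratio: np.ndarray
    abs_ratio: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.conc_ratio = np.asarray(self.conc_ratio, dtype=float)
        self.abs_ratio = np.asarray(self.abs_ratio, dtype=float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
        if self.conc_ratio.shape != self.abs_ratio.shape:
            raise ValueError("conc_ratio and abs_ratio must have equal length")
        if np.any(self.conc_ratio < 0):
            raise ValueError("conc_ratio must be >= 0")
        if np.any(self.abs_ratio <= 0) or np.any(self.abs_ratio > 1.05):
            raise ValueError("abs_ratio must lie in (0, 1] up to noise tolerance")
        if np.unique(self.conc_ratio).size < 2:
            raise ValueError("need at least 2 distinct conc_ratios")

    def __len__(self) -> int:
        return self.conc_ratio.size

    def to_frame(self) -> pd.DataFrame:
        data = {"conc_ratio": self.conc_ratio, "abs_ratio": self.abs_ratio}
        if self.sigma is not None:
            data["sigma"] = self.sigma
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CompetitionDataset":
        df = pd.read_csv(path)
        sigma = df["sigma"].to_numpy() if "sigma" in df.columns else None
        return cls(df["conc_ratio"].to_numpy(), df["abs_ratio"].to_numpy(), sigma)


@dataclass
class RateConstantFit:
    """Result of the competition-kinetics linear fit."""

    k_estimate: float          # mol^-1 L s^-1
    slope: float               # k_pep / k_SCN
    intercept: float           # of Abs0/Abs vs ratio (1.0 when fixed)
    standard_error: float      # SE of k_estimate, mol^-1 L s^-1
    r_squared: float
    k_scn_used: float
    intercept_fixed: bool = True
    n_points: int = 0

    def to_dict(self) -> dict:
        return {
            "k_estimate_M_s": self.k_estimate,
            "slope": self.slope,
            "intercept": self.intercept,
            "standard_error_M_s": self.standard_error,
            "r_squared": self.r_squared,
            "k_scn_used_M_s": self.k_scn_used,
            "intercept_fixed": self.intercept_fixed,
            "n_points": self.n_points,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


# ---------------------------------------------------------------------------
# Observables
# ---------------------------------------------------------------------------

def absorbance_trace(
    tc: TimeCourse,
    species: str = "(SCN)2-",
    wavelength: float = 472.0,
    path_length: float = 1.0,
) -> np.ndarray:
    """Beer-Lambert absorbance A(t) = eps * l * c(t) for one species."""
    if tc.network is None or species not in tc.network.species:
        raise KeyError(f"species {species!r} not in time course")
    eps_map = tc.network.species[species].extinction
    if wavelength not in eps_map:
        raise KeyError(
            f"species {species!r} has no extinction coefficient at "
            f"{wavelength:g} nm (known: {sorted(eps_map)})"
        )
    return eps_map[wavelength] * path_length * tc[species]


def dose_from_dosimetry(
    abs_max: float,
    epsilon: float = EPS_SCN_DIMER_472,
    path_length: float = 1.0,
    g_dimer: float = G_DIMER_DEFAULT,
) -> float:
    """Absorbed dose (Gy) from the plateau absorbance of the dosimeter.

    ``g_dimer`` is the (SCN)2-. radiation-chemical yield in umol L^-1 Gy^-1
    (full OH + e_aq conversion under N2O by default).
    """
    if abs_max < 0:
        raise ValueError("abs_max must be >= 0")
    if epsilon <= 0 or path_length <= 0 or g_dimer <= 0:
        raise ValueError("epsilon, path_length and g_dimer must be > 0")
    return abs_max / (epsilon * path_length * g_dimer * 1e-6)


def competition_ratio(
    k_pep: float, conc_ratio, k_scn: float = K_SCN_OH
):
    """Analytic Abs/Abs0 = 1 / (1 + (k_pep/k_scn) * [P]/[SCN-])."""
    if k_scn <= 0:
        raise ValueError("k_scn must be > 0")
    if k_pep < 0:
        raise ValueError("k_pep must be >= 0")
    conc_ratio = np.asarray(conc_ratio, dtype=float)
    if np.any(conc_ratio < 0):
        raise ValueError("conc_ratio must be >= 0")
    out = 1.0 / (1.0 + (k_pep / k_scn) * conc_ratio)
    return float(out) if out.ndim == 0 else out


def fit_competition(
    data: CompetitionDataset,
    k_scn: float = K_SCN_OH,
    fix_intercept: bool = True,
) -> RateConstantFit:
    """Estimate k_pep from a competition dataset.

    Regresses ``Abs0/Abs - 1`` on the concentration ratio.  With the
    intercept fixed (default) the line is forced through Abs/Abs0 = 1 at
    ratio 0, matching the competition expression; the free-intercept mode
    fits ``Abs0/Abs`` with a constant term.  ``k_estimate = slope * k_scn``
    and its SE propagates from the slope SE.

    When the dataset carries a known noise SD per point (``sigma``, on the
    Abs/Abs0 scale), it is propagated to the regression scale by the delta
    method (sd(1/y) = sigma / y^2) and the slope SE is the known-variance
    weighted-least-squares one; otherwise the SE is residual-based.
    """
    if k_scn <= 0:
        raise ValueError("k_scn must be > 0")
    x = data.conc_ratio
    if np.unique(x).size < 2:
        raise ValueError("degenerate design: all conc_ratios equal")
    inv = 1.0 / data.abs_ratio  # Abs0/Abs

    sigma = data.sigma
    known_noise = sigma is not None and np.all(np.asarray(sigma) > 0)
    if known_noise:
        s_inv = np.asarray(sigma) / data.abs_ratio**2
        w = 1.0 / s_inv**2
        if fix_intercept:
            sxx = float(np.sum(w * x * x))
            slope = float(np.sum(w * x * (inv - 1.0)) / sxx)
            slope_se = sxx ** -0.5
            intercept, fitted = 1.0, 1.0 + slope * x
        else:
            X = np.column_stack([np.ones_like(x), x])
            xtwx = X.T @ (w[:, None] * X)
            beta = np.linalg.solve(xtwx, X.T @ (w * inv))
            cov = np.linalg.inv(xtwx)
            intercept, slope = float(beta[0]), float(beta[1])
            slope_se = float(np.sqrt(cov[1, 1]))
            fitted = X @ beta
        ss_res = float(np.sum((inv - fitted) ** 2))
        ss_tot = float(np.sum((inv - inv.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    elif fix_intercept:
        res = sm.OLS(inv - 1.0, x).fit()
        slope = float(res.params[0])
        slope_se = float(res.bse[0])
        intercept = 1.0
        r2 = float(res.rsquared) if np.isfinite(res.rsquared) else 1.0
    else:
        X = sm.add_constant(x)
        res = sm.OLS(inv, X).fit()
        intercept = float(res.params[0])
        slope = float(res.params[1])
        slope_se = float(res.bse[1])
        r2 = float(res.rsquared) if np.isfinite(res.rsquared) else 1.0
    return RateConstantFit(
        k_estimate=slope * k_scn,
        slope=slope,
        intercept=intercept,
        standard_error=slope_se * k_scn,
        r_squared=r2,
        k_scn_used=k_scn,
        intercept_fixed=fix_intercept,
        n_points=len(data),
    )


# ---------------------------------------------------------------------------
# Pulse simulation
# ---------------------------------------------------------------------------

def build_pulse_network(
    kscn_conc: float = DEFAULT_KSCN_CONC,
    peptide: PeptideSpec | None = None,
    peptide_conc: float = 0.0,
    condition: ConditionSpec = N2O_SATURATED,
) -> ReactionNetwork:
    """N2O-saturated KSCN network, optionally with a competing peptide."""
    net = build_water_network(condition)
    add_kscn_chemistry(net, kscn_conc)
    if peptide is not None and peptide_conc > 0:
        add_peptide_scavenger(net, peptide, peptide_conc)
    return net


def simulate_pulse(
    dose: float = DEFAULT_PULSE_DOSE,
    kscn_conc: float = DEFAULT_KSCN_CONC,
    peptide: PeptideSpec | None = None,
    peptide_conc: float = 0.0,
    t_end: float = DEFAULT_PULSE_WINDOW,
    output_grid=None,
    condition: ConditionSpec = N2O_SATURATED,
    delivery: str = "instantaneous",
) -> TimeCourse:
    """Single electron pulse into (peptide +) KSCN solution."""
    net = build_pulse_network(kscn_conc, peptide, peptide_conc, condition)
    protocol = IrradiationProtocol.single_pulse(dose, delivery=delivery)
    return integrate(net, protocol, t_end, output_grid=output_grid, n_points=400)


def plateau_absorbance(tc: TimeCourse, path_length: float = 1.0) -> float:
    """Plateau = maximum of the (SCN)2-. trace over the simulated window."""
    return float(absorbance_trace(tc, path_length=path_length).max())


def saturation_time(tc: TimeCourse, level: float = 0.99) -> float:
    """First time (s) the (SCN)2-. concentration reaches ``level`` x plateau."""
    trace = tc["(SCN)2-"]
    plateau = trace.max()
    if plateau <= 0:
        raise ValueError("trace has no plateau (zero chromophore)")
    idx = int(np.argmax(trace >= level * plateau))
    return float(tc.times[idx])


def simulate_competition_experiment(
    peptide: PeptideSpec,
    kscn_conc: float = DEFAULT_KSCN_CONC,
    conc_ratios=(0.25, 0.5, 1.0, 1.5, 2.0),
    dose: float = DEFAULT_PULSE_DOSE,
    t_end: float = DEFAULT_PULSE_WINDOW,
) -> CompetitionDataset:
    """Run the full pulse network at each [peptide]/[SCN-] ratio.

    Abs0 comes from a matched peptide-free simulation in the same run; the
    returned abs_ratio column is the plateau Abs/Abs0 per ratio (a ratio of 0
    yields 1 by construction).
    """
    ratios = np.asarray(conc_ratios, dtype=float)
    if np.any(ratios < 0):
        raise ValueError("conc_ratios must be >= 0")
    tc0 = simulate_pulse(dose, kscn_conc, t_end=t_end)
    abs0 = plateau_absorbance(tc0)
    abs_ratios = np.empty_like(ratios)
    for i, r in enumerate(ratios):
        if r == 0:
            abs_ratios[i] = 1.0
            continue
        tc = simulate_pulse(dose, kscn_conc, peptide, r * kscn_conc, t_end=t_end)
        abs_ratios[i] = plateau_absorbance(tc) / abs0
    return CompetitionDataset(ratios, abs_ratios)
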