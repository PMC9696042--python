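"""Seeded synthetic-data generators for the pulse/competition analyses.

The generators wrap the package's own forward models and add Gaussian noise,
so every fitting stage can be exercised (and its bias/coverage measured) with
no experimental data.  Noise-free output is bit-identical to the forward
model; identical seeds give identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .networks import PeptideSpec
from .pulse import (
    CompetitionDataset,
    absorbance_trace,
    competition_ratio,
    simulate_pulse,
)

__all__ = ["NoiseModel", "synth_competition", "synth_pulse_trace"]

ABS_RATIO_CLIP = (1e-9, 1.05)  # abs_ratio stays in (0, 1.05]


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian noise with a reproducible seed."""

    sd: float = 0.01
    seed: int = 0
    kind: str = "gaussian_additive"

    def __post_init__(self) -> None:
        if self.kind != "gaussian_additive":
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def synth_competition(
    k_pep_true: float,
    conc_ratios,
    noise: NoiseModel = NoiseModel(),
    k_scn: float | None = None,
) -> CompetitionDataset:
    """Competition dataset from the analytic curve plus additive noise."""
    ratios = np.asarray(conc_ratios, dtype=float)
    kwargs = {} if k_scn is None else {"k_scn": k_scn}
    clean = competition_ratio(k_pep_true, ratios, **kwargs)
    clean = np.atleast_1d(np.asarray(clean, dtype=float))
    noisy = clean + noise.rng().normal(0.0, noise.sd, size=clean.shape)
    noisy = np.clip(noisy, *ABS_RATIO_CLIP)
    sigma = np.full_like(noisy, noise.sd)
    return CompetitionDataset(ratios, noisy, sigma)


def synth_pulse_trace(
    dose: float,
    kscn_conc: float = 1e-3,
    peptide: PeptideSpec | None = None,
    peptide_conc: float = 0.0,
    noise: NoiseModel = NoiseModel(),
    t_grid=None,
    path_length: float = 1.0,
) -> pd.DataFrame:
    """Simulated noisy (SCN)2-. absorbance trace after one electron pulse.

    Returns a frame with columns ``time_s`` and ``absorbance``; the noiseless
    part equals ``absorbance_trace`` on the same simulation exactly.
    """
    if dose < 0:
        raise ValueError("dose must be >= 0")
    if t_grid is None:
        t_grid = np.linspace(0.0, 10e-6, 400)
    t_grid = np.asarray(t_grid, dtype=float)
    tc = simulate_pulse(
        dose, kscn_conc, peptide, peptide_conc,
        t_end=float(t_grid[-1]), output_grid=t_grid,
    )
    clean = absorbance_trace(tc, path_length=path_length)
    noisy = clean + noise.rng().normal(0.0, noise.sd, size=clean.shape)
    return pd.DataFrame({"time_s": tc.times, "absorbance": noisy})
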