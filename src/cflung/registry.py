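"""Synthetic patient-registry generator.

Emulates the statistical structure of an adult-CF clinic registry --
per-patient sex, age, height and raw FVC in litres -- with each patient's
percent-predicted FVC read from an independent disease-model replicate at
their age, plus Gaussian observation noise.  The raw FVC is back-computed
through the spirometric reference equations, so downstream consumers
exercise the full normalization path (raw litres -> percent predicted ->
age averaging).

This is a synthetic stand-in for clinical registry data; its demographic
defaults are unremarkable adult values, not estimates of any particular
clinic population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import AirwayTree
from .model import SimParams, simulate
from .spirometry import ReferenceCoefficients, load_default_coefficients, predicted_fvc

__all__ = ["CohortSpec", "synthesize_cohort"]


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic cross-sectional cohort (one visit per patient).

    ``noise_sd`` is the SD (percentage points) of Gaussian observation
    noise added to the model percent; results are truncated to [0, 100].
    ``n_replicates`` disease courses are simulated and patients are dealt
    to them round-robin, so at most ``n_replicates`` distinct underlying
    trajectories exist.
    """

    n_patients: int = 200
    age_min: int = 18
    age_max: int = 50
    male_fraction: float = 0.5
    height_mean_cm: dict = field(
        default_factory=lambda: {"male": 176.0, "female": 163.0})
    height_sd_cm: dict = field(
        default_factory=lambda: {"male": 7.0, "female": 6.5})
    noise_sd: float = 5.0
    n_replicates: int = 20
    params: SimParams = field(default_factory=SimParams)
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("n_patients must be at least 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not (0.0 <= self.male_fraction <= 1.0):
            raise ValueError("male_fraction must lie in [0, 1]")
        if self.age_max * 12 > self.params.horizon:
            raise ValueError("simulation horizon shorter than age_max")


def synthesize_cohort(spec: CohortSpec, tree: AirwayTree,
                      coeffs: ReferenceCoefficients | None = None,
                      trajectories=None) -> pd.DataFrame:
    """Generate a cohort table (columns ``patient_id, sex, age_years,
    height_cm, fvc_L, fvc_pct_true``), deterministic given the spec seed.

    ``trajectories`` may supply a pre-computed replicate set for
    ``spec.params`` (as returned by :func:`cflung.model.simulate`) to avoid
    re-simulating; otherwise ``spec.n_replicates`` runs are performed with
    the spec's ground-truth parameters.
    """
    coeffs = coeffs if coeffs is not None else load_default_coefficients()
    rng = np.random.default_rng(spec.seed)
    if trajectories is None:
        trajectories = simulate(spec.params.with_(seed=spec.params.seed),
                                tree, spec.n_replicates)
    values = trajectories.values

    n = spec.n_patients
    sexes = np.where(rng.random(n) < spec.male_fraction, "male", "female")
    ages = rng.integers(spec.age_min, spec.age_max + 1, size=n)
    heights = np.array([
        rng.normal(spec.height_mean_cm[s], spec.height_sd_cm[s]) for s in sexes
    ])
    heights = np.round(np.clip(heights, 140.0, 205.0), 1)
    replicate = np.arange(n) % values.shape[0]
    pct_true = values[replicate, ages * 12]
    pct_obs = np.clip(pct_true + rng.normal(0.0, spec.noise_sd, size=n), 0.0, 100.0)
    fvc = np.array([
        pct / 100.0 * predicted_fvc(s, float(a), float(h), coeffs)
        for pct, s, a, h in zip(pct_obs, sexes, ages, heights)
    ])
    return pd.DataFrame({
        "patient_id": [f"SYN{i:04d}" for i in range(n)],
        "sex": sexes,
        "age_years": ages.astype(float),
        "height_cm": heights,
        "fvc_L": fvc,
        "fvc_pct_true": pct_obs,
    })
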