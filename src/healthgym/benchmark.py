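"""Desk-scale end-to-end training study.

Full-size replication of the published synthetic cohorts needs GPU-scale
training; this module defines the package's standard scaled study instead:
a 200-patient, 8-timestep, 6-variable simulated cohort with moderate
cross-channel correlation and AR(1) persistence, trained for ~500 generator
steps on one CPU.  It is used by the acceptance script and the end-to-end
tests to check two qualitative properties of the method:

* the logged correlation-alignment term decreases over training, and
* removing the alignment penalty (``lambda_corr = 0``) leaves a larger
  final gap between the synthetic and real Kendall-tau matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gan import CriticSpec, GeneratorSpec, HealthGymGAN, TrainingConfig
from .realisticness import static_kendall
from .schema import CohortSchema, VariableSpec
from .simulator import SimulatorConfig, simulate_cohort


def scaled_schema() -> CohortSchema:
    """Six mixed-type variables: 4 numeric, 1 categorical, 1 binary flag."""
    variables = (
        VariableSpec("pressure", "numeric", "mmHg"),
        VariableSpec("lab_a", "numeric", "IU/L"),
        VariableSpec("lab_b", "numeric", "mg/dL"),
        VariableSpec("output", "numeric", "mL"),
        VariableSpec("dose", "categorical", classes=("none", "low", "high"),
                     class_shares=(70.0, 20.0, 10.0)),
        VariableSpec("lab_a (M)", "binary", classes=("False", "True"),
                     measured_indicator_of="lab_a", class_shares=(75.0, 25.0)),
    )
    return CohortSchema("scaled", variables, "pid", "step", 8)


def scaled_cohort(seed: int = 0, n_patients: int = 200):
    """The study cohort: correlated channels, right-skewed labs, AR(1)."""
    schema = scaled_schema()
    C = len(schema.variables)
    idx = np.arange(C)
    latent_corr = 0.5 ** np.abs(idx[:, None] - idx[None, :])
    config = SimulatorConfig(
        schema=schema,
        n_patients=n_patients,
        latent_corr=latent_corr,
        ar_coefficient=0.5,
        marginals={
            "pressure": ("normal", 65.0, 10.0),
            "lab_a": ("lognormal", 3.5, 0.6),
            "lab_b": ("lognormal", 0.1, 0.5),
            "output": ("lognormal", 4.6, 0.8),
        },
        cutpoints={"dose": (0.70, 0.90)},
        indicator_rate={"lab_a (M)": 0.25},
        seed=seed,
    )
    return simulate_cohort(config)


@dataclass
class ScaledRunResult:
    alignment_first_decile: float
    alignment_last_decile: float
    tau_gap: float
    log: "object"


def run_scaled_training(
    seed: int,
    lambda_corr: float,
    total_steps: int = 500,
    n_patients: int = 200,
    cohort=None,
) -> ScaledRunResult:
    """Train the GAN on the scaled cohort and measure the outcomes.

    Returns the mean logged alignment term over the first and last deciles
    of generator steps, and the Frobenius norm of the difference between
    the synthetic and real static Kendall-tau matrices (synthetic cohort
    sampled at the real cohort's size).
    """
    real = cohort if cohort is not None else scaled_cohort(seed, n_patients)
    model = HealthGymGAN(
        real,
        GeneratorSpec(latent_dim=6, hidden_size=12, dense_widths=(24, 24)),
        CriticSpec(embedding_dim=3, dense_widths=(24, 24), hidden_size=12),
    )
    config = TrainingConfig(
        lambda_corr=lambda_corr,
        critic_steps_per_generator_step=2,
        total_steps=total_steps,
        batch_size=64,
        seed=seed,
    )
    results = model.fit(config)
    syn = results.sample(real.n_patients, seed=seed + 1000)
    gap = float(np.linalg.norm(
        static_kendall(syn).r - static_kendall(real).r, ord="fro"
    ))
    k = max(1, total_steps // 10)
    log = results.log
    return ScaledRunResult(
        alignment_first_decile=float(log["alignment"].head(k).mean()),
        alignment_last_decile=float(log["alignment"].tail(k).mean()),
        tau_gap=gap,
        log=log,
    )
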