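"""Subject-level cohort simulator for statistical calibration.

Generates paired patient/control cohorts at the level the statistics
operate on — per-subject metric summaries — without rendering images.
Pairing is modelled as a shared pair effect: with between-subject SD s and
pair correlation rho, each value is mean + sqrt(rho) s z_pair +
sqrt(1-rho) s z_subject, so the paired-difference SD is s sqrt(2(1-rho)).
Used for type-I-error and power checks of the cohort comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from calmito.stats.cohort import SubjectSummary

#: control-group (mean, between-subject SD) per metric; bounds for clipping
DEFAULT_METRIC_DISTRIBUTIONS: dict[str, tuple[float, float, float, float]] = {
    # metric: (mean, sd, lo, hi)
    "pct_responders": (57.3, 20.0, 0.0, 100.0),
    "mean_max_amplitude_pct": (3.6, 1.5, 0.0, np.inf),
    "volume_ratio": (0.20, 0.05, 0.0, 1.0),
    "density_per_1000um3": (9.0, 2.5, 0.0, np.inf),
    "mean_single_volume_um3": (0.8, 0.2, 0.0, np.inf),
    "fluctuation_score_pct": (8.0, 2.0, 0.0, np.inf),
}


@dataclass
class CohortSimParams:
    """Conditions for one simulated paired cohort.

    pd_shift maps metric name -> additive shift applied to the PD group
    (empty = a null cohort). pair_correlation is the within-pair
    correlation induced by the shared household/lifestyle effect.
    """

    n_pairs: int = 15
    metric_distributions: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_METRIC_DISTRIBUTIONS)
    )
    pd_shift: dict[str, float] = field(default_factory=dict)
    pair_correlation: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_pairs < 5:
            raise ValueError("need at least 5 pairs for the paired tests")
        if not (0.0 <= self.pair_correlation < 1.0):
            raise ValueError("pair_correlation must lie in [0, 1)")
        for m, (mean, sd, lo, hi) in self.metric_distributions.items():
            if sd < 0 or not (lo < hi):
                raise ValueError(f"bad distribution for metric {m!r}")
        unknown = set(self.pd_shift) - set(self.metric_distributions)
        if unknown:
            raise ValueError(f"pd_shift names unknown metrics: {sorted(unknown)}")


def simulate_cohort(params: CohortSimParams) -> list[SubjectSummary]:
    """Draw one paired cohort of 2 * n_pairs SubjectSummary records.

    Clinical covariates follow the cohort being emulated: age ~ N(58, 9)
    shared within a pair up to a few years, SCOPA and UPDRS-III scores
    higher/defined in the PD group, disease duration 2-17 years.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    rho = params.pair_correlation
    subjects: list[SubjectSummary] = []
    for pair in range(params.n_pairs):
        pair_age = rng.normal(58.0, 9.0)
        z_pair = {m: rng.standard_normal() for m in params.metric_distributions}
        for group in ("control", "PD"):
            metrics: dict[str, float] = {}
            for m, (mean, sd, lo, hi) in params.metric_distributions.items():
                val = (
                    mean
                    + (params.pd_shift.get(m, 0.0) if group == "PD" else 0.0)
                    + sd
                    * (
                        np.sqrt(rho) * z_pair[m]
                        + np.sqrt(1.0 - rho) * rng.standard_normal()
                    )
                )
                metrics[m] = float(np.clip(val, lo, hi))
            covariates = {
                "age": float(np.clip(pair_age + rng.normal(0.0, 3.0), 30.0, 90.0)),
                "scopa_total": float(
                    np.clip(rng.normal(12.3 if group == "PD" else 5.6, 4.0), 0, 42)
                ),
                "scopa_gi": float(
                    np.clip(rng.normal(2.7 if group == "PD" else 0.9, 1.2), 0, 12)
                ),
            }
            if group == "PD":
                covariates["updrs3_off"] = float(np.clip(rng.normal(23.3, 10.0), 5, 60))
                covariates["disease_duration_years"] = float(
                    np.clip(rng.normal(7.8, 3.9), 2.0, 17.0)
                )
            subjects.append(
                SubjectSummary(
                    subject_id=f"P{pair:02d}-{group}",
                    pair_id=pair,
                    group=group,
                    metrics=metrics,
                    covariates=covariates,
                )
            )
    return subjects
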