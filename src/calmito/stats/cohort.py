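"""Paired-cohort orchestration.

Subjects enter as one row per subject (imaging summaries joined to clinical
covariates), organized in patient/control pairs — here, a patient and their
healthy partner, which controls diet, lifestyle and environment. For each
imaging metric the two groups are compared with a normality-gated paired
test; within the patient group each metric is correlated (Spearman) with
the clinical covariates; p-values are Bonferroni-corrected within each
family of tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from calmito.stats.tests import (
    StatResult,
    bonferroni,
    paired_ttest,
    paired_wilcoxon,
    shapiro_gate,
    spearman_corr,
)

GROUPS = ("PD", "control")

#: clinical covariates correlated with each imaging metric in the PD group
DEFAULT_COVARIATES = ("age", "scopa_gi", "updrs3_off", "disease_duration_years")

#: imaging metrics compared between groups, by pipeline family
CALCIUM_METRICS = ("pct_responders", "mean_max_amplitude_pct")
MITO_METRICS = (
    "volume_ratio",
    "density_per_1000um3",
    "mean_single_volume_um3",
    "fluctuation_score_pct",
)


@dataclass
class SubjectSummary:
    """Per-subject imaging summary plus clinical covariates."""

    subject_id: str
    pair_id: int
    group: str
    metrics: dict[str, float] = field(default_factory=dict)
    covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}; got {self.group!r}")

    def to_row(self) -> dict:
        row = {
            "subject_id": self.subject_id,
            "pair_id": self.pair_id,
            "group": self.group,
        }
        row.update(self.metrics)
        row.update(self.covariates)
        return row


def cohort_frame(subjects: list[SubjectSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.to_row() for s in subjects])


def _paired_arrays(
    df: pd.DataFrame, metric: str
) -> tuple[np.ndarray, np.ndarray]:
    """Pair-aligned (PD, control) value arrays for one metric."""
    counts = df.groupby(["pair_id", "group"]).size().unstack(fill_value=0)
    for g in GROUPS:
        if g not in counts.columns or not (counts[g] == 1).all():
            raise ValueError(
                "cohort must contain exactly one PD and one control per pair_id"
            )
    wide = df.pivot(index="pair_id", columns="group", values=metric).sort_index()
    if wide.isna().any().any():
        raise ValueError(f"metric {metric!r} missing for some subjects")
    return wide["PD"].to_numpy(float), wide["control"].to_numpy(float)


def compare_metric(
    df: pd.DataFrame, metric: str, force_nonparametric: bool = False
) -> StatResult:
    """Normality-gated paired comparison of one metric between groups.

    Shapiro-Wilk is run on each group's values; if either rejects (or
    force_nonparametric), the paired Wilcoxon signed-rank test is used,
    otherwise the paired t-test. With all differences zero (identical
    groups) the result carries p = NaN: no evidence either way, reported as
    not significant.
    """
    pd_vals, ct_vals = _paired_arrays(df, metric)
    p_pd, fam_pd = shapiro_gate(pd_vals)
    p_ct, fam_ct = shapiro_gate(ct_vals)
    normality_p = min(p_pd, p_ct)
    nonparam = force_nonparametric or "nonparametric" in (fam_pd, fam_ct)
    if np.all(pd_vals == ct_vals):
        res = StatResult(
            test="degenerate",
            statistic=float("nan"),
            p_value=float("nan"),
            n=len(pd_vals),
        )
        res.normality_p = normality_p
        return res
    try:
        if nonparam:
            res = paired_wilcoxon(pd_vals, ct_vals)
        else:
            res = paired_ttest(pd_vals, ct_vals)
    except ValueError:
        res = StatResult(
            test="degenerate",
            statistic=float("nan"),
            p_value=float("nan"),
            n=len(pd_vals),
        )
    res.normality_p = normality_p
    return res


def run_cohort_comparison(
    subjects: list[SubjectSummary] | pd.DataFrame,
    metrics: dict[str, tuple[str, ...]] | None = None,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    force_nonparametric: bool = False,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Full statistical table for a paired cohort.

    metrics maps a family name to the metric columns corrected together
    (default: the calcium family and the mito family). For every metric a
    paired group comparison is run with Bonferroni correction over its
    family; for every metric x covariate pair a Spearman correlation is run
    in the PD group, corrected over the covariate family of that metric.

    Returns a tidy table: family, metric, covariate (empty for group
    comparisons), test, statistic, n, p_value, corrected_p, normality_p,
    significant.
    """
    df = subjects if isinstance(subjects, pd.DataFrame) else cohort_frame(subjects)
    if metrics is None:
        metrics = {
            "calcium": tuple(m for m in CALCIUM_METRICS if m in df.columns),
            "mito": tuple(m for m in MITO_METRICS if m in df.columns),
        }
    rows: list[dict] = []
    for family, cols in metrics.items():
        if not cols:
            continue
        results = [
            compare_metric(df, m, force_nonparametric=force_nonparametric)
            for m in cols
        ]
        corrected = bonferroni([r.p_value for r in results], m=len(cols))
        for metric, res, cp in zip(cols, results, corrected):
            rows.append(
                {
                    "family": family,
                    "metric": metric,
                    "covariate": "",
                    "test": res.test,
                    "statistic": res.statistic,
                    "n": res.n,
                    "p_value": res.p_value,
                    "corrected_p": cp,
                    "normality_p": res.normality_p,
                    "significant": bool(cp < alpha) if not np.isnan(cp) else False,
                }
            )
    pd_df = df[df["group"] == "PD"]
    avail_cov = [c for c in covariates if c in df.columns]
    for family, cols in metrics.items():
        for metric in cols:
            cres: list[StatResult | None] = []
            for cov in avail_cov:
                sub = pd_df[[metric, cov]].dropna()
                try:
                    cres.append(spearman_corr(sub[metric], sub[cov]))
                except ValueError:
                    cres.append(None)
            pvals = [r.p_value if r is not None else float("nan") for r in cres]
            corrected = bonferroni(pvals, m=len(avail_cov)) if avail_cov else []
            for cov, res, cp in zip(avail_cov, cres, corrected):
                rows.append(
                    {
                        "family": family,
                        "metric": metric,
                        "covariate": cov,
                        "test": "spearman" if res is not None else "degenerate",
                        "statistic": res.statistic if res is not None else float("nan"),
                        "n": res.n if res is not None else 0,
                        "p_value": res.p_value if res is not None else float("nan"),
                        "corrected_p": cp,
                        "normality_p": float("nan"),
                        "significant": bool(cp < alpha) if not np.isnan(cp) else False,
                    }
                )
    return pd.DataFrame(rows)
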