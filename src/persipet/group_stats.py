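"""Between-group discrimination statistics: Cohen's d and rank-based ROC AUC.

Effect sizes use the symmetric two-group form
``d = (mean_a - mean_b) / sqrt((sd_a^2 + sd_b^2) / 2)`` and are reported
signed, oriented patient minus control. The AUC is the nonparametric
Mann-Whitney probability ``P(patient > control) + 0.5 P(tie)``, computed
from midranks, which equals the trapezoidal area under the empirical ROC
curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import CohortError, ValidationError
from .quantify import SuvrTable


@dataclass
class GroupComparison:
    """Discrimination of one group pair in one region under one method."""

    region: str
    method: str
    pair: str  # e.g. "HC_vs_AD"; the second group is the positive (patient) class
    cohens_d: float
    auc: float
    n_a: int
    n_b: int

    def __post_init__(self):
        if not 0.0 <= self.auc <= 1.0:
            raise ValidationError(f"AUC out of range: {self.auc}")
        if self.n_a < 2 or self.n_b < 2:
            raise ValidationError("each group needs at least 2 subjects")


def cohens_d(mean_a: float, sd_a: float, mean_b: float, sd_b: float) -> float:
    """Symmetric standardized mean difference (a minus b)."""
    if sd_a < 0 or sd_b < 0:
        raise ValidationError("standard deviations must be non-negative")
    denom = np.sqrt((sd_a**2 + sd_b**2) / 2.0)
    if denom == 0:
        raise ValidationError("effect size undefined: both SDs are zero")
    return float((mean_a - mean_b) / denom)


def cohens_d_from_samples(a: np.ndarray, b: np.ndarray) -> float:
    """Cohen's d from raw samples (sample SDs, ddof=1), oriented a minus b."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("need at least 2 values per group")
    return cohens_d(a.mean(), a.std(ddof=1), b.mean(), b.std(ddof=1))


def auc_rank(values_a, values_b) -> float:
    """Nonparametric AUC, b as the positive class: P(b > a) + 0.5 P(b = a).

    Computed from midranks (the Mann-Whitney identity), with half credit
    for ties; equals brute-force pairwise counting.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("need at least 2 finite values per group")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValidationError("AUC inputs must be finite")
    ranks = rankdata(np.concatenate([a, b]))
    rank_sum_b = ranks[a.size :].sum()
    u_b = rank_sum_b - b.size * (b.size + 1) / 2.0
    return float(u_b / (a.size * b.size))


def compare_groups(
    table: SuvrTable,
    pair: tuple[str, str] = ("HC", "AD"),
) -> list[GroupComparison]:
    """One comparison per (region, method); ``pair[1]`` is the patient class.

    Cohen's d is oriented patient minus control, so positive d means
    higher uptake in the patient group.
    """
    control, patient = pair
    present = set(table.records["group"].unique())
    missing = [g for g in pair if g not in present]
    if missing:
        raise CohortError(f"groups absent from the SUVR table: {missing}")
    out: list[GroupComparison] = []
    regions = table.records["region"].unique()
    methods = table.records["method"].unique()
    for region in regions:
        for method in methods:
            va = table.subject_values(control, region, method)
            vb = table.subject_values(patient, region, method)
            if va.size < 2 or vb.size < 2:
                raise CohortError(
                    f"fewer than 2 subjects for {region}/{method} in pair {pair}"
                )
            out.append(
                GroupComparison(
                    region=region,
                    method=method,
                    pair=f"{control}_vs_{patient}",
                    cohens_d=cohens_d_from_samples(vb, va),
                    auc=auc_rank(va, vb),
                    n_a=int(va.size),
                    n_b=int(vb.size),
                )
            )
    return out


def comparisons_to_dataframe(comparisons: list[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame([vars(c) for c in comparisons])


def bootstrap_auc_ci(
    values_a,
    values_b,
    n_boot: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, float]:
    """Optional seeded percentile bootstrap CI for the AUC point estimate."""
    rng = np.random.default_rng(seed)
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    stats = np.empty(n_boot)
    for i in range(n_boot):
        stats[i] = auc_rank(rng.choice(a, a.size), rng.choice(b, b.size))
    lo, hi = np.quantile(stats, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)
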