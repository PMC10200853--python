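"""Per-sample summaries and Welch two-sample comparisons between tumour groups.

The quantities compared across groups are the per-sample variant count, the
per-sample mean heteroplasmy (VAF) of classified variants — averaged within
the sample first, then compared across samples — the pathogenic-variant
stratum of the same, and the mtDNA copy number. Group means are compared
with Welch's unequal-variance two-sample t-test (two-sided), with no
multiple-testing correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import Consequence
from .copy_number import MtCopyNumberResult
from .variant_filter import LABEL_DYSPLASTIC, LABEL_SOMATIC, ClassifiedVariant


@dataclass
class SampleSummary:
    sample_id: str
    group: str
    n_total_variants: int
    n_somatic: int
    n_dysplastic: int
    n_pathogenic: int
    n_nonsilent: int
    mean_vaf_total: Optional[float]
    mean_vaf_pathogenic: Optional[float]
    mtCN: float


@dataclass
class WelchResult:
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    two_sided: bool = True


def summarize_sample(classified: Sequence[ClassifiedVariant],
                     cn: MtCopyNumberResult,
                     group: str,
                     consequences: Optional[Mapping[tuple, Consequence]] = None) -> SampleSummary:
    """Summary of one tumour sample's classified variants and copy number.

    ``consequences`` maps (position, ref, alt) to the variant's annotation;
    without it the pathogenic and non-silent strata are zero.
    """
    consequences = consequences or {}
    sample_ids = {v.call.sample_id for v in classified}
    if len(sample_ids) > 1:
        raise ValueError(f"variants from multiple samples: {sorted(sample_ids)}")
    if classified and sample_ids != {cn.sample_id}:
        raise ValueError("classified variants and copy number are from different samples")

    vafs = [v.tumour_vaf for v in classified]
    pathogenic_vafs = []
    n_pathogenic = n_nonsilent = 0
    for v in classified:
        csq = consequences.get(v.call.key)
        if csq is None:
            continue
        if csq.pathogenic_flag:
            n_pathogenic += 1
            pathogenic_vafs.append(v.tumour_vaf)
        if csq.is_nonsilent:
            n_nonsilent += 1
    return SampleSummary(
        sample_id=cn.sample_id,
        group=group,
        n_total_variants=len(classified),
        n_somatic=sum(v.label == LABEL_SOMATIC for v in classified),
        n_dysplastic=sum(v.label == LABEL_DYSPLASTIC for v in classified),
        n_pathogenic=n_pathogenic,
        n_nonsilent=n_nonsilent,
        mean_vaf_total=float(np.mean(vafs)) if vafs else None,
        mean_vaf_pathogenic=float(np.mean(pathogenic_vafs)) if pathogenic_vafs else None,
        mtCN=cn.mtCN,
    )


def welch_t_test(a: Sequence[float], b: Sequence[float]) -> WelchResult:
    """Welch's unequal-variance two-sample t-test, two-sided.

    t = (mean_a - mean_b) / sqrt(s_a^2/n_a + s_b^2/n_b) with n-1 sample
    variances; degrees of freedom by Welch–Satterthwaite.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("Welch's t-test needs at least 2 observations per group")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        raise ValueError("both groups have zero variance; test is degenerate")
    res = stats.ttest_ind(a, b, equal_var=False)
    return WelchResult(
        t_statistic=float(res.statistic),
        degrees_of_freedom=float(res.df),
        p_value=float(res.pvalue),
    )


#: SampleSummary attributes compared between groups
COMPARED_QUANTITIES = ("n_total_variants", "mean_vaf_total",
                       "mean_vaf_pathogenic", "mtCN")


def compare_groups(summaries: Sequence[SampleSummary],
                   quantities: Sequence[str] = COMPARED_QUANTITIES) -> pd.DataFrame:
    """Welch tests for every group pair and quantity.

    Pairs where either group has fewer than two defined values, or where the
    test is degenerate, are reported with NaN statistics rather than omitted,
    so that the run report stays reconcilable.
    """
    rows = []
    groups = sorted({s.group for s in summaries})
    for quantity in quantities:
        values = {
            g: [getattr(s, quantity) for s in summaries
                if s.group == g and getattr(s, quantity) is not None]
            for g in groups
        }
        for i, ga in enumerate(groups):
            for gb in groups[i + 1:]:
                a, b = values[ga], values[gb]
                row = {"quantity": quantity, "group_a": ga, "group_b": gb,
                       "n_a": len(a), "n_b": len(b),
                       "t": np.nan, "df": np.nan, "p": np.nan}
                if len(a) >= 2 and len(b) >= 2:
                    try:
                        res = welch_t_test(a, b)
                        row.update(t=res.t_statistic, df=res.degrees_of_freedom,
                                   p=res.p_value)
                    except ValueError:
                        pass
                rows.append(row)
    return pd.DataFrame(rows)


def null_rejection_rate(n: int = 20, reps: int = 10_000, alpha: float = 0.05,
                        seed: int = 0) -> float:
    """Empirical type-I error of the Welch test on same-mean Gaussian groups."""
    rng = np.random.default_rng(seed)
    a = rng.standard_normal((reps, n))
    b = rng.standard_normal((reps, n))
    res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    return float(np.mean(res.pvalue < alpha))


def write_summaries(summaries: Iterable[SampleSummary], path) -> None:
    cols = ["sample_id", "group", "n_total_variants", "n_somatic", "n_dysplastic",
            "n_pathogenic", "n_nonsilent", "mean_vaf_total", "mean_vaf_pathogenic",
            "mtCN"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for s in summaries:
            row = []
            for c in cols:
                v = getattr(s, c)
                row.append("NA" if v is None else (f"{v:.6g}" if isinstance(v, float) else str(v)))
            fh.write("\t".join(row) + "\n")
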