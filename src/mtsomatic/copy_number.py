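"""mtDNA copy number per cell from the chrM/autosome depth ratio.

A diploid cell contributes two autosomal genome copies; a tumour cell of
mean ploidy ``p`` contributes ``p``. In a tissue of tumour purity ``f`` the
autosomal depth therefore corresponds to ``f*p + (1-f)*2`` genome copies per
cell, and the mitochondrial copy number per cell is

    mtCN = (mean.DPchrM / mean.DPauto) * (f * ploidy + (1 - f) * 2)

with depths measured at germline-variant sites on autosomes and on chrM.
Normal tissues use f = 1, ploidy = 2, reducing the correction factor to 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .io_formats import DepthTableRow


@dataclass
class PurityPloidy:
    """Tumour purity f in [0,1] (1 for normal tissue) and mean autosomal ploidy."""

    sample_id: str
    f: float
    ploidy: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.f <= 1.0:
            raise ValueError(f"sample {self.sample_id}: purity f={self.f} outside [0,1]")
        if self.ploidy <= 0:
            raise ValueError(f"sample {self.sample_id}: ploidy {self.ploidy} must be > 0")


@dataclass
class MtCopyNumberResult:
    sample_id: str
    mtCN: float
    depth_ratio: float
    f: float
    ploidy: float


def correction_factor(f: float, ploidy: float) -> float:
    """Genome copies per cell implied by purity and tumour ploidy."""
    return f * ploidy + (1.0 - f) * 2.0


def estimate_mt_copy_number(depth: DepthTableRow, pp: PurityPloidy) -> MtCopyNumberResult:
    """Estimate mtDNA copies per cell for one sample.

    Strictly monotone increasing in ``mean_dp_chrm``; the intermediate
    depth ratio is carried on the result for auditing.
    """
    if depth.sample_id != pp.sample_id:
        raise ValueError(
            f"sample mismatch: depth row {depth.sample_id!r} vs purity row {pp.sample_id!r}"
        )
    ratio = depth.mean_dp_chrm / depth.mean_dp_auto
    return MtCopyNumberResult(
        sample_id=depth.sample_id,
        mtCN=ratio * correction_factor(pp.f, pp.ploidy),
        depth_ratio=ratio,
        f=pp.f,
        ploidy=pp.ploidy,
    )


def estimate_cohort(depths: Iterable[DepthTableRow],
                    purities: Iterable[PurityPloidy]) -> list:
    """Copy-number estimates for every sample present in the depth table.

    Samples absent from the purity table default to f=1, ploidy=2 (normal
    tissue assumption), which is logged upstream by the pipeline.
    """
    by_sample = {pp.sample_id: pp for pp in purities}
    results = []
    for row in depths:
        pp = by_sample.get(row.sample_id, PurityPloidy(row.sample_id, 1.0, 2.0))
        results.append(estimate_mt_copy_number(row, pp))
    return results


def summarize_copy_number_by_group(results: Iterable[MtCopyNumberResult],
                                   grouping: Mapping[str, str]) -> pd.DataFrame:
    """Per-group n / mean / median of mtCN; groups with no samples are omitted."""
    results = list(results)
    missing = [r.sample_id for r in results if r.sample_id not in grouping]
    if missing:
        raise KeyError(f"samples missing from grouping: {missing}")
    df = pd.DataFrame(
        {"group": [grouping[r.sample_id] for r in results],
         "mtCN": [r.mtCN for r in results]}
    )
    if df.empty:
        return pd.DataFrame(columns=["n", "mean", "median"])
    summary = df.groupby("group")["mtCN"].agg(n="size", mean="mean", median="median")
    summary["n"] = summary["n"].astype(int)
    return summary.sort_index()


def write_copy_number_table(results: Iterable[MtCopyNumberResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tdepth_ratio\tf\tploidy\tmtCN\n")
        for r in results:
            fh.write(f"{r.sample_id}\t{r.depth_ratio:.6g}\t{r.f:.6g}\t"
                     f"{r.ploidy:.6g}\t{r.mtCN:.6g}\n")
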