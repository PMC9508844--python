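"""Pooled dropout-screen count analysis.

Guides whose double-strand break is toxic deplete from the population
between an early reference timepoint (day 4, shortly after infection)
and a late one (day 8 or 16). Analysis steps: reads-per-million
normalization, per-sample size factors estimated by median-of-ratios
over the non-targeting control guides only, paired per-replicate log2
fold changes with a symmetric pseudocount, and per-chromosome /
region-dose summaries. Depletion inference here is fold change plus a
two-sided Wilcoxon rank-sum comparison; no count GLM is fitted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_tracks import CountMatrix

__all__ = [
    "SamplePair",
    "FoldChangeTable",
    "pairs_from_metadata",
    "total_count_normalize",
    "control_size_factors",
    "log2_fold_change",
    "region_dose_comparison",
    "chromosome_summary",
]


@dataclass(frozen=True)
class SamplePair:
    """A paired (reference, target) comparison within one replicate."""

    replicate: str
    reference: str
    target: str


@dataclass
class FoldChangeTable:
    """Per-guide log2 fold changes: replicate-level columns plus mean."""

    per_replicate: pd.DataFrame  # guides x replicates
    mean: pd.Series              # guides

    def __post_init__(self) -> None:
        if not np.isfinite(self.per_replicate.to_numpy()).all():
            raise ValueError("non-finite log2 fold change")


def pairs_from_metadata(
    cm: CountMatrix, reference_day: int = 4, target_day: int = 16
) -> list[SamplePair]:
    """Build per-replicate (reference, target) pairs from sample metadata."""
    if cm.sample_info is None:
        raise ValueError("count matrix carries no sample metadata")
    info = cm.sample_info
    pairs = []
    for rep, group in info.groupby("replicate"):
        ref = group.index[group["timepoint"] == reference_day]
        tgt = group.index[group["timepoint"] == target_day]
        if len(ref) != 1 or len(tgt) != 1:
            raise ValueError(
                f"replicate {rep!r} lacks a unique day-{reference_day}/"
                f"day-{target_day} sample pair"
            )
        pairs.append(SamplePair(replicate=str(rep), reference=ref[0], target=tgt[0]))
    return pairs


def total_count_normalize(cm: CountMatrix) -> pd.DataFrame:
    """Scale every sample to reads per million."""
    totals = cm.counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"samples with zero total counts: {list(zero.index)}")
    return cm.counts / totals * 1e6


def control_size_factors(cm: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors over control guides only.

    For sample j the factor is the median over controls i of
    count_ij / geomean_i, with geomean_i the geometric mean of control i
    across samples. Controls with any zero count are excluded (their
    geometric mean is zero).
    """
    controls = cm.counts.loc[cm.is_control]
    if controls.empty:
        raise ValueError("no control guides in count matrix")
    usable = controls[(controls > 0).all(axis=1)]
    if usable.empty:
        raise ValueError("no control guide has nonzero counts in every sample")
    log_counts = np.log(usable.to_numpy(dtype=float))
    geomean = np.exp(log_counts.mean(axis=1))
    ratios = usable.div(geomean, axis=0)
    factors = ratios.median(axis=0)
    factors.name = "size_factor"
    return factors


def log2_fold_change(
    cm: CountMatrix,
    size_factors: pd.Series,
    pairs: Sequence[SamplePair],
    pseudocount: float = 0.5,
) -> FoldChangeTable:
    """Paired per-replicate log2 fold changes (target vs reference).

    Counts are scaled by their sample's size factor, the pseudocount is
    added symmetrically, and per-guide values are averaged over
    replicate pairs.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if not pairs:
        raise ValueError("no sample pairs given")
    used: set[str] = set()
    for p in pairs:
        for s in (p.reference, p.target):
            if s not in cm.counts.columns:
                raise KeyError(f"sample {s!r} not in count matrix")
            if s not in size_factors.index:
                raise KeyError(f"sample {s!r} has no size factor")
            if s in used:
                raise ValueError(f"sample {s!r} appears in more than one pair")
            used.add(s)
    cols = {}
    for p in pairs:
        ref = cm.counts[p.reference] / size_factors[p.reference] + pseudocount
        tgt = cm.counts[p.target] / size_factors[p.target] + pseudocount
        cols[p.replicate] = np.log2(tgt / ref)
    per_replicate = pd.DataFrame(cols, index=cm.counts.index)
    return FoldChangeTable(per_replicate=per_replicate, mean=per_replicate.mean(axis=1))


def _split_by_region(
    fold_changes: pd.Series, guides: pd.DataFrame, region: tuple[str, int, int]
) -> tuple[pd.Series, pd.Series]:
    chrom, start, end = region
    placed = guides.loc[~guides["is_control"].astype(bool)]
    placed = placed.set_index("id") if "id" in placed.columns else placed
    common = fold_changes.index.intersection(placed.index)
    placed = placed.loc[common]
    fc = fold_changes.loc[common]
    inside_mask = (
        (placed["chrom"] == chrom)
        & (placed["cut_pos"] >= start)
        & (placed["cut_pos"] < end)
    )
    return fc[inside_mask], fc[~inside_mask]


def region_dose_comparison(
    fold_changes: pd.Series,
    guides: pd.DataFrame,
    region: tuple[str, int, int],
) -> dict:
    """Compare fold changes of guides cutting inside vs outside a region.

    Guides in a higher-copy (e.g. amplified or trisomic) region receive
    more breaks per cell, so a dose effect shows as a more negative
    median inside the region. Returns group medians, their difference
    (inside − outside) and a two-sided Wilcoxon rank-sum p-value.
    """
    inside, outside = _split_by_region(fold_changes, guides, region)
    if len(inside) < 2 or len(outside) < 2:
        raise ValueError(
            f"need >= 2 guides on each side of the region, got "
            f"{len(inside)} inside / {len(outside)} outside"
        )
    stat, pvalue = stats.ranksums(inside, outside)
    return {
        "n_inside": int(len(inside)),
        "n_outside": int(len(outside)),
        "median_inside": float(inside.median()),
        "median_outside": float(outside.median()),
        "median_difference": float(inside.median() - outside.median()),
        "statistic": float(stat),
        "pvalue": float(pvalue),
    }


def chromosome_summary(fold_changes: pd.Series, guides: pd.DataFrame) -> pd.DataFrame:
    """Per-chromosome n, median and MAD of guide-level fold changes."""
    placed = guides.loc[~guides["is_control"].astype(bool)]
    placed = placed.set_index("id") if "id" in placed.columns else placed
    common = fold_changes.index.intersection(placed.index)
    df = pd.DataFrame(
        {"chrom": placed.loc[common, "chrom"], "lfc": fold_changes.loc[common]}
    )
    rows = []
    for chrom, group in df.groupby("chrom", sort=True):
        rows.append(
            {
                "chrom": chrom,
                "n": int(len(group)),
                "median": float(group["lfc"].median()),
                "mad": float(stats.median_abs_deviation(group["lfc"])),
            }
        )
    return pd.DataFrame(rows)
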