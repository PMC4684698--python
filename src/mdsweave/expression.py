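"""Expression divergence of genes that share germline segments.

Raw RNA-seq counts over the six-point developmental time course (vegetative
plus 0, 10, 20, 40, 60 h post mixing) are normalized by median-of-ratios size
factors, expressed as reads per kb of the quantified (alternative/unique)
region, filtered at 10 normalized reads/kb total, and compared within sharing
groups: do member genes peak at the same time point, and how different are
their germline DNA copy numbers?
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TIMEPOINTS", "ExpressionGroupProfile",
    "median_ratio_size_factors", "reads_per_kb", "peak_timepoint",
    "filter_low_expression_groups", "peak_divergence_summary",
    "copy_number_fold_summary", "round_half_up_pct",
]

TIMEPOINTS = ("Veg", "0h", "10h", "20h", "40h", "60h")


def median_ratio_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (the DESeq default method).

    The reference is the per-region geometric mean over samples; regions with
    any zero count are excluded from the reference set (only).  The size
    factor of a sample is the median over reference regions of count/reference.
    """
    mat = counts.to_numpy(dtype=float)
    all_nonzero = (mat > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError("no region has nonzero counts in all samples")
    ref = np.exp(np.log(mat[all_nonzero]).mean(axis=1))
    factors = np.median(mat[all_nonzero] / ref[:, None], axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def reads_per_kb(normalized_counts, region_length: int):
    """Normalized counts scaled to reads per kb of the quantified region."""
    if region_length <= 0:
        raise ValueError("region length must be positive")
    return np.asarray(normalized_counts, dtype=float) * 1000.0 / region_length


def peak_timepoint(profile) -> int:
    """Index of the expression peak; ties break toward the earliest point."""
    values = np.asarray(profile, dtype=float)
    if not (values > 0).any():
        raise ValueError("all-zero profile has no defined peak")
    return int(np.argmax(values))


@dataclass
class ExpressionGroupProfile:
    """Per-gene normalized expression and copy number for one sharing case."""

    case_id: str
    topology: str
    genes: list[str]
    per_kb: dict[str, np.ndarray]        # gene -> normalized reads/kb per time point
    totals: dict[str, float] = field(default_factory=dict)
    peaks: dict[str, int] = field(default_factory=dict)
    copy_number: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not self.totals:
            self.totals = {g: float(np.sum(v)) for g, v in self.per_kb.items()}
        if not self.peaks:
            self.peaks = {g: peak_timepoint(v) for g, v in self.per_kb.items()
                          if (np.asarray(v) > 0).any()}

    @property
    def same_peak(self) -> bool:
        peaks = [self.peaks[g] for g in self.genes if g in self.peaks]
        return len(set(peaks)) == 1


def filter_low_expression_groups(groups: list[ExpressionGroupProfile],
                                 threshold: float = 10.0
                                 ) -> tuple[list[ExpressionGroupProfile],
                                            dict[str, int]]:
    """Drop groups where any member's total reads/kb is below threshold (strict).

    Quantification is on the alternative/unique regions (for shared-3' groups
    these are the 5' ends, sidestepping the poly(A) 3' bias).  Returns the
    retained groups and the per-topology exclusion tally.
    """
    retained = []
    excluded: dict[str, int] = {}
    for g in groups:
        if any(g.totals[gene] < threshold for gene in g.genes):
            excluded[g.topology] = excluded.get(g.topology, 0) + 1
        else:
            retained.append(g)
    return retained, excluded


def round_half_up_pct(x: float) -> int:
    """Percentages are printed half-up (71% for 22/31, 81% for 13/16)."""
    return int(np.floor(x + 0.5))


def peak_divergence_summary(groups: list[ExpressionGroupProfile]) -> dict:
    """Per-topology counts of same-peak vs different-peak groups."""
    out: dict[str, dict] = {}
    for g in groups:
        d = out.setdefault(g.topology, {"n_groups": 0, "same_peak": 0,
                                        "different_peak": 0})
        d["n_groups"] += 1
        d["same_peak" if g.same_peak else "different_peak"] += 1
    for d in out.values():
        d["pct_different"] = (round_half_up_pct(100.0 * d["different_peak"]
                                                / d["n_groups"])
                              if d["n_groups"] else 0)
    return out


def copy_number_fold_summary(groups: list[ExpressionGroupProfile]) -> dict:
    """Within-group DNA copy-number fold differences.

    fold = max/min per group; groups with fold > 3 and fold > 2 are tallied
    (the y = 3x and y = 2x guide lines of the copy-number plot).
    """
    per_group = []
    for g in groups:
        values = [g.copy_number[gene] for gene in g.genes if gene in g.copy_number]
        if not values:
            continue
        if min(values) <= 0:
            raise ValueError(f"{g.case_id}: nonpositive DNA coverage")
        per_group.append({"case_id": g.case_id, "min": min(values),
                          "max": max(values), "fold": max(values) / min(values)})
    return {
        "groups": per_group,
        "n_above_3fold": sum(d["fold"] > 3 for d in per_group),
        "n_above_2fold": sum(d["fold"] > 2 for d in per_group),
    }
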