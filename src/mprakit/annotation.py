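"""Downstream annotation arithmetic for assayed variants.

Four independent pieces, each consuming externally produced tracks:

* depletion rank (DR): a 0–1 constraint score tiled over 500 bp genomic
  windows at a 50 bp step; a variant inherits the mean of the ~10 windows
  covering it;
* transcription-factor binding-site delta scores in [-1, 1] (negative =
  binding disrupted by the alternate allele, positive = created), thresholded
  at |score| >= 0.8 for "high-confidence" calls (inclusive boundary);
* overlap of the assayed element footprint (variant position ±100 bp) with
  epigenetic annotation intervals (BED, 0-based half-open);
* k×2 chi-square proportion tests comparing annotation-overlap rates between
  enhancer groups, with Yates continuity correction applied only for 2×2
  layouts (matching the default behaviour of the classical proportion test).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .library_design import VariantRecord

DR_WINDOW = 500
DR_STEP = 50
TFBS_CUTOFF = 0.8
OVERLAP_FLANK = 100


class AnnotationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Depletion rank


def dr_mean(variant: VariantRecord, track: pd.DataFrame) -> float:
    """Mean depletion rank over the windows covering the variant base.

    ``track`` has columns chrom, start, end, dr with 0-based half-open
    windows of width 500.  Returns NaN when no window covers the variant.
    """
    widths = track["end"] - track["start"]
    if (widths != DR_WINDOW).any():
        bad = track.loc[widths != DR_WINDOW].iloc[0]
        raise AnnotationError(
            f"malformed DR window {bad['chrom']}:{bad['start']}-{bad['end']} "
            f"(width != {DR_WINDOW})"
        )
    p0 = variant.pos - 1
    covering = track[
        (track["chrom"] == variant.chrom) & (track["start"] <= p0) & (p0 < track["end"])
    ]
    if covering.empty:
        return float("nan")
    return float(covering["dr"].mean())


def dr_mean_table(variants: Iterable[VariantRecord], track: pd.DataFrame) -> pd.Series:
    return pd.Series(
        {v.variant_id: dr_mean(v, track) for v in variants}, name="dr_mean"
    ).rename_axis("variant_id")


# ---------------------------------------------------------------------------
# TFBS delta scores


def filter_tfbs(
    scores: pd.DataFrame, cutoff: float = TFBS_CUTOFF
) -> tuple[pd.DataFrame, pd.Series]:
    """Keep high-confidence TFBS predictions and flag variants having any.

    ``scores`` has columns variant_id, tf, score with score in [-1, 1].
    Returns the kept rows (with a ``direction`` column: disrupt for negative
    scores, create for positive) and a per-variant boolean ``disrupts_tfbs``
    covering every input variant.
    """
    if (scores["score"].abs() > 1).any():
        raise AnnotationError("TFBS delta scores must lie in [-1, 1]")
    kept = scores[scores["score"].abs() >= cutoff].copy()
    kept["direction"] = np.where(kept["score"] < 0, "disrupt", "create")
    flags = (
        scores.assign(hit=scores["score"].abs() >= cutoff)
        .groupby("variant_id")["hit"]
        .any()
        .rename("disrupts_tfbs")
    )
    return kept, flags


# ---------------------------------------------------------------------------
# Interval overlap


def overlap_flank(
    variants: Iterable[VariantRecord],
    intervals: pd.DataFrame,
    flank: int = OVERLAP_FLANK,
) -> pd.DataFrame:
    """Flag variants whose ±flank footprint intersects each annotation track.

    ``intervals`` has columns chrom, start, end (0-based half-open) and
    optionally ``track`` (default "annotation").  The element footprint of a
    variant at 1-based pos is the half-open window [pos-1-flank, pos+flank).
    Returns a boolean frame indexed by variant_id with one column per track.
    """
    if flank < 0:
        raise AnnotationError("flank must be non-negative")
    intervals = intervals.copy()
    if "track" not in intervals.columns:
        intervals["track"] = "annotation"
    tracks = sorted(intervals["track"].unique())
    variants = list(variants)
    out = pd.DataFrame(
        False,
        index=pd.Index([v.variant_id for v in variants], name="variant_id"),
        columns=tracks,
    )
    grouped = {
        key: (grp["start"].to_numpy(), grp["end"].to_numpy())
        for key, grp in intervals.groupby(["track", "chrom"])
    }
    for v in variants:
        lo, hi = v.pos - 1 - flank, v.pos + flank
        for track in tracks:
            hit = grouped.get((track, v.chrom))
            if hit is None:
                continue
            starts, ends = hit
            out.loc[v.variant_id, track] = bool(np.any((starts < hi) & (ends > lo)))
    return out


# ---------------------------------------------------------------------------
# Proportion tests and the overlap summary


@dataclass(frozen=True)
class ProportionTestResult:
    statistic: float
    df: int
    pvalue: float


def proportion_test(
    counts: Sequence[int], sizes: Sequence[int], correction: bool | None = None
) -> ProportionTestResult:
    """Pearson chi-square test of equal proportions across k groups.

    Yates continuity correction is applied iff k == 2 (override with
    ``correction``).  Groups enter as (overlap count, group size).
    """
    counts = np.asarray(counts, int)
    sizes = np.asarray(sizes, int)
    if counts.size < 2:
        raise AnnotationError("need at least 2 groups")
    if np.any(sizes < 1) or np.any(counts < 0) or np.any(counts > sizes):
        raise AnnotationError("counts must satisfy 0 <= count <= size, sizes >= 1")
    if correction is None:
        correction = counts.size == 2
    table = np.column_stack([counts, sizes - counts])
    res = sstats.chi2_contingency(table, correction=correction)
    return ProportionTestResult(float(res.statistic), int(res.dof), float(res.pvalue))


def _pct(count: int, size: int) -> float:
    """Percentage rounded half-up to 2 decimals (report parity)."""
    return float(
        (Decimal(100 * count) / Decimal(size)).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
    )


def summarize_overlaps(
    group_counts: Mapping[str, Mapping[str, int]],
    group_sizes: Mapping[str, int],
    enhancer_groups: Sequence[str] | None = None,
    background_group: str | None = None,
) -> pd.DataFrame:
    """Tabulate overlap counts/percentages per group and run both test layouts.

    ``group_counts[group][annotation_class]`` is the number of variants in
    ``group`` overlapping that class.  The k-group test compares all groups;
    the merged layout pools every non-background group ("all enhancers") and
    compares against ``background_group`` (default: the last group).  Rows:
    one per group plus the two test rows (p_groups, p_merged); columns: one
    per annotation class, plus ``size``.
    """
    groups = list(group_counts)
    if len(groups) < 2:
        raise AnnotationError("need at least 2 groups")
    classes = sorted({c for g in groups for c in group_counts[g]})
    if background_group is None:
        background_group = groups[-1]
    if enhancer_groups is None:
        enhancer_groups = [g for g in groups if g != background_group]

    rows = []
    for g in groups:
        size = group_sizes[g]
        row: dict[str, object] = {"group": g, "size": size}
        for c in classes:
            n = group_counts[g].get(c, 0)
            row[f"{c}_count"] = n
            row[f"{c}_pct"] = _pct(n, size)
        rows.append(row)

    p_groups: dict[str, object] = {"group": "p_groups", "size": sum(group_sizes.values())}
    p_merged: dict[str, object] = {
        "group": "p_merged",
        "size": sum(group_sizes.values()),
    }
    merged_size = sum(group_sizes[g] for g in enhancer_groups)
    for c in classes:
        counts = [group_counts[g].get(c, 0) for g in groups]
        sizes = [group_sizes[g] for g in groups]
        p_groups[f"{c}_pct"] = proportion_test(counts, sizes).pvalue
        merged_count = sum(group_counts[g].get(c, 0) for g in enhancer_groups)
        bg_count = group_counts[background_group].get(c, 0)
        p_merged[f"{c}_pct"] = proportion_test(
            [merged_count, bg_count], [merged_size, group_sizes[background_group]]
        ).pvalue
    rows.extend([p_groups, p_merged])
    return pd.DataFrame(rows).set_index("group")
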