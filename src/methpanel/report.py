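"""Coverage, capture-efficiency and concordance summaries.

Per-region depth summaries mirror how targeted-capture performance is
reported: median and range of depth per designed region, the fraction of
bases reaching each of a ladder of thresholds (10/20/30/50/100X), the
fraction of regions "captured", and flank coverage outside the targets.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval
from .methylome import MethylTable
from .simulate import ReadObservation, deduplicated_segments

DEFAULT_THRESHOLDS = (10, 20, 30, 50, 100)
DEFAULT_CAPTURED_MIN_COV = 10


def depth_track(
    observations: Iterable[ReadObservation], reference
) -> dict[str, np.ndarray]:
    """Per-base fragment depth (mate overlaps counted once)."""
    diffs: dict[str, np.ndarray] = {}
    for seg in deduplicated_segments(observations):
        if seg.chrom not in diffs:
            diffs[seg.chrom] = np.zeros(len(reference[seg.chrom]) + 1, dtype=np.int64)
        diffs[seg.chrom][seg.start] += 1
        diffs[seg.chrom][seg.end] -= 1
    return {c: np.cumsum(d[:-1]) for c, d in diffs.items()}


def region_coverage(
    depth: Mapping[str, np.ndarray],
    regions: Sequence[GenomicInterval],
    thresholds: Sequence[int] = DEFAULT_THRESHOLDS,
    captured_min_cov: int = DEFAULT_CAPTURED_MIN_COV,
) -> pd.DataFrame:
    """Per-region depth summary; absent depth counts as zero.

    A region is "captured" when at least one of its bases reaches
    ``captured_min_cov`` (the 10X filter analogue).
    """
    if not regions:
        raise ValueError("no regions given")
    rows = []
    for iv in regions:
        d = depth.get(iv.chrom)
        vals = (
            d[iv.start : iv.end]
            if d is not None
            else np.zeros(iv.length, dtype=np.int64)
        )
        if len(vals) < iv.length:  # region runs past the depth track
            vals = np.concatenate([vals, np.zeros(iv.length - len(vals), int)])
        row = {
            "region": str(iv),
            "chrom": iv.chrom,
            "start": iv.start,
            "end": iv.end,
            "n_bases": iv.length,
            "median_depth": float(np.median(vals)),
            "min_depth": int(vals.min()),
            "max_depth": int(vals.max()),
            "captured": bool((vals >= captured_min_cov).any()),
        }
        for t in thresholds:
            row[f"frac_ge_{t}x"] = float(np.mean(vals >= t))
        rows.append(row)
    return pd.DataFrame(rows)


def coverage_totals(summary: pd.DataFrame) -> dict[str, float]:
    """Panel-level roll-up of a region_coverage table."""
    captured = summary["captured"]
    return {
        "n_regions": int(len(summary)),
        "n_captured": int(captured.sum()),
        "fraction_captured": float(captured.mean()),
        "median_of_medians": float(summary["median_depth"].median()),
        "min_depth": int(summary["min_depth"].min()),
        "max_depth": int(summary["max_depth"].max()),
    }


def flank_coverage(
    depth: Mapping[str, np.ndarray],
    regions: Sequence[GenomicInterval],
    windows: Sequence[int] = (100, 200),
    threshold: int = 30,
) -> dict[int, float]:
    """Fraction of flank bases (region +/- w, excluding the region) >= threshold.

    Window 0 has an empty flank and is reported as NaN (not applicable).
    """
    from .intervals import merge_intervals

    merged = merge_intervals(regions)
    target_mask: dict[str, np.ndarray] = {}
    for chrom, d in depth.items():
        m = np.zeros(len(d), dtype=bool)
        for iv in merged:
            if iv.chrom == chrom:
                m[iv.start : iv.end] = True
        target_mask[chrom] = m
    out: dict[int, float] = {}
    for w in windows:
        if w < 0:
            raise ValueError("windows must be non-negative")
        if w == 0:
            out[w] = float("nan")
            continue
        covered = total = 0
        for chrom, d in depth.items():
            flank = np.zeros(len(d), dtype=bool)
            for iv in merged:
                if iv.chrom != chrom:
                    continue
                flank[max(0, iv.start - w) : iv.start] = True
                flank[iv.end : min(len(d), iv.end + w)] = True
            flank &= ~target_mask[chrom]
            total += int(flank.sum())
            covered += int((d[flank] >= threshold).sum())
        out[w] = covered / total if total else float("nan")
    return out


def beta_correlation(
    table_x: MethylTable,
    table_y: MethylTable,
    regions: Sequence[GenomicInterval] | None = None,
) -> tuple[float, int]:
    """Spearman rank correlation of beta values over shared CpGs."""
    x = table_x.records[["chrom", "pos", "beta"]].rename(columns={"beta": "x"})
    y = table_y.records[["chrom", "pos", "beta"]].rename(columns={"beta": "y"})
    shared = x.merge(y, on=["chrom", "pos"])
    if regions is not None:
        keep = np.zeros(len(shared), dtype=bool)
        for iv in regions:
            keep |= (
                (shared["chrom"] == iv.chrom)
                & (shared["pos"] >= iv.start)
                & (shared["pos"] < iv.end)
            ).to_numpy()
        shared = shared[keep]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared CpGs for a rank correlation")
    rho = stats.spearmanr(shared["x"], shared["y"]).statistic
    return float(rho), int(len(shared))
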