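"""Differential methylation: DMP/DMR calling and cross-method consensus.

A CpG is a differentially methylated position (DMP) when the absolute
beta difference between the two samples exceeds a fixed threshold
(default |delta| > 0.1, strictly); a differentially methylated region
(DMR) is a maximal run of at least ``min_consecutive`` consecutive shared
CpGs that are DMPs with the same direction.  This is an effect-size rule,
not a statistical test — no multiple-testing machinery applies.

The cross-method consensus keeps CpGs where one chemistry (BS or EM)
shows |delta| above a primary threshold and the other confirms with
|delta| at or above a secondary threshold in the same direction.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval
from .methylome import MethylTable

DEFAULT_DMP_THRESHOLD = 0.1
DEFAULT_MIN_CONSECUTIVE = 2
DEFAULT_PRIMARY_THRESHOLD = 0.10
DEFAULT_SECONDARY_THRESHOLD = 0.05

DMP_COLUMNS = ["chrom", "pos", "beta_a", "beta_b", "delta", "is_dmp", "direction"]
DMR_COLUMNS = ["chrom", "start", "end", "n_cpgs", "direction", "members"]


def methylation_diff(
    table_a: MethylTable,
    table_b: MethylTable,
    dmp_threshold: float = DEFAULT_DMP_THRESHOLD,
) -> pd.DataFrame:
    """Per-CpG beta difference over the CpGs shared by both tables.

    delta = beta_a - beta_b (first sample minus second); a CpG is a DMP
    iff |delta| is strictly greater than ``dmp_threshold``.
    """
    a = table_a.records[["chrom", "pos", "beta"]].rename(columns={"beta": "beta_a"})
    b = table_b.records[["chrom", "pos", "beta"]].rename(columns={"beta": "beta_b"})
    shared = a.merge(b, on=["chrom", "pos"], how="inner")
    if shared.empty:
        raise ValueError("the two samples share no covered CpGs")
    shared["delta"] = shared["beta_a"] - shared["beta_b"]
    shared["is_dmp"] = np.abs(shared["delta"]) > dmp_threshold
    shared["direction"] = np.sign(shared["delta"]).astype(int)
    return shared.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def call_dmrs(
    dmps: pd.DataFrame,
    min_consecutive: int = DEFAULT_MIN_CONSECUTIVE,
    max_gap: int | None = None,
) -> pd.DataFrame:
    """Maximal runs of consecutive same-direction DMPs in the shared list.

    Adjacency is positional in the shared-CpG list (a covered non-DMP CpG
    breaks a run); ``max_gap``, if set, additionally breaks runs whose
    neighbouring member CpGs are more than that many bases apart.  Each
    DMR spans from its first member's C to the end of its last member's
    CpG dinucleotide (half-open).
    """
    rows = []
    for chrom, grp in dmps.groupby("chrom", sort=True):
        grp = grp.sort_values("pos", kind="stable")
        run: list[tuple[int, int]] = []  # (pos, direction)
        def flush():
            if len(run) >= min_consecutive:
                positions = [p for p, _ in run]
                rows.append(
                    {
                        "chrom": chrom,
                        "start": positions[0],
                        "end": positions[-1] + 2,
                        "n_cpgs": len(positions),
                        "direction": run[0][1],
                        "members": positions,
                    }
                )
        for _, rec in grp.iterrows():
            pos, direction = int(rec["pos"]), int(rec["direction"])
            if not rec["is_dmp"]:
                flush()
                run = []
                continue
            if run and (
                direction != run[-1][1]
                or (max_gap is not None and pos - run[-1][0] > max_gap)
            ):
                flush()
                run = []
            run.append((pos, direction))
        flush()
    return pd.DataFrame(rows, columns=DMR_COLUMNS)


def cross_method_consensus(
    bs_dmps: pd.DataFrame,
    em_dmps: pd.DataFrame,
    primary_threshold: float = DEFAULT_PRIMARY_THRESHOLD,
    secondary_threshold: float = DEFAULT_SECONDARY_THRESHOLD,
) -> pd.DataFrame:
    """CpGs confirmed by both chemistries in the same direction.

    Keep CpGs present in both difference tables where |delta| exceeds the
    primary threshold (strictly) in at least one method, the other method
    reaches at least the secondary threshold, and the signs agree.
    ``primary_method`` records which chemistry cleared the primary bar.
    """
    bs = bs_dmps[["chrom", "pos", "delta"]].rename(columns={"delta": "delta_bs"})
    em = em_dmps[["chrom", "pos", "delta"]].rename(columns={"delta": "delta_em"})
    m = bs.merge(em, on=["chrom", "pos"], how="inner")
    abs_bs, abs_em = np.abs(m["delta_bs"]), np.abs(m["delta_em"])
    same_sign = np.sign(m["delta_bs"]) == np.sign(m["delta_em"])
    bs_primary = (abs_bs > primary_threshold) & (abs_em >= secondary_threshold)
    em_primary = (abs_em > primary_threshold) & (abs_bs >= secondary_threshold)
    keep = same_sign & (bs_primary | em_primary)
    out = m[keep].reset_index(drop=True)
    out["direction"] = np.sign(out["delta_bs"]).astype(int)
    out["primary_method"] = np.select(
        [bs_primary[keep] & em_primary[keep], bs_primary[keep]],
        ["both", "BS"],
        default="EM",
    )
    return out


def annotate_nearest_feature(
    records: pd.DataFrame,
    features: Sequence[tuple[GenomicInterval, str]],
) -> pd.DataFrame:
    """Attach the nearest feature (promoter/gene) to each consensus CpG.

    A feature containing the CpG wins with distance 0; otherwise the
    feature with the nearest midpoint is chosen.  Exact ties go to the
    lexicographically smallest feature id, with ``tie`` flagged.
    """
    if not features:
        raise ValueError("feature set is empty")
    feats = sorted(features, key=lambda f: f[1])
    ids, names, dists, ties = [], [], [], []
    for _, rec in records.iterrows():
        pos, chrom = int(rec["pos"]), rec["chrom"]
        containers = [
            fid
            for iv, fid in feats
            if iv.chrom == chrom and iv.start <= pos < iv.end
        ]
        if containers:
            best_ids, best_d = sorted(containers), 0.0
        else:
            best_d, best_ids = np.inf, []
            for iv, fid in feats:
                if iv.chrom != chrom:
                    continue
                d = abs(pos - (iv.start + iv.end - 1) / 2.0)
                if d < best_d - 1e-9:
                    best_d, best_ids = d, [fid]
                elif abs(d - best_d) <= 1e-9:
                    best_ids.append(fid)
            if not best_ids:
                raise ValueError(f"no feature on chromosome {chrom}")
            best_ids = sorted(best_ids)
        names.append(best_ids[0])
        dists.append(float(best_d))
        ties.append(len(best_ids) > 1)
    out = records.copy().reset_index(drop=True)
    out["feature"] = names
    out["distance"] = dists
    out["tie"] = ties
    return out
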