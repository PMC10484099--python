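"""Capture panel design: probe tiling, repeat masking, GC boosting, coverage.

The design procedure mirrors hybridization-capture array design practice:
fixed-length probes (default 120 nt) are tiled across each target region at
a requested density k (each base covered on average by ~k probes), probes
falling in consensus-masked repeats are rejected, and probes over GC-rich
sequence are replicated ("boosted", up to 16 copies) to compensate for
their weaker capture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import (
    GenomicInterval,
    MaskTrack,
    intersect_two,
    merge_intervals,
    total_bases,
)
from .refutil import chrom_length, fetch, gc_fraction

DEFAULT_PROBE_LENGTH = 120
DEFAULT_TILING_DENSITY = 3
DEFAULT_BOOST_CAP = 16
DEFAULT_MAX_MASKED_FRACTION = 0.25

#: GC fraction upper bound (inclusive) -> copy number; a doubling ladder
#: capped at 16 copies for the most GC-rich probes.
DEFAULT_BOOST_SCHEDULE: tuple[tuple[float, int], ...] = (
    (0.60, 1),
    (0.65, 2),
    (0.70, 4),
    (0.75, 8),
    (1.00, 16),
)


@dataclass
class Probe:
    """A single capture probe with its synthesis copy number."""

    id: str
    interval: GenomicInterval
    gc_fraction: float
    copy_number: int = 1
    masked_bases: int = 0
    sequence: str | None = None

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass
class PanelDesign:
    """A probe panel with its target groups and design parameters."""

    probes: list[Probe]
    target_groups: dict[str, list[GenomicInterval]]
    params: dict = field(default_factory=dict)

    @property
    def targets(self) -> list[GenomicInterval]:
        return [iv for ivs in self.target_groups.values() for iv in ivs]

    def footprint(self) -> list[GenomicInterval]:
        """Union of probe intervals (copy numbers ignored)."""
        return merge_intervals(p.interval for p in self.probes)


def tile_probes(
    targets: Sequence[GenomicInterval],
    reference,
    probe_len: int = DEFAULT_PROBE_LENGTH,
    tiling_density: int = DEFAULT_TILING_DENSITY,
    id_prefix: str = "probe",
    keep_sequence: bool = False,
) -> list[Probe]:
    """Tile fixed-length probes across target regions at density k.

    Probes step left-to-right by ``round(probe_len / tiling_density)``; the
    terminal probe of each region is right-aligned to the region end so no
    target base is left uncovered.  Regions shorter than a probe get one
    probe centered on the region, extended into the flanks and clipped at
    chromosome bounds.  Probes containing ambiguous bases (N) are dropped —
    they could not be synthesized.
    """
    if probe_len < 1:
        raise ValueError("probe_len must be >= 1")
    if tiling_density < 1:
        raise ValueError("tiling_density must be a positive integer")
    step = max(1, round(probe_len / tiling_density))

    probes: list[Probe] = []
    counter = 0
    for region in targets:
        clen = chrom_length(reference, region.chrom)
        if region.end > clen:
            raise ValueError(
                f"target {region} extends beyond {region.chrom} length {clen}"
            )
        starts: list[int] = []
        if region.length >= probe_len:
            s = region.start
            while s + probe_len <= region.end:
                starts.append(s)
                s += step
            last = region.end - probe_len
            if starts[-1] != last:
                starts.append(last)
        else:
            center = (region.start + region.end) // 2
            s = center - probe_len // 2
            s = min(max(0, s), clen - probe_len)
            if s < 0:
                continue  # chromosome shorter than a probe
            starts.append(s)
        for s in starts:
            seq = fetch(reference, region.chrom, s, s + probe_len)
            if "N" in seq:
                continue
            iv = GenomicInterval(region.chrom, s, s + probe_len)
            probes.append(
                Probe(
                    id=f"{id_prefix}_{counter:06d}",
                    interval=iv,
                    gc_fraction=gc_fraction(seq),
                    sequence=seq if keep_sequence else None,
                )
            )
            counter += 1
    return probes


def consensus_mask(
    tracks: Sequence[MaskTrack], policy: str = "least_stringent"
) -> MaskTrack:
    """Combine masker tracks into one consensus track.

    ``least_stringent``: a base is masked only if *every* masker flags it
    (set intersection) — fewer bases masked, more probes survive.
    ``most_stringent``: masked if *any* masker flags it (union).
    """
    if not tracks:
        raise ValueError("need at least one mask track")
    if policy not in {"least_stringent", "most_stringent"}:
        raise ValueError(f"unknown mask policy {policy!r}")
    if policy == "most_stringent":
        combined = merge_intervals(
            iv for track in tracks for iv in track.intervals
        )
    else:
        combined = list(tracks[0].intervals)
        for track in tracks[1:]:
            combined = intersect_two(combined, track.intervals)
    return MaskTrack(name=f"consensus_{policy}", intervals=combined)


def filter_masked_probes(
    probes: Iterable[Probe],
    mask: MaskTrack,
    max_masked_fraction: float = DEFAULT_MAX_MASKED_FRACTION,
) -> list[Probe]:
    """Annotate masked-base overlap and drop probes exceeding the tolerance.

    A probe is removed when masked_bases / length is *strictly greater*
    than ``max_masked_fraction``; probes sitting exactly at the threshold
    are retained.  Input order is preserved.
    """
    kept: list[Probe] = []
    for probe in probes:
        probe.masked_bases = mask.overlap_bases(probe.interval)
        if probe.masked_bases / probe.length <= max_masked_fraction:
            kept.append(probe)
    return kept


def boost_probes(
    probes: Iterable[Probe],
    schedule: Sequence[tuple[float, int]] = DEFAULT_BOOST_SCHEDULE,
    cap: int = DEFAULT_BOOST_CAP,
) -> list[Probe]:
    """Assign synthesis copy numbers from probe GC content.

    ``schedule`` is an ordered list of (gc upper bound, copy number); a
    probe receives the copy number of the first bin whose bound is >= its
    GC fraction, clipped to ``cap``.  The schedule must be monotone
    non-decreasing in both GC and copies so boosting is monotone in GC.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    bounds = [b for b, _ in schedule]
    copies = [c for _, c in schedule]
    if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])) or any(
        c2 < c1 for c1, c2 in zip(copies, copies[1:])
    ):
        raise ValueError("boost schedule must be monotone non-decreasing in GC")
    out = list(probes)
    for probe in out:
        copy = copies[-1]
        for bound, c in schedule:
            if probe.gc_fraction <= bound:
                copy = c
                break
        probe.copy_number = max(1, min(copy, cap))
    return out


def in_silico_coverage(design: PanelDesign) -> dict[str, float]:
    """Fraction of target bases covered by >= 1 probe footprint, per group.

    Copy numbers are ignored: a boosted probe covers the same bases as a
    single copy, so coverage is computed on the deduplicated footprint.
    """
    footprint = design.footprint()
    result: dict[str, float] = {}
    all_targets: list[GenomicInterval] = []
    for group, targets in design.target_groups.items():
        merged = merge_intervals(targets)
        all_targets.extend(merged)
        denom = sum(iv.length for iv in merged)
        covered = sum(iv.length for iv in intersect_two(footprint, merged))
        result[group] = covered / denom if denom else 0.0
    merged_all = merge_intervals(all_targets)
    denom = sum(iv.length for iv in merged_all)
    covered = sum(iv.length for iv in intersect_two(footprint, merged_all))
    result["overall"] = covered / denom if denom else 0.0
    return result


def _assign_group(probe: Probe, design: PanelDesign) -> str:
    best, best_ov = "unassigned", 0
    for group, targets in design.target_groups.items():
        ov = sum(probe.interval.overlap_length(t) for t in merge_intervals(targets))
        if ov > best_ov:
            best, best_ov = group, ov
    return best


def panel_summary(design: PanelDesign) -> pd.DataFrame:
    """Panel accounting table: probes, oligos, footprint kb per target group.

    ``n_probes`` counts distinct probe placements; ``n_oligos`` counts
    synthesized copies (sum of copy numbers); ``capture_kb`` is the
    deduplicated probe footprint in kilobases.
    """
    groups = list(design.target_groups)
    rows = []
    by_group: dict[str, list[Probe]] = {g: [] for g in groups}
    for probe in design.probes:
        g = _assign_group(probe, design)
        by_group.setdefault(g, []).append(probe)
    for group in by_group:
        probes = by_group[group]
        targets = design.target_groups.get(group, [])
        rows.append(
            {
                "group": group,
                "n_regions": len(targets),
                "n_probes": len(probes),
                "n_oligos": int(sum(p.copy_number for p in probes)),
                "capture_kb": total_bases(p.interval for p in probes) / 1000.0,
                "tiling": design.params.get("tiling", {}).get(group, np.nan)
                if isinstance(design.params.get("tiling"), dict)
                else design.params.get("tiling", np.nan),
            }
        )
    total = {
        "group": "total",
        "n_regions": sum(r["n_regions"] for r in rows),
        "n_probes": len(design.probes),
        "n_oligos": int(sum(p.copy_number for p in design.probes)),
        "capture_kb": total_bases(p.interval for p in design.probes) / 1000.0,
        "tiling": np.nan,
    }
    return pd.DataFrame(rows + [total])


def design_panel(
    target_groups: Mapping[str, Sequence[GenomicInterval]],
    reference,
    mask_tracks: Sequence[MaskTrack] = (),
    mask_policy: str = "least_stringent",
    probe_len: int = DEFAULT_PROBE_LENGTH,
    tiling_density: int | Mapping[str, int] = DEFAULT_TILING_DENSITY,
    max_masked_fraction: float = DEFAULT_MAX_MASKED_FRACTION,
    boost_schedule: Sequence[tuple[float, int]] = DEFAULT_BOOST_SCHEDULE,
    boost_cap: int = DEFAULT_BOOST_CAP,
) -> PanelDesign:
    """End-to-end design: tile, consensus-mask, filter, boost."""
    probes: list[Probe] = []
    for group, targets in target_groups.items():
        k = (
            tiling_density[group]
            if isinstance(tiling_density, Mapping)
            else tiling_density
        )
        probes.extend(
            tile_probes(
                list(targets),
                reference,
                probe_len=probe_len,
                tiling_density=k,
                id_prefix=group,
            )
        )
    if mask_tracks:
        mask = consensus_mask(list(mask_tracks), policy=mask_policy)
        probes = filter_masked_probes(probes, mask, max_masked_fraction)
    probes = boost_probes(probes, schedule=boost_schedule, cap=boost_cap)
    params = {
        "probe_len": probe_len,
        "tiling": dict(tiling_density)
        if isinstance(tiling_density, Mapping)
        else tiling_density,
        "mask_policy": mask_policy,
        "max_masked_fraction": max_masked_fraction,
        "boost_cap": boost_cap,
        "boost_schedule": list(boost_schedule),
    }
    return PanelDesign(
        probes=probes,
        target_groups={g: list(t) for g, t in target_groups.items()},
        params=params,
    )
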