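"""Per-cytosine methylation quantification from converted-read observations.

Methylation at a cytosine is the number of reads calling C divided by the
total number of calls (C + T) — the standard beta value.  A directional
protocol is assumed: original-top (OT) reads interrogate only plus-strand
cytosines, original-bottom (OB) reads only minus-strand cytosines (which
appear as G>A on the reference strand).  The two symmetric cytosines of a
CpG dinucleotide are merged into one strand-merged unit, reported at the
plus-strand C coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .refutil import chrom_names, encode, fetch, chrom_length
from .simulate import ReadObservation, deduplicated_segments

CYTOSINE_COLUMNS = ["chrom", "pos", "strand", "context", "meth", "unmeth"]
CPG_COLUMNS = ["chrom", "pos", "meth", "unmeth", "beta"]


@dataclass
class MethylTable:
    """Coordinate-sorted strand-merged CpG counts for one sample/library."""

    sample: str
    library: str  # BS | EM
    records: pd.DataFrame  # CPG_COLUMNS
    coverage_filter: int = 0

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in ("chrom", "pos", "meth", "unmeth") if c not in df]
        if missing:
            raise ValueError(f"MethylTable records missing columns {missing}")
        df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
        df["beta"] = df["meth"] / (df["meth"] + df["unmeth"])
        self.records = df

    def __len__(self) -> int:
        return len(self.records)


def _context_arrays(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-position context codes (0=CpG, 1=CHG, 2=CHH) for +C and -G sites."""
    n = len(codes)
    ctx_plus = np.full(n, 2, dtype=np.uint8)
    ctx_minus = np.full(n, 2, dtype=np.uint8)
    nxt = np.roll(codes, -1)
    nxt[-1] = 4
    nxt2 = np.roll(codes, -2)
    nxt2[-2:] = 4
    prv = np.roll(codes, 1)
    prv[0] = 4
    prv2 = np.roll(codes, 2)
    prv2[:2] = 4
    ctx_plus[nxt2 == 2] = 1  # CHG
    ctx_plus[nxt == 2] = 0  # CpG wins
    ctx_minus[prv2 == 1] = 1
    ctx_minus[prv == 1] = 0
    return ctx_plus, ctx_minus

_CTX_NAMES = np.array(["CpG", "CHG", "CHH"])


def call_cytosines(
    observations: Iterable[ReadObservation],
    reference,
    min_base_quality: int = 20,
) -> pd.DataFrame:
    """Count methylated (C) vs unmethylated (T) calls per reference cytosine.

    OT reads inform plus-strand Cs (C call = methylated, T = unmethylated);
    OB reads inform minus-strand Cs, read as G (methylated) vs A on the
    reference strand.  Other base calls are genetic mismatches and are
    ignored for methylation.  Context (CpG/CHG/CHH) comes from the
    reference trinucleotide, never from the reads.  Overlapping mates are
    deduplicated so each molecule counts once per position.

    ``min_base_quality`` applies only to quality-bearing input; the
    simulator's observation table carries no qualities.
    """
    acc: dict[str, dict[str, np.ndarray]] = {}
    ref_codes: dict[str, np.ndarray] = {}

    def _chrom_arrays(chrom: str):
        if chrom not in acc:
            n = chrom_length(reference, chrom)
            ref_codes[chrom] = encode(fetch(reference, chrom, 0, n))
            acc[chrom] = {
                k: np.zeros(n, dtype=np.int64)
                for k in ("mp", "up", "mm", "um")
            }
        return ref_codes[chrom], acc[chrom]

    for seg in deduplicated_segments(observations):
        codes, a = _chrom_arrays(seg.chrom)
        if seg.end > len(codes) or seg.start < 0:
            raise ValueError(
                f"observation {seg.read_id} at {seg.chrom}:{seg.start}-{seg.end} "
                "lies outside the reference"
            )
        refseg = codes[seg.start : seg.end]
        readseg = encode(seg.bases)
        if seg.strand == "OT":
            sites = refseg == 1
            meth = sites & (readseg == 1)
            unmeth = sites & (readseg == 3)
            np.add.at(a["mp"], np.flatnonzero(meth) + seg.start, 1)
            np.add.at(a["up"], np.flatnonzero(unmeth) + seg.start, 1)
        else:
            sites = refseg == 2
            meth = sites & (readseg == 2)
            unmeth = sites & (readseg == 0)
            np.add.at(a["mm"], np.flatnonzero(meth) + seg.start, 1)
            np.add.at(a["um"], np.flatnonzero(unmeth) + seg.start, 1)

    frames = []
    for chrom in sorted(acc):
        codes = ref_codes[chrom]
        ctx_plus, ctx_minus = _context_arrays(codes)
        a = acc[chrom]
        for strand, mk, uk, ctx in (
            ("+", "mp", "up", ctx_plus),
            ("-", "mm", "um", ctx_minus),
        ):
            pos = np.flatnonzero(a[mk] + a[uk] > 0)
            if len(pos) == 0:
                continue
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": pos,
                        "strand": strand,
                        "context": _CTX_NAMES[ctx[pos]],
                        "meth": a[mk][pos],
                        "unmeth": a[uk][pos],
                    }
                )
            )
    if not frames:
        return pd.DataFrame(columns=CYTOSINE_COLUMNS)
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["chrom", "pos", "strand"], kind="stable").reset_index(
        drop=True
    )


def merge_cpg_strands(records: pd.DataFrame, reference) -> pd.DataFrame:
    """Merge the two symmetric cytosines of each CpG by summing counts.

    The minus-strand C at position p+1 is folded into the plus-strand C at
    p; the merged unit is reported at p.  Non-CpG records are excluded.
    Records whose claimed CpG context disagrees with the reference raise.
    """
    if "context" not in records.columns:
        raise ValueError("records must carry a context column")
    cpg = records[records["context"] == "CpG"].copy()
    if cpg.empty:
        return pd.DataFrame(columns=CPG_COLUMNS)
    unit_pos = np.where(cpg["strand"] == "+", cpg["pos"], cpg["pos"] - 1)
    cpg["unit"] = unit_pos
    for chrom, grp in cpg.groupby("chrom", sort=False):
        seq_len = chrom_length(reference, chrom)
        lo, hi = int(grp["unit"].min()), int(grp["unit"].max())
        if lo < 0 or hi + 2 > seq_len:
            raise ValueError("CpG record outside reference bounds")
        seq = fetch(reference, chrom, 0, seq_len)
        for u in grp["unit"].unique():
            if seq[u : u + 2] != "CG":
                raise ValueError(
                    f"record at {chrom}:{u} is not a reference CpG; "
                    "refusing to merge records of different contexts"
                )
    merged = (
        cpg.groupby(["chrom", "unit"], sort=True)[["meth", "unmeth"]]
        .sum()
        .reset_index()
        .rename(columns={"unit": "pos"})
    )
    merged["beta"] = merged["meth"] / (merged["meth"] + merged["unmeth"])
    return merged[CPG_COLUMNS]


def filter_coverage(table: "MethylTable | pd.DataFrame", min_cov: int) -> MethylTable:
    """Keep strand-merged CpGs with depth >= min_cov (10X filter analogue)."""
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    if isinstance(table, MethylTable):
        df, sample, library = table.records, table.sample, table.library
    else:
        df, sample, library = table, "sample", "BS"
    kept = df[(df["meth"] + df["unmeth"]) >= min_cov].reset_index(drop=True)
    return MethylTable(
        sample=sample, library=library, records=kept, coverage_filter=min_cov
    )


def conversion_efficiency(records: pd.DataFrame) -> dict[str, float]:
    """Apparent methylation at non-CpG cytosines: the conversion-failure QC.

    Returns the pooled CHG+CHH methylated fraction plus per-context
    values.  When true non-CpG methylation is zero (as in most somatic
    cells), the pooled fraction estimates the conversion failure rate
    directly; 1 - fraction is the conversion efficiency.
    """
    non_cpg = records[records["context"].isin(["CHG", "CHH"])]
    depth = int((non_cpg["meth"] + non_cpg["unmeth"]).sum())
    if depth == 0:
        raise ValueError("no non-CpG coverage: cannot estimate conversion rate")
    out = {"pooled": float(non_cpg["meth"].sum() / depth), "n_calls": depth}
    for ctx in ("CHG", "CHH"):
        sub = non_cpg[non_cpg["context"] == ctx]
        d = int((sub["meth"] + sub["unmeth"]).sum())
        out[ctx] = float(sub["meth"].sum() / d) if d else float("nan")
    return out


def quantify(
    observations: Iterable[ReadObservation],
    reference,
    sample: str = "sample",
    library: str = "BS",
    min_cov: int = 10,
) -> MethylTable:
    """Observations -> cytosine calls -> strand-merged, coverage-filtered CpGs."""
    cyt = call_cytosines(observations, reference)
    merged = merge_cpg_strands(cyt, reference)
    table = MethylTable(sample=sample, library=library, records=merged)
    return filter_coverage(table, min_cov)
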