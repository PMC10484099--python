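"""Readers and writers for the on-disk formats the toolkit exchanges.

Conventions: BED is 0-based half-open; the Bismark coverage dialect
(``.cov``) is 1-based inclusive with methylation as a 0-100 percentage;
VCF is 1-based.  Internally everything is 0-based half-open with beta
values as fractions; conversions happen only here.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genotyping import GenotypeCall
from .intervals import GenomicInterval, MaskTrack
from .methylome import CPG_COLUMNS, MethylTable
from .panel import Probe
from .refutil import revcomp
from .simulate import DiploidTruth, ReadObservation

# ---------------------------------------------------------------- BED


def read_bed(path) -> list[GenomicInterval]:
    """Read BED3+ target/mask intervals (extra columns ignored)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            out.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2])))
    return out


def read_bed_named(path) -> list[tuple[GenomicInterval, str]]:
    """Read BED with a name column (column 4)."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            name = parts[3] if len(parts) > 3 else f"feature_{i}"
            out.append((GenomicInterval(parts[0], int(parts[1]), int(parts[2])), name))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path, names=None) -> None:
    names = list(names) if names is not None else None
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if names is not None:
                cols.append(str(names[i]))
            fh.write("\t".join(cols) + "\n")


def read_mask_tracks(paths: Sequence[str]) -> list[MaskTrack]:
    return [
        MaskTrack(name=Path(p).stem, intervals=read_bed(p)) for p in paths
    ]


def write_panel_bed(probes: Iterable[Probe], path) -> None:
    """Panel BED with name, GC fraction and copy number columns."""
    with open(path, "w") as fh:
        for p in probes:
            iv = p.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.id}\t"
                f"{p.gc_fraction:.4f}\t{p.copy_number}\n"
            )


def read_panel_bed(path) -> list[Probe]:
    probes = []
    with open(path) as fh:
        for line in fh:
            chrom, start, end, pid, gc, copies = line.rstrip("\n").split("\t")
            probes.append(
                Probe(
                    id=pid,
                    interval=GenomicInterval(chrom, int(start), int(end)),
                    gc_fraction=float(gc),
                    copy_number=int(copies),
                )
            )
    return probes


# ---------------------------------------------------------------- FASTA


def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------- Bismark coverage


def write_bismark_cov(table: "MethylTable | pd.DataFrame", path) -> None:
    """Write strand-merged CpG counts in the Bismark coverage dialect.

    Columns: chrom, start (1-based), end (1-based inclusive),
    methylation percentage, methylated count, unmethylated count.
    The percentage is recomputed from the counts, so a read/write cycle
    is byte-stable.
    """
    df = table.records if isinstance(table, MethylTable) else table
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            pct = 100.0 * row.meth / (row.meth + row.unmeth)
            fh.write(
                f"{row.chrom}\t{row.pos + 1}\t{row.pos + 1}\t{pct:g}\t"
                f"{int(row.meth)}\t{int(row.unmeth)}\n"
            )


def read_bismark_cov(
    path, sample: str = "sample", library: str = "BS", coverage_filter: int = 0
) -> MethylTable:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "pct", "meth", "unmeth"],
        dtype={"chrom": str},
    )
    records = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["start"] - 1,
            "meth": df["meth"],
            "unmeth": df["unmeth"],
        }
    )
    records["beta"] = records["meth"] / (records["meth"] + records["unmeth"])
    return MethylTable(
        sample=sample,
        library=library,
        records=records[CPG_COLUMNS],
        coverage_filter=coverage_filter,
    )


# ---------------------------------------------------------------- cytosine / observation tables


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_cytosine_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


OBS_COLUMNS = [
    "read_id",
    "fragment_id",
    "chrom",
    "start",
    "end",
    "strand",
    "mate",
    "haplotype",
    "library",
    "bases",
]


def write_observations(observations: Iterable[ReadObservation], path) -> None:
    df = pd.DataFrame([dataclasses.asdict(o) for o in observations])
    df[OBS_COLUMNS].to_csv(path, sep="\t", index=False)


def read_observations(path) -> list[ReadObservation]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "bases": str})
    return [ReadObservation(**row) for row in df[OBS_COLUMNS].to_dict("records")]


def write_fastq(
    observations: Sequence[ReadObservation], prefix: str | Path
) -> tuple[Path, Path]:
    """Write paired FASTQ (R1/R2) in sequencing orientation.

    Observation bases are stored in reference orientation; for OT
    molecules R1 is the stored left segment and R2 the reverse complement
    of the right one, and vice versa for OB molecules.
    """
    prefix = Path(prefix)
    p1, p2 = prefix.with_suffix(".R1.fastq"), prefix.with_suffix(".R2.fastq")
    by_frag: dict[int, dict[int, ReadObservation]] = {}
    for o in observations:
        by_frag.setdefault(o.fragment_id, {})[o.mate] = o
    with open(p1, "w") as f1, open(p2, "w") as f2:
        for frag_id in sorted(by_frag):
            mates = by_frag[frag_id]
            if 1 not in mates or 2 not in mates:
                continue
            r1, r2 = mates[1], mates[2]
            if r1.strand == "OT":
                s1, s2 = r1.bases, revcomp(r2.bases)
            else:
                s1, s2 = revcomp(r2.bases), r1.bases
            name = r1.read_id.split("/")[0]
            f1.write(f"@{name}/1\n{s1}\n+\n{'I' * len(s1)}\n")
            f2.write(f"@{name}/2\n{s2}\n+\n{'I' * len(s2)}\n")
    return p1, p2


# ---------------------------------------------------------------- VCF

_GT_STRINGS = {"hom_ref": (0, 0), "het": (0, 1), "hom_alt": (1, 1)}


def _vcf_header(reference) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for chrom in sorted(reference.keys()):
        header.contigs.add(chrom, length=len(reference[chrom]))
    header.info.add("CONVAMB", 0, "Flag", "Site is conversion-ambiguous")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("GQ", 1, "Integer", "Genotype quality (phred)")
    header.formats.add("DP", 1, "Integer", "Informative read depth")
    header.add_sample("sample")
    return header


def write_vcf(calls: Sequence[GenotypeCall], reference, path) -> None:
    """Write variant calls (non-reference genotypes) as VCF v4.2."""
    header = _vcf_header(reference)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for call in sorted(calls, key=lambda c: (c.chrom, c.pos)):
            if call.genotype == "hom_ref":
                continue
            alts = call.alts
            rec = vcf.new_record(
                contig=call.chrom,
                start=call.pos,
                stop=call.pos + 1,
                alleles=(call.ref,) + alts,
            )
            if call.genotype == "het" and call.ref not in call.alleles:
                rec.samples["sample"]["GT"] = (1, 2) if len(alts) > 1 else (1, 1)
            else:
                rec.samples["sample"]["GT"] = _GT_STRINGS[call.genotype]
            rec.samples["sample"].phased = False
            rec.samples["sample"]["GQ"] = int(round(call.gq))
            rec.samples["sample"]["DP"] = call.depth
            if call.conversion_ambiguous:
                rec.info["CONVAMB"] = True
            vcf.write(rec)


def read_vcf(path) -> list[GenotypeCall]:
    calls = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            gt = rec.samples["sample"]["GT"]
            alleles_all = (rec.ref,) + tuple(rec.alts or ())
            pair = tuple(sorted(alleles_all[i] for i in gt))
            if pair[0] == pair[1]:
                genotype = "hom_ref" if pair[0] == rec.ref else "hom_alt"
            else:
                genotype = "het"
            gq = rec.samples["sample"].get("GQ")
            dp = rec.samples["sample"].get("DP")
            calls.append(
                GenotypeCall(
                    chrom=rec.chrom,
                    pos=rec.start,
                    ref=rec.ref,
                    alleles=pair,
                    gq=float(gq) if gq is not None else 0.0,
                    depth=int(dp) if dp is not None else 0,
                    genotype=genotype,
                    conversion_ambiguous="CONVAMB" in rec.info,
                )
            )
    return calls


def write_truth_vcf(truth: DiploidTruth, path) -> None:
    """Write the simulator's planted variants as a truth VCF."""
    header = _vcf_header(truth.reference)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for v in sorted(truth.variants, key=lambda v: (v.chrom, v.pos)):
            rec = vcf.new_record(
                contig=v.chrom,
                start=v.pos,
                stop=v.pos + 1,
                alleles=(v.ref, v.alt),
            )
            rec.samples["sample"]["GT"] = _GT_STRINGS[
                "het" if v.genotype == "het" else "hom_alt"
            ]
            rec.samples["sample"].phased = False
            vcf.write(rec)
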