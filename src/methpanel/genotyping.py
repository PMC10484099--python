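"""Diploid SNV genotyping from captured-read pileups.

A minimal explicit likelihood model: with per-base error rate e,
P(base | allele) is 1 - e for a match and e/3 otherwise, a heterozygote
emits each allele at 1/2, and the ten unordered diploid genotypes are
scored under a flat prior.  Sites with informative depth below
``min_depth`` (default 30X) are left uncalled rather than called at low
confidence.

Converted (BS/EM) libraries carry a systematic confound: on an
original-top read a T may be a converted unmethylated C, and on an
original-bottom read an A may be a converted C on the other strand.  In
bisulfite-aware mode those read bases (C/T on OT, G/A on OB) are excluded
from the informative set, which removes spurious C>T / G>A calls at
unmethylated cytosines at the cost of coverage at such sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement
from typing import Iterable, Sequence

import numpy as np

from .refutil import chrom_length, encode, fetch
from .simulate import ReadObservation, deduplicated_segments

_BASES = "ACGT"
GENOTYPES = list(combinations_with_replacement(range(4), 2))  # 10 unordered pairs


@dataclass
class PileupColumn:
    chrom: str
    pos: int
    ref: str
    entries: list[tuple[str, str, str]]  # (base, conversion strand, library)

    @property
    def depth(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class GenotypeCall:
    chrom: str
    pos: int
    ref: str
    alleles: tuple[str, str]  # sorted
    genotype: str  # hom_ref | het | hom_alt
    gq: float  # phred-scaled 1 - posterior(best)
    depth: int  # informative depth used
    conversion_ambiguous: bool = False

    @property
    def alts(self) -> tuple[str, ...]:
        return tuple(sorted({a for a in self.alleles if a != self.ref}))


def pileup(
    observations: Iterable[ReadObservation], reference
) -> list[PileupColumn]:
    """One column per covered position, mate overlaps counted once."""
    cols: dict[tuple[str, int], list[tuple[str, str, str]]] = {}
    seqs: dict[str, str] = {}
    for seg in deduplicated_segments(observations):
        if seg.chrom not in seqs:
            seqs[seg.chrom] = fetch(
                reference, seg.chrom, 0, chrom_length(reference, seg.chrom)
            )
        if seg.end > len(seqs[seg.chrom]):
            raise ValueError(f"observation beyond reference bounds: {seg.read_id}")
        for i, base in enumerate(seg.bases):
            cols.setdefault((seg.chrom, seg.start + i), []).append(
                (base, seg.strand, seg.library)
            )
    return [
        PileupColumn(chrom, pos, seqs[chrom][pos], entries)
        for (chrom, pos), entries in sorted(cols.items())
    ]


def _log_emission(error_rate: float) -> np.ndarray:
    """log10 P(base | genotype), shape (4 bases, 10 genotypes)."""
    p_match = 1.0 - error_rate
    p_mis = error_rate / 3.0
    single = np.full((4, 4), p_mis)
    np.fill_diagonal(single, p_match)
    emis = np.empty((4, len(GENOTYPES)))
    for gi, (a1, a2) in enumerate(GENOTYPES):
        emis[:, gi] = 0.5 * (single[:, a1] + single[:, a2])
    return np.log10(emis)


def _informative(base: str, strand: str, bisulfite_aware: bool) -> bool:
    if not bisulfite_aware:
        return base in _BASES
    if base not in _BASES:
        return False
    if strand == "OT" and base in "CT":
        return False
    if strand == "OB" and base in "GA":
        return False
    return True


def _classify(
    chrom: str,
    pos: int,
    ref: str,
    counts: np.ndarray,
    emis: np.ndarray,
    ambiguous: bool,
) -> GenotypeCall:
    ll = counts @ emis
    best = int(np.argmax(ll))
    post = 10.0 ** (ll - ll[best])
    post /= post.sum()
    p_err = max(1.0 - float(post[best]), 1e-10)
    gq = min(99.0, -10.0 * np.log10(p_err))
    a1, a2 = GENOTYPES[best]
    alleles = (_BASES[a1], _BASES[a2])
    if alleles[0] == alleles[1]:
        genotype = "hom_ref" if alleles[0] == ref else "hom_alt"
    else:
        genotype = "het"
    return GenotypeCall(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alleles=alleles,
        genotype=genotype,
        gq=round(gq, 2),
        depth=int(counts.sum()),
        conversion_ambiguous=ambiguous,
    )


def call_genotype(
    column: PileupColumn,
    error_rate: float = 0.001,
    min_depth: int = 30,
    bisulfite_aware: bool = False,
) -> GenotypeCall | None:
    """Genotype one pileup column; None when informative depth < min_depth."""
    if not (0 < error_rate < 0.5):
        raise ValueError("error_rate must lie in (0, 0.5)")
    if column.ref not in _BASES:
        raise ValueError(f"non-ACGT reference base {column.ref!r} at {column.pos}")
    counts = np.zeros(4)
    excluded = 0
    for base, strand, _lib in column.entries:
        if _informative(base, strand, bisulfite_aware):
            counts[_BASES.index(base)] += 1
        else:
            excluded += 1
    if counts.sum() < min_depth:
        return None
    ambiguous = bisulfite_aware and excluded > 0 and counts.sum() == 0
    return _classify(
        column.chrom, column.pos, column.ref, counts, _log_emission(error_rate),
        ambiguous,
    )


def genotype_likelihoods(
    column: PileupColumn, error_rate: float = 0.001, bisulfite_aware: bool = False
) -> np.ndarray:
    """Posterior over the 10 genotypes under a flat prior (sums to 1)."""
    counts = np.zeros(4)
    for base, strand, _lib in column.entries:
        if _informative(base, strand, bisulfite_aware):
            counts[_BASES.index(base)] += 1
    ll = counts @ _log_emission(error_rate)
    post = 10.0 ** (ll - ll.max())
    return post / post.sum()


def call_genotypes(
    observations: Iterable[ReadObservation],
    reference,
    error_rate: float = 0.001,
    min_depth: int = 30,
    bisulfite_aware: bool = False,
) -> tuple[list[GenotypeCall], list[tuple[str, int]]]:
    """Genotype every sufficiently covered position (vectorized).

    Returns (calls, conversion-ambiguous sites) where the second list
    holds positions at which every read was excluded by the
    bisulfite-aware strand rule despite raw coverage >= min_depth.
    """
    if not (0 < error_rate < 0.5):
        raise ValueError("error_rate must lie in (0, 0.5)")
    per_chrom: dict[str, dict[str, np.ndarray]] = {}
    ref_codes: dict[str, np.ndarray] = {}

    for seg in deduplicated_segments(observations):
        chrom = seg.chrom
        if chrom not in per_chrom:
            n = chrom_length(reference, chrom)
            ref_codes[chrom] = encode(fetch(reference, chrom, 0, n))
            per_chrom[chrom] = {
                "ot": np.zeros((4, n), dtype=np.int32),
                "ob": np.zeros((4, n), dtype=np.int32),
            }
        if seg.end > len(ref_codes[chrom]):
            raise ValueError(f"observation beyond reference bounds: {seg.read_id}")
        codes = encode(seg.bases)
        tgt = per_chrom[chrom]["ot" if seg.strand == "OT" else "ob"]
        span = np.arange(seg.start, seg.end)
        for b in range(4):
            sel = codes == b
            if sel.any():
                np.add.at(tgt[b], span[sel], 1)

    emis = _log_emission(error_rate)
    calls: list[GenotypeCall] = []
    ambiguous_sites: list[tuple[str, int]] = []
    for chrom in sorted(per_chrom):
        ot, ob = per_chrom[chrom]["ot"], per_chrom[chrom]["ob"]
        raw = ot + ob
        if bisulfite_aware:
            informative = raw.astype(float).copy()
            informative[1] -= ot[1]  # C on OT
            informative[3] -= ot[3]  # T on OT
            informative[2] -= ob[2]  # G on OB
            informative[0] -= ob[0]  # A on OB
        else:
            informative = raw.astype(float)
        info_depth = informative.sum(axis=0)
        raw_depth = raw.sum(axis=0)
        callable_pos = np.flatnonzero(info_depth >= min_depth)
        if bisulfite_aware:
            amb = np.flatnonzero((raw_depth >= min_depth) & (info_depth == 0))
            ambiguous_sites.extend((chrom, int(p)) for p in amb)
        if len(callable_pos) == 0:
            continue
        N = informative[:, callable_pos].T  # (npos, 4)
        ll = N @ emis
        best = np.argmax(ll, axis=1)
        post = 10.0 ** (ll - ll[np.arange(len(ll)), best][:, None])
        post /= post.sum(axis=1, keepdims=True)
        p_err = np.maximum(1.0 - post[np.arange(len(post)), best], 1e-10)
        gq = np.minimum(99.0, -10.0 * np.log10(p_err))
        rc = ref_codes[chrom]
        for i, p in enumerate(callable_pos):
            refc = int(rc[p])
            if refc > 3:
                continue
            a1, a2 = GENOTYPES[int(best[i])]
            alleles = (_BASES[a1], _BASES[a2])
            if a1 == a2:
                genotype = "hom_ref" if a1 == refc else "hom_alt"
            else:
                genotype = "het"
            calls.append(
                GenotypeCall(
                    chrom=chrom,
                    pos=int(p),
                    ref=_BASES[refc],
                    alleles=alleles,
                    genotype=genotype,
                    gq=round(float(gq[i]), 2),
                    depth=int(info_depth[p]),
                )
            )
    return calls, ambiguous_sites


@dataclass(frozen=True)
class OverlapStats:
    shared: int
    n_a: int
    n_b: int

    @property
    def fraction_a(self) -> float:
        return self.shared / self.n_a if self.n_a else 0.0

    @property
    def fraction_b(self) -> float:
        return self.shared / self.n_b if self.n_b else 0.0


def variant_calls(calls: Iterable[GenotypeCall]) -> list[GenotypeCall]:
    """Calls carrying at least one non-reference allele."""
    return [c for c in calls if c.genotype != "hom_ref"]


def replicate_overlap(
    calls_a: Sequence[GenotypeCall], calls_b: Sequence[GenotypeCall]
) -> OverlapStats:
    """Concordance of variant calls between technical replicates.

    A variant is shared when chromosome, position, alternate alleles and
    zygosity all match.
    """
    def keyset(calls):
        return {
            (c.chrom, c.pos, c.alts, c.genotype) for c in variant_calls(calls)
        }

    ka, kb = keyset(calls_a), keyset(calls_b)
    return OverlapStats(shared=len(ka & kb), n_a=len(ka), n_b=len(kb))
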