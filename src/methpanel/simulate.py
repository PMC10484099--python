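"""Seeded simulator of diploid capture bisulfite/enzymatic sequencing.

The simulator emulates the study system end to end so every analysis stage
can be exercised against known truth: a small reference genome with tunable
GC and CpG density, planted tandem repeats and a diverged paralog
(pseudogene stand-in); a diploid sample with a variant-dense region
(mimicking a highly polymorphic HLA-like locus); bimodal CpG methylation
with plantable differential regions; and probe-weighted capture of ~250 bp
fragments read as a directional paired-end library, with bisulfite (BS) or
enzymatic (EM) C->T conversion chemistry and its failure modes.

Reads carry their true origin (chromosome, start, haplotype, conversion
strand), so downstream modules are tested without an alignment step;
paired FASTQ can still be written for external aligners.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from .intervals import GenomicInterval, MaskTrack
from .panel import PanelDesign
from .refutil import decode, encode

_BASES = "ACGT"

# -----------------------------------------------------------------------
# reference simulation
# -----------------------------------------------------------------------


@dataclass
class RepeatSpec:
    """Plant ``count`` tandem repeats of ``copies`` x ``unit_length`` bases."""

    count: int = 0
    unit_length: int = 25
    copies: int = 8


@dataclass
class ParalogSpec:
    """Copy a segment elsewhere with per-base divergence (pseudogene stand-in)."""

    length: int = 2000
    divergence: float = 0.05
    count: int = 1


@dataclass
class SimulatedReference:
    sequences: dict[str, str]
    gc_target: float
    cpg_rate: float
    repeats: MaskTrack = field(default_factory=lambda: MaskTrack("planted_repeats"))
    paralogs: list[tuple[GenomicInterval, GenomicInterval]] = field(
        default_factory=list
    )

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def keys(self):
        return self.sequences.keys()

    def codes(self, chrom: str) -> np.ndarray:
        return encode(self.sequences[chrom])

    def cpg_positions(self, chrom: str) -> np.ndarray:
        """0-based positions of the + strand C of each reference CpG."""
        c = self.codes(chrom)
        return np.flatnonzero((c[:-1] == 1) & (c[1:] == 2))


def _transition_matrix(gc: float, cpg_rate: float) -> np.ndarray:
    """First-order Markov transitions hitting target GC and CpG density."""
    pi = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    t_cg = cpg_rate / pi[1]
    T = np.tile(pi, (4, 1))
    # row C: fix P(G|C), rescale the rest
    T[1] = pi * (1 - t_cg) / (1 - pi[2])
    T[1, 2] = t_cg
    # rows A,G,T: compensate so that the stationary mass of G is preserved
    g_rest = (pi[2] - pi[1] * t_cg) / (1 - pi[1])
    for b in (0, 2, 3):
        T[b] = pi * (1 - g_rest) / (1 - pi[2])
        T[b, 2] = g_rest
    return T / T.sum(axis=1, keepdims=True)


def _stationary(T: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eig(T.T)
    v = np.real(vecs[:, np.argmin(np.abs(vals - 1))])
    v = np.abs(v)
    return v / v.sum()


def _markov_sequence(T: np.ndarray, length: int, rng: np.random.Generator) -> np.ndarray:
    cum = np.cumsum(T, axis=1)
    u = rng.random(length)
    out = np.empty(length, dtype=np.uint8)
    pi0 = _stationary(T)
    state = int(np.searchsorted(np.cumsum(pi0), u[0]))
    out[0] = state
    row = cum
    for i in range(1, length):
        state = int(np.searchsorted(row[state], u[i]))
        out[i] = state
    return out


def simulate_reference(
    n_chrom: int = 1,
    length: int = 200_000,
    gc_target: float = 0.45,
    cpg_rate: float = 0.02,
    repeat_spec: RepeatSpec | None = None,
    paralog_spec: ParalogSpec | None = None,
    seed: int = 0,
) -> SimulatedReference:
    """Generate a synthetic reference with controlled GC and CpG density.

    ``cpg_rate`` is the expected fraction of dinucleotide starts that are
    CpG.  Raises on infeasible parameter combinations (the implied
    P(G | C) must stay well below 1).
    """
    if length < 1000:
        raise ValueError("length must be >= 1000")
    if not (0 < gc_target < 1) or not (0 <= cpg_rate < 1):
        raise ValueError("gc_target and cpg_rate must be valid rates")
    if cpg_rate / (gc_target / 2) > 0.95 or cpg_rate > 4 * gc_target**2:
        raise ValueError(
            f"infeasible cpg_rate {cpg_rate} for gc_target {gc_target}"
        )
    rng = np.random.default_rng(seed)
    T = _transition_matrix(gc_target, cpg_rate)
    # one corrective rebuild against the chain's realized stationary GC
    gc_obs = float(_stationary(T)[[1, 2]].sum())
    if abs(gc_obs - gc_target) > 0.002:
        T = _transition_matrix(gc_target + (gc_target - gc_obs), cpg_rate)

    sequences: dict[str, str] = {}
    repeat_ivs: list[GenomicInterval] = []
    paralogs: list[tuple[GenomicInterval, GenomicInterval]] = []
    for ci in range(n_chrom):
        chrom = f"chr{ci + 1}"
        codes = _markov_sequence(T, length, rng)
        if repeat_spec is not None and repeat_spec.count > 0:
            rlen = repeat_spec.unit_length * repeat_spec.copies
            taken: list[tuple[int, int]] = []
            for _ in range(repeat_spec.count):
                for _attempt in range(100):
                    s = int(rng.integers(0, length - rlen))
                    if all(s + rlen <= a or s >= b for a, b in taken):
                        break
                else:
                    continue
                unit = rng.integers(0, 4, size=repeat_spec.unit_length)
                codes[s : s + rlen] = np.tile(unit, repeat_spec.copies)
                taken.append((s, s + rlen))
                repeat_ivs.append(GenomicInterval(chrom, s, s + rlen))
        if paralog_spec is not None and paralog_spec.count > 0:
            plen = paralog_spec.length
            for _ in range(paralog_spec.count):
                src = int(rng.integers(0, length // 2 - plen))
                dst = int(rng.integers(length // 2, length - plen))
                copy = codes[src : src + plen].copy()
                mut = rng.random(plen) < paralog_spec.divergence
                copy[mut] = (copy[mut] + rng.integers(1, 4, size=int(mut.sum()))) % 4
                codes[dst : dst + plen] = copy
                paralogs.append(
                    (
                        GenomicInterval(chrom, src, src + plen),
                        GenomicInterval(chrom, dst, dst + plen),
                    )
                )
        sequences[chrom] = decode(codes)
    return SimulatedReference(
        sequences=sequences,
        gc_target=gc_target,
        cpg_rate=cpg_rate,
        repeats=MaskTrack("planted_repeats", repeat_ivs),
        paralogs=paralogs,
    )


# -----------------------------------------------------------------------
# diploid truth
# -----------------------------------------------------------------------

_TRANSITION = {0: 2, 2: 0, 1: 3, 3: 1}  # A<->G, C<->T
_TRANSVERSIONS = {0: (1, 3), 1: (0, 2), 2: (1, 3), 3: (0, 2)}


@dataclass(frozen=True)
class Variant:
    chrom: str
    pos: int
    ref: str
    alt: str
    genotype: str  # "het" or "hom_alt"
    haplotype: int  # carrying haplotype for het variants; -1 for hom_alt


@dataclass
class DiploidTruth:
    """Two haplotypes plus truth variants and per-CpG methylation."""

    reference: SimulatedReference
    haplotypes: dict[str, tuple[str, str]]
    variants: list[Variant]
    cpg_positions: dict[str, np.ndarray] = field(default_factory=dict)
    beta: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    dmr_truth: list[tuple[GenomicInterval, float]] = field(default_factory=list)

    def haplotype_codes(self, chrom: str, hap: int) -> np.ndarray:
        return encode(self.haplotypes[chrom][hap])


def simulate_diploid(
    ref: SimulatedReference,
    snv_rate: float = 1e-3,
    het_fraction: float = 0.8,
    dense_region: GenomicInterval | None = None,
    dense_multiplier: float = 5.0,
    titv_ratio: float = 2.0,
    seed: int = 0,
) -> DiploidTruth:
    """Place SNVs on two haplotypes, denser inside ``dense_region``.

    Per-base substitution probability is ``snv_rate`` (times
    ``dense_multiplier`` inside the dense region); each variant is het
    with probability ``het_fraction`` (assigned to one haplotype) and
    hom-alt otherwise; transitions outnumber transversions ``titv_ratio``:1.
    """
    if snv_rate < 0 or not (0 <= het_fraction <= 1):
        raise ValueError("invalid rates")
    rng = np.random.default_rng(seed)
    haplotypes: dict[str, tuple[str, str]] = {}
    variants: list[Variant] = []
    p_ti = titv_ratio / (titv_ratio + 1.0)
    for chrom, seq in ref.sequences.items():
        codes = encode(seq)
        rate = np.full(len(seq), snv_rate)
        if dense_region is not None and dense_region.chrom == chrom:
            rate[dense_region.start : dense_region.end] *= dense_multiplier
        hit = np.flatnonzero(rng.random(len(seq)) < rate)
        h0, h1 = codes.copy(), codes.copy()
        for pos in hit:
            refc = int(codes[pos])
            if refc > 3:
                continue
            if rng.random() < p_ti:
                altc = _TRANSITION[refc]
            else:
                altc = _TRANSVERSIONS[refc][int(rng.integers(0, 2))]
            if rng.random() < het_fraction:
                hap = int(rng.integers(0, 2))
                (h0 if hap == 0 else h1)[pos] = altc
                gt = "het"
            else:
                h0[pos] = altc
                h1[pos] = altc
                gt = "hom_alt"
                hap = -1
            variants.append(
                Variant(chrom, int(pos), _BASES[refc], _BASES[altc], gt, hap)
            )
        haplotypes[chrom] = (decode(h0), decode(h1))
    return DiploidTruth(reference=ref, haplotypes=haplotypes, variants=variants)


def assign_methylation(
    truth: DiploidTruth,
    mix_weight: float = 0.5,
    low_shape: tuple[float, float] = (1.0, 9.0),
    high_shape: tuple[float, float] = (9.0, 1.0),
    dmr_spec: Sequence[tuple[GenomicInterval, float]] = (),
    dmr_baseline_shape: tuple[float, float] | None = (2.0, 5.0),
    conditions: tuple[str, str] = ("A", "B"),
    seed: int = 0,
) -> DiploidTruth:
    """Draw per-CpG true methylation from a bimodal Beta mixture.

    Each reference CpG gets a beta for condition A (`mix_weight` is the
    probability of the high-methylation component); condition B equals A
    except inside ``dmr_spec`` intervals, where the stated delta is added
    (clipped to [0, 1]) — the plantable truth for differential calling.

    So that a planted delta really is an effect of the stated size,
    baseline betas inside planted intervals are redrawn from
    Beta(*dmr_baseline_shape) oriented away from the saturating boundary
    (hypomethylated baselines for methylation gains, mirroring
    stimulus-responsive promoters, and vice versa); without this, a +0.3
    shift planted on a CpG already at 0.95 would silently shrink to 0.05.
    Pass ``dmr_baseline_shape=None`` to shift the existing betas as-is.
    """
    rng = np.random.default_rng(seed)
    cond_a, cond_b = conditions
    truth.beta = {cond_a: {}, cond_b: {}}
    truth.cpg_positions = {}
    for chrom in truth.reference.sequences:
        pos = truth.reference.cpg_positions(chrom)
        truth.cpg_positions[chrom] = pos
        high = rng.random(len(pos)) < mix_weight
        beta = np.where(
            high,
            rng.beta(*high_shape, size=len(pos)),
            rng.beta(*low_shape, size=len(pos)),
        )
        truth.beta[cond_a][chrom] = beta
        truth.beta[cond_b][chrom] = beta.copy()
    truth.dmr_truth = []
    for interval, delta in dmr_spec:
        pos = truth.cpg_positions.get(interval.chrom)
        if pos is None:
            continue
        mask = (pos >= interval.start) & (pos < interval.end)
        if not mask.any():
            warnings.warn(f"DMR interval {interval} contains no CpGs")
        a = truth.beta[cond_a][interval.chrom]
        if dmr_baseline_shape is not None and mask.any():
            s1, s2 = dmr_baseline_shape
            if delta < 0:
                s1, s2 = s2, s1  # headroom below for losses
            a[mask] = rng.beta(s1, s2, size=int(mask.sum()))
        b = truth.beta[cond_b][interval.chrom]
        b[mask] = np.clip(a[mask] + delta, 0.0, 1.0)
        truth.dmr_truth.append((interval, delta))
    return truth


# -----------------------------------------------------------------------
# conversion chemistry and capture
# -----------------------------------------------------------------------


@dataclass(frozen=True)
class ConversionModel:
    """C->T conversion chemistry with failure modes.

    ``failure_rate``: probability an unmethylated C escapes conversion and
    reads as C (apparent methylation).  ``overconversion_rate``:
    probability a methylated C is converted anyway.
    """

    kind: str = "none"  # none | BS | EM
    failure_rate: float = 0.0
    overconversion_rate: float = 0.0
    directional: bool = True

    def __post_init__(self) -> None:
        if self.kind not in {"none", "BS", "EM"}:
            raise ValueError(f"unknown conversion kind {self.kind!r}")
        for r in (self.failure_rate, self.overconversion_rate):
            if not (0 <= r <= 1):
                raise ValueError("conversion rates must lie in [0, 1]")

    @classmethod
    def none(cls) -> "ConversionModel":
        return cls("none", 0.0, 0.0)

    @classmethod
    def bisulfite(
        cls, failure_rate: float = 0.015, overconversion_rate: float = 0.005
    ) -> "ConversionModel":
        return cls("BS", failure_rate, overconversion_rate)

    @classmethod
    def enzymatic(
        cls, failure_rate: float = 0.006, overconversion_rate: float = 0.005
    ) -> "ConversionModel":
        return cls("EM", failure_rate, overconversion_rate)

    @property
    def library(self) -> str:
        return "DNA" if self.kind == "none" else self.kind


@dataclass
class ReadObservation:
    """One sequenced read with its true origin (alignment-free).

    ``bases`` is stored in reference (top-strand) orientation covering
    [start, end); ``strand`` is the conversion strand of the source
    molecule (OT = original top, OB = original bottom).
    """

    read_id: str
    fragment_id: int
    chrom: str
    start: int
    end: int
    strand: str  # OT | OB
    mate: int  # 1 | 2
    haplotype: int
    library: str  # DNA | BS | EM
    bases: str


def _probe_weight_index(panel: PanelDesign) -> dict[str, tuple]:
    """Per-chrom weighted prefix sums for fragment/probe overlap queries."""
    index: dict[str, tuple] = {}
    by_chrom: dict[str, list] = {}
    for p in panel.probes:
        by_chrom.setdefault(p.interval.chrom, []).append(p)
    for chrom, probes in by_chrom.items():
        starts = np.array([p.interval.start for p in probes])
        ends = np.array([p.interval.end for p in probes])
        copies = np.array([p.copy_number for p in probes], dtype=float)
        so = np.argsort(starts, kind="stable")
        eo = np.argsort(ends, kind="stable")
        index[chrom] = (
            starts[so],
            np.cumsum(copies[so]),
            ends[eo],
            np.cumsum(copies[eo]),
        )
    return index


def _overlap_weight(index, chrom, frag_start, frag_end) -> np.ndarray:
    """Summed copy numbers of probes overlapping each fragment."""
    if chrom not in index:
        return np.zeros(len(frag_start))
    starts, cum_s, ends, cum_e = index[chrom]
    n_started = np.searchsorted(starts, frag_end, side="left")
    n_ended = np.searchsorted(ends, frag_start, side="right")
    total_started = np.where(n_started > 0, cum_s[n_started - 1], 0.0)
    total_ended = np.where(n_ended > 0, cum_e[n_ended - 1], 0.0)
    return total_started - total_ended


def simulate_capture_reads(
    truth: DiploidTruth,
    panel: PanelDesign,
    n_fragments: int = 50_000,
    insert_mean: float = 250.0,
    insert_sd: float = 30.0,
    off_target_rate: float = 0.01,
    conversion: ConversionModel | None = None,
    seq_error: float = 0.001,
    read_len: int = 150,
    capture_coefficient: float = 0.1,
    condition: str = "A",
    seed: int = 0,
) -> list[ReadObservation]:
    """Draw captured paired-end fragments and apply conversion chemistry.

    Fragment starts are uniform over the genome, insert sizes
    ~Normal(insert_mean, insert_sd) truncated to [read_len, 2*insert_mean].
    A fragment is retained with probability
    min(1, capture_coefficient * sum of copy numbers of overlapping probes),
    so probe boosting is observable in coverage; off-target fragments are
    admitted at ``off_target_rate``.  Each fragment comes from one uniformly
    chosen haplotype and one conversion strand (OT/OB, directional
    protocol); per-molecule CpG methylation is Bernoulli(true beta);
    conversion and i.i.d. sequencing errors are then applied.
    """
    if conversion is None:
        conversion = ConversionModel.none()
    if not panel.probes:
        raise ValueError("panel has no probes")
    if n_fragments < 1:
        raise ValueError("n_fragments must be >= 1")
    rng = np.random.default_rng(seed)
    ref = truth.reference
    chroms = list(ref.sequences)
    lengths = np.array([len(ref.sequences[c]) for c in chroms])
    index = _probe_weight_index(panel)

    # propose fragments
    chrom_idx = rng.choice(len(chroms), size=n_fragments, p=lengths / lengths.sum())
    frag_len = np.clip(
        np.round(rng.normal(insert_mean, insert_sd, size=n_fragments)),
        read_len,
        2 * insert_mean,
    ).astype(int)
    starts = np.empty(n_fragments, dtype=int)
    for ci in range(len(chroms)):
        m = chrom_idx == ci
        hi = np.maximum(1, lengths[ci] - frag_len[m])
        starts[m] = (rng.random(int(m.sum())) * hi).astype(int)
    ends = starts + frag_len

    # capture retention
    retain = np.zeros(n_fragments, dtype=bool)
    for ci, chrom in enumerate(chroms):
        m = chrom_idx == ci
        w = _overlap_weight(index, chrom, starts[m], ends[m])
        p = np.where(
            w > 0, np.minimum(1.0, capture_coefficient * w), off_target_rate
        )
        retain[m] = rng.random(int(m.sum())) < p
    keep = np.flatnonzero(retain)
    if len(keep) == 0:
        raise RuntimeError(
            "no fragments were retained by capture; increase n_fragments"
        )

    haps = rng.integers(0, 2, size=len(keep))
    ot = rng.random(len(keep)) < 0.5

    # per-chromosome haplotype code arrays and methylation lookups
    hap_codes = {
        c: (truth.haplotype_codes(c, 0), truth.haplotype_codes(c, 1)) for c in chroms
    }
    beta_full: dict[str, np.ndarray] = {}
    for c in chroms:
        arr = np.zeros(lengths[chroms.index(c)])
        if truth.beta and condition in truth.beta:
            pos = truth.cpg_positions[c]
            arr[pos] = truth.beta[condition][c]
        beta_full[c] = arr

    observations: list[ReadObservation] = []
    lib = conversion.library
    for fi, k in enumerate(keep):
        chrom = chroms[chrom_idx[k]]
        s, e = int(starts[k]), int(ends[k])
        hap = int(haps[fi])
        strand = "OT" if ot[fi] else "OB"
        hcodes = hap_codes[chrom][hap]
        frag = hcodes[s:e].copy()
        if conversion.kind != "none":
            if strand == "OT":
                cpos = np.flatnonzero(frag == 1)
                if len(cpos):
                    abspos = cpos + s
                    is_cpg = np.zeros(len(cpos), dtype=bool)
                    inb = abspos + 1 < len(hcodes)
                    is_cpg[inb] = hcodes[abspos[inb] + 1] == 2
                    beta = np.where(is_cpg, beta_full[chrom][abspos], 0.0)
                    meth = rng.random(len(cpos)) < beta
                    u = rng.random(len(cpos))
                    convert = np.where(
                        meth,
                        u < conversion.overconversion_rate,
                        u < 1.0 - conversion.failure_rate,
                    )
                    frag[cpos[convert]] = 3  # C -> T
            else:
                gpos = np.flatnonzero(frag == 2)
                if len(gpos):
                    abspos = gpos + s
                    is_cpg = np.zeros(len(gpos), dtype=bool)
                    inb = abspos - 1 >= 0
                    is_cpg[inb] = hcodes[abspos[inb] - 1] == 1
                    beta = np.where(
                        is_cpg, beta_full[chrom][np.maximum(abspos - 1, 0)], 0.0
                    )
                    meth = rng.random(len(gpos)) < beta
                    u = rng.random(len(gpos))
                    convert = np.where(
                        meth,
                        u < conversion.overconversion_rate,
                        u < 1.0 - conversion.failure_rate,
                    )
                    frag[gpos[convert]] = 0  # G -> A (bottom-strand C -> T)
        if seq_error > 0:
            err = np.flatnonzero(rng.random(len(frag)) < seq_error)
            if len(err):
                frag[err] = (frag[err] + rng.integers(1, 4, size=len(err))) % 4
        flen = e - s
        r1 = (s, s + min(read_len, flen))
        r2 = (max(s, e - read_len), e)
        for mate, (rs, re_) in ((1, r1), (2, r2)):
            observations.append(
                ReadObservation(
                    read_id=f"frag{int(k):08d}/{mate}",
                    fragment_id=int(k),
                    chrom=chrom,
                    start=rs,
                    end=re_,
                    strand=strand,
                    mate=mate,
                    haplotype=hap,
                    library=lib,
                    bases=decode(frag[rs - s : re_ - s]),
                )
            )
    return observations


def deduplicated_segments(
    observations: Iterable[ReadObservation],
) -> Iterator[ReadObservation]:
    """Yield mate-overlap-deduplicated segments, one molecule per base.

    Mate 1 is kept whole; mate 2 is clipped to the part not already
    covered by mate 1 of the same fragment (and dropped if fully
    redundant), so each fragment contributes each position exactly once.
    """
    r1_end: dict[int, int] = {}
    pending: list[ReadObservation] = []
    for obs in observations:
        if obs.mate == 1:
            r1_end[obs.fragment_id] = obs.end
            yield obs
        else:
            pending.append(obs)
    for obs in pending:
        clip = r1_end.get(obs.fragment_id, obs.start)
        new_start = max(obs.start, clip)
        if new_start >= obs.end:
            continue
        if new_start == obs.start:
            yield obs
        else:
            off = new_start - obs.start
            yield ReadObservation(
                read_id=obs.read_id,
                fragment_id=obs.fragment_id,
                chrom=obs.chrom,
                start=new_start,
                end=obs.end,
                strand=obs.strand,
                mate=obs.mate,
                haplotype=obs.haplotype,
                library=obs.library,
                bases=obs.bases[off:],
            )
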