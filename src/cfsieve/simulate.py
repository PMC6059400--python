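"""Synthetic ccfDNA sequencing experiments.

This module generates every input the analysis consumes: a small capture-panel
reference, cell-free DNA fragments whose insert sizes follow the nucleosomal
mixture seen in plasma (mononucleosome peak near 167 bp plus a dinucleosome
component, with tumor-derived fragments shifted shorter), UMI-tagged PCR
duplicated paired-end reads, spike-in dilution series with fixed-length
constructs, and droplet digital PCR partitioning experiments.

Reads are emitted pre-aligned at their true coordinates: alignment is not part
of the analysis under study, and removing it keeps the simulation exact (every
read maps back to exactly one template molecule).

The PCR model has three error channels:

* first-copy errors - introduced by the first synthesis off the original
  molecule (adapter fill-in / first extension) and therefore shared by *all*
  duplicates of that molecule.  Single-strand UMI consensus cannot remove
  these; they are the reason duplex barcoding exists.
* per-cycle tree errors - each amplification cycle copies every molecule once;
  an error on a copy propagates to that copy's descendants only.  Early-cycle
  errors reach roughly half of a family, late errors very few.
* sequencing errors - independent per emitted read.

Family sizes are emergent: sequencer reads are sampled multinomially across
molecules with per-molecule lognormal amplification weights, which reproduces
the overdispersed duplicate spectra of real capture libraries (both singleton
families and families of twenty-plus duplicates at moderate mean duplication).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .ddpcr import DropletCounts

_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")
_BASES = b"ACGT"
# ASCII code -> 0..3 index, 255 for anything else
_BASE_INDEX = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _BASE_INDEX[_b] = _i


class ConfigError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT_STR)[::-1]


_COMPLEMENT_STR = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated ccfDNA library.

    Insert-size defaults follow the fragmentomics of plasma DNA: wild-type
    inserts from a mononucleosome Gaussian (166.9 +- 2.5 bp) mixed with a
    dinucleosome component (334 +- 10 bp), variant-bearing inserts from a
    shorter, wider Gaussian (151.8 +- 12.8 bp).  Reads are 2x125 bp with an
    8-base UMI.
    """

    seed: int = 0
    panel_size_bp: int = 128_000
    n_targets: int = 8
    target_gap_bp: int = 2_000
    flank_bp: int = 2_000
    n_unique_molecules: int = 50_000
    total_reads: int = 500_000
    tumor_fraction: float = 0.05
    wt_mono_mean_bp: float = 166.9
    wt_mono_sd_bp: float = 2.5
    variant_mean_bp: float = 151.8
    variant_sd_bp: float = 12.8
    dinucleosome_weight: float = 0.15
    dinucleosome_mean_bp: float = 334.0
    dinucleosome_sd_bp: float = 10.0
    min_fragment_bp: int = 50
    umi_length: int = 8
    read_length_bp: int = 125
    pcr_error_rate: float = 0.0
    pcr_cycles: int = 6
    seq_error_rate: float = 0.0
    on_target_fraction: float = 0.97
    amplification_sigma: float = 1.0
    base_quality: int = 30

    def __post_init__(self) -> None:
        for name in ("tumor_fraction", "dinucleosome_weight", "on_target_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} must lie in [0, 1]")
        for name in (
            "panel_size_bp", "n_targets", "n_unique_molecules", "total_reads",
            "umi_length", "read_length_bp", "min_fragment_bp",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("wt_mono_mean_bp", "wt_mono_sd_bp", "variant_mean_bp",
                     "variant_sd_bp", "dinucleosome_mean_bp", "dinucleosome_sd_bp"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("pcr_error_rate", "seq_error_rate"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.pcr_cycles < 0:
            raise ConfigError("pcr_cycles must be >= 0")
        if self.amplification_sigma < 0:
            raise ConfigError("amplification_sigma must be >= 0")

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic stream for one simulation stage."""
        return np.random.default_rng([int(self.seed) & 0x7FFFFFFF, int(stream)])


@dataclass(frozen=True)
class VariantLocus:
    chrom: str
    position: int  # 0-based
    ref: str
    alt: str


@dataclass
class Reference:
    """A single-contig panel reference with target intervals and assay loci."""

    chrom: str
    sequence: str
    intervals: list[tuple[int, int]]  # 0-based half-open, the capture panel
    variant_loci: list[VariantLocus]

    @property
    def variant_locus(self) -> VariantLocus:
        return self.variant_loci[0]

    def __len__(self) -> int:
        return len(self.sequence)

    def panel_length(self) -> int:
        return sum(e - s for s, e in self.intervals)

    def write_fasta(self, path) -> None:
        from Bio.Seq import Seq
        from Bio.SeqIO import write as seqio_write
        from Bio.SeqRecord import SeqRecord

        rec = SeqRecord(Seq(self.sequence), id=self.chrom, description="")
        seqio_write([rec], str(path), "fasta")

    def write_bed(self, path) -> None:
        with open(path, "w") as fh:
            for i, (s, e) in enumerate(self.intervals):
                fh.write(f"{self.chrom}\t{s}\t{e}\ttarget_{i + 1}\n")


@dataclass
class FragmentRecord:
    """One simulated ccfDNA molecule before amplification."""

    fragment_id: int
    chrom: str
    start: int  # 0-based
    insert_length_bp: int
    allele_class: str  # WT | VARIANT | OFF_TARGET
    umi: str
    template_sequence: str

    @property
    def end(self) -> int:
        return self.start + self.insert_length_bp


@dataclass(frozen=True)
class DropletExperiment:
    n_droplets: int
    input_copies_wt: int
    input_copies_variant: int
    false_positive_lambda: float = 0.0

    def __post_init__(self) -> None:
        if self.n_droplets <= 0:
            raise ConfigError("n_droplets must be positive")
        if self.input_copies_wt < 0 or self.input_copies_variant < 0:
            raise ConfigError("input copy numbers must be >= 0")
        if self.false_positive_lambda < 0:
            raise ConfigError("false_positive_lambda must be >= 0")


@dataclass
class SimRead:
    """A simulated, pre-aligned read (one mate of a pair)."""

    name: str
    chrom: str
    start: int  # 0-based leftmost aligned position
    strand: str  # '+' or '-'
    seq: str
    base_quality: int
    umi: str
    tlen: int  # signed template length, SAM convention
    fragment_id: int
    is_read1: bool

    @property
    def insert_size(self) -> int:
        return abs(self.tlen)


# ---------------------------------------------------------------------------
# reference

def make_reference(config: SimConfig) -> Reference:
    """Build a random panel reference.

    The contig is laid out as flank / target / gap / target ... / flank so that
    off-target reads have somewhere to land.  Each target interval carries one
    designated assay locus at its midpoint with a recorded WT and alternative
    base.
    """
    if config.panel_size_bp < 1000:
        raise ConfigError("panel_size_bp must be >= 1000")
    lengths = [config.panel_size_bp // config.n_targets] * config.n_targets
    lengths[-1] += config.panel_size_bp % config.n_targets
    if min(lengths) < config.read_length_bp:
        raise ConfigError(
            "panel targets are too small to host read-length windows: "
            f"min target {min(lengths)} bp < read length {config.read_length_bp} bp"
        )
    rng = config.rng(0)
    intervals = []
    pos = config.flank_bp
    for L in lengths:
        intervals.append((pos, pos + L))
        pos += L + config.target_gap_bp
    total = pos - config.target_gap_bp + config.flank_bp
    seq_codes = rng.integers(0, 4, total)
    sequence = bytes(np.frombuffer(_BASES, np.uint8)[seq_codes]).decode()
    chrom = "panel1"
    loci = []
    for s, e in intervals:
        p = (s + e) // 2
        ref_base = sequence[p]
        alt_base = "ACGT"[("ACGT".index(ref_base) + 1) % 4]
        loci.append(VariantLocus(chrom, p, ref_base, alt_base))
    return Reference(chrom, sequence, intervals, loci)


# ---------------------------------------------------------------------------
# fragments

def _sample_lengths(rng: np.random.Generator, n: int, config: SimConfig,
                    variant: bool) -> np.ndarray:
    if variant:
        x = rng.normal(config.variant_mean_bp, config.variant_sd_bp, n)
    else:
        di = rng.random(n) < config.dinucleosome_weight
        x = rng.normal(config.wt_mono_mean_bp, config.wt_mono_sd_bp, n)
        if di.any():
            x[di] = rng.normal(config.dinucleosome_mean_bp,
                               config.dinucleosome_sd_bp, int(di.sum()))
    x = np.rint(x).astype(int)
    # truncate at the configured floor by resampling
    while True:
        bad = x < config.min_fragment_bp
        if not bad.any():
            return x
        m = int(bad.sum())
        if variant:
            x[bad] = np.rint(rng.normal(config.variant_mean_bp,
                                        config.variant_sd_bp, m)).astype(int)
        else:
            x[bad] = np.rint(rng.normal(config.wt_mono_mean_bp,
                                        config.wt_mono_sd_bp, m)).astype(int)


def draw_umis(rng: np.random.Generator, n: int, umi_length: int) -> list[str]:
    """Random UMIs; collision-free while the tag space allows it."""
    space = 4 ** umi_length
    if n <= space and space <= 2 ** 24:
        codes = rng.choice(space, size=n, replace=False)
    else:
        codes = rng.integers(0, space, size=n)
    out = []
    for c in codes:
        c = int(c)
        out.append("".join(_BASES[(c >> (2 * k)) & 3: ((c >> (2 * k)) & 3) + 1].decode()
                           for k in range(umi_length)))
    return out


def simulate_fragments(config: SimConfig, reference: Reference, n: int,
                       locus: VariantLocus | None = None,
                       rng: np.random.Generator | None = None,
                       id_offset: int = 0) -> list[FragmentRecord]:
    """Simulate an assay-locus cohort of ccfDNA molecules.

    Every fragment fully contains the 11-bp assay window centred on ``locus``,
    so each molecule is classifiable downstream.  The number of VARIANT
    molecules is exactly ``round(tumor_fraction * n)``; which molecules carry
    the variant is randomised.
    """
    if n <= 0:
        raise ConfigError("n must be positive")
    locus = locus or reference.variant_locus
    rng = rng if rng is not None else config.rng(1)
    n_var = int(round(config.tumor_fraction * n))
    is_var = np.zeros(n, dtype=bool)
    is_var[rng.permutation(n)[:n_var]] = True

    lengths = np.empty(n, dtype=int)
    if n_var:
        lengths[is_var] = _sample_lengths(rng, n_var, config, variant=True)
    if n - n_var:
        lengths[~is_var] = _sample_lengths(rng, n - n_var, config, variant=False)

    w0, w1 = locus.position - 5, locus.position + 6  # 11-bp window
    lo = np.maximum(w1 - lengths, 0)
    hi = np.minimum(w0, len(reference) - lengths)
    starts = lo + (rng.random(n) * (hi - lo + 1)).astype(int)
    umis = draw_umis(rng, n, config.umi_length)

    frags = []
    for i in range(n):
        s, L = int(starts[i]), int(lengths[i])
        template = reference.sequence[s:s + L]
        cls = "WT"
        if is_var[i]:
            cls = "VARIANT"
            off = locus.position - s
            template = template[:off] + locus.alt + template[off + 1:]
        frags.append(FragmentRecord(id_offset + i, reference.chrom, s, L,
                                    cls, umis[i], template))
    return frags


def simulate_background_fragments(config: SimConfig, reference: Reference, n: int,
                                  rng: np.random.Generator | None = None,
                                  id_offset: int = 0) -> list[FragmentRecord]:
    """Panel-wide wild-type molecules plus an off-target component.

    ``round(n * on_target_fraction)`` molecules start inside randomly chosen
    panel targets; the remainder land in the flank/gap regions and are tagged
    OFF_TARGET.  All carry the reference sequence.
    """
    if n <= 0:
        raise ConfigError("n must be positive")
    rng = rng if rng is not None else config.rng(2)
    n_on = int(round(n * config.on_target_fraction))
    lengths = _sample_lengths(rng, n, config, variant=False)
    umis = draw_umis(rng, n, config.umi_length)

    iv = reference.intervals
    iv_len = np.array([e - s for s, e in iv], dtype=float)
    pick = rng.choice(len(iv), size=n_on, p=iv_len / iv_len.sum())
    # complement regions (flanks and gaps) for off-target placement
    comp = []
    prev = 0
    for s, e in iv:
        if s > prev:
            comp.append((prev, s))
        prev = e
    if prev < len(reference):
        comp.append((prev, len(reference)))
    comp_len = np.array([e - s for s, e in comp], dtype=float)
    pick_off = rng.choice(len(comp), size=n - n_on, p=comp_len / comp_len.sum())

    frags = []
    for i in range(n):
        L = int(lengths[i])
        if i < n_on:
            s0, e0 = iv[pick[i]]
            cls = "WT"
        else:
            s0, e0 = comp[pick_off[i - n_on]]
            cls = "OFF_TARGET"
        hi = max(s0, min(e0 - L, len(reference) - L))
        start = int(s0 + rng.random() * (hi - s0 + 1))
        frags.append(FragmentRecord(id_offset + i, reference.chrom, start, L,
                                    cls, umis[i], reference.sequence[start:start + L]))
    return frags


# ---------------------------------------------------------------------------
# spike-in dilution series

@dataclass
class SpikeSeriesStep:
    step: int  # 1-based dilution step
    target_vaf: float  # fraction, per spike locus
    fragments: list[FragmentRecord]
    spike_counts: dict[str, int]  # locus name -> spike molecules


def simulate_spike_series(config: SimConfig, reference: Reference,
                          lengths: tuple[int, ...] = (130, 165),
                          dilution_steps: int = 8,
                          start_vaf: float = 0.128,
                          dilution_factor: float = 2.0,
                          n_per_locus: int = 4000,
                          rng: np.random.Generator | None = None) -> list[SpikeSeriesStep]:
    """Serial dilution of fixed-length synthetic variant constructs.

    Each step holds ``n_per_locus`` molecules per spike locus; the spike
    molecules have exactly the requested construct length and the VAF halves
    (``dilution_factor``) per step from ``start_vaf``.
    """
    if dilution_steps < 1:
        raise ConfigError("dilution_steps must be >= 1")
    if start_vaf <= 0:
        raise ConfigError("start_vaf must be > 0")
    if dilution_factor <= 0:
        raise ConfigError("dilution_factor must be > 0")
    if len(lengths) > len(reference.variant_loci):
        raise ConfigError("not enough assay loci on the reference for the spikes")
    rng = rng if rng is not None else config.rng(3)
    steps = []
    fid = 0
    for step in range(1, dilution_steps + 1):
        vaf = start_vaf / dilution_factor ** (step - 1)
        frags: list[FragmentRecord] = []
        counts: dict[str, int] = {}
        for spike_idx, L in enumerate(lengths):
            locus = reference.variant_loci[spike_idx]
            n_spike = int(round(vaf * n_per_locus))
            counts[f"spike_{L}bp"] = n_spike
            # background WT molecules at the locus
            bg_cfg = config.replace(tumor_fraction=0.0)
            bg = simulate_fragments(bg_cfg, reference, n_per_locus - n_spike,
                                    locus=locus, rng=rng, id_offset=fid)
            fid += len(bg)
            frags.extend(bg)
            w0, w1 = locus.position - 5, locus.position + 6
            for _ in range(n_spike):
                lo = max(w1 - L, 0)
                hi = min(w0, len(reference) - L)
                s = int(lo + rng.random() * (hi - lo + 1))
                template = reference.sequence[s:s + L]
                off = locus.position - s
                template = template[:off] + locus.alt + template[off + 1:]
                umi = draw_umis(rng, 1, config.umi_length)[0]
                frags.append(FragmentRecord(fid, reference.chrom, s, L,
                                            "VARIANT", umi, template))
                fid += 1
        steps.append(SpikeSeriesStep(step, vaf, frags, counts))
    return steps


# ---------------------------------------------------------------------------
# amplification and sequencing

def _mutate(arr: np.ndarray, positions: np.ndarray, draws: np.ndarray) -> None:
    """Substitute bases in-place; ``draws`` in 1..3 select a different base."""
    idx = _BASE_INDEX[arr[positions]]
    arr[positions] = np.frombuffer(_BASES, np.uint8)[(idx + draws) % 4]


def amplify_and_sequence(fragments: list[FragmentRecord], config: SimConfig,
                         rng: np.random.Generator | None = None) -> list[SimRead]:
    """PCR-amplify molecules and emit paired-end reads.

    With ``pcr_cycles == 0`` the library is amplification-free: each molecule
    is sequenced exactly once (``total_reads`` is ignored).  Otherwise
    ``total_reads`` read pairs are sampled multinomially across molecules with
    lognormal amplification weights, so family sizes are emergent.
    """
    if not fragments:
        return []
    rng = rng if rng is not None else config.rng(4)
    n = len(fragments)
    rl = config.read_length_bp

    if config.pcr_cycles == 0:
        counts = np.ones(n, dtype=int)
    else:
        if config.amplification_sigma > 0:
            w = rng.lognormal(-config.amplification_sigma ** 2 / 2,
                              config.amplification_sigma, n)
        else:
            w = np.ones(n)
        counts = rng.multinomial(config.total_reads, w / w.sum())

    p_pcr = config.pcr_error_rate
    p_seq = config.seq_error_rate
    cycles = config.pcr_cycles
    reads: list[SimRead] = []
    for i, frag in enumerate(fragments):
        c = int(counts[i])
        if c == 0:
            continue
        L = frag.insert_length_bp
        template = np.frombuffer(frag.template_sequence.encode(), np.uint8).copy()
        if p_pcr > 0:
            k = rng.binomial(L, p_pcr)  # first-copy errors, shared family-wide
            if k:
                pos = rng.choice(L, size=k, replace=False)
                _mutate(template, pos, rng.integers(1, 4, k))
        if p_pcr > 0 and cycles > 0:
            leaves = rng.integers(0, 2 ** cycles, size=c)
            node_errors: dict[tuple[int, int], list[tuple[int, int]]] = {}
        rl1 = min(rl, L)
        for j in range(c):
            full = template
            if p_pcr > 0 and cycles > 0:
                leaf = int(leaves[j])
                errs: list[tuple[int, int]] = []
                for d in range(1, cycles + 1):
                    if not (leaf >> (cycles - d)) & 1:
                        continue  # this cycle reused the parent strand
                    key = (d, leaf >> (cycles - d))
                    if key not in node_errors:
                        k = rng.binomial(L, p_pcr)
                        node_errors[key] = (
                            [(int(p), int(o)) for p, o in
                             zip(rng.choice(L, size=k, replace=False),
                                 rng.integers(1, 4, k))] if k else [])
                    errs.extend(node_errors[key])
                if errs:
                    full = template.copy()
                    pos = np.array([p for p, _ in errs])
                    _mutate(full, pos, np.array([o for _, o in errs]))
            r1 = full[:rl1].copy()
            r2 = full[L - rl1:].copy()
            if p_seq > 0:
                k1 = rng.binomial(rl1, p_seq)
                if k1:
                    _mutate(r1, rng.choice(rl1, size=k1, replace=False),
                            rng.integers(1, 4, k1))
                k2 = rng.binomial(rl1, p_seq)
                if k2:
                    _mutate(r2, rng.choice(rl1, size=k2, replace=False),
                            rng.integers(1, 4, k2))
            name = f"f{frag.fragment_id}:{j}"
            reads.append(SimRead(name, frag.chrom, frag.start, "+",
                                 bytes(r1).decode(), config.base_quality,
                                 frag.umi, L, frag.fragment_id, True))
            # aligned representation: SEQ on the forward genome strand
            reads.append(SimRead(name, frag.chrom, frag.start + L - rl1, "-",
                                 bytes(r2).decode(), config.base_quality,
                                 frag.umi, -L, frag.fragment_id, False))
    return reads


# ---------------------------------------------------------------------------
# ddPCR droplets

def simulate_droplets(exp: DropletExperiment, seed: int | np.random.Generator = 0
                      ) -> DropletCounts:
    """Partition input copies into droplets uniformly at random.

    Droplet occupancy is Poisson in the large-droplet-count limit.  False
    positive droplets (Poisson with mean ``false_positive_lambda``) are added
    to the variant channel among variant-negative droplets.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = exp.n_droplets
    wt_mask = np.zeros(n, dtype=bool)
    var_mask = np.zeros(n, dtype=bool)
    if exp.input_copies_wt:
        wt_mask[rng.integers(0, n, size=exp.input_copies_wt)] = True
    if exp.input_copies_variant:
        var_mask[rng.integers(0, n, size=exp.input_copies_variant)] = True
    n_fp = int(rng.poisson(exp.false_positive_lambda))
    if n_fp:
        candidates = np.flatnonzero(~var_mask)
        if len(candidates):
            flip = rng.choice(candidates, size=min(n_fp, len(candidates)),
                              replace=False)
            var_mask[flip] = True
    double = int((wt_mask & var_mask).sum())
    wt_only = int((wt_mask & ~var_mask).sum())
    var_only = int((var_mask & ~wt_mask).sum())
    return DropletCounts(
        n_total=n,
        n_wt_pos=wt_only,
        n_var_pos=var_only,
        n_double_pos=double,
        n_empty=n - wt_only - var_only - double,
    )


# ---------------------------------------------------------------------------
# I/O

def write_sam(reads: list[SimRead], reference: Reference, path) -> None:
    """Write coordinate-sorted SAM with the UMI in the RX tag."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": reference.chrom, "LN": len(reference)}],
    }
    ordered = sorted(reads, key=lambda r: (r.chrom, r.start, r.name, not r.is_read1))
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in ordered:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.name
            a.query_sequence = r.seq
            flag = 0x1 | 0x2
            flag |= 0x40 if r.is_read1 else 0x80
            # FR pair: the mate is always on the opposite strand
            flag |= 0x10 if r.strand == "-" else 0x20
            a.flag = flag
            a.reference_id = 0
            a.reference_start = r.start
            a.mapping_quality = 60
            a.cigartuples = [(0, len(r.seq))]
            a.next_reference_id = 0
            if r.strand == "+":
                mate_start = r.start + abs(r.tlen) - len(r.seq)
            else:
                mate_start = r.start + len(r.seq) - abs(r.tlen)
            a.next_reference_start = max(0, mate_start)
            a.template_length = r.tlen
            a.query_qualities = pysam.qualitystring_to_array(
                chr(r.base_quality + 33) * len(r.seq))
            a.set_tag("RX", r.umi)
            out.write(a)


def write_fastq(reads: list[SimRead], path_r1, path_r2) -> None:
    with open(path_r1, "w") as f1, open(path_r2, "w") as f2:
        for r in sorted(reads, key=lambda r: (r.name, not r.is_read1)):
            fh = f1 if r.is_read1 else f2
            seq = r.seq if r.strand == "+" else revcomp(r.seq)
            fh.write(f"@{r.name} RX:Z:{r.umi}\n{seq}\n+\n"
                     f"{chr(r.base_quality + 33) * len(seq)}\n")


def fragments_to_tsv(fragments: list[FragmentRecord], path) -> None:
    import pandas as pd

    pd.DataFrame([dataclasses.asdict(f) for f in fragments]).to_csv(
        path, sep="\t", index=False)


def fragments_from_tsv(path) -> list[FragmentRecord]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"umi": str, "template_sequence": str})
    return [FragmentRecord(int(r.fragment_id), str(r.chrom), int(r.start),
                           int(r.insert_length_bp), str(r.allele_class),
                           str(r.umi), str(r.template_sequence))
            for r in df.itertuples()]
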