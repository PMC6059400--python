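"""UMI family grouping and consensus calling.

Aligned reads are grouped into families of PCR duplicates: reads sharing a
strand-aware unclipped alignment start are clustered on UMI similarity
(strictly greater than 0.875 on 8-base tags, i.e. identical tags), and each
family is collapsed to one error-corrected consensus read.  Per column, bases
with quality >= Q20 are counted; if the predominant base exceeds 0.66
concordance it is called, otherwise the column becomes N.  Both thresholds are
compared as exact rationals so that boundary family sizes (7/8 similarity,
2-of-3 concordance) behave exactly as specified.

Grouping detail: within one position key, distinct UMIs are seeded in order of
descending read abundance (ties broken lexicographically) and each UMI joins
the first existing family whose representative tag it exceeds the similarity
threshold against, otherwise founds a new family.
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_REF_CONSUMING = set("MDN=X")
_BASES = b"ACGT"
_BASE_INDEX = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _BASE_INDEX[_b] = _i


def _as_fraction(x) -> Fraction:
    """Exact threshold: floats are taken at their printed decimal value."""
    if isinstance(x, Fraction):
        return x
    if isinstance(x, float):
        return Fraction(str(x))
    return Fraction(x)


@dataclass
class AlignedRead:
    """Normalized view of one aligned read (simulated or from SAM)."""

    name: str
    chrom: str
    start: int                  # 0-based leftmost reference position
    strand: str                 # '+' or '-'
    cigar: str
    seq: str
    qualities: "int | np.ndarray"  # scalar Phred or per-base array
    umi: str | None
    tlen: int
    mapq: int = 60
    is_mapped: bool = True

    @classmethod
    def from_sim(cls, read) -> "AlignedRead":
        return cls(read.name, read.chrom, read.start, read.strand,
                   f"{len(read.seq)}M", read.seq, read.base_quality,
                   read.umi, read.tlen)

    @classmethod
    def from_pysam(cls, aln) -> "AlignedRead":
        umi = aln.get_tag("RX") if aln.has_tag("RX") else None
        quals = (np.array(aln.query_qualities, dtype=np.int16)
                 if aln.query_qualities is not None else 0)
        return cls(aln.query_name, aln.reference_name or "*",
                   aln.reference_start if aln.reference_start is not None else -1,
                   "-" if aln.is_reverse else "+",
                   aln.cigarstring or "", aln.query_sequence or "",
                   quals, umi, aln.template_length or 0,
                   aln.mapping_quality, not aln.is_unmapped)

    def qual_array(self) -> np.ndarray:
        if isinstance(self.qualities, np.ndarray):
            return self.qualities
        return np.full(len(self.seq), int(self.qualities), dtype=np.int16)

    @property
    def insert_size(self) -> int:
        return abs(self.tlen)


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    return [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]


def reference_span(cigar: str) -> int:
    return sum(n for n, op in parse_cigar(cigar) if op in _REF_CONSUMING)


def has_indel(cigar: str) -> bool:
    return any(op in "ID" for _, op in parse_cigar(cigar))


def unclipped_start(read: AlignedRead) -> int:
    """Strand-aware unclipped position key (0-based).

    Forward reads are keyed by the alignment start pushed left past leading
    soft/hard clips; reverse reads by the alignment end (exclusive) pushed
    right past trailing clips, so duplicates agree on the key regardless of
    clipping.
    """
    if not read.is_mapped:
        raise ValueError("unmapped reads carry no position key")
    ops = parse_cigar(read.cigar)
    if read.strand == "+":
        lead = 0
        for n, op in ops:
            if op in "SH":
                lead += n
            else:
                break
        return read.start - lead
    trail = 0
    for n, op in reversed(ops):
        if op in "SH":
            trail += n
        else:
            break
    return read.start + reference_span(read.cigar) + trail


def umi_similarity(u1: str, u2: str) -> Fraction:
    """Fraction of matching positions between two equal-length tags."""
    if len(u1) != len(u2):
        raise ValueError("UMIs must have equal length")
    if len(u1) == 0:
        raise ValueError("UMIs must be non-empty")
    matches = sum(a == b for a, b in zip(u1, u2))
    return Fraction(matches, len(u1))


@dataclass
class ReadFamily:
    family_id: int
    chrom: str
    strand: str
    position: int               # strand-aware unclipped start key
    umi: str                    # representative (most abundant) tag
    reads: list[AlignedRead]

    @property
    def family_size(self) -> int:
        return len(self.reads)


def group_families(reads, similarity_threshold=0.875,
                   ) -> tuple[list[ReadFamily], Counter]:
    """Partition reads into UMI families.

    Returns the families plus a counter of excluded reads by reason
    (``unmapped``, ``missing_umi``).  Every remaining read lands in exactly
    one family.
    """
    thr = _as_fraction(similarity_threshold)
    excluded: Counter = Counter()
    by_key: dict[tuple, list[AlignedRead]] = defaultdict(list)
    for r in reads:
        if not isinstance(r, AlignedRead):
            r = AlignedRead.from_sim(r)
        if not r.is_mapped:
            excluded["unmapped"] += 1
            continue
        if not r.umi:
            excluded["missing_umi"] += 1
            continue
        by_key[(r.chrom, r.strand, unclipped_start(r))].append(r)

    families: list[ReadFamily] = []
    fid = 0
    for key in sorted(by_key):
        chrom, strand, pos = key
        members = by_key[key]
        counts = Counter(r.umi for r in members)
        ordered = sorted(counts, key=lambda u: (-counts[u], u))
        reps: list[str] = []
        assignment: dict[str, int] = {}
        local: list[list[AlignedRead]] = []
        for u in ordered:
            placed = False
            for fi, rep in enumerate(reps):
                if umi_similarity(u, rep) > thr:
                    assignment[u] = fi
                    placed = True
                    break
            if not placed:
                assignment[u] = len(reps)
                reps.append(u)
                local.append([])
        for r in members:
            local[assignment[r.umi]].append(r)
        for fi, group in enumerate(local):
            families.append(ReadFamily(fid, chrom, strand, pos, reps[fi], group))
            fid += 1
    return families, excluded


@dataclass(eq=False)  # identity comparison; the concordance field is an array
class ConsensusRead:
    """Error-corrected consensus of one UMI family."""

    sequence: str
    concordance: np.ndarray     # per-base predominant fraction, 0 where no data
    family_size: int
    chrom: str
    start: int
    strand: str
    insert_size_bp: int
    umi: str
    mapping_quality: int = 60
    n_excluded_indel: int = 0

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def end(self) -> int:
        return self.start + len(self.sequence)

    @property
    def fragment_start(self) -> int:
        """Leftmost coordinate of the template molecule this family samples."""
        if self.strand == "+":
            return self.start
        return self.start + len(self.sequence) - self.insert_size_bp

    def quality_array(self) -> np.ndarray:
        """Phred-like consensus quality derived from concordance, capped at 40."""
        with np.errstate(divide="ignore"):
            q = -10.0 * np.log10(1.0 - self.concordance + 1e-4)
        return np.minimum(40, np.rint(q)).astype(np.int16)

    def mean_concordance(self) -> float:
        return float(self.concordance.mean()) if len(self.concordance) else 0.0


def call_consensus(family: ReadFamily, concordance_threshold=0.66,
                   min_base_quality: int = 20) -> ConsensusRead | None:
    """Collapse one family to a consensus read.

    Per column only bases with quality >= ``min_base_quality`` count; the
    predominant base is called when its fraction strictly exceeds the
    concordance threshold (exact rational comparison), otherwise N.  Columns
    with no quality bases and ties are N.  Members whose CIGAR contains an
    indel are excluded (columns would not be reference-aligned); if no member
    remains the family yields no consensus.
    """
    thr = _as_fraction(concordance_threshold)
    members = [r for r in family.reads if not has_indel(r.cigar)]
    n_excl = len(family.reads) - len(members)
    if not members:
        return None
    length = min(len(m.seq) for m in members)
    mat = np.vstack([np.frombuffer(m.seq[:length].encode(), np.uint8)
                     for m in members])
    quals = np.vstack([m.qual_array()[:length] for m in members])
    idx = _BASE_INDEX[mat]
    ok = (quals >= min_base_quality) & (idx < 4)
    counts = np.zeros((4, length), dtype=np.int32)
    for b in range(4):
        counts[b] = ((idx == b) & ok).sum(axis=0)
    total = counts.sum(axis=0)
    best = counts.max(axis=0)
    best_base = counts.argmax(axis=0)
    tie = (counts == best).sum(axis=0) > 1

    seq = np.full(length, ord("N"), dtype=np.uint8)
    conc = np.zeros(length, dtype=float)
    nz = total > 0
    conc[nz] = best[nz] / total[nz]
    for i in np.flatnonzero(nz):
        if not tie[i] and Fraction(int(best[i]), int(total[i])) > thr:
            seq[i] = _BASES[best_base[i]]
    rep = members[0]
    return ConsensusRead(bytes(seq).decode(), conc, family.family_size,
                         family.chrom, rep.start, family.strand,
                         abs(rep.tlen), family.umi,
                         min(m.mapq for m in members), n_excl)


def consensus_reads(families, concordance_threshold=0.66,
                    min_base_quality: int = 20) -> list[ConsensusRead]:
    out = []
    for fam in families:
        c = call_consensus(fam, concordance_threshold, min_base_quality)
        if c is not None:
            out.append(c)
    return out


def family_size_spectrum(items, max_k: int | None = None) -> np.ndarray:
    """Counts of consensus reads (or sizes) at family size >= k, k = 1..K.

    The spectrum is monotone non-increasing and its first entry equals the
    total number of inputs.
    """
    sizes = [it if isinstance(it, int) else it.family_size for it in items]
    if max_k is None:
        max_k = max(sizes, default=1)
    if max_k < 1:
        raise ValueError("max_k must be >= 1")
    arr = np.asarray(sizes, dtype=int)
    return np.array([(arr >= k).sum() for k in range(1, max_k + 1)], dtype=int)


def run_metrics(reads, families, consensuses, panel_intervals=None,
                pad_bp: int = 25) -> dict:
    """Per-run summary: totals, mean family size, on-target fraction."""
    n_reads = sum(f.family_size for f in families)
    metrics = {
        "total_reads": n_reads,
        "n_families": len(families),
        "n_consensus_reads": len(consensuses),
        "mean_family_size": (n_reads / len(families)) if families else None,
    }
    if panel_intervals is not None:
        on = 0
        for c in consensuses:
            for s, e in panel_intervals:
                if c.start < e + pad_bp and c.end > s - pad_bp:
                    on += 1
                    break
        metrics["on_target_fraction"] = on / len(consensuses) if consensuses else None
    return metrics


# ---------------------------------------------------------------------------
# SAM round trip for consensus reads

def write_consensus_sam(consensuses: list[ConsensusRead], chrom_lengths: dict,
                        path) -> None:
    """Consensus reads as single-end SAM; family size in cD, insert in XI."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": int(l)} for c, l in chrom_lengths.items()],
    }
    tid = {c: i for i, c in enumerate(chrom_lengths)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i, c in enumerate(sorted(consensuses, key=lambda c: (c.chrom, c.start))):
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"consensus_{i}"
            a.query_sequence = c.sequence
            a.flag = 16 if c.strand == "-" else 0
            a.reference_id = tid[c.chrom]
            a.reference_start = c.start
            a.mapping_quality = c.mapping_quality
            a.cigartuples = [(0, len(c.sequence))]
            a.query_qualities = [int(q) for q in c.quality_array()]
            a.set_tag("RX", c.umi)
            a.set_tag("cD", int(c.family_size))
            a.set_tag("XI", int(c.insert_size_bp))
            out.write(a)


def read_consensus_sam(path) -> list[ConsensusRead]:
    import pysam

    out = []
    with pysam.AlignmentFile(str(path), "r") as fh:
        for a in fh:
            quals = np.array(a.query_qualities, dtype=np.int16)
            conc = 1.0 - np.power(10.0, -quals / 10.0)
            out.append(ConsensusRead(
                a.query_sequence, conc, int(a.get_tag("cD")),
                a.reference_name, a.reference_start,
                "-" if a.is_reverse else "+", int(a.get_tag("XI")),
                a.get_tag("RX") if a.has_tag("RX") else "",
                a.mapping_quality))
    return out
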