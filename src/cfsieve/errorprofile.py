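"""Background sequencing-error analysis of consensus alignments.

Two analyzers mirror the standard germline-control workflow:

* a global base-error-rate estimator: the padded capture panel is scanned in
  overlapping 7-base windows; a window is eligible when every column has
  adequate quality depth (>= 100 Q20 bases), no indel evidence, and no sign of
  a germline allele (pooled non-reference AF <= 0.1).  Good-quality
  non-reference observations of window *centres* are tabulated (each position
  once) into per-substitution and total error rates, at each family-size
  threshold.
* a per-position non-reference AF scan: every passing base is emitted with its
  observed non-reference allele frequencies per allele, positions with
  germline evidence (AF > 0.1) dropped; the records serialize as BED.

Allele frequencies across control samples are binned (<0.1%, 0.1-1.0%,
1-2.0%) at family size >= 1, split into "shared" (seen in at least
``shared_min`` controls) versus "unique" (stochastic noise), and tracked for
presence at larger family sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_BASES = "ACGT"
_BASE_INDEX = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i

DEFAULT_FS_THRESHOLDS = (1, 5, 10, 15, 20)
AF_BIN_EDGES = (0.001, 0.01, 0.02)
AF_BIN_LABELS = ("<0.1%", "0.1-1.0%", "1.0-2.0%")


@dataclass
class PileupColumn:
    chrom: str
    position: int
    ref_base: str
    counts: dict  # base -> quality-passing count (N excluded)
    indel_observed: bool = False

    @property
    def depth_q20(self) -> int:
        return sum(self.counts.values())

    @property
    def nonref_af(self) -> float:
        d = self.depth_q20
        if d == 0:
            return 0.0
        return (d - self.counts.get(self.ref_base, 0)) / d


@dataclass
class PositionAF:
    chrom: str
    position: int
    non_ref_allele: str
    af: float
    fs_threshold: int
    sample_id: str = ""


@dataclass
class ErrorRateTable:
    fs_threshold: int
    n_eligible_centers: int
    n_center_observations: int
    n_nonref_observations: int
    per_substitution: dict = field(default_factory=dict)

    @property
    def total_error_rate(self) -> float | None:
        if self.n_center_observations == 0:
            return None
        return self.n_nonref_observations / self.n_center_observations


@dataclass
class _Block:
    start: int  # 0-based
    counts: np.ndarray      # (4, L) quality-passing base counts
    indel: np.ndarray       # (L,) bool
    ref_idx: np.ndarray     # (L,) uint8

    @property
    def length(self) -> int:
        return self.counts.shape[1]


@dataclass
class Pileup:
    chrom: str
    blocks: list

    def columns(self):
        """Iterate PileupColumn records over all covered positions."""
        for b in self.blocks:
            for i in range(b.length):
                yield PileupColumn(
                    self.chrom, b.start + i, _BASES[b.ref_idx[i]],
                    {_BASES[j]: int(b.counts[j, i]) for j in range(4)},
                    bool(b.indel[i]))


def _merge_padded(intervals, pad: int, contig_len: int) -> list[tuple[int, int]]:
    padded = sorted((max(0, s - pad), min(contig_len, e + pad))
                    for s, e in intervals)
    merged: list[list[int]] = []
    for s, e in padded:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def build_pileup(consensuses, intervals, ref_sequence: str, chrom: str,
                 pad_bp: int = 25, min_fs: int = 1, min_mapq: int = 20,
                 min_base_quality: int = 20) -> Pileup:
    """Pile consensus reads over the padded panel.

    Only reads with family size >= ``min_fs`` and mapping quality >= MQ20
    contribute; bases below Q20 and N bases are excluded from the counts.
    Indel-containing reads flag every column they span.
    """
    regions = _merge_padded(intervals, pad_bp, len(ref_sequence))
    blocks = []
    for s, e in regions:
        ref = np.frombuffer(ref_sequence[s:e].encode(), np.uint8)
        ref_idx = _BASE_INDEX[ref]
        if (ref_idx > 3).any():
            raise ValueError("reference contains non-ACGT bases in the panel")
        blocks.append(_Block(s, np.zeros((4, e - s), dtype=np.int64),
                             np.zeros(e - s, dtype=bool), ref_idx))
    for c in consensuses:
        if c.chrom != chrom or c.family_size < min_fs or c.mapping_quality < min_mapq:
            continue
        seq = np.frombuffer(c.sequence.encode(), np.uint8)
        quals = c.quality_array()
        for b in blocks:
            lo = max(c.start, b.start)
            hi = min(c.end, b.start + b.length)
            if lo >= hi:
                continue
            roff = lo - c.start
            boff = lo - b.start
            sub = seq[roff:roff + (hi - lo)]
            qsub = quals[roff:roff + (hi - lo)]
            idx = _BASE_INDEX[sub]
            ok = (idx < 4) & (qsub >= min_base_quality)
            cols = boff + np.flatnonzero(ok)
            np.add.at(b.counts, (idx[ok], cols), 1)
            if getattr(c, "has_indel", False):
                b.indel[boff:boff + (hi - lo)] = True
    return Pileup(chrom, blocks)


def eligible_region(columns) -> bool:
    """Whether 7 adjacent columns form an eligible background window."""
    cols = list(columns)
    if len(cols) != 7:
        raise ValueError("an eligible region is exactly 7 adjacent bases")
    return all(c.depth_q20 >= 100 and not c.indel_observed and
               c.nonref_af <= 0.1 for c in cols)


def _block_masks(block: _Block, min_depth: int = 100):
    depth = block.counts.sum(axis=0)
    ref_count = block.counts[block.ref_idx, np.arange(block.length)]
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(depth > 0, (depth - ref_count) / np.maximum(depth, 1), 0.0)
    ok = (depth >= min_depth) & ~block.indel & (af <= 0.1)
    return depth, ref_count, af, ok


def _eligible_centers(ok: np.ndarray, window: int = 7) -> np.ndarray:
    if len(ok) < window:
        return np.zeros(len(ok), dtype=bool)
    runs = np.convolve(ok.astype(int), np.ones(window, dtype=int), mode="same")
    # 'same' centres the window; edge positions can never host a full window
    centers = runs == window
    half = window // 2
    centers[:half] = False
    centers[len(ok) - half:] = False
    return centers


def estimate_error_rates(consensuses, intervals, ref_sequence: str, chrom: str,
                         fs_thresholds=DEFAULT_FS_THRESHOLDS, pad_bp: int = 25,
                         min_depth: int = 100) -> list[ErrorRateTable]:
    """Global and per-substitution error rates at each family-size threshold.

    Overlapping 7-base windows slide one base at a time; each eligible centre
    is tabulated exactly once.  A threshold with no eligible region yields a
    table with missing rates and zero counts.
    """
    tables = []
    for k in fs_thresholds:
        pileup = build_pileup(consensuses, intervals, ref_sequence, chrom,
                              pad_bp=pad_bp, min_fs=k)
        n_centers = n_obs = n_nonref = 0
        subs = {f"{r}>{a}": 0 for r in _BASES for a in _BASES if r != a}
        for b in pileup.blocks:
            depth, ref_count, _af, ok = _block_masks(b, min_depth)
            centers = _eligible_centers(ok)
            if not centers.any():
                continue
            n_centers += int(centers.sum())
            n_obs += int(depth[centers].sum())
            n_nonref += int((depth[centers] - ref_count[centers]).sum())
            for r in range(4):
                at = centers & (b.ref_idx == r)
                if not at.any():
                    continue
                for a in range(4):
                    if a != r:
                        subs[f"{_BASES[r]}>{_BASES[a]}"] += int(
                            b.counts[a, at].sum())
        table = ErrorRateTable(k, n_centers, n_obs, n_nonref)
        table.per_substitution = {
            key: (v / n_obs if n_obs else None) for key, v in subs.items()}
        tables.append(table)
    return tables


def nonref_af_scan(consensuses, intervals, ref_sequence: str, chrom: str,
                   fs_thresholds=DEFAULT_FS_THRESHOLDS, pad_bp: int = 25,
                   min_depth: int = 100, sample_id: str = ""
                   ) -> list[PositionAF]:
    """Per-position, per-allele non-reference AFs at each threshold.

    Positions with germline evidence (pooled AF > 0.1) are dropped; a position
    whose supporting families all fall below a threshold simply disappears
    from that threshold's records.
    """
    out: list[PositionAF] = []
    for k in fs_thresholds:
        pileup = build_pileup(consensuses, intervals, ref_sequence, chrom,
                              pad_bp=pad_bp, min_fs=k)
        for b in pileup.blocks:
            depth, ref_count, af, ok = _block_masks(b, min_depth)
            passing = np.flatnonzero(ok & (depth > 0))
            for i in passing:
                for a in range(4):
                    if a == b.ref_idx[i]:
                        continue
                    cnt = int(b.counts[a, i])
                    if cnt > 0:
                        out.append(PositionAF(chrom, int(b.start + i),
                                              _BASES[a], cnt / int(depth[i]),
                                              k, sample_id))
    return out


def positionaf_to_bed(records, path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.chrom}\t{r.position}\t{r.position + 1}\t"
                     f"{r.non_ref_allele}\t{r.af:.6g}\t.\t{r.fs_threshold}\t"
                     f"{r.sample_id}\n")


def af_bin(af: float) -> str | None:
    """Bin an FS>=1 allele frequency; None when above the 2% reporting range.

    Edges: [0, 0.1%), [0.1%, 1.0%], (1.0%, 2.0%].
    """
    if af < AF_BIN_EDGES[0]:
        return AF_BIN_LABELS[0]
    if af <= AF_BIN_EDGES[1]:
        return AF_BIN_LABELS[1]
    if af <= AF_BIN_EDGES[2]:
        return AF_BIN_LABELS[2]
    return None


def bin_and_classify(records_by_sample: dict, shared_min: int = 3
                     ) -> pd.DataFrame:
    """Bin control-sample alleles and split unique vs shared locations.

    ``records_by_sample`` maps sample id -> list of PositionAF (all family
    size thresholds).  A (position, allele) present in at least ``shared_min``
    samples at FS>=1 is "shared", otherwise "unique".  Each allele is binned
    by its FS>=1 AF and tracked for presence at every threshold it was
    scanned at.  Returns a tidy frame of counts per
    (fs_threshold, bin, classification).
    """
    if not records_by_sample:
        raise ValueError("at least one sample is required")
    base_key = lambda r: (r.chrom, r.position, r.non_ref_allele)
    presence: dict[tuple, set] = {}
    for sid, recs in records_by_sample.items():
        for r in recs:
            if r.fs_threshold == 1:
                presence.setdefault(base_key(r), set()).add(sid)
    shared = {k for k, sids in presence.items() if len(sids) >= shared_min}

    fs_values = sorted({r.fs_threshold for recs in records_by_sample.values()
                        for r in recs})
    rows = []
    counts: dict[tuple, int] = {}
    for sid, recs in records_by_sample.items():
        baseline = {base_key(r): r.af for r in recs if r.fs_threshold == 1}
        present_at = {}
        for r in recs:
            present_at.setdefault(r.fs_threshold, set()).add(base_key(r))
        for key, af1 in baseline.items():
            bin_label = af_bin(af1)
            if bin_label is None:
                continue
            cls = "shared" if key in shared else "unique"
            for k in fs_values:
                if key in present_at.get(k, ()):  # still detected at FS>=k
                    counts[(k, bin_label, cls)] = counts.get(
                        (k, bin_label, cls), 0) + 1
    for k in fs_values:
        for bin_label in AF_BIN_LABELS:
            for cls in ("unique", "shared"):
                rows.append({"fs_threshold": k, "bin": bin_label,
                             "classification": cls,
                             "n_alleles": counts.get((k, bin_label, cls), 0)})
    return pd.DataFrame(rows)


def error_tables_to_tsv(tables, path) -> None:
    rows = []
    for t in tables:
        row = {"fs_threshold": t.fs_threshold,
               "n_eligible_centers": t.n_eligible_centers,
               "n_center_observations": t.n_center_observations,
               "n_nonref_observations": t.n_nonref_observations,
               "total_error_rate": t.total_error_rate}
        row.update(t.per_substitution)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
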