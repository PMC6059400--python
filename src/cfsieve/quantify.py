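"""Variant-allele quantification from consensus reads.

A consensus read is classified WT or VARIANT by a 100% match to an 11-bp
string centred on the variant base, anchored at the reference coordinate of
the assay (not a floating substring search); any mismatch, an N inside the
window, or incomplete window coverage leaves the read unclassified.

Counting is aggregated per *molecule*: the forward- and reverse-strand
families of one template share chromosome, fragment span and UMI, and each
molecule contributes a single count, matching the interpretation that every
consensus count represents one unique input molecule.  VAF is reported in
percent and as missing (None) rather than zero when the denominator is empty,
so "no data" is distinguishable from "variant lost".
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .consensus import ConsensusRead

WT, VARIANT, UNCLASSIFIED = "WT", "VARIANT", "UNCLASSIFIED"


@dataclass(frozen=True)
class VariantAssay:
    """An 11-mer allele-discrimination assay at one locus."""

    name: str
    chrom: str
    position: int  # 0-based coordinate of the variant base
    wt_11mer: str
    variant_11mer: str

    def __post_init__(self) -> None:
        if len(self.wt_11mer) != 11 or len(self.variant_11mer) != 11:
            raise ValueError("assay strings must be exactly 11 bp")
        if self.wt_11mer.upper() == self.variant_11mer.upper():
            raise ValueError("WT and variant 11-mers must differ")

    @property
    def window(self) -> tuple[int, int]:
        """0-based half-open reference window covered by the 11-mer."""
        return self.position - 5, self.position + 6

    @classmethod
    def from_reference(cls, reference, locus=None, name: str | None = None
                       ) -> "VariantAssay":
        locus = locus or reference.variant_locus
        w0 = locus.position - 5
        wt = reference.sequence[w0:w0 + 11]
        var = wt[:5] + locus.alt + wt[6:]
        return cls(name or f"assay_{locus.position}", locus.chrom,
                   locus.position, wt, var)


def assays_to_tsv(assays: list[VariantAssay], path) -> None:
    pd.DataFrame([a.__dict__ for a in assays]).to_csv(path, sep="\t", index=False)


def assays_from_tsv(path) -> list[VariantAssay]:
    df = pd.read_csv(path, sep="\t")
    return [VariantAssay(str(r.name), str(r.chrom), int(r.position),
                         str(r.wt_11mer), str(r.variant_11mer))
            for r in df.itertuples(index=False)]


def classify_consensus(consensus: ConsensusRead, assay: VariantAssay) -> str:
    """Classify one consensus read by exact, case-insensitive 11-mer match."""
    if consensus.chrom != assay.chrom:
        return UNCLASSIFIED
    w0, w1 = assay.window
    if consensus.start > w0 or consensus.end < w1:
        return UNCLASSIFIED  # incomplete window coverage
    sub = consensus.sequence[w0 - consensus.start:w1 - consensus.start].upper()
    if sub == assay.wt_11mer.upper():
        return WT
    if sub == assay.variant_11mer.upper():
        return VARIANT
    return UNCLASSIFIED


@dataclass
class Molecule:
    """The one or two strand consensus reads of a single template molecule."""

    chrom: str
    fragment_start: int
    insert_size_bp: int
    umi: str
    consensuses: list[ConsensusRead]

    @property
    def family_size(self) -> int:
        return max(c.family_size for c in self.consensuses)

    @property
    def end(self) -> int:
        return self.fragment_start + self.insert_size_bp


def molecules_from_consensus(consensuses) -> list[Molecule]:
    groups: dict[tuple, list[ConsensusRead]] = defaultdict(list)
    for c in consensuses:
        groups[(c.chrom, c.fragment_start, c.insert_size_bp, c.umi)].append(c)
    return [Molecule(k[0], k[1], k[2], k[3], v)
            for k, v in sorted(groups.items())]


def classify_molecule(mol: Molecule, assay: VariantAssay) -> str:
    """Molecule call: strand calls must not conflict; any single call decides."""
    calls = {classify_consensus(c, assay) for c in mol.consensuses}
    calls.discard(UNCLASSIFIED)
    if len(calls) == 1:
        return calls.pop()
    return UNCLASSIFIED


@dataclass
class AlleleCounts:
    wt_count: int
    variant_count: int
    unclassified_count: int
    fs_threshold: int = 1

    @property
    def vaf_percent(self) -> float | None:
        denom = self.wt_count + self.variant_count
        if denom == 0:
            return None
        return 100.0 * self.variant_count / denom

    @property
    def variant_lost(self) -> bool:
        return self.variant_count == 0 and self.wt_count > 0


def vaf(counts: AlleleCounts) -> float | None:
    """VAF in percent, missing (None) when there are no classified counts."""
    return counts.vaf_percent


def allele_counts(consensuses, assay: VariantAssay, fs_threshold: int = 1,
                  molecule_level: bool = True) -> AlleleCounts:
    """Classify and count at a family-size threshold.

    ``molecule_level=True`` merges strand families per template molecule;
    ``False`` counts individual consensus reads.
    """
    if fs_threshold < 1:
        raise ValueError("fs_threshold must be >= 1")
    wt = var = uncl = 0
    if molecule_level:
        items = molecules_from_consensus(consensuses)
        w0, w1 = assay.window
        for m in items:
            if m.family_size < fs_threshold:
                continue
            if m.chrom != assay.chrom or m.fragment_start > w0 or m.end < w1:
                continue  # molecule does not span the assay window
            call = classify_molecule(m, assay)
            if call == WT:
                wt += 1
            elif call == VARIANT:
                var += 1
            else:
                uncl += 1
    else:
        w0, w1 = assay.window
        for c in consensuses:
            if c.family_size < fs_threshold:
                continue
            if c.chrom != assay.chrom or c.start > w0 or c.end < w1:
                continue
            call = classify_consensus(c, assay)
            if call == WT:
                wt += 1
            elif call == VARIANT:
                var += 1
            else:
                uncl += 1
    return AlleleCounts(wt, var, uncl, fs_threshold)


def vaf_at_fs(consensuses, assay: VariantAssay, k: int,
              molecule_level: bool = True) -> AlleleCounts:
    """Allele counts restricted to family size >= k (k=1 is unrestricted)."""
    return allele_counts(consensuses, assay, fs_threshold=k,
                         molecule_level=molecule_level)


def vaf_table(consensuses, assay: VariantAssay, max_k: int = 20,
              molecule_level: bool = True) -> pd.DataFrame:
    """VAF and counts across family-size thresholds 1..max_k."""
    rows = []
    for k in range(1, max_k + 1):
        c = vaf_at_fs(consensuses, assay, k, molecule_level)
        rows.append({"fs_threshold": k, "wt_count": c.wt_count,
                     "variant_count": c.variant_count,
                     "unclassified_count": c.unclassified_count,
                     "vaf_percent": c.vaf_percent,
                     "variant_lost": c.variant_lost})
    return pd.DataFrame(rows)


def insert_size_summary(consensuses, assay: VariantAssay,
                        max_insert: int = 250) -> dict:
    """Per-allele insert-size medians.

    Medians are computed over inserts <= ``max_insert`` (the mononucleosome
    range); the longer subset is summarised separately.  Missing classes give
    None.
    """
    inserts = {WT: [], VARIANT: []}
    for m in molecules_from_consensus(consensuses):
        call = classify_molecule(m, assay)
        if call in inserts:
            inserts[call].append(m.insert_size_bp)

    def _med(values):
        return float(np.median(values)) if values else None

    out = {}
    for cls, vals in inserts.items():
        short = [v for v in vals if v <= max_insert]
        long = [v for v in vals if v > max_insert]
        out[cls] = {
            "median_insert_bp": _med(short),
            "n": len(short),
            "median_insert_over_max_bp": _med(long),
            "n_over_max": len(long),
        }
    return out


def enrichment_fold_change(vaf_fraction: float | None,
                           vaf_unselected: float | None) -> float | None:
    """VAF ratio of a size fraction over the unselected library.

    Missing when the unselected VAF is zero or either value is missing
    (mirrors reporting only above the limit of blank).
    """
    if vaf_fraction is None or vaf_unselected is None or vaf_unselected == 0:
        return None
    return vaf_fraction / vaf_unselected


def relative_percent_change(vaf_k: float | None, vaf_ref: float | None
                            ) -> float | None:
    """Absolute relative percent change of VAF against the FS>=1 reference."""
    if vaf_ref is None or vaf_ref == 0 or vaf_k is None:
        return None
    return 100.0 * abs(vaf_k - vaf_ref) / vaf_ref
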