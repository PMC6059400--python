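"""Droplet digital PCR quantification.

Digital PCR partitions a reaction into droplets and reads each droplet out as
positive or negative per channel.  Because a positive droplet may contain more
than one template molecule, concentrations are estimated with the standard
Poisson correction: if a fraction ``f`` of droplets is negative for a target,
the per-droplet mean occupancy is ``lambda = -ln(f)`` and the total input is
``lambda * n_droplets`` copies.

The limit of blank (LOB) of an assay is derived from false-positive droplet
counts observed across negative controls: a Poisson mean is fitted (the MLE is
the sample mean) and the LOB is the smallest droplet count k whose Poisson CDF
reaches 0.95; the 95% point of the empirical distribution is reported
alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class DropletCounts:
    """Droplet class counts of one well (classes are mutually exclusive)."""

    n_total: int
    n_wt_pos: int       # wild-type channel only
    n_var_pos: int      # variant channel only
    n_double_pos: int   # positive in both channels
    n_empty: int

    def __post_init__(self) -> None:
        parts = (self.n_wt_pos, self.n_var_pos, self.n_double_pos, self.n_empty)
        if any(v < 0 for v in parts) or self.n_total <= 0:
            raise ValueError("droplet counts must be non-negative, total positive")
        if sum(parts) != self.n_total:
            raise ValueError("droplet classes must sum to n_total")

    def positives(self, target: str) -> int:
        """Droplets positive for ``target`` ('wt' or 'variant'), doubles included."""
        if target == "wt":
            return self.n_wt_pos + self.n_double_pos
        if target == "variant":
            return self.n_var_pos + self.n_double_pos
        raise ValueError(f"unknown target {target!r}")


@dataclass
class Concentration:
    lambda_per_droplet: float | None  # None when saturated
    total_copies: float | None
    quantifiable: bool


@dataclass
class LobResult:
    lambda_fp: float
    lob_droplets: int      # 95% Poisson quantile
    lob_empirical: int     # 95% point of the observed counts


def concentration(counts: DropletCounts, target: str) -> Concentration:
    """Poisson-corrected copies of one target from droplet counts."""
    neg = counts.n_total - counts.positives(target)
    if neg == 0:
        return Concentration(None, None, False)
    lam = -math.log(neg / counts.n_total)
    return Concentration(lam, lam * counts.n_total, True)


def vaf_from_droplets(counts: DropletCounts) -> float | None:
    """Variant allele frequency (percent) from Poisson-corrected concentrations.

    Returns None when neither channel carries signal or either channel is
    saturated (occupancy not quantifiable).
    """
    wt = concentration(counts, "wt")
    var = concentration(counts, "variant")
    if not (wt.quantifiable and var.quantifiable):
        return None
    tot = wt.lambda_per_droplet + var.lambda_per_droplet
    if tot == 0:
        return None
    return 100.0 * var.lambda_per_droplet / tot


def fit_lob(false_positive_counts) -> LobResult:
    """Fit a Poisson to per-assay false-positive droplet counts and derive LOB."""
    x = np.asarray(list(false_positive_counts), dtype=float)
    if x.size == 0:
        raise ValueError("at least one control observation is required")
    if (x < 0).any():
        raise ValueError("false-positive counts must be >= 0")
    lam = float(x.mean())
    lob = 0 if lam == 0 else int(stats.poisson.ppf(0.95, lam))
    emp = int(np.quantile(x, 0.95, method="higher"))
    return LobResult(lam, lob, emp)


def expected_ngs_counts(ddpcr_copies: float, ddpcr_input_mass_ng: float,
                        ngs_input_mass_ng: float) -> float:
    """Extrapolate ddPCR molecule counts to expected NGS consensus counts.

    Assumes a lossless system: copy number scales linearly with the DNA mass
    carried into each assay.
    """
    if ddpcr_input_mass_ng <= 0 or ngs_input_mass_ng <= 0:
        raise ValueError("input masses must be positive")
    return ddpcr_copies * ngs_input_mass_ng / ddpcr_input_mass_ng


def copies_per_ml_plasma(copies: float, reaction_fraction_analyzed: float,
                         input_volume_ul: float, extract_volume_ul: float,
                         plasma_volume_ml: float) -> float:
    """Extrapolate assay copies to copies per millilitre of plasma.

    Scales by the fraction of the reaction actually analyzed, by how much of
    the DNA extract was loaded, and by the plasma volume extracted.
    """
    if not 0 < reaction_fraction_analyzed <= 1:
        raise ValueError("reaction_fraction_analyzed must be in (0, 1]")
    if input_volume_ul <= 0 or extract_volume_ul <= 0 or plasma_volume_ml <= 0:
        raise ValueError("volumes must be positive")
    return (copies / reaction_fraction_analyzed
            * (extract_volume_ul / input_volume_ul)
            / plasma_volume_ml)
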