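"""Heterozygote-balance statistics and the exact small-copy-number oracle.

Heterozygote balance at a two-allele locus is the ratio of the
high-molecular-weight allele signal to the low-molecular-weight one,

    Hb = signal_HMW / signal_LMW,

computed from molecule counts when no peak-height scaling is used, or
from RFU heights otherwise.  Loci with a dropped allele are excluded from
the ratio and counted as drop-out.  A locus is conventionally called
"balanced" when Hb lies in the closed range [0.6, 1.67].

For n haploid cells the allele split at a heterozygous locus is exactly
Binomial(n, 1/2), so the full Hb distribution — including the two
drop-out atoms at splits 0/n and n/0 — can be enumerated in closed form;
:func:`enumerate_haploid_hb` is that oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction
from math import comb
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import EPG, KitDef

__all__ = [
    "HB_ACCEPTED_RANGE",
    "HbRecord",
    "HbDistribution",
    "heterozygote_balance",
    "exclude_stutter_pairs",
    "saturation_filter",
    "enumerate_haploid_hb",
    "hb_summary",
]

#: Closed interval conventionally accepted as a balanced locus.
HB_ACCEPTED_RANGE = (Fraction(3, 5), Fraction(167, 100))


@dataclass(frozen=True)
class HbRecord:
    """Per-locus heterozygote-balance observation.

    Signals are molecule counts (identity CE) or peak heights in RFU
    (calibrated CE).  ``hb`` is HMW/LMW; it is only defined when both
    signals are positive.
    """

    locus: str
    hmw_signal: float
    lmw_signal: float
    hmw_size: int
    lmw_size: int
    hb: float

    def __post_init__(self) -> None:
        if self.lmw_signal <= 0 or self.hmw_signal <= 0:
            raise ValueError("Hb is undefined when either signal is 0")


@dataclass(frozen=True)
class HbDistribution:
    """Exact Hb distribution for n haploid cells.

    ``support`` maps each finite ratio (a Fraction, HMW over LMW split)
    to its exact probability; ``p_dropout`` is the combined mass of the
    0/n and n/0 atoms where one allele is absent.  All probabilities sum
    to 1 exactly.
    """

    n_cells: int
    support: dict[Fraction, Fraction]
    p_dropout: Fraction

    @property
    def p_balanced(self) -> float:
        """P(Hb == 1), i.e. a perfectly even split."""
        return float(self.support.get(Fraction(1), Fraction(0)))

    @property
    def p_accepted(self) -> float:
        """Unconditional P(0.6 <= Hb <= 1.67); drop-out atoms count against."""
        lo, hi = HB_ACCEPTED_RANGE
        return float(sum(p for r, p in self.support.items() if lo <= r <= hi))

    def total_mass(self) -> Fraction:
        return sum(self.support.values(), start=Fraction(0)) + self.p_dropout

    def quantile(self, q: float) -> float:
        """Quantile of the finite-ratio part (drop-outs excluded)."""
        items = sorted(self.support.items())
        total = sum(p for _, p in items)
        acc = Fraction(0)
        for r, p in items:
            acc += p
            if acc / total >= Fraction(q).limit_denominator(10**9):
                return float(r)
        return float(items[-1][0])


def heterozygote_balance(epg: EPG, kit: KitDef) -> tuple[list[HbRecord], int]:
    """Score Hb at every heterozygous locus of an EPG.

    Uses detected peaks at the two expected allele positions; the HMW
    allele is the one with the larger fragment length.  Returns the
    records together with the number of heterozygous loci excluded
    because at least one allele dropped out.
    """
    if epg.genotype is None:
        raise ValueError("EPG carries no genotype; cannot locate allele peaks")
    by_pos = {(p.locus, p.size_bp): p for p in epg.peaks if p.detected}
    records: list[HbRecord] = []
    n_dropout = 0
    for locus in kit:
        pair = epg.genotype.alleles.get(locus.name)
        if pair is None or len(pair) != 2:
            continue
        sizes = sorted(locus.size_of(a) for a in pair)
        lmw = by_pos.get((locus.name, sizes[0]))
        hmw = by_pos.get((locus.name, sizes[1]))
        if lmw is None or hmw is None or lmw.height <= 0 or hmw.height <= 0:
            n_dropout += 1
            continue
        records.append(
            HbRecord(
                locus=locus.name,
                hmw_signal=hmw.height,
                lmw_signal=lmw.height,
                hmw_size=sizes[1],
                lmw_size=sizes[0],
                hb=hmw.height / lmw.height,
            )
        )
    return records, n_dropout


def exclude_stutter_pairs(records: Iterable[HbRecord], kit: KitDef) -> list[HbRecord]:
    """Drop loci whose two alleles sit exactly one repeat unit apart.

    At such loci the stutter of the HMW allele co-migrates with the LMW
    allele (and a surviving stutter can masquerade as a dropped partner
    allele), biasing Hb; the standard remedy is to remove them.
    """
    out = []
    for r in records:
        if r.hmw_size - r.lmw_size == kit.locus(r.locus).repeat_bp:
            continue
        out.append(r)
    return out


def saturation_filter(records: Iterable[HbRecord], threshold: float = 10_000.0) -> list[HbRecord]:
    """Drop loci whose mean peak height exceeds the saturation threshold.

    CE detectors saturate (typically around 10,000 RFU on a 3130xL-class
    instrument), flattening strong peaks and distorting their ratio; the
    comparison is strict, so a mean exactly at the threshold is kept.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    return [r for r in records if (r.hmw_signal + r.lmw_signal) / 2.0 <= threshold]


def enumerate_haploid_hb(n: int) -> HbDistribution:
    """Exact Hb distribution for n haploid cells at a heterozygous locus.

    The a-allele count is k ~ Binomial(n, 1/2); the finite support is
    {k/(n-k) : 0 < k < n} with exact rational probabilities, and the two
    atoms k = 0 and k = n (each probability 2^-n) are drop-outs.  With
    ideal amplification every downstream signal ratio equals the input
    copy ratio, so this enumeration is the molecule-level ground truth
    the full pipeline must reproduce.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    denom = Fraction(1, 2**n)
    support: dict[Fraction, Fraction] = {}
    for k in range(1, n):
        ratio = Fraction(k, n - k)
        support[ratio] = support.get(ratio, Fraction(0)) + comb(n, k) * denom
    p_dropout = 2 * denom if n >= 1 else Fraction(0)
    return HbDistribution(n_cells=n, support=support, p_dropout=p_dropout)


def hb_summary(
    df: pd.DataFrame,
    group_cols: Sequence[str],
    quantiles: Sequence[float] = (0.05, 0.95),
    hb_col: str = "hb",
) -> pd.DataFrame:
    """Per-condition summary of simulated Hb values.

    Expects a tidy frame with one row per scored locus, ``hb`` as NaN for
    drop-out rows.  Reports, per group: number of observations, drop-out
    fraction, the requested quantiles, the fraction within the accepted
    range [0.6, 1.67] (unconditional, drop-outs in the denominator), and
    the SD of log10(hb) over finite values.
    """
    lo, hi = float(HB_ACCEPTED_RANGE[0]), float(HB_ACCEPTED_RANGE[1])

    def _one(g: pd.DataFrame) -> pd.Series:
        hb = g[hb_col]
        finite = hb.dropna()
        out: dict[str, float] = {
            "n": float(len(hb)),
            "dropout_fraction": float(hb.isna().mean()) if len(hb) else np.nan,
            "p_accepted": float(((finite >= lo) & (finite <= hi)).sum() / len(hb)) if len(hb) else np.nan,
            "sd_log10_hb": float(np.log10(finite).std(ddof=1)) if len(finite) > 1 else np.nan,
        }
        for q in quantiles:
            out[f"q{int(round(q * 100)):02d}"] = float(finite.quantile(q)) if len(finite) else np.nan
        return pd.Series(out)

    grouped = df.groupby(list(group_cols), sort=True, dropna=False)
    return grouped.apply(_one, include_groups=False).reset_index()
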