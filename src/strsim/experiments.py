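"""Config-driven simulation experiments.

Each ``run_*`` function reproduces one of the simulator's standard
studies — parameter sweeps of heterozygote balance (Hb) over PCR
efficiency, PCR aliquot, extraction efficiency and their combination,
the serial-dilution versus crime-stain comparison, the degraded-fragment
demonstration, and Hb versus DNA amount with stutter and a calibrated
instrument.  All return a tidy :class:`pandas.DataFrame` (one row per
scored heterozygous locus; ``hb`` is NaN for a locus lost to drop-out)
plus a parameter manifest, and are bit-reproducible under a fixed
(spec, seed).

Replicate counts default to the study sizes the experiments were
designed with; pass ``replicates`` in the :class:`ExperimentSpec` to
scale them (e.g. down for quick checks).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .balance import exclude_stutter_pairs, heterozygote_balance, saturation_filter
from .core import (
    CEParams,
    Genotype,
    KitDef,
    ProcessParams,
    make_fixture_kit,
    random_genotype,
    sample_rng,
)
from .process import binomial_thin, ce_detect, pcr_amplify, sample_cells, simulate_sample

__all__ = [
    "ExperimentSpec",
    "PG_PER_DIPLOID_CELL",
    "run_efficiency_sweep",
    "run_aliquot_sweep",
    "run_extraction_sweep",
    "run_combined_sweep",
    "run_dilution_vs_stain",
    "run_degradation_demo",
    "run_hb_vs_amount",
    "rank_compare",
    "EXPERIMENTS",
]

#: DNA mass per diploid cell used for pg <-> cells conversion in experiments.
PG_PER_DIPLOID_CELL = 6.6

DIPLOID_CELL_GRID = tuple(2**k for k in range(0, 8))  # 1..128
HAPLOID_CELL_GRID = tuple(2**k for k in range(1, 9))  # 2..256


@dataclass
class ExperimentSpec:
    """Shared experiment configuration.

    ``replicates=None`` means "use this experiment's default study size".
    A small kit (few loci) speeds things up roughly proportionally; Hb
    observations at different loci of one sample are i.i.d. under these
    idealised settings.
    """

    name: str = ""
    replicates: int | None = None
    seed: int = 0
    kit: KitDef | None = None
    n_loci: int = 4

    def resolved_kit(self) -> KitDef:
        return self.kit if self.kit is not None else make_fixture_kit(self.n_loci, (70, 450))

    def n_reps(self, default: int) -> int:
        n = self.replicates if self.replicates is not None else default
        if n < 1:
            raise ValueError("replicate count must be >= 1")
        return n


def _hb_rows(
    epg, kit: KitDef, tags: dict, use_filters: bool = False, saturation: float = 10_000.0
) -> list[dict]:
    records, n_dropout = heterozygote_balance(epg, kit)
    if use_filters:
        records = saturation_filter(exclude_stutter_pairs(records, kit), saturation)
    rows = [
        {**tags, "locus": r.locus, "hb": r.hb, "hmw_signal": r.hmw_signal, "lmw_signal": r.lmw_signal}
        for r in records
    ]
    rows.extend(
        {**tags, "locus": None, "hb": np.nan, "hmw_signal": np.nan, "lmw_signal": np.nan}
        for _ in range(n_dropout)
    )
    return rows


def _sweep(
    spec: ExperimentSpec,
    default_reps: int,
    conditions: Sequence[dict],
    pcr_c: int = 28,
    mode: str = "fixed",
) -> tuple[pd.DataFrame, dict]:
    """Grid of idealised Hb sweeps with identity CE (molecule counts)."""
    kit = spec.resolved_kit()
    reps = spec.n_reps(default_reps)
    ce = CEParams.identity()
    rows: list[dict] = []
    stream = 0
    geno_rng = sample_rng(spec.seed, 2**20)
    genotypes = {
        "diploid": random_genotype(kit, geno_rng, heterozygous_only=True, ploidy="diploid"),
        "haploid": random_genotype(kit, geno_rng, heterozygous_only=True, ploidy="haploid"),
    }
    for cond in conditions:
        params = ProcessParams(
            extraction_efficiency=cond.get("ex_e", 1.0),
            pcr_aliquot=cond.get("pcr_a", 1.0),
            pcr_cycles=pcr_c,
            pcr_efficiency=cond.get("pcr_e", 1.0),
            stutter_probability=0.0,
            ce_aliquot=1.0,
        )
        grids = {"diploid": DIPLOID_CELL_GRID, "haploid": HAPLOID_CELL_GRID}
        for ploidy, grid in grids.items():
            for cells in grid:
                for rep in range(reps):
                    rng = sample_rng(spec.seed, stream)
                    stream += 1
                    epg, _ = simulate_sample(
                        genotypes[ploidy], params, ce, kit, rng, cells, mode=mode
                    )
                    tags = {**cond, "ploidy": ploidy, "cells": cells, "replicate": rep}
                    rows.extend(_hb_rows(epg, kit, tags))
    manifest = {
        "experiment": spec.name,
        "seed": spec.seed,
        "replicates": reps,
        "pcr_cycles": pcr_c,
        "kit": kit.name,
        "n_loci": len(kit),
        "conditions": list(conditions),
        "ce": "identity",
    }
    return pd.DataFrame(rows), manifest


def run_efficiency_sweep(spec: ExperimentSpec) -> tuple[pd.DataFrame, dict]:
    """Hb versus PCR efficiency (0.20, 0.80, 1.00), diploid and haploid.

    Direct PCR (ex_e = pcr_a = ce_a = 1), fixed cell counts on a doubling
    grid, identity CE, stutter off; 500 samples per condition by default.
    """
    spec.name = spec.name or "efficiency_sweep"
    return _sweep(spec, 500, [{"pcr_e": e} for e in (0.20, 0.80, 1.00)])


def run_aliquot_sweep(spec: ExperimentSpec) -> tuple[pd.DataFrame, dict]:
    """Hb versus PCR aliquot (0.05, 0.35, 1.00); 1500 samples/condition."""
    spec.name = spec.name or "aliquot_sweep"
    return _sweep(spec, 1500, [{"pcr_a": a} for a in (0.05, 0.35, 1.00)])


def run_extraction_sweep(spec: ExperimentSpec) -> tuple[pd.DataFrame, dict]:
    """Hb versus extraction efficiency (0.30, 0.60, 1.00); 1000 samples."""
    spec.name = spec.name or "extraction_sweep"
    return _sweep(spec, 1000, [{"ex_e": e} for e in (0.30, 0.60, 1.00)])


def run_combined_sweep(spec: ExperimentSpec) -> tuple[pd.DataFrame, dict]:
    """Joint (ex_e, pcr_a) grid at pcr_e = 0.90, 30 cycles; 250 samples."""
    spec.name = spec.name or "combined_sweep"
    conds = [
        {"ex_e": e, "pcr_a": a, "pcr_e": 0.90}
        for e, a in itertools.product((0.30, 1.00), (0.05, 0.35, 1.00))
    ]
    return _sweep(spec, 250, conds, pcr_c=30)


def run_dilution_vs_stain(spec: ExperimentSpec) -> tuple[pd.DataFrame, dict]:
    """Serial dilution versus crime-stain simulation.

    The dilution arm starts from a concentrated stock (57 ng/µl, 450 µl
    transfer volumes, so ~3.9e6 copies per allele), halves it nine times
    by binomial thinning, and pipettes a fixed fraction of each level
    into PCR so the mean amounts span 845 down to 1.65 pg.  Crime-stain
    arms draw Poisson cell counts targeting the same amounts (diploid
    0.25–128 cells, haploid 0.5–256 at 6.6 pg per diploid cell) under
    four (ex_e, pcr_a) settings.  All arms use pcr_e = 0.90, 28 cycles,
    ce_a = 1, a 3500xL-calibrated CE and LDT = 200 RFU; Hb is scored on
    peak heights.  1000 replicates per arm by default.
    """
    spec.name = spec.name or "dilution_vs_stain"
    kit = spec.resolved_kit()
    reps = spec.n_reps(1000)
    ce = CEParams.calibration_3500xl(ldt=200.0)
    n_levels = 10
    amounts = [845.0 / 2**k for k in range(n_levels)]

    stock_ng_ul, transfer_ul = 57.0, 450.0
    stock_copies = int(round(stock_ng_ul * transfer_ul * 1000.0 / PG_PER_DIPLOID_CELL))
    pipette_fraction = (amounts[0] / PG_PER_DIPLOID_CELL) / stock_copies

    geno_rng = sample_rng(spec.seed, 2**20)
    geno_d = random_genotype(kit, geno_rng, heterozygous_only=True, ploidy="diploid")
    geno_h = random_genotype(kit, geno_rng, heterozygous_only=True, ploidy="haploid")

    rows: list[dict] = []
    stream = 0

    # Dilution arm: one replicate = one full dilution chain.
    for rep in range(reps):
        rng = sample_rng(spec.seed, stream)
        stream += 1
        table = sample_cells(stock_copies, geno_d, kit, rng, mode="fixed")
        for level, amount in enumerate(amounts):
            if level > 0:
                table = binomial_thin(table, 0.5, "sampled", rng)
            pcr_in = binomial_thin(table, pipette_fraction, "aliquoted", rng)
            amplified = pcr_amplify(pcr_in, 28, 0.90, 0.0, kit, rng)
            epg, _ = ce_detect(amplified, ce, rng, ce_a=1.0, genotype=geno_d)
            tags = {"arm": "dilution", "ex_e": np.nan, "pcr_a": np.nan,
                    "amount_pg": amount, "replicate": rep}
            rows.extend(_hb_rows(epg, kit, tags))

    # Crime-stain arms.
    settings = list(itertools.product((0.30, 1.00), (0.35, 1.00)))
    for ploidy, geno, pg_cell in (
        ("diploid", geno_d, PG_PER_DIPLOID_CELL),
        ("haploid", geno_h, PG_PER_DIPLOID_CELL / 2),
    ):
        for ex_e, pcr_a in settings:
            params = ProcessParams(
                extraction_efficiency=ex_e,
                pcr_aliquot=pcr_a,
                pcr_cycles=28,
                pcr_efficiency=0.90,
                ce_aliquot=1.0,
            )
            for amount in amounts:
                # Target cells in the stain so that the PCR-reaction mean
                # amount matches the dilution arm's.
                cells = amount / pg_cell / (ex_e * pcr_a)
                for rep in range(reps):
                    rng = sample_rng(spec.seed, stream)
                    stream += 1
                    epg, _ = simulate_sample(geno, params, ce, kit, rng, cells, mode="poisson")
                    tags = {"arm": f"stain_{ploidy}", "ex_e": ex_e, "pcr_a": pcr_a,
                            "amount_pg": amount, "replicate": rep}
                    rows.extend(_hb_rows(epg, kit, tags))

    manifest = {
        "experiment": spec.name, "seed": spec.seed, "replicates": reps,
        "kit": kit.name, "n_loci": len(kit), "amounts_pg": amounts,
        "stock_copies": stock_copies, "pipette_fraction": pipette_fraction,
        "stain_settings": settings, "pcr": {"cycles": 28, "efficiency": 0.90},
        "ce": "3500xL", "ldt": 200.0,
    }
    return pd.DataFrame(rows), manifest


def run_degradation_demo(spec: ExperimentSpec, p_deg: float = 0.0099) -> tuple[pd.DataFrame, dict]:
    """Degraded-fragment survival demonstration.

    1000 draws of Binomial(167, P(intact)) per fragment size, for a
    300 bp fragment (P(intact) ≈ 0.05 — often too few survivors to
    trigger a signal) and a 100 bp fragment (P(intact) ≈ 0.37); 167
    copies correspond to 1 ng of DNA in haploid genome equivalents.
    """
    from .degradation import p_intact

    spec.name = spec.name or "degradation_demo"
    reps = spec.n_reps(1000)
    n_copies = 167
    rows = []
    for i, size in enumerate((300, 100)):
        rng = sample_rng(spec.seed, i)
        p = p_intact(p_deg, size)
        draws = rng.binomial(n_copies, p, size=reps)
        rows.append(
            pd.DataFrame({"size_bp": size, "p_intact": p, "replicate": np.arange(reps), "intact": draws})
        )
    manifest = {
        "experiment": spec.name, "seed": spec.seed, "replicates": reps,
        "n_copies": n_copies, "p_deg": p_deg, "sizes_bp": [300, 100],
    }
    return pd.concat(rows, ignore_index=True), manifest


def run_hb_vs_amount(
    spec: ExperimentSpec,
    amounts_pg: Sequence[float] = (2.4, 19.5, 31.7, 63.3),
) -> tuple[pd.DataFrame, dict]:
    """Hb versus DNA amount with stutter and a calibrated instrument.

    One-tube extraction (ex_e = 1), pcr_a = 0.05, 30–35 cycles (cycled
    per replicate, observations pooled per amount), pcr_e = 0.90,
    stutter_p = 0.005, 3130xL calibration, LDT = 50 RFU.  Amounts are
    mean pg of DNA in the PCR reaction; cell targets are Poisson.
    Stutter-pair exclusion and the 10,000-RFU saturation filter are
    applied.  50 samples per amount by default (200 total).
    """
    spec.name = spec.name or "hb_vs_amount"
    kit = spec.resolved_kit()
    reps = spec.n_reps(50)
    ce = CEParams.calibration_3130xl(ldt=50.0)
    geno_rng = sample_rng(spec.seed, 2**20)
    geno = random_genotype(kit, geno_rng, heterozygous_only=True, ploidy="diploid")
    pcr_a = 0.05
    cycles = (30, 31, 32, 33, 34, 35)
    rows: list[dict] = []
    stream = 0
    for amount in amounts_pg:
        cells = amount / PG_PER_DIPLOID_CELL / pcr_a  # mean cells in the extract
        for rep in range(reps):
            rng = sample_rng(spec.seed, stream)
            stream += 1
            params = ProcessParams(
                extraction_efficiency=1.0,
                pcr_aliquot=pcr_a,
                pcr_cycles=cycles[rep % len(cycles)],
                pcr_efficiency=0.90,
                stutter_probability=0.005,
                ce_aliquot=1.0,
            )
            epg, _ = simulate_sample(geno, params, ce, kit, rng, cells, mode="poisson")
            tags = {"amount_pg": amount, "pcr_c": params.pcr_cycles, "replicate": rep}
            rows.extend(_hb_rows(epg, kit, tags, use_filters=True))
    manifest = {
        "experiment": spec.name, "seed": spec.seed, "replicates_per_amount": reps,
        "amounts_pg": list(amounts_pg), "kit": kit.name, "n_loci": len(kit),
        "pcr": {"aliquot": pcr_a, "cycles": list(cycles), "efficiency": 0.90, "stutter_p": 0.005},
        "ce": "3130xL", "ldt": 50.0, "saturation_rfu": 10_000.0,
    }
    return pd.DataFrame(rows), manifest


def rank_compare(x: Iterable[float], y: Iterable[float]) -> float:
    """Two-sided Mann-Whitney rank test p-value on |log10 Hb|.

    The magnitude of log-balance is compared (Hb and 1/Hb are equally
    imbalanced), dropping non-finite values; used to make "practically
    identical" / "clearly different" distribution claims assertable at a
    fixed significance level.
    """
    fx = np.abs(np.log10(np.asarray([v for v in x if np.isfinite(v) and v > 0])))
    fy = np.abs(np.log10(np.asarray([v for v in y if np.isfinite(v) and v > 0])))
    if len(fx) == 0 or len(fy) == 0:
        return np.nan
    return float(stats.mannwhitneyu(fx, fy, alternative="two-sided").pvalue)


EXPERIMENTS = {
    "efficiency": run_efficiency_sweep,
    "aliquot": run_aliquot_sweep,
    "extraction": run_extraction_sweep,
    "combined": run_combined_sweep,
    "dilution-vs-stain": run_dilution_vs_stain,
    "degradation-demo": run_degradation_demo,
    "hb-vs-amount": run_hb_vs_amount,
}
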