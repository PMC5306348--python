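"""Stage operators of the whole-process STR simulation.

Every lossy laboratory step (extraction, PCR aliquot, CE aliquot) is a
binomial selection of molecules; PCR is a per-cycle branching process in
which each template independently yields an allele copy, a stutter copy
one repeat unit shorter, or nothing; degradation thins post-PCR counts by
the length-dependent intact probability ``(1 - p_deg)^x``; and CE
detection converts surviving molecule counts into peaks.

The composition, :func:`simulate_sample`, records a :class:`StageTrace`
of every intermediate :class:`~strsim.core.MoleculeTable`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    CEParams,
    ConfigError,
    EPG,
    Fragment,
    Genotype,
    KitDef,
    MoleculeTable,
    Peak,
    ProcessParams,
)
from .degradation import p_intact

__all__ = [
    "StageTrace",
    "sample_cells",
    "binomial_thin",
    "pcr_amplify",
    "apply_degradation",
    "ce_detect",
    "simulate_sample",
]


@dataclass
class StageTrace:
    """Ordered molecule-table snapshots for one simulated sample."""

    tables: list[MoleculeTable] = field(default_factory=list)

    def append(self, table: MoleculeTable) -> None:
        self.tables.append(table)

    def stage(self, label: str) -> MoleculeTable:
        for t in self.tables:
            if t.stage == label:
                return t
        raise KeyError(label)

    @property
    def stages(self) -> list[str]:
        return [t.stage for t in self.tables]


def sample_cells(
    target: float,
    genotype: Genotype,
    kit: KitDef,
    rng: np.random.Generator,
    mode: str = "fixed",
) -> MoleculeTable:
    """Sample cells into the reaction tube.

    ``mode="fixed"`` requires an integer ``target`` and deposits exactly
    that many cells; ``mode="poisson"`` draws the cell count from
    Poisson(``target``), the natural model for crime stains with a
    fractional mean number of cells.

    Each diploid cell contributes one molecule of every allele at every
    locus.  Each haploid cell carries only one allele per locus, chosen
    with probability 1/2 independently per cell and locus, so the per-locus
    split of n cells over a heterozygote (a, b) is Binomial(n, 1/2).
    """
    if target < 0:
        raise ConfigError(f"target cell count must be >= 0, got {target!r}")
    if mode == "fixed":
        if int(target) != target:
            raise ConfigError("fixed mode requires an integer target cell count")
        n_cells = int(target)
    elif mode == "poisson":
        n_cells = int(rng.poisson(target))
    else:
        raise ConfigError(f"mode must be fixed|poisson, got {mode!r}")

    counts: dict[Fragment, int] = {}
    for locus in kit:
        pair = genotype.alleles[locus.name]
        if genotype.ploidy == "diploid":
            if len(pair) == 2:
                per_allele = {pair[0]: n_cells, pair[1]: n_cells}
            else:
                # Homozygote: both copies pool into one fragment identity.
                per_allele = {pair[0]: 2 * n_cells}
        else:
            if len(pair) == 2:
                a_count = int(rng.binomial(n_cells, 0.5)) if n_cells else 0
                per_allele = {pair[0]: a_count, pair[1]: n_cells - a_count}
            else:
                per_allele = {pair[0]: n_cells}
        for allele, n in per_allele.items():
            if n > 0:
                frag = Fragment(locus.name, allele, 0, locus.size_of(allele))
                counts[frag] = n
    return MoleculeTable(stage="sampled", counts=counts)


def binomial_thin(
    table: MoleculeTable,
    p: float,
    new_stage: str,
    rng: np.random.Generator,
) -> MoleculeTable:
    """Binomially select each molecule with probability ``p``.

    Models any step where each molecule independently survives a transfer:
    extraction (p = ex_e), PCR aliquot (p = pcr_a), CE aliquot (p = ce_a).
    """
    if not (0.0 <= p <= 1.0):
        raise ConfigError(f"selection probability must be in [0, 1], got {p!r}")
    if p == 1.0:
        return table.with_counts(new_stage, dict(table.counts))
    frags = list(table.counts)
    ns = np.fromiter((table.counts[f] for f in frags), dtype=np.int64, count=len(frags))
    kept = rng.binomial(ns, p) if len(frags) else np.empty(0, dtype=np.int64)
    return table.with_counts(new_stage, {f: int(k) for f, k in zip(frags, kept)})


def pcr_amplify(
    table: MoleculeTable,
    pcr_c: int,
    pcr_e: float,
    stutter_p: float,
    kit: KitDef,
    rng: np.random.Generator,
    new_stage: str = "amplified",
) -> MoleculeTable:
    """Per-cycle branching-process PCR with multinomial stutter.

    In every cycle each template molecule independently produces one
    correct copy with probability ``pcr_e * (1 - stutter_p)``, one stutter
    copy one repeat unit shorter with probability ``pcr_e * stutter_p``,
    and nothing otherwise.  Templates persist, and all products (stutter
    included) serve as templates in later cycles, so double-stutter
    (two repeats down) is possible with probability ~``stutter_p**2``.

    The expected yield after c cycles is ``N * (1 + pcr_e)^c`` when
    stutter is off.
    """
    if not (0.0 <= pcr_e <= 1.0):
        raise ConfigError(f"pcr_e must be in [0, 1], got {pcr_e!r}")
    if not (0.0 <= stutter_p <= 1.0):
        raise ConfigError(f"stutter_p must be in [0, 1], got {stutter_p!r}")
    if int(pcr_c) != pcr_c or pcr_c < 0:
        raise ConfigError(f"pcr_c must be a non-negative integer, got {pcr_c!r}")

    counts: dict[Fragment, int] = dict(table.counts)
    repeat_of = {locus.name: locus.repeat_bp for locus in kit}
    for _ in range(int(pcr_c)):
        frags = list(counts)
        if not frags:
            break
        ns = np.fromiter((counts[f] for f in frags), dtype=np.int64, count=len(frags))
        copied = rng.binomial(ns, pcr_e)
        stutters = rng.binomial(copied, stutter_p) if stutter_p > 0 else np.zeros_like(copied)
        for f, n_copy, n_stut in zip(frags, copied, stutters):
            counts[f] = counts[f] + int(n_copy) - int(n_stut)
            if n_stut > 0:
                child_size = f.size_bp - repeat_of[f.locus]
                if child_size <= 0:
                    continue  # cannot stutter below zero length
                child = Fragment(f.locus, f.allele, f.stutter + 1, child_size)
                counts[child] = counts.get(child, 0) + int(n_stut)
    return table.with_counts(new_stage, counts)


def apply_degradation(
    table: MoleculeTable,
    p_deg: float,
    kit: KitDef,
    rng: np.random.Generator,
    new_stage: str = "degraded",
) -> MoleculeTable:
    """Thin each fragment by its length-dependent intact probability.

    A fragment of x bases survives with probability ``(1 - p_deg)^x``
    (one cleavage anywhere destroys it); stutter fragments use their own,
    shorter length.  Applied post-PCR by default in
    :func:`simulate_sample`, mirroring the thinning
    ``N_intact = Bin(N_molecules, P(!drop))`` of the degradation model.
    """
    if not (0.0 <= p_deg < 1.0):
        raise ConfigError(f"p_deg must be in [0, 1), got {p_deg!r}")
    if p_deg == 0.0:
        return table.with_counts(new_stage, dict(table.counts))
    frags = list(table.counts)
    out: dict[Fragment, int] = {}
    for f in frags:
        surv = p_intact(p_deg, f.size_bp)
        out[f] = int(rng.binomial(table.counts[f], surv))
    return table.with_counts(new_stage, out)


def _merge_by_size(table: MoleculeTable) -> dict[tuple[str, int], dict]:
    """Pool fragments co-migrating at the same (locus, size) into one peak.

    A stutter product that lands on another true allele's position merges
    into that allele's peak (the physical reality behind stutter-pair
    filtering in balance statistics).
    """
    merged: dict[tuple[str, int], dict] = {}
    for f, n in table.counts.items():
        key = (f.locus, f.size_bp)
        slot = merged.setdefault(key, {"molecules": 0, "allele": None, "pure_stutter": True})
        slot["molecules"] += n
        if not f.is_stutter:
            slot["allele"] = f.allele
            slot["pure_stutter"] = False
        elif slot["allele"] is None:
            slot["allele"] = f"{f.allele}{'-' * f.stutter}"
    return merged


def ce_detect(
    table: MoleculeTable,
    ce: CEParams,
    rng: np.random.Generator,
    ce_a: float = 1.0,
    genotype: Genotype | None = None,
    params: dict | None = None,
) -> tuple[EPG, MoleculeTable]:
    """Capillary-electrophoresis injection and detection.

    First a CE aliquot (binomial thinning by ``ce_a``), then per-peak
    detection.  Identity mode: height equals molecule count and the
    trigger threshold is zero.  Calibrated mode: a peak of N molecules
    triggers when ``ln N`` exceeds the calibrated threshold (Gaussian
    jitter ``threshold_sigma``), and its height is log-log linear in N
    with residual scatter ``scaling_sigma``.  Any peak below ``ldt`` RFU
    is marked not detected.  N = 0 yields no peak at all (drop-out).

    Returns the EPG and the post-aliquot ("injected") molecule table.
    """
    injected = binomial_thin(table, ce_a, "injected", rng)
    peaks: list[Peak] = []
    for (locus, size), slot in sorted(_merge_by_size(injected).items()):
        n = slot["molecules"]
        if n <= 0:
            continue
        if ce.identity_mode:
            height = float(n)
            detected = height >= ce.ldt
        else:
            log_n = np.log(n)
            trigger_level = (
                ce.threshold_intercept
                + ce.threshold_slope * np.log(ce.h0)
                + (rng.normal(0.0, ce.threshold_sigma) if ce.threshold_sigma > 0 else 0.0)
            )
            if log_n < trigger_level:
                height, detected = 0.0, False
            else:
                log_h = (
                    ce.scaling_intercept
                    + ce.scaling_slope * log_n
                    + (rng.normal(0.0, ce.scaling_sigma) if ce.scaling_sigma > 0 else 0.0)
                )
                height = float(np.exp(log_h))
                detected = height >= ce.ldt
        peaks.append(
            Peak(
                locus=locus,
                allele=slot["allele"],
                size_bp=size,
                molecules=int(n),
                height=height,
                detected=detected,
                is_stutter=slot["pure_stutter"],
            )
        )
    epg = EPG(peaks=peaks, genotype=genotype, params=params or {})
    return epg, injected


def simulate_sample(
    genotype: Genotype,
    params: ProcessParams,
    ce: CEParams,
    kit: KitDef,
    rng: np.random.Generator,
    target_cells: float,
    mode: str = "fixed",
    p_deg: float = 0.0,
    degrade_pre_pcr: bool = False,
) -> tuple[EPG, StageTrace]:
    """Run one sample through the full pipeline.

    Stages: cell sampling → extraction thinning (ex_e) → PCR-aliquot
    thinning (pcr_a) → per-cycle PCR with stutter → degradation thinning →
    CE aliquot and detection.  Degradation is applied post-PCR by default
    (set ``degrade_pre_pcr`` to thin templates before amplification
    instead, the physically earlier but non-default placement).
    """
    trace = StageTrace()
    t = sample_cells(target_cells, genotype, kit, rng, mode=mode)
    trace.append(t)
    t = binomial_thin(t, params.extraction_efficiency, "extracted", rng)
    trace.append(t)
    t = binomial_thin(t, params.pcr_aliquot, "aliquoted", rng)
    trace.append(t)
    if degrade_pre_pcr and p_deg > 0:
        t = apply_degradation(t, p_deg, kit, rng, new_stage="aliquoted_degraded")
        trace.append(t)
    t = pcr_amplify(
        t, params.pcr_cycles, params.pcr_efficiency, params.stutter_probability, kit, rng
    )
    trace.append(t)
    if not degrade_pre_pcr:
        t = apply_degradation(t, p_deg, kit, rng)
        trace.append(t)
    run_params = {
        "process": params,
        "ce": ce,
        "p_deg": p_deg,
        "target_cells": target_cells,
        "mode": mode,
        "degrade_pre_pcr": degrade_pre_pcr,
    }
    epg, injected = ce_detect(t, ce, rng, ce_a=params.ce_aliquot, genotype=genotype, params=run_params)
    trace.append(injected)
    return epg, trace
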