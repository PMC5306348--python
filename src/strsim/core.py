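"""Domain types shared by the STR-process simulator.

Forensic STR profiling turns a handful of cells into an electropherogram
(EPG) through a chain of lossy, stochastic steps: cell sampling, DNA
extraction, transfer of an aliquot to PCR, cyclic amplification (with
stutter artefacts), optional degradation, and capillary-electrophoresis
(CE) detection.  The types here carry the state of that chain:

* :class:`ProcessParams` / :class:`CEParams` — the tunable step parameters.
* :class:`LocusDef` / :class:`KitDef` — an STR typing panel mapping allele
  designations to fragment lengths in base pairs.
* :class:`Genotype` — the donor's allele pair per locus (diploid or haploid).
* :class:`MoleculeTable` — per-fragment molecule counts at a named stage.
* :class:`Peak` / :class:`EPG` — the detected signal.

All physics keys off fragment length in base pairs; allele designations are
opaque labels.  Randomness flows through numpy Generators; per-sample
substreams are derived deterministically from a master seed so that any run
is bit-reproducible under a fixed (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ProcessParams",
    "CEParams",
    "LocusDef",
    "KitDef",
    "Genotype",
    "Fragment",
    "MoleculeTable",
    "Peak",
    "EPG",
    "ConfigError",
    "sample_rng",
    "make_fixture_kit",
    "random_genotype",
    "STAGES",
]

#: Pipeline stage labels in order.
STAGES = ("sampled", "extracted", "aliquoted", "amplified", "degraded", "injected")

DYES = ("blue", "green", "yellow", "red")


class ConfigError(ValueError):
    """Raised for parameter or configuration values outside their domain."""


def _check_prob(name: str, value: float) -> float:
    if not (0.0 <= value <= 1.0):
        raise ConfigError(f"{name} must be in [0, 1], got {value!r}")
    return float(value)


@dataclass(frozen=True)
class ProcessParams:
    """Pre-CE stochastic process parameters.

    Parameters
    ----------
    extraction_efficiency : float
        Probability that a given DNA molecule survives extraction (``ex_e``).
    pcr_aliquot : float
        Fraction of the extract transferred to the PCR tube (``pcr_a``);
        equivalently the per-molecule selection probability.
    pcr_cycles : int
        Number of PCR cycles (``pcr_c``).
    pcr_efficiency : float
        Per-cycle probability that a template molecule is copied (``pcr_e``).
    stutter_probability : float
        Conditional on being copied, the probability that the copy is a
        stutter product one repeat unit shorter (``stutter_p``).
    ce_aliquot : float
        Fraction of PCR product transferred to the CE injection plate
        (``ce_a``).
    """

    extraction_efficiency: float = 1.0
    pcr_aliquot: float = 1.0
    pcr_cycles: int = 28
    pcr_efficiency: float = 0.90
    stutter_probability: float = 0.0
    ce_aliquot: float = 1.0

    def __post_init__(self) -> None:
        _check_prob("extraction_efficiency", self.extraction_efficiency)
        _check_prob("pcr_aliquot", self.pcr_aliquot)
        _check_prob("pcr_efficiency", self.pcr_efficiency)
        _check_prob("stutter_probability", self.stutter_probability)
        _check_prob("ce_aliquot", self.ce_aliquot)
        if int(self.pcr_cycles) != self.pcr_cycles or self.pcr_cycles < 0:
            raise ConfigError(f"pcr_cycles must be a non-negative integer, got {self.pcr_cycles!r}")


@dataclass(frozen=True)
class CEParams:
    """Capillary-electrophoresis detection and peak-height calibration.

    In ``identity_mode`` the peak height equals the molecule count exactly
    and the trigger threshold is zero — the convention used to study
    molecule-level balance without instrument effects.

    In calibrated mode both the trigger threshold and the height scaling
    are log-log linear with additive Gaussian error on the log scale:
    a peak of N molecules triggers when ``ln N >= threshold_intercept +
    threshold_slope * ln(h0) + eps_T`` (``h0`` = 1 RFU reference, ``eps_T ~
    N(0, threshold_sigma^2)``) and its height satisfies ``ln h =
    scaling_intercept + scaling_slope * ln N + eps_S``.  Peaks below the
    limit-of-detection threshold ``ldt`` (RFU) are marked not detected.
    """

    threshold_intercept: float = 0.0
    threshold_slope: float = 0.0
    threshold_sigma: float = 0.0
    scaling_intercept: float = 0.0
    scaling_slope: float = 1.0
    scaling_sigma: float = 0.0
    ldt: float = 0.0
    identity_mode: bool = True
    h0: float = 1.0

    def __post_init__(self) -> None:
        if self.threshold_sigma < 0 or self.scaling_sigma < 0:
            raise ConfigError("sigma values must be >= 0")
        if self.ldt < 0:
            raise ConfigError("ldt must be >= 0")

    @classmethod
    def identity(cls, ldt: float = 0.0) -> "CEParams":
        """Molecule-count identity detection (threshold 0, height = count)."""
        return cls(identity_mode=True, ldt=ldt)

    @classmethod
    def calibration_3500xl(cls, ldt: float = 200.0) -> "CEParams":
        """Calibration constants for a 3500xL-class instrument."""
        return cls(
            threshold_intercept=14.03744,
            threshold_slope=0.82254,
            threshold_sigma=0.1319579,
            scaling_intercept=-14.38233,
            scaling_slope=1.173163,
            scaling_sigma=0.0,
            ldt=ldt,
            identity_mode=False,
        )

    @classmethod
    def calibration_3130xl(cls, ldt: float = 50.0) -> "CEParams":
        """Calibration constants for a 3130xL-class instrument."""
        return cls(
            threshold_intercept=15.4653,
            threshold_slope=0.9044,
            threshold_sigma=0.364,
            scaling_intercept=-13.66131,
            scaling_slope=1.0047,
            scaling_sigma=0.3836,
            ldt=ldt,
            identity_mode=False,
        )


@dataclass(frozen=True)
class LocusDef:
    """One STR locus: dye label, repeat-unit length, allele→size map."""

    name: str
    dye: str
    repeat_bp: int
    alleles: Mapping[str, int]  # designation -> fragment length (bp)

    def __post_init__(self) -> None:
        if self.repeat_bp <= 0:
            raise ConfigError(f"repeat_bp must be positive at locus {self.name}")
        if not self.alleles:
            raise ConfigError(f"locus {self.name} has no alleles")
        for a, size in self.alleles.items():
            if size <= 0:
                raise ConfigError(f"allele {a} at locus {self.name} has non-positive size")

    def size_of(self, allele: str) -> int:
        return self.alleles[allele]


@dataclass(frozen=True)
class KitDef:
    """Ordered collection of loci forming a typing kit/panel."""

    name: str
    loci: tuple[LocusDef, ...]

    def __post_init__(self) -> None:
        if not self.loci:
            raise ConfigError("kit must contain at least one locus")
        names = [l.name for l in self.loci]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate locus names in kit")

    def __iter__(self) -> Iterator[LocusDef]:
        return iter(self.loci)

    def __len__(self) -> int:
        return len(self.loci)

    def locus(self, name: str) -> LocusDef:
        for l in self.loci:
            if l.name == name:
                return l
        raise KeyError(name)

    @property
    def locus_names(self) -> tuple[str, ...]:
        return tuple(l.name for l in self.loci)


@dataclass(frozen=True)
class Genotype:
    """Per-locus allele pair of a contributor.

    ``alleles[locus]`` is a tuple of one (homozygote) or two (heterozygote)
    allele designations.  ``ploidy`` is ``"diploid"`` or ``"haploid"``;
    haploid cells carry a single allele per locus per cell.
    """

    alleles: Mapping[str, tuple[str, ...]]
    ploidy: str = "diploid"

    def __post_init__(self) -> None:
        if self.ploidy not in ("diploid", "haploid"):
            raise ConfigError(f"ploidy must be diploid|haploid, got {self.ploidy!r}")
        for locus, pair in self.alleles.items():
            if len(pair) not in (1, 2):
                raise ConfigError(f"locus {locus} must carry 1 or 2 alleles")
            if len(pair) == 2 and pair[0] == pair[1]:
                raise ConfigError(f"heterozygote alleles must be distinct at {locus}")

    def is_heterozygous(self, locus: str) -> bool:
        return len(self.alleles[locus]) == 2


@dataclass(frozen=True)
class Fragment:
    """Identity of a simulated DNA fragment.

    ``stutter`` counts repeat units lost relative to the parent allele
    (0 = true allele, 1 = back-stutter, ...); ``size_bp`` is the physical
    fragment length that degradation acts on.
    """

    locus: str
    allele: str
    stutter: int
    size_bp: int

    @property
    def is_stutter(self) -> bool:
        return self.stutter > 0


@dataclass
class MoleculeTable:
    """Per-fragment molecule counts at one named pipeline stage."""

    stage: str
    counts: dict[Fragment, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for frag, n in self.counts.items():
            if n < 0 or int(n) != n:
                raise ValueError(f"count for {frag} must be a non-negative integer")

    def total(self) -> int:
        return int(sum(self.counts.values()))

    def count(self, locus: str, allele: str, stutter: int = 0) -> int:
        for frag, n in self.counts.items():
            if frag.locus == locus and frag.allele == allele and frag.stutter == stutter:
                return n
        return 0

    def with_counts(self, stage: str, counts: dict[Fragment, int]) -> "MoleculeTable":
        """New table at ``stage``; zero-count fragments are dropped."""
        return MoleculeTable(stage=stage, counts={f: int(n) for f, n in counts.items() if n > 0})

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "stage": self.stage,
                "locus": f.locus,
                "allele": f.allele,
                "is_stutter": f.is_stutter,
                "stutter_steps": f.stutter,
                "size_bp": f.size_bp,
                "molecules": n,
            }
            for f, n in sorted(self.counts.items(), key=lambda kv: (kv[0].locus, kv[0].size_bp))
        ]
        return pd.DataFrame(
            rows,
            columns=["stage", "locus", "allele", "is_stutter", "stutter_steps", "size_bp", "molecules"],
        )


@dataclass(frozen=True)
class Peak:
    """One EPG peak (possibly sub-threshold, then ``detected`` is False)."""

    locus: str
    allele: str
    size_bp: int
    molecules: int
    height: float
    detected: bool
    is_stutter: bool

    def __post_init__(self) -> None:
        if self.height < 0:
            raise ValueError("peak height must be >= 0")


@dataclass
class EPG:
    """Electropherogram of one simulated sample."""

    peaks: list[Peak]
    genotype: Genotype
    params: dict = field(default_factory=dict)

    def detected(self) -> list[Peak]:
        return [p for p in self.peaks if p.detected]

    def to_frame(self, sample_id: str = "s1") -> pd.DataFrame:
        rows = [
            {
                "sample_id": sample_id,
                "locus": p.locus,
                "allele": p.allele,
                "is_stutter": p.is_stutter,
                "size_bp": p.size_bp,
                "molecules": p.molecules,
                "height_rfu": p.height,
                "detected": p.detected,
            }
            for p in sorted(self.peaks, key=lambda q: (q.locus, q.size_bp))
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "sample_id", "locus", "allele", "is_stutter",
                "size_bp", "molecules", "height_rfu", "detected",
            ],
        )


def sample_rng(seed: int, index: int = 0) -> np.random.Generator:
    """Deterministic per-sample random stream.

    Stream ``index`` under master ``seed`` is independent of every other
    index, and identical (seed, index) pairs always yield the same stream.
    """
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(int(index),)))


def make_fixture_kit(
    n_loci: int,
    size_range: tuple[int, int] = (70, 450),
    n_alleles: int = 10,
    repeat_bp: int = 4,
    name: str = "fixture",
) -> KitDef:
    """Deterministic synthetic STR kit emulating a modern 16–17-locus panel.

    Loci are spread evenly over ``size_range`` with ``n_alleles`` alleles
    each, one repeat unit (``repeat_bp``) apart, and assigned to dyes in
    contiguous blocks so loci are size-ordered within each dye.
    """
    lo, hi = size_range
    if n_loci < 1:
        raise ConfigError("n_loci must be >= 1")
    if n_alleles < 8:
        raise ConfigError("n_alleles must be >= 8")
    if not (50 <= lo <= hi <= 500):
        raise ConfigError(f"size_range must satisfy 50 <= lo <= hi <= 500, got {size_range!r}")

    span = (n_alleles - 1) * repeat_bp
    usable = hi - lo - span
    if usable < 0:
        # Degenerate narrow range: stack all loci at the range start.
        bases = [lo] * n_loci
    elif n_loci == 1:
        bases = [lo]
    else:
        bases = [round(lo + i * usable / (n_loci - 1)) for i in range(n_loci)]

    per_dye = -(-n_loci // len(DYES))  # ceil
    loci = []
    for i, base in enumerate(bases):
        alleles = {str(8 + j): base + j * repeat_bp for j in range(n_alleles)}
        loci.append(
            LocusDef(
                name=f"L{i + 1:02d}",
                dye=DYES[i // per_dye],
                repeat_bp=repeat_bp,
                alleles=alleles,
            )
        )
    return KitDef(name=name, loci=tuple(loci))


def random_genotype(
    kit: KitDef,
    rng: np.random.Generator,
    heterozygous_only: bool = True,
    ploidy: str = "diploid",
) -> Genotype:
    """Draw one genotype uniformly from the kit's allele ranges.

    With ``heterozygous_only`` the two designations differ at every locus
    (required wherever heterozygote balance is scored).
    """
    alleles: dict[str, tuple[str, ...]] = {}
    for locus in kit:
        designations = list(locus.alleles)
        if heterozygous_only:
            if len(designations) < 2:
                raise ConfigError(f"locus {locus.name} has < 2 alleles; cannot be heterozygous")
            pair = rng.choice(len(designations), size=2, replace=False)
            alleles[locus.name] = (designations[int(pair[0])], designations[int(pair[1])])
        else:
            pair = rng.integers(0, len(designations), size=2)
            if pair[0] == pair[1]:
                alleles[locus.name] = (designations[int(pair[0])],)
            else:
                alleles[locus.name] = (designations[int(pair[0])], designations[int(pair[1])])
    return Genotype(alleles=alleles, ploidy=ploidy)
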