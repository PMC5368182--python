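"""Seeded synthetic-data generators emulating every input the pipeline reads.

Four generators mirror the wet-lab inputs of an intragenomic 16S rRNA
heterogeneity study:

* a multi-paralog 16S gene family with intact degenerate-primer binding
  sites, controlled thermometer-region GC content, and controlled divergence
  between paralogs;
* a qPCR plate (dilution-series standards plus unknown cDNA wells) generated
  from the log-linear standard-curve model Ct = intercept + slope *
  log10(copies) + N(0, sd);
* three-phase growth curves (flat lag, exponential growth at a set rate,
  logistic saturation) with multiplicative OD noise;
* OD/cell-count calibration pairs on a through-origin line with lognormal
  noise.

Every generator is deterministic for a given (config, seed): the same seed
reproduces byte-identical output.  Defaults reflect the H. hispanica study
design: three paralogs with region GC 58.9/56.5/56.4 %, a 3 technical x 4
biological qPCR replicate design with a 1/10..1/10000 dilution series and
0.15-cycle Ct noise, a 25-50 degC temperature grid with a 0.16/h optimum,
and a 2.1e9 cells/ml per OD660 conversion factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import GenerationError
from .growth import GrowthCurve
from .qpcr import QpcrPlate, QpcrWell
from .sequences import (
    CANONICAL_PRIMER_STARTS,
    DEFAULT_PRIMERS,
    IUPAC_SETS,
    Primer,
    SequenceRecord,
    reverse_complement,
)

# ---------------------------------------------------------------------------
# 16S paralog family


@dataclass(frozen=True)
class ParalogSpec:
    """One paralog: target thermometer-region GC (%) and divergence from the
    family template (substitutions per site, outside primer sites)."""

    label: str
    region_gc: float
    divergence: float

    def __post_init__(self) -> None:
        if not 0.0 < self.region_gc < 100.0:
            raise GenerationError(f"{self.label}: region_gc must be in (0, 100)")
        if not 0.0 <= self.divergence <= 0.2:
            raise GenerationError(f"{self.label}: divergence must be in [0, 0.2]")


@dataclass
class RrnFamilyConfig:
    """Configuration of a synthetic multi-paralog 16S family.

    ``primer_starts`` places each named default primer at a 1-based start on
    the template; sites must be ordered and non-overlapping.  The divergence
    defaults give a nearly identical rrsB/rrsC pair (~99.6 % identity) and a
    clearly divergent rrsA, with region GC values 58.9/56.5/56.4 %.
    """

    template_length: int = 1450
    primer_starts: dict[str, int] = field(
        default_factory=lambda: dict(CANONICAL_PRIMER_STARTS)
    )
    paralogs: tuple[ParalogSpec, ...] = (
        ParalogSpec("rrsA", 58.9, 0.054),
        ParalogSpec("rrsB", 56.5, 0.0),
        ParalogSpec("rrsC", 56.4, 0.004),
    )
    fill_gc: float = 57.0  # GC of the random fill outside targeted regions
    seed: int = 0

    def primer_site_spans(self) -> list[tuple[str, int, int]]:
        """(name, start0, end0) half-open 0-based spans, sorted by start."""
        spans = []
        for name, start in self.primer_starts.items():
            primer = DEFAULT_PRIMERS[name]
            spans.append((name, start - 1, start - 1 + len(primer)))
        spans.sort(key=lambda s: s[1])
        for (_, _, e1), (_, s2, _) in zip(spans, spans[1:]):
            if s2 < e1:
                raise GenerationError("primer sites overlap")
        if spans and spans[-1][2] > self.template_length:
            raise GenerationError("primer site extends past template end")
        return spans


def _concrete_expansion(primer: Primer, rng: np.random.Generator) -> str:
    """One unambiguous realisation of a degenerate primer, as it appears on
    the + strand of the template."""
    concrete = "".join(
        rng.choice(sorted(IUPAC_SETS[b])) for b in primer.sequence_5to3
    )
    return concrete if primer.orientation == "forward" else reverse_complement(concrete)


_GC_SWAP = {"A": "T", "T": "A", "G": "C", "C": "G"}
_AT_TO_GC = {"A": "G", "T": "C"}
_GC_TO_AT = {"G": "A", "C": "T"}


def _adjust_region_gc(
    bases: np.ndarray,
    region: tuple[int, int],
    frozen: np.ndarray,
    target_gc: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Flip free bases inside ``region`` (0-based half-open) until the region's
    G+C count equals round(target_gc/100 * length).  In-place; returns the
    flipped positions."""
    start, end = region
    length = end - start
    target_count = round(target_gc / 100.0 * length)
    idx = np.arange(start, end)
    is_gc = np.isin(bases[idx], list("GC"))
    current = int(is_gc.sum())
    free = ~frozen[idx]
    if current < target_count:
        candidates, table = idx[free & ~is_gc], _AT_TO_GC
        need = target_count - current
    elif current > target_count:
        candidates, table = idx[free & is_gc], _GC_TO_AT
        need = current - target_count
    else:
        return np.empty(0, dtype=int)
    if len(candidates) < need:
        raise GenerationError(
            f"target region GC {target_gc}% unreachable: only "
            f"{len(candidates)} adjustable bases for {need} required flips"
        )
    chosen = rng.choice(candidates, size=need, replace=False)
    for i in chosen:
        bases[i] = table[str(bases[i])]
    return chosen


def generate_rrn_family(config: RrnFamilyConfig) -> list[SequenceRecord]:
    """Generate a template-derived family of 16S paralog sequences.

    The template carries one concrete expansion of each configured primer at
    its configured site; its thermometer region (109aF start through 915aR
    end, primer sites included) is first set to the least-divergent paralog's
    GC target.  Each paralog is then derived by (a) GC-adjusting flips that
    bring its region to its own GC target and (b) GC-neutral substitutions
    (A<->T, G<->C) at further free positions, so that total substitutions vs
    the template equal round(divergence * length) and pairwise identities
    track the configured divergences.  Achieved region GC is exact to the
    nearest integer base count (within +/-0.07 points for a 795 bp region).
    """
    rng = np.random.default_rng(config.seed)
    spans = config.primer_site_spans()
    n = config.template_length

    p_gc = config.fill_gc / 100.0
    probs = [(1 - p_gc) / 2, p_gc / 2, p_gc / 2, (1 - p_gc) / 2]
    bases = rng.choice(list("AGCT"), size=n, p=probs)

    frozen = np.zeros(n, dtype=bool)
    for name, s, e in spans:
        expansion = _concrete_expansion(DEFAULT_PRIMERS[name], rng)
        bases[s:e] = list(expansion)
        frozen[s:e] = True

    if "109aF" not in config.primer_starts or "915aR" not in config.primer_starts:
        raise GenerationError("family config must place the 109aF and 915aR primers")
    region = (
        config.primer_starts["109aF"] - 1,
        config.primer_starts["915aR"] - 1 + len(DEFAULT_PRIMERS["915aR"]),
    )

    # Anchor the template's region GC at the least-divergent paralog's target
    # so that paralog-specific flips measure divergence, not fill noise.
    anchor = min(config.paralogs, key=lambda s: s.divergence)
    _adjust_region_gc(bases, region, frozen, anchor.region_gc, rng)

    free_idx = np.flatnonzero(~frozen)
    records = []
    for spec in config.paralogs:
        par = bases.copy()
        flipped = _adjust_region_gc(par, region, frozen, spec.region_gc, rng)
        n_sub = round(spec.divergence * n)
        extra = n_sub - len(flipped)
        if extra > 0:
            candidates = np.setdiff1d(free_idx, flipped)
            sites = rng.choice(candidates, size=extra, replace=False)
            for i in sites:
                par[i] = _GC_SWAP[str(par[i])]
        records.append(
            SequenceRecord(
                id=spec.label,
                residues="".join(par),
                description=f"synthetic 16S paralog, target region GC {spec.region_gc}%",
            )
        )
    return records


# ---------------------------------------------------------------------------
# qPCR plates


@dataclass
class QpcrSimConfig:
    """Configuration of a synthetic qPCR experiment at one temperature.

    Ct values follow the log-linear model Ct = intercept + slope *
    log10(copies) + N(0, ct_sd).  ``true_copies`` sets the relative template
    amount per target; the default rrsA:rrsBC quotient is 0.56, the ratio
    observed at the low end of the temperature range.  Standard wells hold
    ``standard_stock_copies`` times their dilution, so with the defaults the
    dilution series (1e6 .. 1e3 copies) brackets the unknowns and
    quantification interpolates rather than extrapolates.  The 35-cycle
    intercept is arbitrary plumbing (only differences in Ct matter).
    """

    true_copies: dict[str, float] = field(
        default_factory=lambda: {"rrsA": 5.6e5, "rrsBC": 1.0e6}
    )
    slope: float = -3.32
    intercept: float = 35.0
    ct_sd: float = 0.15
    tech_reps: int = 3
    bio_reps: int = 4
    dilutions: tuple[float, ...] = (1e-1, 1e-2, 1e-3, 1e-4)
    standard_stock_copies: float = 1e7
    temperature: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise GenerationError("standard-curve slope must be negative")
        if self.ct_sd < 0:
            raise GenerationError("Ct noise sd must be >= 0")


def generate_qpcr_experiment(config: QpcrSimConfig) -> QpcrPlate:
    """Simulate standards (dilution series) and unknown wells for each target.

    Standards span the configured dilution series with ``tech_reps`` wells
    each; unknowns cover ``bio_reps`` biological replicates x ``tech_reps``
    technical replicates per target.  Deterministic per seed.
    """
    rng = np.random.default_rng(config.seed)
    wells: list[QpcrWell] = []
    for target in sorted(config.true_copies):
        for dilution in config.dilutions:
            base_ct = config.intercept + config.slope * np.log10(
                config.standard_stock_copies * dilution
            )
            for tech in range(1, config.tech_reps + 1):
                wells.append(
                    QpcrWell(
                        target=target,
                        ct=float(base_ct + rng.normal(0.0, config.ct_sd)),
                        role="standard",
                        dilution=dilution,
                        temperature=config.temperature,
                        tech_rep=tech,
                    )
                )
    temp_label = "NA" if config.temperature is None else f"{config.temperature:g}"
    for bio in range(1, config.bio_reps + 1):
        for target in sorted(config.true_copies):
            base_ct = config.intercept + config.slope * np.log10(
                config.true_copies[target]
            )
            for tech in range(1, config.tech_reps + 1):
                wells.append(
                    QpcrWell(
                        target=target,
                        ct=float(base_ct + rng.normal(0.0, config.ct_sd)),
                        role="unknown",
                        sample_id=f"T{temp_label}_bio{bio}",
                        temperature=config.temperature,
                        tech_rep=tech,
                    )
                )
    return QpcrPlate(wells)


# ---------------------------------------------------------------------------
# Growth curves


@dataclass(frozen=True)
class TemperatureGrowthSpec:
    """True growth parameters at one culture temperature.

    Curves are flat during the lag, grow purely exponentially at ``mu`` until
    OD reaches ``sat_start_frac`` of the carrying capacity, then follow a
    logistic approach to capacity.  The pure-exponential window makes the
    interval growth-rate estimator exact on noiseless curves.
    """

    temperature: float
    mu: float  # exponential-phase specific growth rate, 1/h
    lag: float = 8.0  # h
    initial_od: float = 0.02
    capacity_od: float = 1.2
    sat_start_frac: float = 0.5

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise GenerationError("mu must be >= 0")
        if self.capacity_od <= self.initial_od:
            raise GenerationError("carrying capacity must exceed initial OD")
        if not 0.0 < self.sat_start_frac < 1.0:
            raise GenerationError("sat_start_frac must be in (0, 1)")


# Per-temperature growth-rate presets for the default 25-50 degC grid; the
# 45 degC optimum grows at 0.16/h, the observed wild-type maximum.
DEFAULT_GROWTH_SPECS: tuple[TemperatureGrowthSpec, ...] = (
    TemperatureGrowthSpec(25.0, 0.02),
    TemperatureGrowthSpec(30.0, 0.05),
    TemperatureGrowthSpec(35.0, 0.09),
    TemperatureGrowthSpec(40.0, 0.13),
    TemperatureGrowthSpec(45.0, 0.16),
    TemperatureGrowthSpec(50.0, 0.10),
)


@dataclass
class GrowthSimConfig:
    """Configuration of synthetic growth-curve experiments.

    Curves have a flat lag, exponential growth at the per-temperature rate,
    and logistic saturation toward the carrying capacity; observed OD is the
    true OD times a lognormal factor with sigma ``od_noise_sd`` (i.e. ~1 %
    multiplicative noise by default).  Sampling runs at ``sampling_interval``
    until the exponential phase would reach capacity, plus two extra points.
    """

    strain: str = "wild-type"
    specs: tuple[TemperatureGrowthSpec, ...] = DEFAULT_GROWTH_SPECS
    sampling_interval: float = 4.0  # h
    od_noise_sd: float = 0.01
    replicates: int = 4
    max_points: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.od_noise_sd < 0:
            raise GenerationError("OD noise sd must be >= 0")
        if self.sampling_interval <= 0:
            raise GenerationError("sampling interval must be positive")


def _true_od(spec: TemperatureGrowthSpec, t: float) -> float:
    """Lag / pure-exponential / logistic three-phase OD at time t."""
    if t <= spec.lag or spec.mu == 0:
        return spec.initial_od
    tau = t - spec.lag
    k, o = spec.capacity_od, spec.initial_od
    switch_od = spec.sat_start_frac * k
    tau_switch = np.log(switch_od / o) / spec.mu
    if tau <= tau_switch:
        return o * np.exp(spec.mu * tau)
    # logistic continuation seeded at the switch point (continuous join)
    g = np.exp(spec.mu * (tau - tau_switch))
    return k * switch_od * g / (k + switch_od * (g - 1.0))


def _sampling_times(spec: TemperatureGrowthSpec, config: GrowthSimConfig) -> np.ndarray:
    if spec.mu > 0:
        horizon = spec.lag + np.log(spec.capacity_od / spec.initial_od) / spec.mu
        horizon += 2 * config.sampling_interval
    else:
        horizon = 48.0
    n = min(int(horizon // config.sampling_interval) + 1, config.max_points)
    return np.arange(n) * config.sampling_interval


def generate_growth_curves(config: GrowthSimConfig) -> list[GrowthCurve]:
    """Simulate OD660 curves for each temperature x replicate; deterministic
    per seed."""
    rng = np.random.default_rng(config.seed)
    curves = []
    for spec in config.specs:
        times = _sampling_times(spec, config)
        for rep in range(1, config.replicates + 1):
            noise = np.exp(rng.normal(0.0, config.od_noise_sd, size=len(times)))
            obs = tuple(
                (float(t), float(_true_od(spec, t) * z)) for t, z in zip(times, noise)
            )
            curves.append(
                GrowthCurve(
                    strain=config.strain,
                    temperature=spec.temperature,
                    replicate=rep,
                    observations=obs,
                )
            )
    return curves


# ---------------------------------------------------------------------------
# OD / cell-count calibration pairs


def generate_od_count_pairs(
    factor: float = 2.1e9,
    n: int = 20,
    noise_cv: float = 0.05,
    seed: int = 0,
    od_range: tuple[float, float] = (0.05, 1.0),
) -> list[tuple[float, float]]:
    """(OD660, cells/ml) pairs on a through-origin line with multiplicative
    lognormal noise of coefficient of variation ~``noise_cv``."""
    if factor <= 0:
        raise GenerationError("factor must be positive")
    rng = np.random.default_rng(seed)
    od = rng.uniform(*od_range, size=n)
    counts = factor * od * np.exp(rng.normal(0.0, noise_cv, size=n))
    return [(float(o), float(c)) for o, c in zip(od, counts)]
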