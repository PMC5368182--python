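"""Standard-curve qPCR quantification and paralog expression-ratio analysis.

Absolute quantification: each target (here the divergent 16S paralog rrsA and
the near-identical pair rrsBC) gets a standard curve fitted from a serial
dilution of PCR product, Ct = slope * log10(concentration) + intercept.
Unknown wells are back-calculated through the curve, technical replicates are
averaged on the quantity scale, and the rrsA:rrsBC ratio is formed per
biological replicate before summarising across replicates.  Units of the
quantities are relative (dilutions of PCR product); they cancel in the ratio.

Delta-delta-Ct analysis is deliberately not implemented — the dilution-series
design calls for standard-curve quantification.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import QpcrError


@dataclass(frozen=True)
class QpcrWell:
    """One qPCR well: a standard-dilution well or an unknown (cDNA) well.

    ``ct`` is the threshold cycle, or ``None`` for a not-detected well.
    Standards carry ``dilution`` (relative concentration, e.g. 1e-1..1e-4);
    unknowns carry ``sample_id`` (one biological replicate at one
    temperature).
    """

    target: str
    ct: float | None
    role: str  # "standard" | "unknown"
    dilution: float | None = None
    sample_id: str | None = None
    temperature: float | None = None
    tech_rep: int = 1

    def __post_init__(self) -> None:
        if self.role not in ("standard", "unknown"):
            raise QpcrError(f"unknown well role {self.role!r}")
        if self.ct is not None and self.ct <= 0:
            raise QpcrError(f"Ct must be positive, got {self.ct}")
        if self.role == "standard" and self.dilution is None:
            raise QpcrError("standard wells must carry a dilution")
        if self.role == "unknown" and self.sample_id is None:
            raise QpcrError("unknown wells must carry a sample_id")

    @property
    def detected(self) -> bool:
        return self.ct is not None


@dataclass
class QpcrPlate:
    """A collection of wells, typically one run's standards plus unknowns."""

    wells: list[QpcrWell] = field(default_factory=list)

    def standards(self, target: str) -> list[QpcrWell]:
        return [w for w in self.wells if w.role == "standard" and w.target == target]

    def unknowns(
        self, target: str | None = None, temperature: float | None = None
    ) -> list[QpcrWell]:
        out = [w for w in self.wells if w.role == "unknown"]
        if target is not None:
            out = [w for w in out if w.target == target]
        if temperature is not None:
            out = [w for w in out if w.temperature == temperature]
        return out

    @property
    def targets(self) -> list[str]:
        return sorted({w.target for w in self.wells})

    @property
    def temperatures(self) -> list[float]:
        return sorted(
            {w.temperature for w in self.unknowns() if w.temperature is not None}
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "target": [w.target for w in self.wells],
                "role": [w.role for w in self.wells],
                "dilution": [w.dilution for w in self.wells],
                "sample_id": [w.sample_id for w in self.wells],
                "temperature": [w.temperature for w in self.wells],
                "tech_rep": [w.tech_rep for w in self.wells],
                "ct": [w.ct for w in self.wells],
            }
        )


@dataclass(frozen=True)
class StandardCurve:
    """A fitted log-linear standard curve for one target.

    ``slope`` is in cycles per decade of template concentration (negative for
    a working assay); ``efficiency`` is the per-cycle amplification gain
    minus one, 10**(-1/slope) - 1, so a slope of -3.32 corresponds to ~100 %
    efficiency.
    """

    target: str
    slope: float
    intercept: float
    r_squared: float

    @property
    def efficiency(self) -> float:
        return 10.0 ** (-1.0 / self.slope) - 1.0


def read_well_table(path) -> QpcrPlate:
    """Read a delimited well table (TSV/CSV sniffed from extension).

    Expected columns: target, role, dilution, sample_id, temperature,
    tech_rep, ct.  Empty/NA ct means not detected.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    wells = []
    for row in df.itertuples(index=False):
        ct = getattr(row, "ct", None)
        wells.append(
            QpcrWell(
                target=str(row.target),
                ct=None if pd.isna(ct) else float(ct),
                role=str(row.role),
                dilution=None if pd.isna(getattr(row, "dilution", None)) else float(row.dilution),
                sample_id=None if pd.isna(getattr(row, "sample_id", None)) else str(row.sample_id),
                temperature=None if pd.isna(getattr(row, "temperature", None)) else float(row.temperature),
                tech_rep=int(getattr(row, "tech_rep", 1)),
            )
        )
    return QpcrPlate(wells)


def write_well_table(plate: QpcrPlate, path) -> None:
    sep = "," if str(path).endswith(".csv") else "\t"
    plate.to_frame().to_csv(path, sep=sep, index=False)


def fit_standard_curve(
    wells: Sequence[QpcrWell], per_well: bool = False
) -> StandardCurve:
    """Least-squares fit of Ct versus log10(dilution) for one target.

    By default technical replicates are collapsed to the mean Ct per dilution
    before fitting; ``per_well`` fits on all individual detected wells.
    Requires >=3 distinct detected dilutions; a non-negative slope marks a
    failed assay and raises.
    """
    wells = [w for w in wells if w.role == "standard" and w.detected]
    if not wells:
        raise QpcrError("no detected standard wells")
    targets = {w.target for w in wells}
    if len(targets) != 1:
        raise QpcrError(f"standards span multiple targets: {sorted(targets)}")
    (target,) = targets
    by_dilution: dict[float, list[float]] = {}
    for w in wells:
        by_dilution.setdefault(w.dilution, []).append(w.ct)
    if len(by_dilution) < 3:
        raise QpcrError(
            f"target {target!r}: need >=3 distinct dilutions, got {len(by_dilution)}"
        )
    if per_well:
        x = np.log10([w.dilution for w in wells])
        y = np.asarray([w.ct for w in wells])
    else:
        x = np.log10(sorted(by_dilution))
        y = np.asarray([float(np.mean(by_dilution[d])) for d in sorted(by_dilution)])
    res = stats.linregress(x, y)
    if res.slope >= 0:
        raise QpcrError(
            f"target {target!r}: non-negative standard-curve slope "
            f"{res.slope:.3g} (Ct must decrease with concentration)"
        )
    return StandardCurve(
        target=target,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def quantify(ct: float | None, curve: StandardCurve) -> float | None:
    """Back-calculate relative template quantity from a Ct value.

    quantity = 10**((ct - intercept) / slope); strictly decreasing in Ct.
    Not-detected wells (ct None) return None (flagged, never imputed).
    """
    if ct is None:
        warnings.warn(
            f"not-detected well for target {curve.target!r} excluded from "
            "quantification",
            stacklevel=2,
        )
        return None
    return 10.0 ** ((ct - curve.intercept) / curve.slope)


@dataclass(frozen=True)
class ExpressionRatio:
    """rrsA:rrsBC-style expression ratio at one temperature.

    ``ratios`` holds one ratio per biological replicate; ``mean``/``sd`` are
    computed across them (sd with n-1 denominator, 0.0 for n == 1).
    """

    temperature: float
    ratios: tuple[float, ...]
    numerator_target: str
    denominator_target: str

    @property
    def n(self) -> int:
        return len(self.ratios)

    @property
    def mean(self) -> float:
        return float(np.mean(self.ratios))

    @property
    def sd(self) -> float:
        return float(np.std(self.ratios, ddof=1)) if self.n > 1 else 0.0


def expression_ratio(
    plate: QpcrPlate,
    curves: Mapping[str, StandardCurve],
    temperature: float,
    numerator: str = "rrsA",
    denominator: str = "rrsBC",
    scale: str = "quantity",
) -> ExpressionRatio:
    """Per-biological-replicate expression ratio of two targets.

    For each biological replicate the detected technical replicates of each
    target are quantified through that target's standard curve and averaged
    (on the quantity scale by default; ``scale="ct"`` averages Ct first and
    quantifies the mean).  The ratio is the numerator-target mean over the
    denominator-target mean.  Replicates missing either target entirely are
    dropped with a warning; if all are dropped an error is raised.
    """
    if scale not in ("quantity", "ct"):
        raise ValueError(f"unknown averaging scale {scale!r}")
    wells = plate.unknowns(temperature=temperature)
    sample_ids = sorted({w.sample_id for w in wells})
    if not sample_ids:
        raise QpcrError(f"no unknown wells at temperature {temperature}")
    ratios = []
    for sid in sample_ids:
        means = {}
        for target in (numerator, denominator):
            cts = [
                w.ct
                for w in wells
                if w.sample_id == sid and w.target == target and w.detected
            ]
            if not cts:
                continue
            if scale == "quantity":
                means[target] = float(
                    np.mean([quantify(c, curves[target]) for c in cts])
                )
            else:
                means[target] = quantify(float(np.mean(cts)), curves[target])
        if numerator not in means or denominator not in means:
            warnings.warn(
                f"biological replicate {sid!r} missing a target at "
                f"{temperature} degC; dropped",
                stacklevel=2,
            )
            continue
        ratios.append(means[numerator] / means[denominator])
    if not ratios:
        raise QpcrError(
            f"no biological replicate at {temperature} degC has both targets"
        )
    return ExpressionRatio(
        temperature=temperature,
        ratios=tuple(ratios),
        numerator_target=numerator,
        denominator_target=denominator,
    )


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    df: float
    pvalue: float


def compare_ratio_groups(
    group_a: Sequence[float],
    group_b: Sequence[float],
    equal_var: bool = True,
) -> TTestResult:
    """Two-sided two-sample t-test between groups of expression ratios.

    Pooled-variance Student's t by default; ``equal_var=False`` selects the
    Welch variant.  Two identical zero-variance groups return t = 0, p = 1
    by convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise QpcrError("each group needs n >= 2")
    if a.std() == 0 and b.std() == 0 and math.isclose(a.mean(), b.mean()):
        return TTestResult(0.0, float(len(a) + len(b) - 2), 1.0)
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return TTestResult(float(res.statistic), float(res.df), float(res.pvalue))


def ratio_table(ratios: Iterable[ExpressionRatio]) -> pd.DataFrame:
    """Summarise ratios per temperature for TSV export."""
    ratios = list(ratios)
    return pd.DataFrame(
        {
            "temperature": [r.temperature for r in ratios],
            "mean_ratio": [r.mean for r in ratios],
            "sd": [r.sd for r in ratios],
            "n": [r.n for r in ratios],
        }
    )
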