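"""Linear GC-content "molecular thermometer" for archaeal 16S rRNA genes.

The empirical molecular-thermometer relationship states that the GC content
(P_GC) of a 16S rRNA gene region is linearly related to the host's cardinal
growth temperatures: hot-adapted archaea carry GC-rich rRNA, cold-adapted ones
GC-poor rRNA.  This module fits per-cardinal-temperature lines

    T_c = slope_c * P_GC + intercept_c,    c in {min, opt, max}

from (P_GC, T) calibration pairs, predicts cardinal temperatures for new
regions, and reports intragenomic offsets between divergent 16S paralogs.

The shipped default calibration uses the published per-paralog P_GC values and
estimated growth temperatures for the three 16S genes (rrsA/rrsB/rrsC) of
*Haloarcula hispanica* JCM8911, which are collinear to within 0.1 degC.  The
original regression coefficients of the thermometer are not re-derived here;
users who hold them can supply their own model via :func:`calibrate` or a
serialized model file.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import CalibrationError
from .sequences import (
    Primer,
    SequenceRecord,
    extract_thermometer_region,
    gc_content,
    pairwise_identity,
)

CARDINALS = ("min", "opt", "max")

# Published per-paralog reference data for H. hispanica JCM8911: thermometer
# region P_GC (%) and estimated cardinal temperatures (degC) with +/- half-widths.
HALOARCULA_REFERENCE: dict[str, dict] = {
    "rrsA": {
        "accession": "LC085245",
        "p_gc": 58.9,
        "min": (32.6, 16.7),
        "opt": (51.6, 11.8),
        "max": (59.7, 13.1),
    },
    "rrsB": {
        "accession": "LC085246",
        "p_gc": 56.5,
        "min": (22.2, 16.4),
        "opt": (39.8, 11.6),
        "max": (48.1, 12.8),
    },
    "rrsC": {
        "accession": "LC085247",
        "p_gc": 56.4,
        "min": (21.7, 16.4),
        "opt": (39.3, 11.5),
        "max": (47.6, 12.8),
    },
}


@dataclass
class ThermometerModel:
    """Per-cardinal-temperature linear coefficients plus uncertainty anchors.

    ``coefficients`` maps each cardinal ("min"/"opt"/"max") to (slope, intercept)
    in degC per %GC and degC.  ``uncertainty_anchors`` maps each cardinal to a
    list of (P_GC, half_width) pairs; prediction half-widths are linearly
    interpolated between anchors and clamped outside their P_GC range.
    """

    coefficients: dict[str, tuple[float, float]]
    uncertainty_anchors: dict[str, list[tuple[float, float]]] = field(
        default_factory=dict
    )
    calibration_range: tuple[float, float] = (0.0, 100.0)
    residuals: dict[str, list[float]] = field(default_factory=dict)

    def predict(self, cardinal: str, p_gc: float) -> float:
        slope, intercept = self.coefficients[cardinal]
        return slope * p_gc + intercept

    def half_width(self, cardinal: str, p_gc: float) -> float:
        anchors = sorted(self.uncertainty_anchors.get(cardinal, []))
        if not anchors:
            return float("nan")
        xs = [a[0] for a in anchors]
        ys = [a[1] for a in anchors]
        return float(np.interp(p_gc, xs, ys))  # clamps outside anchor range

    def to_dict(self) -> dict:
        return {
            "coefficients": {c: list(self.coefficients[c]) for c in self.coefficients},
            "uncertainty_anchors": {
                c: [list(a) for a in v] for c, v in self.uncertainty_anchors.items()
            },
            "calibration_range": list(self.calibration_range),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ThermometerModel":
        return cls(
            coefficients={c: tuple(v) for c, v in d["coefficients"].items()},
            uncertainty_anchors={
                c: [tuple(a) for a in v]
                for c, v in d.get("uncertainty_anchors", {}).items()
            },
            calibration_range=tuple(d.get("calibration_range", (0.0, 100.0))),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ThermometerModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class TemperatureEstimate:
    """Cardinal-temperature estimates (degC) for one region's P_GC."""

    p_gc: float
    t_min: float
    t_opt: float
    t_max: float
    u_min: float
    u_opt: float
    u_max: float
    extrapolated: bool = False


def calibrate(
    points: Mapping[str, Sequence[tuple[float, float]]],
    uncertainty_anchors: Mapping[str, Sequence[tuple[float, float]]] | None = None,
) -> ThermometerModel:
    """Fit one line per cardinal temperature by ordinary least squares.

    With exactly two points the fit is the interpolating line.  At least two
    points with distinct P_GC are required per cardinal; a non-positive
    fitted slope violates the thermometer premise and triggers a warning.
    """
    coefficients: dict[str, tuple[float, float]] = {}
    residuals: dict[str, list[float]] = {}
    lo, hi = np.inf, -np.inf
    for cardinal, pairs in points.items():
        if cardinal not in CARDINALS:
            raise CalibrationError(f"unknown cardinal temperature {cardinal!r}")
        x = np.asarray([p for p, _ in pairs], dtype=float)
        t = np.asarray([v for _, v in pairs], dtype=float)
        if len(np.unique(x)) < 2:
            raise CalibrationError(
                f"cardinal {cardinal!r}: need >=2 points with distinct P_GC"
            )
        slope, intercept = np.polyfit(x, t, 1)
        if slope <= 0:
            warnings.warn(
                f"cardinal {cardinal!r}: non-positive slope {slope:.3g} violates "
                "the thermometer premise",
                stacklevel=2,
            )
        coefficients[cardinal] = (float(slope), float(intercept))
        residuals[cardinal] = list(t - (slope * x + intercept))
        lo, hi = min(lo, x.min()), max(hi, x.max())
    if not coefficients:
        raise CalibrationError("no calibration points supplied")
    return ThermometerModel(
        coefficients=coefficients,
        uncertainty_anchors={
            c: sorted(tuple(a) for a in v)
            for c, v in (uncertainty_anchors or {}).items()
        },
        calibration_range=(float(lo), float(hi)),
        residuals=residuals,
    )


def default_model(paralogs: Sequence[str] = ("rrsA", "rrsB", "rrsC")) -> ThermometerModel:
    """The thermometer calibrated on the H. hispanica reference paralogs.

    ``paralogs`` selects which reference rows enter the fit; the two-row
    (rrsA, rrsC) variant gives the exact interpolating line through the
    extreme P_GC values.
    """
    points = {
        c: [(HALOARCULA_REFERENCE[p]["p_gc"], HALOARCULA_REFERENCE[p][c][0]) for p in paralogs]
        for c in CARDINALS
    }
    anchors = {
        c: [(HALOARCULA_REFERENCE[p]["p_gc"], HALOARCULA_REFERENCE[p][c][1]) for p in paralogs]
        for c in CARDINALS
    }
    return calibrate(points, anchors)


def estimate_temperatures(
    p_gc: float,
    model: ThermometerModel,
    extrapolation_margin: float = 5.0,
) -> TemperatureEstimate:
    """Predict (T_min, T_opt, T_max) with uncertainty half-widths for a P_GC.

    Estimates outside the calibration P_GC range by more than
    ``extrapolation_margin`` percentage points are flagged ``extrapolated``.
    """
    if not 0.0 < p_gc < 100.0:
        raise ValueError(f"p_gc must be in (0, 100), got {p_gc}")
    lo, hi = model.calibration_range
    extrapolated = p_gc < lo - extrapolation_margin or p_gc > hi + extrapolation_margin
    t = {c: model.predict(c, p_gc) for c in CARDINALS}
    u = {c: model.half_width(c, p_gc) for c in CARDINALS}
    return TemperatureEstimate(
        p_gc=p_gc,
        t_min=t["min"],
        t_opt=t["opt"],
        t_max=t["max"],
        u_min=u["min"],
        u_opt=u["opt"],
        u_max=u["max"],
        extrapolated=extrapolated,
    )


@dataclass
class HeterogeneityReport:
    """Per-paralog thermometer estimates and all pairwise offsets.

    ``paralogs`` has one row per successfully processed record (id, region
    coordinates and length, P_GC, cardinal-temperature estimates);
    ``pairs`` has one row per unordered pair (identity %, delta P_GC and
    delta T for each cardinal, computed as first minus second).
    ``failures`` lists (record id, error message) for records whose region
    extraction failed.
    """

    paralogs: pd.DataFrame
    pairs: pd.DataFrame
    failures: list[tuple[str, str]] = field(default_factory=list)


def heterogeneity_report(
    records: Sequence[SequenceRecord],
    fwd: Primer,
    rev: Primer,
    model: ThermometerModel,
    max_mismatch: int = 0,
) -> HeterogeneityReport:
    """Thermometer-region analysis of a multi-paralog 16S family.

    Extracts each record's thermometer region, computes P_GC and cardinal
    temperature estimates, and tabulates pairwise identities, P_GC offsets
    and temperature offsets for every unordered pair.  Records whose primers
    cannot be located are reported as failures and excluded from pairing.
    """
    if len(records) < 2:
        raise ValueError("need at least two records for a heterogeneity report")
    rows, failures, ok = [], [], []
    for rec in records:
        try:
            region = extract_thermometer_region(rec, fwd, rev, max_mismatch)
        except Exception as exc:  # propagate per-record, keep going
            failures.append((rec.id, str(exc)))
            continue
        p_gc = gc_content(region)
        est = estimate_temperatures(p_gc, model)
        ok.append((rec, est))
        rows.append(
            {
                "id": rec.id,
                "region_start": region.start,
                "region_end": region.end,
                "region_length": len(region),
                "p_gc": p_gc,
                "t_min": est.t_min,
                "t_opt": est.t_opt,
                "t_max": est.t_max,
                "u_min": est.u_min,
                "u_opt": est.u_opt,
                "u_max": est.u_max,
            }
        )
    pair_rows = []
    for (ra, ea), (rb, eb) in combinations(ok, 2):
        pair_rows.append(
            {
                "id_a": ra.id,
                "id_b": rb.id,
                "identity": pairwise_identity(ra, rb),
                "delta_p_gc": ea.p_gc - eb.p_gc,
                "delta_t_min": ea.t_min - eb.t_min,
                "delta_t_opt": ea.t_opt - eb.t_opt,
                "delta_t_max": ea.t_max - eb.t_max,
            }
        )
    return HeterogeneityReport(
        paralogs=pd.DataFrame(rows),
        pairs=pd.DataFrame(pair_rows),
        failures=failures,
    )
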