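"""Bliss-independence synergy scoring for clonal-isolate pairings.

A 2x2 pairing design (ancestral x ancestral, evolved x ancestral,
ancestral x evolved, evolved x evolved) yields fractional growth-rate or
yield effects f_Dv and f_Mm for each evolved partner alone.  Under Bliss
independence the combined fractional effect is

    f_DvMm = 1 - (1 - f_Dv)(1 - f_Mm) = f_Dv + f_Mm - f_Dv f_Mm

and the Excess over Bliss of the measured combined effect f_z is

    EOB = (f_z - f_DvMm) x 100

with first-order error propagation of the replicate standard deviations.
EOB near zero is additive; positive / negative EOB beyond the error band
is synergistic / antagonistic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "PairingMeasurement",
    "SynergyReport",
    "fractional_effect",
    "bliss_expected",
    "excess_over_bliss",
    "synergy_report",
    "pairings_to_frame",
    "frame_to_pairings",
]

logger = logging.getLogger(__name__)

PAIRINGS = ("AcAc", "EvAc", "AcEv", "EvEv")
METRICS = ("growth_rate", "yield")


@dataclass(frozen=True)
class PairingMeasurement:
    """Replicate measurements for one pairing and one metric."""

    pairing: str  # AcAc | EvAc | AcEv | EvEv
    metric: str   # growth_rate | yield
    replicates: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.pairing not in PAIRINGS:
            raise ValueError(f"pairing must be one of {PAIRINGS}")
        if self.metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}")
        if len(self.replicates) < 2:
            raise ValueError("need >= 2 replicates")

    @property
    def mean(self) -> float:
        return float(np.mean(self.replicates))

    @property
    def sd(self) -> float:
        return float(np.std(self.replicates, ddof=1))


@dataclass(frozen=True)
class SynergyReport:
    metric: str
    f_dv: float
    f_mm: float
    f_z: float
    f_dvmm: float        # Bliss expectation
    eob: float           # percentage points
    sd_eob: float        # percentage points
    classification: str  # additive | synergistic | antagonistic
    normalization: str = "relative_to_baseline"


def fractional_effect(
    v_pair: float,
    v_baseline: float,
    normalization: str = "relative_to_baseline",
    v_full: float | None = None,
) -> float:
    """Fractional improvement of a pairing over the ancestral baseline.

    ``relative_to_baseline``: f = (v_pair - v_baseline) / v_baseline;
    ``relative_to_full``: f = (v_pair - v_baseline) / (v_full - v_baseline).
    Negative values are clamped to 0 (and logged): a pairing cannot
    contribute a negative fractional effect to the Bliss product.
    """
    if v_baseline <= 0:
        raise ValueError("baseline must be positive")
    if normalization == "relative_to_baseline":
        f = (v_pair - v_baseline) / v_baseline
    elif normalization == "relative_to_full":
        if v_full is None or v_full <= v_baseline:
            raise ValueError("relative_to_full requires v_full > v_baseline")
        f = (v_pair - v_baseline) / (v_full - v_baseline)
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    if f < 0:
        logger.warning("negative fractional effect %.4f clamped to 0", f)
        return 0.0
    return float(f)


def bliss_expected(f_dv: float, f_mm: float) -> float:
    """Bliss-independence expectation f_Dv + f_Mm - f_Dv * f_Mm."""
    for f in (f_dv, f_mm):
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"fractional effect {f} outside [0, 1]")
    return float(f_dv + f_mm - f_dv * f_mm)


def excess_over_bliss(
    f_z: float,
    f_dvmm: float,
    sd_fz: float = 0.0,
    sd_fdv: float = 0.0,
    sd_fmm: float = 0.0,
    f_dv: float = 0.0,
    f_mm: float = 0.0,
) -> tuple[float, float, str]:
    """EOB, its propagated sd (both in percentage points) and the class.

    First-order propagation under independence:
    sd(f_DvMm)^2 = (1 - f_Mm)^2 sd(f_Dv)^2 + (1 - f_Dv)^2 sd(f_Mm)^2,
    sd(EOB) = 100 sqrt(sd(f_z)^2 + sd(f_DvMm)^2).  Classification is
    additive when |EOB| <= 2 sd(EOB), else synergistic (EOB > 0) or
    antagonistic (EOB < 0); with zero error the additive band collapses
    to EOB == 0 within numerical tolerance.
    """
    if min(sd_fz, sd_fdv, sd_fmm) < 0:
        raise ValueError("standard deviations must be >= 0")
    eob = (f_z - f_dvmm) * 100.0
    var_fdvmm = (1 - f_mm) ** 2 * sd_fdv**2 + (1 - f_dv) ** 2 * sd_fmm**2
    sd_eob = 100.0 * math.sqrt(sd_fz**2 + var_fdvmm)
    band = 2.0 * sd_eob if sd_eob > 0 else 1e-9
    if abs(eob) <= band:
        cls = "additive"
    elif eob > 0:
        cls = "synergistic"
    else:
        cls = "antagonistic"
    return eob, sd_eob, cls


def synergy_report(
    measurements: Iterable[PairingMeasurement],
    metric: str = "growth_rate",
    normalization: str = "relative_to_baseline",
) -> SynergyReport:
    """Full synergy analysis of a 2x2 pairing design for one metric.

    f_Dv comes from EvAc vs AcAc, f_Mm from AcEv vs AcAc and f_z from
    EvEv vs AcAc.  Because each fraction is computed from replicate
    means, the error propagated to it is the standard error of the mean
    (replicate sd / sqrt(n)), including the baseline's own error.
    """
    by_pairing = {m.pairing: m for m in measurements if m.metric == metric}
    missing = set(PAIRINGS) - set(by_pairing)
    if missing:
        raise ValueError(f"missing pairings for {metric}: {sorted(missing)}")
    base = by_pairing["AcAc"]
    full = by_pairing["EvEv"]

    def frac_and_sd(pm: PairingMeasurement) -> tuple[float, float]:
        if normalization == "relative_to_full":
            f = fractional_effect(pm.mean, base.mean, normalization, full.mean)
            denom = full.mean - base.mean
        else:
            f = fractional_effect(pm.mean, base.mean, normalization)
            denom = base.mean
        # first-order propagation of standard errors of the means;
        # baseline term uses the derivative of (v - b)/b at the means
        sem = pm.sd / math.sqrt(len(pm.replicates))
        sem_b = base.sd / math.sqrt(len(base.replicates))
        if normalization == "relative_to_baseline":
            var = (sem / base.mean) ** 2 + (pm.mean * sem_b / base.mean**2) ** 2
        else:
            var = (sem / denom) ** 2 + (sem_b / denom) ** 2
        f = min(f, 1.0)
        return f, math.sqrt(var)

    f_dv, sd_fdv = frac_and_sd(by_pairing["EvAc"])
    f_mm, sd_fmm = frac_and_sd(by_pairing["AcEv"])
    f_z, sd_fz = frac_and_sd(full)
    f_dvmm = bliss_expected(f_dv, f_mm)
    eob, sd_eob, cls = excess_over_bliss(f_z, f_dvmm, sd_fz, sd_fdv, sd_fmm, f_dv, f_mm)
    return SynergyReport(
        metric=metric,
        f_dv=f_dv,
        f_mm=f_mm,
        f_z=f_z,
        f_dvmm=f_dvmm,
        eob=eob,
        sd_eob=sd_eob,
        classification=cls,
        normalization=normalization,
    )


def pairings_to_frame(measurements: Iterable[PairingMeasurement]) -> pd.DataFrame:
    rows = []
    for m in measurements:
        for i, v in enumerate(m.replicates):
            rows.append(
                {"pairing": m.pairing, "metric": m.metric, "replicate": i, "value": v}
            )
    return pd.DataFrame(rows, columns=["pairing", "metric", "replicate", "value"])


def frame_to_pairings(df: pd.DataFrame) -> list[PairingMeasurement]:
    out = []
    for (pairing, metric), grp in df.groupby(["pairing", "metric"], sort=True):
        values = tuple(
            float(v)
            for _, v in sorted(zip(grp["replicate"], grp["value"]))
        )
        out.append(PairingMeasurement(str(pairing), str(metric), values))
    return out
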