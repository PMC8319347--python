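"""Growth-curve parameter estimation and minimal permissive density.

OD600 time series are fit with the reparameterized logistic and Gompertz
models whose parameters are directly interpretable: maximum growth rate
``mu`` (OD/h), lag time ``lambda`` (h) and carrying capacity ``A`` (OD):

    logistic:  y(t) = A / (1 + exp(4 mu (lambda - t) / A + 2))
    gompertz:  y(t) = A exp(-exp(mu e (lambda - t) / A + 1))

Dilution plates (1.5-fold series with blank wells) are summarized into
per-density growth counts and the minimal cell density that still
supports population growth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "GrowthCurve",
    "GrowthFit",
    "PlateAssay",
    "logistic_model",
    "gompertz_model",
    "fit_growth",
    "minimal_permissive_density",
]


def logistic_model(t, A, mu, lam):
    return A / (1.0 + np.exp(4.0 * mu * (lam - t) / A + 2.0))


def gompertz_model(t, A, mu, lam):
    return A * np.exp(-np.exp(mu * math.e * (lam - t) / A + 1.0))


_MODELS = {"logistic": logistic_model, "gompertz": gompertz_model}


@dataclass
class GrowthCurve:
    """A single well's OD600 time series."""

    times: np.ndarray  # hours, strictly increasing
    od: np.ndarray     # OD600 >= 0
    well: str = ""
    initial_density: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.shape != self.od.shape:
            raise ValueError("times and od must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.od < 0):
            raise ValueError("od readings must be >= 0")


@dataclass
class GrowthFit:
    """Fitted growth parameters for one well."""

    well: str
    grew: bool
    model: str | None = None   # logistic | gompertz | None when no growth/fit
    mu: float | None = None    # maximum growth rate (OD/h)
    lam: float | None = None   # lag time (h)
    A: float | None = None     # carrying capacity above baseline (OD)
    baseline: float = 0.0
    aicc: float | None = None
    rss: float | None = None
    diagnostic: str = ""


@dataclass
class PlateAssay:
    """A dilution plate: densities (strictly decreasing by a fixed fold),
    replicate growth curves per density, and blank wells."""

    densities: tuple[float, ...]
    wells: dict[str, GrowthCurve]
    well_map: dict[str, tuple[str, int]]  # well -> ("blank" | density index, replicate)
    dilution_fold: float = 1.5

    def __post_init__(self) -> None:
        d = np.asarray(self.densities)
        if np.any(d <= 0) or np.any(np.diff(d) >= 0):
            raise ValueError("densities must be positive and strictly decreasing")
        if not any(kind == "blank" for kind, _ in self.well_map.values()):
            raise ValueError("plate must contain blank wells")

    def blanks(self) -> list[GrowthCurve]:
        return [
            self.wells[w] for w, (kind, _) in self.well_map.items() if kind == "blank"
        ]

    def wells_at(self, density_index: int) -> list[GrowthCurve]:
        return [
            self.wells[w]
            for w, (kind, _) in self.well_map.items()
            if kind == density_index
        ]

    def to_csv(self, plate_path: str | Path, map_path: str | Path) -> None:
        any_curve = next(iter(self.wells.values()))
        df = pd.DataFrame({"time": any_curve.times})
        for well in sorted(self.wells):
            df[well] = self.wells[well].od
        df.to_csv(plate_path, index=False)
        rows = []
        for well, (kind, rep) in sorted(self.well_map.items()):
            rows.append(
                {
                    "well": well,
                    "density": "" if kind == "blank" else self.densities[kind],
                    "blank": kind == "blank",
                    "replicate": rep,
                }
            )
        pd.DataFrame(rows).to_csv(map_path, index=False)

    @classmethod
    def from_csv(
        cls, plate_path: str | Path, map_path: str | Path, dilution_fold: float = 1.5
    ) -> "PlateAssay":
        plate = pd.read_csv(plate_path)
        pmap = pd.read_csv(map_path)
        times = plate["time"].to_numpy(dtype=float)
        densities = sorted(
            {float(d) for d in pmap.loc[~pmap["blank"], "density"]}, reverse=True
        )
        dix = {d: i for i, d in enumerate(densities)}
        wells: dict[str, GrowthCurve] = {}
        well_map: dict[str, tuple[str, int]] = {}
        for rec in pmap.itertuples():
            well = str(rec.well)
            density = 0.0 if rec.blank else float(rec.density)
            wells[well] = GrowthCurve(
                times, plate[well].to_numpy(dtype=float), well, density
            )
            well_map[well] = (
                ("blank", int(rec.replicate))
                if rec.blank
                else (dix[density], int(rec.replicate))
            )
        return cls(tuple(densities), wells, well_map, dilution_fold)


# ---------------------------------------------------------------------------
# Fitting


def _aicc(rss: float, n: int, k: int) -> float:
    rss = max(rss, 1e-12)
    return n * math.log(rss / n) + 2 * k + (2 * k * (k + 1)) / max(n - k - 1, 1)


def _sustained_above(od: np.ndarray, level: float, run: int = 3) -> bool:
    above = od >= level
    count = 0
    for a in above:
        count = count + 1 if a else 0
        if count >= run:
            return True
    return False


def fit_growth(
    curve: GrowthCurve,
    models: Sequence[str] = ("logistic", "gompertz"),
    growth_threshold: float = 0.05,
) -> GrowthFit:
    """Fit parametric growth models and call growth.

    Both requested models are fit by bounded least squares on
    baseline-subtracted OD (baseline = median of the first three
    readings); the winner is chosen by small-sample-corrected AIC, ties
    going to the logistic.  ``grew`` requires the fitted capacity to
    exceed ``growth_threshold`` above baseline *and* at least three
    consecutive raw readings above baseline + threshold; non-convergence
    yields ``grew=False`` with a diagnostic rather than an exception.
    """
    if len(curve.times) < 5:
        raise ValueError("need at least 5 time points to fit")
    unknown = set(models) - set(_MODELS)
    if unknown:
        raise ValueError(f"unknown models {sorted(unknown)}")

    t, y_raw = curve.times, curve.od
    baseline0 = float(np.median(y_raw[:3]))

    sustained = _sustained_above(y_raw, baseline0 + growth_threshold)
    if float((y_raw - baseline0).max(initial=0.0)) < growth_threshold or not sustained:
        return GrowthFit(curve.well, grew=False, baseline=baseline0,
                         diagnostic="no rise above threshold")

    # initialization heuristics: A from the plateau, mu from the max slope,
    # lambda from the max-slope tangent's intercept with the baseline
    y = y_raw - baseline0
    A0 = max(float(y.max()), 1e-3)
    slopes = np.gradient(y, t)
    imax = int(np.argmax(slopes))
    mu0 = max(float(slopes[imax]), 1e-3)
    lam0 = float(t[imax] - y[imax] / mu0)

    best: GrowthFit | None = None
    for name in models:
        fn = _MODELS[name]

        def with_offset(t, A, mu, lam, y0, _fn=fn):
            return y0 + _fn(t, A, mu, lam)

        try:
            popt, _ = curve_fit(
                with_offset,
                t,
                y_raw,
                p0=[A0, mu0, max(lam0, 0.0), baseline0],
                bounds=(
                    [1e-6, 1e-6, -t[-1], 0.0],
                    [10 * A0 + 1, np.inf, t[-1], max(baseline0 * 4, 0.5)],
                ),
                maxfev=20000,
            )
        except (RuntimeError, ValueError):
            continue
        A, mu, lam, y0 = (float(v) for v in popt)
        rss = float(np.sum((y_raw - with_offset(t, *popt)) ** 2))
        aicc = _aicc(rss, len(t), 4)
        fit = GrowthFit(curve.well, grew=True, model=name, mu=mu, lam=lam, A=A,
                        baseline=y0, aicc=aicc, rss=rss)
        if best is None or aicc < best.aicc - 1e-9:
            best = fit
    if best is None:
        return GrowthFit(curve.well, grew=False, baseline=baseline0,
                         diagnostic="fit did not converge")
    if best.A < growth_threshold:
        return GrowthFit(curve.well, grew=False, model=best.model,
                         baseline=baseline, diagnostic="fitted capacity below threshold")
    return best


def minimal_permissive_density(
    plate: PlateAssay,
    growth_threshold: float = 0.05,
    min_replicates_growing: int = 1,
) -> tuple[float | None, pd.DataFrame]:
    """Lowest seeding density that still supports growth.

    Blanks are first checked for contamination (any blank rising above
    the growth threshold is an error).  Every non-blank well is fit and
    scored with :func:`fit_growth`; the function returns the lowest
    density with at least ``min_replicates_growing`` growing replicates
    plus the per-density growth-count profile.
    """
    for blank in plate.blanks():
        base = float(np.median(blank.od[:3]))
        if _sustained_above(blank.od, base + growth_threshold):
            raise ValueError(f"contaminated blank well {blank.well!r}")

    rows = []
    for i, density in enumerate(plate.densities):
        curves = plate.wells_at(i)
        n_grow = sum(
            fit_growth(c, growth_threshold=growth_threshold).grew for c in curves
        )
        rows.append({"density": density, "n_replicates": len(curves), "n_growing": n_grow})
    profile = pd.DataFrame(rows)
    growing = profile[profile["n_growing"] >= min_replicates_growing]
    minimal = float(growing["density"].min()) if not growing.empty else None
    return minimal, profile
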