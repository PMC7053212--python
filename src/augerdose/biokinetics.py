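"""Time-activity curves and time-integrated activity from %ID/g tables.

Biodistribution studies report, for each tissue and sacrifice time, the
percent of injected activity per gram of tissue (%ID/g) measured by gamma
counting, usually decay-corrected to the time of injection.  Organ dose
requires the integral of the *physical* activity concentration over all
time, so the workflow is:

1. load the per-tissue %ID/g table (`load_biodistribution`),
2. re-apply physical decay if the data are decay-corrected
   (`apply_physical_decay`),
3. fit a hybrid trapezoid + mono-exponential time-activity curve: the tail
   is the earliest suffix of the data that a log-linear fit describes with
   R^2 above threshold, the earlier points are kept as trapezoid nodes
   (`fit_tail_exponential`),
4. integrate head trapezoidally and the tail analytically to infinity
   (`time_integrated_activity`), yielding a time-integrated activity
   coefficient (TIAC) in MBq.h per gram per MBq injected.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .physics import EmissionSpectrum

__all__ = [
    "BiodistributionSample",
    "BiodistributionSeries",
    "TimeActivityCurve",
    "TiacCoefficient",
    "load_biodistribution",
    "apply_physical_decay",
    "fit_tail_exponential",
    "time_integrated_activity",
]

VALID_FLAGS = ("ok", "saturated", "below_lod")


@dataclass(frozen=True)
class BiodistributionSample:
    """One (tissue, time) summary row: mean %ID/g over ``n`` animals."""

    time_h: float
    pct_id_per_g: float
    sd: float = 0.0
    n: int = 1
    flag: str = "ok"

    def __post_init__(self) -> None:
        if self.flag not in VALID_FLAGS:
            raise ValueError(f"unknown flag {self.flag!r}")
        if self.flag == "ok" and self.pct_id_per_g < 0:
            raise ValueError("concentration must be non-negative")
        if self.n < 1:
            raise ValueError("n must be >= 1")


@dataclass
class BiodistributionSeries:
    """%ID/g time course for one tissue.

    ``samples`` includes censored rows (``flag != 'ok'``), which behave as
    explicit gaps: they are excluded from fitting and integration but kept
    for provenance (e.g. early kidney points too hot for the gamma counter).
    """

    tissue: str
    samples: list[BiodistributionSample]
    decay_corrected: bool = True

    def __post_init__(self) -> None:
        times = [s.time_h for s in self.samples]
        if any(t < 0 for t in times):
            raise ValueError("times must be non-negative")
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError(
                f"{self.tissue}: times must be strictly increasing"
            )

    @property
    def quantified(self) -> list[BiodistributionSample]:
        """Samples usable for fitting (flag == 'ok')."""
        return [s for s in self.samples if s.flag == "ok"]

    @property
    def gaps(self) -> list[BiodistributionSample]:
        """Censored samples (saturated / below limit of detection)."""
        return [s for s in self.samples if s.flag != "ok"]

    def times(self) -> np.ndarray:
        return np.array([s.time_h for s in self.quantified])

    def concentrations(self) -> np.ndarray:
        return np.array([s.pct_id_per_g for s in self.quantified])


REQUIRED_COLUMNS = ("tissue", "time_h", "pct_id_per_g", "sd", "n")


def load_biodistribution(path) -> list[BiodistributionSeries]:
    """Read a biodistribution CSV into one series per tissue.

    Expected columns: ``tissue, time_h, pct_id_per_g, sd, n`` and an
    optional ``flag`` column (``ok`` / ``saturated`` / ``below_lod``).
    Censored rows may leave ``pct_id_per_g`` empty.  Raises on missing
    columns, duplicate times within a tissue, or negative concentrations.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    if "flag" not in df.columns:
        df["flag"] = "ok"
    df["flag"] = df["flag"].fillna("ok")

    series = []
    for tissue, grp in df.groupby("tissue", sort=False):
        grp = grp.sort_values("time_h")
        if grp["time_h"].duplicated().any():
            raise ValueError(f"{tissue}: duplicate time rows")
        samples = []
        for _, row in grp.iterrows():
            conc = row["pct_id_per_g"]
            flag = str(row["flag"])
            if pd.isna(conc):
                if flag == "ok":
                    raise ValueError(
                        f"{tissue}: missing concentration on an 'ok' row"
                    )
                conc = math.nan
            samples.append(
                BiodistributionSample(
                    time_h=float(row["time_h"]),
                    pct_id_per_g=float(conc),
                    sd=float(row["sd"]) if not pd.isna(row["sd"]) else 0.0,
                    n=int(row["n"]),
                    flag=flag,
                )
            )
        series.append(BiodistributionSeries(tissue=str(tissue), samples=samples))
    return series


def apply_physical_decay(
    series: BiodistributionSeries,
    spectrum: EmissionSpectrum,
    mode: str = "to_physical",
) -> BiodistributionSeries:
    """Convert between decay-corrected and physical activity concentration.

    ``mode='to_physical'`` multiplies decay-corrected values by
    ``exp(-lambda_p * t)`` (re-applying the physical decay removed at
    acquisition); ``mode='to_corrected'`` inverts that.  A series already in
    the requested convention passes through unchanged, so the transformation
    is an involution-free round trip.
    """
    if mode not in ("to_physical", "to_corrected"):
        raise ValueError(f"unknown mode {mode!r}")
    want_corrected = mode == "to_corrected"
    if series.decay_corrected == want_corrected:
        return series
    lam = spectrum.decay_constant_per_hour
    sign = -1.0 if mode == "to_physical" else 1.0
    samples = [
        BiodistributionSample(
            time_h=s.time_h,
            pct_id_per_g=s.pct_id_per_g * math.exp(sign * lam * s.time_h),
            sd=s.sd * math.exp(sign * lam * s.time_h),
            n=s.n,
            flag=s.flag,
        )
        for s in series.samples
    ]
    return BiodistributionSeries(
        tissue=series.tissue, samples=samples, decay_corrected=want_corrected
    )


@dataclass(frozen=True)
class TimeActivityCurve:
    """Hybrid trapezoid + mono-exponential time-activity curve.

    ``head`` holds the (time, concentration) nodes before the breakpoint;
    the tail is ``amplitude * exp(-lambda_eff * t)`` for ``t >=
    tail_start_h``.  Concentrations are physical (decay included) %ID/g.
    """

    tissue: str
    head: tuple[tuple[float, float], ...]
    tail_amplitude: float
    lambda_eff_per_h: float
    tail_start_h: float
    fit_r2: float
    last_datum_h: float

    def __post_init__(self) -> None:
        if self.tail_amplitude < 0:
            raise ValueError("tail amplitude must be >= 0")
        if self.lambda_eff_per_h <= 0:
            raise ValueError(
                "effective decay constant must be positive for an "
                "integrable tail"
            )

    def tail_value(self, t_h: float) -> float:
        return self.tail_amplitude * math.exp(-self.lambda_eff_per_h * t_h)

    @property
    def effective_half_life_h(self) -> float:
        return math.log(2.0) / self.lambda_eff_per_h


def _loglinear_fit(t: np.ndarray, c: np.ndarray) -> tuple[float, float, float]:
    """OLS fit of log(c) vs t; returns (amplitude, lambda, r2)."""
    y = np.log(c)
    slope, intercept = np.polyfit(t, y, 1)
    pred = slope * t + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res < 1e-20 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return float(np.exp(intercept)), float(-slope), r2


def fit_tail_exponential(
    series: BiodistributionSeries,
    r2_threshold: float = 0.9,
    min_tail_points: int = 3,
) -> TimeActivityCurve:
    """Fit the hybrid trapezoid-exponential time-activity curve.

    The breakpoint is the *earliest* time point such that an ordinary
    least-squares log-linear fit of that point and all later points reaches
    ``R^2 >= r2_threshold`` with at least ``min_tail_points`` points; all
    earlier points become trapezoid head nodes.  The series must be in
    physical-activity convention (apply :func:`apply_physical_decay` first).
    Zero or negative values cannot enter the log fit and are dropped from
    tail candidates with a warning.
    """
    if series.decay_corrected:
        raise ValueError(
            "series is decay-corrected; apply_physical_decay(..., "
            "'to_physical') before fitting"
        )
    if not 0.0 < r2_threshold < 1.0:
        raise ValueError("r2_threshold must lie in (0, 1)")
    quantified = series.quantified
    if len(quantified) < min_tail_points:
        raise ValueError(
            f"{series.tissue}: need at least {min_tail_points} quantified "
            "points"
        )
    pos = [s for s in quantified if s.pct_id_per_g > 0]
    if len(pos) < len(quantified):
        warnings.warn(
            f"{series.tissue}: dropped {len(quantified) - len(pos)} "
            "non-positive values from tail candidates"
        )
    t = np.array([s.time_h for s in pos])
    c = np.array([s.pct_id_per_g for s in pos])

    for i in range(0, len(t) - min_tail_points + 1):
        amp, lam, r2 = _loglinear_fit(t[i:], c[i:])
        if r2 >= r2_threshold and lam > 0:
            head = tuple((float(tt), float(cc)) for tt, cc in zip(t[:i], c[:i]))
            return TimeActivityCurve(
                tissue=series.tissue,
                head=head,
                tail_amplitude=amp,
                lambda_eff_per_h=lam,
                tail_start_h=float(t[i]),
                fit_r2=r2,
                last_datum_h=float(t[-1]),
            )
    raise ValueError(
        f"{series.tissue}: no breakpoint gives a tail with R^2 >= "
        f"{r2_threshold}; relax the threshold or supply more points"
    )


@dataclass(frozen=True)
class TiacCoefficient:
    """Time-integrated activity coefficient for one tissue.

    ``value`` is in MBq.h per gram of tissue per MBq injected, i.e. the
    integral of the physical fractional activity concentration (fraction of
    injected activity per gram) over all time, in hours.  Equivalently,
    1 MBq.h/g per MBq is 3.6e9 decays per gram per MBq injected.
    """

    tissue: str
    value: float
    breakpoint_time_h: float
    extrapolated_fraction: float

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("TIAC must be positive")
        if not 0.0 <= self.extrapolated_fraction <= 1.0:
            raise ValueError("extrapolated fraction must lie in [0, 1]")


def time_integrated_activity(curve: TimeActivityCurve) -> TiacCoefficient:
    """Integrate a time-activity curve to a TIAC.

    Head: trapezoid over the head nodes plus the tail value at the
    breakpoint, with a flat-back extrapolation from the first node to t=0
    (conservative default when the earliest points are censored).  Tail:
    analytic ``A*exp(-lambda*t)/lambda`` from the breakpoint to infinity.
    Input concentrations are %ID/g; the returned value is per-unit (fraction
    of injected activity), hence the /100.
    """
    if curve.lambda_eff_per_h <= 0:
        raise ValueError("tail is not integrable (lambda_eff <= 0)")
    nodes = list(curve.head) + [(curve.tail_start_h, curve.tail_value(curve.tail_start_h))]
    t = np.array([n[0] for n in nodes])
    c = np.array([n[1] for n in nodes])
    head_integral = float(np.trapezoid(c, t))
    # flat-back extrapolation from the first quantified node to t = 0
    head_integral += float(c[0] * t[0])
    tail_integral = curve.tail_value(curve.tail_start_h) / curve.lambda_eff_per_h
    beyond_last = curve.tail_value(curve.last_datum_h) / curve.lambda_eff_per_h
    total = head_integral + tail_integral
    return TiacCoefficient(
        tissue=curve.tissue,
        value=total / 100.0,
        breakpoint_time_h=curve.tail_start_h,
        extrapolated_fraction=beyond_last / total,
    )
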