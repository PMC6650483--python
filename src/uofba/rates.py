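"""Growth and exchange rate calculation from cell-culture time courses.

A batch culture growing exponentially obeys

    N_x(t) = N_x0 * exp(mu * t)

and the cell-specific exchange rate of a metabolite over a window follows
from dividing the concentration change by the integral of viable cell
density (IVCD):

    r = V * dC / integral(N_x dt) = mu * V * dC / (N_x0 * (exp(mu*t) - 1))

with r in mmol per 10^6 cells per hour (production positive, consumption
negative), V the culture volume in mL, dC in mM and t the window length in
hours.  Rates are converted to genome-scale model units (mmol/gDW/h) with an
assumed cell dry weight, 216.1 pg/cell by default; reported literature values
for mammalian cells range several-fold higher, so the dry weight is always an
explicit, overridable parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "TimeCourse",
    "RateEstimates",
    "fit_growth_rate",
    "specific_exchange_rate",
    "to_dw_specific",
    "estimate_rates",
    "read_timecourse",
    "write_timecourse",
    "DEFAULT_DRY_WEIGHT_PG",
]

#: assumed cell dry weight (pg/cell) used for unit conversion by default
DEFAULT_DRY_WEIGHT_PG = 216.1

#: below this value of mu*t the exponential quotient is replaced by its limit
_SMALL_MUT = 1e-8


@dataclass
class TimeCourse:
    """A batch-culture time course (constant volume).

    times in hours; vcd in 10^6 viable cells/mL; concentrations in mM.
    """

    times: np.ndarray
    vcd: np.ndarray
    concentrations: Dict[str, np.ndarray]
    volume: float
    viability: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.vcd = np.asarray(self.vcd, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.vcd < 0):
            raise ValueError("viable cell density must be non-negative")
        if len(self.vcd) != len(self.times):
            raise ValueError("vcd and times must have equal length")
        self.concentrations = {k: np.asarray(v, dtype=float) for k, v in self.concentrations.items()}
        for k, v in self.concentrations.items():
            if len(v) != len(self.times):
                raise ValueError(f"concentration series {k!r} length mismatch")
            if np.any(v < -1e-12):
                raise ValueError(f"concentration series {k!r} has negative values")

    def window_slice(self, window: Optional[Tuple[float, float]]) -> np.ndarray:
        if window is None:
            return np.ones_like(self.times, dtype=bool)
        t0, t1 = window
        if t0 < self.times[0] - 1e-9 or t1 > self.times[-1] + 1e-9:
            raise ValueError(f"window {window} outside the time course")
        return (self.times >= t0 - 1e-9) & (self.times <= t1 + 1e-9)


@dataclass
class RateEstimates:
    mu: float                       # 1/h
    mu_stderr: float                # 1/h
    window: Tuple[float, float]     # h
    specific_rates: Dict[str, float]      # mmol/10^6 cells/h, production positive
    dw_specific_rates: Dict[str, float]   # mmol/gDW/h, production positive
    dry_weight: float = DEFAULT_DRY_WEIGHT_PG  # pg/cell


def fit_growth_rate(tc: TimeCourse, window: Optional[Tuple[float, float]] = None
                    ) -> Tuple[float, float]:
    """Least-squares fit of ln(VCD) against time; returns (mu, standard error).

    The log-linear form of the exponential growth model keeps the fit
    deterministic and makes the standard error the usual OLS slope error.
    """
    mask = tc.window_slice(window)
    t = tc.times[mask]
    n = tc.vcd[mask]
    if len(t) < 3:
        raise ValueError(f"need at least 3 time points in the window, got {len(t)}")
    if np.any(n <= 0):
        raise ValueError("all VCD values in the fit window must be positive")
    from scipy.stats import linregress

    fit = linregress(t, np.log(n))
    stderr = float(fit.stderr) if np.isfinite(fit.stderr) else 0.0
    return float(fit.slope), stderr


def specific_exchange_rate(
    tc: TimeCourse,
    metabolite: str,
    mu: float,
    window: Optional[Tuple[float, float]] = None,
) -> float:
    """Cell-specific exchange rate over a window (mmol/10^6 cells/h).

    Production is positive, consumption negative.  For vanishing ``mu*t`` the
    exponential IVCD denominator is replaced by its linear limit
    ``N_x0 * t``, which removes the 0/0.
    """
    mask = tc.window_slice(window)
    t = tc.times[mask]
    conc = tc.concentrations[metabolite][mask]
    n0 = tc.vcd[mask][0] * tc.volume  # 10^6 cells at window start
    dt = t[-1] - t[0]
    dC = conc[-1] - conc[0]
    if dt <= 0:
        raise ValueError("window must span positive time")
    if n0 <= 0:
        raise ValueError("initial cell count in the window must be positive")
    mut = mu * dt
    if abs(mut) < _SMALL_MUT:
        ivcd = n0 * dt
    else:
        ivcd = n0 * (math.exp(mut) - 1.0) / mu
    return tc.volume * dC / ivcd


def to_dw_specific(rate: float, dry_weight: float = DEFAULT_DRY_WEIGHT_PG) -> float:
    """Convert mmol/10^6 cells/h to mmol/gDW/h for a given dry weight (pg/cell)."""
    if dry_weight <= 0:
        raise ValueError("dry weight must be positive")
    grams_per_1e6_cells = dry_weight * 1e6 * 1e-12
    return rate / grams_per_1e6_cells


def estimate_rates(
    tc: TimeCourse,
    growth_window: Optional[Tuple[float, float]] = None,
    rate_window: Optional[Tuple[float, float]] = None,
    dry_weight: float = DEFAULT_DRY_WEIGHT_PG,
) -> RateEstimates:
    """Full pipeline: growth fit, per-metabolite exchange rates, unit conversion.

    Separate growth and rate windows mirror common practice of fitting growth
    over the whole growth phase while computing exchange rates over a later
    sub-window with denser metabolite coverage.
    """
    mu, stderr = fit_growth_rate(tc, growth_window)
    mask = tc.window_slice(rate_window)
    window = (float(tc.times[mask][0]), float(tc.times[mask][-1]))
    rates = {
        met: specific_exchange_rate(tc, met, mu, rate_window)
        for met in sorted(tc.concentrations)
    }
    dw_rates = {met: to_dw_specific(r, dry_weight) for met, r in rates.items()}
    return RateEstimates(
        mu=mu,
        mu_stderr=stderr,
        window=window,
        specific_rates=rates,
        dw_specific_rates=dw_rates,
        dry_weight=dry_weight,
    )


# ---------------------------------------------------------------------------
# tidy TSV IO
# ---------------------------------------------------------------------------

def read_timecourse(path) -> TimeCourse:
    """Read a tidy TSV: columns time_h, vcd_e6_per_ml, volume_ml, then metabolites (mM)."""
    df = pd.read_csv(path, sep="\t")
    required = {"time_h", "vcd_e6_per_ml", "volume_ml"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"time-course file {path} missing columns {sorted(missing)}")
    vol = df["volume_ml"].iloc[0]
    if not np.allclose(df["volume_ml"], vol):
        raise ValueError("constant culture volume expected (batch assumption)")
    mets = [c for c in df.columns if c not in required]
    return TimeCourse(
        times=df["time_h"].to_numpy(),
        vcd=df["vcd_e6_per_ml"].to_numpy(),
        concentrations={m: df[m].to_numpy() for m in mets},
        volume=float(vol),
    )


def write_timecourse(tc: TimeCourse, path) -> None:
    data = {"time_h": tc.times, "vcd_e6_per_ml": tc.vcd,
            "volume_ml": np.full_like(tc.times, tc.volume)}
    for met in sorted(tc.concentrations):
        data[met] = tc.concentrations[met]
    pd.DataFrame(data).to_csv(Path(path), sep="\t", index=False, float_format="%.9g")
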