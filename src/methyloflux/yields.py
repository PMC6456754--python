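"""Growth rates from OD time series and specific-rate / yield arithmetic."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

METHANOL_MOLAR_MASS = 0.03204  # g/mmol


@dataclass
class RateSet:
    """Measured specific rates, all in mmol/(gcdw.h) except growth_rate."""

    methanol_uptake: float
    product_rates: dict[str, float] = field(default_factory=dict)
    growth_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.methanol_uptake < 0 or self.growth_rate < 0:
            raise ValueError("rates must be >= 0")
        for prod, rate in self.product_rates.items():
            if rate < 0:
                raise ValueError(f"product rate for {prod} must be >= 0")


@dataclass
class YieldResult:
    product_yield: dict[str, float]   # mmol product / mmol methanol
    biomass_yield: float              # g biomass / g methanol


def fit_growth_rate(times, ods) -> tuple[float, float]:
    """Least-squares slope of ln(OD) vs time.

    Returns (rate in 1/h, R^2).  Requires >= 3 strictly increasing time
    points and positive ODs.
    """
    times = np.asarray(times, dtype=float)
    ods = np.asarray(ods, dtype=float)
    if times.size < 3 or times.size != ods.size:
        raise ValueError("need >= 3 matching (time, OD) points")
    if (np.diff(times) <= 0).any():
        raise ValueError("time points must be strictly increasing")
    if (ods <= 0).any():
        raise ValueError("ODs must be positive")
    y = np.log(ods)
    slope, intercept = np.polyfit(times, y, 1)
    fitted = slope * times + intercept
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(slope), r2


def product_yield(rates: RateSet) -> dict[str, float]:
    """Per-product yield: rate / methanol uptake (mmol/mmol)."""
    if rates.methanol_uptake <= 0:
        raise ZeroDivisionError("methanol uptake must be > 0 for yields")
    return {p: r / rates.methanol_uptake
            for p, r in rates.product_rates.items()}


def biomass_yield(growth_rate: float, methanol_uptake: float,
                  methanol_molar_mass: float = METHANOL_MOLAR_MASS) -> float:
    """g biomass per g methanol: growth / (uptake * molar mass)."""
    if methanol_uptake <= 0:
        raise ZeroDivisionError("methanol uptake must be > 0")
    return growth_rate / (methanol_uptake * methanol_molar_mass)


def yields(rates: RateSet,
           methanol_molar_mass: float = METHANOL_MOLAR_MASS) -> YieldResult:
    return YieldResult(
        product_yield=product_yield(rates),
        biomass_yield=biomass_yield(rates.growth_rate, rates.methanol_uptake,
                                    methanol_molar_mass),
    )
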