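"""Seeded synthetic-data generators for every pipeline input.

All generators are pure functions of their spec (seed included): the same
spec yields byte-identical files.  Numeric output uses fixed formatting to
guarantee this.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .mid import LabelParams, LabelDataset, simulate_labeling

FLOAT_FMT = "%.10g"

#: strain presets mirroring the wild type and the double knockout
STRAIN_PRESETS: dict[str, LabelParams] = {
    "WT": LabelParams(p_pdh=0.33, f_co2=0.24),
    "dldh_dmdh": LabelParams(p_pdh=0.73, f_co2=0.24),
}

#: default pool fold changes (methanol over methane); KDPG dominates the
#: increases, lower-glycolysis and pentose pools decrease
DEFAULT_POOL_EFFECTS: dict[str, float] = {
    "KDPG": 60.0,
    "6PG": 4.0,
    "G6P": 3.0,
    "FBP": 3.0,
    "F6P": 2.5,
    "citrate": 2.5,
    "PEP": 0.3,
    "2PG+3PG": 0.35,
    "R5P": 0.35,
    "malate": 1.0,
    "succinate": 1.0,
    "2-oxoglutarate": 1.0,
}


@dataclass
class SynthSpec:
    seed: int = 0
    label_params: dict[str, LabelParams] = field(
        default_factory=lambda: {k: LabelParams(v.p_pdh, v.f_co2)
                                 for k, v in STRAIN_PRESETS.items()})
    pool_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_POOL_EFFECTS))
    replicate_count: int = 3
    noise_cv: float = 0.2
    growth_mu: dict[str, float] = field(
        default_factory=lambda: {"methanol": 0.205, "methane": 0.23})
    od_noise_cv: float = 0.0
    od_start: float = 0.01
    od_duration_h: float = 24.0
    od_points: int = 13

    def __post_init__(self) -> None:
        if any(fc <= 0 for fc in self.pool_effects.values()):
            raise ValueError("pool fold changes must be > 0")
        if self.replicate_count < 2:
            raise ValueError("need >= 2 replicates per condition")


# ---------------------------------------------------------------------------
# labeling data


def gen_label_datasets(spec: SynthSpec) -> dict[str, LabelDataset]:
    return {strain: simulate_labeling(params, seed=spec.seed, strain=strain)
            for strain, params in sorted(spec.label_params.items())}


def label_table(datasets: dict[str, LabelDataset]) -> pd.DataFrame:
    rows = []
    for strain in sorted(datasets):
        ds = datasets[strain]
        for met in sorted(ds.mids):
            mid = ds.mids[met]
            for shift, frac in enumerate(mid.fractions):
                rows.append({"strain": strain, "metabolite": met,
                             "mass_shift": shift, "fraction": frac})
    return pd.DataFrame(rows)


def gen_label_data(spec: SynthSpec, path: str | Path) -> Path:
    """Write MID tables (columns strain, metabolite, mass_shift, fraction)."""
    path = Path(path)
    df = label_table(gen_label_datasets(spec))
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    return path


def read_label_data(path: str | Path) -> dict[str, LabelDataset]:
    from .mid import MID
    df = pd.read_csv(path, sep="\t")
    needed = {"strain", "metabolite", "mass_shift", "fraction"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"MID table {path} missing columns: {sorted(missing)}")
    out: dict[str, LabelDataset] = {}
    for strain, sgrp in df.groupby("strain"):
        mids = {}
        for met, mgrp in sgrp.groupby("metabolite"):
            mgrp = mgrp.sort_values("mass_shift")
            n = int(mgrp["mass_shift"].max())
            frac = np.zeros(n + 1)
            frac[mgrp["mass_shift"].to_numpy(int)] = mgrp["fraction"]
            mids[str(met)] = MID(str(met), frac / frac.sum())
        out[str(strain)] = LabelDataset(str(strain), mids)
    return out


# ---------------------------------------------------------------------------
# metabolite pools


def gen_pool_table(spec: SynthSpec) -> pd.DataFrame:
    """Lognormal replicate pools whose condition means differ by the
    configured fold changes, with internal-standard and biomass columns."""
    rng = np.random.default_rng(spec.seed)
    sigma = np.sqrt(np.log(1.0 + spec.noise_cv ** 2))
    rows = []
    for met in sorted(spec.pool_effects):
        fc = spec.pool_effects[met]
        for condition, mean in (("methane", 1.0), ("methanol", fc)):
            for rep in range(1, spec.replicate_count + 1):
                abundance = rng.lognormal(np.log(mean) - sigma ** 2 / 2, sigma)
                is_signal = rng.lognormal(0.0, 0.05)
                biomass = 5e-4 * rng.lognormal(0.0, 0.05)
                rows.append({
                    "metabolite": met, "condition": condition,
                    "replicate": rep,
                    "signal": abundance * is_signal * biomass,
                    "is_signal": is_signal, "biomass": biomass,
                })
    return pd.DataFrame(rows)


def gen_pool_data(spec: SynthSpec, path: str | Path) -> Path:
    path = Path(path)
    gen_pool_table(spec).to_csv(path, sep="\t", index=False,
                                float_format=FLOAT_FMT)
    return path


# ---------------------------------------------------------------------------
# growth curves


def gen_growth_table(spec: SynthSpec) -> pd.DataFrame:
    """Exponential OD600 series from the configured start OD, one series per
    condition, with optional multiplicative lognormal noise."""
    rng = np.random.default_rng(spec.seed)
    times = np.linspace(0.0, spec.od_duration_h, spec.od_points)
    sigma = (np.sqrt(np.log(1.0 + spec.od_noise_cv ** 2))
             if spec.od_noise_cv > 0 else 0.0)
    rows = []
    for condition in sorted(spec.growth_mu):
        mu = spec.growth_mu[condition]
        if mu < 0:
            raise ValueError("growth_mu must be >= 0")
        od = spec.od_start * np.exp(mu * times)
        if sigma > 0:
            od = od * rng.lognormal(-sigma ** 2 / 2, sigma, size=od.size)
        for t, o in zip(times, od):
            rows.append({"condition": condition, "time_h": t, "od600": o})
    return pd.DataFrame(rows)


def gen_growth_curves(spec: SynthSpec, path: str | Path) -> Path:
    path = Path(path)
    gen_growth_table(spec).to_csv(path, sep="\t", index=False,
                                  float_format=FLOAT_FMT)
    return path
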