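"""Metabolite-pool fold-change (volcano) analysis.

Pools are normalized to an internal standard and to cell biomass, compared
between two growth conditions (methanol vs methane) as log2 fold changes of
normalized means, and tested with Welch's unequal-variance t-test on
log-transformed normalized abundances.  No multiple-testing correction by
default; Benjamini-Hochberg optionally.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CONDITIONS = ("methane", "methanol")

POOL_COLUMNS = ["metabolite", "condition", "replicate", "signal",
                "is_signal", "biomass"]


@dataclass
class PoolMeasurement:
    metabolite: str
    condition: str      # "methane" | "methanol"
    replicate: int
    signal: float       # raw peak response
    is_signal: float    # internal-standard peak response
    biomass: float      # gcdw of the extracted sample

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.signal <= 0 or self.is_signal <= 0 or self.biomass <= 0:
            raise ValueError("signal, is_signal and biomass must be > 0")


def normalize_pool(m: PoolMeasurement) -> float:
    """Normalized abundance: signal / (internal standard * biomass)."""
    return m.signal / (m.is_signal * m.biomass)


def _normalized_frame(pools) -> pd.DataFrame:
    if isinstance(pools, pd.DataFrame):
        df = pools.copy()
        missing = [c for c in POOL_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"pool table missing columns: {missing}")
        bad = (df[["signal", "is_signal", "biomass"]] <= 0).any(axis=1)
        if bad.any():
            raise ValueError("signal, is_signal and biomass must be > 0")
    else:
        df = pd.DataFrame([vars(p) for p in pools])
    df["abundance"] = df["signal"] / (df["is_signal"] * df["biomass"])
    return df


def volcano(pools, fc_threshold: float = 2.0, p_threshold: float = 0.05,
            bh_correct: bool = False) -> pd.DataFrame:
    """Per-metabolite log2 fold change (methanol over methane) and two-sided
    Welch p-value on log abundances, with category assignment.

    ``pools`` is a list of :class:`PoolMeasurement` or a DataFrame with the
    same columns.  Metabolites lacking either condition (or with < 2
    replicates in one) are skipped with a warning.  Returns a DataFrame with
    columns metabolite, log2_fc, p_value, category and attrs recording the
    test used.
    """
    if fc_threshold < 1:
        raise ValueError("fc_threshold must be >= 1")
    df = _normalized_frame(pools)
    rows = []
    for met, grp in df.groupby("metabolite", sort=True):
        a = grp.loc[grp["condition"] == "methanol", "abundance"].to_numpy()
        b = grp.loc[grp["condition"] == "methane", "abundance"].to_numpy()
        if len(a) < 2 or len(b) < 2:
            logger.warning("metabolite %s skipped: needs >=2 replicates per "
                           "condition (have %d methanol, %d methane)",
                           met, len(a), len(b))
            continue
        log2_fc = float(np.log2(a.mean() / b.mean()))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            _, p = stats.ttest_ind(np.log(a), np.log(b), equal_var=False)
        p = float(p) if np.isfinite(p) else 1.0
        rows.append({"metabolite": met, "log2_fc": log2_fc, "p_value": p})
    out = pd.DataFrame(rows, columns=["metabolite", "log2_fc", "p_value"])
    if bh_correct and len(out):
        out["p_value"] = _benjamini_hochberg(out["p_value"].to_numpy())
    thr = np.log2(fc_threshold)
    cat = np.where(
        (out["log2_fc"] >= thr) & (out["p_value"] < p_threshold), "increased",
        np.where((out["log2_fc"] <= -thr) & (out["p_value"] < p_threshold),
                 "decreased", "unchanged"))
    out["category"] = cat
    out.attrs["test"] = "welch_t_log"
    out.attrs["bh_corrected"] = bh_correct
    out.attrs["fc_threshold"] = fc_threshold
    out.attrs["p_threshold"] = p_threshold
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0, 1)
    return out


def read_pool_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in POOL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"pool table {path} missing columns: {missing}")
    return df
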