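"""Mass-isotopomer distribution (MID) algebra for the acetyl-CoA node.

Forward model (single ring-labeled C source, partially labeled CO2 pool):

* De novo OAA and malate come from carboxylation of a fully labeled C3
  backbone, so their MIDs sit on M+3 (unlabeled CO2 incorporated) and M+4
  (labeled CO2 incorporated): ``(M+3, M+4) = (1-f, f)`` with ``f`` the
  labeled fraction of the CO2 pool.
* Acetyl-CoA from pyruvate (PDH route) is fully labeled (M+2); acetyl-CoA
  from malate cleavage (MCL route) inherits one carbon from the CO2 pool,
  so it is M+2 with probability ``f`` and M+1 otherwise.
* Citrate is the condensation of OAA with acetyl-CoA: its MID is the
  convolution of the two.

Inverse estimators recover the acetyl-CoA MID from citrate and an OAA
proxy (threonine backbone), the PDH/MCL split from the acetyl-CoA MID and
malate, and the CO2 labeled fraction from the OAA proxy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

IDENTIFIABILITY_TOL = 1e-9
NORMALIZATION_TOL = 1e-6


class DegenerateInputError(ValueError):
    pass


class UnidentifiableError(ValueError):
    pass


@dataclass
class MID:
    """Fractional mass-isotopomer vector M+0..M+n for one metabolite."""

    metabolite: str
    fractions: np.ndarray

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.fractions.ndim != 1 or self.fractions.size == 0:
            raise ValueError("fractions must be a nonempty 1-D vector")
        if (self.fractions < -NORMALIZATION_TOL).any():
            raise ValueError(f"{self.metabolite}: negative MID fraction")
        total = self.fractions.sum()
        if abs(total - 1.0) > NORMALIZATION_TOL:
            raise ValueError(
                f"{self.metabolite}: MID sums to {total:.6g}, not 1 "
                "(use normalize_mid first)")

    def __getitem__(self, mass_shift: int) -> float:
        if 0 <= mass_shift < self.fractions.size:
            return float(self.fractions[mass_shift])
        return 0.0

    @property
    def n_carbons(self) -> int:
        return self.fractions.size - 1


def normalize_mid(raw, metabolite: str = "") -> MID:
    """Scale a nonnegative vector to sum to 1 (order preserved)."""
    raw = np.asarray(raw, dtype=float)
    if (raw < 0).any():
        raise ValueError("raw MID entries must be nonnegative")
    total = raw.sum()
    if total <= 0:
        raise DegenerateInputError("all-zero MID vector cannot be normalized")
    return MID(metabolite, raw / total)


def convolve_mids(a: MID, b: MID, metabolite: str = "") -> MID:
    """MID of a condensation product: result[k] = sum_i a[i] * b[k-i]."""
    out = np.convolve(a.fractions, b.fractions)
    out = np.clip(out, 0.0, None)
    return MID(metabolite or f"{a.metabolite}+{b.metabolite}",
               out / out.sum())


@dataclass
class LabelParams:
    """Two-parameter forward labeling model plus measurement noise."""

    p_pdh: float       # fraction of de novo AcCoA made via PDH
    f_co2: float       # labeled fraction of the CO2 pool
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.p_pdh <= 1:
            raise ValueError("p_pdh must be in [0, 1]")
        if not 0 <= self.f_co2 <= 1:
            raise ValueError("f_co2 must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class FluxSplit:
    """Relative PDH vs MCL contributions to de novo acetyl-CoA."""

    f_pdh: float
    f_mcl: float
    raw_pdh: float
    raw_mcl: float
    clipped: bool = False


@dataclass
class LabelDataset:
    strain: str
    mids: dict[str, MID]

    def require(self, metabolite: str) -> MID:
        if metabolite not in self.mids:
            raise KeyError(
                f"dataset {self.strain!r} lacks required metabolite "
                f"{metabolite!r}")
        return self.mids[metabolite]


@dataclass
class AnalysisResult:
    strain: str
    flux_split: FluxSplit
    co2_fraction: float
    accoa_m1: float
    accoa_m2: float
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# forward model


def accoa_mid(params: LabelParams) -> MID:
    """Noise-free acetyl-CoA MID implied by (p_pdh, f_co2)."""
    p, f = params.p_pdh, params.f_co2
    m2 = p + (1.0 - p) * f
    m1 = (1.0 - p) * (1.0 - f)
    return MID("AcCoA", np.array([0.0, m1, m2]))


def oaa_mid(params: LabelParams) -> MID:
    """Noise-free OAA/malate MID: fully labeled C3 + CO2 carboxylation."""
    f = params.f_co2
    return MID("OAA", np.array([0.0, 0.0, 0.0, 1.0 - f, f]))


def simulate_labeling(params: LabelParams, seed: int | None = 0,
                      strain: str = "WT") -> LabelDataset:
    """Generate a labeling dataset (citrate, threonine, malate, succinate)
    from the two-parameter model, with optional truncated-Gaussian noise per
    mass channel followed by renormalization.  Deterministic under seed."""
    oaa = oaa_mid(params)
    acc = accoa_mid(params)
    citrate = convolve_mids(oaa, acc, metabolite="citrate")
    clean = {
        "citrate": citrate.fractions,
        "threonine": oaa.fractions.copy(),   # 4-carbon OAA proxy
        "malate": oaa.fractions.copy(),
        "succinate": oaa.fractions.copy(),   # carried, unused in estimation
    }
    rng = np.random.default_rng(seed)
    mids = {}
    for met, frac in clean.items():
        if params.noise_sd > 0:
            noisy = frac + rng.normal(0.0, params.noise_sd, size=frac.size)
            noisy = np.clip(noisy, 0.0, None)  # truncation at zero
            mids[met] = normalize_mid(noisy, met)
        else:
            mids[met] = MID(met, frac)
    return LabelDataset(strain, mids)


# ---------------------------------------------------------------------------
# inverse estimators


def estimate_accoa_mid(citrate: MID, oaa: MID) -> tuple[float, float, bool]:
    """Recover acetyl-CoA M+1/M+2 from citrate and OAA MIDs.

    Solves citrate[M+4] = OAA[M+3]*Ac[M+1] and
    citrate[M+5] = OAA[M+3]*Ac[M+2] + OAA[M+4]*Ac[M+1].
    Returns (m1, m2, clipped); negatives are clipped to 0 and flagged.
    """
    if oaa[3] <= IDENTIFIABILITY_TOL:
        raise UnidentifiableError(
            "OAA M+3 fraction ~ 0: acetyl-CoA MID not identifiable")
    m1 = citrate[4] / oaa[3]
    m2 = (citrate[5] - oaa[4] * m1) / oaa[3]
    clipped = False
    if m1 < 0:
        m1, clipped = 0.0, True
    if m2 < 0:
        m2, clipped = 0.0, True
    return m1, m2, clipped


def estimate_flux_split(accoa_m1: float, accoa_m2: float,
                        malate: MID) -> FluxSplit:
    """PDH/MCL split from the acetyl-CoA MID and the malate MID.

    Solves F_MCL * Mal[M+3] = Ac[M+1] and
    F_PDH + F_MCL * Mal[M+4] = Ac[M+2], then normalizes to fractions.
    """
    if malate[3] <= IDENTIFIABILITY_TOL:
        raise UnidentifiableError(
            "malate M+3 fraction ~ 0: flux split not identifiable")
    raw_mcl = accoa_m1 / malate[3]
    raw_pdh = accoa_m2 - raw_mcl * malate[4]
    clipped = False
    if raw_pdh < 0:
        raw_pdh, clipped = 0.0, True
    if raw_mcl < 0:
        raw_mcl, clipped = 0.0, True
    total = raw_pdh + raw_mcl
    if total <= IDENTIFIABILITY_TOL:
        raise UnidentifiableError("both route contributions ~ 0")
    return FluxSplit(f_pdh=raw_pdh / total, f_mcl=raw_mcl / total,
                     raw_pdh=raw_pdh, raw_mcl=raw_mcl, clipped=clipped)


def estimate_co2_fraction(oaa: MID) -> float:
    """Labeled fraction of the CO2 pool from the OAA (threonine) MID:
    M+4 / (M+3 + M+4)."""
    denom = oaa[3] + oaa[4]
    if denom <= IDENTIFIABILITY_TOL:
        raise UnidentifiableError("OAA M+3 + M+4 ~ 0: CO2 pool unidentifiable")
    return oaa[4] / denom


def analyze_dataset(data: LabelDataset) -> AnalysisResult:
    """Full estimator chain: citrate + threonine -> acetyl-CoA MID ->
    PDH/MCL split (malate) and CO2 labeled fraction (threonine).

    Diagnostics carry clipping flags and the naive alternative ratio
    Ac[M+1]/Ac[M+2] (which equates PDH/MCL with the M+1/M+2 ratio); it is
    inconsistent with the route mechanism and reported for comparison only.
    """
    citrate = data.require("citrate")
    threonine = data.require("threonine")
    malate = data.require("malate")
    m1, m2, acc_clipped = estimate_accoa_mid(citrate, threonine)
    split = estimate_flux_split(m1, m2, malate)
    co2 = estimate_co2_fraction(threonine)
    alt_ratio = (m1 / m2) if m2 > IDENTIFIABILITY_TOL else float("inf")
    primary_ratio = (split.f_pdh / split.f_mcl
                     if split.f_mcl > IDENTIFIABILITY_TOL else float("inf"))
    # residual of the condensation model on the unused citrate M+6 channel
    resid_m6 = citrate[6] - threonine[4] * m2
    diagnostics = {
        "accoa_clipped": acc_clipped,
        "split_clipped": split.clipped,
        "alt_pdh_mcl_ratio": alt_ratio,
        "primary_pdh_mcl_ratio": primary_ratio,
        "alt_ratio_discrepancy": alt_ratio - primary_ratio,
        "citrate_m6_residual": resid_m6,
    }
    return AnalysisResult(strain=data.strain, flux_split=split,
                          co2_fraction=co2, accoa_m1=m1, accoa_m2=m2,
                          diagnostics=diagnostics)
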