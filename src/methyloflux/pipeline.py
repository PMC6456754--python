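"""End-to-end orchestration: labeling analysis -> flux-ratio constraint ->
FBA scenario ladder -> pool volcano -> yields -> combined report.

Stage failures are isolated: each stage records ok/error status in the
summary, downstream stages that depend on a failed stage are skipped, and
the run exits nonzero iff any stage errored.
"""

from __future__ import annotations

import json
import logging
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import fba, metabolomics, mid, model_io, synth
from .yields import RateSet, yields as compute_yields

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    model_path: str | None = None
    mid_table: str | None = None
    pool_table: str | None = None
    rates_path: str | None = None
    ladder_path: str | None = None
    out_dir: str = "methyloflux_out"
    seed: int = 0
    pinned_mcl_pdh_ratio: float | None = None
    reference_strain: str = "WT"
    minimize_total_flux: bool = False


# ---------------------------------------------------------------------------
# scenario (de)serialization


def scenario_from_dict(d: dict) -> fba.ScenarioConfig:
    maint = d.get("maintenance")
    return fba.ScenarioConfig(
        name=d.get("name", "scenario"),
        methanol_uptake=d.get("methanol_uptake"),
        formate_production=d.get("formate_production"),
        glycogen_fraction=d.get("glycogen_fraction"),
        eps_fraction=d.get("eps_fraction"),
        o2_per_methanol_min=d.get("o2_per_methanol_min"),
        maintenance=(fba.MaintenanceConfig(**maint) if maint else None),
        ratio_constraints=[
            fba.RatioConstraint(rc["numerator"], rc["denominator"],
                                float(rc["ratio"]))
            for rc in d.get("ratio_constraints", [])],
        order_constraints=[
            fba.OrderConstraint(oc["greater"], oc["lesser"])
            for oc in d.get("order_constraints", [])],
        fixed_fluxes={k: float(v)
                      for k, v in d.get("fixed_fluxes", {}).items()},
    )


def load_scenario(path: str | Path) -> fba.ScenarioConfig:
    with open(path, encoding="utf-8") as fh:
        return scenario_from_dict(yaml.safe_load(fh))


def load_ladder(path: str | Path) -> list[fba.ScenarioConfig]:
    """Load a scenario ladder.  Each entry after the first is merged onto the
    previous one: scalar fields override, constraint lists append, fixed
    fluxes update (nested-scenario semantics)."""
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    entries = doc["scenarios"] if isinstance(doc, dict) else doc
    scenarios: list[fba.ScenarioConfig] = []
    for entry in entries:
        sc = scenario_from_dict(entry)
        if scenarios:
            prev = scenarios[-1]
            merged = prev.extended(
                ratio_constraints=sc.ratio_constraints,
                order_constraints=sc.order_constraints,
                fixed_fluxes=sc.fixed_fluxes,
            )
            merged.name = sc.name
            for attr in ("methanol_uptake", "formate_production",
                         "glycogen_fraction", "eps_fraction",
                         "o2_per_methanol_min", "maintenance"):
                val = getattr(sc, attr)
                if val is not None:
                    setattr(merged, attr, val)
            sc = merged
        scenarios.append(sc)
    return scenarios


def default_control_scenario() -> fba.ScenarioConfig:
    """Measured-rate control condition (methanol vials)."""
    return fba.ScenarioConfig(
        name="control",
        methanol_uptake=19.3,
        formate_production=1.82,
        glycogen_fraction=0.42,
        eps_fraction=0.10,
        o2_per_methanol_min=0.5,
        maintenance=fba.MaintenanceConfig(gam=54.35, ngam=8.39),
    )


def default_ladder(model: model_io.MetabolicModel,
                   mcl_pdh_ratio: float = 3.0) -> list[fba.ScenarioConfig]:
    """Control -> TCA-constrained -> MCL/PDH ratio -> ED/EMP = 1 ladder,
    resolved against the model's role annotations."""
    roles = model.annotations.get("roles", {})

    def need(role: str) -> str:
        rid = roles.get(role)
        if rid is None:
            raise fba.ConfigurationError(
                f"default ladder needs model role {role!r}")
        return rid

    control = default_control_scenario()
    tca = control.extended(
        order_constraints=[fba.OrderConstraint(need("akgdh"), need("scs"))],
        fixed_fluxes={need("fumarase"): 0.0})
    tca.name = "TCA_constrained"
    mclpdh = tca.extended(ratio_constraints=[
        fba.RatioConstraint(need("mcl"), need("pdh"), mcl_pdh_ratio)])
    mclpdh.name = "MCL_PDH_constrained"
    edemp = mclpdh.extended(ratio_constraints=[
        fba.RatioConstraint(need("ed"), need("emp"), 1.0)])
    edemp.name = "ED_EMP_constrained"
    return [control, tca, mclpdh, edemp]


# ---------------------------------------------------------------------------
# run-all


def _stage(summary: dict, name: str):
    """Record stage status; exceptions are captured, not propagated."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is None:
                summary[name] = {"status": "ok"}
            else:
                logger.error("stage %s failed: %s", name, exc)
                summary[name] = {
                    "status": "error",
                    "error": f"{exc_type.__name__}: {exc}",
                }
                logger.debug("%s", "".join(traceback.format_exception(exc)))
            return True  # swallow; isolation contract

    return _Ctx()


def run_all(config: RunConfig) -> dict:
    """Execute every stage, write artifacts under ``config.out_dir`` and
    return the summary dict (also written as summary.json).  Key
    ``exit_code`` is 0 iff all executed stages succeeded."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "stages": {}}
    stages = summary["stages"]

    mid_results: dict[str, mid.AnalysisResult] = {}
    with _stage(stages, "mid"):
        if config.mid_table:
            datasets = synth.read_label_data(config.mid_table)
        else:
            datasets = synth.gen_label_datasets(
                synth.SynthSpec(seed=config.seed))
        for strain, ds in sorted(datasets.items()):
            mid_results[strain] = mid.analyze_dataset(ds)
        payload = {
            strain: {
                "f_pdh": r.flux_split.f_pdh,
                "f_mcl": r.flux_split.f_mcl,
                "raw_pdh": r.flux_split.raw_pdh,
                "raw_mcl": r.flux_split.raw_mcl,
                "co2_fraction": r.co2_fraction,
                "diagnostics": r.diagnostics,
            } for strain, r in mid_results.items()
        }
        (out / "mid_results.json").write_text(
            json.dumps(payload, indent=1, sort_keys=True) + "\n")

    ladder_rows: list[dict] = []
    with _stage(stages, "fba"):
        if config.model_path is None:
            raise FileNotFoundError("no model path configured")
        model = model_io.read_model(config.model_path)
        if config.ladder_path:
            scenarios = load_ladder(config.ladder_path)
        else:
            ratio = config.pinned_mcl_pdh_ratio
            source = "pinned"
            if ratio is None:
                ref = mid_results.get(config.reference_strain)
                if ref is not None and ref.flux_split.raw_pdh > 0:
                    ratio = (ref.flux_split.raw_mcl
                             / ref.flux_split.raw_pdh)
                    source = f"13C estimate ({config.reference_strain})"
                else:
                    ratio = 3.0
                    source = "fallback default"
            logger.info("MCL/PDH ratio constraint %.4g (%s)", ratio, source)
            stages.setdefault("fba_meta", {})
            stages["fba_meta"] = {"mcl_pdh_ratio": ratio,
                                  "ratio_source": source}
            scenarios = default_ladder(model, mcl_pdh_ratio=ratio)
        ladder_rows = fba.run_scenario_ladder(
            model, scenarios, minimize_total_flux=config.minimize_total_flux)
        pd.DataFrame(ladder_rows).to_csv(out / "ladder.tsv", sep="\t",
                                         index=False, float_format="%.6g")

    with _stage(stages, "volcano"):
        if config.pool_table:
            pools = metabolomics.read_pool_table(config.pool_table)
        else:
            pools = synth.gen_pool_table(synth.SynthSpec(seed=config.seed))
        vol = metabolomics.volcano(pools)
        vol.to_csv(out / "volcano.tsv", sep="\t", index=False,
                   float_format="%.6g")

    with _stage(stages, "yields"):
        if config.rates_path:
            with open(config.rates_path, encoding="utf-8") as fh:
                rates_doc = yaml.safe_load(fh)
        else:
            rates_doc = {"methanol_uptake": 19.3, "growth_rate": 0.205,
                         "products": {"formate": 1.82}}
        rates = RateSet(
            methanol_uptake=float(rates_doc["methanol_uptake"]),
            growth_rate=float(rates_doc.get("growth_rate", 0.0)),
            product_rates={k: float(v)
                           for k, v in rates_doc.get("products", {}).items()})
        yr = compute_yields(rates)
        (out / "yields.json").write_text(json.dumps(
            {"product_yield": yr.product_yield,
             "biomass_yield": yr.biomass_yield}, indent=1, sort_keys=True)
            + "\n")

    summary["exit_code"] = int(any(
        s.get("status") == "error" for s in stages.values()
        if isinstance(s, dict) and "status" in s))
    (out / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True) + "\n")
    _write_report(out, summary, mid_results, ladder_rows)
    return summary


def _write_report(out: Path, summary: dict,
                  mid_results: dict, ladder_rows: list[dict]) -> None:
    lines = ["methyloflux run report", "=" * 22, ""]
    for name, st in summary["stages"].items():
        if isinstance(st, dict) and "status" in st:
            lines.append(f"stage {name}: {st['status']}"
                         + (f" ({st.get('error')})"
                            if st["status"] == "error" else ""))
    lines.append("")
    for strain, r in sorted(mid_results.items()):
        lines.append(
            f"{strain}: PDH {100 * r.flux_split.f_pdh:.0f}% / "
            f"MCL {100 * r.flux_split.f_mcl:.0f}%, "
            f"CO2 labeled fraction {r.co2_fraction:.2f}")
    if ladder_rows:
        lines.append("")
        lines.append("scenario ladder (growth 1/h):")
        for row in ladder_rows:
            mu = row["growth_rate"]
            lines.append(f"  {row['scenario']}: "
                         + (f"{mu:.3f}" if mu == mu else row["status"]))
    (out / "report.txt").write_text("\n".join(lines) + "\n")
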