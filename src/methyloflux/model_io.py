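"""Metabolic model data structures and serialization.

Two on-disk formats are supported:

* A native JSON schema (full fidelity: metabolites, reactions, annotations).
* A delimited reaction table (TSV/CSV) with columns
  ``id, name, equation, lb, ub, objective``.  Metabolites are inferred from
  the equations; species whose id ends in ``_ext`` are treated as external
  (boundary) species and are excluded from mass balance.  Metabolites or
  annotations that cannot be inferred from the equations are carried in
  ``#!``-prefixed comment lines so that the table round-trips losslessly.

Exchange reactions are single-metabolite reactions on external species;
an equation like ``A_ext ->`` (no products) is the uptake/excretion
convention used throughout.
"""

from __future__ import annotations

import csv
import io
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

DEFAULT_UB = 1000.0
DEFAULT_LB_REVERSIBLE = -1000.0

TABLE_COLUMNS = ["id", "name", "equation", "lb", "ub", "objective"]


class ModelParseError(ValueError):
    """Raised when a model file cannot be parsed."""


class ModelValidationError(ValueError):
    """Raised when a model violates a structural invariant."""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    is_external: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelValidationError("metabolite id must be nonempty")
        if not self.name:
            self.name = self.id


@dataclass
class Reaction:
    """One reaction: signed stoichiometry (negative = consumed) and flux bounds
    in mmol/(gcdw.h)."""

    id: str
    stoichiometry: dict[str, float]
    name: str = ""
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_UB
    objective_coefficient: float = 0.0

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelValidationError("reaction id must be nonempty")
        if not self.name:
            self.name = self.id
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )
        if not any(c != 0 for c in self.stoichiometry.values()):
            raise ModelValidationError(
                f"reaction {self.id}: needs at least one nonzero coefficient"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    def is_exchange(self, externals: set[str]) -> bool:
        mets = [m for m, c in self.stoichiometry.items() if c != 0]
        return len(mets) == 1 or all(m in externals for m in mets)


@dataclass
class Finding:
    severity: str  # "error" | "warning"
    message: str
    subject: str = ""

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.severity}] {self.subject}: {self.message}"


@dataclass
class MetabolicModel:
    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    annotations: dict = field(default_factory=dict)

    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    def external_ids(self) -> set[str]:
        return {m.id for m in self.metabolites if m.is_external}

    def get_reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(f"reaction {rid!r} not in model")

    def has_reaction(self, rid: str) -> bool:
        return any(r.id == rid for r in self.reactions)

    def role(self, name: str) -> str | None:
        """Reaction/metabolite id registered under a functional role
        (annotations['roles'])."""
        return self.annotations.get("roles", {}).get(name)

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolites=[Metabolite(m.id, m.name, m.compartment, m.is_external)
                         for m in self.metabolites],
            reactions=[Reaction(r.id, dict(r.stoichiometry), r.name,
                                r.lower_bound, r.upper_bound,
                                r.objective_coefficient)
                       for r in self.reactions],
            annotations=json.loads(json.dumps(self.annotations)),
        )


# ---------------------------------------------------------------------------
# validation

def validate_model(model: MetabolicModel) -> list[Finding]:
    """Structural checks.  Empty list iff all invariants hold; orphan
    metabolites are warnings, everything else errors."""
    findings: list[Finding] = []
    met_ids = model.metabolite_ids()
    seen: set[str] = set()
    for mid in met_ids:
        if mid in seen:
            findings.append(Finding("error", "duplicate metabolite id", mid))
        seen.add(mid)
    rseen: set[str] = set()
    used: set[str] = set()
    for r in model.reactions:
        if r.id in rseen:
            findings.append(Finding("error", "duplicate reaction id", r.id))
        rseen.add(r.id)
        if r.lower_bound > r.upper_bound:
            findings.append(Finding(
                "error", f"bounds ({r.lower_bound}, {r.upper_bound}) inverted",
                r.id))
        for m in r.stoichiometry:
            if m not in seen:
                findings.append(Finding(
                    "error", f"references undeclared metabolite {m!r}", r.id))
            used.add(m)
    for mid in met_ids:
        if mid not in used:
            findings.append(Finding("warning", "metabolite in no reaction", mid))
    if not any(r.objective_coefficient != 0 for r in model.reactions):
        findings.append(Finding(
            "warning", "no reaction carries a nonzero objective coefficient",
            ""))
    return findings


def assert_valid(model: MetabolicModel) -> None:
    errors = [f for f in validate_model(model) if f.severity == "error"]
    if errors:
        raise ModelValidationError("; ".join(str(f) for f in errors))


# ---------------------------------------------------------------------------
# equation parsing / formatting

_ARROWS = ("<=>", "<->", "-->", "->")
_TERM_RE = re.compile(r"^\s*(?:(\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)\s+)?(\S+)\s*$")


def parse_equation(text: str) -> tuple[dict[str, float], bool]:
    """Parse ``2 A + B -> C`` into signed stoichiometry.

    Returns (stoichiometry, reversible).  ``<=>`` marks reversible.
    """
    arrow = None
    for a in _ARROWS:
        if a in text:
            arrow = a
            break
    if arrow is None:
        raise ModelParseError(f"no reaction arrow in equation: {text!r}")
    reversible = arrow in ("<=>", "<->")
    lhs, rhs = text.split(arrow, 1)
    stoich: dict[str, float] = {}

    def add_side(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split(" + "):
            term = term.strip()
            if not term:
                continue
            m = _TERM_RE.match(term)
            if m is None:
                raise ModelParseError(f"malformed term {term!r} in {text!r}")
            coeff = float(m.group(1)) if m.group(1) else 1.0
            met = m.group(2)
            stoich[met] = stoich.get(met, 0.0) + sign * coeff

    add_side(lhs, -1.0)
    add_side(rhs, +1.0)
    stoich = {m: c for m, c in stoich.items() if c != 0}
    if not stoich:
        raise ModelParseError(f"equation cancels to nothing: {text!r}")
    return stoich, reversible


def _fmt_coeff(c: float) -> str:
    return format(c, ".12g")


def format_equation(stoich: Mapping[str, float], reversible: bool) -> str:
    lhs = [(m, -c) for m, c in sorted(stoich.items()) if c < 0]
    rhs = [(m, c) for m, c in sorted(stoich.items()) if c > 0]

    def side(terms: list[tuple[str, float]]) -> str:
        parts = []
        for m, c in terms:
            parts.append(m if c == 1 else f"{_fmt_coeff(c)} {m}")
        return " + ".join(parts)

    arrow = "<=>" if reversible else "->"
    return f"{side(lhs)} {arrow} {side(rhs)}".strip()


# ---------------------------------------------------------------------------
# JSON format

def _model_to_dict(model: MetabolicModel) -> dict:
    return {
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment,
             "is_external": m.is_external}
            for m in model.metabolites
        ],
        "reactions": [
            {"id": r.id, "name": r.name, "stoichiometry": dict(r.stoichiometry),
             "lower_bound": r.lower_bound, "upper_bound": r.upper_bound,
             "objective_coefficient": r.objective_coefficient}
            for r in model.reactions
        ],
        "annotations": model.annotations,
    }


def _model_from_dict(d: dict) -> MetabolicModel:
    try:
        mets = [Metabolite(**m) for m in d.get("metabolites", [])]
        rxns = [
            Reaction(
                id=r["id"],
                name=r.get("name", ""),
                stoichiometry={k: float(v)
                               for k, v in r["stoichiometry"].items()},
                lower_bound=float(r.get("lower_bound", 0.0)),
                upper_bound=float(r.get("upper_bound", DEFAULT_UB)),
                objective_coefficient=float(r.get("objective_coefficient", 0.0)),
            )
            for r in d.get("reactions", [])
        ]
    except (KeyError, TypeError) as exc:
        raise ModelParseError(f"malformed model JSON: {exc}") from exc
    model = MetabolicModel(mets, rxns, d.get("annotations", {}))
    assert_valid(model)
    return model


# ---------------------------------------------------------------------------
# reaction-table format

def _infer_metabolite(mid: str) -> Metabolite:
    ext = mid.endswith("_ext")
    return Metabolite(mid, name=mid, compartment="e" if ext else "c",
                      is_external=ext)


def _read_table(text: str, delimiter: str) -> MetabolicModel:
    annotations: dict = {}
    declared_mets: dict[str, Metabolite] = {}
    body_lines: list[str] = []
    for line in text.splitlines():
        if line.startswith("#! annotations "):
            annotations = json.loads(line[len("#! annotations "):])
        elif line.startswith("#! metabolite "):
            d = json.loads(line[len("#! metabolite "):])
            declared_mets[d["id"]] = Metabolite(**d)
        elif line.startswith("#"):
            continue
        else:
            body_lines.append(line)
    reader = csv.DictReader(io.StringIO("\n".join(body_lines)),
                            delimiter=delimiter)
    if reader.fieldnames is None:
        raise ModelParseError("empty reaction table")
    unknown = [c for c in reader.fieldnames if c not in TABLE_COLUMNS]
    if unknown:
        logger.warning("ignoring unknown reaction-table columns: %s", unknown)
    missing = [c for c in ("id", "equation") if c not in reader.fieldnames]
    if missing:
        raise ModelParseError(f"reaction table missing columns: {missing}")

    reactions: list[Reaction] = []
    met_ids: dict[str, None] = {}
    seen_rids: set[str] = set()
    for i, row in enumerate(reader, start=2):
        rid = (row.get("id") or "").strip()
        if not rid:
            raise ModelParseError(f"row {i}: empty reaction id")
        if rid in seen_rids:
            raise ModelValidationError(f"row {i}: duplicate reaction id {rid!r}")
        seen_rids.add(rid)
        try:
            stoich, reversible = parse_equation(row["equation"])
        except ModelParseError as exc:
            raise ModelParseError(f"row {i} ({rid}): {exc}") from exc
        lb_raw = (row.get("lb") or "").strip()
        ub_raw = (row.get("ub") or "").strip()
        lb = float(lb_raw) if lb_raw else (
            DEFAULT_LB_REVERSIBLE if reversible else 0.0)
        ub = float(ub_raw) if ub_raw else DEFAULT_UB
        obj_raw = (row.get("objective") or "").strip()
        obj = float(obj_raw) if obj_raw else 0.0
        reactions.append(Reaction(rid, stoich, name=row.get("name") or rid,
                                  lower_bound=lb, upper_bound=ub,
                                  objective_coefficient=obj))
        for m in stoich:
            met_ids.setdefault(m, None)

    # declared metabolites (``#!`` lines) come first in declaration order;
    # remaining ids inferred from the equations in appearance order
    mets = list(declared_mets.values())
    mets += [_infer_metabolite(m) for m in met_ids if m not in declared_mets]
    model = MetabolicModel(mets, reactions, annotations)
    assert_valid(model)
    return model


def _write_table(model: MetabolicModel, delimiter: str) -> str:
    out = io.StringIO()
    if model.annotations:
        out.write("#! annotations "
                  + json.dumps(model.annotations, sort_keys=True) + "\n")
    # a bare table reconstructs metabolites from the equations in appearance
    # order with attributes inferred from the `_ext` suffix convention; if
    # that reconstruction would not reproduce this model exactly, declare
    # every metabolite explicitly so the table stays lossless
    appearance: dict[str, None] = {}
    for r in model.reactions:
        # mirror the term order the reader will see (format_equation sorts
        # each side alphabetically, consumed side first)
        for m, c in sorted(r.stoichiometry.items()):
            if c < 0:
                appearance.setdefault(m, None)
        for m, c in sorted(r.stoichiometry.items()):
            if c > 0:
                appearance.setdefault(m, None)
    inferable = (list(appearance) == model.metabolite_ids() and all(
        (m.name, m.compartment, m.is_external)
        == ((i := _infer_metabolite(m.id)).name, i.compartment, i.is_external)
        for m in model.metabolites))
    if not inferable:
        for m in model.metabolites:
            out.write("#! metabolite " + json.dumps(
                {"id": m.id, "name": m.name, "compartment": m.compartment,
                 "is_external": m.is_external}, sort_keys=True) + "\n")
    writer = csv.writer(out, delimiter=delimiter, lineterminator="\n")
    writer.writerow(TABLE_COLUMNS)
    for r in model.reactions:
        writer.writerow([
            r.id, r.name, format_equation(r.stoichiometry, r.reversible),
            format(r.lower_bound, ".12g"), format(r.upper_bound, ".12g"),
            format(r.objective_coefficient, ".12g"),
        ])
    return out.getvalue()


# ---------------------------------------------------------------------------
# public I/O

def _delimiter_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_model(path: str | Path, format: str | None = None) -> MetabolicModel:
    """Load a model from JSON or a delimited reaction table.

    ``format`` is ``"json"`` or ``"reaction-table"``; inferred from the file
    extension when omitted (.json vs .tsv/.csv/.txt).
    """
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "reaction-table"
    text = path.read_text(encoding="utf-8")
    if format == "json":
        return _model_from_dict(json.loads(text))
    if format == "reaction-table":
        return _read_table(text, _delimiter_for(path))
    raise ValueError(f"unknown model format {format!r}")


def write_model(model: MetabolicModel, path: str | Path,
                format: str | None = None) -> None:
    """Serialize a model; ``read_model(write_model(m))`` reproduces ``m``."""
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "reaction-table"
    if format == "json":
        path.write_text(json.dumps(_model_to_dict(model), indent=1,
                                   sort_keys=False) + "\n", encoding="utf-8")
    elif format == "reaction-table":
        path.write_text(_write_table(model, _delimiter_for(path)),
                        encoding="utf-8")
    else:
        raise ValueError(f"unknown model format {format!r}")


def models_equal(a: MetabolicModel, b: MetabolicModel) -> bool:
    return _model_to_dict(a) == _model_to_dict(b)


# ---------------------------------------------------------------------------
# core fixture
#
# Small methylotroph core network with lumped ATP/NAD(P)H pseudo-metabolites.
# Its purpose is to exercise the solver and the scenario machinery at desk
# scale; its biomass equation is illustrative and it does NOT reproduce the
# genome-scale predictions (load the published genome-scale reaction table
# for those).

GAM_DEFAULT = 54.35  # mmol ATP/gcdw
NGAM_DEFAULT = 8.39  # mmol ATP/(gcdw.h)

_CORE_REACTIONS: list[tuple[str, str, str, float, float, float]] = [
    # id, name, equation, lb, ub, objective
    ("MEOH_EX", "methanol exchange", "MEOH_ext ->", 0, 1000, 0),
    ("MEOH_UPT", "methanol uptake", "MEOH_ext -> MEOH", 0, 1000, 0),
    ("MDH", "methanol dehydrogenase",
     "MEOH + 0.5 ADP -> FALD + 0.5 ATP", 0, 1000, 0),
    ("FALDH", "formaldehyde dehydrogenase",
     "FALD + NAD -> FOR + NADH", 0, 1000, 0),
    ("FDH", "formate dehydrogenase", "FOR + NAD -> CO2 + NADH", 0, 1000, 0),
    ("FOR_EXC", "formate excretion", "FOR -> FOR_ext", 0, 1000, 0),
    ("FOR_EX", "formate exchange", "FOR_ext ->", -1000, 1000, 0),
    ("RUMP", "RuMP formaldehyde fixation (lumped)",
     "6 FALD -> H6P", 0, 1000, 0),
    ("EMP", "EMP branch: FBP aldolase route (lumped)",
     "H6P + 2 NAD + ADP -> 2 PEP + 2 NADH + ATP", 0, 1000, 0),
    ("EDD", "ED branch: 6-phosphogluconate dehydratase route (lumped)",
     "H6P + 2 NAD + ADP -> PYR + PEP + 2 NADH + ATP", 0, 1000, 0),
    ("PYK", "pyruvate kinase", "PEP + ADP -> PYR + ATP", 0, 1000, 0),
    ("PPC", "PEP carboxylase", "PEP + CO2 -> OAA", 0, 1000, 0),
    ("PYC", "pyruvate carboxylase",
     "PYR + CO2 + ATP -> OAA + ADP", 0, 1000, 0),
    ("PDH", "pyruvate dehydrogenase",
     "PYR + NAD -> ACCOA + CO2 + NADH", 0, 1000, 0),
    ("MDH_OAA", "malate dehydrogenase",
     "OAA + NADH <=> MAL + NAD", -1000, 1000, 0),
    ("MCL", "malyl-CoA route (MTK + malyl-CoA lyase, lumped)",
     "MAL + ATP -> GLX + ACCOA + ADP", 0, 1000, 0),
    ("GLXA", "glyoxylate assimilation (serine-cycle lump)",
     "GLX + FALD + NADH -> PYR + NAD", 0, 1000, 0),
    ("CS", "citrate synthase", "OAA + ACCOA -> CIT", 0, 1000, 0),
    ("ICD", "isocitrate dehydrogenase (lumped aconitase)",
     "CIT + NAD -> AKG + CO2 + NADH", 0, 1000, 0),
    ("AKGDH", "alpha-ketoglutarate dehydrogenase",
     "AKG + NAD -> SUCCOA + CO2 + NADH", 0, 1000, 0),
    ("SCS", "succinyl-CoA synthetase", "SUCCOA + ADP -> SUC + ATP", 0, 1000, 0),
    ("SDH", "succinate dehydrogenase", "SUC + NAD -> FUMA + NADH", 0, 1000, 0),
    ("FUM", "fumarase", "FUMA <=> MAL", -1000, 1000, 0),
    ("OXPHOS", "oxidative phosphorylation (P/O = 2)",
     "NADH + 0.5 O2 + 2 ADP -> NAD + 2 ATP", 0, 1000, 0),
    ("O2_UPT", "oxygen uptake", "O2_ext -> O2", 0, 1000, 0),
    ("O2_EX", "oxygen exchange", "O2_ext ->", 0, 1000, 0),
    ("CO2_EXC", "CO2 excretion", "CO2 <=> CO2_ext", -1000, 1000, 0),
    ("CO2_EX", "CO2 exchange", "CO2_ext ->", -1000, 1000, 0),
    ("GLYC_SYN", "glycogen synthesis", "H6P + ATP -> GLYC + ADP", 0, 1000, 0),
    ("GLYC_SINK", "glycogen sink", "GLYC -> GLYC_ext", 0, 1000, 0),
    ("GLYC_EX", "glycogen exchange", "GLYC_ext ->", 0, 1000, 0),
    ("EPS_SYN", "EPS synthesis", "H6P + ATP -> EPS + ADP", 0, 1000, 0),
    ("EPS_SINK", "EPS sink", "EPS -> EPS_ext", 0, 1000, 0),
    ("EPS_EX", "EPS exchange", "EPS_ext ->", 0, 1000, 0),
    ("ATPM", "ATP maintenance", "ATP -> ADP", NGAM_DEFAULT, 1000, 0),
    ("BIOMASS", "biomass (illustrative composition + GAM ATP)",
     "0.8 H6P + 2 PYR + 1.2 ACCOA + 1.2 OAA + 0.8 AKG + 54.35 ATP + 8 NADH"
     " -> 54.35 ADP + 8 NAD + BIOMASS_ext", 0, 1000, 1),
    ("BIOMASS_EX", "biomass exchange", "BIOMASS_ext ->", 0, 1000, 0),
]

CORE_ROLES = {
    "methanol_uptake": "MEOH_UPT",
    "formate_excretion": "FOR_EXC",
    "o2_uptake": "O2_UPT",
    "maintenance": "ATPM",
    "biomass": "BIOMASS",
    "glycogen_sink": "GLYC_SINK",
    "eps_sink": "EPS_SINK",
    "emp": "EMP",
    "ed": "EDD",
    "pdh": "PDH",
    "mcl": "MCL",
    "fumarase": "FUM",
    "akgdh": "AKGDH",
    "scs": "SCS",
    "gam_atp": "ATP",
    "gam_adp": "ADP",
}


def core_model_fixture() -> MetabolicModel:
    """Small core network (methanol oxidation, RuMP, EMP/ED split, C3-C4
    carboxylation, PDH/MCL acetyl-CoA node, TCA, maintenance, sinks).

    Lumped cofactors; illustrative biomass.  Exercises the FBA engine; not a
    substitute for the genome-scale reaction table.
    """
    reactions = []
    met_ids: dict[str, None] = {}
    for rid, name, eq, lb, ub, obj in _CORE_REACTIONS:
        stoich, _ = parse_equation(eq)
        reactions.append(Reaction(rid, stoich, name=name, lower_bound=lb,
                                  upper_bound=ub, objective_coefficient=obj))
        for m in stoich:
            met_ids.setdefault(m, None)
    mets = [_infer_metabolite(m) for m in met_ids]
    annotations = {
        "roles": dict(CORE_ROLES),
        "monomer_mass": {"glycogen": 0.162, "eps": 0.162},  # g/mmol
        "gam_in_biomass": GAM_DEFAULT,
        "description": "desk-scale core fixture; illustrative stoichiometry",
    }
    model = MetabolicModel(mets, reactions, annotations)
    assert_valid(model)
    return model
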