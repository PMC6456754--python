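import numpy as np
import pytest

from methyloflux.model_io import (MetabolicModel, Metabolite, Reaction,
                                  core_model_fixture, parse_equation)


def make_model(reactions, annotations=None):
    """Build a model from (id, equation, lb, ub, objective) tuples; external
    metabolites follow the `_ext` suffix convention."""
    rxns = []
    met_ids: dict[str, None] = {}
    for rid, eq, lb, ub, obj in reactions:
        stoich, _ = parse_equation(eq)
        rxns.append(Reaction(rid, stoich, lower_bound=lb, upper_bound=ub,
                             objective_coefficient=obj))
        for m in stoich:
            met_ids.setdefault(m, None)
    mets = [Metabolite(m, is_external=m.endswith("_ext"),
                       compartment="e" if m.endswith("_ext") else "c")
            for m in met_ids]
    return MetabolicModel(mets, rxns, annotations or {})


@pytest.fixture
def core_model():
    return core_model_fixture()


# --------------------------------------------------------------------------
# packaged toy networks (all <= 6 reactions, finite bounds)


def toy_chain():
    """A_ext -> A -> biomass at yield 0.1/A; uptake <= 10 => growth 1.0."""
    return make_model([
        ("UPT", "A_ext -> A", 0, 10, 0),
        ("BIO", "10 A -> BIO_ext", 0, 100, 1),
    ])


def toy_branch():
    """Chain plus a dead-end waste branch (ratio-constraint target)."""
    return make_model([
        ("UPT", "A_ext -> A", 0, 10, 0),
        ("WASTE", "A -> W_ext", 0, 100, 0),
        ("BIO", "10 A -> BIO_ext", 0, 100, 1),
    ])


def toy_parallel():
    """Two stoichiometrically equivalent routes A -> B."""
    return make_model([
        ("UPT", "A_ext -> A", 0, 10, 0),
        ("R1", "A -> B", 0, 100, 0),
        ("R2", "A -> B", 0, 100, 0),
        ("BIO", "10 B -> BIO_ext", 0, 100, 1),
    ])


def toy_atp_waste():
    """Route R2 additionally burns one ATP (made from A) per unit flux.

    With ratio r = v_R2/v_R1 the optimum is mu = 5(1+r)/(1+2r).
    """
    return make_model([
        ("UPT", "A_ext -> A", 0, 10, 0),
        ("R1", "A -> B", 0, 100, 0),
        ("R2", "A + ATP -> B", 0, 100, 0),
        ("ATPS", "A -> ATP", 0, 100, 0),
        ("BIO", "2 B -> BIO_ext", 0, 100, 1),
    ])


def toy_maintenance():
    """Each NGAM ATP burns one A, so mu(ngam) = 1 - 0.1*ngam."""
    return make_model([
        ("UPT", "A_ext -> A", 0, 10, 0),
        ("ATPS", "A -> ATP", 0, 100, 0),
        ("ATPM", "ATP -> ATPW_ext", 0, 100, 0),
        ("BIO", "10 A -> BIO_ext", 0, 100, 1),
    ], annotations={"roles": {"biomass": "BIO", "maintenance": "ATPM",
                              "gam_atp": "ATP"}})


TOY_BUILDERS = [toy_chain, toy_branch, toy_parallel, toy_atp_waste,
                toy_maintenance]


@pytest.fixture(params=TOY_BUILDERS, ids=lambda b: b.__name__)
def toy_model(request):
    return request.param()


# --------------------------------------------------------------------------
# random small networks for property tests


def random_toy_model(rng: np.random.Generator) -> MetabolicModel:
    """Random bounded network: one uptake, 1-3 internal conversions with
    random stoichiometry over {A, B, C}, one biomass reaction."""
    mets = ["A", "B", "C"]
    reactions = [("UPT", "A_ext -> A", 0.0, float(rng.uniform(2, 15)), 0.0)]
    n_conv = rng.integers(1, 4)
    for k in range(n_conv):
        src, dst = rng.choice(mets, size=2, replace=False)
        cs = round(float(rng.uniform(0.5, 2.0)), 3)
        cd = round(float(rng.uniform(0.5, 2.0)), 3)
        reactions.append((f"C{k}", f"{cs} {src} -> {cd} {dst}",
                          0.0, float(rng.uniform(5, 50)), 0.0))
    precursor = rng.choice(mets)
    cb = round(float(rng.uniform(1.0, 5.0)), 3)
    reactions.append(("BIO", f"{cb} {precursor} -> BIO_ext",
                      0.0, 100.0, 1.0))
    return make_model(reactions)
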