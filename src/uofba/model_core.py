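"""Stoichiometric model representation, standard-format IO and fixture networks.

The in-memory types are deliberately small: a model is a list of metabolites,
a list of reactions with signed stoichiometry and flux bounds, plus the ids of
the biomass (growth) pseudo-reaction, an optional product (e.g. IgG) reaction,
and the registry of exchange reactions.  Heavy lifting for SBML / BiGG-JSON
parsing is delegated to cobrapy; this module owns the domain types, the sign
conventions and the built-in toy networks used throughout the test-suite and
documentation.

Sign convention: exchange fluxes are stored export-positive, i.e. uptake is a
negative flux, matching published genome-scale model files.  User-facing
tables produced by the analysis modules report uptake as a positive number;
the conversion happens only at that reporting boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "NetworkFixtureSpec",
    "ModelFormatError",
    "load_model",
    "save_model",
    "build_fixture",
    "hypothetical_network",
    "toy_mammalian",
    "stoichiometric_matrix",
    "ESSENTIAL_NAMES",
    "NONESSENTIAL_NAMES",
]

#: default magnitude used for "practically unbounded" fluxes (mmol/gDW/h)
BIG_BOUND = 1000.0

#: canonical essential amino-acid names used by the mammalian-like toy network
ESSENTIAL_NAMES = [
    "lys", "his", "phe", "met", "trp", "ile",
    "leu", "val", "thr", "arg", "cys", "pro",
]

#: canonical non-essential nutrient names used by the toy network
NONESSENTIAL_NAMES = ["tyr", "ser", "asn", "asp", "glu", "ala"]


class ModelFormatError(ValueError):
    """Raised when a model file does not parse under the named standard."""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.compartment:
            raise ValueError(f"metabolite {self.id!r}: compartment must be non-empty")


@dataclass
class Reaction:
    """A reaction with signed stoichiometry (substrates negative).

    ``is_exchange`` marks single-metabolite boundary pseudo-reactions whose
    flux is the secretion (positive) or uptake (negative) rate.
    """

    id: str
    stoichiometry: Dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = BIG_BOUND
    name: str = ""
    is_exchange: bool = False
    notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise ValueError(f"reaction {self.id!r}: stoichiometry must be non-empty")
        if self.lower_bound > self.upper_bound:
            raise ValueError(
                f"reaction {self.id!r}: lower_bound {self.lower_bound} exceeds "
                f"upper_bound {self.upper_bound}"
            )
        if self.is_exchange and len(self.stoichiometry) != 1:
            raise ValueError(
                f"reaction {self.id!r}: an exchange reaction touches exactly one metabolite"
            )
        self.lower_bound = float(self.lower_bound)
        self.upper_bound = float(self.upper_bound)

    @property
    def exchanged_metabolite(self) -> str:
        if not self.is_exchange:
            raise ValueError(f"reaction {self.id!r} is not an exchange reaction")
        return next(iter(self.stoichiometry))


@dataclass
class MetabolicModel:
    id: str
    metabolites: List[Metabolite]
    reactions: List[Reaction]
    biomass_reaction_id: Optional[str] = None
    product_reaction_id: Optional[str] = None
    notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- lookups -----------------------------------------------------------
    def metabolite(self, mid: str) -> Metabolite:
        return self._met_index[mid]

    def reaction(self, rid: str) -> Reaction:
        return self._rxn_index[rid]

    @property
    def exchange_ids(self) -> List[str]:
        return [r.id for r in self.reactions if r.is_exchange]

    def exchange_for(self, metabolite_id: str) -> Reaction:
        """The exchange reaction moving ``metabolite_id`` across the boundary."""
        for r in self.reactions:
            if r.is_exchange and r.exchanged_metabolite == metabolite_id:
                return r
        raise KeyError(f"no exchange reaction for metabolite {metabolite_id!r}")

    def validate(self) -> None:
        self._met_index = {m.id: m for m in self.metabolites}
        if len(self._met_index) != len(self.metabolites):
            raise ValueError("metabolite ids must be unique within a model")
        self._rxn_index = {r.id: r for r in self.reactions}
        if len(self._rxn_index) != len(self.reactions):
            raise ValueError("reaction ids must be unique within a model")
        for r in self.reactions:
            for mid in r.stoichiometry:
                if mid not in self._met_index:
                    raise ModelFormatError(
                        f"reaction {r.id!r} references undeclared metabolite {mid!r}"
                    )
        for attr in ("biomass_reaction_id", "product_reaction_id"):
            rid = getattr(self, attr)
            if rid is not None and rid not in self._rxn_index:
                raise ValueError(f"{attr} {rid!r} does not resolve to a reaction")

    # -- cobra bridge ------------------------------------------------------
    def to_cobra(self):
        """Convert to a :class:`cobra.Model` (cached; treat as read-through)."""
        cached = getattr(self, "_cobra_cache", None)
        if cached is not None:
            return cached
        import cobra

        cm = cobra.Model(self.id)
        cmets = {}
        for m in self.metabolites:
            cmet = cobra.Metabolite(m.id, name=m.name, compartment=m.compartment)
            if m.notes:
                cmet.notes.update(m.notes)
            cmets[m.id] = cmet
        crxns = []
        for r in self.reactions:
            cr = cobra.Reaction(
                r.id, name=r.name, lower_bound=r.lower_bound, upper_bound=r.upper_bound
            )
            cr.add_metabolites({cmets[k]: v for k, v in r.stoichiometry.items()})
            if r.notes:
                cr.notes.update(r.notes)
            crxns.append(cr)
        cm.add_reactions(crxns)
        if self.notes:
            cm.notes.update(self.notes)
        if self.biomass_reaction_id:
            cm.objective = self.biomass_reaction_id
        self._cobra_cache = cm
        return cm

    def invalidate_cache(self) -> None:
        self._cobra_cache = None


@dataclass
class NetworkFixtureSpec:
    """Parameters of a built-in toy network.

    ``hypothetical_network1`` / ``hypothetical_network2`` are the two hypothetical four-
    component assembly networks (the second adds a reversible 1:1 B-C
    interconversion); ``toy_mammalian`` is a miniature mammalian-like network
    with essential and non-essential nutrients, an energy currency and
    by-product secretion.
    """

    variant: str
    availabilities: Dict[str, float] = field(default_factory=dict)
    n_essential: int = 12
    n_nonessential: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in {"hypothetical_network1", "hypothetical_network2", "toy_mammalian"}:
            raise ValueError(f"unknown fixture variant {self.variant!r}")
        for k, v in self.availabilities.items():
            if v <= 0:
                raise ValueError(f"availability for {k!r} must be strictly positive")
        if self.n_essential < 0 or self.n_nonessential < 0:
            raise ValueError("nutrient counts must be non-negative")


def build_fixture(spec: NetworkFixtureSpec) -> MetabolicModel:
    """Construct one of the built-in toy networks."""
    if spec.variant in ("hypothetical_network1", "hypothetical_network2"):
        avail = {"A": 4.0, "B": 6.0, "C": 8.0, "D": 10.0}
        avail.update(spec.availabilities)
        return hypothetical_network(spec.variant == "hypothetical_network2", avail)
    return toy_mammalian(
        n_essential=spec.n_essential,
        n_nonessential=spec.n_nonessential,
        seed=spec.seed,
        availabilities=spec.availabilities,
    )


def hypothetical_network(with_interconversion: bool, availabilities: Dict[str, float]) -> MetabolicModel:
    """Four building blocks A-D assembled 1:1:1:1 into a macro-component X.

    Availabilities cap the uptake of each component.  The optional reversible
    B<->C interconversion is the single reaction distinguishing the two
    network variants.
    """
    mets = [Metabolite(x, name=f"component {x}", notes={"tokens": {"U": 1}}) for x in "ABCD"]
    mets.append(Metabolite("X", name="macro-component X", notes={"tokens": {"U": 4}}))
    rxns = [
        Reaction(
            f"EX_{x}",
            {x: -1.0},
            lower_bound=-float(availabilities[x]),
            upper_bound=BIG_BOUND,
            is_exchange=True,
        )
        for x in "ABCD"
    ]
    rxns.append(
        Reaction(
            "ASSEMBLY",
            {"A": -1.0, "B": -1.0, "C": -1.0, "D": -1.0, "X": 1.0},
            lower_bound=0.0,
        )
    )
    rxns.append(Reaction("EX_X", {"X": -1.0}, lower_bound=0.0, is_exchange=True))
    if with_interconversion:
        rxns.append(Reaction("BC_CONV", {"B": -1.0, "C": 1.0}, lower_bound=-BIG_BOUND))
    name = "hypothetical_network2" if with_interconversion else "hypothetical_network1"
    return MetabolicModel(name, mets, rxns, biomass_reaction_id="EX_X")


def toy_mammalian(
    n_essential: int = 12,
    n_nonessential: int = 6,
    seed: int = 0,
    availabilities: Optional[Dict[str, float]] = None,
) -> MetabolicModel:
    """Miniature mammalian-like metabolic network.

    Structure (all coefficients drawn deterministically from ``seed``):

    * glucose is the sole energy source, oxidized by three routes —
      glycolysis (``glc -> 2 lac + 2 ATP``), respiration
      (``glc -> 6 co2 + 10 ATP``) and an uncoupled oxidation that captures
      no energy;
    * essential nutrients (``lys``, ``his``, ``phe``, ...) have no internal
      synthesis route and are consumed by the biomass reaction;
    * non-essential nutrients (``tyr``, ``ser``, ...) can also be synthesized
      from glucose at an ATP cost, except tyrosine which is produced only by
      a 1:1 conversion from phenylalanine;
    * methionine lacks a plain degradation route — its catabolism consumes
      serine and ATP, mirroring the metabolic burden of excess methionine;
    * a biomass assembly drains fixed stoichiometric amounts of every
      nutrient plus ATP into a macro-component ``X`` with a boundary sink,
      and an optional product reaction assembles ``P`` (an IgG stand-in).

    Token counts (carbon-like ``C`` and phosphate-like ``P``) are carried in
    metabolite notes so that internal reactions can be audited for balance.
    """
    rng = np.random.default_rng(seed)
    ess = [ESSENTIAL_NAMES[i] if i < len(ESSENTIAL_NAMES) else f"ess{i + 1}" for i in range(n_essential)]
    non = [NONESSENTIAL_NAMES[i] if i < len(NONESSENTIAL_NAMES) else f"nes{i + 1}" for i in range(n_nonessential)]

    avail = {n: 10.0 for n in ess + non}
    avail["glc"] = 10.0
    if availabilities:
        avail.update(availabilities)

    c_ess = {n: round(float(rng.uniform(0.05, 0.35)), 3) for n in ess}
    d_non = {n: round(float(rng.uniform(0.05, 0.35)), 3) for n in non}
    e_atp = round(float(rng.uniform(2.0, 5.0)), 2)

    mets = [
        Metabolite("glc", "glucose", notes={"tokens": {"C": 6}}),
        Metabolite("lac", "lactate", notes={"tokens": {"C": 3}}),
        Metabolite("co2", "carbon dioxide", notes={"tokens": {"C": 1}}),
        Metabolite("atp", "ATP", notes={"tokens": {"P": 1}}),
        Metabolite("adp", "ADP", notes={"tokens": {}}),
        Metabolite("pi", "phosphate", notes={"tokens": {"P": 1}}),
    ]
    for n in ess:
        mets.append(Metabolite(n, f"essential nutrient {n}", notes={"tokens": {"C": 3}}))
    for n in non:
        mets.append(Metabolite(n, f"non-essential nutrient {n}", notes={"tokens": {"C": 3}}))

    biomass_c = 3 * (sum(c_ess.values()) + sum(d_non.values()))
    mets.append(Metabolite("X", "biomass macro-component", notes={"tokens": {"C": biomass_c}}))

    rxns: List[Reaction] = []

    def exchange(met: str, lb: float, ub: float = BIG_BOUND) -> None:
        rxns.append(Reaction(f"EX_{met}", {met: -1.0}, lower_bound=lb, upper_bound=ub, is_exchange=True))

    exchange("glc", -avail["glc"])
    for n in ess + non:
        exchange(n, -avail[n])
    exchange("lac", 0.0)   # secretion only: lactate is not an alternative carbon source here
    exchange("co2", 0.0)
    exchange("X", 0.0)

    rxns.append(
        Reaction(
            "GLYC",
            {"glc": -1.0, "adp": -2.0, "pi": -2.0, "lac": 2.0, "atp": 2.0},
            name="glycolysis to lactate",
        )
    )
    rxns.append(
        Reaction(
            "RESP",
            {"glc": -1.0, "adp": -10.0, "pi": -10.0, "co2": 6.0, "atp": 10.0},
            name="full oxidation, energy-coupled",
        )
    )
    rxns.append(Reaction("OX_WASTE", {"glc": -1.0, "co2": 6.0}, name="uncoupled oxidation"))
    rxns.append(Reaction("ATPM", {"atp": -1.0, "adp": 1.0, "pi": 1.0}, name="ATP maintenance sink"))

    has_phe_tyr = "phe" in ess and "tyr" in non
    has_met_ser = "met" in ess and "ser" in non
    for n in non:
        if n == "tyr" and has_phe_tyr:
            rxns.append(Reaction("PHE_TYR", {"phe": -1.0, "tyr": 1.0}, name="phe -> tyr conversion"))
        else:
            rxns.append(
                Reaction(
                    f"SYN_{n}",
                    {"glc": -1.0, "atp": -1.0, n: 2.0, "adp": 1.0, "pi": 1.0},
                    name=f"synthesis of {n} from glucose",
                )
            )
        rxns.append(Reaction(f"DEG_{n}", {n: -1.0, "co2": 3.0}, name=f"degradation of {n}"))
    for n in ess:
        if n == "met" and has_met_ser:
            rxns.append(
                Reaction(
                    "MET_CAT",
                    {"met": -1.0, "ser": -1.0, "atp": -2.0, "co2": 6.0, "adp": 2.0, "pi": 2.0},
                    name="methionine catabolism (consumes serine + ATP)",
                )
            )
        else:
            rxns.append(Reaction(f"DEG_{n}", {n: -1.0, "co2": 3.0}, name=f"degradation of {n}"))

    biomass_stoich: Dict[str, float] = {n: -c for n, c in c_ess.items()}
    biomass_stoich.update({n: -d for n, d in d_non.items()})
    biomass_stoich.update({"atp": -e_atp, "adp": e_atp, "pi": e_atp, "X": 1.0})
    rxns.append(Reaction("BIOMASS", biomass_stoich, name="biomass assembly"))

    product_id = None
    if ess:
        p_stoich: Dict[str, float] = {n: -round(0.2 * c, 4) for n, c in c_ess.items()}
        p_atp = 1.0
        p_c = 3 * sum(-v for v in p_stoich.values())
        p_stoich.update({"atp": -p_atp, "adp": p_atp, "pi": p_atp, "P": 1.0})
        mets.append(Metabolite("P", "recombinant product", notes={"tokens": {"C": p_c}}))
        rxns.append(Reaction("PRODUCT", p_stoich, name="product assembly"))
        exchange("P", 0.0)
        product_id = "PRODUCT"

    model = MetabolicModel(
        f"toy_mammalian_s{seed}",
        mets,
        rxns,
        biomass_reaction_id="BIOMASS",
        product_reaction_id=product_id,
        notes={
            "essential_nutrients": ess,
            "nonessential_nutrients": non,
            "biomass_coefficients": {**c_ess, **d_non},
            "atp_per_biomass": e_atp,
        },
    )
    return model


# ---------------------------------------------------------------------------
# standard-format IO (delegated to cobrapy)
# ---------------------------------------------------------------------------

def _looks_like_biomass(rid: str) -> bool:
    low = rid.lower()
    return "biomass" in low or low.startswith("bof")


def _looks_like_product(rid: str) -> bool:
    low = rid.lower()
    return low.startswith("product") or "igg" in low


def from_cobra(cm, biomass_reaction_id: Optional[str] = None,
               product_reaction_id: Optional[str] = None) -> MetabolicModel:
    """Convert a cobra model, auto-detecting exchanges and the biomass reaction.

    Exchange reactions are detected structurally as single-metabolite boundary
    reactions.  The biomass reaction is taken from the model objective when
    present (stored objective coefficients are otherwise ignored — this tool
    always supplies the objective per solve), falling back to an id match.
    Gene-reaction rules are preserved as opaque notes and never evaluated.
    """
    mets = [
        Metabolite(m.id, name=m.name or "", compartment=m.compartment or "c",
                   notes=dict(m.notes) if m.notes else {})
        for m in cm.metabolites
    ]
    rxns = []
    for r in cm.reactions:
        notes = dict(r.notes) if r.notes else {}
        if r.gene_reaction_rule:
            notes["gene_reaction_rule"] = r.gene_reaction_rule
        rxns.append(
            Reaction(
                r.id,
                {m.id: float(v) for m, v in r.metabolites.items()},
                lower_bound=float(r.lower_bound),
                upper_bound=float(r.upper_bound),
                name=r.name or "",
                is_exchange=len(r.metabolites) == 1,
                notes=notes,
            )
        )
    if biomass_reaction_id is None:
        try:
            from cobra.util.solver import linear_reaction_coefficients

            coeffs = linear_reaction_coefficients(cm)
            if coeffs:
                biomass_reaction_id = next(iter(coeffs)).id
        except Exception:  # pragma: no cover - objective machinery absent
            pass
        if biomass_reaction_id is None:
            matches = [r.id for r in cm.reactions if _looks_like_biomass(r.id)]
            biomass_reaction_id = matches[0] if matches else None
        if biomass_reaction_id is None:
            import warnings

            warnings.warn(f"model {cm.id!r}: no biomass reaction identified", stacklevel=2)
    if product_reaction_id is None:
        matches = [r.id for r in cm.reactions if _looks_like_product(r.id)]
        product_reaction_id = matches[0] if matches else None
    return MetabolicModel(cm.id or "model", mets, rxns,
                          biomass_reaction_id=biomass_reaction_id,
                          product_reaction_id=product_reaction_id,
                          notes=dict(cm.notes) if cm.notes else {})


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".json":
        return "bigg_json"
    if suffix in (".xml", ".sbml"):
        return "sbml"
    raise ModelFormatError(f"cannot infer model format from extension {suffix!r}")


def load_model(path, format: str = "auto") -> MetabolicModel:
    """Load an SBML or BiGG-style JSON model from ``path``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"model file not found: {path}")
    fmt = _infer_format(path) if format == "auto" else format
    import cobra.io

    try:
        if fmt == "bigg_json":
            cm = cobra.io.load_json_model(str(path))
        elif fmt == "sbml":
            cm = cobra.io.read_sbml_model(str(path))
        else:
            raise ModelFormatError(f"unknown model format {fmt!r}")
    except ModelFormatError:
        raise
    except Exception as exc:
        raise ModelFormatError(f"failed to parse {path} as {fmt}: {exc}") from exc
    return from_cobra(cm)


def save_model(model: MetabolicModel, path, format: str = "auto") -> None:
    """Write ``model`` as BiGG-style JSON or SBML (Level 3 + FBC)."""
    path = Path(path)
    fmt = _infer_format(path) if format == "auto" else format
    cm = model.to_cobra()
    import cobra.io

    if fmt == "bigg_json":
        cobra.io.save_json_model(cm, str(path))
    elif fmt == "sbml":
        cobra.io.write_sbml_model(cm, str(path))
    else:
        raise ModelFormatError(f"unknown model format {fmt!r}")


def stoichiometric_matrix(model: MetabolicModel) -> pd.DataFrame:
    """Dense stoichiometric matrix S (metabolites x reactions)."""
    S = pd.DataFrame(
        0.0,
        index=[m.id for m in model.metabolites],
        columns=[r.id for r in model.reactions],
    )
    for r in model.reactions:
        for mid, coef in r.stoichiometry.items():
            S.loc[mid, r.id] = coef
    return S


def token_imbalance(model: MetabolicModel, reaction_id: str) -> Dict[str, float]:
    """Net token production of a reaction, from metabolite ``tokens`` notes.

    Internal (non-exchange) reactions of the built-in fixtures conserve every
    declared token kind (assembly reactions bank them in the macro-component);
    exchanges intentionally do not — they move tokens across the boundary.
    """
    rxn = model.reaction(reaction_id)
    net: Dict[str, float] = {}
    for mid, coef in rxn.stoichiometry.items():
        for token, count in model.metabolite(mid).notes.get("tokens", {}).items():
            net[token] = net.get(token, 0.0) + coef * count
    return {t: v for t, v in net.items() if not math.isclose(v, 0.0, abs_tol=1e-9)}
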