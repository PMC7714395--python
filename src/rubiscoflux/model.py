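"""Stoichiometric metabolic models: domain types, validation, and I/O.

A :class:`MetabolicModel` is the minimal substrate for constraint-based
analysis: a list of metabolites, a list of reactions (each a sparse column of
the stoichiometric matrix ``S`` with flux bounds), and a biomass objective.
The canonical on-disk format is a small JSON dialect; an SBML Level 3 (fbc)
subset can be imported when ``python-libsbml`` is available.

Sign conventions follow the constraint-based modeling community: consumption
is negative, production positive, and uptake through an exchange reaction is
a negative flux (a negative lower bound opens uptake).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "ModelValidationError",
    "ModelParseError",
    "load_model",
    "write_model",
    "set_carbon_source",
    "apply_knockouts",
    "INORGANIC_SPECIES",
]

#: Default bounds applied when a document omits them (mmol/gDW/h).
DEFAULT_REVERSIBLE_BOUNDS = (-1000.0, 1000.0)
DEFAULT_IRREVERSIBLE_BOUNDS = (0.0, 1000.0)

#: Species whose exchanges stay open when a single carbon source is selected.
#: Matched against exchange ids after stripping the ``EX_`` prefix and any
#: trailing compartment tag (``_e``, ``(e)``).  Covers the common ids of the
#: E. coli core model plus the toy networks used here.
INORGANIC_SPECIES = frozenset(
    {
        "co2", "o2", "h2o", "h", "h2", "pi", "nh4", "so4", "so3", "hco3",
        "k", "na1", "na", "cl", "fe2", "fe3", "mg2", "ca2", "mn2", "zn2",
        "cu2", "cobalt2", "mobd", "ni2", "sel", "slnt", "tungs", "cbl1",
    }
)


class ModelValidationError(ValueError):
    """A model or document violates a structural invariant."""


class ModelParseError(ValueError):
    """A document could not be parsed as a metabolic model."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelValidationError("metabolite id must be nonempty")


@dataclass(frozen=True)
class Reaction:
    """A column of S: metabolite id -> signed stoichiometric coefficient."""

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = DEFAULT_IRREVERSIBLE_BOUNDS[0]
    upper_bound: float = DEFAULT_IRREVERSIBLE_BOUNDS[1]
    is_exchange: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelValidationError("reaction id must be nonempty")
        if not self.stoichiometry:
            raise ModelValidationError(f"reaction {self.id!r}: empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id!r}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )
        if self.is_exchange and len(self.stoichiometry) != 1:
            raise ModelValidationError(
                f"exchange reaction {self.id!r} must touch exactly one metabolite"
            )

    def with_bounds(self, lower: float, upper: float) -> "Reaction":
        return replace(self, lower_bound=lower, upper_bound=upper)


@dataclass(frozen=True)
class MetabolicModel:
    metabolites: tuple[Metabolite, ...]
    reactions: tuple[Reaction, ...]
    objective_id: str
    name: str = ""
    _rxn_index: dict[str, int] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            raise ModelValidationError("duplicate metabolite ids")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            raise ModelValidationError("duplicate reaction ids")
        known = set(met_ids)
        for r in self.reactions:
            missing = set(r.stoichiometry) - known
            if missing:
                raise ModelValidationError(
                    f"reaction {r.id!r} references unknown metabolites: "
                    f"{sorted(missing)}"
                )
        if self.reactions and self.objective_id not in set(rxn_ids):
            raise ModelValidationError(
                f"objective {self.objective_id!r} is not a reaction of the model"
            )
        object.__setattr__(
            self, "_rxn_index", {r.id: i for i, r in enumerate(self.reactions)}
        )

    # -- lookups ----------------------------------------------------------
    def reaction(self, reaction_id: str) -> Reaction:
        try:
            return self.reactions[self._rxn_index[reaction_id]]
        except KeyError:
            raise KeyError(f"unknown reaction id {reaction_id!r}") from None

    @property
    def reaction_ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.reactions)

    @property
    def exchanges(self) -> tuple[Reaction, ...]:
        return tuple(r for r in self.reactions if r.is_exchange)

    # -- functional edits (originals are never mutated) -------------------
    def with_reaction(self, new: Reaction) -> "MetabolicModel":
        """Replace (by id) or append a reaction, returning a new model."""
        if new.id in self._rxn_index:
            rxns = tuple(
                new if r.id == new.id else r for r in self.reactions
            )
        else:
            rxns = self.reactions + (new,)
        return replace(self, reactions=rxns, _rxn_index={})

    def with_metabolites(self, mets: list[Metabolite]) -> "MetabolicModel":
        existing = {m.id for m in self.metabolites}
        added = tuple(m for m in mets if m.id not in existing)
        return replace(self, metabolites=self.metabolites + added, _rxn_index={})

    def without_reaction(self, reaction_id: str) -> "MetabolicModel":
        self.reaction(reaction_id)  # raises on unknown id
        rxns = tuple(r for r in self.reactions if r.id != reaction_id)
        return replace(self, reactions=rxns, _rxn_index={})


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------

def _reaction_to_doc(r: Reaction) -> dict:
    return {
        "id": r.id,
        "stoichiometry": {k: r.stoichiometry[k] for k in sorted(r.stoichiometry)},
        "lower_bound": None if math.isinf(r.lower_bound) else r.lower_bound,
        "upper_bound": None if math.isinf(r.upper_bound) else r.upper_bound,
        "is_exchange": r.is_exchange,
    }


def write_model(model: MetabolicModel, format: str = "json") -> str:
    """Serialize a model canonically (sorted ids) so diffs are stable."""
    if format != "json":
        raise ValueError(f"unsupported output format {format!r}")
    doc = {
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in sorted(model.metabolites, key=lambda m: m.id)
        ],
        "reactions": [
            _reaction_to_doc(r)
            for r in sorted(model.reactions, key=lambda r: r.id)
        ],
        "objective": model.objective_id,
    }
    if model.name:
        doc["name"] = model.name
    return json.dumps(doc, indent=2, sort_keys=True) + "\n"


def _model_from_doc(doc: dict) -> MetabolicModel:
    try:
        met_docs = doc["metabolites"]
        rxn_docs = doc["reactions"]
        objective = doc["objective"]
    except (KeyError, TypeError) as exc:
        raise ModelParseError(f"missing required top-level key: {exc}") from None
    mets = []
    for d in met_docs:
        if "id" not in d:
            raise ModelParseError(f"metabolite without id: {d!r}")
        mets.append(
            Metabolite(d["id"], d.get("name", ""), d.get("compartment", "c"))
        )
    rxns = []
    for d in rxn_docs:
        if "id" not in d or "stoichiometry" not in d:
            raise ModelParseError(f"reaction missing id/stoichiometry: {d!r}")
        lb = d.get("lower_bound")
        ub = d.get("upper_bound")
        if lb is None and ub is None and "lower_bound" not in d:
            lb, ub = DEFAULT_IRREVERSIBLE_BOUNDS
        else:
            lb = -math.inf if lb is None else float(lb)
            ub = math.inf if ub is None else float(ub)
        rxns.append(
            Reaction(
                d["id"],
                {k: float(v) for k, v in d["stoichiometry"].items()},
                lb,
                ub,
                bool(d.get("is_exchange", False)),
            )
        )
    return MetabolicModel(
        tuple(mets), tuple(rxns), objective, name=doc.get("name", "")
    )


def _load_sbml(text: str) -> MetabolicModel:
    try:
        import libsbml
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ModelParseError(
            "SBML import requires the python-libsbml package"
        ) from exc
    reader = libsbml.SBMLReader()
    doc = reader.readSBMLFromString(text)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getError(0)
        raise ModelParseError(f"SBML parse error: {err.getMessage().strip()}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelParseError("SBML document contains no model element")
    mets = [
        Metabolite(
            s.getId(),
            s.getName() or "",
            s.getCompartment() or "c",
        )
        for s in sbml_model.getListOfSpecies()
    ]
    # fbc flux bounds live in global parameters referenced per reaction
    params = {
        p.getId(): p.getValue() for p in sbml_model.getListOfParameters()
    }
    rxns = []
    for r in sbml_model.getListOfReactions():
        stoich: dict[str, float] = {}
        for sr in r.getListOfReactants():
            stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) - sr.getStoichiometry()
        for sr in r.getListOfProducts():
            stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) + sr.getStoichiometry()
        fbc = r.getPlugin("fbc")
        lb = ub = None
        if fbc is not None:
            if fbc.isSetLowerFluxBound():
                lb = params.get(fbc.getLowerFluxBound())
            if fbc.isSetUpperFluxBound():
                ub = params.get(fbc.getUpperFluxBound())
        if lb is None or ub is None:
            default = (
                DEFAULT_REVERSIBLE_BOUNDS
                if r.getReversible()
                else DEFAULT_IRREVERSIBLE_BOUNDS
            )
            lb = default[0] if lb is None else lb
            ub = default[1] if ub is None else ub
        rxns.append(
            Reaction(r.getId(), stoich, lb, ub, is_exchange=len(stoich) == 1)
        )
    objective_id = ""
    fbc_model = sbml_model.getPlugin("fbc")
    if fbc_model is not None and fbc_model.getNumObjectives() > 0:
        obj = fbc_model.getActiveObjective() or fbc_model.getObjective(0)
        if obj is not None and obj.getNumFluxObjectives() > 0:
            objective_id = obj.getFluxObjective(0).getReaction()
    if not objective_id:
        raise ModelParseError("SBML document declares no flux objective")
    return MetabolicModel(tuple(mets), tuple(rxns), objective_id,
                          name=sbml_model.getId() or "")


def load_model(source, format: str = "json") -> MetabolicModel:
    """Load a model from a path or document text.

    Parameters
    ----------
    source
        A filesystem path, or the document itself as a string.
    format
        ``"json"`` (canonical dialect) or ``"sbml"`` (Level 3 fbc subset,
        import only).
    """
    text = None
    if hasattr(source, "read"):
        text = source.read()
    else:
        s = str(source)
        if "\n" in s or s.lstrip().startswith(("{", "<")):
            text = s
        else:
            with open(s) as fh:
                text = fh.read()
    if format == "json":
        try:
            doc = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ModelParseError(f"invalid JSON: {exc}") from None
        return _model_from_doc(doc)
    if format == "sbml":
        return _load_sbml(text)
    raise ValueError(f"unsupported format {format!r}")


# ---------------------------------------------------------------------------
# Model edits
# ---------------------------------------------------------------------------

def _species_of_exchange(rxn: Reaction) -> str:
    (met_id,) = rxn.stoichiometry
    base = rxn.id
    if base.upper().startswith("EX_"):
        base = base[3:]
    for suffix in ("_e", "(e)", "_ext"):
        if base.endswith(suffix):
            base = base[: -len(suffix)]
    return base.lower()


def set_carbon_source(
    model: MetabolicModel,
    exchange_id: str,
    max_uptake: float,
    keep_open=None,
) -> MetabolicModel:
    """Make one exchange the sole organic-carbon source.

    The named exchange gets ``lower_bound = -max_uptake``; every other
    exchange not recognized as inorganic (:data:`INORGANIC_SPECIES`, or the
    explicit ``keep_open`` iterable of exchange ids) has uptake closed
    (``lower_bound = 0``).  Secretion bounds are untouched and the input
    model is not modified.
    """
    if max_uptake <= 0:
        raise ValueError("max_uptake must be positive")
    rxn = model.reaction(exchange_id)
    if not rxn.is_exchange:
        raise ValueError(f"{exchange_id!r} is not an exchange reaction")
    keep = set(keep_open or ())
    out = model
    for r in model.exchanges:
        if r.id == exchange_id:
            out = out.with_reaction(r.with_bounds(-float(max_uptake), r.upper_bound))
        elif r.id in keep or _species_of_exchange(r) in INORGANIC_SPECIES:
            continue
        elif r.lower_bound < 0:
            out = out.with_reaction(r.with_bounds(0.0, r.upper_bound))
    return out


def apply_knockouts(model: MetabolicModel, reaction_ids) -> MetabolicModel:
    """Return a copy of the model with the named reactions forced to zero flux."""
    out = model
    for rid in sorted(set(reaction_ids)):
        rxn = model.reaction(rid)  # raises KeyError on unknown id
        out = out.with_reaction(rxn.with_bounds(0.0, 0.0))
    return out
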