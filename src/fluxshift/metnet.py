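"""Stoichiometric metabolic network data model and JSON/SBML readers/writers.

The in-memory containers (:class:`Metabolite`, :class:`Reaction`,
:class:`MetabolicModel`) are deliberately small value objects: every
transformation in the package (bound overrides, perturbation presets)
returns a new model rather than mutating its input, so a wild-type model
and the knock-out/over-expression models derived from it can coexist and
be compared safely.

Two interchange formats are supported:

* a versioned JSON dialect (schema below), written with sorted keys so
  serializations are diff-stable;
* SBML Level 3 core with fbc-style flux bounds and objective, and
  subsystem labels taken from the groups package (falling back to a
  ``SUBSYSTEM:`` note, else ``"Unassigned"``).

JSON schema (version 1)::

    {
      "schema_version": 1,
      "id": "<model id>",
      "metabolites": [{"id": str, "name": str, "compartment": str}, ...],
      "reactions": [{"id": str, "name": str,
                     "stoichiometry": {"<met id>": float, ...},
                     "lower_bound": float, "upper_bound": float,
                     "subsystem": str, "genes": [str, ...]}, ...],
      "objective": {"<reaction id>": float, ...}
    }

Flux bounds are in nominal units of mmol·gDW⁻¹·h⁻¹; no unit conversion is
performed. Reversible reactions default to bounds (-1000, 1000), irreversible
ones to (0, 1000) when a file omits them.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .exceptions import (
    BoundError,
    FormatError,
    ModelValidationError,
    UnknownReactionError,
)

JSON_SCHEMA_VERSION = 1

#: conventional default bounds for genome-scale models
DEFAULT_REVERSIBLE_BOUNDS = (-1000.0, 1000.0)
DEFAULT_IRREVERSIBLE_BOUNDS = (0.0, 1000.0)

UNASSIGNED_SUBSYSTEM = "Unassigned"


@dataclass(frozen=True)
class Metabolite:
    """A chemical species localized to a compartment."""

    id: str
    name: str = ""
    compartment: str = "c"

    def __post_init__(self):
        if not self.id:
            raise ModelValidationError("metabolite id must be non-empty")


@dataclass(frozen=True)
class Reaction:
    """A bounded, subsystem-labelled biochemical conversion.

    ``stoichiometry`` maps metabolite ids to signed coefficients: negative
    for consumed species, positive for produced ones. A reaction with an
    empty stoichiometry is only legal when ``exchange=True`` (boundary
    pseudo-reactions).
    """

    id: str
    stoichiometry: Mapping[str, float]
    lower_bound: float = DEFAULT_IRREVERSIBLE_BOUNDS[0]
    upper_bound: float = DEFAULT_IRREVERSIBLE_BOUNDS[1]
    name: str = ""
    subsystem: str = UNASSIGNED_SUBSYSTEM
    genes: tuple[str, ...] = ()
    exchange: bool = False

    def __post_init__(self):
        if not self.id:
            raise ModelValidationError("reaction id must be non-empty")
        if self.lower_bound > self.upper_bound:
            raise BoundError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} "
                f"exceeds upper bound {self.upper_bound}"
            )
        if not self.stoichiometry and not self.exchange:
            raise ModelValidationError(
                f"reaction {self.id!r} has empty stoichiometry and is not "
                "flagged as exchange/demand",
                offending_ids=[self.id],
            )
        # normalize numerics to float so serialization is representation-stable
        object.__setattr__(
            self, "stoichiometry", {k: float(v) for k, v in self.stoichiometry.items()}
        )
        object.__setattr__(self, "lower_bound", float(self.lower_bound))
        object.__setattr__(self, "upper_bound", float(self.upper_bound))
        object.__setattr__(self, "genes", tuple(self.genes))

    @property
    def bounds(self) -> tuple[float, float]:
        return (self.lower_bound, self.upper_bound)

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0


@dataclass(frozen=True)
class MetabolicModel:
    """An ordered collection of metabolites and bounded reactions plus a
    linear objective (reaction id → weight)."""

    id: str
    metabolites: tuple[Metabolite, ...]
    reactions: tuple[Reaction, ...]
    objective: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "metabolites", tuple(self.metabolites))
        object.__setattr__(self, "reactions", tuple(self.reactions))
        object.__setattr__(
            self, "objective", {k: float(v) for k, v in self.objective.items()}
        )
        validate_model(self)

    # -- lookups ---------------------------------------------------------

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def reaction(self, reaction_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == reaction_id:
                return r
        raise UnknownReactionError(reaction_id)

    def has_reaction(self, reaction_id: str) -> bool:
        return any(r.id == reaction_id for r in self.reactions)

    def reactions_by_subsystem(self) -> dict[str, list[Reaction]]:
        out: dict[str, list[Reaction]] = {}
        for r in self.reactions:
            out.setdefault(r.subsystem, []).append(r)
        return out

    def content_hash(self) -> str:
        """SHA-256 of the canonical JSON serialization; identifies the model
        content independently of file provenance."""
        return hashlib.sha256(to_json(self).encode()).hexdigest()


def validate_model(model: MetabolicModel) -> None:
    """Check all structural invariants; raise ModelValidationError listing
    the offending ids on the first violated invariant."""
    met_ids = [m.id for m in model.metabolites]
    dup_mets = _duplicates(met_ids)
    if dup_mets:
        raise ModelValidationError(
            f"duplicate metabolite ids: {dup_mets}", offending_ids=dup_mets
        )
    rxn_ids = [r.id for r in model.reactions]
    dup_rxns = _duplicates(rxn_ids)
    if dup_rxns:
        raise ModelValidationError(
            f"duplicate reaction ids: {dup_rxns}", offending_ids=dup_rxns
        )
    met_set = set(met_ids)
    dangling = sorted(
        {
            mid
            for r in model.reactions
            for mid in r.stoichiometry
            if mid not in met_set
        }
    )
    if dangling:
        raise ModelValidationError(
            f"reactions reference undeclared metabolites: {dangling}",
            offending_ids=dangling,
        )
    rxn_set = set(rxn_ids)
    bad_obj = sorted(k for k in model.objective if k not in rxn_set)
    if bad_obj:
        raise ModelValidationError(
            f"objective references unknown reactions: {bad_obj}",
            offending_ids=bad_obj,
        )


def _duplicates(items: Iterable[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for x in items:
        if x in seen and x not in dups:
            dups.append(x)
        seen.add(x)
    return dups


# ---------------------------------------------------------------------------
# core operations
# ---------------------------------------------------------------------------


def stoichiometric_matrix(model: MetabolicModel) -> np.ndarray:
    """Dense stoichiometric matrix S, shape (n_metabolites, n_reactions).

    Entry (i, j) is the signed coefficient of metabolite i in reaction j;
    the steady-state constraint of FBA/MOMA is S·v = 0.
    """
    met_index = {m.id: i for i, m in enumerate(model.metabolites)}
    S = np.zeros((len(model.metabolites), len(model.reactions)))
    for j, rxn in enumerate(model.reactions):
        for mid, coef in rxn.stoichiometry.items():
            S[met_index[mid], j] = coef
    return S


def set_bounds(
    model: MetabolicModel, reaction_id: str, lower: float, upper: float
) -> MetabolicModel:
    """Return a copy of ``model`` with the named reaction's bounds replaced.

    The input model is never mutated; every other reaction is shared
    unchanged. Raises UnknownReactionError / BoundError.
    """
    if lower > upper:
        raise BoundError(
            f"reaction {reaction_id!r}: lower bound {lower} exceeds upper {upper}"
        )
    if not model.has_reaction(reaction_id):
        raise UnknownReactionError(reaction_id)
    new_reactions = tuple(
        replace(r, lower_bound=float(lower), upper_bound=float(upper))
        if r.id == reaction_id
        else r
        for r in model.reactions
    )
    return replace(model, reactions=new_reactions)


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------


def to_json(model: MetabolicModel) -> str:
    """Serialize to the versioned JSON dialect (sorted keys, diff-stable)."""
    doc = {
        "schema_version": JSON_SCHEMA_VERSION,
        "id": model.id,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": {k: r.stoichiometry[k] for k in sorted(r.stoichiometry)},
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "subsystem": r.subsystem,
                "genes": list(r.genes),
                "exchange": r.exchange,
            }
            for r in model.reactions
        ],
        "objective": {k: model.objective[k] for k in sorted(model.objective)},
    }
    return json.dumps(doc, sort_keys=True, indent=1)


def from_json(text: str) -> MetabolicModel:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise FormatError(f"not valid JSON: {exc}") from exc
    if not isinstance(doc, dict) or "reactions" not in doc:
        raise FormatError("JSON document lacks a 'reactions' element")
    version = doc.get("schema_version", JSON_SCHEMA_VERSION)
    if version != JSON_SCHEMA_VERSION:
        raise FormatError(f"unsupported schema_version {version!r}")
    try:
        mets = tuple(
            Metabolite(
                id=m["id"],
                name=m.get("name", ""),
                compartment=m.get("compartment", "c"),
            )
            for m in doc.get("metabolites", [])
        )
        rxns = []
        for r in doc["reactions"]:
            stoich = {k: float(v) for k, v in r.get("stoichiometry", {}).items()}
            explicit_exchange = bool(r.get("exchange", False))
            lb = r.get("lower_bound")
            ub = r.get("upper_bound")
            if lb is None or ub is None:
                default = (
                    DEFAULT_REVERSIBLE_BOUNDS
                    if r.get("reversible", False)
                    else DEFAULT_IRREVERSIBLE_BOUNDS
                )
                lb = default[0] if lb is None else lb
                ub = default[1] if ub is None else ub
            rxns.append(
                Reaction(
                    id=r["id"],
                    name=r.get("name", ""),
                    stoichiometry=stoich,
                    lower_bound=float(lb),
                    upper_bound=float(ub),
                    subsystem=r.get("subsystem") or UNASSIGNED_SUBSYSTEM,
                    genes=tuple(r.get("genes", [])),
                    exchange=explicit_exchange,
                )
            )
    except KeyError as exc:
        raise FormatError(f"model element missing required field {exc}") from exc
    objective = {k: float(v) for k, v in doc.get("objective", {}).items()}
    return MetabolicModel(
        id=doc.get("id", "model"),
        metabolites=mets,
        reactions=tuple(rxns),
        objective=objective,
    )


# ---------------------------------------------------------------------------
# file-level API
# ---------------------------------------------------------------------------


def load_model(path: str | Path, format: str | None = None) -> MetabolicModel:
    """Load a model from ``path``; ``format`` is "json" or "sbml".

    When ``format`` is omitted it is inferred from the file suffix
    (``.json`` vs ``.xml``/``.sbml``). Reaction order is preserved from the
    file. Raises FormatError on unparseable content and
    ModelValidationError (listing ids) on invariant violations.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "sbml"
    if format == "json":
        return from_json(path.read_text())
    if format == "sbml":
        from . import _sbml

        return _sbml.read_sbml(path)
    raise FormatError(f"unknown model format {format!r}")


def save_model(model: MetabolicModel, path: str | Path, format: str | None = None) -> None:
    """Write a model to disk in the JSON dialect or SBML L3+fbc."""
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "sbml"
    if format == "json":
        path.write_text(to_json(model) + "\n")
    elif format == "sbml":
        from . import _sbml

        _sbml.write_sbml(model, path)
    else:
        raise FormatError(f"unknown model format {format!r}")


def models_equal(a: MetabolicModel, b: MetabolicModel, tol: float = 1e-9) -> bool:
    """Structural equality: ids, ordering, stoichiometry, subsystems,
    objective, and bounds to within ``tol``."""
    if a.id != b.id or a.metabolite_ids != b.metabolite_ids:
        return False
    if a.reaction_ids != b.reaction_ids:
        return False
    for ra, rb in zip(a.reactions, b.reactions):
        if ra.subsystem != rb.subsystem:
            return False
        if not math.isclose(ra.lower_bound, rb.lower_bound, abs_tol=tol):
            return False
        if not math.isclose(ra.upper_bound, rb.upper_bound, abs_tol=tol):
            return False
        if set(ra.stoichiometry) != set(rb.stoichiometry):
            return False
        if any(
            not math.isclose(ra.stoichiometry[k], rb.stoichiometry[k], abs_tol=tol)
            for k in ra.stoichiometry
        ):
            return False
    if set(a.objective) != set(b.objective):
        return False
    return all(
        math.isclose(a.objective[k], b.objective[k], abs_tol=tol) for k in a.objective
    )
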