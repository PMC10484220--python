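"""Knock-out / over-expression model construction by flux-bound overrides.

Genetic perturbations are simulated at the reaction level: a knock-out
(KO) or over-expression (OE) is a list of bound overrides applied to the
reactions catalyzed by the targeted gene. The published HMGCS2 protocols
for the colon cancer model and the iHepatocytes2322 liver model ship as
presets (:func:`hmgcs2_presets`):

===========  =======================================================  ==================
preset       reactions                                                bounds (lb, ub)
===========  =======================================================  ==================
colon KO     HMR1437, HMR4604, HMR1573                                (9, keep)
colon OE     HMR1437, HMR4604, HMR1573                                (keep, 4000)
liver KO     HMR1437, HMR4604, HMR1573, HMR0027, HMR0030              (0, keep)
liver OE     HMR1437, HMR4604, HMR1573, HMR0027, HMR0030              (2000, 4000)
===========  =======================================================  ==================

The colon-KO lower bound of 9 is anomalous for a knock-out — it *forces*
flux through the target reactions instead of abolishing it — but it is the
published protocol, so it is reproduced verbatim as the default and a
prominent warning is emitted whenever the preset is built. Callers who
want a conventional knock-out can pass ``ko_bound_override=0`` (mirroring
the liver protocol) or use ``strict_ko=True`` to pin bounds to (0, 0).

Override targets absent from a model are collected and returned, not
raised: downstream classification reports them as "unidentified".
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal, Union

from .exceptions import BoundError, ConfigurationError, ModelValidationError
from .metnet import MetabolicModel, Reaction

#: sentinel for "leave this side of the bound untouched"
KEEP = "keep"

BoundValue = Union[float, Literal["keep"]]

#: reactions associated with HMGCS2 in the colon cancer model
HMGCS2_COLON_REACTIONS = ("HMR1437", "HMR4604", "HMR1573")
#: reactions associated with HMGCS2 in iHepatocytes2322
HMGCS2_LIVER_REACTIONS = (
    "HMR1437",
    "HMR4604",
    "HMR1573",
    "HMR0027",
    "HMR0030",
)

COLON_KO_LOWER_BOUND = 9.0
COLON_OE_UPPER_BOUND = 4000.0
LIVER_KO_LOWER_BOUND = 0.0
LIVER_OE_BOUNDS = (2000.0, 4000.0)

_COLON_KO_WARNING = (
    "the colon knock-out preset sets a LOWER bound of 9 on the HMGCS2 "
    "reactions, which forces flux through them rather than abolishing it; "
    "this reproduces the published protocol verbatim. Pass "
    "ko_bound_override=0 for a conventional knock-out."
)


@dataclass(frozen=True)
class BoundOverride:
    """One reaction's new bounds; either side may be KEEP."""

    reaction_id: str
    new_lower: BoundValue = KEEP
    new_upper: BoundValue = KEEP

    def __post_init__(self):
        if not self.reaction_id:
            raise ModelValidationError("override reaction_id must be non-empty")
        if (
            self.new_lower != KEEP
            and self.new_upper != KEEP
            and float(self.new_lower) > float(self.new_upper)
        ):
            raise BoundError(
                f"override for {self.reaction_id!r}: lower {self.new_lower} "
                f"> upper {self.new_upper}"
            )


@dataclass(frozen=True)
class PerturbationSpec:
    """A named KO/OE protocol: a non-empty list of bound overrides."""

    name: str
    mode: Literal["knockout", "overexpression"]
    overrides: tuple[BoundOverride, ...]

    def __post_init__(self):
        if self.mode not in ("knockout", "overexpression"):
            raise ConfigurationError(f"unknown perturbation mode {self.mode!r}")
        if not self.overrides:
            raise ModelValidationError(
                f"perturbation {self.name!r} has no overrides"
            )
        object.__setattr__(self, "overrides", tuple(self.overrides))

    @property
    def reaction_ids(self) -> list[str]:
        return [o.reaction_id for o in self.overrides]

    # -- JSON round trip -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "mode": self.mode,
            "overrides": [
                {
                    "reaction_id": o.reaction_id,
                    "new_lower": o.new_lower,
                    "new_upper": o.new_upper,
                }
                for o in self.overrides
            ],
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "PerturbationSpec":
        return cls(
            name=doc["name"],
            mode=doc["mode"],
            overrides=tuple(
                BoundOverride(
                    reaction_id=o["reaction_id"],
                    new_lower=o.get("new_lower", KEEP),
                    new_upper=o.get("new_upper", KEEP),
                )
                for o in doc["overrides"]
            ),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PerturbationSpec":
        return cls.from_dict(json.loads(Path(path).read_text()))


def apply_perturbation(
    model: MetabolicModel, spec: PerturbationSpec
) -> tuple[MetabolicModel, list[str]]:
    """Return (perturbed model, missing reaction ids).

    Each override replaces the named reaction's bounds (KEEP leaves that
    side untouched). Targets absent from the model are returned in
    ``missing`` in override order; they are not an error because the
    downstream classification has an explicit "unidentified" category.
    Raises BoundError when an applied override leaves lower > upper.
    """
    by_id = {r.id: r for r in model.reactions}
    missing: list[str] = []
    new_bounds: dict[str, tuple[float, float]] = {}
    for o in spec.overrides:
        rxn = by_id.get(o.reaction_id)
        if rxn is None:
            if o.reaction_id not in missing:
                missing.append(o.reaction_id)
            continue
        lo = rxn.lower_bound if o.new_lower == KEEP else float(o.new_lower)
        hi = rxn.upper_bound if o.new_upper == KEEP else float(o.new_upper)
        if lo > hi:
            raise BoundError(
                f"perturbation {spec.name!r} leaves reaction "
                f"{o.reaction_id!r} with lower {lo} > upper {hi}"
            )
        new_bounds[o.reaction_id] = (lo, hi)

    def _updated(r: Reaction) -> Reaction:
        if r.id in new_bounds:
            lo, hi = new_bounds[r.id]
            return replace(r, lower_bound=lo, upper_bound=hi)
        return r

    perturbed = replace(
        model, reactions=tuple(_updated(r) for r in model.reactions)
    )
    return perturbed, missing


def hmgcs2_presets(
    organ: Literal["colon", "liver"],
    ko_bound_override: float | None = None,
    strict_ko: bool = False,
) -> tuple[PerturbationSpec, PerturbationSpec]:
    """(knock-out, over-expression) specs for the published HMGCS2 protocols.

    ``ko_bound_override`` substitutes the colon-KO lower bound of 9 (see
    module docstring); ``strict_ko`` pins KO bounds to (0, 0) instead of
    only lowering the lower bound. Raises ConfigurationError for an
    unknown organ.
    """
    if organ == "colon":
        ko_lower = COLON_KO_LOWER_BOUND if ko_bound_override is None else float(
            ko_bound_override
        )
        if ko_bound_override is None and not strict_ko:
            warnings.warn(_COLON_KO_WARNING, UserWarning, stacklevel=2)
        ko = PerturbationSpec(
            name="colon-ko",
            mode="knockout",
            overrides=tuple(
                BoundOverride(rid, 0.0, 0.0) if strict_ko
                else BoundOverride(rid, ko_lower, KEEP)
                for rid in HMGCS2_COLON_REACTIONS
            ),
        )
        oe = PerturbationSpec(
            name="colon-oe",
            mode="overexpression",
            overrides=tuple(
                BoundOverride(rid, KEEP, COLON_OE_UPPER_BOUND)
                for rid in HMGCS2_COLON_REACTIONS
            ),
        )
        return ko, oe
    if organ == "liver":
        ko_lower = (
            LIVER_KO_LOWER_BOUND if ko_bound_override is None else float(ko_bound_override)
        )
        ko = PerturbationSpec(
            name="liver-ko",
            mode="knockout",
            overrides=tuple(
                BoundOverride(rid, 0.0, 0.0) if strict_ko
                else BoundOverride(rid, ko_lower, KEEP)
                for rid in HMGCS2_LIVER_REACTIONS
            ),
        )
        oe = PerturbationSpec(
            name="liver-oe",
            mode="overexpression",
            overrides=tuple(
                BoundOverride(rid, *LIVER_OE_BOUNDS)
                for rid in HMGCS2_LIVER_REACTIONS
            ),
        )
        return ko, oe
    raise ConfigurationError(f"unknown organ {organ!r}; expected 'colon' or 'liver'")
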