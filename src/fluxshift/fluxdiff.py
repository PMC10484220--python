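"""Flux-change classification and per-subsystem summarization.

A perturbed reaction flux is compared against the wild type by the 10%
rule: with delta = v_pert − v_orig, a reaction is

* ``up_regulated``   when delta >  max(rel_threshold·|v_orig|, abs_floor),
* ``down_regulated`` when delta < −max(rel_threshold·|v_orig|, abs_floor),
* ``no_change``      otherwise (ties at exactly the threshold included).

The relative threshold is taken on |v_orig| so the rule is well defined
for negative fluxes through reversible reactions; the absolute floor
(default 1e−6) keeps solver noise around zero-flux reactions from being
classified as a change.

Combining the knock-out (KO) and over-expression (OE) responses gives the
per-reaction verdict, named after the KO response:

* ``flux_decreasing``: down in KO and up in OE,
* ``flux_increasing``: up in KO and down in OE,
* ``unchanged``: no_change in both,
* ``inconsistent``: every other combination (e.g. a change in only one arm),
* ``unidentified``: the reaction was missing from the model or a
  perturbation arm did not solve.

Verdicts are then aggregated per subsystem as counts and count/total
fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .exceptions import ContractError
from .metnet import MetabolicModel
from .solvers import FluxDistribution

UP = "up_regulated"
DOWN = "down_regulated"
NO_CHANGE = "no_change"
UNIDENTIFIED = "unidentified"

FLUX_DECREASING = "flux_decreasing"
FLUX_INCREASING = "flux_increasing"
UNCHANGED = "unchanged"
INCONSISTENT = "inconsistent"

DEFAULT_REL_THRESHOLD = 0.10
DEFAULT_ABS_FLOOR = 1e-6


@dataclass(frozen=True)
class ReactionFluxChange:
    """One reaction's wild-type vs perturbed flux and its direction label."""

    reaction_id: str
    v_orig: float
    v_pert: float
    label: str

    @property
    def delta(self) -> float:
        return self.v_pert - self.v_orig


@dataclass(frozen=True)
class KoOeClassification:
    """Direction labels of both perturbation arms plus the combined verdict."""

    reaction_id: str
    ko_label: str
    oe_label: str
    verdict: str
    v_orig: float = math.nan
    v_ko: float = math.nan
    v_oe: float = math.nan


@dataclass(frozen=True)
class SubsystemSummary:
    """Counts and fractions of flux-increasing/-decreasing reactions in one
    subsystem; fractions are counts over the subsystem's total reactions."""

    subsystem: str
    n_total: int
    n_increasing: int
    n_decreasing: int

    @property
    def frac_increasing(self) -> float:
        return self.n_increasing / self.n_total

    @property
    def frac_decreasing(self) -> float:
        return self.n_decreasing / self.n_total


def classify_flux_change(
    v_orig: float,
    v_pert: float,
    rel_threshold: float = DEFAULT_REL_THRESHOLD,
    abs_floor: float = DEFAULT_ABS_FLOOR,
) -> str:
    """Direction label for one reaction under the 10% rule (module docstring).

    Raises ContractError on non-finite fluxes or invalid thresholds.
    """
    if not (math.isfinite(v_orig) and math.isfinite(v_pert)):
        raise ContractError(
            f"fluxes must be finite, got v_orig={v_orig}, v_pert={v_pert}"
        )
    if not rel_threshold > 0:
        raise ContractError(f"rel_threshold must be > 0, got {rel_threshold}")
    if abs_floor < 0:
        raise ContractError(f"abs_floor must be ≥ 0, got {abs_floor}")
    delta = v_pert - v_orig
    threshold = max(rel_threshold * abs(v_orig), abs_floor)
    # a delta at exactly the threshold is not a change (strict rule); the
    # isclose guard keeps binary round-off from breaking exact ties
    if math.isclose(abs(delta), threshold, rel_tol=1e-9, abs_tol=1e-12):
        return NO_CHANGE
    if delta > threshold:
        return UP
    if delta < -threshold:
        return DOWN
    return NO_CHANGE


def _verdict(ko_label: str, oe_label: str) -> str:
    if ko_label == DOWN and oe_label == UP:
        return FLUX_DECREASING
    if ko_label == UP and oe_label == DOWN:
        return FLUX_INCREASING
    if ko_label == NO_CHANGE and oe_label == NO_CHANGE:
        return UNCHANGED
    return INCONSISTENT


def classify_ko_oe(
    orig: FluxDistribution,
    ko: FluxDistribution,
    oe: FluxDistribution,
    rel_threshold: float = DEFAULT_REL_THRESHOLD,
    abs_floor: float = DEFAULT_ABS_FLOOR,
    missing: Iterable[str] = (),
) -> list[KoOeClassification]:
    """Per-reaction verdicts over the shared reaction universe of the three
    distributions, plus one ``unidentified`` record per id in ``missing``
    (perturbation targets absent from the model).

    All three distributions must be optimal solves; classifying an
    infeasible solve would be meaningless, so it is a ContractError.
    """
    for name, dist in (("orig", orig), ("ko", ko), ("oe", oe)):
        if dist.status != "optimal":
            raise ContractError(
                f"{name} distribution has status {dist.status!r}; "
                "classification requires optimal solves"
            )
    universe = list(orig.fluxes)
    for dist in (ko, oe):
        extra = set(dist.fluxes) - set(universe)
        if extra:
            raise ContractError(
                f"flux distributions disagree on the reaction universe: "
                f"unexpected ids {sorted(extra)}"
            )
    out = []
    for rid in universe:
        v0, vk, vo = orig[rid], ko.get(rid, 0.0), oe.get(rid, 0.0)
        ko_label = classify_flux_change(v0, vk, rel_threshold, abs_floor)
        oe_label = classify_flux_change(v0, vo, rel_threshold, abs_floor)
        out.append(
            KoOeClassification(
                reaction_id=rid,
                ko_label=ko_label,
                oe_label=oe_label,
                verdict=_verdict(ko_label, oe_label),
                v_orig=v0,
                v_ko=vk,
                v_oe=vo,
            )
        )
    for rid in missing:
        out.append(
            KoOeClassification(
                reaction_id=rid,
                ko_label=UNIDENTIFIED,
                oe_label=UNIDENTIFIED,
                verdict=UNIDENTIFIED,
            )
        )
    return out


def summarize_subsystems(
    classifications: Sequence[KoOeClassification],
    model: MetabolicModel,
) -> list[SubsystemSummary]:
    """One summary per subsystem present in the model, sorted by
    frac_decreasing then frac_increasing, both descending (subsystem name
    breaks remaining ties).

    Every classified reaction must exist in the model; ``unidentified``
    records (missing targets) are skipped.
    """
    verdict_of = {}
    for c in classifications:
        if c.verdict == UNIDENTIFIED:
            continue
        if not model.has_reaction(c.reaction_id):
            raise ContractError(
                f"classified reaction {c.reaction_id!r} not in model {model.id!r}"
            )
        verdict_of[c.reaction_id] = c.verdict

    summaries = []
    for subsystem, rxns in model.reactions_by_subsystem().items():
        verdicts = [verdict_of.get(r.id) for r in rxns]
        summaries.append(
            SubsystemSummary(
                subsystem=subsystem,
                n_total=len(rxns),
                n_increasing=sum(v == FLUX_INCREASING for v in verdicts),
                n_decreasing=sum(v == FLUX_DECREASING for v in verdicts),
            )
        )
    summaries.sort(
        key=lambda s: (-s.frac_decreasing, -s.frac_increasing, s.subsystem)
    )
    return summaries


# ---------------------------------------------------------------------------
# TSV emission
# ---------------------------------------------------------------------------


def classifications_to_tsv(
    classifications: Sequence[KoOeClassification],
    model: MetabolicModel,
    path: str | Path,
) -> None:
    """Per-reaction table: reaction_id, subsystem, v_orig, v_ko, v_oe,
    ko_label, oe_label, verdict. Missing targets carry NA fluxes."""
    subsystem_of = {r.id: r.subsystem for r in model.reactions}
    lines = ["reaction_id\tsubsystem\tv_orig\tv_ko\tv_oe\tko_label\toe_label\tverdict"]
    for c in classifications:
        fmt = lambda x: "NA" if math.isnan(x) else f"{x:.9g}"
        lines.append(
            "\t".join(
                [
                    c.reaction_id,
                    subsystem_of.get(c.reaction_id, UNIDENTIFIED),
                    fmt(c.v_orig),
                    fmt(c.v_ko),
                    fmt(c.v_oe),
                    c.ko_label,
                    c.oe_label,
                    c.verdict,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def summaries_to_tsv(
    summaries: Sequence[SubsystemSummary], path: str | Path
) -> None:
    """Subsystem table with both raw counts and count/total fractions."""
    lines = [
        "subsystem\tn_total\tn_increasing\tn_decreasing\t"
        "frac_increasing\tfrac_decreasing"
    ]
    for s in summaries:
        lines.append(
            f"{s.subsystem}\t{s.n_total}\t{s.n_increasing}\t{s.n_decreasing}\t"
            f"{s.frac_increasing:.9g}\t{s.frac_decreasing:.9g}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
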