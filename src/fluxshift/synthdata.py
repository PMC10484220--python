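"""Synthetic desk-scale inputs: a toy ketogenesis network, random feasible
metabolic models with a feasibility witness, and labelled DE tables.

All generators are pure functions of their parameters and seed (a fresh
``numpy.random.default_rng`` per call, no global state), so the same call
always yields byte-identical output.

The toy network is a minimal central-carbon model with a ketogenesis
branch around an HMGCS2 analog (HMGCS2x, acetoacetyl-CoA + acetyl-CoA →
HMG-CoA). Oxidative phosphorylation is capacity-limited (upper bound 12),
which is the deliberate bottleneck of the design: at the wild-type optimum
glucose-derived acetyl-CoA exceeds respiratory capacity and the excess
drains through the ketone branch, so a knock-out of HMGCS2x has real flux
to reroute and knock-out/over-expression sign patterns are non-vacuous.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .degfilter import DeRecord
from .exceptions import ConfigurationError
from .metnet import MetabolicModel, Metabolite, Reaction
from .solvers import STATUS_FEASIBLE, FluxDistribution


def toy_ketone_model() -> MetabolicModel:
    """The fixed 8-metabolite, 13-reaction ketogenesis toy model.

    Glucose uptake (≤ 10) feeds glycolysis and pyruvate dehydrogenase;
    acetyl-CoA is burned by capacity-limited oxidative phosphorylation
    (≤ 12), exported through the ketone branch (ACAT → HMGCS2x → HMGL →
    acetoacetate), or stored via fatty-acid synthesis; fatty acids can
    also be imported (≤ 2) and β-oxidized. The objective maximizes the
    ATP-demand reaction ATPM.
    """

    def met(mid: str, name: str) -> Metabolite:
        return Metabolite(id=mid, name=name, compartment="c")

    mets = (
        met("glc", "glucose"),
        met("pyr", "pyruvate"),
        met("accoa", "acetyl-CoA"),
        met("aacoa", "acetoacetyl-CoA"),
        met("hmgcoa", "HMG-CoA"),
        met("acac", "acetoacetate"),
        met("fa", "fatty acid"),
        met("atp", "ATP"),
    )

    def rxn(rid, stoich, lb, ub, subsystem, name="", genes=(), exchange=False):
        return Reaction(
            id=rid,
            name=name or rid,
            stoichiometry=stoich,
            lower_bound=lb,
            upper_bound=ub,
            subsystem=subsystem,
            genes=genes,
            exchange=exchange,
        )

    rxns = (
        rxn("EX_glc", {"glc": 1}, 0, 10, "Exchange", "glucose uptake"),
        rxn("GLYC", {"glc": -1, "pyr": 2, "atp": 2}, 0, 1000, "Glycolysis"),
        rxn("PDH", {"pyr": -1, "accoa": 1}, 0, 1000, "Pyruvate metabolism"),
        rxn("OXP", {"accoa": -1, "atp": 10}, 0, 12, "Oxidative phosphorylation"),
        rxn("ACAT", {"accoa": -2, "aacoa": 1}, 0, 1000, "Ketone synthesis"),
        rxn(
            "HMGCS2x",
            {"aacoa": -1, "accoa": -1, "hmgcoa": 1},
            0,
            1000,
            "Ketone synthesis",
            "HMG-CoA synthase (HMGCS2 analog)",
            genes=("HMGCS2",),
        ),
        rxn("HMGL", {"hmgcoa": -1, "acac": 1, "accoa": 1}, 0, 1000, "Ketone synthesis"),
        rxn("EX_acac", {"acac": -1}, 0, 1000, "Exchange", "acetoacetate export"),
        rxn(
            "FAS",
            {"accoa": -8, "atp": -7, "fa": 1},
            0,
            1000,
            "Fatty acid biosynthesis",
        ),
        rxn("EX_fa_in", {"fa": 1}, 0, 2, "Exchange", "fatty acid uptake"),
        rxn("FAO", {"fa": -1, "accoa": 8}, 0, 1000, "Beta oxidation"),
        rxn("EX_fa_out", {"fa": -1}, 0, 1000, "Exchange", "fatty acid export"),
        rxn("ATPM", {"atp": -1}, 1, 1000, "Energy demand", "ATP maintenance"),
    )
    return MetabolicModel(
        id="toy_ketone",
        metabolites=mets,
        reactions=rxns,
        objective={"ATPM": 1.0},
    )


def random_feasible_model(
    n_metabolites: int,
    n_reactions: int,
    seed: int,
) -> tuple[MetabolicModel, FluxDistribution]:
    """A random sparse stoichiometric model plus a certified witness flux.

    Generation is witness-first: internal fluxes are sampled, exchange
    fluxes are set to balance every metabolite exactly, and each bound is
    sampled to strictly bracket the witness value — so the model is
    feasible by construction and no solver call is needed. The first
    ``n_metabolites`` reactions are per-metabolite exchanges; the rest are
    sparse internal conversions. The objective is the last internal
    reaction (or the last exchange when there are none).

    The witness is returned as a :class:`FluxDistribution` with status
    ``"feasible"``; it certifies solvability and serves as a MOMA
    reference in tests.
    """
    if n_metabolites < 2:
        raise ConfigurationError("need at least 2 metabolites")
    if n_reactions < n_metabolites:
        raise ConfigurationError("need n_reactions ≥ n_metabolites (one exchange each)")
    rng = np.random.default_rng(seed)

    met_ids = [f"M{i}" for i in range(n_metabolites)]
    mets = tuple(Metabolite(id=m, name=m, compartment="c") for m in met_ids)

    n_internal = n_reactions - n_metabolites
    internal: list[dict[str, float]] = []
    for _ in range(n_internal):
        k = int(rng.integers(2, min(4, n_metabolites) + 1))
        chosen = rng.choice(n_metabolites, size=k, replace=False)
        coefs = rng.choice([-2.0, -1.0, 1.0, 2.0], size=k)
        # force at least one substrate and one product
        if np.all(coefs > 0):
            coefs[0] = -1.0
        if np.all(coefs < 0):
            coefs[-1] = 1.0
        internal.append({met_ids[m]: float(c) for m, c in zip(chosen, coefs)})

    v_internal = rng.uniform(-5.0, 5.0, size=n_internal)
    # net production of each metabolite by internal reactions
    net = np.zeros(n_metabolites)
    for stoich, v in zip(internal, v_internal):
        for mid, coef in stoich.items():
            net[met_ids.index(mid)] += coef * v
    # exchange M_i -> (coefficient −1) carries flux equal to net production
    v_exchange = net
    witness = np.concatenate([v_exchange, v_internal])

    reactions = []
    margins_lo = rng.uniform(0.5, 3.0, size=n_reactions)
    margins_hi = rng.uniform(0.5, 3.0, size=n_reactions)
    for i, mid in enumerate(met_ids):
        reactions.append(
            Reaction(
                id=f"EX_{mid}",
                name=f"{mid} exchange",
                stoichiometry={mid: -1.0},
                lower_bound=round(float(witness[i] - margins_lo[i]), 6),
                upper_bound=round(float(witness[i] + margins_hi[i]), 6),
                subsystem="Exchange",
            )
        )
    for j, stoich in enumerate(internal):
        i = n_metabolites + j
        reactions.append(
            Reaction(
                id=f"R{j}",
                name=f"internal {j}",
                stoichiometry=stoich,
                lower_bound=round(float(witness[i] - margins_lo[i]), 6),
                upper_bound=round(float(witness[i] + margins_hi[i]), 6),
                subsystem=f"Subsystem {j % 3}",
            )
        )

    objective_rxn = reactions[-1].id
    model = MetabolicModel(
        id=f"random_{n_metabolites}x{n_reactions}_s{seed}",
        metabolites=mets,
        reactions=tuple(reactions),
        objective={objective_rxn: 1.0},
    )
    fluxes = {r.id: float(v) for r, v in zip(model.reactions, witness)}
    obj = fluxes[objective_rxn]
    witness_dist = FluxDistribution(
        model_id=model.id,
        fluxes=fluxes,
        status=STATUS_FEASIBLE,
        objective_value=obj,
    )
    return model, witness_dist


@dataclass(frozen=True)
class SyntheticDeTruth:
    """Ground-truth labels for a generated DE table: gene → 'up' / 'down' /
    'null', plus the noiseless log2FC each label was drawn around."""

    labels: Mapping[str, str]
    true_log2fc: Mapping[str, float]
    na_genes: frozenset[str]

    def genes_with_label(self, label: str) -> set[str]:
        return {g for g, lab in self.labels.items() if lab == label}


def synthetic_de_table(
    n_genes: int,
    frac_up: float,
    frac_down: float,
    effect_log2fc: float,
    null_sd: float,
    seed: int,
    na_fraction: float = 0.0,
) -> tuple[list[DeRecord], SyntheticDeTruth]:
    """A labelled synthetic DE table emulating a count-based DE fit output.

    Up-regulated genes draw log2FC ~ N(+effect, 0.1·effect) with
    p_adj ~ U(1e−12, 1e−4); down-regulated genes are mirrored negative;
    null genes draw log2FC ~ N(0, null_sd) with p_adj ~ U(0.5, 1). The raw
    p-value is p_adj scaled down by U(0.1, 1). ``na_fraction`` of rows get
    NA injected — always into p_adj, half the time into log2FC as well —
    emulating genes the DE fit could not test; their truth label is
    unchanged (an NA masks detection, it does not flip biology), and after
    NA→1 cleaning such rows can never pass the significance filter.
    """
    if frac_up < 0 or frac_down < 0:
        raise ConfigurationError("fractions must be non-negative")
    if frac_up + frac_down > 1:
        raise ConfigurationError(
            f"frac_up + frac_down must be ≤ 1, got {frac_up + frac_down}"
        )
    if effect_log2fc <= 0:
        raise ConfigurationError("effect_log2fc must be > 0")
    if not 0 <= na_fraction <= 1:
        raise ConfigurationError("na_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)

    n_up = round(n_genes * frac_up)
    n_down = round(n_genes * frac_down)
    labels = ["up"] * n_up + ["down"] * n_down + ["null"] * (n_genes - n_up - n_down)

    width = len(str(max(n_genes, 1)))
    records: list[DeRecord] = []
    truth_labels: dict[str, str] = {}
    truth_lfc: dict[str, float] = {}
    na_genes: set[str] = set()
    for i, label in enumerate(labels):
        gene = f"G{i:0{width}d}"
        if label == "up":
            lfc = float(rng.normal(effect_log2fc, 0.1 * effect_log2fc))
            padj = float(rng.uniform(1e-12, 1e-4))
            true_lfc = effect_log2fc
        elif label == "down":
            lfc = float(rng.normal(-effect_log2fc, 0.1 * effect_log2fc))
            padj = float(rng.uniform(1e-12, 1e-4))
            true_lfc = -effect_log2fc
        else:
            lfc = float(rng.normal(0.0, null_sd))
            padj = float(rng.uniform(0.5, 1.0))
            true_lfc = 0.0
        pvalue = padj * float(rng.uniform(0.1, 1.0))
        log2fc_out: float | None = lfc
        padj_out: float | None = padj
        if na_fraction > 0 and rng.random() < na_fraction:
            # an untestable gene always lacks p_adj, and half the time the
            # fold change too (as when every count is zero); p_adj is never
            # present alone with an NA fold change, since NA→1 would then
            # let the row pass the |log2FC| cutoff spuriously
            na_genes.add(gene)
            padj_out = None
            if rng.random() < 0.5:
                log2fc_out = None
        records.append(
            DeRecord(gene=gene, log2fc=log2fc_out, pvalue=pvalue, padj=padj_out)
        )
        truth_labels[gene] = label
        truth_lfc[gene] = true_lfc

    truth = SyntheticDeTruth(
        labels=truth_labels,
        true_log2fc=truth_lfc,
        na_genes=frozenset(na_genes),
    )
    return records, truth
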