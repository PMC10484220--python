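"""Differential-expression table cleaning, DEG retention and intersections.

Operates on precomputed DE result tables (gene, log2FC, p-value, adjusted
p-value) as produced by standard count-based DE fits; the fit itself is
not performed here. The processing rules are:

* low-count prefilter: genes with mean raw count < 1 across all samples
  are dropped before any DE fit;
* NA cleaning: an NA adjusted p-value or log2FC is replaced by 1 — such a
  gene can then never pass the significance filter;
* DEG retention: up-regulated = log2FC > 0.58 and p_adj < 0.01;
  down-regulated = log2FC < −0.58 and p_adj < 0.01 (strict inequalities,
  so boundary rows are excluded);
* intersections: common up/down gene sets between two cohorts, optionally
  restricted to an annotation gene set (e.g. mitochondrial genes), with
  Venn counts on the union of up and down per side.

Gene identity is the symbol string, case-sensitive; no alias resolution
is attempted because it is annotation-database-version-dependent.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ContractError, ModelValidationError

DEFAULT_LFC_CUTOFF = 0.58
DEFAULT_PADJ_CUTOFF = 0.01

#: TSV column order for DE tables
DE_COLUMNS = ("gene", "log2FC", "pvalue", "padj")


@dataclass(frozen=True)
class DeRecord:
    """One gene's DE-fit result; ``None`` encodes NA."""

    gene: str
    log2fc: float | None
    pvalue: float | None
    padj: float | None

    def __post_init__(self):
        if not self.gene:
            raise ModelValidationError("DeRecord gene symbol must be non-empty")
        for name, value in (
            ("log2fc", self.log2fc),
            ("pvalue", self.pvalue),
            ("padj", self.padj),
        ):
            if value is not None and not math.isfinite(value):
                raise ModelValidationError(
                    f"gene {self.gene!r}: {name} must be finite or NA, got {value}"
                )


@dataclass(frozen=True)
class DegFilterResult:
    """Retained up-/down-regulated gene sets and the cutoffs that produced
    them; up and down are disjoint by construction."""

    up: frozenset[str]
    down: frozenset[str]
    lfc_cutoff: float = DEFAULT_LFC_CUTOFF
    padj_cutoff: float = DEFAULT_PADJ_CUTOFF

    def to_json(self, path: str | Path) -> None:
        doc = {
            "up": sorted(self.up),
            "down": sorted(self.down),
            "params": {
                "lfc_cutoff": self.lfc_cutoff,
                "padj_cutoff": self.padj_cutoff,
            },
        }
        Path(path).write_text(json.dumps(doc, indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "DegFilterResult":
        doc = json.loads(Path(path).read_text())
        return cls(
            up=frozenset(doc["up"]),
            down=frozenset(doc["down"]),
            lfc_cutoff=doc["params"]["lfc_cutoff"],
            padj_cutoff=doc["params"]["padj_cutoff"],
        )


@dataclass(frozen=True)
class IntersectionResult:
    """Common up/down genes between two cohorts plus Venn counts computed
    on up ∪ down per side (a_only, b_only, common)."""

    common_up: frozenset[str]
    common_down: frozenset[str]
    venn: tuple[int, int, int]

    def to_json(self, path: str | Path) -> None:
        a_only, b_only, common = self.venn
        doc = {
            "common_up": sorted(self.common_up),
            "common_down": sorted(self.common_down),
            "venn": {"a_only": a_only, "b_only": b_only, "common": common},
        }
        Path(path).write_text(json.dumps(doc, indent=1) + "\n")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def prefilter_counts(counts: pd.DataFrame) -> list[str]:
    """Genes (rows) whose mean raw count across samples (columns) is ≥ 1.

    Raises ContractError on an empty matrix or negative counts.
    """
    if counts.empty:
        raise ContractError("count matrix is empty")
    values = counts.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ContractError("count matrix contains negative values")
    keep = values.mean(axis=1) >= 1.0
    return [str(g) for g in counts.index[keep]]


def clean_na(table: Iterable[DeRecord]) -> list[DeRecord]:
    """Replace NA adjusted p-values and log2FC with 1; idempotent, other
    fields untouched (an NA raw p-value stays NA)."""
    return [
        DeRecord(
            gene=r.gene,
            log2fc=1.0 if r.log2fc is None else r.log2fc,
            pvalue=r.pvalue,
            padj=1.0 if r.padj is None else r.padj,
        )
        for r in table
    ]


def filter_degs(
    table: Iterable[DeRecord],
    lfc_cutoff: float = DEFAULT_LFC_CUTOFF,
    padj_cutoff: float = DEFAULT_PADJ_CUTOFF,
) -> DegFilterResult:
    """Retain DEGs under strict |log2FC| and adjusted-p cutoffs.

    Expects a cleaned table (:func:`clean_na`); records still carrying NA
    in log2FC or p_adj are treated as non-significant.
    """
    up, down = set(), set()
    for r in table:
        if r.log2fc is None or r.padj is None:
            continue
        if r.padj < padj_cutoff:
            if r.log2fc > lfc_cutoff:
                up.add(r.gene)
            elif r.log2fc < -lfc_cutoff:
                down.add(r.gene)
    return DegFilterResult(
        up=frozenset(up),
        down=frozenset(down),
        lfc_cutoff=lfc_cutoff,
        padj_cutoff=padj_cutoff,
    )


def intersect_degs(
    a: DegFilterResult,
    b: DegFilterResult,
    annotation: Iterable[str] | None = None,
) -> IntersectionResult:
    """Common up/down genes between two cohorts.

    When ``annotation`` is given (e.g. a mitochondrial gene list), every
    set is first restricted to it. Venn counts are computed on up ∪ down
    per side: (|a only|, |b only|, |common|).
    """
    a_up, a_down, b_up, b_down = set(a.up), set(a.down), set(b.up), set(b.down)
    if annotation is not None:
        ann = set(annotation)
        a_up, a_down = a_up & ann, a_down & ann
        b_up, b_down = b_up & ann, b_down & ann
    a_all, b_all = a_up | a_down, b_up | b_down
    common = a_all & b_all
    return IntersectionResult(
        common_up=frozenset(a_up & b_up),
        common_down=frozenset(a_down & b_down),
        venn=(len(a_all - b_all), len(b_all - a_all), len(common)),
    )


# ---------------------------------------------------------------------------
# TSV / text I/O
# ---------------------------------------------------------------------------


def read_de_table(path: str | Path) -> list[DeRecord]:
    """Read a DE TSV with header ``gene  log2FC  pvalue  padj`` (literal
    "NA" for missing values)."""
    df = pd.read_csv(
        path, sep="\t", dtype={"gene": str}, na_values=["NA"], keep_default_na=False
    )
    missing = [c for c in DE_COLUMNS if c not in df.columns]
    if missing:
        raise ContractError(f"DE table {path} lacks columns {missing}")

    def _opt(x) -> float | None:
        return None if pd.isna(x) else float(x)

    return [
        DeRecord(
            gene=row.gene,
            log2fc=_opt(row.log2FC),
            pvalue=_opt(row.pvalue),
            padj=_opt(row.padj),
        )
        for row in df.itertuples()
    ]


def write_de_table(table: Sequence[DeRecord], path: str | Path) -> None:
    def _fmt(x: float | None) -> str:
        return "NA" if x is None else f"{x:.6g}"

    lines = ["\t".join(DE_COLUMNS)]
    lines += [
        f"{r.gene}\t{_fmt(r.log2fc)}\t{_fmt(r.pvalue)}\t{_fmt(r.padj)}"
        for r in table
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_gene_list(path: str | Path) -> set[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return out
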