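"""Bundled worked-example data: published top DEG tables.

The ten most significant up- and down-regulated genes reported for
early-stage colon adenocarcinoma (TCGA COAD, tumor vs normal) and
hepatocellular carcinoma (TCGA LIHC), as printed in the source study's
results tables. They serve as desk-scale worked examples for the DEG
filtering rules: every row clears |log2FC| > 0.58 and p_adj < 0.01, so
the filter must retain all of them.

Values are (gene, p-value, adjusted p-value, log2FC).
"""

from __future__ import annotations

from .degfilter import DeRecord

_COAD_UP = [
    ("ETV4", 6.69e-249, 1.92e-244, 5.388356),
    ("KRT80", 4.39e-223, 6.29e-219, 6.767),
    ("FOXQ1", 2.57e-207, 2.46e-203, 6.185771),
    ("CDH3", 3.61e-205, 2.59e-201, 5.942379),
    ("CEMIP", 5.39e-154, 3.09e-150, 5.079765),
    ("CLDN1", 4.40e-137, 1.80e-133, 5.050994),
    ("AJUBA", 1.66e-122, 3.97e-119, 3.008937),
    ("CASC19", 1.92e-122, 4.23e-119, 4.896743),
    ("ESM1", 2.16e-116, 4.29e-113, 5.556778),
    ("NFE2L3", 2.24e-116, 4.29e-113, 2.753282),
]

_COAD_DOWN = [
    ("BEST4", 9.91e-148, 4.73e-144, -5.91417),
    ("GLTP", 8.82e-133, 3.16e-129, -1.59429),
    ("CA7", 9.20e-129, 2.93e-125, -5.9989),
    ("ABCA8", 2.90e-124, 8.33e-121, -5.48495),
    ("TMEM100", 7.48e-124, 1.95e-120, -4.4167),
    ("SLC25A34", 2.61e-116, 4.68e-113, -4.19548),
    ("FAM135B", 7.26e-116, 1.22e-112, -4.71194),
    ("MAMDC2", 1.54e-108, 1.84e-105, -5.73998),
    ("PCSK2", 2.00e-108, 2.29e-105, -6.76073),
    ("GLP2R", 4.44e-106, 4.72e-103, -3.9582),
]

_LIHC_UP = [
    ("PLVAP", 2.52e-111, 6.97e-107, 3.002353),
    ("COL15A1", 1.26e-90, 1.74e-86, 4.023823),
    ("GABRD", 3.05e-88, 2.81e-84, 4.507174),
    ("GPC3", 2.33e-82, 1.61e-78, 6.061433),
    ("THBS4", 4.98e-78, 2.29e-74, 5.593584),
    ("DIPK2B", 7.57e-75, 2.99e-71, 2.301232),
    ("SLC26A6", 1.27e-74, 4.39e-71, 2.598325),
    ("CDKN3", 2.48e-74, 7.62e-71, 3.725304),
    ("FOXM1", 1.17e-72, 3.23e-69, 3.231552),
    ("NUF2", 2.19e-72, 5.50e-69, 3.854367),
]

_LIHC_DOWN = [
    ("ADAMTS13", 1.38e-81, 7.63e-78, -2.70486),
    ("OIT3", 6.41e-72, 1.26e-68, -3.10719),
    ("STAB2", 4.16e-67, 4.79e-64, -4.43614),
    ("ECM1", 1.75e-57, 1.10e-54, -3.08879),
    ("MAP2K1", 2.27e-55, 1.08e-52, -1.33004),
    ("CCL23", 4.26e-55, 1.96e-52, -2.87074),
    ("BMPER", 4.82e-52, 1.73e-49, -4.41371),
    ("TRIB1", 1.33e-51, 4.61e-49, -1.99208),
    ("PTH1R", 1.68e-50, 5.00e-48, -3.26794),
    ("LYVE1", 5.70e-50, 1.56e-47, -3.28161),
]


def _records(rows: list[tuple[str, float, float, float]]) -> list[DeRecord]:
    return [
        DeRecord(gene=g, log2fc=lfc, pvalue=p, padj=padj)
        for g, p, padj, lfc in rows
    ]


def coad_top_degs(direction: str = "both") -> list[DeRecord]:
    """Published top-ten colon adenocarcinoma DEG rows.

    ``direction`` is "up", "down" or "both".
    """
    return _select(_COAD_UP, _COAD_DOWN, direction)


def lihc_top_degs(direction: str = "both") -> list[DeRecord]:
    """Published top-ten hepatocellular carcinoma DEG rows."""
    return _select(_LIHC_UP, _LIHC_DOWN, direction)


def _select(up, down, direction: str) -> list[DeRecord]:
    if direction == "up":
        return _records(up)
    if direction == "down":
        return _records(down)
    if direction == "both":
        return _records(up) + _records(down)
    raise ValueError(f"direction must be 'up', 'down' or 'both', got {direction!r}")
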