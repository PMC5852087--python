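"""Per-locus contribution-to-function and pathway-step abundance reports.

The contribution of a locus to a function is its share of that function's
total expression: with two equally expressed loci on one function each
contributes 50%.  Expression defaults to length-normalised depth (reads
per gene base), which removes gene-length bias between the loci of one
function; raw counts are available as a switch.  Pathway-step abundances
are percentages of all counted mRNA reads, displayed on a log10 scale with
zero-abundance steps removed.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)


def contribution(
    expr_by_locus: Mapping[str, Mapping[str, float]],
) -> pd.DataFrame:
    """Percent contribution of each locus to each function.

    ``expr_by_locus`` maps function -> (locus -> non-negative expression).
    Contribution of locus *i* to function *f* is
    ``100 * expr(i, f) / sum_j expr(j, f)``; functions with zero total
    expression are omitted with a logged note.  Scale-invariant and
    permutation-invariant; within each function contributions sum to 100.
    """
    rows = []
    for function in expr_by_locus:
        loci = expr_by_locus[function]
        if any(v < 0 for v in loci.values()):
            raise ValueError(f"negative expression in function {function}")
        total = sum(loci.values())
        if total == 0:
            logger.info("function %s has zero total expression; omitted", function)
            continue
        for locus, value in loci.items():
            rows.append((function, locus, value, 100.0 * value / total))
    return pd.DataFrame(
        rows, columns=["function", "locus_tag", "expression", "contribution_pct"]
    )


def contribution_from_pathway_map(
    pathway_map: pd.DataFrame,
) -> pd.DataFrame:
    """Contribution table keyed by pathway step.

    Takes the output of :func:`metatrx.annotation.map_to_pathways` (columns
    pathway, step, locus_tag, expression) and treats each (pathway, step)
    pair as one function.  A locus feeding several steps contributes its
    full expression to each.
    """
    expr: dict[str, dict[str, float]] = {}
    for row in pathway_map.itertuples(index=False):
        key = f"{row.pathway}:{row.step}"
        expr.setdefault(key, {})[row.locus_tag] = float(row.expression)
    return contribution(expr)


def step_abundance(
    step_expression: Mapping[str, float],
    grand_total: float,
    floor: float = 1e-12,
) -> pd.DataFrame:
    """Relative abundance of each pathway step as percent of all reads.

    ``abundance = 100 * step count / grand_total``; the display value is
    ``log10(abundance)``.  Steps whose abundance does not exceed ``floor``
    are marked excluded (zero values are removed from the log display).
    """
    if grand_total <= 0:
        raise ValueError("grand_total must be positive")
    for step, count in step_expression.items():
        if count > grand_total:
            raise ValueError(f"step {step} count exceeds grand total")
    rows = []
    for step, count in step_expression.items():
        abundance = 100.0 * count / grand_total
        included = abundance > floor
        display = math.log10(abundance) if included else float("nan")
        rows.append((step, abundance, display, included))
    return pd.DataFrame(
        rows, columns=["step", "abundance_pct", "log10_display", "included"]
    )


def format_table1(
    contrib: pd.DataFrame,
    locus_taxon: Mapping[str, str] | None = None,
    round_pct: bool = True,
) -> pd.DataFrame:
    """Report-style table: gene label, locus tag, contig taxon, contribution.

    Contributions are rounded to whole percent for the report (internal
    values keep full precision).
    """
    out = contrib.copy()
    out["taxon"] = [
        (locus_taxon or {}).get(l, "") for l in out["locus_tag"]
    ]
    if round_pct:
        out["contribution_pct"] = out["contribution_pct"].round(0).astype(int)
    return out[["function", "locus_tag", "taxon", "contribution_pct"]]
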