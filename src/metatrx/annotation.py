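"""Functional annotation merging and pathway mapping.

Gene-level KO and EC labels from external annotators (KEGG-orthology
assignment, InterProScan domain scans, PRIAM EC prediction) arrive as TSV
tables.  Additional EC numbers are mined by matching protein-domain names
against an enzyme-name table (normalised exact match by default, an
order-insensitive token-set mode optionally).  Merged per-locus function
sets are then projected onto pathway definitions — ordered steps, each
accepting a set of KO/EC identifiers — to find which loci feed which
pathway step, with ambiguous (multi-step) loci flagged.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Dotted 4-field EC pattern, trailing fields may be dashes or n-numbers.
EC_PATTERN = re.compile(r"^\d+\.(\d+|-)\.(\d+|-)\.(n?\d+|-)$")

_PUNCT = re.compile(r"[^a-z0-9\s]+")
_WS = re.compile(r"\s+")


def normalize_name(name: str) -> str:
    """Lowercase, strip punctuation, collapse whitespace."""
    return _WS.sub(" ", _PUNCT.sub(" ", name.lower())).strip()


def _token_key(name: str) -> frozenset[str]:
    return frozenset(normalize_name(name).split())


@dataclass
class FunctionMap:
    """Per-locus KO and EC assignments with provenance.

    ``provenance`` maps (locus, identifier) to the set of sources that
    asserted it: ``ko-table``, ``ec-table`` or ``name-match``.
    """

    kos: dict[str, set[str]] = field(default_factory=dict)
    ecs: dict[str, set[str]] = field(default_factory=dict)
    provenance: dict[tuple[str, str], set[str]] = field(default_factory=dict)

    def loci(self) -> list[str]:
        return sorted(set(self.kos) | set(self.ecs))

    def functions_of(self, locus: str) -> set[str]:
        return self.kos.get(locus, set()) | self.ecs.get(locus, set())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for locus in self.loci():
            rows.append(
                (
                    locus,
                    ",".join(sorted(self.kos.get(locus, set()))),
                    ",".join(sorted(self.ecs.get(locus, set()))),
                )
            )
        return pd.DataFrame(rows, columns=["locus_tag", "KO", "EC"])


@dataclass(frozen=True)
class PathwayStep:
    label: str            # display gene symbol, e.g. "abcA", "bamB"
    identifiers: frozenset[str]  # acceptable KO/EC identifiers

    def __post_init__(self) -> None:
        if not self.identifiers:
            raise ValueError(f"step {self.label} has no identifiers")


@dataclass(frozen=True)
class PathwayDefinition:
    pathway_id: str
    steps: tuple[PathwayStep, ...]


def match_domain_names(
    domain_names: Mapping[str, Sequence[str]],
    enzyme_names: Mapping[str, str],
    mode: str = "exact",
) -> dict[str, set[str]]:
    """Derive per-locus EC numbers by matching domain names to enzyme names.

    ``mode="exact"`` matches after normalisation (lowercase, punctuation
    stripped, whitespace collapsed); ``mode="tokens"`` additionally ignores
    word order by comparing word multisets.  Idempotent and case-insensitive.
    """
    if mode == "exact":
        lookup = {normalize_name(k): v for k, v in enzyme_names.items()}
        keyer = normalize_name
    elif mode == "tokens":
        lookup = {_token_key(k): v for k, v in enzyme_names.items()}
        keyer = _token_key
    else:
        raise ValueError(f"unknown mode {mode!r}")
    out: dict[str, set[str]] = {}
    for locus, names in domain_names.items():
        for name in names:
            ec = lookup.get(keyer(name))
            if ec is not None:
                out.setdefault(locus, set()).add(ec)
    return out


def merge_annotations(
    ko_table: Mapping[str, Iterable[str]] | None = None,
    ec_table: Mapping[str, Iterable[str]] | None = None,
    name_match_ec: Mapping[str, Iterable[str]] | None = None,
) -> FunctionMap:
    """Union per-locus annotations from the three sources with provenance.

    Malformed EC strings are skipped with a logged warning; no other
    assignment is lost.  Output is independent of table input order.
    """
    fm = FunctionMap()
    for locus, kos in (ko_table or {}).items():
        for ko in kos:
            fm.kos.setdefault(locus, set()).add(ko)
            fm.provenance.setdefault((locus, ko), set()).add("ko-table")
    for source, table in (("ec-table", ec_table), ("name-match", name_match_ec)):
        for locus, ecs in (table or {}).items():
            for ec in ecs:
                if not EC_PATTERN.match(ec):
                    logger.warning(
                        "%s: skipping malformed EC %r for locus %s",
                        source, ec, locus,
                    )
                    continue
                fm.ecs.setdefault(locus, set()).add(ec)
                fm.provenance.setdefault((locus, ec), set()).add(source)
    return fm


def map_to_pathways(
    functions: FunctionMap,
    pathways: Sequence[PathwayDefinition],
    coverage: pd.DataFrame | None = None,
    expression_column: str = "depth",
) -> pd.DataFrame:
    """Project loci onto pathway steps via their KO/EC identifier sets.

    A locus contributes to a step when its function set intersects the
    step's acceptable identifiers; it may contribute to several steps, in
    which case it is flagged ambiguous.  With a coverage table the locus's
    expression (``expression_column``) is attached; otherwise expression
    is NaN.
    """
    step_hits: list[tuple[str, str, str]] = []
    locus_steps: dict[str, int] = {}
    for pw in pathways:
        for step in pw.steps:
            for locus in functions.loci():
                if functions.functions_of(locus) & step.identifiers:
                    step_hits.append((pw.pathway_id, step.label, locus))
                    locus_steps[locus] = locus_steps.get(locus, 0) + 1
    rows = []
    for pathway_id, step_label, locus in step_hits:
        expr = float("nan")
        if coverage is not None and locus in coverage.index:
            expr = float(coverage.loc[locus, expression_column])
        rows.append(
            (pathway_id, step_label, locus, expr, locus_steps[locus] > 1)
        )
    return pd.DataFrame(
        rows,
        columns=["pathway", "step", "locus_tag", "expression", "ambiguous"],
    )


# -- table plumbing -------------------------------------------------------


def read_annotation_table(path) -> dict[str, set[str]]:
    """Read a two/three-column TSV (locus, identifier[, score])."""
    df = pd.read_csv(str(path), sep="\t", header=None, comment="#")
    out: dict[str, set[str]] = {}
    for locus, ident in zip(df[0], df[1]):
        out.setdefault(str(locus), set()).add(str(ident))
    return out


def read_enzyme_names(path) -> dict[str, str]:
    """Read a two-column name -> EC TSV."""
    df = pd.read_csv(str(path), sep="\t", header=None, comment="#")
    return {str(name): str(ec) for name, ec in zip(df[0], df[1])}


def load_pathways(path=None) -> list[PathwayDefinition]:
    """Load pathway definitions from TSV (pathway, step order, label, ids).

    Without an explicit path the packaged benzene-degradation /
    nitrogen-cycle definitions are loaded.
    """
    if path is None:
        with resources.as_file(
            resources.files("metatrx").joinpath("data/pathways.tsv")
        ) as p:
            df = pd.read_csv(p, sep="\t", comment="#")
    else:
        df = pd.read_csv(str(path), sep="\t", comment="#")
    pathways = []
    for pw_id, group in df.groupby("pathway", sort=False):
        steps = tuple(
            PathwayStep(row.step, frozenset(str(row.identifiers).split(",")))
            for row in group.sort_values("order").itertuples(index=False)
        )
        pathways.append(PathwayDefinition(pw_id, steps))
    return pathways
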