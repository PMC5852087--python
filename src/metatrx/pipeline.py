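"""End-to-end orchestration: QC -> contig filter -> taxonomy -> counts ->
annotation -> contribution, from the standard file formats the external
tools produce (and the simulator emulates)."""

from __future__ import annotations

import logging
import os
from typing import Mapping

import pandas as pd

from . import annotation as ann
from .contribution import contribution_from_pathway_map, step_abundance
from .contigs import filter_contigs, read_fasta, write_fasta
from .lca import LCAParams, read_hit_table, two_pass_assign, assignments_to_frame
from .quant import count_reads, read_gene_calls, taxon_profile
from .readqc import qc_fastq, read_fastq
from .taxonomy import TaxonomyTree

logger = logging.getLogger(__name__)


def run_all(
    paths: Mapping[str, str],
    outdir: str | os.PathLike,
    min_len: int = 40,
    min_mean_q: float = 30,
    max_n: int = 3,
    min_q: int = 30,
    lca_params: LCAParams = LCAParams(),
    rank: str = "family",
    profile_use: str = "count",
    expression_column: str = "depth",
) -> dict[str, pd.DataFrame | pd.Series | dict]:
    """Run the whole pipeline from input files and write report TSVs.

    ``paths`` must provide: ``fastq`` (reads), ``fasta`` (contigs), ``gff``
    (gene calls), ``sam`` (alignments), ``hits`` (pass-1 hit table),
    ``nodes``/``names`` (taxonomy dumps), ``ko`` and optionally ``ec``
    (annotation TSVs: locus, identifier), optionally ``hits2`` (pass-2 hit
    table), ``domains`` (locus, domain name) + ``enzyme_names``
    (name, EC) for text-mined ECs, and ``pathways`` (definitions TSV;
    packaged defaults otherwise).

    Returns the in-memory results; writes qc_reads.fastq, kept_contigs.fasta,
    complexity.tsv, assignments.tsv, coverage.tsv, taxon_profile.tsv,
    function_map.tsv, pathway_map.tsv, contribution.tsv and
    step_abundance.tsv into *outdir*.
    """
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)

    # 1. read QC
    qc_fq = os.path.join(outdir, "qc_reads.fastq")
    qc_counts = qc_fastq(paths["fastq"], qc_fq, min_len, min_mean_q, max_n, min_q)
    kept_ids = {r.id for r in read_fastq(qc_fq)}

    # 2. contig complexity filter
    kept, removed = filter_contigs(read_fasta(paths["fasta"]))
    write_fasta(kept, os.path.join(outdir, "kept_contigs.fasta"))
    complexity = pd.DataFrame(
        [r.__dict__ | {"contig_id": c.id} for c, r in removed]
    )
    complexity.to_csv(os.path.join(outdir, "complexity.tsv"), sep="\t", index=False)
    kept_ids_contig = {c.id for c in kept}

    # 3. two-pass filtered-LCA taxonomy
    tree = TaxonomyTree.from_ncbi_dumps(paths["nodes"], paths["names"])
    pass1 = {
        q: h for q, h in read_hit_table(paths["hits"]).items()
        if q in kept_ids_contig
    }
    pass2 = {}
    if paths.get("hits2"):
        pass2 = {
            q: h for q, h in read_hit_table(paths["hits2"]).items()
            if q in kept_ids_contig
        }
    assignments = two_pass_assign(
        pass1, pass2, tree, lca_params, contigs=sorted(kept_ids_contig)
    )
    assignments_to_frame(assignments, tree).to_csv(
        os.path.join(outdir, "assignments.tsv"), sep="\t", index=False
    )

    # 4. per-gene counting on kept contigs, QC-kept reads only
    genes = [g for g in read_gene_calls(paths["gff"]) if g.contig in kept_ids_contig]
    coverage = count_reads(paths["sam"], genes, keep_reads=kept_ids)
    coverage.to_csv(os.path.join(outdir, "coverage.tsv"), sep="\t")

    # 5. taxon mRNA profile
    gene_contig = {g.locus_tag: g.contig for g in genes}
    profile = taxon_profile(coverage, gene_contig, assignments, tree, rank, profile_use)
    profile.rename_axis("taxon").to_csv(
        os.path.join(outdir, "taxon_profile.tsv"), sep="\t"
    )

    # 6. annotation merge + pathway mapping
    ko_table = ann.read_annotation_table(paths["ko"]) if paths.get("ko") else {}
    ec_table = ann.read_annotation_table(paths["ec"]) if paths.get("ec") else {}
    name_ec: dict[str, set[str]] = {}
    if paths.get("domains") and paths.get("enzyme_names"):
        domains_raw = pd.read_csv(paths["domains"], sep="\t", header=None, comment="#")
        domains = {}
        for locus, name in zip(domains_raw[0], domains_raw[1]):
            domains.setdefault(str(locus), []).append(str(name))
        name_ec = ann.match_domain_names(
            domains, ann.read_enzyme_names(paths["enzyme_names"])
        )
    functions = ann.merge_annotations(ko_table, ec_table, name_ec)
    functions.to_frame().to_csv(
        os.path.join(outdir, "function_map.tsv"), sep="\t", index=False
    )
    pathways = ann.load_pathways(paths.get("pathways"))
    pathway_map = ann.map_to_pathways(functions, pathways, coverage, expression_column)
    pathway_map.to_csv(os.path.join(outdir, "pathway_map.tsv"), sep="\t", index=False)

    # 7. contribution + step-abundance reports
    contribution_table = contribution_from_pathway_map(pathway_map)
    contribution_table.to_csv(
        os.path.join(outdir, "contribution.tsv"), sep="\t", index=False
    )
    grand_total = float(coverage["count"].sum())
    step_counts = {
        f"{row.pathway}:{row.step}": 0.0 for row in pathway_map.itertuples(index=False)
    }
    for row in pathway_map.itertuples(index=False):
        key = f"{row.pathway}:{row.step}"
        if row.locus_tag in coverage.index:
            step_counts[key] += float(coverage.loc[row.locus_tag, "count"])
    steps = (
        step_abundance(step_counts, grand_total)
        if grand_total > 0 and step_counts
        else pd.DataFrame(columns=["step", "abundance_pct", "log10_display", "included"])
    )
    steps.to_csv(os.path.join(outdir, "step_abundance.tsv"), sep="\t", index=False)

    return {
        "qc_counts": qc_counts,
        "kept_contigs": kept,
        "removed_contigs": removed,
        "assignments": assignments,
        "coverage": coverage,
        "taxon_profile": profile,
        "function_map": functions,
        "pathway_map": pathway_map,
        "contribution": contribution_table,
        "step_abundance": steps,
    }
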