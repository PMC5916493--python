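"""End-to-end orchestration: qc -> hgt -> synteny -> diverge -> collapse.

Runs the full comparative analysis on one species' inputs (GFF3 + FASTA +
hit tables + trees + VCF + depth profile) and produces the headline
per-species summary table. Any stage can be skipped; missing inputs for a
requested stage fail before any computation.
"""
from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict
from typing import Optional

import pandas as pd
import yaml

from . import collinearity as col
from . import divergence as div
from . import hgt as hgtmod
from . import inventory as inv
from .align import align_cds_pair
from .io_formats import (
    attach_sequences,
    read_class_map,
    read_depth_profile,
    read_gff3,
    read_hits_table,
    read_newick,
    read_vcf,
)
from .models import SpeciesSummary, ValidationError

log = logging.getLogger(__name__)

ALL_STAGES = ("qc", "hgt", "synteny", "diverge", "collapse")

DEFAULTS = {
    "hu_min": 30.0, "chs_min": 0.90, "heavy_frac": 0.95,
    "min_genes": 5, "max_gaps": 10, "ks_threshold": 0.3,
    "max_evalue": 1e-5, "min_mq": 30.0, "min_qual": 20.0, "depth_frac": 0.25,
}

_STAGE_INPUTS = {
    "qc": ["gff"],
    "hgt": ["gff", "hits", "classmap"],
    "synteny": ["gff", "pairs", "cds"],
    "diverge": ["self_hits"],
    "collapse": ["vcf", "depth", "gff"],
}


def load_config(path: str) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _require_inputs(config: dict, stages) -> None:
    inputs = config.get("inputs", {})
    for stage in stages:
        for key in _STAGE_INPUTS.get(stage, []):
            if key not in inputs:
                raise ValidationError(f"stage {stage!r} requires input {key!r}")
            if not os.path.exists(inputs[key]):
                raise ValidationError(f"input {key!r} not found: {inputs[key]}")


def run_pipeline(config: dict, outdir: Optional[str] = None) -> tuple[SpeciesSummary, dict]:
    """Run the requested stages and return (SpeciesSummary, artifacts).

    ``config`` holds ``species``, ``inputs`` (paths keyed gff/cds/proteins/
    hits/classmap/self_hits/pairs/trees/vcf/depth/te_hits), optional
    ``stages`` and threshold overrides under ``params``.
    """
    stages = tuple(config.get("stages", ALL_STAGES))
    params = {**DEFAULTS, **(config.get("params") or {})}
    _require_inputs(config, stages)
    inputs = config.get("inputs", {})

    genes = read_gff3(inputs["gff"])
    attach_sequences(genes, inputs.get("cds"), inputs.get("proteins"))
    summary = SpeciesSummary(species=config.get("species", "sample"),
                             total_genes=len(genes))
    artifacts: dict = {"params": params, "stages": list(stages)}

    # ---------------------------------------------------------------- qc
    if "qc" in stages:
        uniref_ids: set = set()
        if "hits" in inputs:
            uniref_ids = {h.query_id for h in read_hits_table(inputs["hits"])
                          if h.taxon_class != "self"}
        te_hits: dict = {}
        if inputs.get("te_hits"):
            te = pd.read_csv(inputs["te_hits"], sep="\t", header=None,
                             names=["gene", "evalue"])
            te_hits = dict(zip(te["gene"], te["evalue"]))
        genes, qc_report = inv.hq_gene_filter(genes, uniref_ids, te_hits)
        artifacts["qc"] = qc_report
    summary.hq_genes = len(genes)
    total = len(genes)

    # --------------------------------------------------------------- hgt
    if "hgt" in stages:
        hits = read_hits_table(inputs["hits"], read_class_map(inputs["classmap"]))
        trees = {}
        tree_dir = inputs.get("trees")
        if tree_dir and os.path.isdir(tree_dir):
            for fn in sorted(os.listdir(tree_dir)):
                if fn.endswith((".nwk", ".newick", ".tre")):
                    trees[fn.rsplit(".", 1)[0]] = read_newick(os.path.join(tree_dir, fn))
        evidence, hgt_sum, dropped = hgtmod.run_hgt_pipeline(
            hits, genes, trees=trees or None,
            hu_min=params["hu_min"], chs_min=params["chs_min"],
            heavy_frac=params["heavy_frac"], max_evalue=params["max_evalue"],
        )
        summary.n_hgt_candidates = hgt_sum["hgt_candidates"]["count"]
        summary.frac_hgt_candidates = hgt_sum["hgt_candidates"]["pct"]
        summary.n_hgt_linked = hgt_sum["linked_to_metazoan"]["count"]
        summary.n_hgt_clan = hgt_sum["clan_support"]["count"]
        summary.n_hgt_monophyly = hgt_sum["monophyly_support"]["count"]
        artifacts["hgt"] = {"summary": hgt_sum, "dropped_scaffolds": dropped,
                            "evidence": evidence}
        if inputs.get("pairs"):
            groups = _copy_groups_from_pairs(inputs["pairs"])
            cands = [gid for gid, ev in evidence.items() if ev.is_candidate]
            artifacts["hgt"]["copy_classes"] = hgtmod.copy_class_counts(cands, groups)

    # ----------------------------------------------- synteny (+ diverge)
    blocks = []
    if "synteny" in stages:
        orders = col.gene_orders(genes)
        raw = pd.read_csv(inputs["pairs"], sep="\t", header=None,
                          names=["a", "b", "sim"])
        pairs = col.build_pairs(raw.itertuples(index=False), orders)
        blocks = col.chain_blocks(pairs, orders, min_genes=params["min_genes"],
                                  max_gaps=params["max_gaps"])
        cds = {g.gene_id: g.cds_seq for g in genes if g.cds_seq}
        pair_divs = {}
        for b in blocks:
            for p in b.pairs:
                key = frozenset((p.gene_a, p.gene_b))
                if key in pair_divs or p.gene_a not in cds or p.gene_b not in cds:
                    continue
                aln = align_cds_pair(cds[p.gene_a], cds[p.gene_b])
                pair_divs[key] = div.ka_ks(aln, p.gene_a, p.gene_b)
        for b in blocks:
            div.block_mean_divergence(b, pair_divs)
        col.partition_blocks(blocks, ks_threshold=params["ks_threshold"])
        hom = [b for b in blocks if b.category == "homolog"]
        ohn = [b for b in blocks if b.category == "ohnolog"]
        summary.n_homolog_blocks = len(hom)
        summary.n_ohnolog_blocks = len(ohn)
        fracs = col.genes_in_blocks(blocks, total)
        summary.frac_genes_homolog_blocks = fracs.get("homolog", {}).get("pct", 0.0)
        summary.frac_genes_ohnolog_blocks = fracs.get("ohnolog", {}).get("pct", 0.0)
        n_bp, per_scaffold, frac_bp = col.count_breakpoints(hom)
        summary.n_breakpoints = n_bp
        summary.frac_breakpoints = frac_bp
        arrangements = col.classify_same_scaffold_blocks(hom)
        summary.n_tandem = sum(1 for v in arrangements.values() if v == "tandem")
        summary.n_palindrome = sum(1 for v in arrangements.values() if v == "palindrome")
        hom_ks = [b.mean_KS for b in hom if b.mean_KS is not None]
        ohn_ks = [b.mean_KS for b in ohn if b.mean_KS is not None]
        summary.mean_ks_homolog = sum(hom_ks) / len(hom_ks) if hom_ks else None
        summary.mean_ks_ohnolog = sum(ohn_ks) / len(ohn_ks) if ohn_ks else None
        artifacts["synteny"] = {
            "blocks": blocks, "breakpoints_per_scaffold": per_scaffold,
            "arrangements": arrangements, "genes_in_blocks": fracs,
            "block_sizes": col.block_size_summary(blocks),
            "pair_divergences": pair_divs,
        }

    if "diverge" in stages:
        self_hits = read_hits_table(inputs["self_hits"])
        divs, median, mode, n_omitted = div.top_nonself_identity(self_hits)
        summary.median_tophit_divergence_pct = median
        artifacts["diverge"] = {"median": median, "mode": mode,
                                "n_omitted": n_omitted, "n_genes_scored": len(divs)}

    # ---------------------------------------------------------- collapse
    if "collapse" in stages:
        records, n_skipped = read_vcf(inputs["vcf"])
        profile = read_depth_profile(inputs["depth"])
        centers = [(lo + hi) / 2 for lo, hi in zip(profile.bin_edges, profile.bin_edges[1:])]
        tot_sites = sum(profile.counts)
        mean_cov = sum(c * n for c, n in zip(centers, profile.counts)) / tot_sites
        kept = div.filter_snps(records, min_mq=params["min_mq"],
                               min_qual=params["min_qual"], mean_cov=mean_cov,
                               depth_frac=params["depth_frac"])
        from cyvcf2 import VCF
        contigs = set(VCF(inputs["vcf"]).seqnames)
        cds_span = sum(len(g.cds_seq) for g in genes
                       if g.scaffold_id in contigs and g.cds_seq)
        if cds_span > 0:
            summary.snp_divergence_pct = div.snp_divergence(len(kept), cds_span)
        spectrum = div.fold_maf(kept)
        summary.maf_mode = spectrum.mode_bin if kept else None
        collapse_diag = None
        try:
            collapse_diag = div.coverage_collapse_profile(
                profile, [r.depth for r in kept])
        except ValidationError:
            pass
        artifacts["collapse"] = {
            "n_records": len(records), "n_skipped": n_skipped,
            "n_filtered": len(kept), "cds_span": cds_span,
            "mean_cov": mean_cov, "maf": spectrum, "diagnostics": collapse_diag,
        }

    if outdir:
        _write_outputs(summary, artifacts, outdir)
    return summary, artifacts


def _copy_groups_from_pairs(path: str) -> list[list[str]]:
    """Connected components of the homolog-pair graph (union-find)."""
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    df = pd.read_csv(path, sep="\t", header=None, names=["a", "b", "sim"])
    for a, b in zip(df["a"], df["b"]):
        ra, rb = find(str(a)), find(str(b))
        if ra != rb:
            parent[ra] = rb
    groups: dict[str, list[str]] = {}
    for x in list(parent):
        groups.setdefault(find(x), []).append(x)
    return [sorted(v) for v in groups.values()]


def _write_outputs(summary: SpeciesSummary, artifacts: dict, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    doc = asdict(summary)
    with open(os.path.join(outdir, "summary.json"), "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True, default=str)
    hgt_art = artifacts.get("hgt")
    if hgt_art:
        rows = []
        for gid, ev in hgt_art["evidence"].items():
            rows.append({
                "gene_id": gid, "B_IN": ev.B_IN, "B_OUT": ev.B_OUT, "h_U": ev.h_U,
                "chs_class": ev.chs_class, "CHS": round(ev.CHS, 4),
                "is_candidate": ev.is_candidate,
                "on_hgt_heavy_scaffold": ev.on_hgt_heavy_scaffold,
                "linked_to_metazoan": ev.linked_to_metazoan,
                "n_introns": ev.n_introns,
                "clan": ev.tree.clan_nonmetazoan if ev.tree else None,
                "monophyly": ev.tree.monophyly_nonmetazoan if ev.tree else None,
            })
        pd.DataFrame(rows).to_csv(os.path.join(outdir, "hgt_evidence.tsv"),
                                  sep="\t", index=False)
        with open(os.path.join(outdir, "hgt_dropped_scaffolds.txt"), "w") as fh:
            fh.write("\n".join(hgt_art["dropped_scaffolds"]) + "\n")
    syn = artifacts.get("synteny")
    if syn:
        rows = []
        for b in syn["blocks"]:
            rows.append({
                "block_id": b.block_id, "scaffold_a": b.scaffold_a,
                "scaffold_b": b.scaffold_b, "n_pairs": b.n_pairs,
                "orientation": b.orientation, "CI": round(b.CI, 4),
                "mean_KS": b.mean_KS, "mean_KA": b.mean_KA,
                "category": b.category,
            })
        pd.DataFrame(rows).to_csv(os.path.join(outdir, "blocks.tsv"),
                                  sep="\t", index=False)


def compare_species(summaries: list[SpeciesSummary]) -> pd.DataFrame:
    """Aligned cross-species table, one row per species, in the given order."""
    if not summaries:
        raise ValidationError("need at least one summary")
    return pd.DataFrame([asdict(s) for s in summaries])


def run_from_yaml(path: str, outdir: Optional[str] = None) -> tuple[SpeciesSummary, dict]:
    config = load_config(path)
    return run_pipeline(config, outdir=outdir)
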