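"""Readers and writers for the standard formats every stage touches.

GFF3 goes through :mod:`gffutils`, VCF through :mod:`cyvcf2`, trees through
:mod:`dendropy` and FASTA through Biopython; everything is normalised into
the dataclasses of :mod:`tetracomp.models` with 1-based inclusive
coordinates.
"""
from __future__ import annotations

import logging
import os
import tempfile
from typing import Iterable, Optional

import dendropy
import gffutils
import pandas as pd
from Bio import SeqIO

from .models import (
    DepthProfile,
    GeneModel,
    HomologyHit,
    ParseError,
    ValidationError,
    VariantRecord,
)

log = logging.getLogger(__name__)

HITS_COLUMNS = [
    "query", "subject", "pct_identity", "aln_length", "mismatches",
    "gapopens", "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


# ---------------------------------------------------------------------------
# GFF3

def read_gff3(path: str) -> list[GeneModel]:
    """Parse a GFF3 file into one :class:`GeneModel` per gene.

    Genes are linked to exons through ID/Parent either via mRNA children or
    directly (both BRAKER- and MAKER-style dialects are accepted). Genes
    with no exon features get a single exon spanning the gene.
    """
    with open(path) as fh:
        if not any(line.strip() and not line.startswith("#") for line in fh):
            return []
    try:
        db = gffutils.create_db(
            path, dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="create_unique", sort_attribute_values=True,
        )
    except Exception as exc:  # gffutils raises assorted exceptions
        raise ParseError(f"{path}: not parseable as GFF3 ({exc})") from exc

    genes: list[GeneModel] = []
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        exons = []
        for ex in db.children(g, featuretype="exon", order_by="start"):
            exons.append((ex.start, ex.end))
        if not exons:
            for cds in db.children(g, featuretype="CDS", order_by="start"):
                exons.append((cds.start, cds.end))
        if not exons:
            exons = [(g.start, g.end)]
        for s, e in exons:
            if s < g.start or e > g.end:
                raise ValidationError(
                    f"{g.id}: exon {s}-{e} outside gene span {g.start}-{g.end}"
                )
        genes.append(
            GeneModel(
                gene_id=g.id,
                scaffold_id=g.seqid,
                start=g.start,
                end=g.end,
                strand=g.strand if g.strand in "+-" else "+",
                exons=sorted(set(exons)),
            )
        )
    return genes


def write_gff3(genes: Iterable[GeneModel], path: str, scaffold_lengths: Optional[dict] = None) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if scaffold_lengths:
            for sc, ln in scaffold_lengths.items():
                fh.write(f"##sequence-region {sc} 1 {ln}\n")
        for g in genes:
            fh.write(
                f"{g.scaffold_id}\ttetracomp\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            mrna = f"{g.gene_id}.t1"
            fh.write(
                f"{g.scaffold_id}\ttetracomp\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={mrna};Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.scaffold_id}\ttetracomp\texon\t{s}\t{e}\t.\t{g.strand}\t.\tID={mrna}.exon{i};Parent={mrna}\n"
                )
                fh.write(
                    f"{g.scaffold_id}\ttetracomp\tCDS\t{s}\t{e}\t.\t{g.strand}\t0\tID={mrna}.cds{i};Parent={mrna}\n"
                )


def attach_sequences(genes: list[GeneModel], cds_fasta: Optional[str] = None,
                     protein_fasta: Optional[str] = None) -> list[GeneModel]:
    """Populate cds_seq / protein_seq from FASTA files keyed by gene id."""
    if cds_fasta:
        cds = {r.id: str(r.seq).upper() for r in SeqIO.parse(cds_fasta, "fasta")}
        for g in genes:
            g.cds_seq = cds.get(g.gene_id, g.cds_seq)
    if protein_fasta:
        prot = {r.id: str(r.seq).upper() for r in SeqIO.parse(protein_fasta, "fasta")}
        for g in genes:
            g.protein_seq = prot.get(g.gene_id, g.protein_seq)
    return genes


# ---------------------------------------------------------------------------
# Homology hit tables (outfmt-6 style, 12 or 13 columns)

def read_class_map(path: str) -> dict[str, str]:
    """Two-column TSV mapping subject id (or taxon id) -> ingroup/outgroup."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{i}: expected 2 columns, got {len(parts)}")
            if parts[1] not in ("ingroup", "outgroup"):
                raise ValidationError(f"{path}:{i}: class must be ingroup/outgroup")
            out[parts[0]] = parts[1]
    return out


def read_hits_table(path: str, class_map: Optional[dict[str, str]] = None) -> list[HomologyHit]:
    """Parse a 12/13-column tabular homology-search result.

    The optional 13th column is a taxon id; ``class_map`` is consulted first
    by subject id, then by taxon id, defaulting to ``unknown``.
    """
    class_map = class_map or {}
    hits: list[HomologyHit] = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (12, 13):
                raise ParseError(f"{path}:{i}: expected 12 or 13 columns, got {len(parts)}")
            try:
                q, s = parts[0], parts[1]
                pct = float(parts[2])
                alen = int(parts[3])
                ev = float(parts[10])
                bits = float(parts[11])
            except ValueError as exc:
                raise ParseError(f"{path}:{i}: {exc}") from exc
            if bits < 0:
                raise ValidationError(f"{path}:{i}: negative bitscore")
            taxid = parts[12] if len(parts) == 13 else None
            if s == q:
                cls = "self"
            else:
                cls = class_map.get(s) or (class_map.get(taxid) if taxid else None) or "unknown"
            hits.append(HomologyHit(q, s, pct, alen, ev, bits, taxon_class=cls))
    return hits


def write_hits_table(hits: Iterable[HomologyHit], path: str) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query_id, h.subject_id, f"{h.pct_identity:.2f}",
                        str(h.aln_length), "0", "0", "1", str(h.aln_length),
                        "1", str(h.aln_length), f"{h.evalue:.3g}", f"{h.bitscore:.1f}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Trees

def read_newick(path: str) -> dendropy.Tree:
    """Read a single newick tree; duplicate leaf labels are rejected."""
    try:
        tree = dendropy.Tree.get(path=path, schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:
        if "Duplicate taxon labels" in str(exc):
            raise ValidationError(f"{path}: duplicate leaf labels") from exc
        raise ParseError(f"{path}: not parseable as newick ({exc})") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon]
    if len(labels) != len(set(labels)):
        raise ValidationError(f"{path}: duplicate leaf labels")
    return tree


def read_newick_string(newick: str) -> dendropy.Tree:
    with tempfile.NamedTemporaryFile("w", suffix=".nwk", delete=False) as fh:
        fh.write(newick)
        tmp = fh.name
    try:
        return read_newick(tmp)
    finally:
        os.unlink(tmp)


# ---------------------------------------------------------------------------
# VCF

def read_vcf(path: str) -> tuple[list[VariantRecord], int]:
    """Read biallelic SNPs from a VCF 4.x file.

    Returns (records, n_skipped); rows that are not biallelic SNPs are
    skipped and counted. Allele depths come from the AD FORMAT field of the
    first sample; mapping quality from the MQ INFO field.
    """
    from cyvcf2 import VCF

    records: list[VariantRecord] = []
    skipped = 0
    vcf = VCF(path)
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            skipped += 1
            continue
        ad = v.format("AD")
        if ad is None:
            raise ValidationError(f"{v.CHROM}:{v.POS}: missing AD (allele depth) field")
        depth_ref, depth_alt = int(ad[0][0]), int(ad[0][1])
        mq = v.INFO.get("MQ")
        if mq is None:
            raise ValidationError(f"{v.CHROM}:{v.POS}: missing MQ INFO field")
        records.append(
            VariantRecord(
                scaffold_id=v.CHROM, pos=v.POS, ref_allele=v.REF,
                alt_allele=v.ALT[0], mapq=float(mq),
                qual=float(v.QUAL if v.QUAL is not None else 0.0),
                depth_ref=depth_ref, depth_alt=depth_alt,
            )
        )
    if skipped:
        log.info("read_vcf(%s): skipped %d non-biallelic-SNP rows", path, skipped)
    return records, skipped


def write_vcf(records: Iterable[VariantRecord], path: str,
              contigs: Optional[dict[str, int]] = None) -> None:
    """Emit a minimal single-sample VCF 4.2 with AD depths and MQ INFO."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=tetracomp\n")
        if contigs:
            for name, ln in contigs.items():
                fh.write(f"##contig=<ID={name},length={ln}>\n")
        fh.write('##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample\n")
        for r in records:
            fh.write(
                f"{r.scaffold_id}\t{r.pos}\t.\t{r.ref_allele}\t{r.alt_allele}\t"
                f"{r.qual:.1f}\t.\tMQ={r.mapq:.1f}\tGT:AD\t0/1:{r.depth_ref},{r.depth_alt}\n"
            )


# ---------------------------------------------------------------------------
# Depth profiles / misc TSV

def read_depth_profile(path: str) -> DepthProfile:
    """TSV with columns bin_lo, bin_hi, count (contiguous increasing bins)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["lo", "hi", "count"])
    if df.empty:
        raise ValidationError(f"{path}: empty depth profile")
    edges = list(df["lo"]) + [df["hi"].iloc[-1]]
    return DepthProfile(bin_edges=[float(e) for e in edges],
                        counts=[int(c) for c in df["count"]])


def write_depth_profile(profile: DepthProfile, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("#bin_lo\tbin_hi\tcount\n")
        for lo, hi, c in zip(profile.bin_edges, profile.bin_edges[1:], profile.counts):
            fh.write(f"{lo:g}\t{hi:g}\t{c}\n")


def write_fasta(seqs: dict[str, str], path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
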