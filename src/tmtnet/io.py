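"""Interchange formats: FASTA, GFF3 gene models, tabular TSVs, manifests.

All external coordinates are 1-based inclusive (GFF3 convention); internal
representation is 0-based half-open, converted at the I/O boundary.  All
tabular outputs are TSV with a header line.
"""

from __future__ import annotations

import json
import logging
import platform
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("tmtnet")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Junction-evidence TSV columns (1-based inclusive exonic coordinates).
JUNCTION_EVIDENCE_COLUMNS = [
    "chrom", "strand", "left_end", "right_start",
    "read_id", "left_overlap_nt", "right_overlap_nt",
]


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """A single-transcript gene model with an annotated CDS.

    ``exons`` and ``cds`` are 0-based half-open intervals in ascending
    genomic order; transcript order is reversed for minus-strand genes.
    ``cds_phase`` is the GFF3 phase of the transcript-first CDS segment.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]
    cds_phase: int = 0

    def transcript_order(self, intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
        return intervals if self.strand == "+" else list(reversed(intervals))

    def cds_sequence(self, chrom_seq: str) -> str:
        """Spliced CDS in transcript orientation, phase applied."""
        parts = [chrom_seq[a:b] for a, b in self.cds]
        spliced = "".join(parts)
        if self.strand == "-":
            spliced = revcomp(spliced)
        return spliced[self.cds_phase:]

    def protein(self, chrom_seq: str) -> str:
        """Translation of the annotated CDS, truncated at the first stop."""
        cds = self.cds_sequence(chrom_seq)
        cds = cds[: len(cds) - len(cds) % 3]
        aa = str(Seq(cds).translate())
        stop = aa.find("*")
        return aa if stop < 0 else aa[:stop]


@dataclass
class GenomeBundle:
    """Chromosome sequences plus gene models and canonical proteins."""

    sequences: dict[str, str]
    genes: list[GeneModel]
    proteins: dict[str, str] = field(default_factory=dict)

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read FASTA records; sequences normalized to uppercase.

    Raises on duplicate ids or empty sequences; lowercase input is
    accepted with a warning.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id: {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"empty sequence for FASTA id {rec.id!r}")
        if not seq.isupper():
            logger.warning("FASTA %s: lowercase sequence normalized to uppercase", rec.id)
            rec.seq = Seq(seq.upper())
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, wrap: int = 60) -> None:
    records = list(records)
    ids = [r.id for r in records]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate ids in FASTA output")
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap or None)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------

def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as a gene/mRNA/exon/CDS hierarchy (1-based inclusive)."""
    lines = ["##gff-version 3"]
    for g in genes:
        start = min(a for a, _ in g.exons) + 1
        end = max(b for _, b in g.exons)
        lines.append("\t".join([
            g.chrom, "tmtnet", "gene", str(start), str(end), ".", g.strand,
            ".", f"ID={g.gene_id}"]))
        mrna = f"{g.gene_id}.t1"
        lines.append("\t".join([
            g.chrom, "tmtnet", "mRNA", str(start), str(end), ".", g.strand,
            ".", f"ID={mrna};Parent={g.gene_id}"]))
        for a, b in g.exons:
            lines.append("\t".join([
                g.chrom, "tmtnet", "exon", str(a + 1), str(b), ".", g.strand,
                ".", f"Parent={mrna}"]))
        # phase per GFF3: nt to skip before the first complete codon
        phase = g.cds_phase
        for a, b in g.transcript_order(g.cds):
            lines.append("\t".join([
                g.chrom, "tmtnet", "CDS", str(a + 1), str(b), ".", g.strand,
                str(phase), f"Parent={mrna}"]))
            seg_len = b - a - phase
            phase = (3 - (seg_len % 3)) % 3 if seg_len % 3 else 0
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3_gene_models(path: str | Path,
                          sequences: dict[str, str] | None = None) -> list[GeneModel]:
    """Parse gene models from GFF3, resolving the Parent hierarchy.

    Exon chains are stored in ascending genomic order; minus-strand
    transcript order is obtained via :meth:`GeneModel.transcript_order`.
    Coordinates are validated against ``sequences`` when provided.
    """
    db = gffutils.create_db(str(path), dbfn=":memory:", keep_order=True,
                            merge_strategy="create_unique", force=True)
    known_parents = {f.id for f in db.all_features() if f.featuretype in ("gene", "mRNA")}
    for feat in db.all_features():
        if feat.featuretype in ("exon", "CDS"):
            parents = feat.attributes.get("Parent", [])
            if not parents or any(p not in known_parents for p in parents):
                raise ValueError(
                    f"orphan {feat.featuretype} at {feat.seqid}:{feat.start}-{feat.end}")
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        for mrna in db.children(gene, featuretype="mRNA"):
            exons = sorted((f.start - 1, f.end) for f in db.children(mrna, featuretype="exon"))
            cds_feats = sorted(db.children(mrna, featuretype="CDS"), key=lambda f: f.start)
            cds = [(f.start - 1, f.end) for f in cds_feats]
            if cds_feats:
                first = cds_feats[0] if gene.strand == "+" else cds_feats[-1]
                phase = int(first.frame) if first.frame not in (None, ".") else 0
            else:
                phase = 0
            if sequences is not None:
                clen = len(sequences.get(gene.seqid, ""))
                for a, b in exons + cds:
                    if a < 0 or b > clen:
                        raise ValueError(
                            f"{gene.id}: interval {a + 1}-{b} outside {gene.seqid} "
                            f"(length {clen})")
            genes.append(GeneModel(gene_id=gene.id, chrom=gene.seqid,
                                   strand=gene.strand, exons=exons, cds=cds,
                                   cds_phase=phase))
    return genes


def read_genome(fasta_path: str | Path, gff3_path: str | Path) -> GenomeBundle:
    records = read_fasta(fasta_path)
    sequences = {r.id: str(r.seq) for r in records}
    genes = read_gff3_gene_models(gff3_path, sequences=sequences)
    proteins = {g.gene_id: g.protein(sequences[g.chrom]) for g in genes}
    return GenomeBundle(sequences=sequences, genes=genes, proteins=proteins)


# ---------------------------------------------------------------------------
# Junction evidence TSV
# ---------------------------------------------------------------------------

def write_junction_evidence(records: pd.DataFrame, path: str | Path) -> None:
    """Write per-read junction evidence; internal 0-based -> 1-based on disk."""
    out = records.copy()
    out["left_end"] = out["left_end"] + 1
    out["right_start"] = out["right_start"] + 1
    out[JUNCTION_EVIDENCE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_junction_evidence(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str})
    missing = set(JUNCTION_EVIDENCE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"junction evidence missing columns: {sorted(missing)}")
    df["left_end"] = df["left_end"] - 1
    df["right_start"] = df["right_start"] - 1
    return df


# ---------------------------------------------------------------------------
# Tables and manifests
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_table(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_manifest(path: str | Path, stage: str, seed: int | None,
                   params: dict, counts: dict | None = None) -> None:
    """Record parameters, seed, versions, and per-filter counts for a run."""
    import tmtnet
    manifest = {
        "stage": stage,
        "seed": seed,
        "params": params,
        "counts": counts or {},
        "versions": {"tmtnet": tmtnet.__version__, "python": platform.python_version()},
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
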