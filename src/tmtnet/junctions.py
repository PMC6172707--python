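"""Alternative exon-exon junction (alt-EEjxn) peptide database construction.

From gapped-read junction evidence and a genome, this module
(1) summarizes junctions supported by >= 2 reads with >= 4 nt exonic
overlap on each side, (2) keeps only *alternative* junctions — those
sharing a donor (5') or acceptor (3') end with another junction —
(3) translates the junction-flanking exonic sequence (annotated CDS frame
where available, otherwise all three frames with stop-codon truncation),
(4) digests in silico with LysC [K|P] (cleavage C-terminal to lysine,
including Lys-Pro bonds, with and without miscleavage at proline), and
(5) keeps peptides that genuinely span the junction with at least one
residue fully encoded on each side, deduplicated against other genomic
loci and the canonical proteome, for appending to a FASTA search database.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .config import JunctionParams
from .io import GeneModel, GenomeBundle, revcomp, write_fasta

logger = logging.getLogger("tmtnet")

_AA20 = set("ACDEFGHIKLMNPQRSTVWY")
_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class Junction:
    """An exon-exon junction on the + reference axis (0-based positions).

    ``left_end`` is the last exonic base of the genomic-left exon and
    ``right_start`` the first exonic base of the genomic-right exon; for a
    minus-strand junction the transcript 5' side is the right one.
    """

    chrom: str
    strand: str
    left_end: int
    right_start: int
    support: int = 0
    max_min_overlap: int = 0
    is_alternative: bool = False

    def key(self) -> tuple:
        return (self.chrom, self.strand, self.left_end, self.right_start)


@dataclass
class JunctionPeptide:
    """A junction-spanning digestion product with provenance."""

    sequence: str
    junction: Junction
    frame: int | str  # 0/1/2 or "annotated"
    miscleaved: bool
    genomic_span: tuple[int, int]  # 0-based half-open on the + axis
    status: str = "candidate"  # novel | canonical-duplicate | multi-locus-duplicate

    def locus(self) -> tuple:
        return (self.junction.chrom, self.junction.strand, *self.genomic_span)


@dataclass
class DigestPeptide:
    sequence: str
    start: int  # residue index in the parent sequence
    n_retained: int = 0

    @property
    def miscleaved(self) -> bool:
        return self.n_retained > 0


# ---------------------------------------------------------------------------
# Junction summarization and classification
# ---------------------------------------------------------------------------

def summarize_junctions(evidence: pd.DataFrame,
                        params: JunctionParams | None = None) -> list[Junction]:
    """Collapse per-read evidence into supported junctions.

    A read contributes support only if both of its exonic overlaps are at
    least ``min_overlap_nt``; junctions with fewer than ``min_reads``
    qualifying reads are dropped.  Identical coordinate records merge.
    Malformed records are skipped with a logged warning.
    """
    params = params or JunctionParams()
    n_skipped = 0
    rows = []
    for rec in evidence.itertuples(index=False):
        try:
            chrom, strand = str(rec.chrom), str(rec.strand)
            left_end, right_start = int(rec.left_end), int(rec.right_start)
            lo, ro = int(rec.left_overlap_nt), int(rec.right_overlap_nt)
            if strand not in "+-" or left_end >= right_start or lo < 0 or ro < 0:
                raise ValueError
        except (ValueError, TypeError):
            n_skipped += 1
            logger.warning("malformed junction evidence record skipped: %r", rec)
            continue
        rows.append((chrom, strand, left_end, right_start, min(lo, ro)))
    if n_skipped:
        logger.warning("summarize_junctions: %d malformed records skipped", n_skipped)

    grouped: dict[tuple, list[int]] = {}
    for chrom, strand, le, rs, mo in rows:
        grouped.setdefault((chrom, strand, le, rs), []).append(mo)
    junctions = []
    for (chrom, strand, le, rs), overlaps in sorted(grouped.items()):
        qualifying = [o for o in overlaps if o >= params.min_overlap_nt]
        if len(qualifying) < params.min_reads:
            continue
        junctions.append(Junction(chrom, strand, le, rs,
                                  support=len(qualifying),
                                  max_min_overlap=max(qualifying)))
    return junctions


def classify_alternative(junctions: list[Junction]) -> list[Junction]:
    """Flag junctions sharing a left end or right start with another junction.

    Junctions that share neither end are singletons/constitutive and are
    excluded from peptide extraction downstream.
    """
    left_counts: dict[tuple, int] = {}
    right_counts: dict[tuple, int] = {}
    for j in junctions:
        lk = (j.chrom, j.strand, j.left_end)
        rk = (j.chrom, j.strand, j.right_start)
        left_counts[lk] = left_counts.get(lk, 0) + 1
        right_counts[rk] = right_counts.get(rk, 0) + 1
    out = []
    for j in junctions:
        alt = (left_counts[(j.chrom, j.strand, j.left_end)] > 1
               or right_counts[(j.chrom, j.strand, j.right_start)] > 1)
        out.append(Junction(j.chrom, j.strand, j.left_end, j.right_start,
                            j.support, j.max_min_overlap, is_alternative=alt))
    return out


# ---------------------------------------------------------------------------
# In-silico digestion
# ---------------------------------------------------------------------------

def digest(sequence: str, enzyme: str = "LysC",
           max_kp_miscleavage: int = 0) -> list[DigestPeptide]:
    """Cleave a protein sequence in silico.

    LysC cleaves C-terminal to every lysine, including Lys|Pro bonds; the
    output contains the fully cleaved products plus, for runs of adjacent
    fragments joined only by K|P bonds, merged forms retaining up to
    ``max_kp_miscleavage`` of those bonds.  Trypsin cleaves after K and R
    but not before P (the standard rule); in trypsin mode the miscleavage
    budget applies to any cleavage site.
    """
    for i, ch in enumerate(sequence):
        if ch not in _AA20 and ch != "X":
            raise ValueError(f"illegal residue {ch!r} at position {i}")
    if enzyme not in ("LysC", "trypsin"):
        raise ValueError(f"unknown enzyme: {enzyme!r}")

    # cleavage points: index i means a cut between residue i-1 and i
    cuts = []
    for i in range(len(sequence) - 1):
        if enzyme == "LysC":
            if sequence[i] == "K":
                cuts.append(i + 1)
        else:
            if sequence[i] in "KR" and sequence[i + 1] != "P":
                cuts.append(i + 1)
    bounds = [0] + cuts + [len(sequence)]
    frags = [(bounds[k], bounds[k + 1]) for k in range(len(bounds) - 1)]

    def retainable(cut_index: int) -> bool:
        if enzyme == "trypsin":
            return True
        return sequence[cut_index] == "P"  # a K|P bond

    out = [DigestPeptide(sequence[a:b], a, 0) for a, b in frags]
    # merged forms: windows of consecutive fragments whose internal bonds
    # are all retainable, retaining at most max_kp_miscleavage bonds
    for i in range(len(frags)):
        for j in range(i + 1, len(frags)):
            n_bonds = j - i
            if n_bonds > max_kp_miscleavage:
                break
            if not retainable(frags[j][0]):
                break
            a, b = frags[i][0], frags[j][1]
            out.append(DigestPeptide(sequence[a:b], a, n_bonds))
    return out


# ---------------------------------------------------------------------------
# Junction-spanning peptide extraction
# ---------------------------------------------------------------------------

def _exon_bound(gene_models: list[GeneModel], chrom: str, strand: str,
                pos: int) -> tuple[int, int] | None:
    """The annotated exon interval containing ``pos``, if any."""
    for g in gene_models:
        if g.chrom != chrom or g.strand != strand:
            continue
        for a, b in g.exons:
            if a <= pos < b:
                return (a, b)
    return None


def _cds_offset(gene_models: list[GeneModel], chrom: str, strand: str,
                pos: int) -> int | None:
    """0-based transcript CDS coordinate of genomic base ``pos``, or None."""
    for g in gene_models:
        if g.chrom != chrom or g.strand != strand:
            continue
        offset = 0
        for a, b in g.transcript_order(g.cds):
            if a <= pos < b:
                within = (pos - a) if strand == "+" else (b - 1 - pos)
                total = offset + within - g.cds_phase
                return total if total >= 0 else None
            offset += b - a
    return None


def junction_window(genome: GenomeBundle, jxn: Junction,
                    params: JunctionParams) -> tuple[str, int, list[int]]:
    """Exonic sequence window around a junction, transcript-oriented.

    Returns ``(window, junction_offset, genomic_positions)`` where
    ``window[:junction_offset]`` is the transcript 5' flank.  Flanks extend
    up to ``flank_nt`` but stop at annotated exon boundaries or chromosome
    ends (with a warning when truncated).
    """
    chrom_seq = genome.sequences.get(jxn.chrom)
    if chrom_seq is None:
        raise ValueError(f"junction on unknown chromosome {jxn.chrom!r}")
    if jxn.left_end < 0 or jxn.right_start >= len(chrom_seq):
        raise ValueError(f"junction {jxn.key()} outside genome bounds")

    fl = params.flank_nt
    lb = _exon_bound(genome.genes, jxn.chrom, jxn.strand, jxn.left_end)
    rb = _exon_bound(genome.genes, jxn.chrom, jxn.strand, jxn.right_start)
    left_lo = max(jxn.left_end + 1 - fl, 0 if lb is None else lb[0], 0)
    right_hi = min(jxn.right_start + fl,
                   len(chrom_seq) if rb is None else rb[1], len(chrom_seq))
    if jxn.left_end + 1 - left_lo < fl and lb is None and jxn.left_end + 1 < fl:
        logger.warning("junction %s: 5' flank truncated at chromosome edge", jxn.key())
    left_seq = chrom_seq[left_lo:jxn.left_end + 1]
    right_seq = chrom_seq[jxn.right_start:right_hi]
    left_pos = list(range(left_lo, jxn.left_end + 1))
    right_pos = list(range(jxn.right_start, right_hi))
    if jxn.strand == "+":
        window = left_seq + right_seq
        positions = left_pos + right_pos
        offset = len(left_seq)
    else:
        window = revcomp(right_seq) + revcomp(left_seq)
        positions = right_pos[::-1] + left_pos[::-1]
        offset = len(right_seq)
    return window, offset, positions


def _annotated_frame(genome: GenomeBundle, jxn: Junction,
                     flank5_len: int) -> int | None:
    """Translation start offset into the window for an annotated junction."""
    anchor = jxn.left_end if jxn.strand == "+" else jxn.right_start
    o = _cds_offset(genome.genes, jxn.chrom, jxn.strand, anchor)
    if o is None:
        return None
    return (-(o - flank5_len + 1)) % 3


def translate_segments(window: str, start: int) -> list[tuple[int, str]]:
    """Translate from ``start``; split at stops.

    Returns ``(first_residue_index, aa_string)`` per stop-free segment,
    residue indices counted in the frame's codon grid.
    """
    n_codons = (len(window) - start) // 3
    aa = str(Seq(window[start:start + 3 * n_codons]).translate())
    segments = []
    pos = 0
    for part in aa.split("*"):
        if part:
            segments.append((pos, part))
        pos += len(part) + 1
    return segments


def extract_junction_peptides(genome: GenomeBundle, junctions: list[Junction],
                              params: JunctionParams | None = None) -> list[JunctionPeptide]:
    """Enumerate LysC [K|P] peptides spanning alternative junctions.

    Translation uses the annotated CDS frame when the junction's transcript
    5' base lies in an annotated CDS (and ``params.frames`` permits),
    otherwise all three frames; open reading is truncated at stop codons.
    A peptide qualifies only if at least one residue is fully encoded on
    each side of the junction and its length lies within bounds.
    """
    params = params or JunctionParams()
    out: list[JunctionPeptide] = []
    seen: set[tuple] = set()
    for jxn in junctions:
        if not jxn.is_alternative:
            continue
        window, joff, positions = junction_window(genome, jxn, params)
        frame_offsets: list[tuple[int | str, int]] = []
        if params.frames == "annotated":
            t = _annotated_frame(genome, jxn, joff)
            if t is not None:
                frame_offsets = [("annotated", t)]
        if not frame_offsets:
            frame_offsets = [(f, f) for f in range(3)]
        for frame_label, t in frame_offsets:
            for seg_start, seg_aa in translate_segments(window, t):
                for pep in digest(seg_aa, "LysC", params.max_kp_miscleavage):
                    if not params.min_pep_len <= len(pep.sequence) <= params.max_pep_len:
                        continue
                    r0 = seg_start + pep.start
                    n_left = n_right = 0
                    for r in range(r0, r0 + len(pep.sequence)):
                        nt_a, nt_b = t + 3 * r, t + 3 * r + 3
                        if nt_b <= joff:
                            n_left += 1
                        elif nt_a >= joff:
                            n_right += 1
                    if n_left < 1 or n_right < 1:
                        continue
                    nt_lo = t + 3 * r0
                    nt_hi = t + 3 * (r0 + len(pep.sequence))
                    gpos = positions[nt_lo:nt_hi]
                    span = (min(gpos), max(gpos) + 1)
                    key = (pep.sequence, jxn.key(), span, frame_label)
                    if key in seen:
                        continue
                    seen.add(key)
                    out.append(JunctionPeptide(
                        sequence=pep.sequence, junction=jxn, frame=frame_label,
                        miscleaved=pep.miscleaved, genomic_span=span))
    return out


# ---------------------------------------------------------------------------
# Deduplication against other loci and the canonical proteome
# ---------------------------------------------------------------------------

def dedupe_and_annotate(peptides: list[JunctionPeptide],
                        canonical_proteins: dict[str, str],
                        max_kp_miscleavage: int = 1) -> list[JunctionPeptide]:
    """Assign status and drop non-novel peptides.

    A sequence arising from two or more distinct genomic loci is removed
    entirely (a shared sequence cannot be attributed to one locus in
    quantification); a sequence present in the LysC digest of the canonical
    proteome is flagged ``canonical-duplicate`` and removed from the novel
    set; survivors are ``novel``.
    """
    canonical_products: set[str] = set()
    for prot in canonical_proteins.values():
        for pep in digest(prot, "LysC", max_kp_miscleavage):
            canonical_products.add(pep.sequence)

    loci_by_seq: dict[str, set[tuple]] = {}
    for p in peptides:
        loci_by_seq.setdefault(p.sequence, set()).add(p.locus())

    novel = []
    for p in peptides:
        if len(loci_by_seq[p.sequence]) > 1:
            p.status = "multi-locus-duplicate"
        elif p.sequence in canonical_products:
            p.status = "canonical-duplicate"
        else:
            p.status = "novel"
            novel.append(p)
    return novel


# ---------------------------------------------------------------------------
# Search-database FASTA
# ---------------------------------------------------------------------------

def peptide_header(p: JunctionPeptide, index: int) -> str:
    """Header grammar: altEEjxn|<n>|<chrom>:<left>-<right>|<strand>|frame=<f>|mc=<0/1>
    with 1-based inclusive junction coordinates."""
    j = p.junction
    return (f"altEEjxn|{index}|{j.chrom}:{j.left_end + 1}-{j.right_start + 1}|"
            f"{j.strand}|frame={p.frame}|mc={int(p.miscleaved)}")


def write_search_db(canonical: list[SeqRecord], novel: list[JunctionPeptide],
                    path: str | Path) -> int:
    """Append novel junction peptides to the canonical FASTA; returns entry count."""
    if not canonical:
        raise ValueError("canonical protein set is empty")
    records = list(canonical)
    for i, p in enumerate(novel, start=1):
        records.append(SeqRecord(Seq(p.sequence), id=peptide_header(p, i),
                                 description=""))
    write_fasta(records, path)
    return len(records)
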