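"""Shared fixtures: toy genomes, synthetic cohorts, and independent oracles."""

import numpy as np
import pandas as pd
import pytest

from tmtnet import gen_genome, gen_junction_evidence, gen_tmt_cohort
from tmtnet.config import CohortDesign, JunctionParams
from tmtnet.io import GeneModel, GenomeBundle, revcomp
from tmtnet.junctions import Junction

# ---------------------------------------------------------------------------
# Genomes and junctions
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def toy_genome():
    return gen_genome(seed=1, n_genes=5)


@pytest.fixture(scope="session")
def toy_evidence(toy_genome):
    evidence, truth = gen_junction_evidence(toy_genome, alt_rate=0.8, depth=4, seed=11)
    return evidence, truth


@pytest.fixture()
def mak_plsk_genome():
    """Hand-built gene: E1=MAK, E2=GVD, E3=PLSK with an exon-2-skip junction.

    The annotated-frame junction E1-E3 must yield the miscleaved
    junction-spanning peptide MAKPLSK.
    """
    e1, e2, e3 = "ATGGCTAAG", "GGCGTTGAC", "CCTTTATCTAAG"
    i1, i2 = "GGGGGGGGGG", "CCCCCCCCCC"
    chrom = "AAAA" + e1 + i1 + e2 + i2 + e3 + "TAAAAAA"
    s1 = 4
    exons = [(s1, s1 + 9), (s1 + 19, s1 + 28), (s1 + 38, s1 + 50)]
    gene = GeneModel(gene_id="G1", chrom="c1", strand="+", exons=exons,
                     cds=list(exons), cds_phase=0)
    genome = GenomeBundle(sequences={"c1": chrom}, genes=[gene],
                          proteins={"G1": gene.protein(chrom)})
    jxn_12 = Junction("c1", "+", exons[0][1] - 1, exons[1][0], support=4,
                      max_min_overlap=8)
    jxn_13 = Junction("c1", "+", exons[0][1] - 1, exons[2][0], support=4,
                      max_min_overlap=8)
    return genome, [jxn_12, jxn_13]


# ---------------------------------------------------------------------------
# Brute-force junction peptide oracle
# ---------------------------------------------------------------------------

_CODON_TABLE = {}


def _translate(nt):
    from Bio.Seq import Seq
    return str(Seq(nt[: len(nt) - len(nt) % 3]).translate())


def brute_force_junction_peptides(genome, junctions, params: JunctionParams):
    """Independent enumeration: all 3 frames x all LysC [K|P] digestion
    products (enumerated as substrings with validated cut sites) x the
    junction-span and length filters.  Returns {(junction key, sequence)}.
    """

    def exon_bound(chrom, strand, pos):
        for g in genome.genes:
            if g.chrom == chrom and g.strand == strand:
                for a, b in g.exons:
                    if a <= pos < b:
                        return a, b
        return None

    results = set()
    for j in junctions:
        if not j.is_alternative:
            continue
        seq = genome.sequences[j.chrom]
        lb = exon_bound(j.chrom, j.strand, j.left_end)
        rb = exon_bound(j.chrom, j.strand, j.right_start)
        left_lo = max(j.left_end + 1 - params.flank_nt, lb[0] if lb else 0)
        right_hi = min(j.right_start + params.flank_nt,
                       rb[1] if rb else len(seq))
        left = seq[left_lo:j.left_end + 1]
        right = seq[j.right_start:right_hi]
        if j.strand == "+":
            window, off = left + right, len(left)
        else:
            window, off = revcomp(right) + revcomp(left), len(right)
        for t in range(3):
            aa = _translate(window[t:])
            # stop-free segments with their global residue offsets
            pos = 0
            for part in aa.split("*"):
                seg_start = pos
                pos += len(part) + 1
                if not part:
                    continue
                n = len(part)
                for i0 in range(n):
                    # valid start: segment start or preceded by K
                    if i0 > 0 and part[i0 - 1] != "K":
                        continue
                    for i1 in range(i0, n):
                        # valid end: K or segment end
                        if part[i1] != "K" and i1 != n - 1:
                            continue
                        pep = part[i0:i1 + 1]
                        # internal K residues must be K|P retained bonds
                        retained = 0
                        legal = True
                        for r in range(i0, i1):
                            if part[r] == "K":
                                if part[r + 1] == "P":
                                    retained += 1
                                else:
                                    legal = False
                                    break
                        if not legal or retained > params.max_kp_miscleavage:
                            continue
                        if not params.min_pep_len <= len(pep) <= params.max_pep_len:
                            continue
                        n_left = sum(
                            1 for r in range(seg_start + i0, seg_start + i1 + 1)
                            if t + 3 * r + 3 <= off)
                        n_right = sum(
                            1 for r in range(seg_start + i0, seg_start + i1 + 1)
                            if t + 3 * r >= off)
                        if n_left >= 1 and n_right >= 1:
                            results.add((j.key(), pep))
    return results


@pytest.fixture(scope="session")
def junction_oracle():
    return brute_force_junction_peptides


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def clean_design():
    return CohortDesign(n_features=120, missing_rate=0.0, batch_effect_sd=0.3,
                        noise_sd=0.0, ptm_split_fraction=0.0)


@pytest.fixture(scope="session")
def clean_cohort(clean_design):
    """Noiseless, fully observed cohort: exact recovery expected."""
    return gen_tmt_cohort(clean_design, seed=3)


@pytest.fixture(scope="session")
def noisy_cohort():
    design = CohortDesign(n_features=150, missing_rate=0.05, noise_sd=0.2,
                          ptm_split_fraction=0.0)
    return gen_tmt_cohort(design, seed=3)


@pytest.fixture(scope="session")
def block_matrix():
    """5 planted blocks of 40 features over 47 samples, strong intra-block
    correlation, with truth labels."""
    rng = np.random.default_rng(7)
    n_s, blocks, per = 47, 5, 40
    z = rng.normal(0, 1, (blocks, n_s))
    rows, truth = [], []
    for b in range(blocks):
        for _ in range(per):
            rows.append(2.0 * z[b] + rng.normal(0, 1, n_s))
            truth.append(b)
    values = pd.DataFrame(rows, index=[f"f{i:03d}" for i in range(blocks * per)],
                          columns=[f"s{i:02d}" for i in range(n_s)])
    return values, truth
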