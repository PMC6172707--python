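"""Synthetic genomes, junction evidence, and TMT cohorts with known truth.

The generator emulates the statistical structure of a pooled isobaric-tag
brain proteomics study: an 8-batch x 10-plex design with a global internal
standard (GIS) channel, three case groups (control / AsymAD / AD), planted
group effects, age/sex/PMI covariate slopes, cell-type mixing on marker
features, block-correlated module structure, batch multiplicative effects,
missing values, and PTM-split peptide rows whose intensities sum to the
base-peptide signal.  Every emitted feature and junction carries a truth
record, so each downstream stage can be validated against ground truth.

Intensities are log-normal on linear scale; all planted effects are
additive on the log2 scale, matching the downstream log2-ratio analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .config import CohortDesign, ConfigurationError
from .deconv import CellTypeReference
from .io import GeneModel, GenomeBundle, revcomp
from .normalize import ReporterMatrix

_AA = "ACDEFGHIKLMNPQRSTVWY"
_CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"], "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"], "E": ["GAA", "GAG"], "F": ["TTT", "TTC"],
    "G": ["GGT", "GGC", "GGA", "GGG"], "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"], "K": ["AAA", "AAG"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"], "M": ["ATG"],
    "N": ["AAT", "AAC"], "P": ["CCT", "CCC", "CCA", "CCG"],
    "Q": ["CAA", "CAG"], "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"], "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"], "Y": ["TAT", "TAC"],
}

CELL_TYPES = ["microglia", "astrocyte", "neuron", "oligodendrocyte"]

#: 10-plex TMT reporter channel names; "126" is the GIS by convention.
TMT10_CHANNELS = ["126", "127N", "127C", "128N", "128C",
                  "129N", "129C", "130N", "130C", "131"]


@dataclass
class TruthBundle:
    """Ground truth for one simulated cohort."""

    true_group_effects: pd.DataFrame       # feature x group, log2 shifts
    true_cell_weights: pd.DataFrame        # sample x 4, rows sum to 1
    true_modules: dict[str, str]           # feature -> module label
    true_covariate_effects: pd.DataFrame   # feature x covariate slopes
    true_alt_junctions: list[dict] = field(default_factory=list)
    seed: int = 0
    planted_log2: pd.DataFrame | None = None  # feature x sample log2(sample/GIS)
    marker_types: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        feats = list(self.true_group_effects.index)
        if set(feats) != set(self.true_modules):
            raise ValueError("truth maps cover different feature sets")
        sums = self.true_cell_weights.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("cell weight rows must sum to 1")

    def to_json_dict(self) -> dict[str, Any]:
        return {
            "seed": self.seed,
            "true_group_effects": self.true_group_effects.to_dict(),
            "true_cell_weights": self.true_cell_weights.to_dict(),
            "true_modules": self.true_modules,
            "true_covariate_effects": self.true_covariate_effects.to_dict(),
            "true_alt_junctions": self.true_alt_junctions,
            "marker_types": self.marker_types,
            "planted_log2": (None if self.planted_log2 is None
                             else self.planted_log2.to_dict()),
        }


@dataclass
class CohortData:
    """One simulated TMT cohort: reporter batches plus metadata and truth."""

    batches: list[ReporterMatrix]
    covariates: pd.DataFrame  # sample x (group, age, sex, pmi, batch)
    traits: pd.DataFrame      # sample x (CERAD, Braak, MMSE, abeta42, ptau)
    truth: TruthBundle
    reference: CellTypeReference | None = None

    @property
    def groups(self) -> pd.Series:
        return self.covariates["group"]


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------

def _random_protein(rng: np.random.Generator, n_res: int) -> str:
    # lysine enriched, and proline favoured after lysine, so LysC [K|P]
    # digestion produces both cleavage and miscleavage cases
    weights = np.ones(len(_AA))
    weights[_AA.index("K")] = 3.0
    weights = weights / weights.sum()
    out = []
    for _ in range(n_res):
        if out and out[-1] == "K" and rng.random() < 0.25:
            out.append("P")
        else:
            out.append(_AA[rng.choice(len(_AA), p=weights)])
    return "".join(out)


def _back_translate(rng: np.random.Generator, protein: str) -> str:
    return "".join(_CODONS[aa][rng.integers(len(_CODONS[aa]))] for aa in protein)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(4, size=n))


def gen_genome(seed: int, n_genes: int = 5,
               exons_per_gene: tuple[int, int] = (3, 5)) -> GenomeBundle:
    """Generate a toy genome: one gene per chromosome, exon lengths in
    whole codons so every gene has an annotated CDS with known frame.

    Deterministic for a fixed seed.  The canonical protein of each gene is
    the translation of its annotated exon chain (stop codon excluded from
    the CDS; a TAA follows the final exon).
    """
    if n_genes < 1:
        raise ConfigurationError("n_genes must be >= 1")
    lo, hi = exons_per_gene
    if lo < 1 or lo > hi:
        raise ConfigurationError("invalid exons_per_gene range")
    rng = np.random.default_rng(seed)
    sequences: dict[str, str] = {}
    genes: list[GeneModel] = []
    proteins: dict[str, str] = {}
    for gi in range(n_genes):
        chrom = f"chr{gi + 1}"
        gene_id = f"G{gi + 1:03d}"
        n_exons = int(rng.integers(lo, hi + 1))
        exon_codons = rng.integers(8, 25, size=n_exons)
        protein = "M" + _random_protein(rng, int(exon_codons.sum()) - 1)
        cds = _back_translate(rng, protein)
        # forward-axis layout; flipped below for minus-strand genes
        parts: list[str] = [_random_dna(rng, 60)]
        exons_fwd: list[tuple[int, int]] = []
        offset = 0
        pos = len(parts[0])
        for j, nc in enumerate(exon_codons):
            exon_seq = cds[offset:offset + 3 * int(nc)]
            offset += 3 * int(nc)
            exons_fwd.append((pos, pos + len(exon_seq)))
            parts.append(exon_seq)
            pos += len(exon_seq)
            if j < n_exons - 1:
                intron = _random_dna(rng, int(rng.integers(40, 120)))
                parts.append(intron)
                pos += len(intron)
        parts.append("TAA" + _random_dna(rng, 60))
        chrom_seq = "".join(parts)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            L = len(chrom_seq)
            chrom_seq = revcomp(chrom_seq)
            exons = sorted((L - b, L - a) for a, b in exons_fwd)
        else:
            exons = exons_fwd
        sequences[chrom] = chrom_seq
        model = GeneModel(gene_id=gene_id, chrom=chrom, strand=strand,
                          exons=exons, cds=list(exons), cds_phase=0)
        genes.append(model)
        proteins[gene_id] = model.protein(chrom_seq)
        assert proteins[gene_id] == protein, "back-translation round trip failed"
    return GenomeBundle(sequences=sequences, genes=genes, proteins=proteins)


# ---------------------------------------------------------------------------
# Junction evidence generation
# ---------------------------------------------------------------------------

def gen_junction_evidence(genome: GenomeBundle, alt_rate: float = 0.5,
                          depth: int = 4, seed: int = 0
                          ) -> tuple[pd.DataFrame, list[dict]]:
    """Emit per-read gapped-alignment evidence plus truth flags.

    Constitutive junctions join consecutive annotated exons.  With
    probability ``alt_rate`` a gene with >= 3 exons also emits an
    exon-skipping junction that shares its donor end with a constitutive
    junction (both become *alternative*).  Singleton junctions with unique
    ends, a below-support junction (single read), and low-overlap reads
    (< 4 nt) are also emitted and flagged in truth.
    """
    if not 0 <= alt_rate <= 1:
        raise ConfigurationError("alt_rate must lie in [0,1]")
    if depth < 1:
        raise ConfigurationError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    junctions: list[dict] = []  # truth records
    for g in genome.genes:
        exons = g.exons  # ascending genomic order
        for (a1, b1), (a2, b2) in zip(exons, exons[1:]):
            junctions.append(dict(chrom=g.chrom, strand=g.strand,
                                  left_end=b1 - 1, right_start=a2,
                                  cls="constitutive", n_reads=depth))
        if len(exons) >= 3 and rng.random() < alt_rate:
            i = int(rng.integers(0, len(exons) - 2))
            skip = dict(chrom=g.chrom, strand=g.strand,
                        left_end=exons[i][1] - 1, right_start=exons[i + 2][0],
                        cls="alternative", n_reads=depth)
            junctions.append(skip)
            # the constitutive junction sharing the donor becomes alternative
            for j in junctions:
                if (j["chrom"], j["strand"], j["left_end"]) == \
                        (g.chrom, g.strand, skip["left_end"]) and j is not skip:
                    j["cls"] = "alternative"
        if alt_rate > 0 and rng.random() < 0.3 and len(exons) >= 2:
            # singleton: internal ends shared with nothing
            a1, b1 = exons[0]
            a2, b2 = exons[1]
            if b1 - 1 - 7 > a1 and a2 + 7 < b2 - 1:
                junctions.append(dict(chrom=g.chrom, strand=g.strand,
                                      left_end=b1 - 1 - 7, right_start=a2 + 7,
                                      cls="singleton", n_reads=depth))
        if alt_rate > 0 and rng.random() < 0.25 and len(exons) >= 2:
            # below-support junction: a single gapped read
            a1, b1 = exons[0]
            a2, b2 = exons[1]
            if b1 - 1 - 11 > a1 and a2 + 11 < b2 - 1:
                junctions.append(dict(chrom=g.chrom, strand=g.strand,
                                      left_end=b1 - 1 - 11, right_start=a2 + 11,
                                      cls="singleton", n_reads=1))

    rows = []
    read_no = 0
    for j in junctions:
        n_qual = 0
        for _ in range(j["n_reads"]):
            lo = int(rng.integers(4, 31))
            ro = int(rng.integers(4, 31))
            n_qual += 1
            rows.append((j["chrom"], j["strand"], j["left_end"],
                         j["right_start"], f"read{read_no:05d}", lo, ro))
            read_no += 1
        has_low = False
        if rng.random() < 0.3:  # extra non-qualifying read, overlap < 4 nt
            rows.append((j["chrom"], j["strand"], j["left_end"],
                         j["right_start"], f"read{read_no:05d}",
                         int(rng.integers(1, 4)), int(rng.integers(8, 20))))
            read_no += 1
            has_low = True
        j["below_support"] = n_qual < 2
        j["has_low_overlap_reads"] = has_low
    evidence = pd.DataFrame(rows, columns=[
        "chrom", "strand", "left_end", "right_start",
        "read_id", "left_overlap_nt", "right_overlap_nt"])
    return evidence, junctions


# ---------------------------------------------------------------------------
# TMT cohort generation
# ---------------------------------------------------------------------------

def _random_peptide_ids(rng: np.random.Generator, n: int, length: int = 10) -> list[str]:
    ids: list[str] = []
    seen: set[str] = set()
    while len(ids) < n:
        pep = "".join(_AA[i] for i in rng.integers(len(_AA), size=length))
        if pep not in seen:
            seen.add(pep)
            ids.append(pep)
    return ids


def _assign_batches(rng: np.random.Generator, covariates: pd.DataFrame,
                    design: CohortDesign) -> pd.Series:
    """Round-robin samples to batches within group, so groups are balanced
    across batches; randomized within group."""
    batch_ids = [f"b{k + 1}" for k in range(design.n_batches)]
    counts = {b: 0 for b in batch_ids}
    assignment = {}
    turn = 0
    for grp in covariates["group"].unique():
        members = list(covariates.index[covariates["group"] == grp])
        rng.shuffle(members)
        for s in members:
            for _ in range(design.n_batches):
                b = batch_ids[turn % design.n_batches]
                turn += 1
                if counts[b] < design.plex - 1:
                    assignment[s] = b
                    counts[b] += 1
                    break
    return pd.Series(assignment).reindex(covariates.index)


def gen_tmt_cohort(design: CohortDesign | None = None, seed: int = 0,
                   noise_sd: float | None = None) -> CohortData:
    """Simulate reporter batches, covariates, traits, and ground truth.

    Per-feature planted log2(sample/GIS) abundances combine group shifts,
    centered covariate slopes, module latent factors, and (for marker
    features) the log of a non-negative cell-type mixture; reporter
    intensities are base intensity x 2^(abundance + batch effect + noise),
    the GIS channel carries base x 2^(batch effect) so its expectation is
    the cohort grand mean, and a configurable fraction of features is split
    into 2-3 modified forms whose intensities sum to the base signal.
    """
    design = design or CohortDesign()
    noise_sd = design.noise_sd if noise_sd is None else noise_sd
    rng = np.random.default_rng(seed)

    # --- samples, covariates, traits ------------------------------------
    sample_ids, group_labels = [], []
    i = 0
    for grp, cnt in design.groups.items():
        for _ in range(cnt):
            sample_ids.append(f"S{i + 1:02d}")
            group_labels.append(grp)
            i += 1
    covariates = pd.DataFrame({
        "group": group_labels,
        "age": rng.uniform(*design.age_range, size=design.n_samples).round(1),
        "sex": rng.integers(0, 2, size=design.n_samples),
        "pmi": rng.uniform(*design.pmi_range, size=design.n_samples).round(1),
    }, index=pd.Index(sample_ids, name="sample"))
    covariates["batch"] = _assign_batches(rng, covariates, design)

    group_order = list(design.groups)
    severity = {g: s for g, s in zip(group_order, [0.0, 1.0, 1.6])}
    pathology = np.array([severity[g] for g in group_labels]) + rng.normal(0, 0.3, design.n_samples)
    traits = pd.DataFrame({
        "CERAD": np.clip(np.round(pathology * 1.6), 0, 3).astype(int),
        "Braak": np.clip(np.round(pathology * 3.2), 0, 6).astype(int),
        "MMSE": np.clip(np.round(29 - 7.5 * np.maximum(pathology - 0.8, 0)
                                 + rng.normal(0, 1.5, design.n_samples)), 0, 30).astype(int),
        "abeta42": (pathology * 0.8 + rng.normal(0, 0.4, design.n_samples)).round(3),
        "ptau": (pathology * 0.6 + rng.normal(0, 0.4, design.n_samples)).round(3),
    }, index=covariates.index)

    # --- feature layout --------------------------------------------------
    n_feat = design.n_features
    n_mark = min(design.n_marker_features, n_feat)
    feature_ids = _random_peptide_ids(rng, n_feat)
    markers = feature_ids[:n_mark]
    others = feature_ids[n_mark:]
    marker_types = {m: CELL_TYPES[k % 4] for k, m in enumerate(markers)}

    module_labels: dict[str, str] = {m: "grey" for m in markers}
    n_bg = max(len(others) // 5, 0)
    for k, f in enumerate(others):
        if k < n_bg:
            module_labels[f] = "grey"
        else:
            module_labels[f] = f"M{(k - n_bg) % design.n_modules + 1}"

    group_effects = pd.DataFrame(0.0, index=feature_ids, columns=group_order)
    hit_candidates = [f for f in others if module_labels[f] == "grey"]
    n_hits = max(len(hit_candidates) // 3, 1)
    for f in hit_candidates[:n_hits]:
        delta = float(rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.5))
        group_effects.loc[f, group_order[2]] = delta
        group_effects.loc[f, group_order[1]] = delta / 2

    cov_effects = pd.DataFrame(0.0, index=feature_ids, columns=["age", "sex", "pmi"])
    for f in hit_candidates[n_hits:2 * n_hits]:
        cov_effects.loc[f, "age"] = float(rng.uniform(0.02, 0.05) * rng.choice([-1, 1]))
        cov_effects.loc[f, "sex"] = float(rng.uniform(0.1, 0.4) * rng.choice([-1, 1]))
        cov_effects.loc[f, "pmi"] = float(rng.uniform(0.01, 0.03) * rng.choice([-1, 1]))

    # --- cell-type weights and marker reference -------------------------
    base_alpha = np.array([1.2, 2.2, 4.5, 2.1])
    weights = np.empty((design.n_samples, 4))
    for s in range(design.n_samples):
        shift = np.array([0.5, 0.5, -0.8, 0.0]) * severity[group_labels[s]] * 0.4
        weights[s] = rng.dirichlet(np.maximum(base_alpha + shift, 0.2) * 12)
    cell_weights = pd.DataFrame(weights, index=covariates.index, columns=CELL_TYPES)

    profile = np.full((n_mark, 4), 0.2)
    for k, m in enumerate(markers):
        profile[k, CELL_TYPES.index(marker_types[m])] = float(rng.uniform(6, 12))
    mixture = profile @ weights.T  # markers x samples, linear
    c = mixture.mean(axis=1, keepdims=True)
    marker_log2 = np.log2(mixture / c)
    # reference on the observed (GIS-ratio) scale: same row normalization
    reference = CellTypeReference(
        marker_ids=markers,
        profile=pd.DataFrame(profile / c, index=markers, columns=CELL_TYPES))

    # --- planted log2(sample/GIS) ----------------------------------------
    module_factor = pd.DataFrame(
        rng.normal(0, 1, size=(design.n_samples, design.n_modules)),
        index=covariates.index,
        columns=[f"M{k + 1}" for k in range(design.n_modules)])
    # module M1 tracks pathology so module-trait correlations are planted
    module_factor["M1"] = (pathology - pathology.mean()) / pathology.std() \
        + rng.normal(0, 0.4, design.n_samples)

    age_c = covariates["age"] - covariates["age"].mean()
    sex_c = covariates["sex"] - covariates["sex"].mean()
    pmi_c = covariates["pmi"] - covariates["pmi"].mean()
    planted = pd.DataFrame(0.0, index=feature_ids, columns=covariates.index)
    for k, m in enumerate(markers):
        planted.loc[m] = marker_log2[k]
    for f in others:
        row = (group_effects.loc[f, covariates["group"]].to_numpy()
               + cov_effects.loc[f, "age"] * age_c.to_numpy()
               + cov_effects.loc[f, "sex"] * sex_c.to_numpy()
               + cov_effects.loc[f, "pmi"] * pmi_c.to_numpy())
        mod = module_labels[f]
        if mod != "grey":
            row = row + rng.uniform(0.5, 0.9) * module_factor[mod].to_numpy()
        planted.loc[f] = row

    # --- reporter intensities per batch ----------------------------------
    base_intensity = np.exp2(rng.normal(14, 1.2, size=n_feat))
    batch_ids = sorted(covariates["batch"].unique())
    batch_shift = {b: float(rng.normal(0, design.batch_effect_sd)) for b in batch_ids}

    n_split = int(round(design.ptm_split_fraction * n_feat))
    split_features = set(feature_ids[n_feat - n_split:] if n_split else [])
    mods = ["[Acetyl]", "[Oxidation]", "[Deamidation]"]
    split_plan: dict[str, list[tuple[str, float]]] = {}
    for f in feature_ids:
        if f in split_features:
            k = int(rng.integers(2, 4))
            props = rng.dirichlet(np.ones(k) * 4)
            forms = [(f if j == 0 else mods[j - 1] + f, float(props[j]))
                     for j in range(k)]
            split_plan[f] = forms
        else:
            split_plan[f] = [(f, 1.0)]

    batches: list[ReporterMatrix] = []
    for b in batch_ids:
        members = list(covariates.index[covariates["batch"] == b])
        channels = TMT10_CHANNELS[:design.plex]
        sample_channels = [c for c in channels if c != design.gis_channel][:len(members)]
        ch_map = dict(zip(sample_channels, members))
        noise = rng.normal(0, noise_sd, size=(n_feat, len(members)))
        log2_ab = planted[members].to_numpy() + noise
        inten = base_intensity[:, None] * np.exp2(log2_ab + batch_shift[b])
        gis = base_intensity * np.exp2(batch_shift[b])
        if design.missing_rate > 0:
            mask = rng.random(inten.shape) < design.missing_rate
            inten = np.where(mask, np.nan, inten)
        form_index, form_rows, gis_rows = [], [], []
        for fi, f in enumerate(feature_ids):
            for form_id, prop in split_plan[f]:
                form_index.append(form_id)
                form_rows.append(inten[fi] * prop)
                gis_rows.append(gis[fi] * prop)
        df = pd.DataFrame(np.asarray(form_rows), index=pd.Index(form_index, name="feature"),
                          columns=sample_channels)
        df[design.gis_channel] = np.asarray(gis_rows)
        batches.append(ReporterMatrix(batch_id=b, intensities=df,
                                      channel_to_sample=ch_map,
                                      gis_channel=design.gis_channel))

    truth = TruthBundle(
        true_group_effects=group_effects,
        true_cell_weights=cell_weights,
        true_modules=module_labels,
        true_covariate_effects=cov_effects,
        seed=seed,
        planted_log2=planted,
        marker_types=marker_types,
    )
    truth.validate()
    return CohortData(batches=batches, covariates=covariates, traits=traits,
                      truth=truth, reference=reference)
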