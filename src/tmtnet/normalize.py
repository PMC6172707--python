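"""TMT reporter normalization: GIS ratios, outlier and missingness filters,
PTM-form summation, and cross-batch scaling.

The pooled global internal standard (GIS) occupies one reporter channel in
every batch; per-feature log2(sample/GIS) ratios make batches comparable.
Ratios at or beyond 100-fold (|log2| >= log2(100) ~ 6.64) are excluded as
extreme outliers.  Features unquantifiable (GIS reporter 0/absent) in more
than ``max_bad_gis_batches`` batches, or missing in more than
``max_missing_protein`` samples (just under 50%), are dropped.  Missing
values are never imputed at any step.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import NormalizationParams

logger = logging.getLogger("tmtnet")


@dataclass
class ReporterMatrix:
    """Per-batch reporter intensities: features x channels, linear scale.

    ``channel_to_sample`` maps sample channels to cohort sample ids; the
    GIS channel is excluded from the map.
    """

    batch_id: str
    intensities: pd.DataFrame
    channel_to_sample: dict[str, str]
    gis_channel: str = "126"

    def __post_init__(self) -> None:
        if self.gis_channel in self.channel_to_sample:
            raise ValueError("GIS channel cannot map to a sample")

    def sample_columns(self) -> pd.DataFrame:
        """Sample-channel intensities with columns renamed to sample ids."""
        cols = [c for c in self.intensities.columns if c in self.channel_to_sample]
        return self.intensities[cols].rename(columns=self.channel_to_sample)

    def gis(self) -> pd.Series:
        if self.gis_channel not in self.intensities.columns:
            raise ValueError(f"batch {self.batch_id}: GIS channel "
                             f"{self.gis_channel!r} absent")
        return self.intensities[self.gis_channel]


@dataclass
class AbundanceMatrix:
    """Feature x sample abundance values (log2), with group labels."""

    values: pd.DataFrame
    groups: pd.Series | None = None
    provenance: str = "protein"  # or "alt-EEjxn peptide"

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        if self.groups is not None:
            self.groups = self.groups.reindex(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# Per-batch ratio computation
# ---------------------------------------------------------------------------

def ratio_to_gis(batch: ReporterMatrix) -> pd.DataFrame:
    """log2(sample/GIS) per feature; missing where either intensity is 0/NA."""
    gis = batch.gis()
    samples = batch.sample_columns()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.log2(samples.where(samples > 0).div(gis.where(gis > 0), axis=0))
    return ratios.replace([np.inf, -np.inf], np.nan)


def filter_outliers(values: pd.DataFrame,
                    params: NormalizationParams | None = None
                    ) -> tuple[pd.DataFrame, int]:
    """Set |log2 ratio| >= outlier_bound to missing; return the count removed."""
    params = params or NormalizationParams()
    mask = values.abs() >= params.outlier_bound - 1e-12
    n = int(mask.sum().sum())
    if n:
        logger.info("filter_outliers: %d extreme values excluded", n)
    return values.mask(mask), n


def gis_intensity_table(batches: list[ReporterMatrix]) -> pd.DataFrame:
    """Feature x batch table of GIS intensities (NaN where feature absent)."""
    cols = {b.batch_id: b.gis() for b in batches}
    return pd.DataFrame(cols)


def filter_features(values: pd.DataFrame, params: NormalizationParams,
                    gis_by_batch: pd.DataFrame
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the unquantifiable-batch and per-sample missingness filters.

    A batch is unquantifiable for a feature when its GIS reporter is 0 or
    absent there.  Returns the filtered matrix and a per-feature exclusion
    report (columns: feature, reason).
    """
    gis = gis_by_batch.reindex(values.index)
    bad_gis = ((gis.isna()) | (gis <= 0)).sum(axis=1)
    missing = values.isna().sum(axis=1)
    cap = params.missing_cap(values.shape[1])
    reasons = []
    for f in values.index:
        if bad_gis[f] > params.max_bad_gis_batches:
            reasons.append((f, f"gis_unquantifiable_in_{int(bad_gis[f])}_batches"))
        elif missing[f] > cap:
            reasons.append((f, f"missing_in_{int(missing[f])}_samples"))
    report = pd.DataFrame(reasons, columns=["feature", "reason"])
    keep = values.index.difference(report["feature"], sort=False)
    logger.info("filter_features: %d of %d features retained",
                len(keep), values.shape[0])
    return values.loc[keep], report


# ---------------------------------------------------------------------------
# PTM-form summation (alt-EEjxn peptide path)
# ---------------------------------------------------------------------------

_MOD_TOKEN = re.compile(r"\[[^\[\]]*\]")


def strip_modifications(modified_sequence: str) -> str:
    """Base peptide from a modified form; mods are bracketed tokens,
    e.g. ``[Acetyl]M[Oxidation]AK`` -> ``MAK``."""
    if modified_sequence.count("[") != modified_sequence.count("]"):
        raise ValueError(f"unbalanced modification brackets in {modified_sequence!r}")
    base = _MOD_TOKEN.sub("", modified_sequence)
    if not base or not re.fullmatch(r"[ACDEFGHIKLMNPQRSTVWYX]+", base):
        raise ValueError(f"unparseable modified sequence {modified_sequence!r}")
    return base


def sum_ptm_forms(peptide_table: pd.DataFrame) -> pd.DataFrame:
    """Sum linear-scale abundances over modified forms of each base peptide.

    The index holds modified sequences; rows sharing a stripped base
    sequence are summed per column (NaN only where all forms are missing).
    """
    try:
        bases = [strip_modifications(str(ix)) for ix in peptide_table.index]
    except ValueError as exc:
        raise ValueError(f"sum_ptm_forms: {exc}") from exc
    grouped = peptide_table.groupby(pd.Index(bases, name=peptide_table.index.name))
    return grouped.sum(min_count=1)


# ---------------------------------------------------------------------------
# Cross-batch scaling and log transform
# ---------------------------------------------------------------------------

def equalize_channel_totals(batch: pd.DataFrame) -> pd.DataFrame:
    """Scale each channel so column totals are equal within the batch
    (a simple stand-in for vendor within-batch normalization)."""
    totals = batch.sum(axis=0, skipna=True)
    target = totals.mean()
    return batch.mul(target / totals, axis=1)


def scale_batches(batch_values: dict[str, pd.DataFrame], gis_column: str
                  ) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Scale linear abundances so the mean GIS measurement is identical
    across batches.

    Each batch is multiplied by grand_mean / batch_gis_mean where the
    grand mean averages per-batch GIS means.  Batches without a single
    usable GIS value are excluded with an error report.
    """
    means = {}
    errors = []
    for bid, df in batch_values.items():
        if gis_column not in df.columns:
            errors.append((bid, "gis_column_absent"))
            continue
        gis = df[gis_column]
        usable = gis[(gis > 0) & gis.notna()]
        if usable.empty:
            errors.append((bid, "no_usable_gis_values"))
            continue
        means[bid] = usable.mean()
    if not means:
        raise ValueError("no batch has usable GIS values")
    grand = float(np.mean(list(means.values())))
    scaled = {bid: batch_values[bid] * (grand / means[bid]) for bid in means}
    report = pd.DataFrame(errors, columns=["batch", "error"])
    for bid, _ in errors:
        logger.error("scale_batches: batch %s excluded", bid)
    return scaled, report


def log2_and_clean(values: pd.DataFrame,
                   params: NormalizationParams | None = None) -> pd.DataFrame:
    """log2-transform linear values; values < 1 removed first (negatives
    after log2) when ``drop_sub_one``."""
    params = params or NormalizationParams()
    vals = values.where(values > 0)
    if params.drop_sub_one:
        n = int((vals < 1).sum().sum())
        if n:
            logger.info("log2_and_clean: %d sub-one values removed", n)
        vals = vals.where(vals >= 1)
    return np.log2(vals)


# ---------------------------------------------------------------------------
# End-to-end convenience pipelines
# ---------------------------------------------------------------------------

def normalize_protein_batches(batches: list[ReporterMatrix],
                              params: NormalizationParams | None = None,
                              groups: pd.Series | None = None
                              ) -> tuple[AbundanceMatrix, pd.DataFrame]:
    """Reporter batches -> filtered cross-batch log2(sample/GIS) matrix."""
    params = params or NormalizationParams()
    ratio_frames = [ratio_to_gis(b) for b in batches]
    combined = pd.concat(ratio_frames, axis=1)
    combined, _ = filter_outliers(combined, params)
    filtered, report = filter_features(combined, params, gis_intensity_table(batches))
    return AbundanceMatrix(filtered, groups=groups, provenance="protein"), report


def normalize_peptide_batches(batches: list[ReporterMatrix],
                              params: NormalizationParams | None = None,
                              groups: pd.Series | None = None,
                              equalize_channels: bool = False
                              ) -> AbundanceMatrix:
    """Modified-form reporter batches -> summed, scaled, log2 peptide matrix.

    Forms of the same base peptide are summed on linear scale per batch,
    batches are scaled to a common GIS mean, the GIS column is dropped, and
    values are log2-transformed with sub-one values removed.
    """
    params = params or NormalizationParams()
    per_batch: dict[str, pd.DataFrame] = {}
    col_map: dict[str, dict[str, str]] = {}
    for b in batches:
        df = b.intensities
        if equalize_channels:
            df = equalize_channel_totals(df)
        per_batch[b.batch_id] = sum_ptm_forms(df)
        col_map[b.batch_id] = b.channel_to_sample
    scaled, _ = scale_batches(per_batch, gis_column=batches[0].gis_channel)
    sample_frames = []
    for bid, df in scaled.items():
        cols = [c for c in df.columns if c in col_map[bid]]
        sample_frames.append(df[cols].rename(columns=col_map[bid]))
    combined = pd.concat(sample_frames, axis=1)
    values = log2_and_clean(combined, params)
    return AbundanceMatrix(values, groups=groups, provenance="alt-EEjxn peptide")
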