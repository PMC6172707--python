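"""Differential abundance and enrichment statistics.

Differential proteins are found by one-way ANOVA followed by Tukey's post
hoc comparison (Tukey-Kramer for unequal group sizes).  Set enrichment
uses hypergeometric overlap tests: the one-tailed Fisher exact upper tail
and the two-tailed overrepresentation variant (sum of outcomes no more
probable than the observed table), with Benjamini-Hochberg FDR correction
applied across the family of tests performed in one call.  Quantifiability
and missingness filters for junction peptides, kME-based assignment of
peptides to network modules, and cross-network module overlap comparison
live here as well.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .network import bicor
from .normalize import AbundanceMatrix

logger = logging.getLogger("tmtnet")


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaN-tolerant)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# ANOVA + Tukey
# ---------------------------------------------------------------------------

class _SturngTail:
    """Studentized-range upper-tail probabilities, batched per (k, df).

    Direct ``studentized_range.sf`` evaluations cost milliseconds each, so
    large batches are served from a dense monotone interpolation grid.
    """

    GRID = 512
    DIRECT_LIMIT = 32

    def __call__(self, q: np.ndarray, k: int, df: int) -> np.ndarray:
        q = np.asarray(q, dtype=float)
        out = np.ones_like(q)
        finite = np.isfinite(q) & (q > 0)
        out[q == np.inf] = 0.0
        out[np.isnan(q)] = np.nan
        if finite.sum() == 0:
            return out
        qs = q[finite]
        if qs.size <= self.DIRECT_LIMIT:
            out[finite] = sps.studentized_range.sf(qs, k, df)
            return out
        grid = np.linspace(0.0, float(qs.max()) * 1.02 + 1e-6, self.GRID)
        sf_grid = sps.studentized_range.sf(grid, k, df)
        out[finite] = np.interp(qs, grid, sf_grid)
        return out


_sturng_tail = _SturngTail()


def anova_tukey(matrix: AbundanceMatrix | pd.DataFrame,
                groups: pd.Series | None = None,
                pairs: list[tuple[str, str]] | None = None) -> pd.DataFrame:
    """Per-feature one-way ANOVA with Tukey HSD post hoc on available cases.

    Groups with fewer than 2 non-missing observations are excluded per
    feature; features with fewer than 2 usable groups are dropped (logged).
    Unequal group sizes use the Tukey-Kramer statistic
    q = |m_a - m_b| / sqrt(MSE/2 (1/n_a + 1/n_b)) referred to the
    studentized range with k groups and N - k degrees of freedom.  Zero
    within-group variance with equal means yields F = 0, p = 1 by
    convention.  Returns one row per tested feature with the F statistic,
    ANOVA p, per-group n, and pairwise mean log2 differences with
    Tukey-adjusted p-values.
    """
    if isinstance(matrix, AbundanceMatrix):
        values, groups = matrix.values, matrix.groups if groups is None else groups
    else:
        values = matrix
    if groups is None:
        raise ValueError("group labels are required")
    groups = groups.reindex(values.columns)
    levels = list(pd.unique(groups.dropna()))
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(levels) for b in levels[i + 1:]]

    rows = []
    q_batches: dict[tuple[int, int], list[tuple[int, str, float]]] = {}
    n_dropped = 0
    for f in values.index:
        y = values.loc[f]
        by_group = {g: y[groups == g].dropna().to_numpy() for g in levels}
        usable = {g: v for g, v in by_group.items() if len(v) >= 2}
        if len(usable) < 2:
            n_dropped += 1
            continue
        k = len(usable)
        ns = {g: len(v) for g, v in usable.items()}
        means = {g: float(v.mean()) for g, v in usable.items()}
        N = sum(ns.values())
        df_w = N - k
        ss_w = sum(float(((v - means[g]) ** 2).sum()) for g, v in usable.items())
        grand = sum(means[g] * ns[g] for g in usable) / N
        ss_b = sum(ns[g] * (means[g] - grand) ** 2 for g in usable)
        mse = ss_w / df_w
        if mse == 0:
            if ss_b == 0:
                F, p = 0.0, 1.0  # no variance anywhere: no evidence of difference
                logger.debug("anova_tukey: degenerate feature %s, p=1", f)
            else:
                F, p = np.inf, 0.0
        else:
            F = (ss_b / (k - 1)) / mse
            p = float(sps.f.sf(F, k - 1, df_w))
        row = {"feature": f, "F": float(F), "p_anova": p}
        for g in levels:
            row[f"n_{g}"] = len(by_group[g])
        for a, b in pairs:
            key = f"{a}-{b}"
            if a in usable and b in usable:
                diff = means[a] - means[b]
                row[f"diff_{key}"] = diff
                se = np.sqrt(mse / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
                if se == 0:
                    row[f"p_tukey_{key}"] = 1.0 if diff == 0 else 0.0
                else:
                    q_batches.setdefault((k, df_w), []).append(
                        (len(rows), f"p_tukey_{key}", abs(diff) / se))
                    row[f"p_tukey_{key}"] = np.nan  # filled below
            else:
                row[f"diff_{key}"] = np.nan
                row[f"p_tukey_{key}"] = np.nan
        rows.append(row)
    for (k, df_w), entries in q_batches.items():
        pvals = _sturng_tail(np.array([q for _, _, q in entries]), k, df_w)
        for (ridx, col, _), pv in zip(entries, pvals):
            rows[ridx][col] = float(pv)
    if n_dropped:
        logger.info("anova_tukey: %d features dropped (fewer than 2 usable groups)",
                    n_dropped)
    return pd.DataFrame(rows).set_index("feature") if rows else pd.DataFrame()


# ---------------------------------------------------------------------------
# Fisher / hypergeometric enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    """One 2x2 overlap test."""

    name: str
    overlap: int
    query_size: int
    target_size: int
    background_size: int
    odds_ratio: float
    p: float
    p_adj: float
    tail: str

    @property
    def table(self) -> tuple[tuple[int, int], tuple[int, int]]:
        a = self.overlap
        b = self.query_size - a
        c = self.target_size - a
        d = self.background_size - a - b - c
        return ((a, b), (c, d))


def _overlap_p(overlap: int, query: int, target: int, background: int,
               tail: str) -> tuple[float, float]:
    a = overlap
    b = query - a
    c = target - a
    d = background - a - b - c
    if min(b, c, d) < 0:
        raise ValueError("query and target must be subsets of the background")
    if tail == "one":
        p = float(sps.hypergeom.sf(a - 1, background, target, query))
    else:
        _, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    odds = (a * d) / (b * c) if b * c > 0 else np.inf
    return float(p), float(odds)


def fisher_enrichment(query, target, background, tail: str = "one",
                      name: str = "test") -> EnrichmentResult:
    """Hypergeometric overlap significance of two sets in a background.

    ``tail='one'`` is the upper-tail (overrepresentation) Fisher exact
    test; ``tail='two'`` sums all hypergeometric outcomes no more probable
    than the observed table (the standard two-sided Fisher exact).
    """
    background = set(background)
    if not background:
        raise ValueError("background is empty")
    query = set(query) & background
    target = set(target) & background
    overlap = len(query & target)
    p, odds = _overlap_p(overlap, len(query), len(target), len(background), tail)
    return EnrichmentResult(name=name, overlap=overlap, query_size=len(query),
                            target_size=len(target),
                            background_size=len(background), odds_ratio=odds,
                            p=p, p_adj=p, tail=tail)


def enrichment_family(tests: list[tuple[str, set, set]], background,
                      tail: str = "one") -> pd.DataFrame:
    """A family of overlap tests with BH correction across the family."""
    results = [fisher_enrichment(q, t, background, tail=tail, name=n)
               for n, q, t in tests]
    df = pd.DataFrame([{
        "name": r.name, "overlap": r.overlap, "query_size": r.query_size,
        "target_size": r.target_size, "background_size": r.background_size,
        "odds_ratio": r.odds_ratio, "p": r.p, "tail": r.tail,
    } for r in results])
    df["p_adj"] = bh_adjust(df["p"])
    return df.set_index("name")


# ---------------------------------------------------------------------------
# Junction-peptide quantifiability and module assignment
# ---------------------------------------------------------------------------

def quantifiable_filter(values: pd.DataFrame, groups: pd.Series,
                        min_per_group: int = 2, min_groups: int = 2) -> pd.Index:
    """Peptides with >= ``min_per_group`` measurements in >= ``min_groups``
    case groups (the quantifiability rule for junction peptides)."""
    groups = groups.reindex(values.columns)
    counts = values.notna().T.groupby(groups).sum().T  # feature x group
    ok = (counts >= min_per_group).sum(axis=1) >= min_groups
    return values.index[ok]


def assign_peptides_to_modules(peptide_values: pd.DataFrame,
                               eigenproteins: pd.DataFrame,
                               max_missing: int = 25) -> pd.DataFrame:
    """Assign each peptide to the module of its highest kME.

    Peptides with more than ``max_missing`` missing values (of the samples
    shared with the eigenproteins) are left unassigned, guarding against
    spurious correlations.  Returns columns: module (NaN if unassigned),
    kme, n_missing.
    """
    shared = [s for s in eigenproteins.columns if s in peptide_values.columns]
    vals = peptide_values[shared]
    eps = eigenproteins[shared]
    rows = []
    for pep in vals.index:
        y = vals.loc[pep]
        n_missing = int(y.isna().sum())
        if n_missing > max_missing or y.notna().sum() == 0:
            if y.notna().sum() == 0:
                logger.info("assign_peptides: %s all-missing, unassigned", pep)
            rows.append((pep, None, np.nan, n_missing))
            continue
        kmes = {m: bicor(y, eps.loc[m]) for m in eps.index}
        best = max(kmes, key=lambda m: (np.nan_to_num(kmes[m], nan=-2), m))
        rows.append((pep, best, kmes[best], n_missing))
    return pd.DataFrame(rows, columns=["peptide", "module", "kme",
                                       "n_missing"]).set_index("peptide")


def module_alt_eejxn_enrichment(assignments: pd.Series,
                                module_feature_counts: pd.Series,
                                tail: str = "one") -> pd.DataFrame:
    """Per-module Fisher enrichment of alt-EEjxn peptides, BH across modules.

    The universe combines network features (per-module counts) with the
    assigned peptides; the query is the peptide set and each module is a
    target in turn.
    """
    assignments = assignments.dropna()
    universe = set()
    tests = []
    peptides = {f"pep::{p}" for p in assignments.index}
    universe |= peptides
    module_members: dict[str, set] = {}
    for m, cnt in module_feature_counts.items():
        members = {f"{m}::feat{i}" for i in range(int(cnt))}
        members |= {f"pep::{p}" for p, mod in assignments.items() if mod == m}
        module_members[m] = members
        universe |= members
    for m in module_feature_counts.index:
        tests.append((m, peptides, module_members[m]))
    return enrichment_family(tests, universe, tail=tail)


# ---------------------------------------------------------------------------
# Cross-network module comparison
# ---------------------------------------------------------------------------

def compare_networks(labels_a: pd.Series, labels_b: pd.Series,
                     exclude: tuple[str, ...] = ("grey",)
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise module-overlap hypergeometric tests on the shared universe.

    Returns the full pairwise table (overlap, p, BH-adjusted p) and a
    per-module best-match summary for network A.
    """
    universe = labels_a.index.intersection(labels_b.index)
    if universe.empty:
        raise ValueError("label universes are disjoint")
    la = labels_a.loc[universe]
    lb = labels_b.loc[universe]
    mods_a = sorted(m for m in la.unique() if m not in exclude)
    mods_b = sorted(m for m in lb.unique() if m not in exclude)
    rows = []
    N = len(universe)
    for ma in mods_a:
        set_a = set(universe[la == ma])
        for mb in mods_b:
            set_b = set(universe[lb == mb])
            ov = len(set_a & set_b)
            p, _ = _overlap_p(ov, len(set_a), len(set_b), N, tail="one")
            rows.append((ma, mb, ov, len(set_a), len(set_b), p))
    table = pd.DataFrame(rows, columns=["module_a", "module_b", "overlap",
                                        "size_a", "size_b", "p"])
    table["p_adj"] = bh_adjust(table["p"])
    best = (table.sort_values(["module_a", "p", "module_b"])
            .groupby("module_a").first().reset_index())
    return table, best
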