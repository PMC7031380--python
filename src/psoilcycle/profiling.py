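"""From KO read-count tables to relative-abundance profiles and shift statistics.

Pipeline order: :func:`median_normalize` (library-size rescaling) →
:func:`relative_abundance` (percent of annotated reads per gene) →
:func:`aggregate_systems` / :func:`category_totals` → :func:`shift_statistic`
for nutrient-input contrasts. :func:`taxon_shift` operates on normalized
absolute read numbers (taxon tables), not relative abundances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import CATEGORIES, GeneCatalog, genes_in_category

logger = logging.getLogger(__name__)

__all__ = [
    "KoCountTable",
    "SampleMetadata",
    "ProfileMatrix",
    "GroupProfile",
    "median_normalize",
    "relative_abundance",
    "aggregate_systems",
    "category_totals",
    "shift_statistic",
    "taxon_shift",
]

#: contrast label -> (metadata column, plus level, minus level)
CONTRASTS = {
    "P": ("p_contrast", "plusP", "minusP"),
    "N": ("n_contrast", "plusN", "minusN"),
}


@dataclass
class KoCountTable:
    """Annotated read counts per KO per sample.

    ``counts`` is a KO × sample table; ``total_annotated`` carries the total
    annotated reads per sample, which may exceed the column sum when the
    table has been restricted to catalog KOs.
    """

    counts: pd.DataFrame
    total_annotated: pd.Series

    def __post_init__(self) -> None:
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample ids in count table")
        if self.counts.index.duplicated().any():
            dupes = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate KO rows: {dupes}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        self.total_annotated = self.total_annotated.reindex(self.counts.columns)
        if self.total_annotated.isna().any():
            missing = self.total_annotated.index[self.total_annotated.isna()].tolist()
            raise ValueError(f"total_annotated missing for samples {missing}")
        colsum = self.counts.sum(axis=0)
        if (self.total_annotated + 1e-9 < colsum).any():
            raise ValueError("total_annotated below column sum of counts")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def ko_ids(self) -> list[str]:
        return list(self.counts.index)


@dataclass
class SampleMetadata:
    """Per-sample design and soil covariates, indexed by sample id."""

    table: pd.DataFrame

    REQUIRED = ("site", "treatment", "p_contrast", "n_contrast", "replicate")

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            raise ValueError("duplicate sample ids in metadata")
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"metadata missing required column(s) {missing}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def contrast_groups(self, contrast: str) -> tuple[list[str], list[str]]:
        """Sample ids in the (+, −) groups of a nutrient contrast ('P' or 'N')."""
        if contrast not in CONTRASTS:
            raise ValueError(f"unknown contrast {contrast!r}; expected 'P' or 'N'")
        col, plus, minus = CONTRASTS[contrast]
        flags = self.table[col].astype(str)
        return (
            list(self.table.index[flags == plus]),
            list(self.table.index[flags == minus]),
        )

    def covariate(self, name: str) -> pd.Series:
        if name not in self.table.columns:
            raise KeyError(f"covariate {name!r} not in metadata")
        return pd.to_numeric(self.table[name], errors="coerce")


@dataclass
class ProfileMatrix:
    """Relative abundances (percent of annotated reads), feature × sample."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < -1e-12).any():
            raise ValueError("negative relative abundances")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_samples(self, sample_ids: list[str]) -> "ProfileMatrix":
        return ProfileMatrix(self.values.loc[:, sample_ids].copy())


@dataclass
class GroupProfile:
    """Per-sample total relative abundance of each functional category."""

    totals: pd.DataFrame  # category × sample

    @property
    def sample_ids(self) -> list[str]:
        return list(self.totals.columns)


def median_normalize(table: KoCountTable) -> KoCountTable:
    """Rescale each sample to the cross-sample median of total annotated reads.

    Sample *j* is multiplied by ``median(total_annotated) / total_annotated[j]``,
    so within-sample proportions are unchanged while library sizes equalize.
    """
    totals = table.total_annotated.astype(float)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"samples with zero annotated reads: {bad}")
    factors = totals.median() / totals
    counts = table.counts.astype(float).mul(factors, axis=1)
    return KoCountTable(counts=counts, total_annotated=totals * factors)


def relative_abundance(table: KoCountTable, catalog: GeneCatalog) -> ProfileMatrix:
    """Percent of annotated reads assigned to each catalog gene, per sample.

    A gene's reads are summed over all of its KO identifiers; the denominator
    is the sample's total annotated reads. Genes whose KOs are absent from
    the table get 0 with a logged warning. Scale-invariant per sample, so the
    result is identical for raw and median-normalized input.
    """
    totals = table.total_annotated.astype(float)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"samples with zero annotated reads: {bad}")
    rows = {}
    for entry in catalog:
        present = [ko for ko in entry.ko_ids if ko in table.counts.index]
        if not present:
            logger.warning(
                "gene %s: none of its KO ids %s found in the count table; "
                "abundance set to 0", entry.gene_symbol, list(entry.ko_ids),
            )
            rows[entry.gene_symbol] = pd.Series(0.0, index=table.counts.columns)
            continue
        rows[entry.gene_symbol] = table.counts.loc[present].sum(axis=0).astype(float)
    values = pd.DataFrame(rows).T.loc[catalog.gene_symbols]
    return ProfileMatrix(values=100.0 * values.div(totals, axis=1))


def aggregate_systems(profile: ProfileMatrix, catalog: GeneCatalog) -> ProfileMatrix:
    """Collapse each system group to the arithmetic mean of its member genes.

    Non-grouped genes pass through unchanged; the output keeps catalog order
    with each group appearing at its first member's position.
    """
    groups = catalog.system_group_members()
    member_of = {g: grp for grp, members in groups.items() for g in members}
    for grp, members in groups.items():
        missing = [m for m in members if m not in profile.values.index]
        if missing:
            raise ValueError(
                f"system group {grp!r} missing member gene(s) {missing} in profile"
            )
    out_rows: list[str] = []
    data = {}
    for gene in profile.feature_ids:
        grp = member_of.get(gene)
        if grp is None:
            out_rows.append(gene)
            data[gene] = profile.values.loc[gene]
        elif grp not in data:
            out_rows.append(grp)
            data[grp] = profile.values.loc[groups[grp]].mean(axis=0)
    return ProfileMatrix(values=pd.DataFrame(data).T.loc[out_rows])


def category_totals(profile: ProfileMatrix, catalog: GeneCatalog) -> GroupProfile:
    """Total relative abundance of each functional category per sample."""
    rows = {}
    for cat in CATEGORIES:
        members = genes_in_category(catalog, cat)
        present = [g for g in members if g in profile.values.index]
        absent = sorted(set(members) - set(present))
        if absent:
            logger.warning("category %s: genes %s absent from profile", cat, absent)
        if present:
            rows[cat] = profile.values.loc[present].sum(axis=0)
        else:
            rows[cat] = pd.Series(0.0, index=profile.values.columns)
    return GroupProfile(totals=pd.DataFrame(rows).T.loc[list(CATEGORIES)])


def shift_statistic(
    values: pd.Series | pd.DataFrame,
    meta: SampleMetadata,
    contrast: str,
) -> float | pd.Series:
    """Percent shift of a quantity in response to a nutrient input.

    ``100 × (mean over +group − mean over −group) / (mean over −group)``,
    pooling replicates across sites within each contrast group. Accepts a
    per-sample Series (returns a float) or a feature × sample DataFrame
    (returns one shift per feature).
    """
    plus_ids, minus_ids = meta.contrast_groups(contrast)
    if not plus_ids or not minus_ids:
        raise ValueError(f"contrast {contrast!r} has an empty group")
    if isinstance(values, pd.DataFrame):
        plus = values.loc[:, plus_ids].mean(axis=1)
        minus = values.loc[:, minus_ids].mean(axis=1)
        if (minus == 0).any():
            bad = minus.index[minus == 0].tolist()
            raise ValueError(f"zero −group mean for feature(s) {bad}")
        return 100.0 * (plus - minus) / minus
    plus_mean = float(values.loc[plus_ids].mean())
    minus_mean = float(values.loc[minus_ids].mean())
    if minus_mean == 0:
        raise ValueError("shift undefined: −group mean is zero")
    return 100.0 * (plus_mean - minus_mean) / minus_mean


def taxon_shift(
    normalized_reads: pd.DataFrame,
    meta: SampleMetadata,
    contrast: str,
    per_site: bool = False,
) -> pd.Series | pd.DataFrame:
    """Change in normalized read numbers per taxon under a nutrient input.

    Per taxon: ``mean(+group reads) − mean(−group reads)``. Expects
    median-normalized absolute reads (taxon × sample). With ``per_site`` the
    subtraction is done within each site and a taxon × site table returned.
    """
    plus_ids, minus_ids = meta.contrast_groups(contrast)
    if not plus_ids or not minus_ids:
        raise ValueError(f"contrast {contrast!r} has an empty group")
    if not per_site:
        return (
            normalized_reads.loc[:, plus_ids].mean(axis=1)
            - normalized_reads.loc[:, minus_ids].mean(axis=1)
        )
    out = {}
    for site, sub in meta.table.groupby("site", sort=True):
        p = [s for s in plus_ids if s in sub.index]
        m = [s for s in minus_ids if s in sub.index]
        if not p or not m:
            raise ValueError(f"site {site!r} has an empty contrast group")
        out[site] = (
            normalized_reads.loc[:, p].mean(axis=1)
            - normalized_reads.loc[:, m].mean(axis=1)
        )
    return pd.DataFrame(out)
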