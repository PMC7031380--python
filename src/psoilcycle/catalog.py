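"""Phosphorus-transformation gene catalog: loading, validation and grouping.

The catalog maps each functional gene symbol to one or more KEGG orthology
(KO) identifiers, assigns it to one of three functional categories

* ``starvation_regulation``     — P-starvation response regulation,
* ``solubilization_mineralization`` — inorganic-P solubilization and
  organic-P mineralization,
* ``uptake_transport``          — P uptake and transport,

and optionally to a subunit/system aggregation group (transporter systems
and the C-P lyase complex) whose member genes are averaged when profiled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = [
    "CATEGORIES",
    "SYSTEM_GROUPS",
    "GeneEntry",
    "GeneCatalog",
    "CatalogFormatError",
    "CatalogValidationError",
    "load_catalog",
    "write_catalog",
    "default_catalog",
    "genes_in_category",
    "aggregation_groups",
]

#: the three functional categories, in report order
CATEGORIES = (
    "starvation_regulation",
    "solubilization_mineralization",
    "uptake_transport",
)

#: expected membership of each aggregation group in the default catalog
SYSTEM_GROUPS = {
    "ugp_transporter": ("ugpB", "ugpA", "ugpE", "ugpC"),
    "phn_transporter": ("phnC", "phnE", "phnD"),
    "pst_transporter": ("pstB", "pstC", "pstA", "pstS"),
    "cp_lyase_subunit": (
        "phnF", "phnG", "phnH", "phnI", "phnJ", "phnK",
        "phnL", "phnM", "phnN", "phnO", "phnP",
    ),
}

_REQUIRED_COLUMNS = ("gene_symbol", "ko_ids", "category", "product", "system_group")

#: number of genes in the packaged scheme
DEFAULT_CATALOG_SIZE = 40


class CatalogFormatError(ValueError):
    """Raised when a catalog file cannot be parsed into the expected columns."""


class CatalogValidationError(ValueError):
    """Raised when a parsed catalog violates a structural invariant."""


@dataclass(frozen=True)
class GeneEntry:
    """A single functional gene in the catalog."""

    gene_symbol: str
    ko_ids: tuple[str, ...]
    category: str
    product: str = ""
    system_group: str | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise CatalogValidationError(
                f"unknown category {self.category!r} for gene {self.gene_symbol!r}; "
                f"expected one of {CATEGORIES}"
            )
        if len(self.ko_ids) == 0:
            raise CatalogValidationError(
                f"gene {self.gene_symbol!r} has no KO identifiers"
            )


@dataclass(frozen=True)
class GeneCatalog:
    """Validated collection of :class:`GeneEntry` rows."""

    entries: tuple[GeneEntry, ...]
    version: str = "default"

    def __post_init__(self) -> None:
        symbols = [e.gene_symbol for e in self.entries]
        if len(symbols) != len(set(symbols)):
            dupes = sorted({s for s in symbols if symbols.count(s) > 1})
            raise CatalogValidationError(f"duplicate gene symbols: {dupes}")
        # system groups must be category-pure
        for group, members in self.system_group_members().items():
            cats = {self[m].category for m in members}
            if len(cats) > 1:
                raise CatalogValidationError(
                    f"system group {group!r} spans multiple categories: {sorted(cats)}"
                )

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, gene_symbol: str) -> GeneEntry:
        for e in self.entries:
            if e.gene_symbol == gene_symbol:
                return e
        raise KeyError(gene_symbol)

    def __contains__(self, gene_symbol: str) -> bool:
        return any(e.gene_symbol == gene_symbol for e in self.entries)

    @property
    def gene_symbols(self) -> list[str]:
        return [e.gene_symbol for e in self.entries]

    def ko_to_gene(self) -> dict[str, str]:
        """Map each KO identifier to the gene symbol claiming it."""
        out: dict[str, str] = {}
        for e in self.entries:
            for ko in e.ko_ids:
                out.setdefault(ko, e.gene_symbol)
        return out

    def system_group_members(self) -> dict[str, list[str]]:
        groups: dict[str, list[str]] = {}
        for e in self.entries:
            if e.system_group:
                groups.setdefault(e.system_group, []).append(e.gene_symbol)
        return groups

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_symbol": [e.gene_symbol for e in self.entries],
                "ko_ids": [",".join(e.ko_ids) for e in self.entries],
                "category": [e.category for e in self.entries],
                "product": [e.product for e in self.entries],
                "system_group": [e.system_group or "none" for e in self.entries],
            }
        )


def _parse_entry(row: pd.Series) -> GeneEntry:
    group = str(row["system_group"]).strip()
    if group in ("", "none", "nan", "None"):
        group_val: str | None = None
    elif group in SYSTEM_GROUPS:
        group_val = group
    else:
        raise CatalogValidationError(
            f"unknown system group {group!r} for gene {row['gene_symbol']!r}"
        )
    kos = tuple(k.strip() for k in str(row["ko_ids"]).split(",") if k.strip())
    return GeneEntry(
        gene_symbol=str(row["gene_symbol"]).strip(),
        ko_ids=kos,
        category=str(row["category"]).strip(),
        product=str(row["product"]).strip(),
        system_group=group_val,
    )


def load_catalog(
    path: str | Path, *, strict_count: bool = False, version: str | None = None
) -> GeneCatalog:
    """Read a gene catalog from a tab-separated file.

    Parameters
    ----------
    path
        TSV with columns ``gene_symbol``, ``ko_ids`` (comma-separated),
        ``category``, ``product``, ``system_group``.
    strict_count
        If true, require exactly :data:`DEFAULT_CATALOG_SIZE` entries
        (the packaged scheme's size).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise CatalogFormatError(f"cannot parse catalog file {path}: {exc}") from exc
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CatalogFormatError(
            f"catalog file {path} is missing required column(s) {missing}"
        )
    entries = tuple(_parse_entry(row) for _, row in df.iterrows())
    if strict_count and len(entries) != DEFAULT_CATALOG_SIZE:
        raise CatalogValidationError(
            f"expected {DEFAULT_CATALOG_SIZE} entries, found {len(entries)}"
        )
    return GeneCatalog(entries=entries, version=version or path.stem)


def write_catalog(catalog: GeneCatalog, path: str | Path) -> None:
    """Write a catalog back to the TSV dialect accepted by :func:`load_catalog`."""
    catalog.to_frame().to_csv(path, sep="\t", index=False)


def default_catalog() -> GeneCatalog:
    """Load the packaged 40-gene P-transformation catalog."""
    ref = resources.files("psoilcycle.data").joinpath("p_gene_catalog.tsv")
    with resources.as_file(ref) as p:
        return load_catalog(p, strict_count=True, version="default")


def genes_in_category(catalog: GeneCatalog, category: str) -> list[str]:
    """All gene symbols in one functional category, in catalog order."""
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}; expected one of {CATEGORIES}")
    return [e.gene_symbol for e in catalog.entries if e.category == category]


def aggregation_groups(catalog: GeneCatalog) -> dict[str, list[str]]:
    """Mapping of system group label to its member gene symbols."""
    return catalog.system_group_members()
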