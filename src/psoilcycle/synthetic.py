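"""Synthetic study generator: KO count tables, taxon tables and soil
covariates with the study design (4 sites × 3 treatments × 3 replicates),
group-level effect multipliers, covariate linkage and overdispersed count
noise. Ground truth for every injected effect is recorded so estimators can
be scored without re-deriving it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import CATEGORIES, GeneCatalog, default_catalog, genes_in_category
from .profiling import KoCountTable, SampleMetadata
from .sem import PathModel

__all__ = [
    "SimulationConfig",
    "SyntheticStudy",
    "simulate_study",
    "simulate_planted_network",
    "simulate_path_data",
]

_DEFAULT_SITES = ("GZ", "JX", "SY", "HB")
#: treatment label -> (p_contrast, n_contrast)
_DEFAULT_TREATMENTS = {
    "CK": ("minusP", "minusN"),
    "N": ("minusP", "plusN"),
    "P": ("plusP", "minusN"),
}
_DEFAULT_TAXA = (
    "Actinobacteria",
    "Alphaproteobacteria",
    "Betaproteobacteria",
    "Gammaproteobacteria",
    "Acidobacteria",
    "Bacilli",
)


@dataclass
class SimulationConfig:
    """Knobs for :func:`simulate_study`.

    ``effect_multipliers`` maps ``(contrast_level, target)`` to a
    multiplicative factor on expected relative abundance, where
    ``contrast_level`` is ``plusN`` or ``plusP`` and ``target`` is a gene
    symbol or a category label. ``couplings`` maps
    ``(covariate, target)`` to a log-linear coefficient applied to the
    mean-centered covariate.
    """

    sites: tuple[str, ...] = _DEFAULT_SITES
    treatments: dict[str, tuple[str, str]] = field(
        default_factory=lambda: dict(_DEFAULT_TREATMENTS)
    )
    n_reps: int = 3
    baseline_abundance: dict[str, float] | None = None  # gene -> percent
    library_size_mean: float = 35e6
    library_scale: float = 1e-3  # desk-scale shrink factor on library size
    library_cv: float = 0.05
    dispersion: float = 50.0  # NB size parameter; larger = less overdispersed
    lognormal_sigma: float = 0.15  # per-gene biological noise on expectations
    effect_multipliers: dict[tuple[str, str], float] = field(default_factory=dict)
    couplings: dict[tuple[str, str], float] = field(default_factory=dict)
    ph_site_baseline: tuple[float, ...] = (5.2, 5.8, 6.4, 7.1)
    ph_shift_plusN: tuple[float, float] = (-1.57, -0.40)  # uniform range
    ph_noise_sd: float = 0.08
    np_ratio_baseline: float = 1.9
    np_shift_plusP: tuple[float, float] = (-1.1, -0.5)
    np_shift_plusN: tuple[float, float] = (0.15, 0.45)
    np_noise_sd: float = 0.08
    taxa: tuple[str, ...] = _DEFAULT_TAXA
    taxon_base_reads: float = 2000.0
    taxon_multipliers: dict[tuple[str, str], float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2")
        if len(self.ph_site_baseline) != len(self.sites):
            raise ValueError("ph_site_baseline length must match sites")
        for key, mult in self.effect_multipliers.items():
            if mult <= 0:
                raise ValueError(f"multiplier for {key} must be > 0")
        for key, mult in self.taxon_multipliers.items():
            if mult <= 0:
                raise ValueError(f"taxon multiplier for {key} must be > 0")
        if self.library_size_mean * self.library_scale < 1:
            raise ValueError("library size collapses to zero; raise library_scale")


@dataclass
class SyntheticStudy:
    """One simulated study plus the ground truth that generated it."""

    ko_table: KoCountTable
    metadata: SampleMetadata
    taxon_table: pd.DataFrame  # taxon × sample, raw reads
    truth: dict


def _default_baselines(catalog: GeneCatalog) -> dict[str, float]:
    # log-spaced baseline percents, 0.004%..0.06%, deterministic in catalog order
    genes = catalog.gene_symbols
    levels = np.exp(np.linspace(np.log(0.004), np.log(0.06), len(genes)))
    return {g: float(v) for g, v in zip(genes, levels)}


def _gene_multiplier(
    gene: str, category: str, level: str,
    multipliers: dict[tuple[str, str], float],
) -> float:
    m = 1.0
    m *= multipliers.get((level, gene), 1.0)
    m *= multipliers.get((level, category), 1.0)
    return m


def simulate_study(
    config: SimulationConfig, catalog: GeneCatalog | None = None
) -> SyntheticStudy:
    """Draw a full synthetic study; deterministic given ``config.seed``.

    Expected gene relative abundance per sample is
    ``baseline × treatment multipliers × exp(Σ coupling × centered covariate)``;
    counts are negative-binomial around expectation × library size after a
    mean-preserving lognormal perturbation.
    """
    catalog = catalog or default_catalog()
    rng = np.random.default_rng(config.seed)
    baselines = config.baseline_abundance or _default_baselines(catalog)
    gene_category = {e.gene_symbol: e.category for e in catalog}
    missing = [g for g in baselines if g not in gene_category]
    if missing:
        raise ValueError(f"baseline genes not in catalog: {missing}")

    # --- design & covariates -------------------------------------------------
    records = []
    for si, site in enumerate(config.sites):
        for treatment, (p_flag, n_flag) in config.treatments.items():
            for rep in range(1, config.n_reps + 1):
                ph = config.ph_site_baseline[si]
                if n_flag == "plusN":
                    ph += rng.uniform(*config.ph_shift_plusN)
                ph += rng.normal(0, config.ph_noise_sd)
                np_ratio = config.np_ratio_baseline
                if p_flag == "plusP":
                    np_ratio += rng.uniform(*config.np_shift_plusP)
                if n_flag == "plusN":
                    np_ratio += rng.uniform(*config.np_shift_plusN)
                np_ratio = max(0.05, np_ratio + rng.normal(0, config.np_noise_sd))
                total_p = 0.6 + (0.5 if p_flag == "plusP" else 0.0) + rng.normal(0, 0.05)
                total_n = total_p * np_ratio
                avail_p = max(
                    1.0,
                    30.0
                    + (90.0 if p_flag == "plusP" else 0.0)
                    - (15.0 if n_flag == "plusN" else 0.0)
                    + rng.normal(0, 5.0),
                )
                mbp = max(
                    1.0,
                    25.0 + (20.0 if p_flag == "plusP" else 0.0) + rng.normal(0, 3.0),
                )
                fractions = {
                    frac: max(
                        0.5,
                        base + (40.0 if p_flag == "plusP" else 0.0) + rng.normal(0, 4.0),
                    )
                    for frac, base in
                    (("Al_P", 40.0), ("Fe_P", 80.0), ("Ca_P", 120.0), ("O_P", 60.0))
                }
                records.append(
                    {
                        "sample_id": f"{site}_{treatment}_{rep}",
                        "site": site,
                        "treatment": treatment,
                        "p_contrast": p_flag,
                        "n_contrast": n_flag,
                        "replicate": rep,
                        "pH": ph,
                        "NP_ratio": np_ratio,
                        "total_N": total_n,
                        "total_P": total_p,
                        "available_P": avail_p,
                        "microbial_biomass_P": mbp,
                        **fractions,
                    }
                )
    meta_df = pd.DataFrame(records).set_index("sample_id")
    metadata = SampleMetadata(table=meta_df)

    # --- expected abundances -------------------------------------------------
    cov_means = {
        c: meta_df[c].mean()
        for c in meta_df.columns
        if c not in ("site", "treatment", "p_contrast", "n_contrast", "replicate")
    }
    n_samples = len(meta_df)
    sample_ids = list(meta_df.index)
    genes = list(baselines)
    expected = np.zeros((len(genes), n_samples))
    for gi, gene in enumerate(genes):
        cat = gene_category[gene]
        for si_, (sid, row) in enumerate(meta_df.iterrows()):
            mult = 1.0
            if row["n_contrast"] == "plusN":
                mult *= _gene_multiplier(gene, cat, "plusN", config.effect_multipliers)
            if row["p_contrast"] == "plusP":
                mult *= _gene_multiplier(gene, cat, "plusP", config.effect_multipliers)
            log_adj = 0.0
            for (cov, target), coef in config.couplings.items():
                if target in (gene, cat):
                    log_adj += coef * (row[cov] - cov_means[cov])
            expected[gi, si_] = baselines[gene] * mult * np.exp(log_adj)

    # --- counts --------------------------------------------------------------
    lib_sizes = rng.normal(
        config.library_size_mean * config.library_scale,
        config.library_size_mean * config.library_scale * config.library_cv,
        size=n_samples,
    )
    lib_sizes = np.maximum(lib_sizes, 100).round()
    sigma = config.lognormal_sigma
    mu = (expected / 100.0) * lib_sizes[None, :]
    if sigma > 0:
        mu = mu * np.exp(rng.normal(0, sigma, size=mu.shape) - sigma**2 / 2.0)
    size = config.dispersion
    counts = rng.negative_binomial(size, size / (size + mu))
    # one KO row per gene: counts are attributed to the gene's first KO id
    ko_of_gene = {e.gene_symbol: e.ko_ids[0] for e in catalog}
    counts_df = pd.DataFrame(
        counts, index=[ko_of_gene[g] for g in genes], columns=sample_ids
    )
    totals = pd.Series(lib_sizes, index=sample_ids, name="total_annotated")
    ko_table = KoCountTable(counts=counts_df.astype(float), total_annotated=totals)

    # --- taxon table ---------------------------------------------------------
    taxon_mu = np.zeros((len(config.taxa), n_samples))
    for ti, taxon in enumerate(config.taxa):
        for si_, (_, row) in enumerate(meta_df.iterrows()):
            mult = 1.0
            if row["n_contrast"] == "plusN":
                mult *= config.taxon_multipliers.get(("plusN", taxon), 1.0)
            if row["p_contrast"] == "plusP":
                mult *= config.taxon_multipliers.get(("plusP", taxon), 1.0)
            taxon_mu[ti, si_] = config.taxon_base_reads * mult * (
                lib_sizes[si_] / lib_sizes.mean()
            )
    taxon_counts = rng.negative_binomial(size, size / (size + taxon_mu))
    taxon_table = pd.DataFrame(taxon_counts, index=list(config.taxa),
                               columns=sample_ids).astype(float)

    truth = {
        "effect_multipliers": {
            f"{lvl}:{tgt}": m for (lvl, tgt), m in config.effect_multipliers.items()
        },
        "couplings": {f"{cov}:{tgt}": c for (cov, tgt), c in config.couplings.items()},
        "taxon_multipliers": {
            f"{lvl}:{tgt}": m for (lvl, tgt), m in config.taxon_multipliers.items()
        },
        "baseline_abundance": dict(baselines),
        "seed": config.seed,
    }
    return SyntheticStudy(
        ko_table=ko_table, metadata=metadata, taxon_table=taxon_table, truth=truth
    )


def simulate_planted_network(
    n_features: int,
    block_spec: list[tuple[int, float]],
    n_samples: int,
    seed: int = 0,
    feature_prefix: str = "F",
    background_rho: float = 0.0,
) -> pd.DataFrame:
    """Latent-factor profile table with planted correlation blocks.

    ``block_spec`` is a list of ``(block_size, target_rho)``; features inside
    a block share a latent factor so their pairwise correlation is about
    ``target_rho``; features across blocks (and outside any block) are
    independent by default. A nonzero ``background_rho`` adds a weak global
    factor so every feature pair correlates at about that level (a dense
    "random" side for threshold-detection fixtures). Returns a
    feature × sample table.
    """
    total_in_blocks = sum(b for b, _ in block_spec)
    if total_in_blocks > n_features:
        raise ValueError("blocks larger than n_features")
    for b, r in block_spec:
        if not 0 < r < 1:
            raise ValueError("target rho must be in (0, 1)")
        if b < 2:
            raise ValueError("block size must be >= 2")
    if not 0 <= background_rho < 1:
        raise ValueError("background_rho must be in [0, 1)")
    if any(r <= background_rho for _, r in block_spec):
        raise ValueError("block rho must exceed background_rho")
    rng = np.random.default_rng(seed)
    x = np.empty((n_features, n_samples))
    g = rng.standard_normal(n_samples)
    bg = np.sqrt(background_rho)
    row = 0
    for b, r in block_spec:
        factor = rng.standard_normal(n_samples)
        lam = np.sqrt(r - background_rho)
        noise = rng.standard_normal((b, n_samples))
        x[row : row + b] = bg * g + lam * factor + np.sqrt(1 - r) * noise
        row += b
    if row < n_features:
        k = n_features - row
        x[row:] = bg * g + np.sqrt(1 - background_rho) * rng.standard_normal(
            (k, n_samples)
        )
    return pd.DataFrame(
        x, index=[f"{feature_prefix}{i:03d}" for i in range(n_features)],
        columns=[f"S{j:03d}" for j in range(n_samples)],
    )


def simulate_path_data(
    model: PathModel,
    coefficients: dict[tuple[str, str], float],
    n: int,
    seed: int = 0,
    binary_exogenous: bool = False,
) -> tuple[pd.DataFrame, dict[tuple[str, str], float]]:
    """Generate data from a recursive path model with unit-variance
    disturbances; returns the table and the implied standardized truth.

    With ``binary_exogenous`` the exogenous variables are balanced 0/1
    indicators instead of standard normals (treatment-style inputs).
    """
    order = model.topological_order()
    if order is None:
        raise ValueError("path model contains a cycle")
    for edge in coefficients:
        if edge not in model.edges:
            raise ValueError(f"coefficient given for non-model edge {edge}")
    rng = np.random.default_rng(seed)
    data: dict[str, np.ndarray] = {}
    for v in order:
        if v in model.exogenous:
            if binary_exogenous:
                vals = np.zeros(n)
                vals[rng.permutation(n)[: n // 2]] = 1.0
            else:
                vals = rng.standard_normal(n)
            data[v] = vals
        else:
            y = rng.standard_normal(n)
            for u in model.parents(v):
                y = y + coefficients.get((u, v), 0.0) * data[u]
            data[v] = y
    frame = pd.DataFrame(data, columns=list(model.variables))

    # implied standardized coefficients via the path covariance algebra
    vars_ = list(model.variables)
    idx = {v: i for i, v in enumerate(vars_)}
    p = len(vars_)
    a = np.zeros((p, p))
    for (u, v), b in coefficients.items():
        a[idx[v], idx[u]] = b
    omega = np.eye(p)
    if binary_exogenous:
        for v in model.exogenous:
            omega[idx[v], idx[v]] = 0.25  # variance of a balanced 0/1 indicator
    inv = np.linalg.inv(np.eye(p) - a)
    sigma = inv @ omega @ inv.T
    sd = np.sqrt(np.diag(sigma))
    truth = {
        (u, v): coefficients.get((u, v), 0.0) * sd[idx[u]] / sd[idx[v]]
        for (u, v) in model.edges
    }
    return frame, truth
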