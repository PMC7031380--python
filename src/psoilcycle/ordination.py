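"""Community-composition statistics: Bray–Curtis dissimilarity, non-metric
multidimensional scaling, ANOSIM and distance-based linear modelling.

ANOSIM and the distance-based linear model (marginal tests, one predictor at
a time on a Gower-centered inner-product matrix) are implemented here with
explicit permutation schemes so every p-value is reproducible from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.spatial.distance
import scipy.stats
from sklearn.manifold import MDS

from .stats import bonferroni

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "AnosimResult",
    "DistlmResult",
    "bray_curtis",
    "nmds",
    "anosim",
    "distlm_marginal",
]


@dataclass
class DistanceMatrix:
    """Symmetric dissimilarity matrix with sample labels."""

    sample_ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.sample_ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match sample ids")
        if not np.allclose(self.d, self.d.T, atol=1e-10):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-10):
            raise ValueError("distance matrix has nonzero diagonal")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.sample_ids, columns=self.sample_ids)


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # samples × k
    stress: float
    converged: bool
    seed: int


@dataclass
class AnosimResult:
    R: float
    p: float
    n_perm: int


@dataclass
class DistlmResult:
    """Marginal distance-based linear model results, one row per predictor."""

    table: pd.DataFrame  # predictor, proportion, pseudo_F, p, p_bonferroni
    n_perm: int


def bray_curtis(profile) -> DistanceMatrix:
    """Bray–Curtis dissimilarity between sample columns of a profile.

    ``d(i,j) = Σ|x_i − x_j| / Σ(x_i + x_j)`` over features; undefined (error)
    if two all-zero samples meet.
    """
    if isinstance(profile, pd.DataFrame):
        values = profile
    elif hasattr(profile, "values") and isinstance(profile.values, pd.DataFrame):
        values = profile.values  # ProfileMatrix
    else:
        values = None
    if values is not None:
        sample_ids = list(values.columns)
        x = values.to_numpy(dtype=float).T  # samples × features
    else:
        x = np.asarray(profile, dtype=float).T
        sample_ids = [f"S{i}" for i in range(x.shape[0])]
    if (x < 0).any():
        raise ValueError("Bray–Curtis requires non-negative abundances")
    zero = ~x.any(axis=1)
    if zero.sum() >= 2:
        raise ValueError("two all-zero samples: Bray–Curtis undefined")
    d = scipy.spatial.distance.squareform(
        scipy.spatial.distance.pdist(x, metric="braycurtis")
    )
    return DistanceMatrix(sample_ids=sample_ids, d=d)


def nmds(
    dm: DistanceMatrix,
    k: int = 2,
    seed: int = 0,
    n_restarts: int = 20,
    max_iter: int = 300,
) -> OrdinationResult:
    """Non-metric MDS minimizing Kruskal stress-1, best of ``n_restarts``
    random starts; deterministic given ``seed``."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if dm.n < k + 2:
        raise ValueError(f"need at least {k + 2} samples for k={k}")
    import inspect

    params = inspect.signature(MDS.__init__).parameters
    kwargs = dict(
        n_components=k,
        n_init=n_restarts,
        max_iter=max_iter,
        random_state=seed,
        normalized_stress=True,  # Kruskal stress-1
        eps=1e-9,
    )
    if "metric_mds" in params:  # scikit-learn >= 1.9 spelling
        kwargs.update(metric_mds=False, metric="precomputed", init="random")
    else:  # pragma: no cover - older scikit-learn
        kwargs.update(metric=False, dissimilarity="precomputed")
    model = MDS(**kwargs)
    coords = model.fit_transform(dm.d)
    coords = coords - coords.mean(axis=0)
    converged = model.n_iter_ < max_iter
    return OrdinationResult(
        coordinates=pd.DataFrame(
            coords, index=dm.sample_ids, columns=[f"NMDS{i + 1}" for i in range(k)]
        ),
        stress=float(model.stress_),
        converged=bool(converged),
        seed=seed,
    )


def _anosim_r(ranks: np.ndarray, within: np.ndarray) -> float:
    m = ranks.size
    return (ranks[~within].mean() - ranks[within].mean()) / (m / 2.0)


def anosim(
    dm: DistanceMatrix,
    groups,
    n_perm: int = 999,
    seed: int = 0,
) -> AnosimResult:
    """ANOSIM R with permutation p-value.

    R = (mean between-group rank − mean within-group rank) / (M/2) over the
    M = n(n−1)/2 ranked pairwise distances; p counts permuted R ≥ observed R
    (ties as exceedances), with the +1 correction.
    """
    groups = np.asarray(groups)
    if len(groups) != dm.n:
        raise ValueError("groups length does not match distance matrix")
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        singles = labels[counts < 2].tolist()
        raise ValueError(f"singleton group(s): {singles}")
    iu = np.triu_indices(dm.n, k=1)
    ranks = scipy.stats.rankdata(dm.d[iu])
    same = groups[iu[0]] == groups[iu[1]]
    r_obs = _anosim_r(ranks, same)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(groups)
        same_p = perm[iu[0]] == perm[iu[1]]
        if _anosim_r(ranks, same_p) >= r_obs - 1e-12:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return AnosimResult(R=float(r_obs), p=float(p), n_perm=n_perm)


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = d.shape[0]
    c = np.eye(n) - np.ones((n, n)) / n
    return c @ a @ c


def _hat(x: np.ndarray) -> np.ndarray:
    q, _ = np.linalg.qr(x)
    return q @ q.T


def distlm_marginal(
    dm: DistanceMatrix,
    predictors: pd.DataFrame | pd.Series,
    n_perm: int = 999,
    seed: int = 0,
) -> DistlmResult:
    """Marginal distance-based linear model: each predictor tested alone.

    The distance matrix is Gower-centered into G; for each predictor the hat
    matrix H of [1, x] gives proportion explained tr(HGH)/tr(G) and
    pseudo-F = [tr(HGH)/m] / [tr((I−H)G(I−H))/(n−m−1)], with a permutation
    p-value (rows of the predictor shuffled) and Bonferroni correction over
    the predictors tested.
    """
    if isinstance(predictors, pd.Series):
        predictors = predictors.to_frame()
    n = dm.n
    if len(predictors) != n:
        raise ValueError("predictor length does not match distance matrix")
    if n < 4:
        raise ValueError("need at least 4 samples")
    g = _gower_center(dm.d)
    trg = np.trace(g)
    if trg <= 0:
        raise ValueError("Gower-centered matrix has non-positive trace")
    rng = np.random.default_rng(seed)
    rows = []
    for name in predictors.columns:
        x = pd.to_numeric(predictors[name], errors="raise").to_numpy(dtype=float)
        if not np.all(np.isfinite(x)):
            raise ValueError(f"predictor {name!r} has non-finite values")
        if np.ptp(x) == 0:
            raise ValueError(f"predictor {name!r} is constant")
        m = 1
        design = np.column_stack([np.ones(n), x])

        def stats_for(xcol: np.ndarray) -> tuple[float, float]:
            h = _hat(np.column_stack([np.ones(n), xcol]))
            ss_fit = np.trace(h @ g @ h)
            ss_res = np.trace((np.eye(n) - h) @ g @ (np.eye(n) - h))
            f = (ss_fit / m) / (ss_res / (n - m - 1))
            return ss_fit / trg, f

        prop, f_obs = stats_for(x)
        exceed = 0
        for _ in range(n_perm):
            _, f_perm = stats_for(rng.permutation(x))
            if f_perm >= f_obs - 1e-12:
                exceed += 1
        p = (1 + exceed) / (1 + n_perm)
        rows.append({"predictor": name, "proportion": prop, "pseudo_F": f_obs, "p": p})
    table = pd.DataFrame(rows)
    table["p_bonferroni"] = bonferroni(table["p"].to_numpy())
    return DistlmResult(table=table, n_perm=n_perm)
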