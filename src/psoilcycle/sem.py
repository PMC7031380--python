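"""Observed-variable path analysis fitted by maximum likelihood.

For a recursive path model with uncorrelated disturbances, per-equation
least squares gives the maximum-likelihood point estimates; the global
discrepancy function evaluated at those estimates yields the model
chi-square, degrees of freedom and RMSEA. The default model wires binary
N/P input indicators through soil pH and N:P ratio to the three functional
gene-category abundances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

__all__ = ["PathModel", "PathFit", "default_path_model", "fit_path_model", "rmsea"]


@dataclass(frozen=True)
class PathModel:
    """Directed acyclic path model over observed variables.

    ``edges`` are (source, target) pairs; ``exogenous`` variables have no
    parents and are allowed to covary freely.
    """

    variables: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    exogenous: tuple[str, ...]

    def __post_init__(self) -> None:
        known = set(self.variables)
        for u, v in self.edges:
            if u not in known or v not in known:
                raise ValueError(f"edge ({u!r}, {v!r}) references undeclared variable")
        for x in self.exogenous:
            if x not in known:
                raise ValueError(f"exogenous variable {x!r} not declared")
        targets = {v for _, v in self.edges}
        if targets & set(self.exogenous):
            bad = sorted(targets & set(self.exogenous))
            raise ValueError(f"exogenous variable(s) with incoming edges: {bad}")
        endo = [v for v in self.variables if v not in self.exogenous]
        orphans = [v for v in endo if v not in targets]
        if orphans:
            raise ValueError(f"endogenous variable(s) without parents: {orphans}")
        if self.topological_order() is None:
            raise ValueError("path model contains a cycle")

    @property
    def endogenous(self) -> tuple[str, ...]:
        return tuple(v for v in self.variables if v not in self.exogenous)

    def parents(self, v: str) -> list[str]:
        return [u for u, w in self.edges if w == v]

    def topological_order(self) -> list[str] | None:
        order: list[str] = []
        placed: set[str] = set()
        pending = list(self.variables)
        while pending:
            progressed = False
            for v in list(pending):
                if all(p in placed for p in self.parents(v)):
                    order.append(v)
                    placed.add(v)
                    pending.remove(v)
                    progressed = True
            if not progressed:
                return None
        return order


@dataclass
class PathFit:
    """Fitted path model: standardized coefficients, fit indices, r²."""

    coefficients: pd.DataFrame  # source, target, estimate, std_estimate, p
    chi_square: float
    df: int
    chi_p: float
    rmsea: float
    r2: dict[str, float]
    n: int

    def std_coefficient(self, source: str, target: str) -> float:
        row = self.coefficients[
            (self.coefficients["source"] == source)
            & (self.coefficients["target"] == target)
        ]
        if row.empty:
            raise KeyError((source, target))
        return float(row["std_estimate"].iloc[0])

    def to_dict(self) -> dict:
        return {
            "coefficients": self.coefficients.to_dict(orient="records"),
            "chi_square": self.chi_square,
            "df": self.df,
            "chi_p": self.chi_p,
            "rmsea": self.rmsea,
            "r2": self.r2,
            "n": self.n,
        }


def default_path_model() -> PathModel:
    """N and P inputs → soil pH and N:P ratio → the three gene categories."""
    cats = (
        "starvation_regulation",
        "solubilization_mineralization",
        "uptake_transport",
    )
    edges = [("N_input", "pH"), ("N_input", "NP_ratio"),
             ("P_input", "pH"), ("P_input", "NP_ratio")]
    edges += [("pH", c) for c in cats] + [("NP_ratio", c) for c in cats]
    return PathModel(
        variables=("N_input", "P_input", "pH", "NP_ratio") + cats,
        edges=tuple(edges),
        exogenous=("N_input", "P_input"),
    )


def rmsea(chi_square: float, df: int, n: int) -> float:
    """Root mean square error of approximation:
    ``sqrt(max(0, χ² − df) / (df × (n − 1)))``."""
    if df < 1:
        raise ValueError("rmsea undefined for df < 1")
    if n < 2:
        raise ValueError("rmsea requires n >= 2")
    return float(np.sqrt(max(0.0, chi_square - df) / (df * (n - 1))))


def _implied_covariance(
    model: PathModel, coef: dict[tuple[str, str], float],
    exo_cov: np.ndarray, resid_var: dict[str, float],
) -> np.ndarray:
    vars_ = list(model.variables)
    idx = {v: i for i, v in enumerate(vars_)}
    p = len(vars_)
    a = np.zeros((p, p))
    for (u, v), b in coef.items():
        a[idx[v], idx[u]] = b
    omega = np.zeros((p, p))
    exo_idx = [idx[v] for v in model.exogenous]
    omega[np.ix_(exo_idx, exo_idx)] = exo_cov
    for v in model.endogenous:
        omega[idx[v], idx[v]] = resid_var[v]
    inv = np.linalg.inv(np.eye(p) - a)
    return inv @ omega @ inv.T


def fit_path_model(data: pd.DataFrame, model: PathModel) -> PathFit:
    """Fit a recursive path model by maximum likelihood.

    Point estimates come from per-equation OLS (the ML solution when
    disturbances are uncorrelated); the ML discrepancy
    ``F = log|Σ(θ)| − log|S| + tr(SΣ(θ)⁻¹) − p`` at the optimum gives
    ``χ² = (n−1)·F`` with ``df = p(p+1)/2 − #free parameters``.
    """
    missing = [v for v in model.variables if v not in data.columns]
    if missing:
        raise ValueError(f"data missing model variable(s) {missing}")
    data = data[list(model.variables)].astype(float)
    if data.isna().any().any():
        raise ValueError("missing values in model variables")
    n, p = len(data), len(model.variables)
    if n <= p:
        raise ValueError(f"need n > {p} observations, got {n}")
    s = np.cov(data.to_numpy(), rowvar=False, ddof=1)
    if np.linalg.matrix_rank(s) < p:
        raise ValueError("singular sample covariance matrix")
    sd = data.std(ddof=1)

    coef: dict[tuple[str, str], float] = {}
    rows = []
    resid_var: dict[str, float] = {}
    r2: dict[str, float] = {}
    for v in model.endogenous:
        parents = model.parents(v)
        x = np.column_stack([np.ones(n)] + [data[u].to_numpy() for u in parents])
        yv = data[v].to_numpy()
        beta, _, _, _ = np.linalg.lstsq(x, yv, rcond=None)
        fitted = x @ beta
        resid = yv - fitted
        dof = n - x.shape[1]
        sigma2 = float(resid @ resid / n)  # ML (not unbiased) residual variance
        resid_var[v] = sigma2
        ss_tot = float(((yv - yv.mean()) ** 2).sum())
        r2[v] = 1.0 - float((resid @ resid)) / ss_tot if ss_tot > 0 else 0.0
        # standard errors from the unbiased residual variance
        s2_hat = float(resid @ resid / dof) if dof > 0 else np.nan
        xtx_inv = np.linalg.inv(x.T @ x)
        for j, u in enumerate(parents, start=1):
            b = float(beta[j])
            se = float(np.sqrt(s2_hat * xtx_inv[j, j])) if dof > 0 else np.nan
            if dof > 0 and se > 0:
                t = b / se
                pval = 2.0 * scipy.stats.t.sf(abs(t), dof)
            else:
                pval = np.nan
            coef[(u, v)] = b
            rows.append(
                {
                    "source": u,
                    "target": v,
                    "estimate": b,
                    "std_estimate": b * sd[u] / sd[v],
                    "p": pval,
                }
            )

    exo_idx = [list(model.variables).index(v) for v in model.exogenous]
    exo_cov = s[np.ix_(exo_idx, exo_idx)] * (n - 1) / n
    sigma = _implied_covariance(model, coef, exo_cov, resid_var)
    s_ml = s * (n - 1) / n  # ML covariance to match the ML discrepancy
    sign_sigma, logdet_sigma = np.linalg.slogdet(sigma)
    sign_s, logdet_s = np.linalg.slogdet(s_ml)
    if sign_sigma <= 0 or sign_s <= 0:
        raise ValueError("non-positive-definite covariance in ML discrepancy")
    f_ml = logdet_sigma - logdet_s + float(np.trace(s_ml @ np.linalg.inv(sigma))) - p
    f_ml = max(0.0, f_ml)
    chi_square = (n - 1) * f_ml
    n_exo = len(model.exogenous)
    n_params = len(model.edges) + n_exo * (n_exo + 1) // 2 + len(model.endogenous)
    df = p * (p + 1) // 2 - n_params
    if df < 0:
        raise ValueError("model has more free parameters than covariance moments")
    chi_p = float(scipy.stats.chi2.sf(chi_square, df)) if df > 0 else 1.0
    rmsea_val = rmsea(chi_square, df, n) if df > 0 else 0.0
    return PathFit(
        coefficients=pd.DataFrame(rows),
        chi_square=float(chi_square),
        df=int(df),
        chi_p=chi_p,
        rmsea=float(rmsea_val),
        r2=r2,
        n=n,
    )
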