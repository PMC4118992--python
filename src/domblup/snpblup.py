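"""SNP-BLUP: per-marker additive and dominance effects via mixed-model equations.

The marker-effect model is the dual of GBLUP: with per-marker additive
variance sigma2_a / s_a and dominance variance sigma2_d / s_w (s_a, s_w the
coding normalization sums), the ridge parameters are

    lambda_a = s_a * sigma2_e / sigma2_a
    lambda_d = s_w * sigma2_e / sigma2_d

and animal predictions Z a_hat (+ W d_hat) from the marker system equal the
GBLUP predictions from the matched G / D1 / D2 system exactly.

Systems are solved either by direct inversion or by a blend of first- and
second-order Jacobi iteration with two relaxation factors (the route that
scales to the combined data, where expected codings make the coefficient
matrix dense).
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from .coding import CodingSet, ResidualStructure
from .reml import ModelSpec, VarianceComponents

__all__ = [
    "MMESystem",
    "SNPEffects",
    "GeneticPredictions",
    "build_mme",
    "solve_direct",
    "solve_jacobi",
    "predict_genetic_values",
    "rank_snp_effects",
]


@dataclass
class MMESystem:
    lhs: np.ndarray
    rhs: np.ndarray
    k: int
    n_intercepts: int
    has_dominance: bool
    intercept_labels: list
    lambda_a: float
    lambda_d: float | None
    spec: ModelSpec

    @property
    def size(self) -> int:
        return self.lhs.shape[0]


@dataclass
class SNPEffects:
    intercepts: dict
    additive: np.ndarray
    dominance: np.ndarray | None
    spec: ModelSpec
    iterations: int = 0


@dataclass
class GeneticPredictions:
    bv: np.ndarray
    dominance_value: np.ndarray
    total: np.ndarray


def _dominance_design(spec: ModelSpec, codings: CodingSet):
    if not spec.has_dominance:
        return None, None
    if spec.dominance_kind == "D1":
        return codings.H, codings.s_h
    return codings.M, codings.s_m


def build_mme(
    spec: ModelSpec,
    codings: CodingSet,
    varcomp: VarianceComponents,
    y,
    resid_struct: ResidualStructure | None = None,
) -> MMESystem:
    """Assemble the marker-effect mixed-model equations.

    Columns are [intercept(s) | Z | W].  Rows are weighted by the inverse
    record residual variance (group variance times multiplier), which for a
    single residual group reduces to the textbook system with
    lambda = s * sigma2_e / sigma2.  MAD3 adds separate intercept columns
    for the SD and SMGS groups.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if codings.n != n:
        raise ValueError("codings and phenotypes disagree on record count")
    if varcomp.sigma2_a <= 0:
        raise ValueError("sigma2_a must be positive: no additive shrinkage defined")

    W, s_w = _dominance_design(spec, codings)
    if spec.has_dominance and varcomp.sigma2_d <= 0:
        raise ValueError("sigma2_d must be positive for a dominance model")

    cols = [np.ones((n, 1))]
    labels = ["mu"]
    if spec.uses_descendants and resid_struct is not None:
        for grp in ("SD", "SMGS"):
            ind = (resid_struct.groups == grp).astype(float)
            if ind.any():
                cols.append(ind[:, None])
                labels.append(f"mu_{grp}")
    n_int = len(labels)

    T = np.hstack(cols + [codings.Z] + ([W] if W is not None else []))

    if resid_struct is None:
        weights = np.full(n, 1.0 / varcomp.sigma2_e)
    else:
        rvar = np.empty(n)
        for grp, dvec in resid_struct.design().items():
            mask = dvec > 0
            rvar[mask] = varcomp.sigma2_e_by_group[grp] * dvec[mask]
        weights = 1.0 / rvar

    lhs = T.T @ (weights[:, None] * T)
    rhs = T.T @ (weights * y)

    k = codings.k
    lam_a = codings.s_a / varcomp.sigma2_a
    idx = np.arange(n_int, n_int + k)
    lhs[idx, idx] += lam_a
    lam_d = None
    if W is not None:
        lam_d = s_w / varcomp.sigma2_d
        idx = np.arange(n_int + k, n_int + 2 * k)
        lhs[idx, idx] += lam_d

    # report lambdas on the conventional scale (times sigma2_e of group C)
    return MMESystem(
        lhs=lhs,
        rhs=rhs,
        k=k,
        n_intercepts=n_int,
        has_dominance=W is not None,
        intercept_labels=labels,
        lambda_a=lam_a * varcomp.sigma2_e,
        lambda_d=None if lam_d is None else lam_d * varcomp.sigma2_e,
        spec=spec,
    )


def _unpack(mme: MMESystem, x: np.ndarray, iterations: int = 0) -> SNPEffects:
    n_int, k = mme.n_intercepts, mme.k
    dom = x[n_int + k : n_int + 2 * k] if mme.has_dominance else None
    return SNPEffects(
        intercepts=dict(zip(mme.intercept_labels, x[:n_int])),
        additive=x[n_int : n_int + k],
        dominance=dom,
        spec=mme.spec,
        iterations=iterations,
    )


def solve_direct(mme: MMESystem) -> SNPEffects:
    """Exact solution of the mixed-model equations."""
    try:
        x = np.linalg.solve(mme.lhs, mme.rhs)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"singular MME left-hand side: {exc}") from exc
    return _unpack(mme, x)


def solve_jacobi(
    mme: MMESystem,
    relaxation_1: float = 0.9,
    relaxation_2: float = 0.1,
    tol: float = 1e-10,
    max_iter: int = 5000,
) -> SNPEffects:
    """Blended first-/second-order Jacobi iteration.

    x_new = x + w1 * D^-1 (rhs - A x) + w2 * (x - x_prev), stopping when the
    relative residual norm drops below ``tol``.  Raises after 10 consecutive
    residual increases (suggesting smaller relaxation factors) or when the
    iteration stalls at ``max_iter``.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    A, b = mme.lhs, mme.rhs
    d = np.diag(A)
    if np.any(d <= 0):
        raise ValueError("nonpositive diagonal in MME; cannot Jacobi-iterate")
    x = np.zeros_like(b)
    x_prev = x.copy()
    bnorm = np.linalg.norm(b)
    if bnorm == 0:
        return _unpack(mme, x)
    prev_res = np.inf
    n_increase = 0
    for it in range(1, max_iter + 1):
        r = b - A @ x
        res = np.linalg.norm(r) / bnorm
        if res < tol:
            return _unpack(mme, x, iterations=it - 1)
        if res > prev_res:
            n_increase += 1
            if n_increase >= 10:
                raise RuntimeError(
                    "Jacobi iteration diverging; try smaller relaxation factors"
                )
        else:
            n_increase = 0
        prev_res = res
        x_new = x + relaxation_1 * (r / d) + relaxation_2 * (x - x_prev)
        x_prev, x = x, x_new
    raise RuntimeError(f"Jacobi iteration did not converge in {max_iter} iterations")


def predict_genetic_values(codings: CodingSet, effects: SNPEffects) -> GeneticPredictions:
    """Per-animal breeding values, dominance values and totals."""
    if effects.additive.shape[0] != codings.k:
        raise ValueError("effect vector length does not match coding SNP count")
    bv = codings.Z @ effects.additive
    if effects.dominance is not None:
        W, _ = _dominance_design(effects.spec, codings)
        dv = W @ effects.dominance
    else:
        dv = np.zeros_like(bv)
    return GeneticPredictions(bv=bv, dominance_value=dv, total=bv + dv)


def rank_snp_effects(
    effects: SNPEffects,
    snp_map: pd.DataFrame,
    by: str = "dominance",
    top: int = 10,
    exclude_chromosomes: tuple = (),
) -> pd.DataFrame:
    """Rank SNPs by absolute effect size.

    ``snp_map`` needs columns snp_id, chromosome, position covering all
    SNPs.  Rows are sorted by |effect| descending with ties broken by
    (chromosome, position); each row also reports the SNP's rank on the
    other effect scale.  ``exclude_chromosomes`` drops whole chromosomes
    (e.g. the major-gene chromosome) before ranking.
    """
    if by not in ("additive", "dominance"):
        raise ValueError("by must be 'additive' or 'dominance'")
    if len(snp_map) != len(effects.additive):
        raise ValueError("SNP map does not cover all SNPs")
    dom = (
        effects.dominance
        if effects.dominance is not None
        else np.zeros_like(effects.additive)
    )
    table = snp_map.copy().reset_index(drop=True)
    table["additive"] = effects.additive
    table["dominance"] = dom

    def _rank(values: pd.Series) -> np.ndarray:
        order = np.lexsort(
            (table["position"].to_numpy(), table["chromosome"].to_numpy(), -np.abs(values))
        )
        ranks = np.empty(len(values), dtype=int)
        ranks[order] = np.arange(1, len(values) + 1)
        return ranks

    table["rank_additive"] = _rank(table["additive"])
    table["rank_dominance"] = _rank(table["dominance"])
    if exclude_chromosomes:
        table = table[~table["chromosome"].isin(exclude_chromosomes)]
    if top > len(table):
        warnings.warn(
            f"requested top {top} but only {len(table)} SNPs available; truncating"
        )
        top = len(table)
    order = np.lexsort(
        (
            table["position"].to_numpy(),
            table["chromosome"].to_numpy(),
            -np.abs(table[by].to_numpy()),
        )
    )
    return table.iloc[order].head(top).reset_index(drop=True)
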