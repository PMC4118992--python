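"""Ten-fold cross-validation of genomic prediction models.

Genotyped animals are partitioned into approximately equal random folds.
For each fold the remaining animals (plus, for MAD3, all descendant-group
records) train the model: variance components are estimated on the training
set (or reused from a full-data fit), SNP effects are solved from the
mixed-model equations, and test animals are predicted.  Accuracy is the
Pearson correlation between predictions (breeding value alone, or total
genetic value = breeding value + dominance value) and phenotypes; model
pairs are compared fold-wise by paired two-sample t-tests on identical test
sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .coding import CodingSet, ResidualStructure, build_relationship_matrix, stack_codings
from .reml import ModelSpec, REMLFit, VarianceComponents, fit_reml
from .snpblup import build_mme, predict_genetic_values, solve_direct

__all__ = [
    "FoldAssignment",
    "CVData",
    "CVResult",
    "make_folds",
    "cross_validate",
    "paired_ttest",
    "subset_coding",
]


@dataclass
class FoldAssignment:
    folds: np.ndarray  # fold index per animal, 1..n_folds
    n_folds: int
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.folds == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.folds != fold)


@dataclass
class CVData:
    """Inputs for cross-validation: genotyped cows plus optional descendants."""

    codings: CodingSet
    y: np.ndarray
    desc_codings: CodingSet | None = None
    desc_y: np.ndarray | None = None
    desc_records: pd.DataFrame | None = None  # group, n_daughters per desc row


@dataclass
class CVResult:
    per_fold: pd.DataFrame  # fold, model, effect_type, split, correlation
    paired_tests: pd.DataFrame
    varcomps: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        """Mean and SD of correlations per model / effect type / split."""
        return (
            self.per_fold.groupby(["model", "effect_type", "split"])["correlation"]
            .agg(["mean", "std"])
            .reset_index()
        )

    def correlations(self, model: str, effect_type: str, split: str = "test") -> np.ndarray:
        sel = self.per_fold[
            (self.per_fold["model"] == model)
            & (self.per_fold["effect_type"] == effect_type)
            & (self.per_fold["split"] == split)
        ].sort_values("fold")
        return sel["correlation"].to_numpy()


def make_folds(n: int, n_folds: int = 10, seed: int = 0) -> FoldAssignment:
    """Random balanced partition: fold sizes differ by at most one."""
    if n < n_folds:
        raise ValueError(f"cannot split {n} animals into {n_folds} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    for i, chunk in enumerate(np.array_split(perm, n_folds), start=1):
        folds[chunk] = i
    return FoldAssignment(folds=folds, n_folds=n_folds, seed=seed)


def subset_coding(codings: CodingSet, idx: np.ndarray) -> CodingSet:
    """Row subset of a coding set (frequencies and sums unchanged)."""
    return CodingSet(
        Z=codings.Z[idx],
        H=codings.H[idx],
        M=codings.M[idx],
        s_a=codings.s_a,
        s_h=codings.s_h,
        s_m=codings.s_m,
        freqs=codings.freqs,
        n_monomorphic=codings.n_monomorphic,
        ids=[codings.ids[i] for i in idx] if codings.ids else [],
    )


def paired_ttest(corr_a, corr_b) -> float:
    """Two-sided paired t-test p-value on fold-wise correlation differences."""
    a = np.asarray(corr_a, dtype=float)
    b = np.asarray(corr_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("correlation vectors must have equal length")
    if a.size < 2:
        raise ValueError("need at least two folds for a paired test")
    d = a - b
    if np.all(d == 0.0):
        return 1.0
    if np.var(d) == 0.0:
        warnings.warn("zero-variance nonzero differences: p-value degenerate at 0")
        return 0.0
    return float(stats.ttest_rel(a, b).pvalue)


def _fit_varcomp(
    spec: ModelSpec, codings: CodingSet, y: np.ndarray,
    X: np.ndarray | None, resid_struct: ResidualStructure | None,
) -> REMLFit:
    G = build_relationship_matrix(codings, "G")
    D = (
        build_relationship_matrix(codings, spec.dominance_kind)
        if spec.has_dominance
        else None
    )
    return fit_reml(spec, y, X=X, G=G, D=D, resid_struct=resid_struct)


def _training_pieces(spec: ModelSpec, data: CVData, train_idx: np.ndarray):
    """Training codings, phenotypes, fixed effects and residual structure."""
    cod = subset_coding(data.codings, train_idx)
    y = data.y[train_idx]
    if spec.uses_descendants and data.desc_codings is not None:
        cod = stack_codings(cod, data.desc_codings)
        y = np.concatenate([y, data.desc_y])
        rec = pd.concat(
            [
                pd.DataFrame({"group": ["C"] * len(train_idx), "n_daughters": 1.0}),
                data.desc_records[["group", "n_daughters"]],
            ],
            ignore_index=True,
        )
        from .coding import build_residual_structure

        resid = build_residual_structure(rec)
        X_cols = [np.ones(len(y))]
        for grp in ("SD", "SMGS"):
            ind = (resid.groups == grp).astype(float)
            if ind.any():
                X_cols.append(ind)
        X = np.column_stack(X_cols)
        return cod, y, X, resid
    return cod, y, None, None


def cross_validate(
    models: list[ModelSpec],
    data: CVData,
    folds: FoldAssignment,
    varcomp_source: str = "refit",
) -> CVResult:
    """Run k-fold cross-validation for each model on identical test sets.

    ``varcomp_source``: "refit" re-estimates variance components on each
    training fold (the stricter protocol, default); "full" estimates them
    once per model on the complete data and reuses them in every fold.
    """
    if varcomp_source not in ("refit", "full"):
        raise ValueError("varcomp_source must be 'refit' or 'full'")
    n = data.y.shape[0]
    for f in range(1, folds.n_folds + 1):
        if folds.test_indices(f).size < 2:
            raise ValueError(f"fold {f} has fewer than 2 test animals")

    # duplicate model names get a #2, #3 ... suffix so results stay separable
    labels, seen = [], {}
    for spec in models:
        seen[spec.model] = seen.get(spec.model, 0) + 1
        labels.append(
            spec.model if seen[spec.model] == 1 else f"{spec.model}#{seen[spec.model]}"
        )

    full_fits: dict[str, REMLFit] = {}
    if varcomp_source == "full":
        for label, spec in zip(labels, models):
            cod, y, X, resid = _training_pieces(spec, data, np.arange(n))
            full_fits[label] = _fit_varcomp(spec, cod, y, X, resid)

    rows = []
    varcomps: dict[str, list] = {label: [] for label in labels}
    for label, spec in zip(labels, models):
        for f in range(1, folds.n_folds + 1):
            train_idx = folds.train_indices(f)
            test_idx = folds.test_indices(f)
            cod, y_tr, X, resid = _training_pieces(spec, data, train_idx)
            if varcomp_source == "full":
                vc = full_fits[label].estimates
            else:
                vc = _fit_varcomp(spec, cod, y_tr, X, resid).estimates
            vc = _positive_floor(vc, spec, float(np.var(y_tr, ddof=1)))
            varcomps[label].append(vc)
            mme = build_mme(spec, cod, vc, y_tr, resid_struct=resid)
            effects = solve_direct(mme)
            preds = predict_genetic_values(data.codings, effects)
            for split, idx in (("train", train_idx), ("test", test_idx)):
                yv = data.y[idx]
                pairs = [("additive", preds.bv[idx])]
                if spec.has_dominance:
                    pairs.append(("additive+dominance", preds.total[idx]))
                for effect_type, pred in pairs:
                    rows.append(
                        {
                            "fold": f,
                            "model": label,
                            "effect_type": effect_type,
                            "split": split,
                            "correlation": float(np.corrcoef(yv, pred)[0, 1]),
                        }
                    )
    per_fold = pd.DataFrame(rows)

    result = CVResult(per_fold=per_fold, paired_tests=pd.DataFrame(), varcomps=varcomps)
    tests = []
    base = labels[0]
    base_corr = result.correlations(base, "additive")
    for label in labels[1:]:
        for effect_type in ("additive", "additive+dominance"):
            other = result.correlations(label, effect_type)
            if other.size == 0:
                continue
            tests.append(
                {
                    "model_a": base,
                    "model_b": label,
                    "effect_type": effect_type,
                    "p_value": paired_ttest(base_corr, other),
                }
            )
    result.paired_tests = pd.DataFrame(tests)
    return result


def _positive_floor(
    vc: VarianceComponents, spec: ModelSpec, vary: float
) -> VarianceComponents:
    """Keep shrinkage defined when a REML estimate sits on the zero boundary."""
    floor = 1e-6 * vary
    return VarianceComponents(
        sigma2_a=max(vc.sigma2_a, floor),
        sigma2_d=max(vc.sigma2_d, floor) if spec.has_dominance else 0.0,
        sigma2_e_by_group={g: max(v, floor) for g, v in vc.sigma2_e_by_group.items()},
    )
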