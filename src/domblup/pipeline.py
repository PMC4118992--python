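"""End-to-end pipeline driver: simulate -> prep -> varcomp -> SNP effects -> CV.

Every artifact is a TSV/JSON file stamped with the configuration hash and
seed, so a rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dio
from .coding import (
    build_relationship_matrix,
    build_residual_structure,
    compute_codings,
    estimate_allele_frequencies,
    genotype_probs_from_sire_dam,
    genotype_probs_from_sire_mgs,
    GenotypeProbabilityMatrix,
)
from .crossval import CVData, cross_validate, make_folds
from .pheno import DEFAULT_COEFFICIENTS, adjust_phenotype
from .reml import ModelSpec, fit_reml, heritabilities, likelihood_ratio_test
from .simulate import SimConfig, simulate_population
from .snpblup import build_mme, rank_snp_effects, solve_direct, solve_jacobi

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    output_dir: str = "domblup_out"
    seed: int = 0
    trait: str = "milk"
    models: list[str] = field(default_factory=lambda: ["MA", "MAD"])
    simulate: dict | None = None  # SimConfig fields; None = read input files
    genotypes: str | None = None
    phenotypes: str | None = None
    snp_map: str | None = None
    adjust_inbreeding_heterosis: bool = False
    solver: str = "direct"
    omega1: float = 0.9
    omega2: float = 0.1
    solver_tol: float = 1e-10
    top: int = 10
    exclude_chromosomes: list = field(default_factory=list)
    n_folds: int = 10
    varcomp_source: str = "refit"
    run_cv: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**d)

    def hash(self) -> str:
        # hash the scientific configuration only, not where it is written
        payload = dataclasses.asdict(self)
        payload.pop("output_dir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


def _expected_desc_codings(records: pd.DataFrame, geno, freqs):
    """Expected codings for SD / SMGS records from their ancestors' codes."""
    idx = {a: i for i, a in enumerate(geno.ids)}
    probs = np.empty((len(records), geno.k, 3))
    for r, row in enumerate(records.itertuples(index=False)):
        sire = geno.codes[idx[row.sire]]
        if row.group == "SD":
            probs[r] = genotype_probs_from_sire_dam(sire, geno.codes[idx[row.dam]])
        else:
            mgs = geno.codes[idx[row.mgs]]
            probs[r] = genotype_probs_from_sire_mgs(sire, mgs, freqs.q)
    gpm = GenotypeProbabilityMatrix(ids=list(records["id"]), probs=probs)
    return compute_codings(gpm, freqs)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages; returns the report dict written to disk."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.hash(), "seed": config.seed}

    # --- inputs (simulated or read) ----------------------------------------
    if config.simulate is not None:
        sim = SimConfig(seed=config.seed, **config.simulate)
        pop = simulate_population(sim)
        geno = pop.genotypes
        pheno = pop.phenotype_frame()
        dio.write_genotypes_tsv(geno, out / "genotypes.tsv")
        dio.write_phenotypes_tsv(pheno, out / "phenotypes.tsv")
        truth = pd.DataFrame(
            {
                "id": geno.ids,
                "true_bv": pop.true_bv,
                "true_dominance_value": pop.true_dominance_values,
            }
        )
        truth.to_csv(out / "truth.tsv", sep="\t", index=False, float_format="%.17g")
        snp_map = pd.DataFrame(
            {
                "snp_id": [f"snp{j}" for j in range(geno.k)],
                "chromosome": 1 + np.arange(geno.k) % 29,
                "position": 1 + np.arange(geno.k),
            }
        )
    else:
        if config.genotypes is None or config.phenotypes is None:
            raise FileNotFoundError("genotypes and phenotypes paths are required")
        geno = dio.read_genotypes(config.genotypes)
        pheno = dio.read_phenotypes(config.phenotypes)
        snp_map = (
            dio.read_snp_map(config.snp_map)
            if config.snp_map
            else pd.DataFrame(
                {
                    "snp_id": [f"snp{j}" for j in range(geno.k)],
                    "chromosome": 1,
                    "position": 1 + np.arange(geno.k),
                }
            )
        )

    # --- prep ----------------------------------------------------------------
    if config.adjust_inbreeding_heterosis:
        coeffs = DEFAULT_COEFFICIENTS[config.trait]
        pheno = pheno.copy()
        pheno["phenotype"] = adjust_phenotype(
            pheno["phenotype"],
            pheno.get("inbreeding", 0.0),
            pheno.get("heterosis", 0.0),
            coeffs,
        )

    cows = pheno[pheno["group"] == "C"].reset_index(drop=True)
    desc = pheno[pheno["group"] != "C"].reset_index(drop=True)
    order = {a: i for i, a in enumerate(geno.ids)}
    cows = cows.sort_values("id", key=lambda s: s.map(order)).reset_index(drop=True)
    y_c = cows["phenotype"].to_numpy(dtype=float)

    freqs = estimate_allele_frequencies(geno)
    codings = compute_codings(geno, freqs)
    desc_codings = None
    if len(desc) and any(ModelSpec(m).uses_descendants for m in config.models):
        desc_codings = _expected_desc_codings(desc, geno, freqs)

    # --- variance components -------------------------------------------------
    fits = {}
    report_vc = {}
    for name in config.models:
        spec = ModelSpec(name)
        if spec.uses_descendants and desc_codings is not None:
            from .crossval import subset_coding  # noqa: F401  (same helpers)
            from .coding import stack_codings

            cod = stack_codings(codings, desc_codings)
            y = np.concatenate([y_c, desc["phenotype"].to_numpy(dtype=float)])
            rec = pd.concat(
                [
                    pd.DataFrame({"group": ["C"] * len(y_c), "n_daughters": 1.0}),
                    desc[["group", "n_daughters"]],
                ],
                ignore_index=True,
            )
            resid = build_residual_structure(rec)
            X_cols = [np.ones(len(y))]
            for grp in ("SD", "SMGS"):
                ind = (resid.groups == grp).astype(float)
                if ind.any():
                    X_cols.append(ind)
            X = np.column_stack(X_cols)
        else:
            cod, y, X, resid = codings, y_c, None, None
        G = build_relationship_matrix(cod, "G")
        D = (
            build_relationship_matrix(cod, spec.dominance_kind)
            if spec.has_dominance
            else None
        )
        fit = fit_reml(spec, y, X=X, G=G, D=D, resid_struct=resid)
        fits[name] = (fit, cod, y, resid)
        h2a, h2d = heritabilities(fit.estimates, spec)
        report_vc[name] = {
            "sigma2_a": fit.estimates.sigma2_a,
            "sigma2_d": fit.estimates.sigma2_d,
            "sigma2_e": fit.estimates.sigma2_e_by_group,
            "h2_additive": h2a,
            "h2_dominance": h2d,
            "minus2_loglik": fit.minus2_loglik,
            "converged": fit.converged,
            "iterations": fit.iterations,
        }

    lrt = {}
    if "MA" in fits:
        for alt in ("MAD", "MAD2"):
            if alt in fits:
                res = likelihood_ratio_test(fits["MA"][0], fits[alt][0])
                lrt[f"MA_vs_{alt}"] = {"delta": res.delta, "p_value": res.p_value}

    # --- SNP effects -----------------------------------------------------------
    for name, (fit, cod, y, resid) in fits.items():
        spec = ModelSpec(name)
        est = fit.estimates
        if est.sigma2_a <= 0 or (spec.has_dominance and est.sigma2_d <= 0):
            logger.warning("skipping SNP effects for %s: boundary variance", name)
            continue
        mme = build_mme(spec, cod, est, y, resid_struct=resid)
        if config.solver == "jacobi" or (spec.uses_descendants and config.solver == "auto"):
            effects = solve_jacobi(
                mme, config.omega1, config.omega2, tol=config.solver_tol
            )
        else:
            effects = solve_direct(mme)
        ranked = rank_snp_effects(
            effects,
            snp_map,
            by="dominance" if spec.has_dominance else "additive",
            top=config.top,
            exclude_chromosomes=tuple(config.exclude_chromosomes),
        )
        dio.write_snp_effects_tsv(ranked, out / f"snp_effects_{name}.tsv")

    # --- cross-validation ------------------------------------------------------
    cv_summary = None
    if config.run_cv:
        folds = make_folds(len(y_c), config.n_folds, seed=config.seed)
        data = CVData(
            codings=codings,
            y=y_c,
            desc_codings=desc_codings,
            desc_y=desc["phenotype"].to_numpy(dtype=float) if len(desc) else None,
            desc_records=desc if len(desc) else None,
        )
        cv = cross_validate(
            [ModelSpec(m) for m in config.models],
            data,
            folds,
            varcomp_source=config.varcomp_source,
        )
        cv.summary().to_csv(out / "cv_summary.tsv", sep="\t", index=False,
                            float_format="%.17g")
        cv.paired_tests.to_csv(out / "cv_pvalues.tsv", sep="\t", index=False,
                               float_format="%.17g")
        cv_summary = cv.summary().to_dict(orient="records")

    report = {
        **stamp,
        "trait": config.trait,
        "variance_components": report_vc,
        "likelihood_ratio_tests": lrt,
        "cv_summary": cv_summary,
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
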