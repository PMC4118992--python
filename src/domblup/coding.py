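"""Genotype algebra for additive + dominance genomic evaluation.

Genotypes are coded 0/1/2 as the count of the second allele (B) at each
biallelic SNP.  Three coefficient schemes are derived from the codes and the
population allele frequencies ``p`` (of B) and ``q = 1 - p``:

``Z`` (additive)
    code minus ``2p`` — the usual centered genotype matrix.
``H`` (dominance value)
    ``1 - 2pq`` for heterozygotes, ``-2pq`` for either homozygote; models
    dominance as a genotypic value of the heterozygote.
``M`` (dominance deviation)
    ``-2p^2`` / ``2pq`` / ``-2q^2`` for codes 0/1/2; the statistically
    orthogonal dominance deviation — at Hardy-Weinberg equilibrium each
    column of ``M`` has zero mean and zero covariance with the matching
    column of ``Z``.

Genomic relationship matrices are normalized so that their expected diagonal
is 1 at HWE:

    G  = Z Z' / sum_i 2 p_i q_i
    D1 = H H' / sum_i 2 p_i q_i (1 - 2 p_i q_i)
    D2 = M M' / sum_i (2 p_i q_i)^2

Ungenotyped animals enter through per-SNP genotype probability triples
(P0, P1, P2) derived from genotyped ancestors (sire-dam or sire-MGS), and
are coded by linear expectation of the same coefficient schemes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "AlleleFrequencies",
    "GenotypeProbabilityMatrix",
    "CodingSet",
    "RelationshipMatrix",
    "ResidualStructure",
    "estimate_allele_frequencies",
    "compute_codings",
    "stack_codings",
    "genotype_probs_from_sire_dam",
    "genotype_probs_from_sire_mgs",
    "build_relationship_matrix",
    "build_residual_structure",
]

_VALID_CODES = frozenset((0, 1, 2))


@dataclass
class GenotypeMatrix:
    """n x k matrix of exact genotype codes (count of allele B)."""

    ids: list
    codes: np.ndarray

    def __post_init__(self):
        self.codes = np.asarray(self.codes)
        if self.codes.ndim != 2 or self.codes.shape[1] < 1:
            raise ValueError("genotype matrix must be 2-D with at least one SNP")
        if len(self.ids) != self.codes.shape[0]:
            raise ValueError("number of ids does not match number of rows")
        bad = ~np.isin(self.codes, (0, 1, 2))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid genotype code {self.codes[i, j]} at animal row {i}, SNP column {j}"
            )
        self.codes = self.codes.astype(np.int8)

    @property
    def n(self) -> int:
        return self.codes.shape[0]

    @property
    def k(self) -> int:
        return self.codes.shape[1]


@dataclass
class AlleleFrequencies:
    """Per-SNP frequency of the counted allele B."""

    p: np.ndarray

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        if self.p.ndim != 1:
            raise ValueError("allele frequencies must be a vector")
        if np.any(self.p < 0) or np.any(self.p > 1):
            raise ValueError("allele frequencies must lie in [0, 1]")

    @property
    def q(self) -> np.ndarray:
        return 1.0 - self.p

    @property
    def k(self) -> int:
        return self.p.shape[0]


@dataclass
class GenotypeProbabilityMatrix:
    """n x k x 3 array of genotype probability triples (P0, P1, P2)."""

    ids: list
    probs: np.ndarray

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 3 or self.probs.shape[2] != 3:
            raise ValueError("probability array must have shape (n, k, 3)")
        if len(self.ids) != self.probs.shape[0]:
            raise ValueError("number of ids does not match number of rows")
        if np.any(self.probs < -1e-12):
            raise ValueError("negative genotype probability")
        sums = self.probs.sum(axis=2)
        if np.any(np.abs(sums - 1.0) > 1e-12):
            raise ValueError("genotype probability triples must sum to 1")

    @property
    def n(self) -> int:
        return self.probs.shape[0]

    @property
    def k(self) -> int:
        return self.probs.shape[1]


@dataclass
class CodingSet:
    """Additive / dominance coefficient matrices and their normalizations.

    ``s_a``, ``s_h``, ``s_m`` depend only on the allele frequencies and are
    the denominators of G, D1, D2 respectively.
    """

    Z: np.ndarray
    H: np.ndarray
    M: np.ndarray
    s_a: float
    s_h: float
    s_m: float
    freqs: AlleleFrequencies
    n_monomorphic: int = 0
    ids: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.Z.shape[0]

    @property
    def k(self) -> int:
        return self.Z.shape[1]


@dataclass
class RelationshipMatrix:
    values: np.ndarray
    kind: str  # "G", "D1" or "D2"

    def __post_init__(self):
        if self.kind not in ("G", "D1", "D2"):
            raise ValueError(f"unknown relationship-matrix kind {self.kind!r}")
        if np.max(np.abs(self.values - self.values.T)) > 1e-10:
            raise ValueError("relationship matrix is not symmetric")


@dataclass
class ResidualStructure:
    """Per-record residual variance structure.

    Each record belongs to a group C (genotyped cow), SD (sire-dam genotype
    probabilities) or SMGS (sire-MGS daughter-group mean).  The residual
    variance of a record is the group's variance parameter times the
    record's multiplier; the multiplier is 1 except for SMGS group means,
    whose residual is an average of N daughter residuals and so carries 1/N.
    """

    groups: np.ndarray
    n_daughters: np.ndarray
    multipliers: np.ndarray

    @property
    def group_labels(self) -> list:
        out = []
        for g in ("C", "SD", "SMGS"):
            if np.any(self.groups == g):
                out.append(g)
        return out

    def design(self) -> dict:
        """Per-group diagonal of R (multiplier on that group's variance)."""
        return {
            g: np.where(self.groups == g, self.multipliers, 0.0)
            for g in self.group_labels
        }


def estimate_allele_frequencies(genotypes: GenotypeMatrix) -> AlleleFrequencies:
    """Observed B-allele frequency per SNP: column code sum over 2n."""
    if genotypes.n == 0:
        raise ValueError("cannot estimate allele frequencies from an empty matrix")
    p = genotypes.codes.sum(axis=0, dtype=float) / (2.0 * genotypes.n)
    return AlleleFrequencies(p)


def _normalization_sums(freqs: AlleleFrequencies) -> tuple[float, float, float]:
    pq2 = 2.0 * freqs.p * freqs.q
    s_a = float(pq2.sum())
    s_h = float((pq2 * (1.0 - pq2)).sum())
    s_m = float((pq2**2).sum())
    return s_a, s_h, s_m


def compute_codings(
    genotypes: GenotypeMatrix | GenotypeProbabilityMatrix,
    freqs: AlleleFrequencies,
) -> CodingSet:
    """Build the Z / H / M coefficient matrices.

    Exact codes use the three schemes directly; probability triples use the
    expected coefficients, e.g. E[z] = P1 + 2 P2 - 2p.  Monomorphic SNPs
    (p in {0, 1}) contribute zero coefficients and drop out of the
    normalization sums; their count is logged.
    """
    if genotypes.k != freqs.k:
        raise ValueError(
            f"frequency vector length {freqs.k} does not match SNP count {genotypes.k}"
        )
    p, q = freqs.p, freqs.q
    pq2 = 2.0 * p * q

    if isinstance(genotypes, GenotypeMatrix):
        codes = genotypes.codes
        Z = codes - 2.0 * p
        H = (codes == 1).astype(float) - pq2
        M = np.where(
            codes == 0, -2.0 * p**2, np.where(codes == 1, pq2, -2.0 * q**2)
        )
    elif isinstance(genotypes, GenotypeProbabilityMatrix):
        P0 = genotypes.probs[:, :, 0]
        P1 = genotypes.probs[:, :, 1]
        P2 = genotypes.probs[:, :, 2]
        Z = P1 + 2.0 * P2 - 2.0 * p
        H = P1 - pq2
        M = P0 * (-2.0 * p**2) + P1 * pq2 + P2 * (-2.0 * q**2)
    else:
        raise TypeError(f"unsupported genotype container {type(genotypes)!r}")

    mono = (p <= 0.0) | (p >= 1.0)
    n_mono = int(mono.sum())
    if n_mono:
        logger.info("excluding %d monomorphic SNPs from codings", n_mono)
        Z = np.where(mono, 0.0, Z)
        H = np.where(mono, 0.0, H)
        M = np.where(mono, 0.0, M)

    s_a, s_h, s_m = _normalization_sums(freqs)
    return CodingSet(
        Z=Z, H=H, M=M, s_a=s_a, s_h=s_h, s_m=s_m,
        freqs=freqs, n_monomorphic=n_mono, ids=list(genotypes.ids),
    )


def stack_codings(*codings: CodingSet) -> CodingSet:
    """Vertically stack coding sets built against the same frequencies."""
    first = codings[0]
    for c in codings[1:]:
        if c.k != first.k or not np.allclose(c.freqs.p, first.freqs.p):
            raise ValueError("coding sets were built against different frequencies")
    return CodingSet(
        Z=np.vstack([c.Z for c in codings]),
        H=np.vstack([c.H for c in codings]),
        M=np.vstack([c.M for c in codings]),
        s_a=first.s_a, s_h=first.s_h, s_m=first.s_m,
        freqs=first.freqs,
        n_monomorphic=first.n_monomorphic,
        ids=[i for c in codings for i in c.ids],
    )


def _check_codes(*code_arrays) -> list[np.ndarray]:
    out = []
    for c in code_arrays:
        a = np.asarray(c)
        if not np.isin(a, (0, 1, 2)).all():
            raise ValueError("genotype codes must be 0, 1 or 2")
        out.append(a.astype(float))
    return out


def genotype_probs_from_sire_dam(sire_code, dam_code) -> np.ndarray:
    """Mendelian genotype probability triple from two genotyped parents.

    Each parent transmits allele A with probability (2 - code)/2.  Accepts
    scalars or broadcastable arrays; returns an array with a trailing axis
    of length 3 holding (P0, P1, P2).
    """
    s, d = _check_codes(sire_code, dam_code)
    pa_s = (2.0 - s) / 2.0
    pa_d = (2.0 - d) / 2.0
    p0 = pa_s * pa_d
    p1 = pa_s * (1.0 - pa_d) + (1.0 - pa_s) * pa_d
    p2 = (1.0 - pa_s) * (1.0 - pa_d)
    return np.stack([p0, p1, p2], axis=-1)


def genotype_probs_from_sire_mgs(sire_code, mgs_code, q) -> np.ndarray:
    """Genotype probability triple from genotyped sire and maternal grandsire.

    The dam is ungenotyped: the allele she passes on comes from the MGS with
    probability 1/2 and from the population (allele A with frequency ``q``)
    otherwise, so the dam path transmits A with probability
    ``0.5 * (2 - mgs_code)/2 + 0.5 * q``.
    """
    q = np.asarray(q, dtype=float)
    if np.any(q < 0) or np.any(q > 1):
        raise ValueError("population frequency q must lie in [0, 1]")
    s, m = _check_codes(sire_code, mgs_code)
    pa_s = (2.0 - s) / 2.0
    pa_dampath = 0.5 * (2.0 - m) / 2.0 + 0.5 * q
    p0 = pa_s * pa_dampath
    p1 = pa_s * (1.0 - pa_dampath) + (1.0 - pa_s) * pa_dampath
    p2 = (1.0 - pa_s) * (1.0 - pa_dampath)
    return np.stack([p0, p1, p2], axis=-1)


def build_relationship_matrix(coding: CodingSet, kind: str) -> RelationshipMatrix:
    """G = ZZ'/s_a, D1 = HH'/s_h or D2 = MM'/s_m."""
    mat, s = {
        "G": (coding.Z, coding.s_a),
        "D1": (coding.H, coding.s_h),
        "D2": (coding.M, coding.s_m),
    }.get(kind, (None, None))
    if mat is None:
        raise ValueError(f"unknown relationship-matrix kind {kind!r}")
    if s <= 0.0:
        raise ValueError(
            f"normalization sum for {kind} is zero (all SNPs monomorphic?)"
        )
    values = mat @ mat.T / s
    values = 0.5 * (values + values.T)
    return RelationshipMatrix(values=values, kind=kind)


def build_residual_structure(records: pd.DataFrame) -> ResidualStructure:
    """Residual structure from phenotype records.

    ``records`` needs columns ``group`` (C / SD / SMGS) and, for SMGS rows,
    ``n_daughters``.  C and SD records get multiplier 1 on their group's
    residual variance; an SMGS group mean of N daughters gets 1/N.
    """
    groups = records["group"].to_numpy(dtype=object)
    unknown = set(groups) - {"C", "SD", "SMGS"}
    if unknown:
        raise ValueError(f"unknown residual group labels {sorted(unknown)}")
    n = np.ones(len(records), dtype=float)
    if "n_daughters" in records.columns:
        nd = records["n_daughters"].to_numpy(dtype=float)
        is_smgs = groups == "SMGS"
        if np.any(is_smgs & ~np.isfinite(nd)):
            raise ValueError("SMGS record is missing its daughter count N")
        n[is_smgs] = nd[is_smgs]
    elif "SMGS" in groups:
        raise ValueError("SMGS records require an n_daughters column")
    if np.any(n < 1):
        raise ValueError("daughter counts must be >= 1")
    multipliers = np.where(groups == "SMGS", 1.0 / n, 1.0)
    return ResidualStructure(
        groups=np.asarray(groups, dtype=object),
        n_daughters=n,
        multipliers=multipliers,
    )
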