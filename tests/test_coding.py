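import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import domblup as db
from domblup.coding import GenotypeMatrix, GenotypeProbabilityMatrix


# ---------------------------------------------------------------- frequencies


@pytest.mark.parametrize(
    "column, expected",
    [([0, 0, 0], 0.0), ([0, 1, 2], 0.5), ([2, 2, 1, 1], 0.75)],
)
def test_allele_frequency_counts_b_alleles(column, expected):
    g = GenotypeMatrix(ids=[str(i) for i in range(len(column))],
                       codes=np.array(column)[:, None])
    assert db.estimate_allele_frequencies(g).p[0] == pytest.approx(expected)


def test_invalid_genotype_code_rejected():
    with pytest.raises(ValueError, match="invalid genotype code"):
        GenotypeMatrix(ids=["a", "b"], codes=np.array([[0], [3]]))


# ------------------------------------------------------------------- codings


def test_coding_values_at_half_frequency():
    g = GenotypeMatrix(ids=["a", "b", "c"], codes=np.array([[1], [0], [2]]))
    cs = db.compute_codings(g, db.AlleleFrequencies([0.5]))
    # heterozygote: z = 0, h = 1 - 2pq = 0.5, m = 2pq = 0.5
    assert cs.Z[0, 0] == pytest.approx(0.0)
    assert cs.H[0, 0] == pytest.approx(0.5)
    assert cs.M[0, 0] == pytest.approx(0.5)
    # homozygote code 0: m = -2 p^2 = -0.5 (zero mean/covariance with z at HWE)
    assert cs.M[1, 0] == pytest.approx(-0.5)
    assert cs.M[2, 0] == pytest.approx(-0.5)
    # single SNP at p = 0.5: s_a = 0.5, s_h = 0.25, s_m = 0.25
    assert (cs.s_a, cs.s_h, cs.s_m) == pytest.approx((0.5, 0.25, 0.25))


def test_expected_codings_of_hwe_triple_are_zero():
    probs = np.array([[[0.25, 0.5, 0.25]]])
    gpm = GenotypeProbabilityMatrix(ids=["x"], probs=probs)
    cs = db.compute_codings(gpm, db.AlleleFrequencies([0.5]))
    assert cs.Z[0, 0] == pytest.approx(0.0, abs=1e-15)
    assert cs.H[0, 0] == pytest.approx(0.0, abs=1e-15)
    assert cs.M[0, 0] == pytest.approx(0.0, abs=1e-15)


def test_coding_frequency_length_mismatch():
    g = GenotypeMatrix(ids=["a"], codes=np.array([[0, 1]]))
    with pytest.raises(ValueError, match="does not match"):
        db.compute_codings(g, db.AlleleFrequencies([0.5]))


@given(
    code=st.integers(0, 2),
    p=st.floats(0.01, 0.99),
)
@settings(deadline=None, max_examples=50)
def test_degenerate_probability_triple_reproduces_exact_coding(code, p):
    """A probability triple with one entry = 1 must code like the exact genotype."""
    g = GenotypeMatrix(ids=["a"], codes=np.array([[code]]))
    triple = np.zeros((1, 1, 3))
    triple[0, 0, code] = 1.0
    gpm = GenotypeProbabilityMatrix(ids=["a"], probs=triple)
    freqs = db.AlleleFrequencies([p])
    exact = db.compute_codings(g, freqs)
    expect = db.compute_codings(gpm, freqs)
    assert expect.Z[0, 0] == pytest.approx(exact.Z[0, 0], abs=1e-12)
    assert expect.H[0, 0] == pytest.approx(exact.H[0, 0], abs=1e-12)
    assert expect.M[0, 0] == pytest.approx(exact.M[0, 0], abs=1e-12)


# ------------------------------------------------------- genotype probabilities


@pytest.mark.parametrize(
    "sire, dam, expected",
    [
        (0, 0, (1.0, 0.0, 0.0)),
        (1, 1, (0.25, 0.5, 0.25)),
        (1, 2, (0.0, 0.5, 0.5)),
        (2, 2, (0.0, 0.0, 1.0)),
    ],
)
def test_sire_dam_probabilities(sire, dam, expected):
    assert db.genotype_probs_from_sire_dam(sire, dam) == pytest.approx(expected)


@pytest.mark.parametrize(
    "sire, mgs, q, expected",
    [
        (2, 2, 0.0, (0.0, 0.0, 1.0)),  # no A allele anywhere
        (0, 0, 0.0, (0.5, 0.5, 0.0)),  # dam path passes A only via the MGS half
        (1, 1, 0.5, (0.25, 0.5, 0.25)),
    ],
)
def test_sire_mgs_probabilities(sire, mgs, q, expected):
    assert db.genotype_probs_from_sire_mgs(sire, mgs, q) == pytest.approx(expected)


def test_probability_inputs_validated():
    with pytest.raises(ValueError):
        db.genotype_probs_from_sire_dam(3, 0)
    with pytest.raises(ValueError):
        db.genotype_probs_from_sire_mgs(1, 1, 1.5)


@given(s=st.integers(0, 2), d=st.integers(0, 2), q=st.floats(0.0, 1.0))
@settings(deadline=None, max_examples=60)
def test_probability_triples_sum_to_one(s, d, q):
    for triple in (
        db.genotype_probs_from_sire_dam(s, d),
        db.genotype_probs_from_sire_mgs(s, d, q),
    ):
        assert triple.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(triple >= -1e-15)


@pytest.mark.parametrize("q", [0.1, 0.37, 0.5, 0.9])
@pytest.mark.parametrize("sire", [0, 1, 2])
def test_sire_dam_marginalizes_to_population_dam(sire, q):
    """Averaging over an HWE dam (P(A)=q) matches a dam path transmitting A
    with probability q, enumerated over the full parent grid."""
    p = 1.0 - q
    dam_dist = {0: q**2, 1: 2 * p * q, 2: p**2}
    marginal = sum(
        w * db.genotype_probs_from_sire_dam(sire, dam) for dam, w in dam_dist.items()
    )
    pa_s = (2 - sire) / 2
    expected = np.array(
        [
            pa_s * q,
            pa_s * (1 - q) + (1 - pa_s) * q,
            (1 - pa_s) * (1 - q),
        ]
    )
    assert marginal == pytest.approx(expected, abs=1e-12)


# ------------------------------------------------------- relationship matrices


def test_identical_genotypes_have_identical_relationship_rows():
    g = GenotypeMatrix(ids=["a", "b", "c"], codes=np.array([[0, 2], [0, 2], [1, 1]]))
    cs = db.compute_codings(g, db.AlleleFrequencies([0.3, 0.6]))
    G = db.build_relationship_matrix(cs, "G").values
    assert G[0] == pytest.approx(G[1])
    assert G[0, 1] == pytest.approx(G[0, 0])


def test_single_animal_relationship_formula():
    g = GenotypeMatrix(ids=["a"], codes=np.array([[0]]))
    cs = db.compute_codings(g, db.AlleleFrequencies([0.5]))
    G = db.build_relationship_matrix(cs, "G").values
    assert G[0, 0] == pytest.approx((-1.0) ** 2 / 0.5)


def test_monomorphic_only_matrix_errors():
    g = GenotypeMatrix(ids=["a", "b"], codes=np.array([[0], [0]]))
    cs = db.compute_codings(g, db.estimate_allele_frequencies(g))
    assert cs.n_monomorphic == 1
    with pytest.raises(ValueError, match="monomorphic"):
        db.build_relationship_matrix(cs, "G")


def test_hwe_mean_diagonals_near_one():
    """E(z^2)=2pq, E(h^2)=2pq(1-2pq), E(m^2)=(2pq)^2 give unit mean diagonals."""
    cfg = db.SimConfig(n_animals=5000, n_snps=2000, n_sd_offspring=0,
                       n_smgs_groups=0, seed=99)
    pop = db.simulate_genotypes(cfg)
    cs = db.compute_codings(pop.genotypes, db.estimate_allele_frequencies(pop.genotypes))
    for mat, s in ((cs.Z, cs.s_a), (cs.H, cs.s_h), (cs.M, cs.s_m)):
        diag = (mat**2).sum(axis=1) / s
        assert np.mean(diag) == pytest.approx(1.0, abs=0.02)


def test_relationship_matrices_positive_semidefinite(small_codings):
    for kind in ("G", "D1", "D2"):
        vals = db.build_relationship_matrix(small_codings, kind).values
        eig = np.linalg.eigvalsh(vals)
        assert eig[0] > -1e-8 * eig[-1]


def test_additive_and_deviation_codings_orthogonal_under_hwe():
    cfg = db.SimConfig(n_animals=4000, n_snps=300, n_sd_offspring=0,
                       n_smgs_groups=0, seed=7)
    pop = db.simulate_genotypes(cfg)
    cs = db.compute_codings(pop.genotypes, db.estimate_allele_frequencies(pop.genotypes))
    n = cs.n
    cov = (cs.Z * cs.M).mean(axis=0) - cs.Z.mean(axis=0) * cs.M.mean(axis=0)
    assert np.all(np.abs(cov) < 3 / np.sqrt(n))
    for mat in (cs.Z, cs.H, cs.M):
        assert np.all(np.abs(mat.mean(axis=0)) < 3 / np.sqrt(n))


# ----------------------------------------------------------- residual structure


def test_residual_multipliers_by_group():
    rec = pd.DataFrame(
        {
            "group": ["C", "SD", "SMGS", "SMGS"],
            "n_daughters": [1, 1, 20, 1],
        }
    )
    rs = db.build_residual_structure(rec)
    assert rs.multipliers == pytest.approx([1.0, 1.0, 1 / 20, 1.0])
    design = rs.design()
    assert set(design) == {"C", "SD", "SMGS"}
    assert design["SMGS"] == pytest.approx([0.0, 0.0, 1 / 20, 1.0])


def test_smgs_record_requires_daughter_count():
    rec = pd.DataFrame({"group": ["C", "SMGS"], "n_daughters": [1.0, np.nan]})
    with pytest.raises(ValueError, match="daughter count"):
        db.build_residual_structure(rec)
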