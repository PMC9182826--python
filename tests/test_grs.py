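"""GRS builder: instrument filters, LD pruning, imputation, allele
harmonization, the weighted-score formula, and file round trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrsurv import io as io_mod
from mrsurv.grs import (
    GenotypePanel,
    NoInstrumentsError,
    build_grs,
    compute_grs,
    filter_genomewide,
    harmonize_alleles,
    impute_missing,
    ld_prune,
)
from mrsurv.simulate import SimulationScenario, generate_genotypes, simulate_cohort


def weights_frame(snp_ids, betas, pvalues=None, eaf=0.5):
    m = len(snp_ids)
    return pd.DataFrame(
        {
            "snp_id": snp_ids,
            "effect_allele": ["A"] * m,
            "other_allele": ["G"] * m,
            "beta": betas,
            "se": [0.01] * m,
            "pvalue": pvalues if pvalues is not None else [1e-10] * m,
            "eaf": [eaf] * m,
        }
    )


def panel_from(matrix, snp_ids=None):
    matrix = np.asarray(matrix, dtype=float)
    n, m = matrix.shape
    return GenotypePanel(
        dosages=matrix,
        sample_ids=[f"S{i}" for i in range(n)],
        snp_ids=snp_ids or [f"rs{j}" for j in range(m)],
    )


# ---------------------------------------------------------------------------
# p-value filter
# ---------------------------------------------------------------------------


def test_filter_keeps_only_genomewide_significant():
    w = weights_frame(["a", "b", "c"], [0.1, 0.1, 0.1], [1e-9, 1e-7, 4.9e-8])
    kept = filter_genomewide(w, 5e-8)
    assert kept["snp_id"].tolist() == ["a", "c"]


def test_filter_threshold_one_is_identity():
    w = weights_frame(["a", "b"], [0.1, 0.2], [0.5, 1.0])
    assert filter_genomewide(w, 1.0)["snp_id"].tolist() == ["a", "b"]


def test_filter_empty_result_raises():
    w = weights_frame(["a", "b"], [0.1, 0.2], [1e-6, 1e-7])
    with pytest.raises(NoInstrumentsError):
        filter_genomewide(w, 5e-8)


# ---------------------------------------------------------------------------
# weighted score formula
# ---------------------------------------------------------------------------


def test_grs_formula_toy_case():
    """betas [0.2, 0.3], dosages [1, 2]:
    (0.2*1 + 0.3*2) / ((0.2+0.3)/2) = 0.8 / 0.25 = 3.2."""
    panel = panel_from([[1.0, 2.0]])
    w = weights_frame(["rs0", "rs1"], [0.2, 0.3])
    grs = compute_grs(panel, w)
    assert grs.scores.iloc[0] == pytest.approx(3.2, abs=1e-12)


def test_grs_equal_betas_reduce_to_allele_count():
    rng = np.random.default_rng(0)
    dos = rng.integers(0, 3, size=(20, 4)).astype(float)
    panel = panel_from(dos)
    w = weights_frame(list(panel.snp_ids), [0.37] * 4)
    grs = compute_grs(panel, w)
    assert np.allclose(grs.scores.to_numpy(), dos.sum(axis=1), atol=1e-10)


def test_grs_zero_dosages_zero_score():
    panel = panel_from(np.zeros((3, 2)))
    grs = compute_grs(panel, weights_frame(["rs0", "rs1"], [0.2, 0.3]))
    assert np.all(grs.scores.to_numpy() == 0.0)


def test_grs_vanishing_denominator_raises():
    panel = panel_from([[1.0, 1.0]])
    with pytest.raises(ValueError, match="denominator"):
        compute_grs(panel, weights_frame(["rs0", "rs1"], [0.5, -0.5]))
    # |beta| fallback stays defined
    grs = compute_grs(
        panel, weights_frame(["rs0", "rs1"], [0.5, -0.5]), abs_denominator=True
    )
    assert np.isfinite(grs.scores.iloc[0])


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    st.lists(
        st.floats(min_value=0.05, max_value=1.0), min_size=2, max_size=6
    ),
    st.integers(min_value=0, max_value=10_000),
)
def test_grs_is_linear_in_dosages(betas, seed):
    """score(g + g') = score(g) + score(g') for any fixed weights."""
    rng = np.random.default_rng(seed)
    m = len(betas)
    g1 = rng.integers(0, 2, size=(5, m)).astype(float)
    g2 = rng.integers(0, 2, size=(5, m)).astype(float)
    w = weights_frame([f"rs{j}" for j in range(m)], betas)
    s1 = compute_grs(panel_from(g1), w).scores.to_numpy()
    s2 = compute_grs(panel_from(g2), w).scores.to_numpy()
    s12 = compute_grs(panel_from(g1 + g2), w).scores.to_numpy()
    assert np.allclose(s12, s1 + s2, rtol=1e-9, atol=1e-9)


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------


def test_impute_column_mean():
    panel = panel_from(np.array([[0.0], [2.0], [np.nan]]))
    out = impute_missing(panel)
    assert out.dosages[2, 0] == pytest.approx(1.0)


def test_impute_identity_without_missing():
    panel = panel_from(np.array([[0.0, 1.0], [2.0, 1.0]]))
    out = impute_missing(panel)
    assert out is panel


def test_impute_multiple_missing_and_mean_preservation():
    col = np.array([1.0, 1.0, np.nan, np.nan])
    out = impute_missing(panel_from(col[:, None]))
    assert np.allclose(out.dosages[:, 0], 1.0)
    # non-missing mean preserved exactly
    assert out.dosages[:, 0].mean() == pytest.approx(1.0)


def test_impute_fully_missing_snp_named_in_error():
    m = np.array([[1.0, np.nan], [0.0, np.nan]])
    with pytest.raises(ValueError, match="rs1"):
        impute_missing(panel_from(m))


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------


def test_prune_keeps_lower_p_of_correlated_pair():
    rng = np.random.default_rng(1)
    base = rng.integers(0, 3, size=2000).astype(float)
    noisy = base.copy()
    flip = rng.random(2000) < 0.02
    noisy[flip] = rng.integers(0, 3, size=flip.sum())
    panel = panel_from(np.column_stack([base, noisy]), ["lowp", "highp"])
    w = weights_frame(["lowp", "highp"], [0.1, 0.1], [1e-20, 1e-10])
    # oracle: the pair really is correlated beyond the threshold
    r2 = np.corrcoef(base, noisy)[0, 1] ** 2
    assert r2 > 0.1
    retained, _ = ld_prune(panel, w, 0.1)
    assert retained == ["lowp"]


def test_prune_independent_snps_all_retained():
    sc = SimulationScenario(n_samples=3000, n_snps=8, seed=2)
    panel = generate_genotypes(sc)
    w = weights_frame(list(panel.snp_ids), [0.1] * 8)
    retained, _ = ld_prune(panel, w, 0.1)
    assert retained == list(panel.snp_ids)


def test_prune_threshold_one_is_vacuous():
    rng = np.random.default_rng(3)
    dup = rng.integers(0, 3, size=500).astype(float)
    panel = panel_from(np.column_stack([dup, dup + 0.0]), ["a", "b"])
    w = weights_frame(["a", "b"], [0.1, 0.1], [1e-9, 1e-8])
    retained, _ = ld_prune(panel, w, 1.0)
    assert set(retained) == {"a", "b"}


def test_pruned_set_pairwise_r2_below_threshold_brute_force():
    """Self-consistency on an LD-structured panel, verified exhaustively."""
    sc = SimulationScenario(
        n_samples=4000, n_snps=12, ld_block_size=3, ld_rho=0.7, seed=4
    )
    panel = generate_genotypes(sc)
    w = weights_frame(
        list(panel.snp_ids), [0.1] * 12, list(np.linspace(1e-20, 1e-10, 12))
    )
    retained, _ = ld_prune(panel, w, 0.1)
    idx = panel.snp_ids.get_indexer(retained)
    sub = panel.dosages[:, idx]
    corr = np.corrcoef(sub.T)
    off = corr[~np.eye(len(idx), dtype=bool)]
    assert np.all(off**2 <= 0.1 + 1e-9)
    assert len(retained) < 12  # pruning actually removed correlated SNPs


def test_prune_zero_variance_snp_excluded():
    panel = panel_from(
        np.column_stack([np.ones(100), np.arange(100) % 3]).astype(float), ["flat", "ok"]
    )
    w = weights_frame(["flat", "ok"], [0.1, 0.1], [1e-20, 1e-10])
    retained, log = ld_prune(panel, w, 0.1)
    assert retained == ["ok"]
    assert "flat" in log.dropped_zero_variance


# ---------------------------------------------------------------------------
# allele harmonization
# ---------------------------------------------------------------------------


def harm_setup():
    alleles = pd.DataFrame(
        {
            "counted_allele": ["A", "C", "A", "A"],
            "other_allele": ["G", "T", "T", "C"],
        },
        index=pd.Index(["match", "swap", "ambig", "mismatch"], name="snp_id"),
    )
    weights = pd.DataFrame(
        {
            "snp_id": ["match", "swap", "ambig", "mismatch"],
            "effect_allele": ["A", "T", "A", "G"],
            "other_allele": ["G", "C", "T", "T"],
            "beta": [0.1, 0.2, 0.3, 0.4],
            "se": [0.01] * 4,
            "pvalue": [1e-9] * 4,
            "eaf": [0.5] * 4,
        }
    )
    return alleles, weights


def test_harmonize_matching_swapped_ambiguous_mismatch():
    alleles, weights = harm_setup()
    aligned, flip, log = harmonize_alleles(alleles, weights)
    assert aligned["snp_id"].tolist() == ["match", "swap"]
    assert flip.tolist() == [False, True]
    assert log.dropped_ambiguous == ["ambig"]
    assert log.dropped_mismatch == ["mismatch"]


def test_flip_replaces_dosage_with_two_minus_g():
    from mrsurv.grs import apply_flips

    panel = panel_from(np.array([[2.0, 2.0], [0.5, 1.0]]), ["keep", "flip"])
    out = apply_flips(panel, ["flip"])
    assert out.dosages[0, 1] == pytest.approx(0.0)
    assert out.dosages[1, 1] == pytest.approx(1.0)
    assert np.array_equal(out.dosages[:, 0], panel.dosages[:, 0])


# ---------------------------------------------------------------------------
# end-to-end build + fixture round trip
# ---------------------------------------------------------------------------


def test_grs_correlates_with_exposure_when_instruments_exist(demo_sim):
    grs = build_grs(demo_sim.panel, demo_sim.weights)
    r = np.corrcoef(grs.scores.to_numpy(), demo_sim.cohort["exposure_sim"])[0, 1]
    assert r > 0.2


def test_fixture_round_trip_bitwise(tmp_path):
    sc = SimulationScenario(n_samples=50, n_snps=6, missing_rate=0.1, seed=8)
    sim = simulate_cohort(sc)
    paths = io_mod.write_fixture(sim.panel, sim.cohort, sim.weights, tmp_path / "fx")
    panel2, cohort2, weights2 = io_mod.read_fixture(tmp_path / "fx")
    assert np.array_equal(panel2.dosages, sim.panel.dosages, equal_nan=True)
    assert list(panel2.snp_ids) == list(sim.panel.snp_ids)
    pd.testing.assert_series_equal(
        cohort2["followup_years"], sim.cohort["followup_years"], check_exact=False
    )


def test_fixture_determinism_same_seed_same_bytes(tmp_path):
    sc = SimulationScenario(n_samples=40, n_snps=5, missing_rate=0.05, seed=21)
    for d in ("a", "b"):
        sim = simulate_cohort(sc)
        io_mod.write_fixture(sim.panel, sim.cohort, sim.weights, tmp_path / d)
    for name in ("weights.tsv", "dosages.tsv", "cohort.tsv"):
        assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()
    sim3 = simulate_cohort(sc.with_(seed=22))
    io_mod.write_fixture(sim3.panel, sim3.cohort, sim3.weights, tmp_path / "c")
    assert (tmp_path / "a" / "dosages.tsv").read_bytes() != (
        tmp_path / "c" / "dosages.tsv"
    ).read_bytes()
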