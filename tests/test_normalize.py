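"""Normalisation chain: TPM, log-quantile, CPM filter, species scaling, PCA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import castekit as ck


def sample_frame(data, species):
    cols = pd.MultiIndex.from_tuples(
        [(sp, caste) for sp in species for caste in ("queen", "worker")],
        names=["species", "caste"],
    )
    return pd.DataFrame(data, columns=cols)


def test_tpm_of_equal_counts_and_lengths_splits_the_million():
    counts = sample_frame([[10, 10], [10, 10]], ["spA"])
    lengths = pd.DataFrame({"spA": [100, 100]})
    tpm = ck.compute_tpm(counts, lengths)
    assert np.allclose(tpm.to_numpy(), 5e5)


def test_tpm_weights_by_inverse_length():
    counts = sample_frame([[10, 10], [10, 10]], ["spA"])
    lengths = pd.DataFrame({"spA": [1000, 500]})
    tpm = ck.compute_tpm(counts, lengths)
    assert np.allclose(tpm.iloc[0], 1e6 / 3)
    assert np.allclose(tpm.iloc[1], 2e6 / 3)


def test_tpm_columns_always_sum_to_a_million():
    rng = np.random.default_rng(0)
    counts = sample_frame(rng.integers(0, 500, size=(40, 6)) + 1, ["spA", "spB", "spC"])
    lengths = pd.DataFrame(rng.integers(200, 3000, size=(40, 3)),
                           columns=["spA", "spB", "spC"])
    tpm = ck.compute_tpm(counts, lengths)
    assert np.allclose(tpm.sum(axis=0), 1e6, atol=1e-6)


def test_quantile_normalisation_averages_sorted_columns():
    # log2(x+1) of (1, 7) and (3, 15) gives columns (1,3) and (2,4);
    # the reference is the mean of sorted columns: (1.5, 3.5)
    mat = sample_frame(np.array([[1.0, 3.0], [7.0, 15.0]]), ["spA"])
    out = ck.log_quantile(mat)
    assert np.allclose(out.to_numpy(), [[1.5, 1.5], [3.5, 3.5]])


def test_quantile_normalisation_fixes_identical_columns():
    col = np.log2(np.array([4.0, 9.0, 1.0]) + 1)
    mat = sample_frame(np.column_stack([[4.0, 9.0, 1.0]] * 2), ["spA"])
    out = ck.log_quantile(mat)
    assert np.allclose(out[("spA", "queen")], col)
    assert np.allclose(out[("spA", "worker")], col)


def test_quantile_normalised_columns_share_sorted_values():
    rng = np.random.default_rng(1)
    mat = sample_frame(rng.random((30, 8)) * 1000, ["spA", "spB", "spC", "spD"])
    out = ck.log_quantile(mat).to_numpy()
    ref = np.sort(out[:, 0])
    for j in range(1, out.shape[1]):
        assert np.allclose(np.sort(out[:, j]), ref)


@pytest.mark.parametrize(
    "queen, worker, expected",
    [(3.0, 1.0, (0.5, -0.5)), (2.0, 2.0, (0.0, 0.0)), (5.0, 0.0, (1.0, -1.0))],
)
def test_species_scaling_reduces_to_caste_contrast(queen, worker, expected):
    mat = sample_frame([[queen, worker]], ["spA"])
    out = ck.species_scale(mat).values
    assert out.iloc[0, 0] == pytest.approx(expected[0])
    assert out.iloc[0, 1] == pytest.approx(expected[1])


def test_species_scaling_zero_mean_rows_become_zero():
    mat = sample_frame([[0.0, 0.0, 1.0, 3.0]], ["spA", "spB"])
    out = ck.species_scale(mat).values
    assert (out[("spA", "queen")] == 0).all()
    assert out.at[0, ("spB", "queen")] == pytest.approx(-0.5)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(0, 2**32 - 1))
def test_species_scaling_invariants_on_random_matrices(seed):
    rng = np.random.default_rng(seed)
    n_genes = int(rng.integers(1, 12))
    n_species = int(rng.integers(1, 5))
    species = [f"sp{i}" for i in range(n_species)]
    mat = sample_frame(rng.random((n_genes, 2 * n_species)) * 100, species)
    out = ck.species_scale(mat).values
    assert (out.to_numpy() >= -1 - 1e-12).all() and (out.to_numpy() <= 1 + 1e-12).all()
    for sp in species:
        pair_sum = out[(sp, "queen")] + out[(sp, "worker")]
        assert np.allclose(pair_sum, 0, atol=1e-12)
    # multiplying one species' expression by a positive constant changes nothing
    scaled_in = mat.copy()
    scaled_in[species[0]] = scaled_in[species[0]] * 7.3
    out2 = ck.species_scale(scaled_in).values
    assert np.allclose(out.to_numpy(), out2.to_numpy(), atol=1e-9)


def test_cpm_filter_follows_the_both_castes_rule():
    counts = sample_frame(
        [
            [500, 500, 500, 500],  # high everywhere -> kept
            [2, 3, 500, 500],      # both castes low in spA -> dropped
            [2, 300, 2, 300],      # worker rescues it in every species -> kept
        ],
        ["spA", "spB"],
    )
    libs = pd.Series(
        [1_000_000] * 4,
        index=pd.MultiIndex.from_product([["spA", "spB"], ["queen", "worker"]],
                                         names=["species", "caste"]),
    )
    keep = ck.filter_low_expression(counts, libs, threshold_cpm=10.0)
    assert list(keep) == [True, False, True]


def test_cpm_filter_exempt_cells_cannot_trigger_drop():
    counts = sample_frame([[2, 3, 500, 500]], ["spA", "spB"])
    libs = pd.Series(
        [1_000_000] * 4,
        index=pd.MultiIndex.from_product([["spA", "spB"], ["queen", "worker"]],
                                         names=["species", "caste"]),
    )
    exempt = pd.DataFrame({"spA": [True], "spB": [False]})
    keep = ck.filter_low_expression(counts, libs, threshold_cpm=10.0, exempt=exempt)
    assert keep.iloc[0]


def test_pipeline_output_satisfies_matrix_invariants(small_norm):
    vals = small_norm.values
    arr = vals.to_numpy()
    assert (arr >= -1).all() and (arr <= 1).all()
    for sp in small_norm.species:
        assert np.allclose(vals[(sp, "queen")] + vals[(sp, "worker")], 0, atol=1e-12)


def test_pipeline_is_deterministic(small_sim):
    _, counts, ogmap, _ = small_sim
    hm = ck.harmonize(counts, ogmap, mode="isoforms3_na2")
    a = ck.normalize_pipeline(hm).values
    b = ck.normalize_pipeline(hm).values
    pd.testing.assert_frame_equal(a, b)


def test_pca_variance_fractions_are_sorted_and_bounded(small_norm):
    scores, var = ck.pca(small_norm.values, n_components=4)
    assert scores.shape[1] == 4
    assert var.sum() <= 1 + 1e-9
    assert (np.diff(var) <= 1e-12).all()


def test_pca_on_duplicated_samples_has_rank_limited_variance():
    mat = sample_frame(np.tile(np.random.default_rng(2).random((10, 2)), 3),
                       ["spA", "spB", "spC"])
    _, var = ck.pca(mat, n_components=5)
    # only one distinct contrast among duplicated queen/worker pairs
    assert var[0] > 0.99


def test_species_scaling_flips_pca_structure_from_species_to_caste():
    from sklearn.metrics import silhouette_score

    cfg = ck.SimulationConfig(seed=3)  # nine species, strong species offsets
    counts, ogmap, _ = ck.generate_dataset(cfg)
    hm = ck.harmonize(counts, ogmap, mode="isoforms3_na2")
    raw = np.log2(ck.compute_tpm(hm.counts, hm.lengths) + 1)
    nrm = ck.normalize_pipeline(hm).values

    def silhouettes(mat):
        scores, _ = ck.pca(mat, 2)
        sp = list(scores.index.get_level_values("species"))
        caste = list(scores.index.get_level_values("caste"))
        return (silhouette_score(scores.to_numpy(), sp),
                silhouette_score(scores.to_numpy(), caste))

    sp_raw, caste_raw = silhouettes(raw)
    sp_nrm, caste_nrm = silhouettes(nrm)
    assert sp_raw > caste_raw
    assert caste_nrm > sp_nrm
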