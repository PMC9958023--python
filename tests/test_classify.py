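"""Feature ranking, SVM transfer classification, toolkit extraction."""

import numpy as np
import pandas as pd
import pytest

import castekit as ck
from castekit.classify import _split_species

FAST_CONFIG = ck.SVMConfig(gamma_grid=(1e-6, 1e-4, 1e-3), cost_grid=(2.0, 32.0, 1024.0), seed=0)


def sample_frame(data, species, index=None):
    cols = pd.MultiIndex.from_tuples(
        [(sp, caste) for sp in species for caste in ("queen", "worker")],
        names=["species", "caste"],
    )
    return pd.DataFrame(data, columns=cols, index=index)


def planted_matrix(n_genes=60, n_signal=12, n_species=6, amp=0.3, noise=0.1, seed=0):
    """Antisymmetric queen/worker matrix with the first genes caste-informative."""
    rng = np.random.default_rng(seed)
    queen = rng.normal(0, noise, size=(n_genes, n_species))
    queen[:n_signal] += amp
    data = np.empty((n_genes, 2 * n_species))
    data[:, 0::2] = queen
    data[:, 1::2] = -queen
    species = [f"sp{i + 1}" for i in range(n_species)]
    idx = pd.Index([f"OG{i:04d}" for i in range(n_genes)], name="orthogroup")
    return sample_frame(np.clip(data, -1, 1), species, index=idx)


def test_ranking_slope_matches_closed_form_ols():
    x = np.array([-0.5, 0.5, -0.4, 0.4])  # sample order: Q, W, Q, W
    mat = sample_frame([x], ["spA", "spB"], index=pd.Index(["g1"], name="orthogroup"))
    ranking = ck.rank_features(mat)
    y = np.array([1.0, 0.0, 1.0, 0.0])
    beta_expected = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
    assert ranking.table.at["g1", "beta"] == pytest.approx(beta_expected)


def test_constant_gene_is_ranked_last_with_null_statistics():
    mat = planted_matrix(n_genes=10, n_signal=3, seed=1)
    mat.iloc[-1] = 0.42  # identical in every sample
    ranking = ck.rank_features(mat)
    last = mat.index[-1]
    assert ranking.table.at[last, "beta"] == 0.0
    assert ranking.table.at[last, "p"] == 1.0
    assert ranking.table.at[last, "rank"] == len(mat)


def test_perfectly_caste_split_gene_ranks_first():
    mat = planted_matrix(n_genes=30, n_signal=0, noise=0.05, seed=2)
    mat.iloc[0, 0::2] = 0.3   # +c in every queen
    mat.iloc[0, 1::2] = -0.3  # -c in every worker
    ranking = ck.rank_features(mat)
    assert ranking.table.iloc[0]["rank"] == 1
    assert ranking.table.iloc[0]["p"] == pytest.approx(0.0, abs=1e-12)


def test_rank_is_a_permutation_and_orderings_are_available():
    mat = planted_matrix(seed=3)
    for order_by in ("p", "beta"):
        ranking = ck.rank_features(mat, order_by=order_by)
        assert sorted(ranking.table["rank"]) == list(range(1, len(mat) + 1))


def test_ranking_requires_enough_samples_and_both_castes():
    mat = planted_matrix(n_species=1)
    with pytest.raises(ValueError, match="4 training samples"):
        ck.rank_features(mat)


def test_feature_ranking_ignores_the_held_out_species():
    """Leakage guard: a gene that is caste-perfect only in the test species
    must not gain rank in a ranking computed on the training species."""
    mat = planted_matrix(n_genes=40, n_signal=5, n_species=5, seed=4)
    train = _split_species(mat, ["sp1", "sp2", "sp3", "sp4"])
    before = ck.rank_features(train).table["rank"]
    poisoned = mat.copy()
    poisoned.loc[poisoned.index[-1], ("sp5", "queen")] = 1.0
    poisoned.loc[poisoned.index[-1], ("sp5", "worker")] = -1.0
    after = ck.rank_features(_split_species(poisoned, ["sp1", "sp2", "sp3", "sp4"])).table["rank"]
    pd.testing.assert_series_equal(before, after)


def test_separable_toy_problem_reaches_perfect_tuning_accuracy():
    mat = planted_matrix(n_genes=2, n_signal=2, amp=0.5, noise=0.02, seed=5)
    model = ck.train_svm(mat, FAST_CONFIG)
    assert model.cv_accuracy == 1.0


def test_training_rejects_single_class_labels():
    mat = planted_matrix(n_genes=5, seed=6)
    queens_only = mat.loc[:, (slice(None), "queen")]
    with pytest.raises(ValueError, match="class"):
        ck.train_svm(queens_only, FAST_CONFIG)


def test_tuning_is_deterministic_for_fixed_seed():
    mat = planted_matrix(n_genes=50, n_signal=8, noise=0.2, seed=7)
    m1 = ck.train_svm(mat, FAST_CONFIG)
    m2 = ck.train_svm(mat, FAST_CONFIG)
    assert (m1.gamma, m1.cost) == (m2.gamma, m2.cost)


def test_classification_estimates_are_probabilities_with_queen_on_top():
    mat = planted_matrix(n_genes=60, n_signal=15, n_species=7, seed=8)
    train = _split_species(mat, [f"sp{i}" for i in range(1, 7)])
    test = _split_species(mat, ["sp7"])
    model = ck.train_svm(train, FAST_CONFIG)
    est = ck.classify(model, test)
    assert ((est >= 0) & (est <= 1)).all()
    assert est[("sp7", "queen")] > est[("sp7", "worker")]


def test_swapping_caste_labels_mirrors_the_estimates():
    mat = planted_matrix(n_genes=40, n_signal=10, n_species=6, seed=9)
    train = _split_species(mat, [f"sp{i}" for i in range(1, 6)])
    test = _split_species(mat, ["sp6"])
    est = ck.classify(ck.train_svm(train, FAST_CONFIG), test)
    swapped = train.copy()
    swapped.columns = pd.MultiIndex.from_tuples(
        [(sp, "worker" if caste == "queen" else "queen") for sp, caste in train.columns],
        names=["species", "caste"],
    )
    est_swapped = ck.classify(ck.train_svm(swapped, FAST_CONFIG), test)
    assert np.allclose(est.to_numpy(), 1 - est_swapped.to_numpy(), atol=1e-3)


def test_classify_reports_missing_features():
    mat = planted_matrix(n_genes=20, seed=10)
    model = ck.train_svm(_split_species(mat, ["sp1", "sp2", "sp3"]), FAST_CONFIG)
    with pytest.raises(ValueError, match="features"):
        ck.classify(model, mat.iloc[:10])


def test_noise_trained_model_is_uncertain_on_average():
    rng = np.random.default_rng(11)
    mat = planted_matrix(n_genes=50, n_signal=0, noise=0.2, n_species=6, seed=11)
    model = ck.train_svm(_split_species(mat, [f"sp{i}" for i in range(1, 6)]), FAST_CONFIG)
    test = planted_matrix(n_genes=50, n_signal=0, noise=0.2, n_species=20, seed=12)
    est = ck.classify(model, test)
    assert abs(float(est.mean()) - 0.5) < 0.15


def test_leave_one_out_curves_respect_retention_monotonicity(planted_norm):
    nm, _ = planted_norm
    loo = ck.leave_one_species_out(
        nm, fractions=(0.5, 0.2, 0.05), config=ck.SVMConfig(seed=7)
    )
    assert set(loo.results) == set(nm.species)
    for res in loo.results.values():
        nf = res.curve["n_features"].to_numpy()
        assert (np.diff(nf) <= 0).all()
        est = res.curve[["estimate_queen", "estimate_worker"]].to_numpy()
        assert ((est >= 0) & (est <= 1)).all()


def test_leave_one_out_toolkit_recovers_planted_genes(planted_norm):
    """Toolkit extraction enriches planted genes far beyond their 7.5% base rate.

    The caste-on-expression regression inherits optimistic p-values from the
    antisymmetric queen/worker pairs, so about half the intersection is noise;
    precision nevertheless sits an order of magnitude above chance and recall
    is high.
    """
    nm, truth = planted_norm
    loo = ck.leave_one_species_out(nm, fractions=(), config=ck.SVMConfig(seed=7))
    got = loo.toolkit.genes
    toolkit = truth.toolkit_genes
    precision = len(got & toolkit) / len(got)
    recall = len(got & toolkit) / len(toolkit)
    assert precision > 0.4
    assert recall > 0.3
    base_rate = len(toolkit) / nm.values.shape[0]
    assert precision > 4 * base_rate


def test_leave_one_out_requires_three_species():
    mat = planted_matrix(n_species=2)
    with pytest.raises(ValueError, match="3 species"):
        ck.leave_one_species_out(mat, fractions=(0.5,))


def test_group_transfer_rejects_overlapping_groups(planted_norm):
    nm, _ = planted_norm
    with pytest.raises(ValueError, match="overlap"):
        ck.group_transfer(nm, ["sp1", "sp2"], ["sp2", "sp3"], fractions=(0.5,))
    with pytest.raises(ValueError, match="overlap"):
        ck.group_transfer(nm, ["sp1", "sp2"], ["sp1", "sp2"], fractions=(0.5,))


def test_symmetric_groups_transfer_equally_well():
    diffs = []
    for seed in (11, 12):
        cfg = ck.SimulationConfig(
            n_species=6, n_orthogroups=2000, toolkit_size=100,
            private_caste_frac=0.0, seed=seed,
        )
        counts, ogmap, _ = ck.generate_dataset(cfg)
        nm = ck.normalize_pipeline(ck.harmonize(counts, ogmap, mode="isoforms3_na2"))
        g1, g2 = ["sp1", "sp2", "sp3"], ["sp4", "sp5", "sp6"]
        cfg_svm = ck.SVMConfig(seed=seed)
        fwd = ck.group_transfer(nm, g1, g2, fractions=(0.05,), config=cfg_svm)
        rev = ck.group_transfer(nm, g2, g1, fractions=(0.05,), config=cfg_svm)

        def success(transfer):
            rows = [r.curve.iloc[0] for r in transfer.results.values()]
            return np.mean([(r.estimate_queen + 1 - r.estimate_worker) / 2 for r in rows])

        diffs.append(abs(success(fwd) - success(rev)))
    assert np.mean(diffs) < 0.1


def test_learning_curves_error_falls_with_feature_selection():
    cfg = ck.SimulationConfig(
        n_species=6, n_orthogroups=2000, toolkit_size=25,
        private_caste_frac=0.0, effect_log2fc=1.0, seed=5,
    )
    counts, ogmap, _ = ck.generate_dataset(cfg)
    nm = ck.normalize_pipeline(ck.harmonize(counts, ogmap, mode="isoforms3_na2"))
    lc = ck.learning_curves(nm.values, fractions=(0.99, 0.2, 0.05), folds=6,
                            config=ck.SVMConfig(seed=5))
    err = dict(zip(lc["fraction"], lc["cv_error"]))
    assert err[0.05] < err[0.99]
    assert err[0.2] <= err[0.99]
    assert err[0.05] == 0.0  # strong filtering isolates the planted signal


def test_learning_curves_on_noise_stay_near_chance():
    cfg = ck.SimulationConfig(
        n_species=6, n_orthogroups=1000, toolkit_size=0, private_caste_frac=0.0, seed=5,
    )
    counts, ogmap, _ = ck.generate_dataset(cfg)
    nm = ck.normalize_pipeline(ck.harmonize(counts, ogmap, mode="isoforms3_na2"))
    lc = ck.learning_curves(nm.values, fractions=(0.5,), folds=6, config=ck.SVMConfig(seed=5))
    assert 0.25 <= float(lc["cv_error"].iloc[0]) <= 0.9


def test_learning_curves_reject_too_many_folds():
    mat = planted_matrix(n_species=3)
    with pytest.raises(ValueError, match="folds"):
        ck.learning_curves(mat, fractions=(0.5,), folds=7)
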