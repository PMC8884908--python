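from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scsomatic import signatures
from scsomatic.signatures import (
    SignatureSet,
    bootstrap_contributions,
    compare_contribution_profiles,
    cosine_similarity,
    match_to_catalog,
    nmf_extract,
    refit_exposures,
    select_rank,
)
from scsomatic.spectra import SBS96_LABELS


def orthogonal_signatures(rng, k=3, n_cat=96):
    """Signatures on disjoint category blocks: identifiable by construction."""
    W = np.zeros((n_cat, k))
    width = n_cat // k
    for j in range(k):
        W[width * j: width * (j + 1), j] = rng.dirichlet(np.full(width, 1.0))
    return W


def anchored_exposures(rng, k, n_samples, scale=3000.0):
    """Exposure matrix with one pure sample per signature plus mixtures."""
    H = np.zeros((k, n_samples))
    for j in range(k):
        H[j, j] = scale
    H[:, k:] = rng.uniform(0.3, 2.0, size=(k, n_samples - k)) * scale / 2
    return H


class TestCosine:
    def test_identity_and_orthogonality(self):
        assert cosine_similarity([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
        assert cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0)

    def test_hand_value(self):
        assert cosine_similarity([1, 1, 0], [1, 0, 0]) == pytest.approx(0.70711, abs=1e-5)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity([0, 0], [1, 0])

    @settings(derandomize=True, max_examples=50)
    @given(
        a=st.lists(st.floats(0.0, 10.0), min_size=3, max_size=3),
        b=st.lists(st.floats(0.0, 10.0), min_size=3, max_size=3),
        s=st.floats(0.1, 100.0),
    )
    def test_symmetric_and_scale_invariant(self, a, b, s):
        if max(a) < 1e-3 or max(b) < 1e-3:
            return
        assert cosine_similarity(a, b) == pytest.approx(cosine_similarity(b, a))
        assert cosine_similarity(np.array(a) * s, b) == pytest.approx(
            cosine_similarity(a, b), abs=1e-9)


class TestNmfExtract:
    def test_rank_one_recovers_shared_profile(self, rng):
        p = rng.dirichlet(np.full(96, 0.5))
        scales = rng.uniform(500, 2000, size=6)
        V = pd.DataFrame(np.outer(scales, p), columns=SBS96_LABELS)
        sig = nmf_extract(V, 1, n_restarts=3, seed=0)
        assert np.allclose(sig.profiles.iloc[:, 0].to_numpy(), p, atol=1e-6)

    def test_objective_decreases_with_more_iterations(self, rng):
        V = pd.DataFrame(rng.poisson(20, size=(6, 96)).astype(float), columns=SBS96_LABELS)
        short = nmf_extract(V, 3, n_restarts=1, seed=5, max_iter=5, tol=0)
        long = nmf_extract(V, 3, n_restarts=1, seed=5, max_iter=500, tol=0)
        assert long.objective <= short.objective + 1e-9

    def test_exact_rank3_recovery(self, rng):
        W0 = orthogonal_signatures(rng)
        H0 = anchored_exposures(rng, 3, 8)
        V = pd.DataFrame((W0 @ H0).T, columns=SBS96_LABELS)
        sig = nmf_extract(V, 3, n_restarts=5, seed=1)
        W = sig.profiles.to_numpy()
        best = max(
            min(cosine_similarity(W0[:, i], W[:, p[i]]) for i in range(3))
            for p in permutations(range(3))
        )
        assert best >= 0.999

    def test_renormalization_preserves_reconstruction(self, rng):
        V = pd.DataFrame(rng.poisson(30, size=(5, 96)).astype(float), columns=SBS96_LABELS)
        sig = nmf_extract(V, 2, n_restarts=2, seed=3, max_iter=300)
        assert np.allclose(sig.profiles.sum(axis=0), 1.0, atol=1e-9)
        recon = sig.profiles.to_numpy() @ sig.exposures.to_numpy()
        # reconstruction beats the rank-1 row-mean baseline
        baseline = np.outer(V.mean(axis=0), np.ones(len(V)))
        from scsomatic.signatures import _kl_divergence
        assert _kl_divergence(V.to_numpy().T, recon) <= _kl_divergence(
            V.to_numpy().T, baseline) + 1e-6

    def test_invalid_inputs(self):
        V = pd.DataFrame(np.ones((4, 96)), columns=SBS96_LABELS)
        with pytest.raises(ValueError):
            nmf_extract(V, 5)  # k > number of samples
        with pytest.raises(ValueError):
            nmf_extract(V * 0, 2)


class TestSelectRank:
    def test_exact_rank3_selected(self, rng):
        W0 = orthogonal_signatures(rng)
        H0 = anchored_exposures(rng, 3, 8)
        V = pd.DataFrame((W0 @ H0).T, columns=SBS96_LABELS)
        k, diag = select_rank(V, range(1, 6), n_restarts=8, seed=0)
        assert k == 3
        assert set(diag.columns) == {"k", "objective", "stability", "rel_improvement"}

    def test_seed_invariance_on_noiseless_input(self, rng):
        W0 = orthogonal_signatures(rng)
        H0 = anchored_exposures(rng, 3, 8)
        V = pd.DataFrame((W0 @ H0).T, columns=SBS96_LABELS)
        k1, _ = select_rank(V, range(1, 6), n_restarts=8, seed=1)
        k2, _ = select_rank(V, range(1, 6), n_restarts=8, seed=2)
        assert k1 == k2 == 3

    def test_rank_one_matrix(self, rng):
        p = rng.dirichlet(np.full(96, 1.0))
        V = pd.DataFrame(np.outer(rng.uniform(500, 1500, 5), p), columns=SBS96_LABELS)
        k, _ = select_rank(V, range(1, 4), n_restarts=5, seed=0)
        assert k == 1

    def test_single_sample_rejected(self, rng):
        V = pd.DataFrame(rng.poisson(10, size=(1, 96)).astype(float), columns=SBS96_LABELS)
        with pytest.raises(ValueError):
            select_rank(V, range(1, 3))


class TestCatalogMatch:
    def test_exact_member_matches_itself(self, sbs_catalog):
        profiles = sbs_catalog[["TS1"]].copy()
        profiles.columns = ["M1"]
        sig = SignatureSet(profiles=profiles,
                           exposures=pd.DataFrame([[1.0]], index=["M1"], columns=["s"]))
        matches, sim = match_to_catalog(sig, sbs_catalog)
        assert matches[0].catalog == "TS1"
        assert matches[0].cosine == pytest.approx(1.0)
        assert sim.shape == (1, 5)

    def test_orthogonal_catalog(self):
        cat = pd.DataFrame({"A": [1.0, 0.0], "B": [0.0, 1.0]}, index=["x", "y"])
        profiles = pd.DataFrame({"M1": [1.0, 0.0]}, index=["x", "y"])
        sig = SignatureSet(profiles=profiles,
                           exposures=pd.DataFrame([[1.0]], index=["M1"], columns=["s"]))
        matches, sim = match_to_catalog(sig, cat)
        assert matches[0].catalog == "A" and matches[0].cosine == pytest.approx(1.0)
        assert sim.loc["M1", "B"] == pytest.approx(0.0)

    def test_argmax_over_similarity_matrix(self, rng, sbs_catalog):
        profiles = pd.DataFrame(
            rng.dirichlet(np.full(96, 1.0), size=3).T,
            index=sbs_catalog.index, columns=["M1", "M2", "M3"])
        sig = SignatureSet(profiles=profiles,
                           exposures=pd.DataFrame(np.ones((3, 1)),
                                                  index=["M1", "M2", "M3"], columns=["s"]))
        matches, sim = match_to_catalog(sig, sbs_catalog)
        for m in matches:
            assert m.catalog == sim.loc[m.de_novo].idxmax()

    def test_dimension_mismatch(self, sbs_catalog, id_catalog):
        profiles = id_catalog[["TID1"]].copy()
        profiles.columns = ["M1"]
        sig = SignatureSet(profiles=profiles,
                           exposures=pd.DataFrame([[1.0]], index=["M1"], columns=["s"]))
        with pytest.raises(ValueError):
            match_to_catalog(sig, sbs_catalog)


class TestRefitExposures:
    def test_pure_column(self, sbs_catalog):
        v = 100 * sbs_catalog["TS3"].to_numpy()
        rel = refit_exposures(v, sbs_catalog)
        assert rel["TS3"] == pytest.approx(1.0, abs=1e-8)

    def test_disjoint_support_mixture_exact(self):
        c1 = np.array([1.0, 0, 0, 0]) ; c2 = np.array([0, 0, 0.5, 0.5])
        cat = pd.DataFrame({"C1": c1, "C2": c2})
        v = 50 * c1 + 150 * c2
        rel = refit_exposures(v, cat)
        assert rel["C1"] == pytest.approx(0.25)
        assert rel["C2"] == pytest.approx(0.75)

    def test_orthogonal_spectrum_gives_zero(self):
        cat = pd.DataFrame({"C1": [1.0, 0, 0]})
        rel = refit_exposures(np.array([0.0, 3.0, 4.0]), cat)
        assert (rel == 0).all()

    def test_empty_catalog_rejected(self):
        with pytest.raises(ValueError):
            refit_exposures(np.ones(3), pd.DataFrame(index=range(3)))


class TestBootstrap:
    def test_degenerate_single_signature_group(self, sbs_catalog, rng):
        counts = rng.multinomial(20000, sbs_catalog["TS1"].to_numpy())
        spec = pd.DataFrame([counts], index=["g"], columns=sbs_catalog.index)
        est = bootstrap_contributions(spec, sbs_catalog, n_boot=200, seed=0)
        by_sig = {e.signature: e for e in est}
        assert by_sig["TS1"].mean > 0.97
        assert by_sig["TS1"].ci_high - by_sig["TS1"].ci_low < 0.05

    def test_ci_contains_mean_and_sums_to_one(self, sbs_catalog, rng):
        mix = 0.5 * sbs_catalog["TS1"] + 0.5 * sbs_catalog["TS3"]
        counts = rng.multinomial(10000, mix.to_numpy() / mix.sum())
        spec = pd.DataFrame([counts], index=["g"], columns=sbs_catalog.index)
        est = bootstrap_contributions(spec, sbs_catalog, n_boot=200, seed=1)
        assert sum(e.mean for e in est) == pytest.approx(1.0, abs=1e-6)
        for e in est:
            assert e.ci_low <= e.mean <= e.ci_high

    def test_validation(self, sbs_catalog):
        spec = pd.DataFrame([np.zeros(96)], index=["g"], columns=sbs_catalog.index)
        with pytest.raises(ValueError):
            bootstrap_contributions(spec, sbs_catalog, n_boot=200)
        with pytest.raises(ValueError):
            bootstrap_contributions(spec + 1, sbs_catalog, n_boot=50)

    def test_deterministic_given_seed(self, sbs_catalog, rng):
        counts = rng.multinomial(5000, sbs_catalog["TS2"].to_numpy())
        spec = pd.DataFrame([counts], index=["g"], columns=sbs_catalog.index)
        a = bootstrap_contributions(spec, sbs_catalog, n_boot=150, seed=9)
        b = bootstrap_contributions(spec, sbs_catalog, n_boot=150, seed=9)
        assert [(e.mean, e.ci_low, e.ci_high) for e in a] == \
               [(e.mean, e.ci_low, e.ci_high) for e in b]


class TestChiSquared:
    def test_identical_profiles_null(self):
        table = pd.DataFrame([[50, 50], [50, 50]])
        res = compare_contribution_profiles(table)
        assert res["chi2"] == pytest.approx(0.0)
        assert res["p_value"] == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        # [[90,10],[10,90]]: every expected cell is 50 -> chi2 = 4*40^2/50 = 128
        table = pd.DataFrame([[90, 10], [10, 90]])
        res = compare_contribution_profiles(table)
        assert res["chi2"] == pytest.approx(128.0)
        assert res["df"] == 1

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            compare_contribution_profiles(pd.DataFrame([[5, 5]]))


def test_kl_objective_competitive_with_sklearn(rng):
    """Independent oracle: sklearn's KL-NMF should not beat ours materially."""
    sklearn = pytest.importorskip("sklearn.decomposition")
    V = rng.poisson(15, size=(8, 96)).astype(float)
    Vdf = pd.DataFrame(V, columns=SBS96_LABELS)
    ours = nmf_extract(Vdf, 3, n_restarts=10, seed=0, max_iter=2000)
    best_sk = np.inf
    for s in range(5):
        model = sklearn.NMF(n_components=3, beta_loss="kullback-leibler",
                            solver="mu", init="random", random_state=s,
                            max_iter=2000, tol=1e-8)
        W = model.fit_transform(V.T)
        H = model.components_
        from scsomatic.signatures import _kl_divergence
        best_sk = min(best_sk, _kl_divergence(V.T, W @ H))
    assert ours.objective <= best_sk * 1.02 + 1e-6
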