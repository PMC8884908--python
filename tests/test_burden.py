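import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from scsomatic import burden
from scsomatic.burden import (
    fit_nbglm,
    fit_nbglmm,
    fold_change,
    median_per_individual,
    tukey_outliers,
)


class TestTukeyOutliers:
    def test_hand_computed_fences(self):
        rep = tukey_outliers([1, 2, 3, 4, 100])
        assert rep.quartiles == (2.0, 4.0)
        assert rep.fences == (-1.0, 7.0)
        assert list(rep.flagged.values()) == [100.0]

    def test_constant_list_no_flags(self):
        rep = tukey_outliers([5, 5, 5, 5, 5])
        assert rep.flagged == {}

    def test_tight_list_no_flags(self):
        rep = tukey_outliers([10, 11, 12, 13])
        assert rep.fences == (8.5, 14.5)
        assert rep.flagged == {}

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            tukey_outliers([1, 2, 3])

    @settings(derandomize=True, max_examples=30)
    @given(values=st.lists(st.integers(0, 10_000), min_size=4, max_size=20),
           seed=st.integers(0, 100))
    def test_permutation_invariant(self, values, seed):
        rng = np.random.default_rng(seed)
        shuffled = list(values)
        rng.shuffle(shuffled)
        a = tukey_outliers(values)
        b = tukey_outliers(shuffled)
        assert sorted(a.flagged.values()) == sorted(b.flagged.values())
        assert a.fences == b.fences


class TestMedians:
    def _table(self, data):
        rows = []
        for ind, (group, values) in data.items():
            for i, v in enumerate(values):
                rows.append({"cell_id": f"{ind}-{i}", "individual_id": ind,
                             "group": group, "snv_burden": v})
        return pd.DataFrame(rows)

    def test_odd_even_single(self):
        med = median_per_individual(self._table({
            "A": ("g1", [100, 200, 300]),
            "B": ("g1", [100, 200]),
            "C": ("g2", [5143]),
        }))
        by = med.set_index("individual_id")["median"]
        assert by["A"] == 200 and by["B"] == 150 and by["C"] == 5143

    def test_per_cell_permutation_invariant(self):
        a = median_per_individual(self._table({"A": ("g", [3, 1, 2])}))
        b = median_per_individual(self._table({"A": ("g", [1, 2, 3])}))
        assert a.loc[0, "median"] == b.loc[0, "median"] == 2

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            median_per_individual(pd.DataFrame(columns=["individual_id", "group",
                                                        "snv_burden"]))


class TestFoldChange:
    @pytest.mark.parametrize("a, b, expected",
                             [(4196, 1825, 2.3), (397, 231, 1.7), (1902, 1506, 1.3)])
    def test_reported_one_decimal(self, a, b, expected):
        assert round(fold_change(a, b), 1) == expected

    def test_positive_inputs_required(self):
        with pytest.raises(ValueError):
            fold_change(0, 10)
        with pytest.raises(ValueError):
            fold_change(10, 0)


def _nb_counts(rng, mu, theta, n):
    return rng.negative_binomial(theta, theta / (theta + mu), size=n)


class TestNbglm:
    def test_identical_multisets_symmetric(self):
        res = fit_nbglm([5, 8, 13, 5, 8, 13], ["a", "a", "a", "b", "b", "b"])
        assert res.fold_change == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_label_swap_gives_reciprocal(self, rng):
        y = np.concatenate([_nb_counts(rng, 1500, 10, 20), _nb_counts(rng, 3000, 10, 20)])
        g = ["x"] * 20 + ["y"] * 20
        fwd = fit_nbglm(y, g, reference="x")
        rev = fit_nbglm(y, g, reference="y")
        assert fwd.fold_change == pytest.approx(1 / rev.fold_change, rel=1e-6)
        assert fwd.p_value == pytest.approx(rev.p_value, rel=1e-4)

    def test_recovers_known_fold(self, rng):
        y = np.concatenate([_nb_counts(rng, 1500, 10, 200), _nb_counts(rng, 3450, 10, 200)])
        g = ["control"] * 200 + ["carrier"] * 200
        res = fit_nbglm(y, g)
        assert 2.0 <= res.fold_change <= 2.6
        assert 5 < res.theta < 20

    def test_poisson_limit_matches_poisson_glm(self):
        rng = np.random.default_rng(3)
        y = np.concatenate([rng.poisson(1500, 30), rng.poisson(1800, 30)])
        g = ["a"] * 30 + ["b"] * 30
        res = fit_nbglm(y, g)
        X = sm.add_constant(np.array([0.0] * 30 + [1.0] * 30))
        pois = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        assert res.theta > 1e3
        assert abs(res.p_value - pois.pvalues[1]) < 0.01

    def test_validation(self):
        with pytest.raises(ValueError):
            fit_nbglm([1, 2, 3], ["a", "a", "b"])  # <2 in one group
        with pytest.raises(ValueError):
            fit_nbglm([0, 0, 5, 6], ["a", "a", "b", "b"])  # all-zero group
        with pytest.raises(ValueError):
            fit_nbglm([1, 2, 3, 4], ["a", "a", "a", "a"])  # one group only


def _glmm_cohort(rng, fold=1.3, sigma_u=0.3, theta=10.0, base=1500.0,
                 n_ind=(8, 7), cells=(2, 8)):
    rows = []
    for g, n, mu in (("carrier", n_ind[0], base * fold), ("control", n_ind[1], base)):
        for i in range(n):
            m = mu * np.exp(rng.normal(0, sigma_u))
            for v in _nb_counts(rng, m, theta, rng.integers(cells[0], cells[1] + 1)):
                rows.append({"y": int(v), "group": g, "ind": f"{g}{i}"})
    return pd.DataFrame(rows)


class TestNbglmm:
    def test_agrees_with_glm_when_no_individual_variance(self, rng):
        df = _glmm_cohort(rng, fold=1.5, sigma_u=0.0, n_ind=(6, 6), cells=(4, 4))
        mm = fit_nbglmm(df.y, df.group, df.ind)
        glm = fit_nbglm(df.y, df.group)
        assert mm.random_intercept_sd < 0.05
        assert abs(mm.log_fc - glm.log_fc) < 2 * glm.log_fc_se

    def test_cell_order_permutation_invariant(self, rng):
        df = _glmm_cohort(rng, n_ind=(3, 3), cells=(3, 3))
        perm = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = fit_nbglmm(df.y, df.group, df.ind)
        b = fit_nbglmm(perm.y, perm.group, perm.ind)
        assert a.log_fc == pytest.approx(b.log_fc, abs=1e-6)
        assert a.theta == pytest.approx(b.theta, rel=1e-4)

    def test_single_individual_per_group_rejected(self):
        with pytest.raises(ValueError):
            fit_nbglmm([10, 12, 9, 11], ["a", "a", "b", "b"], ["i1", "i1", "i2", "i2"])

    def test_matches_glmmtmb_oracle(self, rng, tmp_path):
        """Cross-check the hand-rolled marginal likelihood against R glmmTMB."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        df = _glmm_cohort(rng, fold=1.4, sigma_u=0.3, n_ind=(5, 5), cells=(3, 5))
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(textwrap.dedent(f"""
            df <- read.csv("{csv}")
            df$group <- relevel(factor(df$group), ref="control")
            suppressMessages(library(glmmTMB))
            m <- glmmTMB(y ~ group + (1|ind), family=nbinom2, data=df)
            co <- summary(m)$coefficients$cond
            cat(co[2,1], co[2,2], sigma(m), sqrt(VarCorr(m)$cond$ind[1,1]), "\\n")
        """))
        out = subprocess.run(["Rscript", str(script)], capture_output=True, text=True,
                             check=True).stdout.split()
        r_logfc, r_se, r_theta, r_sdu = map(float, out)
        res = fit_nbglmm(df.y, df.group, df.ind)
        assert res.log_fc == pytest.approx(r_logfc, abs=0.02)
        assert res.log_fc_se == pytest.approx(r_se, rel=0.10)
        assert res.theta == pytest.approx(r_theta, rel=0.15)
        assert res.random_intercept_sd == pytest.approx(r_sdu, abs=0.05)


class TestCompareBurdens:
    def test_outlier_excluded_and_reported(self, rng):
        rows = []
        for g, mu, n_ind in (("carrier", 1900, 4), ("control", 1500, 4)):
            for i in range(n_ind):
                for j in range(4):
                    y = int(_nb_counts(rng, mu, 30, 1)[0])
                    rows.append({"cell_id": f"{g}{i}-{j}", "individual_id": f"{g}{i}",
                                 "group": g, "snv_count": y, "indel_count": y // 10,
                                 "snv_burden": float(y), "indel_burden": y / 10})
        table = pd.DataFrame(rows)
        # plant one extreme cell, mirroring a hypermutated outlier
        table.loc[table.cell_id == "control0-0",
                  ["snv_count", "snv_burden"]] = [15000, 15000.0]
        results, excluded = burden.compare_burdens(table, exclude_outliers=True)
        assert "control0-0" in excluded
        assert set(results.model) == {"NBGLM", "NBGLMM"}
        assert set(results.response) == {"SNV", "INDEL"}
        kept, _ = burden.compare_burdens(table, exclude_outliers=False)
        assert kept.excluded_outliers.eq("").all()
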