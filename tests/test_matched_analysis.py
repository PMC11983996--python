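import numpy as np
import pandas as pd
import pytest

from meddiet import matched_analysis as ma
from conftest import make_pair_sets


class TestMcNemar:
    def test_symmetric_discordance(self):
        case = [True] * 10 + [False] * 10
        ctrl = [False] * 10 + [True] * 10
        res = ma.mcnemar(case, ctrl)
        assert res.chi2 == 0.0 and res.p == pytest.approx(1.0)

    def test_direct_formula(self):
        # b = 15, c = 5 -> chi2 = 100/20 = 5
        case = [True] * 15 + [False] * 5 + [True] * 3
        ctrl = [False] * 15 + [True] * 5 + [True] * 3
        res = ma.mcnemar(case, ctrl)
        assert res.b == 15 and res.c == 5
        assert res.chi2 == pytest.approx(5.0)
        assert res.p == pytest.approx(0.025347, rel=1e-3)

    def test_no_discordant_pairs_flagged(self):
        res = ma.mcnemar([True, False], [True, False])
        assert not res.defined and np.isnan(res.chi2)


class TestClogitLoglik:
    def test_zero_beta_uniform_probability(self):
        sets = make_pair_sets(np.array([1.0, -2.0, 0.5, 3.0]))
        assert ma.clogit_loglik(np.zeros(1), sets) == pytest.approx(-4 * np.log(2))

    def test_scalar_closed_form(self):
        sets = make_pair_sets(np.array([1.0]))
        expected = -np.log(1 + np.exp(-0.5))
        assert ma.clogit_loglik(np.array([0.5]), sets) == pytest.approx(expected, rel=1e-12)

    def test_two_formula_equivalence(self):
        """Set-sum form equals the pair-difference form on a random instance."""
        rng = np.random.default_rng(17)
        X = rng.normal(size=(6, 2, 3))
        sets = [ma.MatchedSet(f"p{i}", X[i], ("a", "b")) for i in range(6)]
        beta = rng.normal(size=3)
        direct = sum(
            float(x[0] @ beta - np.log(np.sum(np.exp(x @ beta)))) for x in X
        )
        diff_form = -float(
            np.sum(np.log1p(np.exp(-(X[:, 0] - X[:, 1]) @ beta)))
        )
        assert ma.clogit_loglik(beta, sets) == pytest.approx(direct, abs=1e-10)
        assert ma.clogit_loglik(beta, sets) == pytest.approx(diff_form, abs=1e-10)

    def test_non_finite_covariates_rejected(self):
        sets = make_pair_sets(np.array([np.inf]))
        with pytest.raises(ma.AnalysisError, match="non-finite"):
            ma.clogit_loglik(np.zeros(1), sets)


class TestFitClogit:
    def test_symmetric_pairs_give_null_estimate(self):
        fit = ma.fit_clogit(make_pair_sets(np.array([1.0, -1.0])))
        assert fit.converged
        assert fit.beta[0] == pytest.approx(0.0, abs=1e-10)
        assert fit.or_[0] == pytest.approx(1.0)

    def test_two_to_one_discordance_gives_log2(self):
        # maximizing -2 log(1+e^-b) - log(1+e^b) gives b = ln 2
        fit = ma.fit_clogit(make_pair_sets(np.array([1.0, 1.0, -1.0])))
        assert fit.converged
        assert fit.beta[0] == pytest.approx(np.log(2.0), abs=1e-6)
        assert fit.or_[0] == pytest.approx(2.0, abs=1e-5)

    def test_separation_flagged_without_finite_estimate(self):
        fit = ma.fit_clogit(make_pair_sets(np.array([1.0, 1.0, 1.0])), names=("d",))
        assert not fit.converged
        assert any("monotone-likelihood" in f for f in fit.flags)
        assert np.isnan(fit.beta).all()

    def test_pair_constant_shift_leaves_estimates_unchanged(self):
        """Matching factors (constant within pair) carry no information."""
        rng = np.random.default_rng(2)
        D = rng.normal(size=(30, 2))
        sets = make_pair_sets(D)
        base = ma.fit_clogit(sets)
        shifted = []
        for i, s in enumerate(sets):
            X = s.X.copy()
            X[:, 0] += 7.5 * i  # same shift for case and control
            shifted.append(ma.MatchedSet(s.set_id, X, s.subject_ids))
        fit = ma.fit_clogit(shifted)
        np.testing.assert_allclose(fit.beta, base.beta, atol=1e-8)
        assert fit.loglik == pytest.approx(base.loglik, abs=1e-8)

    def test_set_order_permutation_is_invariant(self):
        rng = np.random.default_rng(4)
        D = rng.normal(size=(25, 3))
        sets = make_pair_sets(D)
        base = ma.fit_clogit(sets)
        permuted = [sets[i] for i in rng.permutation(len(sets))]
        fit = ma.fit_clogit(permuted)
        assert np.array_equal(fit.beta, base.beta)
        assert fit.loglik == base.loglik

    def test_collinear_columns_named(self):
        rng = np.random.default_rng(6)
        d = rng.normal(size=(20, 1))
        D = np.hstack([d, 2.0 * d])
        with pytest.raises(ma.AnalysisError, match="x[01]"):
            ma.fit_clogit(make_pair_sets(D), names=("x0", "x1"))

    def test_likelihood_ascent(self):
        """The Newton path never decreases the log-likelihood."""
        rng = np.random.default_rng(9)
        D = rng.normal(size=(40, 2)) + 0.3
        sets = make_pair_sets(D)
        logliks = []
        beta = np.zeros(2)
        stacked = np.stack([s.X for s in sets])
        for _ in range(8):
            ll, grad, info = ma._score_and_info(beta, sets, stacked)
            logliks.append(ll)
            step = np.linalg.solve(info, grad)
            factor = 1.0
            while ma.clogit_loglik(beta + factor * step, sets) < ll - 1e-12:
                factor /= 2.0
            beta = beta + factor * step
        assert all(b >= a - 1e-12 for a, b in zip(logliks, logliks[1:]))

    def test_agrees_with_statsmodels_conditional_logit(self):
        """Independent cross-check against the reference implementation."""
        smd = pytest.importorskip("statsmodels.discrete.conditional_models")
        rng = np.random.default_rng(13)
        n = 120
        X = rng.normal(size=(2 * n, 2))
        groups = np.repeat(np.arange(n), 2)
        beta_true = np.array([0.6, -0.4])
        sets = []
        y = np.zeros(2 * n)
        for i in range(n):
            xi = X[2 * i: 2 * i + 2]
            eta = xi @ beta_true
            p_first = np.exp(eta[0]) / np.exp(eta).sum()
            case = 0 if rng.random() < p_first else 1
            y[2 * i + case] = 1
            rows = np.vstack([xi[case], xi[1 - case]])
            sets.append(ma.MatchedSet(f"p{i}", rows, ("a", "b")))
        fit = ma.fit_clogit(sets, names=("x0", "x1"))
        ref = smd.ConditionalLogit(y, X, groups=groups).fit(disp=False)
        # the reference optimizer converges to ~1e-4; ours to 1e-8
        np.testing.assert_allclose(fit.beta, ref.params, atol=2e-4)
        np.testing.assert_allclose(fit.se, ref.bse, atol=2e-4)


class TestPairDifferenceOracle:
    def test_agrees_with_newton_fit_scalar(self):
        sets = make_pair_sets(np.array([1.0, 1.0, -1.0]))
        oracle = ma.pair_difference_oracle(sets)
        assert oracle.beta[0] == pytest.approx(np.log(2.0), abs=1e-6)

    def test_symmetric_case_is_null(self):
        oracle = ma.pair_difference_oracle(make_pair_sets(np.array([2.0, -2.0])))
        assert oracle.beta[0] == pytest.approx(0.0, abs=1e-6)

    def test_rejects_non_pair_sets(self):
        X = np.zeros((3, 1))
        trio = ma.MatchedSet("t", X, ("a", "b"))
        with pytest.raises(ma.AnalysisError, match="1:1"):
            ma.pair_difference_oracle([trio])


class TestBuildSets:
    def subjects(self):
        rows = []
        specs = [
            ("P0", "colon"), ("P1", "colon"), ("P2", "rectum"),
            ("P3", "other"), ("P4", "rectum"),
        ]
        for i, (pid, sub) in enumerate(specs):
            rows.append({"subject_id": f"C{i}", "pair_id": pid, "status": "case",
                         "sex": "M" if i % 2 == 0 else "F", "subsite": sub,
                         "age": 50.0 + i, "energy_kcal_per_day": 2000.0})
            rows.append({"subject_id": f"K{i}", "pair_id": pid, "status": "control",
                         "sex": "M" if i % 2 == 0 else "F", "subsite": "",
                         "age": 51.0 + i, "energy_kcal_per_day": 2100.0})
        return pd.DataFrame(rows).set_index("subject_id")

    def scores(self, subjects):
        cats = ["low", "medium", "high", "low", "high", "medium", "low", "low",
                "high", "medium", "low", "high"]
        return pd.DataFrame({"category": cats[: len(subjects)]}, index=subjects.index)

    def test_subsite_filter_counts(self):
        subj = self.subjects()
        spec = ma.ModelSpec(covariates=("age",), subsite="colon")
        sets, names, dropped = ma.build_sets(subj, self.scores(subj), spec)
        assert len(sets) == 2 and dropped == 0
        assert names == ("md_medium", "md_high", "age")

    def test_malformed_pair_dropped_and_logged(self, caplog):
        subj = self.subjects()
        extra = subj.loc[["K0"]].rename(index={"K0": "K9"})
        extra["pair_id"] = "P0"  # second control in P0
        subj = pd.concat([subj, extra])
        spec = ma.ModelSpec(covariates=("age",), subsite="all")
        sets, _, dropped = ma.build_sets(subj, self.scores(subj), spec)
        assert dropped == 1 and len(sets) == 4

    def test_matches_row_by_row_filter_oracle(self):
        subj = self.subjects()
        scores = self.scores(subj)
        for subsite in ("all", "colon", "rectum"):
            for sex in ("all", "M", "F"):
                expected = []
                for pid in sorted(subj["pair_id"].unique()):
                    grp = subj[subj["pair_id"] == pid]
                    case = grp[grp["status"] == "case"].iloc[0]
                    if subsite != "all" and case["subsite"] != subsite:
                        continue
                    if sex != "all" and set(grp["sex"]) != {sex}:
                        continue
                    expected.append(pid)
                spec = ma.ModelSpec(covariates=(), subsite=subsite, sex=sex)
                if not expected:
                    with pytest.raises(ma.AnalysisError):
                        ma.build_sets(subj, scores, spec)
                else:
                    sets, _, _ = ma.build_sets(subj, scores, spec)
                    assert [s.set_id for s in sets] == expected

    def test_zero_surviving_sets_is_an_error(self):
        subj = self.subjects()
        subj["subsite"] = subj["subsite"].replace("colon", "other")
        spec = ma.ModelSpec(covariates=(), subsite="colon")
        with pytest.raises(ma.AnalysisError, match="no matched sets"):
            ma.build_sets(subj, self.scores(subj), spec)


class TestOracleEquivalenceProperty:
    def test_randomized_instances_agree(self):
        """Newton fit and the difference-model oracle agree on >= 100 instances."""
        rng = np.random.default_rng(1234)
        checked = 0
        while checked < 100:
            n_pairs = int(rng.integers(4, 21))
            p = int(rng.integers(1, 4))
            D = rng.normal(scale=1.0, size=(n_pairs, p))
            sets = make_pair_sets(D)
            fit = ma.fit_clogit(sets)
            if not fit.converged:
                continue
            if np.abs(fit.beta).max() > 4.0:  # near-separated: oracle grid too coarse
                continue
            oracle = ma.pair_difference_oracle(sets)
            np.testing.assert_allclose(fit.beta, oracle.beta, atol=1e-6)
            assert abs(fit.loglik - oracle.loglik) < 1e-6
            checked += 1


class TestOrTable:
    def fit_with(self, beta, se, names=("md_medium", "md_high")):
        k = len(names)
        return ma.FitResult(names=tuple(names), beta=np.asarray(beta, float),
                            cov=np.diag(np.square(se)), loglik=-1.0, n_sets=10,
                            converged=True, n_iter=3)

    def test_reference_row_is_exactly_one(self):
        rows = [{"subsite": "all", "stratum": "all",
                 "counts": {"low": (5, 6), "medium": (7, 7), "high": (8, 7)},
                 "crude": self.fit_with([0.0, 0.1], [0.1, 0.1]),
                 "adjusted": self.fit_with([0.0, 0.2], [0.1, 0.1])}]
        table = ma.or_table(rows)
        ref = table[table["category"] == "low"].iloc[0]
        assert ref["or_crude"] == 1.0 and ref["or_adjusted"] == 1.0
        assert np.isnan(ref["ci_crude_low"])

    def test_wald_interval_values(self):
        # beta = 0, SE = 0.1 -> OR 1.00, CI (0.82, 1.22)
        rows = [{"subsite": "all", "stratum": "all",
                 "counts": {"low": (1, 1), "medium": (1, 1), "high": (1, 1)},
                 "crude": None,
                 "adjusted": self.fit_with([0.0, 0.0], [0.1, 0.1])}]
        table = ma.or_table(rows)
        med = table[table["category"] == "medium"].iloc[0]
        assert med["or_adjusted"] == pytest.approx(1.0)
        assert med["ci_adjusted_low"] == pytest.approx(np.exp(-0.196), rel=1e-6)
        assert med["ci_adjusted_high"] == pytest.approx(np.exp(0.196), rel=1e-6)
        assert round(med["ci_adjusted_low"], 2) == 0.82
        assert round(med["ci_adjusted_high"], 2) == 1.22

    def test_row_cardinality(self):
        rows = [
            {"subsite": s, "stratum": st, "counts": {}, "crude": None, "adjusted": None}
            for s in ("all", "colon", "rectum") for st in ("all", "M", "F")
        ]
        table = ma.or_table(rows)
        assert len(table) == 3 * 3 * 3  # subsites x strata x categories
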