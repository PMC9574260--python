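"""Growth-curve analysis: orthogonal time basis, empirical log-odds, fitting."""

import numpy as np
import pandas as pd
import pytest

from preflook.gca import (
    GCAModelSpec,
    empirical_log_odds,
    fit_gca,
    orthogonal_time_basis,
    random_structure_backoff,
)


class TestTimeBasis:
    def test_three_bins_linear_contrast(self):
        basis = orthogonal_time_basis(3, order=1)
        np.testing.assert_allclose(
            basis.columns[:, 0], np.array([-1.0, 0.0, 1.0]) / np.sqrt(2), atol=1e-12
        )

    @pytest.mark.parametrize("n_bins,order", [(5, 3), (20, 3), (13, 2)])
    def test_orthonormal_zero_sum(self, n_bins, order):
        cols = orthogonal_time_basis(n_bins, order).columns
        gram = cols.T @ cols
        np.testing.assert_allclose(gram, np.eye(order), atol=1e-9)
        np.testing.assert_allclose(cols.sum(axis=0), 0.0, atol=1e-9)

    def test_matches_gram_schmidt_oracle(self):
        n = 20
        t = np.arange(n, dtype=float)
        # independent Gram-Schmidt of (1, t, t^2, t^3)
        vs = [np.ones(n), t, t**2, t**3]
        basis = []
        for v in vs:
            w = v.copy()
            for b in basis:
                w = w - (w @ b) * b
            basis.append(w / np.linalg.norm(w))
        oracle = np.column_stack(basis[1:])
        mine = orthogonal_time_basis(n, 3).columns
        # align signs column-wise before comparing
        signs = np.sign((oracle * mine).sum(axis=0))
        np.testing.assert_allclose(mine * signs, oracle, atol=1e-9)

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            orthogonal_time_basis(3, order=3)


class TestEmpiricalLogOdds:
    @pytest.mark.parametrize(
        "F,N,c,expected",
        [
            (5, 10, 0.0, 0.0),
            (2, 10, 0.0, np.log(0.25)),
            (10, 10, 0.5, np.log(21.0)),
        ],
    )
    def test_known_values(self, F, N, c, expected):
        assert empirical_log_odds(F, N, c) == pytest.approx(expected, abs=1e-12)

    def test_undefined_cases_are_nan(self):
        assert np.isnan(empirical_log_odds(0, 0, 0.5))
        assert np.isnan(empirical_log_odds(10, 10, 0.0))


class TestBackoffLadder:
    def test_ladder_is_deterministic_and_ordered(self):
        spec = GCAModelSpec()
        ladder = random_structure_backoff(spec)
        assert ladder == [
            "~1 + ot1 + ot2 + ot3",
            "~1 + ot1 + ot2",
            "~1 + ot1",
            "~1",
            "none",
        ]
        assert ladder == random_structure_backoff(spec)


def _uniform_bin_table(n_subj=4, n_items=8, n_bins=21, F=5, N=10):
    rows = []
    for s in range(n_subj):
        for it in range(n_items):
            for b in range(n_bins):
                rows.append(
                    {
                        "participant_id": f"S{s}",
                        "group": "TD",
                        "condition": ["CV", "MV", "UV"][it % 3],
                        "item_id": it + 1,
                        "trial_index": it + 1,
                        "t_start_rel": 4000.0 + 100.0 * b,
                        "F": F,
                        "N": N,
                        "n_grid": N,
                        "p": F / N,
                    }
                )
    return pd.DataFrame(rows)


class TestFitGCA:
    def test_symmetric_data_has_zero_intercept(self):
        bins = _uniform_bin_table(F=5, N=10)
        fit = fit_gca(bins)
        intercept = fit.table.loc[fit.table["term"] == "Intercept", "estimate"].iloc[0]
        assert intercept == pytest.approx(0.0, abs=1e-6)

    def test_wls_rung_matches_lstsq_oracle(self, rng):
        """UV-only data with no random effects reduces to weighted least
        squares on the polynomial design; compare with a direct solve."""
        n_bins = 21
        starts = 4000.0 + 100.0 * np.arange(n_bins)
        rows = []
        for s in range(4):
            for tr in range(6):
                N = rng.integers(3, 6, n_bins)
                F = rng.binomial(N, 0.6)
                for b in range(n_bins):
                    rows.append(
                        {
                            "participant_id": f"S{s}", "group": "TD", "condition": "UV",
                            "item_id": tr + 1, "trial_index": tr + 1,
                            "t_start_rel": starts[b], "F": F[b], "N": N[b],
                            "n_grid": 5, "p": F[b] / N[b],
                        }
                    )
        bins = pd.DataFrame(rows)
        fit = fit_gca(bins, structure="none")
        assert fit.structure_used == "none"

        from preflook.gca import orthogonal_time_basis as otb

        basis = otb(n_bins, 3, bin_starts=starts)
        lookup = {s: basis.columns[i] for i, s in enumerate(starts)}
        d = bins[bins["N"] > 0].copy()
        y = empirical_log_odds(d["F"], d["N"], 0.5)
        X = np.column_stack(
            [np.ones(len(d))] + [np.array([lookup[s][k] for s in d["t_start_rel"]]) for k in range(3)]
        )
        w = d["N"].to_numpy(float)
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
        got = fit.table.set_index("term")["estimate"]
        np.testing.assert_allclose(
            [got["Intercept"], got["Linear"], got["Quadratic"], got["Cubic"]],
            beta,
            atol=1e-8,
        )

    def test_quadratic_condition_contrast_recovered(self, rng):
        """Data built with a pure quadratic condition difference should put the
        largest interaction on the quadratic x condition term."""
        n_bins = 21
        starts = 4000.0 + 100.0 * np.arange(n_bins)
        from preflook.gca import orthogonal_time_basis as otb

        q = otb(n_bins, 3, bin_starts=starts).columns[:, 1]
        rows = []
        for s in range(6):
            subj_eff = rng.normal(0, 0.2)
            for tr in range(8):
                cond = "CV" if tr % 2 else "UV"
                eta = subj_eff + (2.0 * q if cond == "CV" else 0.0)
                p = 1 / (1 + np.exp(-eta))
                N = np.full(n_bins, 40)
                F = rng.binomial(N, p)
                for b in range(n_bins):
                    rows.append(
                        {
                            "participant_id": f"S{s}", "group": "TD", "condition": cond,
                            "item_id": tr + 1, "trial_index": tr + 1,
                            "t_start_rel": starts[b], "F": F[b], "N": int(N[b]),
                            "n_grid": 40, "p": F[b] / N[b],
                        }
                    )
        fit = fit_gca(pd.DataFrame(rows))
        tab = fit.table.set_index("term")
        interactions = [t for t in tab.index if ":" in t]
        largest = max(interactions, key=lambda t: abs(tab.loc[t, "estimate"]))
        assert largest == "Quadratic:CV"
        assert tab.loc["Quadratic:CV", "estimate"] == pytest.approx(2.0, rel=0.15)

    def test_full_cohort_fit_reports_condition_terms(self, ds_bins):
        fit = fit_gca(ds_bins)
        terms = set(fit.table["term"])
        assert {"CV", "MV", "Linear", "Quadratic", "Cubic"} <= terms
        assert fit.converged
        # DS-like cohort anticipates in CV only inside the 4000-6000 window
        cv = fit.table.set_index("term").loc["CV"]
        assert cv["estimate"] > 0 and cv["p"] < 0.05

    def test_group_interaction_signs_for_delayed_profile(self, ds_bins):
        """TD + DS joint fit: positive CV/MV main effects (TD anticipates in
        both) and a negative MV x group interaction (the DS profile lacks MV
        anticipation)."""
        from preflook.preprocess import preprocess_cohort
        from preflook.simulate import generate_cohort

        trials, design = generate_cohort(10, "TD", seed=515)
        td_bins = preprocess_cohort(trials, design)
        both = pd.concat([td_bins, ds_bins], ignore_index=True)
        fit = fit_gca(both)
        tab = fit.table.set_index("term")
        assert tab.loc["CV", "estimate"] > 0
        assert tab.loc["MV", "estimate"] > 0
        assert tab.loc["MV:Group", "estimate"] < 0
        assert tab.loc["MV:Group", "p"] < 0.05

    def test_statistic_is_estimate_over_se(self, td_bins_small):
        fit = fit_gca(td_bins_small)
        tab = fit.table
        np.testing.assert_allclose(
            tab["statistic"], tab["estimate"] / tab["SE"], atol=1e-6
        )

    def test_type_one_error_rate_plausible_under_null(self, rng):
        """Null bin tables (iid binomial at chance): the CV main-effect test
        should reject at roughly the nominal 5% level."""
        rejections = 0
        n_rep = 60
        for rep in range(n_rep):
            rows = []
            for s in range(8):
                for tr in range(12):
                    cond = ["CV", "MV", "UV"][tr % 3]
                    N = np.full(21, 5)
                    F = rng.binomial(N, 0.5)
                    for b in range(21):
                        rows.append(
                            {
                                "participant_id": f"S{s}", "group": "TD", "condition": cond,
                                "item_id": tr + 1, "trial_index": tr + 1,
                                "t_start_rel": 4000.0 + 100.0 * b, "F": F[b],
                                "N": 5, "n_grid": 5, "p": F[b] / 5,
                            }
                        )
            fit = fit_gca(pd.DataFrame(rows), structure="none")
            p = fit.table.set_index("term").loc["CV", "p"]
            rejections += p < 0.05
        assert 0 <= rejections <= int(0.15 * n_rep)
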