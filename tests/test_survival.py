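import itertools

import numpy as np
import pandas as pd
import pytest

from hfnet import cohortsim
from hfnet.survival import (
    fit_cox,
    hr_table,
    kaplan_meier,
    km_median,
    pc_risk,
    quartile_encode,
)


def breslow_free_loglik(beta, x, time, event):
    """Independent partial log-likelihood for tie-free data."""
    ll = 0.0
    for i in range(len(time)):
        if event[i] == 1:
            risk = [j for j in range(len(time)) if time[j] >= time[i]]
            ll += beta * x[i] - np.log(sum(np.exp(beta * x[j]) for j in risk))
    return ll


def grid_max(x, time, event, lo=-6, hi=6):
    # coarse grid then local refinement (two-stage, still oracle-driven)
    grid = np.linspace(lo, hi, 6001)
    vals = [breslow_free_loglik(b, x, time, event) for b in grid]
    best = grid[int(np.argmax(vals))]
    fine = np.linspace(best - 0.005, best + 0.005, 2001)
    vals = [breslow_free_loglik(b, x, time, event) for b in fine]
    return fine[int(np.argmax(vals))]


class TestQuartileEncode:
    def test_hand_example(self):
        np.testing.assert_array_equal(
            quartile_encode(np.arange(1, 9)), [1, 1, 2, 2, 3, 3, 4, 4]
        )

    def test_monotone_invariance(self, rng):
        v = rng.gamma(2, 3, size=57) + 0.1
        np.testing.assert_array_equal(
            quartile_encode(v), quartile_encode(v ** 3)
        )
        np.testing.assert_array_equal(
            quartile_encode(v), quartile_encode(np.exp(v), log_transform=False)
        )

    def test_all_equal_rejected(self):
        with pytest.raises(ValueError):
            quartile_encode(np.ones(10))

    def test_tie_at_quartile_goes_down(self):
        v = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0])
        codes = quartile_encode(v)
        q25 = np.quantile(np.log2(v), 0.25)
        at = np.isclose(np.log2(v), q25)
        if at.any():
            assert codes[at][0] == 1


class TestFitCox:
    def test_four_subject_grid_oracle(self):
        # x=(0,1,0,1) alternates deaths between groups -> finite maximum;
        # the fully separated pattern (0,0,1,1) is covered by
        # test_separation_flagged (its likelihood is monotone)
        time = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.ones(4, dtype=int)
        x = np.array([0.0, 1.0, 0.0, 1.0])
        fit = fit_cox(time, event, x[:, None])
        assert fit.converged
        assert fit.beta[0] == pytest.approx(grid_max(x, time, event), abs=1e-4)

    def test_enumerated_small_datasets_vs_grid(self):
        # all single-covariate binary designs, distinct times, n in 4..6,
        # with every event pattern having >= 2 events
        checked = 0
        for n in (4, 5, 6):
            time = np.arange(1.0, n + 1)
            for xs in itertools.product([0.0, 1.0], repeat=n):
                x = np.array(xs)
                if x.std() == 0:
                    continue
                for ev in ([1] * n, [1] * (n - 1) + [0], [0] + [1] * (n - 1)):
                    event = np.array(ev)
                    # skip degenerate separations (monotone likelihood)
                    fit = fit_cox(time, event, x[:, None])
                    if fit.warnings:
                        continue
                    oracle = grid_max(x, time, event)
                    if abs(oracle) > 5.5:
                        continue  # maximum near the grid edge
                    assert fit.beta[0] == pytest.approx(oracle, abs=1e-4)
                    checked += 1
        assert checked > 50

    def test_matches_lifelines_on_random_datasets(self):
        from lifelines import CoxPHFitter

        for rep in range(50):
            r = np.random.default_rng(rep)
            n = int(r.integers(30, 80))
            p = int(r.integers(1, 4))
            x = r.normal(size=(n, p))
            beta_true = r.uniform(-0.5, 0.5, size=p)
            t = r.exponential(1.0 / (0.3 * np.exp(x @ beta_true)))
            t = np.round(t, 1) + 0.05  # induce ties
            c = r.uniform(0.5, 6.0, size=n)
            event = (t < c).astype(int)
            if event.sum() < 5:
                continue
            time = np.minimum(t, c)
            fit = fit_cox(time, event, x)
            df = pd.DataFrame(x, columns=[f"x{j}" for j in range(p)])
            df["T"], df["E"] = time, event
            cph = CoxPHFitter()
            cph.fit(
                df, duration_col="T", event_col="E",
                fit_options={"precision": 1e-12},
            )
            np.testing.assert_allclose(
                fit.beta, cph.params_.to_numpy(), atol=1e-6
            )
            np.testing.assert_allclose(
                fit.se, cph.standard_errors_.to_numpy(), atol=1e-6
            )

    def test_null_covariate_type_i_error(self):
        rej = 0
        n_rep = 800
        for rep in range(n_rep):
            r = np.random.default_rng(rep)
            n = 80
            x = r.normal(size=n)
            t = r.exponential(2.0, size=n)
            c = r.uniform(0, 4, size=n)
            event = (t < c).astype(int)
            if event.sum() < 2:
                continue
            fit = fit_cox(np.minimum(t, c), event, x[:, None])
            rej += fit.p[0] < 0.05
        assert 0.02 <= rej / n_rep <= 0.08

    def test_parameter_recovery(self):
        betas = []
        for rep in range(40):
            r = np.random.default_rng(rep)
            n = 500
            x = r.normal(size=n)
            t = r.exponential(1.0 / (0.3 * np.exp(0.7 * x)))
            fit = fit_cox(t, np.ones(n, dtype=int), x[:, None])
            betas.append(fit.beta[0])
        assert np.mean(betas) == pytest.approx(0.7, abs=0.05)

    def test_translation_invariance(self, rng):
        n = 100
        x = rng.normal(size=n)
        t = rng.exponential(1.0, size=n)
        event = rng.integers(0, 2, size=n)
        event[0] = 1
        f1 = fit_cox(t, event, x[:, None])
        f2 = fit_cox(t, event, (x + 100.0)[:, None])
        assert f1.beta[0] == pytest.approx(f2.beta[0], abs=1e-6)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-6)

    def test_constant_covariate_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            fit_cox([1.0, 2.0, 3.0], [1, 1, 1], np.ones((3, 1)))

    def test_no_events_rejected(self, rng):
        with pytest.raises(ValueError, match="event"):
            fit_cox([1.0, 2.0], [0, 0], np.array([[0.0], [1.0]]))

    def test_separation_flagged(self):
        # early deaths all in one covariate group -> monotone likelihood
        time = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        event = np.array([1, 1, 1, 0, 0, 0])
        x = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
        fit = fit_cox(time, event, x[:, None])
        assert fit.warnings
        assert not fit.converged

    def test_ci_contains_point_estimate(self, rng):
        n = 200
        x = rng.normal(size=(n, 2))
        t = rng.exponential(1.0 / (0.3 * np.exp(0.4 * x[:, 0])))
        fit = fit_cox(t, np.ones(n, dtype=int), x)
        assert np.all(fit.hr_low <= fit.hr)
        assert np.all(fit.hr <= fit.hr_high)
        assert np.all(fit.hr > 0)


class TestHrTable:
    def test_planted_quartile_hr(self):
        hrs = []
        for rep in range(15):
            r = np.random.default_rng(rep)
            n = 500
            marker = 2.0 ** r.normal(5, 1, size=n)
            q = quartile_encode(marker).astype(float)
            t = r.exponential(1.0 / (0.05 * np.exp(np.log(2.0) * q)))
            c = r.uniform(0.5, 8.0, size=n)
            event = (t < c).astype(int)
            tab = hr_table(
                pd.DataFrame({"m": marker}), np.minimum(t, c), event
            )
            hrs.append(tab.loc["m", "crude_hr"])
        assert np.mean(hrs) == pytest.approx(2.0, rel=0.1)

    def test_null_cohort_fdr(self):
        frac = []
        for rep in range(25):
            r = np.random.default_rng(rep)
            n = 120
            markers = pd.DataFrame(
                2.0 ** r.normal(0, 1, size=(n, 10)),
                columns=[f"m{j}" for j in range(10)],
            )
            t = r.exponential(2.0, size=n)
            c = r.uniform(0, 4.0, size=n)
            tab = hr_table(markers, np.minimum(t, c), (t < c).astype(int))
            frac.append(tab["crude_significant"].mean())
        assert np.mean(frac) <= 0.05

    def test_adjustment_attenuates_proxy(self):
        r = np.random.default_rng(1)
        n = 600
        confounder = r.normal(size=n)
        marker = 2.0 ** (5 + confounder + 0.3 * r.normal(size=n))
        t = r.exponential(1.0 / (0.2 * np.exp(0.8 * confounder)))
        event = np.ones(n, dtype=int)
        adjust = pd.DataFrame({"confounder": confounder})
        tab = hr_table(pd.DataFrame({"m": marker}), t, event, adjust=adjust)
        assert tab.loc["m", "crude_hr"] > 1.3
        assert abs(np.log(tab.loc["m", "adj_hr"])) < abs(
            np.log(tab.loc["m", "crude_hr"])
        )

    def test_q_at_least_p(self, rng):
        n = 200
        markers = pd.DataFrame(
            2.0 ** rng.normal(0, 1, size=(n, 5)), columns=list("abcde")
        )
        t = rng.exponential(2.0, size=n)
        tab = hr_table(markers, t, np.ones(n, dtype=int))
        assert (tab["crude_q"] >= tab["crude_p"] - 1e-15).all()

    def test_missing_covariate_named(self, rng):
        n = 50
        markers = pd.DataFrame(2.0 ** rng.normal(size=(n, 2)), columns=["a", "b"])
        adjust = pd.DataFrame({"egfr": np.full(n, np.nan)})
        with pytest.raises(ValueError, match="egfr"):
            hr_table(markers, rng.exponential(size=n), np.ones(n, dtype=int), adjust)


class TestKaplanMeier:
    def test_no_censoring_matches_ecdf(self, rng):
        t = rng.exponential(2.0, size=100)
        km = kaplan_meier(t, np.ones(100, dtype=int))["all"]
        for _, row in km.iterrows():
            emp = np.mean(t > row["time"])
            assert row["survival"] == pytest.approx(emp, abs=1e-12)

    def test_all_censored_stays_one(self, rng):
        t = rng.exponential(2.0, size=50)
        km = kaplan_meier(t, np.zeros(50, dtype=int))["all"]
        assert (km["survival"] == 1.0).all()

    def test_exponential_median_closed_form(self):
        lam = 0.5
        r = np.random.default_rng(0)
        t = r.exponential(1.0 / lam, size=2000)
        km = kaplan_meier(t, np.ones(2000, dtype=int))["all"]
        assert km_median(km) == pytest.approx(np.log(2) / lam, rel=0.05)

    def test_greenwood_ci_ordering(self, rng):
        t = rng.exponential(2.0, size=80)
        c = rng.uniform(0, 4, size=80)
        km = kaplan_meier(np.minimum(t, c), (t < c).astype(int))["all"]
        assert (km["ci_low"] <= km["survival"] + 1e-12).all()
        assert (km["survival"] <= km["ci_high"] + 1e-12).all()


class TestPcRisk:
    def test_null_scores_hr_near_one(self):
        hrs = []
        for rep in range(30):
            r = np.random.default_rng(rep)
            n = 200
            scores = pd.DataFrame(
                {"PC1": r.normal(size=n), "PC2": r.normal(size=n)}
            )
            t = r.exponential(2.0, size=n)
            c = r.uniform(0, 4, size=n)
            res = pc_risk(scores, np.minimum(t, c), (t < c).astype(int))
            hrs.append(np.log(res.loc["PC1_low_vs_high", "hr"]))
        assert np.mean(hrs) == pytest.approx(0.0, abs=0.1)

    def test_deterministic(self, rng):
        n = 150
        scores = pd.DataFrame({"PC1": rng.normal(size=n), "PC2": rng.normal(size=n)})
        t = rng.exponential(2.0, size=n)
        e = rng.integers(0, 2, size=n)
        e[:5] = 1
        r1 = pc_risk(scores, t, e)
        r2 = pc_risk(scores, t, e)
        pd.testing.assert_frame_equal(r1, r2)

    def test_severity_linked_quadrants(self):
        # worst-vs-best quadrant HR exceeds both single-axis HRs in most
        # replicates when hazard follows the latent severity
        wins = 0
        n_rep = 15
        for rep in range(n_rep):
            r = np.random.default_rng(rep)
            n = 500
            sev = r.standard_normal(n)
            pc1 = -sev + 0.8 * r.normal(size=n)  # higher score = better
            pc2 = -sev + 0.8 * r.normal(size=n)
            t = r.exponential(1.0 / (0.3 * np.exp(0.7 * sev)))
            c = r.uniform(1, 5, size=n)
            event = (t < c).astype(int)
            res = pc_risk(
                pd.DataFrame({"PC1": pc1, "PC2": pc2}),
                np.minimum(t, c), event,
            )
            ll = res.loc["LL_vs_UR", "hr"]
            if ll > res.loc["PC1_low_vs_high", "hr"] and ll > res.loc["PC2_low_vs_high", "hr"]:
                wins += 1
        assert wins / n_rep >= 0.8

    def test_default_cohort_quadrant_direction(self, default_cohort):
        from hfnet.pca_summary import category_scores

        table, _ = default_cohort
        hf = table[(table["group"] == "HF") & table["activity_valid"]].reset_index(drop=True)
        scores, _ = category_scores(hf)
        res = pc_risk(
            scores.rename(columns={"capacity_PC1": "PC1", "myocardial_PC1": "PC2"}),
            hf["time"], hf["event"],
        )
        assert res.loc["LL_vs_UR", "hr"] > 1.0
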