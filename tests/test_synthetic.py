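"""Synthetic cohort generator: determinism, calibration, flow emulation."""

import dataclasses

import numpy as np
import pytest

import mcogscore as m
from mcogscore.roc import LabelledScores, empirical_roc
from mcogscore.synthetic import (
    binormal_auc,
    binormal_scores,
    default_config,
    expected_mmse_moments,
    items_frame,
    missingness_report,
    roster_frame,
)


def clean_config(n_healthy, n_impaired, **overrides):
    """Default calibration without missingness or flow emulation."""
    cfg = default_config(emulate_flow=False)
    cfg = dataclasses.replace(
        cfg,
        healthy=dataclasses.replace(cfg.healthy, n=n_healthy),
        impaired=dataclasses.replace(cfg.impaired, n=n_impaired),
        p_upload_failure=0.0,
        skip={k: dataclasses.replace(v, base=-50.0) for k, v in cfg.skip.items()},
    )
    return dataclasses.replace(cfg, **overrides) if overrides else cfg


def composite_by_group(roster):
    scores = m.score_cohort([r for r in roster])
    comp = scores[scores.status == "complete"]
    return comp


class TestDeterminism:
    def test_same_seed_identical_roster(self):
        cfg = default_config()
        a = m.simulate_cohort(cfg, 123)
        b = m.simulate_cohort(cfg, 123)
        assert roster_frame(a).equals(roster_frame(b))
        assert items_frame(a).equals(items_frame(b))

    def test_different_seed_differs(self):
        cfg = default_config()
        a = m.simulate_cohort(cfg, 1)
        b = m.simulate_cohort(cfg, 2)
        assert not items_frame(a).equals(items_frame(b))


class TestFlowEmulation:
    def test_consented_roster_size_and_dispositions(self):
        roster = m.simulate_cohort(default_config(), 5)
        assert len(roster) == 108
        included, ledger = m.apply_exclusions(roster)
        assert ledger.counts == {
            "included": 72, "revoked_consent": 1, "cdr_gt_1": 2,
            "upload_failed": 7, "incomplete_mcog": 26,
        }
        # 33 participants lack a complete test triplet
        assert ledger.counts["upload_failed"] + ledger.counts["incomplete_mcog"] == 33
        groups = [r.impaired for r in included]
        assert sum(not g for g in groups) == 38 and sum(groups) == 34

    def test_skip_split_expectation(self):
        """Average per-subtest skip counts approach the observed 9:5:12."""
        totals = np.zeros(3)
        n_seeds = 40
        for s in range(n_seeds):
            rep = missingness_report(m.simulate_cohort(default_config(), 200 + s))
            totals += rep.sum(axis=0).to_numpy()
        means = totals / n_seeds
        # multinomial(26, p): 3 MC SEs on the mean over 40 seeds, plus a
        # small allowance for the severity tilt of the section choice
        targets = np.array([9.0, 5.0, 12.0])
        ses = np.sqrt(26 * (targets / 26) * (1 - targets / 26) / n_seeds)
        assert np.all(np.abs(means - targets) < 3 * ses + 0.5)

    def test_missingness_is_severity_linked(self):
        """Stochastic regime: impaired participants skip more often."""
        cfg = default_config(emulate_flow=False)
        cfg = dataclasses.replace(
            cfg,
            healthy=dataclasses.replace(cfg.healthy, n=1200),
            impaired=dataclasses.replace(cfg.impaired, n=1200),
            p_upload_failure=0.0,
        )
        rep = missingness_report(m.simulate_cohort(cfg, 31))
        assert rep.loc["impaired"].sum() > rep.loc["healthy"].sum()

    def test_zero_skip_probability_all_complete(self):
        roster = m.simulate_cohort(clean_config(150, 150), 3)
        rep = missingness_report(roster)
        assert int(rep.to_numpy().sum()) == 0


class TestCalibration:
    def test_mmse_moment_recovery(self):
        """Sample MMSE moments at n = 10,000 match the analytic censored-
        normal targets within 3 standard errors; the analytic healthy and
        impaired means equal the published 28.6 / 26.1."""
        cfg = clean_config(5000, 5000)
        roster = m.simulate_cohort(cfg, 78)
        mmse = {"healthy": [], "impaired": []}
        ages = {"healthy": [], "impaired": []}
        for r in roster:
            g = "impaired" if r.impaired else "healthy"
            mmse[g].append(r.mmse2_total)
            ages[g].append(r.age)
        for group, printed in (("healthy", 28.6), ("impaired", 26.1)):
            mean, sd = expected_mmse_moments(cfg, group)
            assert mean == pytest.approx(printed, abs=0.01)
            sample = np.asarray(mmse[group], dtype=float)
            se = sd / np.sqrt(sample.size)
            assert abs(sample.mean() - mean) < 3 * se
            assert abs(sample.std(ddof=1) - sd) < 0.1
        for group, gcfg in (("healthy", cfg.healthy), ("impaired", cfg.impaired)):
            a = np.asarray(ages[group])
            assert abs(a.mean() - gcfg.age_mean) < 3 * gcfg.age_sd / np.sqrt(a.size)

    def test_group_composite_means_match_study(self):
        """Self-referenced composite means land near +0.47 / -0.52 at the
        38:34 group mix."""
        roster = m.simulate_cohort(clean_config(950, 850), 13)
        comp = composite_by_group(roster)
        means = comp.groupby("impaired").m_cogscore.mean()
        sds = comp.groupby("impaired").m_cogscore.std()
        assert abs(means[False] - 0.47) < 3 * sds[False] / np.sqrt(950) + 0.02
        assert abs(means[True] - (-0.52)) < 3 * sds[True] / np.sqrt(850) + 0.02
        # pooled self-referenced z-scores average zero by construction
        z_cols = comp[["z_stroop", "z_symbols", "z_memory"]].to_numpy()
        assert abs(z_cols.mean()) < 1e-9

    def test_education_marginals(self):
        roster = m.simulate_cohort(clean_config(4000, 4000), 99)
        for flag, probs in ((False, default_config().healthy.edu_probs),
                            (True, default_config().impaired.edu_probs)):
            recs = [r for r in roster if r.impaired is flag]
            counts = np.array([sum(r.education == lvl for r in recs)
                               for lvl in ("none", "GCSE", "A-levels", "University")])
            n = len(recs)
            for c, p in zip(counts, probs):
                assert abs(c / n - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_null_model_auc_half(self):
        """With all severity slopes at zero the groups are exchangeable and
        the composite AUC sits at 1/2."""
        cfg = clean_config(600, 600)
        cfg = dataclasses.replace(
            cfg,
            stroop=dataclasses.replace(cfg.stroop, acc_slope=0.0, rt_slope=0.0),
            symbols=dataclasses.replace(cfg.symbols, acc_slope=0.0, rt_slope=0.0),
            memory=dataclasses.replace(cfg.memory, acc_slope=0.0),
            mmse=dataclasses.replace(cfg.mmse, slope=1e-9),
        )
        comp = composite_by_group(m.simulate_cohort(cfg, 17))
        labels = comp.impaired.astype(int).to_numpy()
        auc = empirical_roc(LabelledScores(comp.m_cogscore.to_numpy(float), labels)).auc
        null_se = np.sqrt((1 / 600 + 1 / 600) / 12)
        assert abs(auc - 0.5) < 3 * null_se

    def test_group_mean_ordering(self):
        """Positive severity slopes put impaired below healthy on MMSE and
        every raw subtest score."""
        roster = m.simulate_cohort(clean_config(800, 800), 53)
        comp = composite_by_group(roster)
        g = comp.groupby("impaired")[["raw_stroop", "raw_symbols", "raw_memory", "mmse2_total"]].mean()
        assert (g.loc[True] < g.loc[False]).all()

    def test_latent_loading_drives_cross_subtest_correlation(self):
        cfg = clean_config(0, 1600)  # single group isolates within-group correlation
        shared = composite_by_group(m.simulate_cohort(cfg, 7))
        r_shared = np.corrcoef(shared.raw_stroop, shared.raw_symbols)[0, 1]
        cfg0 = dataclasses.replace(cfg, loading=0.0)
        indep = composite_by_group(m.simulate_cohort(cfg0, 7))
        r_indep = np.corrcoef(indep.raw_stroop, indep.raw_symbols)[0, 1]
        mc_se = 1 / np.sqrt(1600)
        assert r_shared > 0.2
        assert abs(r_indep) < 3 * mc_se


class TestBinormal:
    def test_closed_form_matches_empirical(self):
        """Composite scores drawn from the published group moments converge
        to the closed-form binormal AUC of about 0.864."""
        closed = binormal_auc(0.47, 0.47, -0.52, 0.77)
        assert closed == pytest.approx(0.8638, abs=5e-4)
        scores, labels = binormal_scores(20000, 20000, 0.47, 0.47, -0.52, 0.77, seed=4)
        auc = empirical_roc(LabelledScores(scores, labels)).auc
        assert auc == pytest.approx(closed, abs=0.01)
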