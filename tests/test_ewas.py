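import logging
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import betainc

from epireverse import ewas
from epireverse.synthetic_methylome import (
    SimulationDesign,
    simulate_annotation,
    simulate_cohort,
    simulate_truth,
)

from conftest import make_matrix, make_sheet


class TestScan:
    def test_t_from_r_forced_value(self):
        # r=0.5, n=12: t = 0.5*sqrt(10)/sqrt(0.75)
        from epireverse._stats import t_from_r
        assert t_from_r(0.5, 12) == pytest.approx(1.82574185835055, rel=1e-12)

    def test_p_and_z_against_reference_cdf(self, rng):
        _, matrix, samples, *_ = _tiny_cohort()
        scan = ewas.ewas_scan(matrix, samples, "age")
        n = scan["n"].iloc[0]
        df = n - 2
        for _, row in scan.head(50).iterrows():
            t = row["r"] * math.sqrt(df) / math.sqrt(1 - row["r"] ** 2)
            p_ref = betainc(df / 2, 0.5, df / (df + t * t))  # independent t-CDF route
            assert row["p"] == pytest.approx(p_ref, rel=1e-9)
            z_ref = math.copysign(stats.norm.isf(p_ref / 2), row["r"])
            assert row["z"] == pytest.approx(z_ref, abs=1e-9)

    def test_matches_scipy_pearsonr(self):
        _, matrix, samples, *_ = _tiny_cohort()
        scan = ewas.ewas_scan(matrix, samples, "treatment")
        ids = (samples.ids_for_group("old_control")
               + samples.ids_for_group("old_treated"))
        sub = matrix.subset_samples(ids)
        x = np.array([0.0] * 6 + [1.0] * 8)
        for j in range(0, 40):
            res = stats.pearsonr(sub.beta[j], x)
            assert scan["r"].iloc[j] == pytest.approx(res.statistic, abs=1e-12)
            assert scan["p"].iloc[j] == pytest.approx(res.pvalue, rel=1e-9)

    def test_zero_variance_cpg_policy(self, caplog):
        beta = np.full((2, 12), 0.5)
        beta[1] = np.linspace(0.2, 0.8, 12)
        matrix = make_matrix(beta)
        sheet = make_sheet({"young": 6, "old_control": 6})
        with caplog.at_level(logging.INFO, logger="epireverse.ewas"):
            scan = ewas.ewas_scan(matrix, sheet, "age")
        row = scan.iloc[0]
        assert row["r"] == 0.0 and row["p"] == 1.0 and row["z"] == 0.0
        assert any("zero-variance" in r.message for r in caplog.records)

    def test_perfect_correlation_capped(self):
        sheet = make_sheet({"young": 3, "old_control": 3})
        x = np.array([0.1, 0.1, 0.1, 0.9, 0.9, 0.9])
        scan = ewas.ewas_scan(make_matrix(x[None, :]), sheet, "age")
        assert scan["p"].iloc[0] > 0.0
        assert abs(scan["z"].iloc[0]) <= 40.0

    def test_z_monotone_in_p(self, rng):
        p = np.sort(rng.uniform(1e-12, 1, 100))
        from epireverse._stats import z_from_p
        z = z_from_p(p, np.ones_like(p))
        assert (np.diff(z) <= 1e-12).all()

    def test_unknown_contrast(self):
        _, matrix, samples, *_ = _tiny_cohort()
        with pytest.raises(ValueError, match="contrast"):
            ewas.ewas_scan(matrix, samples, "sex")

    def test_numeric_age_used_when_informative(self):
        sheet = make_sheet({"young": 3, "old_control": 3},
                           ages=[0.4, 0.5, 0.6, 2.3, 2.5, 2.7])
        beta = np.linspace(0.1, 0.9, 6)[None, :]
        scan = ewas.ewas_scan(make_matrix(beta), sheet, "age")
        ages = np.array([0.4, 0.5, 0.6, 2.3, 2.5, 2.7])
        expected = stats.pearsonr(beta[0], ages).statistic
        assert scan["r"].iloc[0] == pytest.approx(expected, abs=1e-12)


class TestClassify:
    @pytest.mark.parametrize("za,zt,expected", [
        (3.0, -3.0, "rejuvenated"),
        (3.0, 3.0, "aggravated"),
        (3.0, -1.0, "age_only"),
        (-1.0, 3.0, "treat_only"),
        (1.0, -1.0, "null"),
        (-3.0, 3.0, "rejuvenated"),
        (-3.0, -3.0, "aggravated"),
    ])
    def test_sign_logic(self, za, zt, expected):
        assert ewas.classify_cpgs([za], [zt], alpha=0.01)[0] == expected

    def test_threshold_value(self):
        # z* at alpha=0.01 is about 2.576
        zstar = stats.norm.isf(0.005)
        assert ewas.classify_cpgs([zstar + 0.01], [0.0], 0.01)[0] == "age_only"
        assert ewas.classify_cpgs([zstar - 0.01], [0.0], 0.01)[0] == "null"

    def test_swap_symmetry(self, rng):
        za = rng.normal(0, 3, 500)
        zt = rng.normal(0, 3, 500)
        fwd = ewas.classify_cpgs(za, zt, 0.01)
        rev = ewas.classify_cpgs(zt, za, 0.01)
        swap = {"age_only": "treat_only", "treat_only": "age_only"}
        assert all(r == swap.get(f, f) for f, r in zip(fwd, rev))

    def test_bad_alpha(self):
        with pytest.raises(ValueError):
            ewas.classify_cpgs([1.0], [1.0], alpha=0.0)

    def test_bh_adjustment_behind_flag(self):
        _, matrix, samples, *_ = _tiny_cohort()
        age_scan = ewas.ewas_scan(matrix, samples, "age")
        treat_scan = ewas.ewas_scan(matrix, samples, "treatment")
        table = ewas.build_ewas_table(age_scan, treat_scan, adjust=True)
        assert {"q_age", "q_treat"} <= set(table.columns)
        assert (table["q_age"] >= table["p_age"] - 1e-12).all()
        plain = ewas.build_ewas_table(age_scan, treat_scan)
        # headline labels unaffected by the adjustment flag
        assert (plain["label"] == table["label"]).all()

    def test_noiseless_full_reversal_all_rejuvenated(self, noiseless_cohort):
        _, matrix, samples, _, truth = noiseless_cohort
        age_scan = ewas.ewas_scan(matrix, samples, "age")
        treat_scan = ewas.ewas_scan(matrix, samples, "treatment")
        table = ewas.build_ewas_table(age_scan, treat_scan, alpha=0.01)
        reversed_ids = set(truth.loc[truth["is_reversed"], "cpg_id"])
        labels = table.set_index("cpg_id").loc[sorted(reversed_ids), "label"]
        assert (labels == "rejuvenated").all()


class TestOverlap:
    def test_counting(self):
        labels = ["rejuvenated"] * 3 + ["aggravated"] + ["age_only"] * 5
        out = ewas.overlap_summary(labels)
        assert out == {"n_age_significant": 9, "n_treat_significant": 4,
                       "n_overlap": 4, "n_rejuvenated": 3, "n_aggravated": 1}

    def test_empty(self):
        out = ewas.overlap_summary([])
        assert all(v == 0 for v in out.values())

    def test_brute_force_tally(self, rng):
        labels = rng.choice(list(ewas.LABELS), 1000)
        out = ewas.overlap_summary(labels)
        tally = {lab: sum(1 for x in labels if x == lab) for lab in ewas.LABELS}
        assert out["n_rejuvenated"] == tally["rejuvenated"]
        assert out["n_aggravated"] == tally["aggravated"]
        assert out["n_overlap"] == tally["rejuvenated"] + tally["aggravated"]
        assert out["n_age_significant"] == (tally["rejuvenated"]
                                            + tally["aggravated"] + tally["age_only"])
        assert out["n_treat_significant"] == (tally["rejuvenated"]
                                              + tally["aggravated"] + tally["treat_only"])


class TestReversalCorrelation:
    def test_perfect_anticorrelation(self, rng):
        z = rng.normal(0, 2, 50)
        r, p = ewas.reversal_correlation(z, -z)
        assert r == pytest.approx(-1.0)

    def test_independent_vectors_near_zero(self, rng):
        za = rng.normal(0, 1, 10000)
        zt = rng.normal(0, 1, 10000)
        r, _ = ewas.reversal_correlation(za, zt)
        assert abs(r) < 0.05

    def test_subset_filter(self, rng):
        za = np.concatenate([rng.normal(0, 0.5, 100), np.linspace(4.0, 6.0, 20)])
        zt = np.concatenate([rng.normal(0, 0.5, 100), np.linspace(-3.5, -4.5, 20)])
        r_all, _ = ewas.reversal_correlation(za, zt, "all")
        r_sig, _ = ewas.reversal_correlation(za, zt, "significant_either")
        assert r_all < -0.9
        assert not math.isnan(r_sig)
        with pytest.raises(ValueError):
            ewas.reversal_correlation(za, zt, "bogus")

    def test_too_few(self):
        with pytest.raises(ValueError, match="at least 3"):
            ewas.reversal_correlation([1.0, 2.0], [1.0, 2.0])

    def test_planted_reversal_significantly_negative(self):
        hits = 0
        for seed in range(3):
            design = SimulationDesign(n_cpgs=1500, seed=seed,
                                      reversal_fraction=0.6, noise_sd=0.15)
            ann = simulate_annotation(design)
            truth = simulate_truth(design, ann)
            matrix, samples, truth = simulate_cohort(design, ann, truth)
            za = ewas.ewas_scan(matrix, samples, "age")["z"]
            zt = ewas.ewas_scan(matrix, samples, "treatment")["z"]
            r, p = ewas.reversal_correlation(za, zt)
            if r < 0 and p < 0.01:
                hits += 1
        assert hits == 3


class TestTopHits:
    def test_strict_p_order(self, small_cohort):
        _, matrix, samples, annotation, _ = small_cohort
        scan = ewas.ewas_scan(matrix, samples, "age")
        top = ewas.top_hits(scan, annotation, k=15)
        assert len(top) == 15
        assert (top["p"].diff().dropna() >= 0).all()
        assert set(top.columns) >= {"nearest_gene", "direction", "chrom", "start"}

    def test_tie_break_by_position(self, small_cohort):
        *_, annotation, _ = small_cohort
        scan = pd.DataFrame({
            "cpg_id": annotation.cpg_ids[:4],
            "r": [0.5] * 4, "t": [1.0] * 4,
            "p": [0.5, 0.01, 0.01, 0.2], "z": [1.0, 2.0, -2.0, 1.0], "n": [12] * 4,
        })
        top = ewas.top_hits(scan, annotation, k=4)
        tied = top.iloc[:2]
        key = list(zip(tied["chrom"], tied["start"]))
        assert key == sorted(key)

    def test_k_larger_than_table(self, small_cohort):
        _, matrix, samples, annotation, _ = small_cohort
        scan = ewas.ewas_scan(matrix, samples, "age").head(10)
        top = ewas.top_hits(scan, annotation, k=500)
        assert len(top) == 10


def _tiny_cohort():
    design = SimulationDesign(n_cpgs=60, seed=21)
    ann = simulate_annotation(design)
    truth = simulate_truth(design, ann)
    matrix, samples, truth = simulate_cohort(design, ann, truth)
    return design, matrix, samples, ann, truth
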