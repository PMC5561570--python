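"""Attribution statistics: dominant recoding, percentage change vs the
analytic omitted-variable-bias oracle, class assignment and ANOVA."""

import numpy as np
import pandas as pd
import pytest

from oracles import omitted_variable_bias_pct

from mqtlsmoke.attribution import (
    attenuation_pct,
    categorize_and_anova,
    distance_class,
    frequency_class,
    interaction_scan,
    recode_dominant,
    run_attribution,
)
from mqtlsmoke.models import PanelData
from scipy import stats


class TestRecodeDominant:
    def test_mapping(self):
        col = pd.Series([0.0, 1.0, 2.0, np.nan])
        out = recode_dominant(col)
        assert out.tolist()[:3] == [0.0, 1.0, 1.0]
        assert np.isnan(out.iloc[3])

    def test_all_major_homozygotes(self):
        assert (recode_dominant(np.zeros(10)) == 0).all()

    def test_carrier_frequency_under_hwe(self, rng):
        maf = 0.3
        g = rng.binomial(2, maf, 200_000)
        carrier = recode_dominant(g.astype(float))
        expected = 1 - (1 - maf) ** 2
        assert abs(carrier.mean() - expected) < 0.005


class TestAttenuationPct:
    def test_identity(self):
        pct, direction = attenuation_pct(-0.1, -0.1)
        assert pct == 0.0
        assert direction == "strengthened"  # |b2| == |b1| is not attenuated

    def test_attenuated(self):
        pct, direction = attenuation_pct(-0.10, -0.08)
        assert pct == pytest.approx(20.0)
        assert direction == "attenuated"

    def test_strengthened(self):
        pct, direction = attenuation_pct(-0.10, -0.11)
        assert pct == pytest.approx(10.0)
        assert direction == "strengthened"

    def test_zero_beta1_rejected(self):
        with pytest.raises(ValueError):
            attenuation_pct(0.0, 0.1)

    def test_scale_invariance(self, rng):
        """Rescaling the outcome rescales both betas: pct unchanged."""
        for _ in range(20):
            b1, b2 = rng.normal(size=2)
            if b1 == 0:
                continue
            k = rng.uniform(0.1, 10)
            assert attenuation_pct(b1, b2)[0] == pytest.approx(
                attenuation_pct(k * b1, k * b2)[0]
            )


class TestClasses:
    @pytest.mark.parametrize(
        "freq,expected",
        [(2, "weak"), (3, "weak"), (4, "moderate"), (5, "moderate"),
         (6, "high"), (7, "high"), (8, "high"), (9, "high"), (10, "high")],
    )
    def test_frequency_classes(self, freq, expected):
        assert frequency_class(freq) == expected

    def test_frequency_below_two_rejected(self):
        with pytest.raises(ValueError):
            frequency_class(1)

    def test_distance_classes(self):
        assert distance_class(-9_999) == "<10kb"
        assert distance_class(10_000) == ">=10kb"
        assert distance_class(-27_267) == ">=10kb"


def _confounded_panel(rng, n=1200, a=0.08, delta=0.4, noise=0.0):
    """Carrier frequency differs by smoking group -> omitted-variable bias
    in the smoking coefficient when the carrier term is left out."""
    current = rng.binomial(1, 0.4, n)
    p_carrier = 0.3 + delta * current
    carrier = rng.binomial(1, p_carrier)
    dosage = carrier.astype(float)  # carrier == dosage for dominant coding
    beta = 0.5 - 0.05 * current + a * carrier + (
        rng.normal(0, noise, n) if noise > 0 else 0.0
    )
    ids = pd.Index([f"S{i}" for i in range(n)], name="sample_id")
    cohort = pd.DataFrame(
        {
            "age": 61.0 + rng.normal(0, 5, n).round(1),
            "sex": np.where(rng.random(n) < 0.5, "male", "female"),
            "smoking_status": np.where(current == 1, "current", "never"),
            "alcohol": "low",
            "bmi_class": "normal",
            "activity": "low",
            "cvd": 0,
            "diabetes": 0,
            "cancer": 0,
            "batch": "b1",
        },
        index=ids,
    )
    betas = pd.DataFrame({"cg_test": np.clip(beta, 0, 1)}, index=ids)
    dosages = pd.DataFrame({"rs_test": dosage}, index=ids)
    panel = PanelData(cohort=cohort, betas=betas, dosages=dosages)
    return panel, current, carrier, beta


class TestRunAttribution:
    def _pairs(self):
        return pd.DataFrame(
            [{"cpg_id": "cg_test", "snp_id": "rs_test", "distance": 2967}]
        )

    def _manifest(self, freq=3):
        return pd.DataFrame(
            {"chrom": ["1"], "pos": [100], "gene": ["G"],
             "reported_frequency": [freq]},
            index=pd.Index(["cg_test"], name="cpg_id"),
        )

    def test_matches_analytic_ovb_on_noiseless_data(self, rng):
        panel, current, carrier, beta = _confounded_panel(rng, noise=0.0)
        rec = run_attribution(
            self._pairs(), panel, manifest=self._manifest()
        ).iloc[0]
        # analytic oracle: same fits via plain least squares with the same
        # controls (age, sex dummies; constants drop out)
        Z = np.column_stack(
            [np.ones(len(current)),
             panel.cohort["age"].to_numpy(),
             (panel.cohort["sex"] == "male").to_numpy(float)]
        )
        expected = omitted_variable_bias_pct(beta, current, carrier, Z)
        assert rec["pct_change"] == pytest.approx(expected, abs=1e-6)
        # positive carrier effect confounded with smoking masks part of the
        # negative smoking effect: adjusting for it strengthens |beta|
        assert rec["direction"] == "strengthened"
        assert not rec["flagged"]

    def test_zero_mqtl_effect_gives_zero_pct(self, rng):
        panel, *_ = _confounded_panel(rng, a=0.0, delta=0.0, noise=0.0)
        rec = run_attribution(
            self._pairs(), panel, manifest=self._manifest()
        ).iloc[0]
        assert rec["pct_change"] == pytest.approx(0.0, abs=1e-8)

    def test_shuffled_carrier_contributes_nothing(self, rng):
        panel, current, carrier, beta = _confounded_panel(rng, n=2000, noise=0.01)
        perm = rng.permutation(len(carrier))
        panel.dosages["rs_test"] = panel.dosages["rs_test"].to_numpy()[perm]
        rec = run_attribution(
            self._pairs(), panel, manifest=self._manifest()
        ).iloc[0]
        assert rec["pct_change"] < 1.0

    def test_classes_attached(self, rng):
        panel, *_ = _confounded_panel(rng)
        rec = run_attribution(
            self._pairs(), panel, manifest=self._manifest(freq=7)
        ).iloc[0]
        assert rec["frequency_class"] == "high"
        assert rec["distance_class"] == "<10kb"


class TestAnova:
    def _records(self, pcts_by_class):
        rows = []
        for cls, pcts in pcts_by_class.items():
            for v in pcts:
                rows.append(
                    {"pct_change": v, "frequency_class": cls,
                     "distance_class": "<10kb"}
                )
        return pd.DataFrame(rows)

    def test_all_equal_gives_zero_f(self):
        rec = self._records({"weak": [5, 5], "moderate": [5, 5], "high": [5, 5]})
        out = categorize_and_anova(rec)
        assert out["anova_F"] == 0.0

    def test_two_classes_equals_squared_t(self, rng):
        a = rng.normal(10, 2, 12)
        b = rng.normal(12, 2, 15)
        rec = self._records({"weak": a, "high": b})
        out = categorize_and_anova(rec)
        t = stats.ttest_ind(a, b).statistic
        assert out["anova_F"] == pytest.approx(t ** 2, abs=1e-10)

    def test_three_group_manual_sum_of_squares(self):
        groups = {"weak": [1.0, 2.0, 3.0], "moderate": [2.0, 3.0, 4.0],
                  "high": [6.0, 7.0, 8.0]}
        rec = self._records(groups)
        out = categorize_and_anova(rec)
        all_vals = np.concatenate(list(map(np.asarray, groups.values())))
        grand = all_vals.mean()
        ss_between = sum(
            len(v) * (np.mean(v) - grand) ** 2 for v in groups.values()
        )
        ss_within = sum(
            ((np.asarray(v) - np.mean(v)) ** 2).sum() for v in groups.values()
        )
        F = (ss_between / 2) / (ss_within / 6)
        assert out["anova_F"] == pytest.approx(F, abs=1e-10)

    def test_single_class_skips_anova(self):
        out = categorize_and_anova(self._records({"weak": [1.0, 2.0]}))
        assert np.isnan(out["anova_F"])
        assert len(out["frequency_summary"]) == 1


class TestInteractionScan:
    def test_planted_interaction_detected_reference_cells_empty(self, rng):
        n = 2000
        current = rng.binomial(1, 0.4, n)
        dosage = rng.binomial(2, 0.3, n).astype(float)
        carrier = (dosage > 0).astype(float)
        beta = 0.5 - 0.03 * current + 0.08 * carrier * current + rng.normal(
            0, 0.02, n
        )
        ids = pd.Index([f"S{i}" for i in range(n)], name="sample_id")
        cohort = pd.DataFrame(
            {
                "age": 61.0, "sex": "female",
                "smoking_status": np.where(current == 1, "current", "never"),
                "alcohol": "low", "bmi_class": "normal", "activity": "low",
                "cvd": 0, "diabetes": 0, "cancer": 0, "batch": "b1",
            },
            index=ids,
        )
        panel = PanelData(
            cohort=cohort,
            betas=pd.DataFrame({"cg_test": np.clip(beta, 0, 1)}, index=ids),
            dosages=pd.DataFrame({"rs_test": dosage}, index=ids),
        )
        pairs = pd.DataFrame([{"cpg_id": "cg_test", "snp_id": "rs_test"}])
        out = interaction_scan(pairs, panel)
        assert len(out) == 1
        assert bool(out["significant"].iloc[0])
        # reference cells (never x anything, current x hom-major) have no
        # coefficient columns; only the two carrier-genotype contrasts do
        assert set(c for c in out.columns if c.startswith("coef_")) == {
            "coef_current_x_g1", "coef_current_x_g2"
        }

    def test_null_interaction_not_significant(self, rng):
        n = 1500
        current = rng.binomial(1, 0.4, n)
        dosage = rng.binomial(2, 0.3, n).astype(float)
        beta = 0.5 - 0.03 * current + 0.05 * dosage + rng.normal(0, 0.02, n)
        ids = pd.Index([f"S{i}" for i in range(n)], name="sample_id")
        cohort = pd.DataFrame(
            {
                "age": 61.0, "sex": "female",
                "smoking_status": np.where(current == 1, "current", "never"),
                "alcohol": "low", "bmi_class": "normal", "activity": "low",
                "cvd": 0, "diabetes": 0, "cancer": 0, "batch": "b1",
            },
            index=ids,
        )
        panel = PanelData(
            cohort=cohort,
            betas=pd.DataFrame({"cg_test": np.clip(beta, 0, 1)}, index=ids),
            dosages=pd.DataFrame({"rs_test": dosage}, index=ids),
        )
        pairs = pd.DataFrame([{"cpg_id": "cg_test", "snp_id": "rs_test"}])
        out = interaction_scan(pairs, panel)
        assert out["interaction_p"].iloc[0] > 0.05
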