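import numpy as np
import pandas as pd
import pytest
from scipy import stats

from heatmir import diffexpr
from heatmir.errors import ConfigError, FormatError

from conftest import make_matrix

TPS = ("0min", "10min")


def two_group_matrix(control_rows, treatment_rows):
    """Entities x (2 control + 2 treatment) matrix over two timepoints."""
    values = np.column_stack([np.asarray(control_rows), np.asarray(treatment_rows)])
    return make_matrix(values, TPS, n_replicates=2)


class TestComputeDE:
    def test_identical_groups_give_zero_lfc_p_one(self):
        m = two_group_matrix([[5.0, 5.0]], [[5.0, 5.0]])
        res = diffexpr.compute_de(m, "0min", "10min", method="student_t")
        assert res.loc["p0", "log2fc"] == 0.0
        assert res.loc["p0", "pvalue"] == 1.0

    def test_twofold_change_gives_lfc_one(self):
        m = two_group_matrix([[5.0, 5.2]], [[6.0, 6.2]])
        res = diffexpr.compute_de(m, "0min", "10min", method="student_t")
        assert res.loc["p0", "log2fc"] == pytest.approx(1.0)

    def test_student_t_matches_independent_oracle(self):
        """Pooled-variance t on a 6-entity toy table vs scipy's ttest_ind."""
        rng = np.random.default_rng(5)
        ctrl = rng.normal(8, 1, size=(6, 2))
        trt = rng.normal(9, 1, size=(6, 2))
        m = two_group_matrix(ctrl, trt)
        res = diffexpr.compute_de(m, "0min", "10min", method="student_t")
        expected = stats.ttest_ind(trt, ctrl, axis=1, equal_var=True)
        assert np.allclose(res["pvalue"].to_numpy(), expected.pvalue, atol=1e-10)
        assert np.allclose(res["log2fc"].to_numpy(),
                           trt.mean(axis=1) - ctrl.mean(axis=1), atol=1e-10)

    def test_antisymmetry_under_group_swap(self):
        rng = np.random.default_rng(6)
        m = two_group_matrix(rng.normal(8, 1, (20, 2)), rng.normal(9, 1, (20, 2)))
        for method in ("student_t", "moderated_t"):
            fwd = diffexpr.compute_de(m, "0min", "10min", method=method)
            rev = diffexpr.compute_de(m, "10min", "0min", method=method)
            assert np.allclose(fwd["log2fc"], -rev["log2fc"])
            assert np.allclose(fwd["pvalue"], rev["pvalue"])

    def test_moderated_equals_student_when_prior_weight_vanishes(self):
        rng = np.random.default_rng(7)
        m = two_group_matrix(rng.normal(8, 1, (30, 2)), rng.normal(9, 1, (30, 2)))
        plain = diffexpr.compute_de(m, "0min", "10min", method="student_t")
        no_prior = diffexpr.compute_de(m, "0min", "10min", method="moderated_t",
                                       prior_df=0)
        assert np.allclose(plain["pvalue"], no_prior["pvalue"])

    def test_same_timepoint_rejected(self):
        m = two_group_matrix([[1.0, 2.0]], [[1.0, 2.0]])
        with pytest.raises(ConfigError):
            diffexpr.compute_de(m, "0min", "0min")

    def test_single_replicate_rejected_for_student_t(self):
        m = make_matrix(np.zeros((2, 2)), TPS, n_replicates=1)
        with pytest.raises(ConfigError, match="control|treatment"):
            diffexpr.compute_de(m, "0min", "10min", method="student_t")


class TestCallDE:
    def profiles(self, rows):
        tps = ("10min", "20min", "60min", "2h")
        data = {}
        for k, tp in enumerate(tps):
            data[f"log2fc_{tp}"] = [r[0][k] for r in rows]
            data[f"pvalue_{tp}"] = [r[1][k] for r in rows]
        return pd.DataFrame(data, index=[f"e{i}" for i in range(len(rows))])

    def test_boundary_semantics(self):
        rows = [
            # lfc exactly 1.0 with p 0.049 at one timepoint -> DE (inclusive lfc)
            ([1.0, 0.0, 0.0, 0.0], [0.049, 0.9, 0.9, 0.9]),
            # lfc 0.99 everywhere, tiny p -> not DE (below fold threshold)
            ([0.99, 0.99, 0.99, 0.99], [0.001] * 4),
            # p exactly 0.05 -> not DE (strict p inequality)
            ([2.0, 0.0, 0.0, 0.0], [0.05, 0.9, 0.9, 0.9]),
        ]
        out = diffexpr.call_de(self.profiles(rows))
        assert out["de"].tolist() == [True, False, False]

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(8)
        rows = [
            (rng.uniform(-2, 2, 4).tolist(), rng.uniform(0, 0.2, 4).tolist())
            for _ in range(50)
        ]
        profiles = self.profiles(rows)
        base = set(diffexpr.call_de(profiles).index[
            diffexpr.call_de(profiles)["de"]])
        looser_alpha = diffexpr.call_de(profiles, alpha=0.2)
        looser_lfc = diffexpr.call_de(profiles, lfc_threshold=0.5)
        assert base <= set(looser_alpha.index[looser_alpha["de"]])
        assert base <= set(looser_lfc.index[looser_lfc["de"]])

    def test_direction_requires_significance(self):
        out = diffexpr.call_de(
            self.profiles([([1.5, -0.2, 0.0, 0.0], [0.01, 0.01, 0.9, 0.9])])
        )
        assert out.loc["e0", "direction_10min"] == "up"
        assert out.loc["e0", "direction_20min"] == "none"  # |lfc| < 1
        assert out.loc["e0", "overall_direction"] == "up"


class TestFamilyMapping:
    @pytest.mark.parametrize(
        "mirna_id,family",
        [
            ("osa-miR169g", "osa-miR169"),
            ("osa-miR166", "osa-miR166"),
            ("osa-miR397b.2", "osa-miR397"),
            ("osa-miR156a-5p", "osa-miR156"),
            ("ath-miR172b-3p", "ath-miR172"),
        ],
    )
    def test_naming_convention(self, mirna_id, family):
        assert diffexpr.map_to_family(mirna_id) == family
        assert diffexpr.map_to_family(family) == family  # idempotent

    def test_nonconforming_id_raises_unless_lenient(self):
        with pytest.raises(FormatError):
            diffexpr.map_to_family("PC-5P-62245-9")
        assert diffexpr.map_to_family("PC-5P-62245-9", lenient=True) == "PC-5P-62245-9"


class TestFamilyAggregation:
    def calls(self, member_rows):
        tps = ("10min", "20min", "60min", "2h")
        data = {}
        for k, tp in enumerate(tps):
            data[f"log2fc_{tp}"] = [r[k] for r in member_rows.values()]
            data[f"pvalue_{tp}"] = [0.01 if abs(r[k]) >= 1 else 0.9
                                    for r in member_rows.values()]
        profiles = pd.DataFrame(data, index=list(member_rows))
        return diffexpr.call_de(profiles)

    def test_all_members_up_gives_up(self):
        calls = self.calls({"osa-miR1a": [0, 0, 2, 2], "osa-miR1b": [0, 2, 2, 2]})
        prof = diffexpr.aggregate_family("osa-miR1", calls)
        assert prof.overall_direction == "up"
        assert prof.direction_by_timepoint["60min"] == "up"
        assert prof.direction_by_timepoint["10min"] == "none"

    def test_disagreeing_members_give_up_down_and_conflict(self):
        calls = self.calls({"osa-miR9a": [2, 0, 0, 0], "osa-miR9b": [-2, 0, 0, 0]})
        prof = diffexpr.aggregate_family("osa-miR9", calls)
        assert prof.overall_direction == "up_down"
        assert prof.direction_by_timepoint["10min"] == "conflict"

    def test_single_member_family_inherits_direction(self):
        calls = self.calls({"osa-miR5": [0, 0, 0, -2]})
        prof = diffexpr.aggregate_family("osa-miR5", calls)
        assert prof.overall_direction == "down"
        assert prof.members == ["osa-miR5"]

    def test_empty_member_set_rejected(self):
        with pytest.raises(ConfigError):
            diffexpr.aggregate_family("osa-miR5", self.calls({"x": [2, 0, 0, 0]}).iloc[0:0])

    def test_aggregate_families_excludes_non_de_members(self):
        calls = self.calls({"osa-miR7a": [2, 2, 2, 2], "osa-miR7b": [0.2, 0, 0, 0]})
        profiles = diffexpr.aggregate_families(calls)
        assert profiles["osa-miR7"].members == ["osa-miR7a"]


class TestPlantedRecovery:
    def test_sensitivity_and_type_i_error_at_study_conditions(self):
        """Planted log2 effect 2.0, noise sd 0.2, n = 2: the DE caller must
        detect >= 90% of planted entities and call <= 5% of nulls."""
        rng = np.random.default_rng(123)
        n_de, n_null = 1000, 1000
        tps = ("0min", "10min", "20min", "60min", "2h")
        baseline = rng.uniform(8, 12, size=n_de + n_null)
        effect = np.zeros((n_de + n_null, 10))
        signs = rng.choice([-1, 1], size=n_de)
        effect[:n_de, 2:] = (signs * 2.0)[:, None]  # all treatment samples
        values = baseline[:, None] + effect + rng.normal(0, 0.2, (n_de + n_null, 10))
        m = make_matrix(values, tps)
        for method in ("student_t", "moderated_t"):
            calls = diffexpr.call_de(diffexpr.de_profile(m, method=method))
            de = calls["de"].to_numpy()
            sensitivity = de[:n_de].mean()
            fpr = de[n_de:].mean()
            assert sensitivity >= 0.9, (method, sensitivity)
            assert fpr <= 0.05, (method, fpr)
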