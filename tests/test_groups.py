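import numpy as np
import pandas as pd
import pytest

import stepconn as sc
from stepconn import groups as groups_mod
from stepconn.errors import InputError

from _oracles import groupby_mean, pooled_t, welch_t


def _pheno(rows):
    return pd.DataFrame(
        [{"subject_id": f"s{i}", **row} for i, row in enumerate(rows)]
    )


def _assignment(labels, criteria="bmi_whr"):
    series = pd.Series(labels, index=[f"s{i}" for i in range(len(labels))], name="group")
    return groups_mod.GroupAssignment(labels=series, criteria_name=criteria)


class TestAssignGroups:
    @pytest.mark.parametrize(
        "bmi, whr, sex, expected",
        [
            (22, 0.80, "female", "healthy_weight"),
            (26, 0.92, "male", "overweight"),
            (24, 0.95, "female", "unassigned"),  # satisfies neither conjunction
            (26, 0.80, "female", "unassigned"),  # heavy but low WHR
            (24.99, 0.85, "female", "healthy_weight"),  # boundary: WHR <= cutoff
            (25.0, 0.86, "female", "overweight"),
        ],
    )
    def test_bmi_whr_criteria(self, bmi, whr, sex, expected):
        out = sc.assign_groups(_pheno([{"bmi": bmi, "whr": whr, "sex": sex}]))
        assert out.labels.iloc[0] == expected

    @pytest.mark.parametrize(
        "whr, sex, expected",
        [
            (0.79, "female", "low_risk"),
            (0.94, "male", "low_risk"),
            (0.87, "female", "high_risk"),
            (1.01, "male", "high_risk"),
            (0.83, "female", "unassigned"),  # between the WHO cutoffs
        ],
    )
    def test_who_criteria(self, whr, sex, expected):
        out = sc.assign_groups(
            _pheno([{"bmi": 24, "whr": whr, "sex": sex}]), criteria="who_whr"
        )
        assert out.labels.iloc[0] == expected

    def test_missing_field_recorded_not_fatal(self):
        out = sc.assign_groups(_pheno([
            {"bmi": 22, "whr": 0.8, "sex": "female"},
            {"bmi": np.nan, "whr": 0.8, "sex": "female"},
        ]))
        assert out.labels.iloc[1] == "unassigned"
        assert len(out.errors) == 1 and "s1" in out.errors[0]


class TestCompareGroups:
    def _degrees(self, rng, n=30, steps=3, r=28, shift=0.0, members=None):
        d = rng.standard_normal((n, steps, r))
        if shift and members is not None:
            d[members] += shift
        return d

    def test_t_matches_hand_formulas(self, rng):
        d = self._degrees(rng)
        labels = ["overweight"] * 12 + ["healthy_weight"] * 18
        asn = _assignment(labels)
        for variant, oracle in [("welch", welch_t), ("pooled", pooled_t)]:
            contrast = sc.compare_groups(d, asn, variant=variant)
            for k in range(3):
                for j in range(0, 28, 5):
                    want = oracle(d[:12, k, j], d[12:, k, j])
                    assert contrast.t_regional[k, j] == pytest.approx(want, abs=1e-10)

    def test_label_swap_flips_t_sign(self, rng):
        d = self._degrees(rng)
        labels = ["overweight"] * 12 + ["healthy_weight"] * 18
        swapped = ["healthy_weight"] * 12 + ["overweight"] * 18
        t1 = sc.compare_groups(d, _assignment(labels)).t_regional
        t2 = sc.compare_groups(d, _assignment(swapped)).t_regional
        assert np.allclose(t1, -t2, atol=1e-12)

    def test_network_level_and_family_metadata(self, rng):
        d = self._degrees(rng)
        parc = sc.default_parcellation(28)
        asn = _assignment(["overweight"] * 12 + ["healthy_weight"] * 18)
        contrast = sc.compare_groups(d, asn, parcellation=parc)
        assert contrast.fdr_families == {"regional_per_step": 28, "network_per_step": 14}
        assert contrast.t_network.shape == (3, 14)
        assert contrast.group_sizes == {"overweight": 12, "healthy_weight": 18}

    def test_small_group_rejected(self, rng):
        d = self._degrees(rng, n=5)
        asn = _assignment(["overweight"] * 2 + ["healthy_weight"] * 3)
        with pytest.raises(InputError, match="3 subjects"):
            sc.compare_groups(d, asn)

    def test_planted_shift_detected_with_correct_sign(self, rng):
        members = np.arange(12)
        d = self._degrees(rng, shift=1.2, members=members)
        asn = _assignment(["overweight"] * 12 + ["healthy_weight"] * 18)
        contrast = sc.compare_groups(d, asn)
        assert contrast.t_regional.mean() > 3
        assert (contrast.q_regional < 0.05).mean() > 0.5


class TestNetworkDegree:
    def test_constant_degrees(self):
        parc = sc.default_parcellation(28)
        d = np.full((4, 2, 28), 2.5)
        nd, names = sc.network_degree(d, parc)
        assert np.allclose(nd, 2.5)
        assert names == sc.ALL_LABELS

    def test_matches_groupby_oracle(self, rng):
        parc = sc.default_parcellation(30)
        d = rng.standard_normal((3, 2, 30))
        nd, names = sc.network_degree(d, parc)
        for s in range(3):
            for k in range(2):
                ref = groupby_mean(d[s, k], list(parc.labels))
                for j, name in enumerate(names):
                    assert nd[s, k, j] == pytest.approx(ref[name], abs=1e-12)

    def test_single_region_networks(self, rng):
        parc = sc.default_parcellation(14)  # one region per label
        d = rng.standard_normal((2, 1, 14))
        nd, _ = sc.network_degree(d, parc)
        assert np.allclose(nd[:, 0, :], d[:, 0, :])

    def test_pooled_subcortical(self, rng):
        parc = sc.default_parcellation(28)
        d = rng.standard_normal((2, 1, 28))
        nd, names = sc.network_degree(d, parc, subcortical="pooled")
        assert names[-1] == "subcortical"
        sub = parc.members("subcortical")
        assert np.allclose(nd[:, 0, -1], d[:, 0, sub].mean(axis=1))


class TestBalancedBootstrap:
    def test_full_subsample_reproduces_compare_groups(self, rng):
        d = rng.standard_normal((30, 2, 28))
        parc = sc.default_parcellation(28)
        asn = _assignment(["high_risk"] * 10 + ["low_risk"] * 20, criteria="who_whr")
        boot = sc.balanced_bootstrap_compare(
            d, asn, n_iter=5, subsample_size=20, rng=0, parcellation=parc
        )
        contrast = sc.compare_groups(d, asn, parcellation=parc)
        for i in range(5):
            assert np.allclose(boot.t_network[i], contrast.t_network, atol=1e-12)

    def test_deterministic_iteration_sequence(self, rng):
        d = rng.standard_normal((30, 2, 28))
        parc = sc.default_parcellation(28)
        asn = _assignment(["high_risk"] * 8 + ["low_risk"] * 22, criteria="who_whr")
        a = sc.balanced_bootstrap_compare(d, asn, n_iter=10, rng=42, parcellation=parc)
        b = sc.balanced_bootstrap_compare(d, asn, n_iter=10, rng=42, parcellation=parc)
        assert np.array_equal(a.t_network, b.t_network)
        assert a.subsample_size == 8  # defaults to the positive-group size

    def test_oversized_subsample_rejected(self, rng):
        d = rng.standard_normal((20, 1, 28))
        parc = sc.default_parcellation(28)
        asn = _assignment(["high_risk"] * 8 + ["low_risk"] * 12, criteria="who_whr")
        with pytest.raises(InputError, match="exceeds"):
            sc.balanced_bootstrap_compare(
                d, asn, n_iter=2, subsample_size=13, rng=0, parcellation=parc
            )

    def test_planted_sign_stable_across_iterations(self, rng):
        d = rng.standard_normal((60, 1, 28))
        parc = sc.default_parcellation(28)
        vis = parc.members("visual")
        d[:15][:, :, vis] += 1.5  # high-risk visual degrees elevated
        asn = _assignment(["high_risk"] * 15 + ["low_risk"] * 45, criteria="who_whr")
        boot = sc.balanced_bootstrap_compare(d, asn, n_iter=50, rng=1, parcellation=parc)
        j = boot.network_names.index("visual")
        assert (boot.t_network[:, 0, j] > 0).mean() >= 0.95
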