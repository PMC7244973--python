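"""Orthogonal arrays, SN ratios, gains, and variable selection."""

import numpy as np
import pytest

from mtskit import (
    compute_gains,
    fit_space,
    generate_oa,
    run_oa_experiment,
    select_variables,
    sn_ratio_larger_better,
)
from mtskit.datasets import (
    BLOOD_SCREEN_VARIABLES,
    blood_screen_design,
    blood_screen_experiment,
    blood_screen_sn_ratios,
)
from mtskit.exceptions import ContractError
from mtskit.synthetic import SyntheticConfig, generate_population

from conftest import make_table


class TestGenerateOA:
    @pytest.mark.parametrize("n_factors,n_runs", [(1, 2), (3, 4), (7, 8), (15, 16), (31, 32)])
    def test_run_count_is_next_power_of_two(self, n_factors, n_runs):
        oa = generate_oa(n_factors)
        assert oa.n_runs == n_runs
        assert oa.n_columns >= n_factors

    @pytest.mark.parametrize("n_factors", [1, 3, 7, 15, 31, 63])
    def test_balance_and_orthogonality_exhaustively(self, n_factors):
        oa = generate_oa(n_factors)
        oa.validate()  # raises on any unbalanced or non-orthogonal column pair

    def test_l4_column_balance(self):
        oa = generate_oa(3)
        assert ((oa.levels == 1).sum(axis=0) == 2).all()

    def test_l8_pair_counts_by_brute_force(self):
        oa = generate_oa(7)
        for i in range(7):
            for j in range(i + 1, 7):
                pairs = list(zip(oa.levels[:, i], oa.levels[:, j]))
                for combo in [(1, 1), (1, 2), (2, 1), (2, 2)]:
                    assert pairs.count(combo) == 2


class TestSNRatio:
    def test_unit_distances_give_zero_db(self):
        assert sn_ratio_larger_better([1.0, 1.0, 1.0]) == pytest.approx(0.0)

    def test_tens_give_ten_db(self):
        assert sn_ratio_larger_better([10.0, 10.0]) == pytest.approx(10.0)

    def test_mixed_closed_form(self):
        # mean(1/md) for {1, 0.1} is 5.5
        assert sn_ratio_larger_better([1.0, 0.1]) == pytest.approx(-10 * np.log10(5.5))

    def test_random_vectors_match_direct_formula(self, rng):
        for _ in range(20):
            mds = rng.uniform(0.01, 50.0, size=rng.integers(1, 40))
            expected = -10.0 * np.log10(np.mean(1.0 / mds))
            assert sn_ratio_larger_better(mds) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("bad", [[0.0, 1.0], [-1.0, 2.0], []])
    def test_nonpositive_or_empty_rejected(self, bad):
        with pytest.raises(ContractError):
            sn_ratio_larger_better(bad)


class TestComputeGains:
    def test_constant_sn_vector_gives_zero_gains(self):
        oa = generate_oa(5)
        table = compute_gains(np.full(oa.n_runs, 3.3), oa, {f"v{i}": i for i in range(5)})
        assert all(g == pytest.approx(0.0) for g in table.gain.values())

    def test_random_vector_matches_loop_oracle(self, rng):
        oa = generate_oa(9)
        sn = rng.normal(size=oa.n_runs)
        assignment = {f"v{i}": i for i in range(9)}
        table = compute_gains(sn, oa, assignment)
        for var, col in assignment.items():
            lvl1 = [sn[r] for r in range(oa.n_runs) if oa.levels[r, col] == 1]
            lvl2 = [sn[r] for r in range(oa.n_runs) if oa.levels[r, col] == 2]
            assert table.level1_mean[var] == pytest.approx(np.mean(lvl1), abs=1e-12)
            assert table.level2_mean[var] == pytest.approx(np.mean(lvl2), abs=1e-12)
            assert table.gain[var] == pytest.approx(np.mean(lvl1) - np.mean(lvl2), abs=1e-12)

    def test_balance_identity_level_means_average_to_grand_mean(self, rng):
        oa = generate_oa(7)
        sn = rng.normal(size=oa.n_runs)
        table = compute_gains(sn, oa, {f"v{i}": i for i in range(7)})
        grand = sn.mean()
        for var in table.gain:
            assert (table.level1_mean[var] + table.level2_mean[var]) / 2 == pytest.approx(
                grand, abs=1e-10
            )

    def test_permutation_equivariance(self, rng):
        oa = generate_oa(6)
        sn = rng.normal(size=oa.n_runs)
        fwd = compute_gains(sn, oa, {f"v{i}": i for i in range(6)})
        perm = [3, 0, 5, 1, 4, 2]
        swapped = compute_gains(sn, oa, {f"v{i}": perm[i] for i in range(6)})
        for i in range(6):
            assert swapped.gain[f"v{i}"] == pytest.approx(fwd.gain[f"v{perm[i]}"])

    def test_length_mismatch_rejected(self):
        oa = generate_oa(3)
        with pytest.raises(ContractError):
            compute_gains(np.ones(oa.n_runs + 1), oa, {"a": 0})


class TestPackagedBloodScreen:
    """The published 16-run worked example, reproduced from its fixture."""

    def test_fixture_design_is_a_valid_orthogonal_array(self):
        blood_screen_design().validate()

    def test_level_means_and_gains_match_published_values(self):
        table = blood_screen_experiment()
        assert table.level1_mean["PDW"] == pytest.approx(8.16, abs=0.01)
        assert table.level2_mean["PDW"] == pytest.approx(3.05, abs=0.01)
        # Gains that recompute exactly (to printed 2-decimal precision) from
        # the printed per-run SN ratios.
        for var, expected in {
            "PDW": 5.11, "MPV": 0.70, "WBC": 0.39, "EO#": 0.31, "MO#": -0.43,
        }.items():
            assert table.gain[var] == pytest.approx(expected, abs=0.01), var
        # The remaining printed gains were rounded from unrounded SN ratios,
        # so recomputation from the 2-decimal SNs can drift by ~0.02; the
        # sign (which drives selection) always agrees.
        published_sign = {
            "BA#": -1, "LY": 1, "LY#": 1, "MCH": -1, "MCHC": 1, "MO": -1,
            "PLT": -1, "RBC": -1, "RDW": -1,
        }
        for var, sign in published_sign.items():
            assert np.sign(table.gain[var]) == sign, var

    def test_exactly_seven_variables_selected(self):
        selected = select_variables(blood_screen_experiment())
        assert len(selected) == 7
        assert set(selected) == {"EO#", "LY", "LY#", "MCHC", "MPV", "PDW", "WBC"}
        assert selected[0] == "PDW"  # descending gain
        assert selected[1] == "MPV"

    def test_sixteen_published_runs(self):
        assert blood_screen_sn_ratios().shape == (16,)
        assert blood_screen_design().n_runs == 16
        assert len(BLOOD_SCREEN_VARIABLES) == 14


class TestSelectVariables:
    def test_all_negative_gains_give_empty_selection_with_warning(self):
        oa = generate_oa(3)
        sn = np.array([1.0, 2.0, 1.0, 2.0])  # crafted: all gains <= 0
        table = compute_gains(sn, oa, {"a": 0, "b": 1, "c": 2})
        table.gain = {v: -abs(g) - 0.1 for v, g in table.gain.items()}
        with pytest.warns(UserWarning, match="no variable"):
            assert select_variables(table) == []

    def test_tiny_positive_gain_is_still_selected(self):
        oa = generate_oa(1)
        table = compute_gains(np.array([1.0, 1.0]), oa, {"a": 0})
        table.gain["a"] = 1e-12
        assert select_variables(table) == ["a"]


class TestRunOAExperiment:
    @staticmethod
    def _two_group(rng, shift, n=200, k=6):
        names = [f"v{i}" for i in range(k)]
        normal = make_table(rng.standard_normal((n, k)), names)
        abnormal_values = rng.standard_normal((n, k))
        abnormal_values[:, 0] += shift  # shift only v0
        abnormal = make_table(abnormal_values, names)
        return normal, abnormal, names

    def test_single_shifted_variable_gets_largest_positive_gain(self, rng):
        normal, abnormal, names = self._two_group(rng, shift=3.0)
        oa = generate_oa(len(names))
        table = run_oa_experiment(normal, abnormal, oa, names)
        assert table.gain["v0"] > 0
        assert table.gain["v0"] == max(table.gain.values())
        assert "v0" in select_variables(table)

    def test_null_experiment_gains_are_small(self):
        # 10 factors on a 16-run array so every run keeps enough variables
        # for E[1/MD] to stay finite; under the null, gains carry only the
        # small positive inclusion-count bias of the larger-the-better SN.
        gains = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            normal, abnormal, names = self._two_group(rng, shift=0.0, n=300, k=10)
            oa = generate_oa(len(names))
            table = run_oa_experiment(normal, abnormal, oa, names)
            gains.extend(table.gain.values())
        assert abs(np.mean(gains)) < 0.75
        assert np.abs(gains).max() < 2.0

    def test_run_sn_reproducible_by_manual_refit(self, rng):
        normal, abnormal, names = self._two_group(rng, shift=2.0, n=80, k=4)
        oa = generate_oa(len(names))
        table = run_oa_experiment(normal, abnormal, oa, names)
        # recompute run 0 (all variables at level 1) by hand
        from mtskit import compute_md

        included = [v for i, v in enumerate(names) if oa.levels[0, i] == 1]
        space = fit_space(normal, included)
        md = compute_md(space, abnormal).values
        assert table.run_sn[0] == pytest.approx(sn_ratio_larger_better(md), abs=1e-12)
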