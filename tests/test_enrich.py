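"""Statistical stage: normalization, controls, moderated statistic, FDR."""

import subprocess
import sys
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ionnet import (
    IntensityMatrix,
    PipelineConfig,
    build_control_matrix,
    call_interactors,
    complementary_median,
    eligibility_threshold,
    log2_transform,
    permutation_fdr_call,
    pulldown_presence,
    quantile_normalize,
    s0_statistic,
    scale_proteome,
)

from conftest import make_design, make_matrix


def matrix_from(values, columns, proteins=None):
    values = np.asarray(values, dtype=float)
    proteins = proteins or [f"P{i + 1}" for i in range(values.shape[0])]
    return IntensityMatrix(pd.DataFrame(values, index=proteins, columns=columns))


class TestQuantileNormalize:
    def test_rank_mean_oracle_3x2(self):
        # hand-computed: sorted columns (2,4,6) and (3,6,9); row means
        # (2.5, 5, 7.5) assigned back in each column's original rank order
        m = matrix_from([[2, 9], [4, 6], [6, 3]], ["s1", "s2"])
        out = quantile_normalize(m)
        np.testing.assert_allclose(
            out.values, [[2.5, 7.5], [5, 5], [7.5, 2.5]]
        )

    def test_identical_columns_fixed_point(self):
        m = matrix_from([[1, 1], [5, 5], [9, 9]], ["s1", "s2"])
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.values, m.values)

    def test_single_column_identity(self):
        m = matrix_from([[3], [1], [2]], ["s1"])
        np.testing.assert_allclose(quantile_normalize(m).values, m.values)

    def test_idempotent_on_complete_data(self):
        rng = np.random.default_rng(1)
        m = matrix_from(np.exp2(rng.normal(20, 2, (40, 5))), [f"s{j}" for j in range(5)])
        once = quantile_normalize(m)
        twice = quantile_normalize(once)
        np.testing.assert_allclose(twice.values, once.values, rtol=1e-12)

    def test_missing_entries_stay_missing(self):
        vals = np.array([[2, 9], [np.nan, 6], [6, 3]])
        out = quantile_normalize(matrix_from(vals, ["s1", "s2"]))
        assert np.isnan(out.values[1, 0])
        assert np.isfinite(out.values[1, 1])

    def test_within_column_rank_order_preserved(self):
        rng = np.random.default_rng(2)
        vals = np.exp2(rng.normal(20, 2, (30, 4)))
        vals[rng.random(vals.shape) < 0.2] = np.nan
        out = quantile_normalize(matrix_from(vals, list("abcd")))
        for j in range(4):
            obs = ~np.isnan(vals[:, j])
            before = np.argsort(np.argsort(vals[obs, j]))
            after = np.argsort(np.argsort(out.values[obs, j]))
            np.testing.assert_array_equal(before, after)

    def test_ties_get_mean_of_tied_targets(self):
        m = matrix_from([[5, 1], [5, 2], [1, 3]], ["s1", "s2"])
        out = quantile_normalize(m)
        # s1 ties at rank 2-3 share the mean of the top two reference values
        assert out.values[0, 0] == out.values[1, 0]

    def test_all_missing_column_rejected(self):
        vals = np.array([[1.0, np.nan], [2.0, np.nan]])
        with pytest.raises(ValueError, match="s2"):
            quantile_normalize(matrix_from(vals, ["s1", "s2"]))

    def test_matches_limma_reference_implementation(self, tmp_path):
        """Cross-check against Bioconductor limma's normalizeQuantiles."""
        rng = np.random.default_rng(3)
        vals = np.round(np.exp2(rng.normal(16, 1.5, (25, 4))), 4)
        m = matrix_from(vals, list("abcd"))
        ours = quantile_normalize(m).values
        csv = tmp_path / "m.csv"
        pd.DataFrame(vals).to_csv(csv, index=False)
        script = (
            f"suppressMessages(library(limma));"
            f"x <- as.matrix(read.csv('{csv}'));"
            f"write.csv(normalizeQuantiles(x), '{tmp_path}/out.csv', row.names=FALSE)"
        )
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        theirs = pd.read_csv(tmp_path / "out.csv").to_numpy()
        np.testing.assert_allclose(ours, theirs, rtol=1e-6)


class TestEligibility:
    def test_sixteen_by_four_worked_example(self):
        design = make_design(n_baits=16, n_reps=4)
        total, bound = eligibility_threshold(design)
        assert (total, bound) == (64, 32)
        # protein observed in exactly 33 pulldowns is eligible; 32 is not
        vals = np.full((2, 64 + 2), np.nan)
        vals[0, :33] = 2.0
        vals[1, :32] = 2.0
        m = make_matrix(design, values=np.exp2(vals))
        pres = pulldown_presence(m, design)
        assert pres.loc["P1", "n_observed"] == 33 and pres.loc["P1", "eligible"]
        assert pres.loc["P2", "n_observed"] == 32 and not pres.loc["P2", "eligible"]

    def test_igg_columns_excluded_from_count(self):
        design = make_design(n_baits=2, n_reps=2, igg=2)
        vals = np.full((1, 6), np.nan)
        vals[0, 4:] = 2.0  # only the IgG columns observed
        pres = pulldown_presence(make_matrix(design, values=np.exp2(vals)), design)
        assert pres.loc["P1", "n_observed"] == 0
        assert not pres.loc["P1", "eligible"]

    def test_full_and_empty_presence(self):
        design = make_design(n_baits=2, n_reps=2, igg=0)
        vals = np.array([[2.0] * 4, [np.nan] * 4])
        pres = pulldown_presence(make_matrix(design, values=np.exp2(vals)), design)
        assert pres.loc["P1", "eligible"]
        assert pres.loc["P2", "n_observed"] == 0 and not pres.loc["P2", "eligible"]


class TestComplementaryMedian:
    def family_fixture(self, b_value=100.0):
        design = make_design(
            n_baits=3, n_reps=4, families={"b1": "fam", "b2": "fam", "b3": "b3"}
        )
        vals = np.empty((1, 14))
        vals[0, :4] = 50.0  # b1 (target)
        vals[0, 4:8] = b_value  # b2, same family -> excluded
        vals[0, 8:12] = [5, 6, 7, 8]  # b3
        vals[0, 12:] = 1.0  # IgG
        m = log2_transform(make_matrix(design, values=np.exp2(vals)))
        # undo the log for direct value checks: work on plain values instead
        m = IntensityMatrix(
            pd.DataFrame(vals, index=["P1"], columns=m.sample_ids), log_scale=True
        )
        return design, m

    def test_family_excluded_from_median(self):
        design, m = self.family_fixture()
        assert complementary_median(m, design, "b1", "P1") == 6.5

    def test_perturbing_family_values_never_changes_result(self):
        design, m1 = self.family_fixture(b_value=100.0)
        _, m2 = self.family_fixture(b_value=-40.0)
        assert complementary_median(m1, design, "b1", "P1") == complementary_median(
            m2, design, "b1", "P1"
        )

    def test_constant_out_of_family_value(self):
        design = make_design(n_baits=2, n_reps=2, igg=0)
        vals = np.log2(np.array([[3.0, 4.0, 10.0, 10.0]]))
        m = IntensityMatrix(
            pd.DataFrame(
                vals, index=["P1"], columns=design.pulldown_samples
            ),
            log_scale=True,
        )
        assert complementary_median(m, design, "b1", "P1") == pytest.approx(
            np.log2(10.0)
        )

    def test_exclusion_exhausting_data_gives_missing(self):
        design, m = self.family_fixture()
        m.data.loc["P1", design.replicate_map["b3"]] = np.nan
        assert np.isnan(complementary_median(m, design, "b1", "P1"))

    def test_unknown_bait_rejected(self, small_design, small_matrix):
        with pytest.raises(KeyError):
            complementary_median(
                log2_transform(small_matrix), small_design, "nope", "P1"
            )


class TestScaleProteome:
    def _pair(self, shift=0.0, scale=1.0, n=50):
        rng = np.random.default_rng(4)
        base = rng.normal(20, 2, (n, 3))
        pull = IntensityMatrix(
            pd.DataFrame(base, index=[f"P{i}" for i in range(n)], columns=list("abc")),
            log_scale=True,
        )
        prot = IntensityMatrix(
            pd.DataFrame(
                base * scale + shift,
                index=[f"P{i}" for i in range(n)],
                columns=list("xyz"),
            ),
            log_scale=True,
        )
        return prot, pull

    def test_identity_when_already_matched(self):
        prot, pull = self._pair()
        out = scale_proteome(prot, pull)
        np.testing.assert_allclose(out.values, prot.values, atol=1e-9)

    def test_shift_removed_and_medians_match(self):
        prot, pull = self._pair(shift=3.0)
        out = scale_proteome(prot, pull)
        assert np.median(out.values) == pytest.approx(np.median(pull.values))
        np.testing.assert_allclose(out.values, pull.values, atol=1e-9)

    def test_too_few_shared_proteins_rejected(self):
        prot, pull = self._pair(n=5)
        with pytest.raises(ValueError, match="shared proteins"):
            scale_proteome(prot, pull)

    def test_constant_proteome_policy(self):
        _, pull = self._pair()
        const = IntensityMatrix(
            pd.DataFrame(
                np.full((50, 2), 7.0),
                index=[f"P{i}" for i in range(50)],
                columns=["x", "y"],
            ),
            log_scale=True,
        )
        with pytest.raises(ValueError, match="IQR"):
            scale_proteome(const, pull)
        out = scale_proteome(const, pull, iqr_zero_policy="shift")
        assert np.allclose(out.values, np.median(pull.values))


class TestControlCascade:
    def build(self, vals, design, proteome=None, seed=0):
        m = IntensityMatrix(
            pd.DataFrame(
                vals,
                index=[f"P{i + 1}" for i in range(vals.shape[0])],
                columns=design.pulldown_samples + design.igg_samples,
            ),
            log_scale=True,
        )
        cfg = PipelineConfig(rng_seed=seed)
        return build_control_matrix(
            m, design, "b1", cfg, proteome=proteome,
            rng=np.random.default_rng(seed),
        )

    def test_eligible_protein_all_complementary(self):
        design = make_design(n_baits=3, n_reps=4, igg=2)
        vals = np.tile(np.arange(1.0, 15.0), (1, 1))
        control = self.build(vals, design)
        assert set(control.provenance[0]) == {0}
        assert control.provenance_labels()[0] == "complementary_median"

    def test_ineligible_protein_uses_igg(self):
        design = make_design(n_baits=3, n_reps=4, igg=2)
        vals = np.full((1, 14), np.nan)
        vals[0, :4] = 5.0  # only the target bait observed -> not eligible
        vals[0, 12:] = 3.0  # IgG observed
        control = self.build(vals, design)
        assert set(control.provenance[0]) == {1}
        assert np.allclose(control.values[0], 3.0)

    def test_proteome_branch(self):
        design = make_design(n_baits=3, n_reps=4, igg=2)
        vals = np.full((1, 14), np.nan)
        vals[0, :4] = 5.0
        proteome = IntensityMatrix(
            pd.DataFrame([[2.0, 2.5]], index=["P1"], columns=["x", "y"]),
            log_scale=True,
        )
        control = self.build(vals, design, proteome=proteome)
        assert set(control.provenance[0]) == {2}
        assert np.allclose(control.values[0], 2.25)

    def test_random_imputation_matches_left_shifted_closed_form(self):
        # protein absent everywhere but the bait: control drawn from
        # N(mean - 1.8 sd, (0.3 sd)^2) over all observed pulldown values
        design = make_design(n_baits=3, n_reps=4, igg=0)
        rng = np.random.default_rng(5)
        n = 2500  # 2500 proteins x 4 slots = 1e4 draws
        vals = np.full((n, 12), np.nan)
        vals[:, :4] = rng.normal(20, 1, (n, 4))
        control = self.build(vals, design, seed=11)
        assert set(np.unique(control.provenance)) == {3}
        obs = vals[:, :4].ravel()
        expected = obs.mean() - 1.8 * obs.std(ddof=1)
        width = 0.3 * obs.std(ddof=1)
        draws = control.values.ravel()
        assert draws.mean() == pytest.approx(expected, abs=3 * width / np.sqrt(draws.size))
        assert draws.std() == pytest.approx(width, rel=0.1)

    def test_same_seed_reproducible(self):
        design = make_design(n_baits=3, n_reps=4, igg=0)
        vals = np.full((5, 12), np.nan)
        vals[:, :4] = 5.0
        c1 = self.build(vals, design, seed=3)
        c2 = self.build(vals, design, seed=3)
        np.testing.assert_array_equal(c1.values, c2.values)


class TestS0Statistic:
    def test_zero_s0_equals_classical_t(self):
        x, y = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        d, p = s0_statistic(x, y, 0.0)
        ref = stats.ttest_ind(x, y, equal_var=True)
        assert abs(d - ref.statistic) < 1e-10
        assert abs(p - ref.pvalue) < 1e-10

    def test_identical_groups_null(self):
        d, p = s0_statistic([2.0, 2.0, 2.0], [2.0, 2.0, 2.0], 1.0)
        assert d == 0.0 and p == 1.0

    def test_large_s0_limit(self):
        d, _ = s0_statistic([3.0, 3.1], [1.0, 1.1], 1e6)
        assert d == pytest.approx(2.0e-6, rel=1e-3)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            s0_statistic([1.0], [2.0, 3.0], 1.0)

    @given(
        st.lists(st.floats(-10, 10), min_size=3, max_size=6),
        st.lists(st.floats(-10, 10), min_size=3, max_size=6),
        st.floats(0, 5),
        st.floats(0.1, 5),
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_abs_d_nonincreasing_in_s0(self, x, y, s0, ds0):
        d1, _ = s0_statistic(x, y, s0)
        d2, _ = s0_statistic(x, y, s0 + ds0)
        if np.isnan(d1):  # s0 = 0 with two degenerate groups: 0/0
            assert abs(d2) == 0.0 or np.isnan(d2)
        else:
            assert abs(d2) <= abs(d1) + 1e-12


def brute_force_fdr_call(bait, ctrl, s0, q):
    """Independent exhaustive-enumeration oracle for the 4v4 case."""

    def d_stat(x, y):
        n1, n2 = len(x), len(y)
        sp2 = ((n1 - 1) * np.var(x, ddof=1) + (n2 - 1) * np.var(y, ddof=1)) / (
            n1 + n2 - 2
        )
        se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
        return (np.mean(x) - np.mean(y)) / (se + s0)

    pool = np.hstack([bait, ctrl])
    total, n1 = pool.shape[1], bait.shape[1]
    assigns = list(combinations(range(total), n1))
    perm_abs = []
    for pick in assigns:
        rest = [j for j in range(total) if j not in pick]
        for i in range(pool.shape[0]):
            perm_abs.append(abs(d_stat(pool[i, list(pick)], pool[i, rest])))
    perm_abs = np.array(perm_abs)
    d_obs = np.array([d_stat(bait[i], ctrl[i]) for i in range(bait.shape[0])])
    best = None
    for c in sorted(np.unique(np.abs(d_obs))):
        n_obs = np.sum(np.abs(d_obs) >= c)
        n_perm = np.sum(perm_abs >= c) / len(assigns)
        if min(1.0, n_perm / n_obs) <= q:
            best = c
            break
    if best is None:
        return np.zeros(len(d_obs), bool), len(assigns)
    return np.abs(d_obs) >= best, len(assigns)


class TestPermutationFdr:
    def test_exhaustive_enumeration_matches_brute_force(self):
        rng = np.random.default_rng(6)
        bait = rng.normal(0, 1, (40, 4))
        bait[:6] += 4.0  # clear enrichment for six proteins
        ctrl = rng.normal(0, 1, (40, 4))
        call = permutation_fdr_call(bait, ctrl, s0=0.5, fdr_target=0.05)
        expected, n_assign = brute_force_fdr_call(bait, ctrl, 0.5, 0.05)
        assert call.exact and call.n_assignments == n_assign == 70
        np.testing.assert_array_equal(call.significant, expected)

    def test_clear_separation_calls_all_spiked(self):
        rng = np.random.default_rng(7)
        bait = rng.normal(0, 0.1, (30, 4))
        ctrl = rng.normal(0, 0.1, (30, 4))
        bait[:5] += 50.0
        call = permutation_fdr_call(bait, ctrl, s0=1.0, fdr_target=0.05)
        assert call.significant[:5].all()
        assert not call.significant[5:].any()

    def test_monte_carlo_converges_to_exhaustive(self):
        rng = np.random.default_rng(8)
        bait = rng.normal(0, 1, (25, 4))
        bait[:4] += 5.0
        ctrl = rng.normal(0, 1, (25, 4))
        exact = permutation_fdr_call(bait, ctrl, 1.0, 0.05, n_permutations=10)
        # 70 distinct assignments < 250 requested -> still enumerated exactly
        mc = permutation_fdr_call(bait, ctrl, 1.0, 0.05, n_permutations=250)
        assert exact.exact and mc.exact
        np.testing.assert_array_equal(exact.significant, mc.significant)

    def test_unreachable_target_gives_empty_set(self):
        rng = np.random.default_rng(9)
        bait = rng.normal(0, 1, (20, 4))
        ctrl = rng.normal(0, 1, (20, 4))
        call = permutation_fdr_call(bait, ctrl, 2.0, fdr_target=1e-6)
        assert not call.significant.any()
        assert call.threshold == float("inf")


class TestCallInteractors:
    def test_replicate_filter_excludes_two_of_four(self):
        design = make_design(n_baits=3, n_reps=4, igg=2)
        rng = np.random.default_rng(10)
        vals = np.exp2(rng.normal(20, 1, (20, 14)))
        # P1 hugely enriched in b1 but observed in only 2 of 4 replicates
        vals[0, :2] = np.exp2(30.0)
        vals[0, 2:4] = np.nan
        m = make_matrix(design, values=vals)
        res = call_interactors(m, design, PipelineConfig(rng_seed=0))
        assert "P1" not in res["b1"].index
        # present in 3 of 4 -> tested
        vals2 = vals.copy()
        vals2[0, 2] = np.exp2(30.0)
        res2 = call_interactors(make_matrix(design, values=vals2), design,
                                PipelineConfig(rng_seed=0))
        assert "P1" in res2["b1"].index

    def test_significant_implies_min_valid_replicates(self):
        from ionnet import SynthSpec, generate_apms

        spec = SynthSpec(n_proteins=300, n_baits=3, n_true_per_bait=5, rng_seed=2)
        pull, design, ann, truth, prot = generate_apms(spec)
        res = call_interactors(pull, design, PipelineConfig(rng_seed=2), proteome=prot)
        for df in res.values():
            sig = df[df["significant"].astype(bool)]
            assert (sig["n_valid_bait_replicates"] >= 3).all()

    def test_bait_always_reported_and_flagged(self):
        from ionnet import SynthSpec, generate_apms

        spec = SynthSpec(n_proteins=200, n_baits=3, n_true_per_bait=5, rng_seed=3)
        pull, design, ann, truth, prot = generate_apms(spec)
        res = call_interactors(pull, design, PipelineConfig(rng_seed=3), proteome=prot)
        for bait, df in res.items():
            assert bait in df.index
            assert bool(df.loc[bait, "is_bait"])

    def test_per_bait_override_changes_calls(self):
        from ionnet import SynthSpec, generate_apms

        spec = SynthSpec(n_proteins=300, n_baits=3, n_true_per_bait=10, rng_seed=4)
        pull, design, ann, truth, prot = generate_apms(spec)
        strict = PipelineConfig(rng_seed=4, per_bait_overrides={"bait1": (0.001, 6.0)})
        loose = PipelineConfig(rng_seed=4)
        n_strict = call_interactors(pull, design, strict, proteome=prot)["bait1"][
            "significant"
        ].sum()
        n_loose = call_interactors(pull, design, loose, proteome=prot)["bait1"][
            "significant"
        ].sum()
        assert n_strict <= n_loose
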