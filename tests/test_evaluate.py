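"""Statistics oracles (R^2, exact Wilcoxon, F-score), variant admissibility,
and the cross-variant comparison machinery."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import COARSE_EVAL

from dbscompare.cohort import CohortSpec, generate_cohort
from dbscompare.evaluate import (
    VariantSpec,
    compare_variants,
    default_contrasts,
    f_score_presence,
    r_squared,
    run_variant,
    six_variants,
    wilcoxon_signed_rank,
)


class TestRSquared:
    def test_perfect_affine_relation(self):
        x = np.array([1.0, 2.0, 5.0, 7.0])
        assert r_squared(x, 2 * x + 1) == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # Pearson r([1,2,3],[1,3,2]) = 0.5, so R^2 = 0.25
        assert r_squared([1, 2, 3], [1, 3, 2]) == pytest.approx(0.25)

    def test_constant_series_flagged_undefined(self):
        assert np.isnan(r_squared([1, 2, 3], [4, 4, 4]))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            r_squared([1, 2], [3, 4])

    @settings(max_examples=30, deadline=None)
    @given(
        a=st.floats(0.1, 50),
        b=st.floats(-10, 10),
        c=st.floats(0.1, 50),
        d=st.floats(-10, 10),
    )
    def test_invariant_under_positive_affine_rescaling(self, a, b, c, d):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=12), rng.normal(size=12)
        assert r_squared(a * x + b, c * y + d) == pytest.approx(r_squared(x, y), rel=1e-6)


def _brute_force_wilcoxon_two_sided(d: np.ndarray) -> float:
    """Exhaustive enumeration over all sign assignments (oracle)."""
    from scipy.stats import rankdata

    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for s, r in zip(signs, ranks) if s))
    ws = np.asarray(ws)
    p_le = np.mean(ws <= w_obs + 1e-12)
    p_ge = np.mean(ws >= w_obs - 1e-12)
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestWilcoxon:
    def test_eleven_uniform_pairs_exact_p(self):
        x = np.arange(1.0, 12.0)
        stat, p = wilcoxon_signed_rank(x, np.zeros(11))
        assert stat == 66.0
        assert p == pytest.approx(2.0 / 2**11)  # 0.000977

    def test_five_uniform_pairs_exact_p(self):
        _, p = wilcoxon_signed_rank(np.ones(5) * 2.0)
        assert p == pytest.approx(2.0 / 32)  # 0.0625

    def test_mirrored_differences_give_p_one(self):
        d = np.array([3.0, -3.0, 1.5, -1.5, 0.5, -0.5])
        _, p = wilcoxon_signed_rank(d)
        assert p == pytest.approx(1.0)

    def test_all_zero_differences_warns_p_one(self):
        with pytest.warns(UserWarning, match="zero"):
            _, p = wilcoxon_signed_rank(np.zeros(6))
        assert p == 1.0

    @pytest.mark.parametrize("n", [6, 9, 12])
    def test_matches_full_enumeration(self, n):
        rng = np.random.default_rng(n)
        d = np.round(rng.normal(0.3, 1.0, n), 2)
        d[d == 0] = 0.11
        with np.errstate(all="ignore"):
            _, p = wilcoxon_signed_rank(d)
        assert p == pytest.approx(_brute_force_wilcoxon_two_sided(d), abs=1e-12)

    def test_matches_enumeration_with_ties(self):
        d = np.array([1.0, 1.0, -1.0, 2.0, 2.0, 3.0, -2.0, 0.0])
        _, p = wilcoxon_signed_rank(d)
        assert p == pytest.approx(_brute_force_wilcoxon_two_sided(d), abs=1e-12)

    def test_cross_check_against_scipy_exact(self):
        from scipy.stats import wilcoxon as scipy_wilcoxon

        rng = np.random.default_rng(1)
        d = rng.normal(0.4, 1.0, 10)
        _, p = wilcoxon_signed_rank(d)
        ref = scipy_wilcoxon(d, method="exact").pvalue
        assert p == pytest.approx(ref, abs=1e-12)

    def test_normal_approximation_beyond_exact_limit(self):
        rng = np.random.default_rng(2)
        d = rng.normal(0.3, 1.0, 40)
        _, p = wilcoxon_signed_rank(d)
        from scipy.stats import wilcoxon as scipy_wilcoxon

        ref = scipy_wilcoxon(d, method="approx", correction=True).pvalue
        assert p == pytest.approx(ref, rel=0.05)


class TestFScore:
    def test_perfect_agreement(self):
        assert f_score_presence([1, 0, 2, 0], [5, 0, 7, 0]) == pytest.approx(1.0)

    def test_harmonic_mean_of_precision_and_recall(self):
        # precision 0.5, recall 1.0 -> 2/3
        pred = [1, 1, 1, 1, 0]
        obs = [1, 1, 0, 0, 0]
        assert f_score_presence(pred, obs) == pytest.approx(2.0 / 3.0)

    def test_all_zero_observed_excluded(self):
        assert f_score_presence([1, 0, 1], [0, 0, 0]) is None

    def test_no_true_positives_scores_zero(self):
        assert f_score_presence([0, 0, 0], [1, 1, 0]) == 0.0


class TestVariants:
    def test_six_admissible_variants(self):
        vs = six_variants()
        assert len(vs) == 6
        assert len({v.key for v in vs}) == 6

    def test_df_structure_inadmissible(self):
        with pytest.raises(ValueError, match="pathway"):
            VariantSpec("DF", "native", "structure")

    def test_parse_round_trip(self):
        for v in six_variants():
            assert VariantSpec.parse(v.key) == v

    def test_default_contrast_table_lists_ten_pairs(self):
        pairs = default_contrasts()
        assert len(pairs) == 10
        # every pair either includes the reference or differs in exactly one factor
        ref = "DF-Native-Pathway"
        for a, b in pairs:
            va, vb = VariantSpec.parse(a), VariantSpec.parse(b)
            diff = sum(
                getattr(va, f) != getattr(vb, f) for f in ("method", "space", "representation")
            )
            assert ref in (a, b) or diff == 1


class TestRunVariant:
    def test_activation_monotone_in_amplitude_for_all_metrics(self, fixture_cohort, fixture_activations):
        _, subjects, _ = fixture_cohort
        act = fixture_activations
        config = {
            s.setting_id: (s.cathodes, s.anodes, s.amplitude_mA)
            for subj in subjects
            for s in subj.settings
        }
        act = act.assign(
            config=[config[sid][:2] for sid in act["setting_id"]],
            amplitude=[config[sid][2] for sid in act["setting_id"]],
        )
        for (_, _, _, _), g in act.groupby(["subject", "variant", "pathway", "config"]):
            gs = g.sort_values("amplitude")
            assert (np.diff(gs["value"].to_numpy()) >= -1e-9).all()

    def test_values_are_percentages(self, fixture_activations):
        v = fixture_activations["value"]
        assert ((v >= 0) & (v <= 100)).all()

    def test_zero_magnitude_warp_reproduces_native_df(self, fixture_cohort):
        import dataclasses

        spec, _, options = fixture_cohort
        spec0 = dataclasses.replace(spec, warp_magnitude=0.0, seed=17)
        subj = generate_cohort(spec0, eval_options=options)[0]
        nat = run_variant(subj, VariantSpec("DF", "native", "pathway"), options)
        nrm = run_variant(subj, VariantSpec("DF", "normative", "pathway"), options)
        assert np.allclose(nat["value"].to_numpy(), nrm["value"].to_numpy(), atol=1e-6)

    def test_distance_effect_df_reaches_far_bundle_where_vta_does_not(
        self, fixture_cohort, fixture_activations
    ):
        """There exist settings activating >0% of the far large-fiber bundle
        under DF while the VTA streamline metric returns 0%."""
        act = fixture_activations
        merged = act.query("pathway == 'CSBT'").pivot_table(
            index=["subject", "setting_id"], columns="variant", values="value"
        )
        df_pos_vta_zero = (merged["DF-Native-Pathway"] > 0) & (merged["VTA-Native-Pathway"] == 0)
        assert df_pos_vta_zero.any()


class TestCompareVariants:
    def test_report_structure_and_determinism(self, fixture_cohort, fixture_activations):
        _, subjects, _ = fixture_cohort
        r1 = compare_variants(subjects, fixture_activations)
        r2 = compare_variants(subjects, fixture_activations)
        pd.testing.assert_frame_equal(r1.summary, r2.summary)
        assert set(r1.summary["variant"]) == {v.key for v in six_variants()}
        assert set(r1.summary["pathway"]) == {"HDP", "CSBT"}

    def test_directional_grouping_splits_settings(self, fixture_cohort, fixture_activations):
        _, subjects, _ = fixture_cohort
        rep = compare_variants(
            subjects, fixture_activations, groups=("all", "non-directional")
        )
        assert set(rep.r2["group"]) >= {"all", "non-directional"}

    def test_empty_contrast_list_gives_no_p_values(self, fixture_cohort, fixture_activations):
        _, subjects, _ = fixture_cohort
        rep = compare_variants(subjects, fixture_activations, contrasts=[])
        assert rep.contrasts.empty

    def test_unknown_contrast_variant_rejected(self, fixture_cohort, fixture_activations):
        _, subjects, _ = fixture_cohort
        with pytest.raises(ValueError, match="absent"):
            compare_variants(
                subjects,
                fixture_activations,
                contrasts=[("DF-Native-Pathway", "Nope-Native-Pathway")],
            )
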