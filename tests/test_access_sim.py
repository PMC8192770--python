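"""Equilibrium binding, competitive PCR dynamics, backgrounds and accounting."""

import math

import numpy as np
import pytest

from dnapreview import access_sim as ac

T_K = 328.15  # 55 degC


class TestBindingTheta:
    def test_zero_primer_concentration_gives_zero(self):
        assert ac.binding_theta(-15.0, T_K, 0.0) == 0.0

    def test_very_negative_dG_saturates(self):
        assert ac.binding_theta(-1000.0, T_K, 250.0) == pytest.approx(1.0)

    def test_strictly_increasing_in_concentration(self):
        thetas = [ac.binding_theta(-12.0, T_K, c) for c in (50, 125, 250, 500, 1000)]
        assert all(b > a for a, b in zip(thetas, thetas[1:]))

    def test_equilibrium_constant_definition(self):
        eq = ac.BindingEquilibrium(dG=-12.0, T=T_K, primer_conc_nM=250.0)
        assert eq.K_eq == pytest.approx(math.exp(12.0 / (ac.R_KCAL * T_K)))
        cK = 250e-9 * eq.K_eq
        assert eq.theta == pytest.approx(cK / (1 + cK))


class TestCompetitivePcr:
    def test_single_species_amplifies(self, screened_pair):
        primer = screened_pair[0].seq
        sp = [ac.TemplateSpecies("s", 0, 0, 200, 1e6)]
        res = ac.simulate_competitive_pcr(sp, ac.PCRCondition(55.0, 250.0),
                                          primer, primer)
        assert res.final_abundances["s"] > 1e6

    def test_abundances_non_negative_and_non_decreasing(self, screened_pair):
        primer = screened_pair[0].seq
        sp = [
            ac.TemplateSpecies("a", 0, 0, 200, 1e6),
            ac.TemplateSpecies("b", 4, 4, 200, 1e6),
        ]
        res = ac.simulate_competitive_pcr(sp, ac.PCRCondition(46.0, 250.0),
                                          primer, primer)
        diffs = np.diff(res.trajectory, axis=0)
        assert (res.trajectory >= 0).all()
        assert (diffs >= -1e-9).all()

    def test_mass_balance_primers_equal_new_strands(self, screened_pair):
        primer = screened_pair[0].seq
        sp = [
            ac.TemplateSpecies("a", 0, 0, 200, 1e6),
            ac.TemplateSpecies("b", 2, 2, 60, 1e6),
        ]
        res = ac.simulate_competitive_pcr(sp, ac.PCRCondition(45.0, 250.0),
                                          primer, primer)
        per_cycle_growth = res.trajectory[1:].sum(axis=1) - res.trajectory[:-1].sum(
            axis=1
        )
        assert np.allclose(res.new_strands, per_cycle_growth)
        assert np.allclose(res.primers_consumed_fwd, res.new_strands)
        assert np.allclose(res.primers_consumed_rev, res.new_strands)
        assert res.new_strands.sum() <= res.condition.primer_pool_copies + 1e-6

    def test_equal_binding_energies_preserve_copy_ratios_exactly(self):
        sp = [
            ac.TemplateSpecies("x", 0, 0, 200, 1e5, dG_fwd=-13.0, dG_rev=-13.0),
            ac.TemplateSpecies("y", 0, 0, 200, 7e5, dG_fwd=-13.0, dG_rev=-13.0),
        ]
        res = ac.simulate_competitive_pcr(sp, ac.PCRCondition(55.0, 250.0))
        final = res.final_abundances
        assert final["y"] / final["x"] == pytest.approx(7.0, rel=1e-12)

    def test_fig2a_quadrants_stringent_vs_promiscuous(self, screened_pair):
        """250nM/60C and 125nM/55C amplify only the perfect match; 250nM/45C
        and 500nM/55C amplify the 2-HD strand as well."""
        primer = screened_pair[0].seq
        sp = [
            ac.TemplateSpecies("s", 0, 0, 200, 1e6),
            ac.TemplateSpecies("ns", 2, 2, 60, 1e6),
        ]
        for temp, conc in ((60.0, 250.0), (55.0, 125.0)):
            res = ac.simulate_competitive_pcr(
                sp, ac.PCRCondition(temp, conc), primer, primer
            )
            assert res.accessed(1e-2) == {"s"}, (temp, conc)
        for temp, conc in ((45.0, 250.0), (55.0, 500.0)):
            res = ac.simulate_competitive_pcr(
                sp, ac.PCRCondition(temp, conc), primer, primer
            )
            assert res.accessed(1e-2) == {"s", "ns"}, (temp, conc)

    def test_mismatch_fraction_grows_with_primer_concentration(
        self, screened_pair
    ):
        primer = screened_pair[0].seq
        sp = [
            ac.TemplateSpecies("s", 0, 0, 200, 1e6),
            ac.TemplateSpecies("ns", 2, 2, 60, 1e6),
        ]
        fracs = []
        for conc in (125.0, 250.0, 500.0, 1000.0):
            res = ac.simulate_competitive_pcr(
                sp, ac.PCRCondition(54.0, conc), primer, primer
            )
            fracs.append(res.final_fractions()["ns"])
        assert all(b >= a for a, b in zip(fracs, fracs[1:]))

    def test_mismatch_fraction_falls_with_annealing_temperature(
        self, screened_pair
    ):
        primer = screened_pair[0].seq
        sp = [
            ac.TemplateSpecies("s", 0, 0, 200, 1e6),
            ac.TemplateSpecies("ns", 2, 2, 60, 1e6),
        ]
        fracs = []
        for temp in (42.0, 46.0, 50.0, 55.0, 60.0):
            res = ac.simulate_competitive_pcr(
                sp, ac.PCRCondition(temp, 250.0), primer, primer
            )
            fracs.append(res.final_fractions()["ns"])
        assert all(b <= a for a, b in zip(fracs, fracs[1:]))

    def test_mgcl2_promotes_and_kcl_suppresses_mismatch_amplification(
        self, screened_pair
    ):
        primer = screened_pair[0].seq
        sp = [
            ac.TemplateSpecies("s", 0, 0, 200, 1e6),
            ac.TemplateSpecies("ns", 2, 2, 60, 1e6),
        ]
        mg_fracs = [
            ac.simulate_competitive_pcr(
                sp, ac.PCRCondition(55.0, 250.0, mgcl2=mg), primer, primer
            ).final_fractions()["ns"]
            for mg in (1.0, 2.0, 3.0)
        ]
        assert all(b >= a for a, b in zip(mg_fracs, mg_fracs[1:]))
        kcl_fracs = [
            ac.simulate_competitive_pcr(
                sp, ac.PCRCondition(50.0, 250.0, kcl=k), primer, primer
            ).final_fractions()["ns"]
            for k in (50.0, 100.0, 150.0)
        ]
        assert all(b <= a for a, b in zip(kcl_fracs, kcl_fracs[1:]))

    def test_kcl_beyond_150mM_inhibits_amplification_entirely(
        self, screened_pair
    ):
        primer = screened_pair[0].seq
        sp = [ac.TemplateSpecies("s", 0, 0, 200, 1e6)]
        res = ac.simulate_competitive_pcr(
            sp, ac.PCRCondition(50.0, 250.0, kcl=200.0), primer, primer
        )
        assert res.final_abundances["s"] == pytest.approx(1e6)


class TestSimulateAccess:
    def test_default_conditions_access_nested_tier_sets(self, encoded_library,
                                                        screened_pair):
        lib = encoded_library
        fwd, rev = screened_pair[0].seq, screened_pair[1].seq
        sets = []
        for cond in (ac.PREVIEW_CONDITION, ac.INTERMEDIATE_CONDITION,
                     ac.FULL_ACCESS_CONDITION):
            res = ac.simulate_access(lib["strands"], lib["tier_of"], cond,
                                     fwd, rev)
            sets.append(res.accessed_tiers)
        assert sets[0] == {0}
        assert sets[1] == {0, 4}
        assert sets[2] == {0, 4, 6}

    def test_accessed_tiers_monotone_as_temperature_drops(self, encoded_library,
                                                          screened_pair):
        lib = encoded_library
        fwd, rev = screened_pair[0].seq, screened_pair[1].seq
        prev: set[int] = set()
        for temp in (60.0, 55.0, 52.0, 50.0, 48.0, 46.0, 44.0, 43.0, 42.0,
                     41.0, 40.0):
            res = ac.simulate_access(
                lib["strands"], lib["tier_of"],
                ac.PCRCondition(temp, 250.0), fwd, rev,
            )
            assert prev <= res.accessed_tiers, temp
            prev = res.accessed_tiers

    def test_accessed_tiers_monotone_in_primer_concentration(
        self, encoded_library, screened_pair
    ):
        lib = encoded_library
        fwd, rev = screened_pair[0].seq, screened_pair[1].seq
        prev: set[int] = set()
        for conc in (62.5, 125.0, 250.0, 500.0, 1000.0):
            res = ac.simulate_access(
                lib["strands"], lib["tier_of"],
                ac.PCRCondition(46.0, conc), fwd, rev,
            )
            assert prev <= res.accessed_tiers, conc
            prev = res.accessed_tiers


class TestErrorProneBackground:
    def test_identity_profile_copies_template(self):
        ident = ac.ErrorProneProfile(
            matrix=tuple(tuple(1.0 if i == j else 0.0 for j in range(4))
                         for i in range(4)),
            cycles=10,
        )
        pool = ac.error_prone_background("ACGT" * 50, 20, ident,
                                         np.random.default_rng(0))
        assert all(s == "ACGT" * 50 for s in pool)

    def test_mean_divergence_matches_matrix_power_expectation(self):
        template = "ACGT" * 50
        profile = ac.ErrorProneProfile.transition_biased(rate=2e-3, cycles=35)
        rng = np.random.default_rng(42)
        pool = ac.error_prone_background(template, 1000, profile, rng)
        divergences = [
            sum(a != b for a, b in zip(template, s)) for s in pool
        ]
        expected = profile.expected_divergence(template)
        se = np.std(divergences, ddof=1) / math.sqrt(len(divergences))
        assert abs(np.mean(divergences) - expected) < 3 * se

    def test_deterministic_under_seed(self):
        template = "ACGTACGTAC" * 20
        a = ac.error_prone_background(template, 50, rng=np.random.default_rng(9))
        b = ac.error_prone_background(template, 50, rng=np.random.default_rng(9))
        assert a == b

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ValueError):
            ac.ErrorProneProfile(matrix=((0.5, 0.5, 0.0, 0.0),) * 4)


class TestBackgroundAccounting:
    def test_layout_yields_17_bytes_per_strand(self):
        assert ac.BackgroundAccounting().bytes_per_strand == 17

    def test_zero_strands_zero_gb(self):
        assert ac.background_gb(0) == 0.0

    def test_one_and_a_half_gb_inverts_to_strand_count(self):
        acct = ac.BackgroundAccounting()
        n = 1.5e9 * acct.redundancy / acct.bytes_per_strand
        assert ac.background_gb(n) == pytest.approx(1.5)
        assert n == pytest.approx(8.82e8, rel=1e-3)


class TestPrimerScreen:
    def test_ranking_is_sorted_by_tunability(self, screened_pair):
        import numpy as np
        from dnapreview import thermo as th

        rng = np.random.default_rng(55)
        cands = [th.design_random_primer(rng=rng) for _ in range(4)]
        ranked = ac.screen_primers_for_tunability(
            cands, ac.PCRCondition(60.0, 250.0), ac.PCRCondition(45.0, 250.0)
        )
        scores = [t for t, _ in ranked]
        assert scores == sorted(scores, reverse=True)
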