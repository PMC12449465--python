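"""PGS scoring, standardisation and the mixed-ancestry correction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ethnirisk import (
    ANCESTRIES,
    AncestryParams,
    AncestryProfile,
    NormalisedPgs,
    PgsModel,
    SnpEntry,
    alpha_by_proportionality,
    alpha_from_variance,
    classify_profile,
    compute_raw_pgs,
    mixed_sigma,
    mixed_z_alpha,
    normalise_single,
    partition_polygene,
    select_model_variant,
)
from ethnirisk.synthetic import make_toy_pgs_model, simulate_admixed_genotypes


def _uniform_model(weight: float = 1.0, freq: float = 0.5, n: int = 1) -> PgsModel:
    """Panel with identical frequency across ancestries (placeholder params)."""
    snps = [
        SnpEntry(f"1_{1000 + k}_A_G", "G", weight, {a: freq for a in ANCESTRIES})
        for k in range(n)
    ]
    params = {a: AncestryParams(0.0, 1.0, 0.5) for a in ANCESTRIES}
    return PgsModel(name="uniform", snps=snps, params_by_ancestry=params)


# ---------------------------------------------------------------------------
# raw scoring


class TestRawScore:
    def test_zero_dosages_score_zero(self, toy_model):
        dosages = {s.snp_id: 0.0 for s in toy_model.snps}
        assert compute_raw_pgs(dosages, toy_model) == 0.0

    def test_single_snp_linearity(self):
        model = _uniform_model(weight=0.1)
        assert compute_raw_pgs({model.snps[0].snp_id: 2.0}, model) == pytest.approx(0.2)

    def test_matches_termwise_summation(self, rng):
        model = make_toy_pgs_model(n_snps=50, seed=7)
        dosages = {s.snp_id: float(rng.integers(0, 3)) for s in model.snps}
        expected = 0.0
        for snp in model.snps:  # independent term-by-term oracle
            expected += snp.weight * dosages[snp.snp_id]
        assert compute_raw_pgs(dosages, model) == pytest.approx(expected, rel=1e-12)

    def test_missing_snps_imputed_at_expected_dosage(self, toy_model, half_profile):
        held_out = toy_model.snps[0]
        dosages = {s.snp_id: 1.0 for s in toy_model.snps[1:]}
        got = compute_raw_pgs(dosages, toy_model, half_profile)
        q_bar = 0.5 * (held_out.freq_by_ancestry["European"]
                       + held_out.freq_by_ancestry["African"])
        expected = sum(s.weight for s in toy_model.snps[1:]) + held_out.weight * 2 * q_bar
        assert got == pytest.approx(expected, rel=1e-12)

    def test_unknown_ids_warn_and_empty_errors(self, toy_model):
        dosages = {toy_model.snps[0].snp_id: 1.0, "not_a_snp": 2.0}
        with pytest.warns(UserWarning, match="not in model panel"):
            compute_raw_pgs(dosages, toy_model)
        with pytest.raises(ValueError):
            compute_raw_pgs({}, toy_model)
        with pytest.raises(ValueError, match="matches"):
            compute_raw_pgs({"nope": 1.0}, toy_model)


# ---------------------------------------------------------------------------
# single-ancestry standardisation


class TestNormaliseSingle:
    @pytest.mark.parametrize(
        "raw,ancestry,z,alpha",
        [
            (-0.335, "European", 0.0, 0.499),  # published European row
            (0.292, "African", 0.0, 0.196),  # published African row
        ],
    )
    def test_published_parameter_rows(self, table2_model, raw, ancestry, z, alpha):
        n = normalise_single(raw, ancestry, table2_model)
        assert n.z == pytest.approx(z, abs=1e-12)
        assert n.alpha == alpha

    @pytest.mark.parametrize("ancestry", ANCESTRIES)
    def test_one_sd_shift_gives_unit_z(self, table2_model, ancestry):
        par = table2_model.params(ancestry)
        n = normalise_single(par.mu + par.sd, ancestry, table2_model)
        assert n.z == pytest.approx(1.0, rel=1e-12)

    def test_unknown_ancestry_uses_european_parameters(self, table2_model):
        n = normalise_single(0.1, "Amerindian", table2_model)
        eur = normalise_single(0.1, "European", table2_model)
        assert (n.z, n.alpha) == (eur.z, eur.alpha)
        assert n.ancestry_mode == "single:European"

    def test_sample_moments_standardise(self, table2_model, rng):
        par = table2_model.params("SouthAsian")
        raws = rng.normal(par.mu, par.sd, 100_000)
        zs = (raws - par.mu) / par.sd
        assert abs(zs.mean()) < 0.02 and abs(zs.std() - 1.0) < 0.02
        # spot-check the function agrees with the vectorised expression
        i = 17
        assert normalise_single(raws[i], "SouthAsian", table2_model).z == pytest.approx(zs[i])


class TestClassifyProfile:
    @pytest.mark.parametrize(
        "props,expected",
        [
            ({"European": 0.85, "African": 0.15}, "European"),
            ({"SouthAsian": 0.72, "European": 0.28}, "SouthAsian"),
            ({"European": 0.5, "EastAsian": 0.5}, None),
            ({"African": 0.8, "European": 0.2}, "African"),
            ({"European": 0.79, "African": 0.21}, None),
            ({"SouthAsian": 0.7, "African": 0.3}, "SouthAsian"),
        ],
    )
    def test_thresholds(self, props, expected):
        assert classify_profile(AncestryProfile(props)) == expected

    def test_profile_validation(self):
        with pytest.raises(ValueError):
            AncestryProfile({"European": 0.6, "African": 0.5})
        with pytest.raises(ValueError):
            AncestryProfile({"European": 1.2, "African": -0.2})


# ---------------------------------------------------------------------------
# mixed-ancestry correction


class TestMixedSigma:
    @pytest.mark.parametrize("ancestry", ANCESTRIES)
    def test_single_ancestry_collapse_is_exact(self, toy_model, ancestry):
        sigma = mixed_sigma(AncestryProfile.single(ancestry), toy_model)
        assert sigma == pytest.approx(toy_model.params(ancestry).sd, rel=1e-15)

    def test_identical_frequencies_drop_cross_term(self):
        model = _uniform_model(weight=0.3, freq=0.4, n=5)
        profile = AncestryProfile({"European": 0.3, "African": 0.3, "EastAsian": 0.4})
        expected = math.sqrt(sum(0.3 * 1.0**2 for _ in range(2)) + 0.4 * 1.0**2)
        assert mixed_sigma(profile, model) == pytest.approx(expected, rel=1e-12)

    def test_matches_admixture_monte_carlo(self, toy_model, half_profile):
        n = 50_000
        dosages = simulate_admixed_genotypes(toy_model, half_profile, n, seed=11)
        raws = dosages @ toy_model.weights()
        analytic = mixed_sigma(half_profile, toy_model)
        se = analytic / math.sqrt(2 * n)
        assert abs(raws.std(ddof=1) - analytic) < 3 * se

    def test_missing_frequency_names_snp_and_ancestry(self, toy_model):
        snps = [SnpEntry("1_1_A_G", "G", 0.1, {"European": 0.5})]
        model = PgsModel("partial", snps, dict(toy_model.params_by_ancestry))
        with pytest.raises(KeyError, match="1_1_A_G.*African"):
            mixed_sigma(AncestryProfile({"European": 0.5, "African": 0.5}), model)


class TestMixedZAlpha:
    @pytest.mark.parametrize("ancestry", ANCESTRIES)
    def test_degenerate_profile_collapses_to_single(self, table2_model, ancestry):
        raw = 0.37
        single = normalise_single(raw, ancestry, table2_model)
        mixed = mixed_z_alpha(raw, AncestryProfile.single(ancestry), table2_model)
        assert mixed.z == pytest.approx(single.z, rel=1e-12)
        assert mixed.alpha == pytest.approx(single.alpha, rel=1e-12)

    def test_independent_formula_evaluation(self, toy_model, rng):
        for _ in range(25):
            p = rng.dirichlet(np.ones(4))
            profile = AncestryProfile(dict(zip(ANCESTRIES, map(float, p))))
            raw = float(rng.normal(0, 0.3))
            got = mixed_z_alpha(raw, profile, toy_model)
            # step-by-step re-evaluation, coded independently
            pars = [toy_model.params(a) for a in ANCESTRIES]
            z_i = [(raw - par.mu) / par.sd for par in pars]
            sigma = mixed_sigma(profile, toy_model)
            z = sum(pi * par.alpha * zi for pi, par, zi in zip(p, pars, z_i)) / (
                sigma * sum(pi * par.alpha / par.sd for pi, par in zip(p, pars))
            )
            alpha = sum(pi * par.alpha * par.sd for pi, par in zip(p, pars)) / sigma
            assert got.z == pytest.approx(z, rel=1e-12)
            assert got.alpha == pytest.approx(alpha, rel=1e-12)

    def test_half_european_african_alpha_attenuated(self, table2_model, half_profile):
        """Because the mixed sigma exceeds the P-weighted average of the
        ancestry sigmas, the corrected alpha falls strictly below the
        sigma-weighted average of the published European/African alphas."""
        mixed = mixed_z_alpha(0.0, half_profile, table2_model)
        sigma_weighted = (0.5 * 0.499 * 0.615 + 0.5 * 0.196 * 0.547) / (
            0.5 * 0.615 + 0.5 * 0.547
        )
        assert mixed.alpha < sigma_weighted
        assert mixed.ancestry_mode == "mixed"


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.lists(st.floats(0.01, 1.0), min_size=4, max_size=4))
def test_sigma_dominance_and_alpha_attenuation(raw_props):
    """Mixed sigma >= sqrt(sum P sigma_i^2) >= sum P sigma_i, and the mixed
    alpha never exceeds the P-weighted average of the single-ancestry
    alphas."""
    model = test_sigma_dominance_and_alpha_attenuation.model
    p = np.array(raw_props) / sum(raw_props)
    profile = AncestryProfile(dict(zip(ANCESTRIES, map(float, p))))
    sig = np.array([model.params(a).sd for a in ANCESTRIES])
    alph = np.array([model.params(a).alpha for a in ANCESTRIES])
    sigma = mixed_sigma(profile, model)
    assert sigma >= math.sqrt(p @ sig**2) - 1e-12
    assert math.sqrt(p @ sig**2) >= p @ sig - 1e-12
    assert mixed_z_alpha(0.2, profile, model).alpha <= p @ alph + 1e-12


test_sigma_dominance_and_alpha_attenuation.model = make_toy_pgs_model(10, seed=1)


# ---------------------------------------------------------------------------
# polygene partition and alpha derivation


class TestPartition:
    def test_published_alpha_residual_variance(self):
        part = partition_polygene(
            NormalisedPgs(z=0.0, alpha=0.499, sigma_used=0.615, ancestry_mode="single:European")
        )
        assert part.z_scaled == 0.0
        assert part.residual_variance == pytest.approx(1 - 0.499**2)

    def test_total_polygene_has_unit_variance(self, rng):
        alpha = 0.45
        z = rng.standard_normal(1_000_000)
        x_r = rng.normal(0.0, math.sqrt(1 - alpha**2), z.size)
        x_p = alpha * z + x_r
        assert x_p.var() == pytest.approx(1.0, abs=5e-3)

    def test_degenerate_alpha_rejected(self):
        with pytest.raises(ValueError):
            NormalisedPgs(z=1.0, alpha=0.0, sigma_used=1.0, ancestry_mode="mixed")


class TestAlphaDerivation:
    def test_single_snp_closed_form(self):
        model = _uniform_model(weight=1.0, freq=0.5)
        assert alpha_from_variance(model, "European", 1.0) == pytest.approx(math.sqrt(0.5))

    def test_null_weights_give_zero(self):
        model = _uniform_model(weight=0.0, freq=0.3, n=4)
        assert alpha_from_variance(model, "African", 1.0) == 0.0

    def test_matches_hwe_simulation(self, toy_model):
        sd_poly = 2.0
        n = 200_000
        dosages = simulate_admixed_genotypes(
            toy_model, AncestryProfile.single("EastAsian"), n, seed=5
        )
        emp_sd = (dosages @ toy_model.weights()).std(ddof=1)
        got = alpha_from_variance(toy_model, "EastAsian", sd_poly)
        se = (emp_sd / sd_poly) / math.sqrt(2 * n)
        assert abs(got - emp_sd / sd_poly) < 3 * se

    def test_inconsistent_polygenic_sd_rejected(self):
        model = _uniform_model(weight=1.0, freq=0.5)
        with pytest.raises(ValueError, match="alpha >= 1"):
            alpha_from_variance(model, "European", 0.1)

    @pytest.mark.parametrize(
        "alpha_ref,or_ref,or_target,expected",
        [
            (0.326, 1.5, 1.5, 0.326),
            (0.25, 1.4, 1.4**2, 0.50),
        ],
    )
    def test_proportionality_route(self, alpha_ref, or_ref, or_target, expected):
        got = alpha_by_proportionality(alpha_ref, or_ref, or_target)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_proportionality_averaged_targets(self):
        # averaging three target ORs then transferring == hand computation
        alpha_ref, or_ref = 0.326, 1.53
        targets = [1.32, 1.40, 1.27]
        mean_or = sum(targets) / 3
        got = alpha_by_proportionality(alpha_ref, or_ref, mean_or)
        assert got == pytest.approx(alpha_ref * math.log(mean_or) / math.log(or_ref))
        with pytest.raises(ValueError):
            alpha_by_proportionality(0.3, 1.0, 1.5)


class TestModelVariants:
    def _variants(self, toy_model):
        full = PgsModel("BC-309", toy_model.snps, dict(toy_model.params_by_ancestry))
        safe = PgsModel(
            "BC-307",
            toy_model.snps[:-2],
            {a: AncestryParams(-0.005, 0.613, 0.497) for a in ANCESTRIES},
            chek2_safe=True,
        )
        return [full, safe]

    def test_chek2_sequenced_selects_smaller_panel(self, toy_model):
        full, safe = self._variants(toy_model)
        chosen = select_model_variant([full, safe], chek2_sequenced=True)
        assert chosen.chek2_safe and chosen.n_snps == full.n_snps - 2
        assert select_model_variant([full, safe], chek2_sequenced=False) is full

    def test_variant_means_differ(self, table2_model, toy_model):
        _, safe = self._variants(toy_model)
        assert safe.params("European").mu != table2_model.params("European").mu

    def test_missing_variant_errors(self, toy_model):
        full, _ = self._variants(toy_model)
        with pytest.raises(LookupError):
            select_model_variant([full], chek2_sequenced=True)
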