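import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rrtsurvey.design import (
    DesignError,
    RandomizerDesign,
    Stratum,
    StudyDesign,
    default_true_params,
)
from rrtsurvey.simulate import (
    ANALYSIS_COLUMNS,
    TRUTH_ONLY_COLUMNS,
    HouseholdRecord,
    MaskedResponse,
    draw_randomizer,
    households_to_frame,
    simulate_households,
    simulate_responses,
)


def binom99(n, p):
    lo, hi = stats.binom.interval(0.99, n, p)
    return lo / n, hi / n


class TestDrawRandomizer:
    def test_empirical_fraction_within_binomial_band(self, rng):
        r = RandomizerDesign(6, 4)
        n = 100_000
        hits = sum(draw_randomizer(r, rng) == "sensitive" for _ in range(n))
        lo, hi = binom99(n, 2 / 3)
        assert lo <= hits / n <= hi

    def test_degenerate_always_sensitive(self, rng):
        r = RandomizerDesign(6, 6)
        assert all(draw_randomizer(r, rng) == "sensitive" for _ in range(50))

    def test_never_sensitive(self, rng):
        r = RandomizerDesign(6, 0)
        assert all(draw_randomizer(r, rng) == "nonsensitive" for _ in range(50))


class TestHouseholdRecord:
    def test_visits_exclusivity_enforced(self):
        with pytest.raises(DesignError, match="exactly one"):
            HouseholdRecord("h", "manaus", "urban", "single_sited", "dual_adult", 1, 2, 3, 4)
        with pytest.raises(DesignError, match="exactly one"):
            HouseholdRecord("h", "manaus", "urban", "single_sited", "dual_adult", 1, 2, None, None)

    def test_negative_counts_rejected(self):
        with pytest.raises(DesignError, match="n_minors"):
            HouseholdRecord("h", "manaus", "urban", "single_sited", "dual_adult", -1, 2, None, 4)


class TestMaskedResponse:
    def test_quantity_zero_iff_no_use(self):
        with pytest.raises(DesignError, match="quantity_category"):
            MaskedResponse("h", "chelonians:trade", "dry", use=1, quantity_category=0)
        with pytest.raises(DesignError, match="quantity_category"):
            MaskedResponse("h", "chelonians:trade", "dry", use=0, quantity_category=2)
        MaskedResponse("h", "chelonians:trade", "dry", use=1, quantity_category=2)


class TestSimulateHouseholds:
    def test_stratum_counts_exact(self, default_design, default_params):
        records = simulate_households(default_design, default_params, seed=5)
        counts = {}
        for r in records:
            counts[(r.municipality, r.urbanization)] = counts.get((r.municipality, r.urbanization), 0) + 1
        assert counts == {s.key: s.n_households for s in default_design.strata}
        assert sum(1 for r in records if r.municipality == "manaus") == 509

    def test_seed_determinism(self, default_design, default_params):
        a = simulate_households(default_design, default_params, seed=9)
        b = simulate_households(default_design, default_params, seed=9)
        assert a == b
        c = simulate_households(default_design, default_params, seed=10)
        assert a != c

    def test_seed_required(self, default_design, default_params):
        with pytest.raises(ValueError, match="seed"):
            simulate_households(default_design, default_params, seed=None)

    def test_multisited_fraction_near_19_percent(self, default_design, default_params):
        frames = [
            households_to_frame(simulate_households(default_design, default_params, seed=s))
            for s in range(6)
        ]
        df = pd.concat(frames)
        frac = (df["residence_status"] == "multisited").mean()
        lo, hi = binom99(len(df), 0.19)
        assert lo <= frac <= hi

    def test_visits_follow_urbanization(self, default_design, default_params):
        df = households_to_frame(simulate_households(default_design, default_params, seed=3))
        urban = df["urbanization"] == "urban"
        assert df.loc[urban, "visits_urban"].isna().all()
        assert df.loc[urban, "visits_rural"].notna().all()
        assert df.loc[~urban, "visits_urban"].notna().all()
        assert df.loc[~urban, "visits_rural"].isna().all()


def _uniform_cell_design(n, pi_s, pi_ns):
    design = StudyDesign(strata=(Stratum("manaus", "urban", n),))
    params = default_true_params(design)
    for key in list(params.pi_s):
        params.pi_s[key] = pi_s
    for dom in params.pi_ns:
        params.pi_ns[dom] = pi_ns
    return design, params


class TestSimulateResponses:
    def test_saturated_prevalences_force_use(self):
        design, params = _uniform_cell_design(40, 1.0, 1.0)
        hh = simulate_households(design, params, seed=1)
        truth, analysis = simulate_responses(hh, params, design, seed=2)
        assert (analysis["use"] == 1).all()
        assert (analysis["quantity_category"] >= 1).all()

    def test_mixture_identity_closed_form(self):
        # P(y=1) = p_s pi_s + (1-p_s) pi_ns = 2/3*0.6 + 1/3*0.3 = 0.5
        design, params = _uniform_cell_design(2500, 0.6, 0.3)
        hh = simulate_households(design, params, seed=11)
        _, analysis = simulate_responses(hh, params, design, seed=12)
        assert len(analysis) == 30_000
        lo, hi = binom99(len(analysis), 0.5)
        assert lo <= analysis["use"].mean() <= hi

    def test_dry_season_dominates_wet(self, tiny_design):
        params = default_true_params(tiny_design)
        for key in list(params.pi_s):
            params.pi_s[key] = 0.7 if key[3] == "dry" else 0.2
        big = StudyDesign(strata=(Stratum("manaus", "urban", 500),))
        params_big = default_true_params(big)
        for key in list(params_big.pi_s):
            params_big.pi_s[key] = 0.7 if key[3] == "dry" else 0.2
        for seed in range(3):
            hh = simulate_households(big, params_big, seed=seed)
            _, analysis = simulate_responses(hh, params_big, big, seed=seed + 100)
            by_season = analysis.groupby("season")["use"].mean()
            assert by_season["dry"] > by_season["wet"]
            assert len(analysis[analysis["season"] == "dry"]) >= 3000

    def test_truth_analysis_split(self, tiny_design):
        params = default_true_params(tiny_design)
        hh = simulate_households(tiny_design, params, seed=4)
        truth, analysis = simulate_responses(hh, params, tiny_design, seed=5)
        assert list(analysis.columns) == ANALYSIS_COLUMNS
        assert set(TRUTH_ONLY_COLUMNS) <= set(truth.columns)
        for col in TRUTH_ONLY_COLUMNS:
            assert col not in analysis.columns

    def test_observed_use_matches_latent_on_sensitive_rows(self, tiny_design):
        params = default_true_params(tiny_design)
        hh = simulate_households(tiny_design, params, seed=4)
        truth, _ = simulate_responses(hh, params, tiny_design, seed=5)
        sens = truth[truth["z"] == "sensitive"]
        assert (sens["use"] == sens["latent_use"]).all()

    def test_seed_contract_byte_identical(self, tiny_design):
        params = default_true_params(tiny_design)
        hh = simulate_households(tiny_design, params, seed=4)
        t1, a1 = simulate_responses(hh, params, tiny_design, seed=5)
        t2, a2 = simulate_responses(hh, params, tiny_design, seed=5)
        pd.testing.assert_frame_equal(t1, t2)
        pd.testing.assert_frame_equal(a1, a2)

    def test_unknown_stratum_rejected(self, tiny_design):
        params = default_true_params(tiny_design)
        hh = simulate_households(tiny_design, params, seed=4)
        alien = HouseholdRecord("HHX", "manaus", "urban", "single_sited", "dual_adult", 0, 1, None, 2)
        small = StudyDesign(strata=(Stratum("carauari", "rural", 5),))
        with pytest.raises(DesignError, match="absent from design"):
            simulate_responses([alien], default_true_params(small), small, seed=1)

    def test_row_count_is_households_by_domains_by_seasons(self, tiny_design):
        params = default_true_params(tiny_design)
        hh = simulate_households(tiny_design, params, seed=4)
        _, analysis = simulate_responses(hh, params, tiny_design, seed=5)
        assert len(analysis) == len(hh) * 6 * 2
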