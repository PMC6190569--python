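import math

import numpy as np
import pytest
from scipy import stats as sps

from rvpedsim import (
    DiseaseModel,
    EventKind,
    IndividualState,
    ReproductionModel,
    assign_birth_traits,
    draw_death_wait,
    draw_onset_wait,
    draw_repro_wait,
    simulate_life,
)

from conftest import constant_hazards


def make_state(age=0.0, affected=False, carrier=False, gamma=0.0, a1=20.0, a2=35.0, birth_year=1950):
    return IndividualState(
        age=age, affected=affected, carrier=carrier, birth_rate=gamma,
        repro_start=a1, repro_stop=a2, birth_year=birth_year,
    )


class _FixedExp:
    """Stub generator whose exponential() always returns mean * preset."""

    def __init__(self, unit_draw):
        self.unit_draw = unit_draw

    def exponential(self, scale=1.0):
        return self.unit_draw * scale


class TestBirthTraits:
    def test_gamma_moments_and_span_ranges(self, rng):
        model = ReproductionModel()
        draws = [assign_birth_traits(rng, model) for _ in range(100_000)]
        gammas = np.array([d[0] for d in draws])
        a1 = np.array([d[1] for d in draws])
        span = np.array([d[2] - d[1] for d in draws])
        n = gammas.size
        # Gamma(2, 4/3): mean 8/3, variance 32/9
        se_mean = math.sqrt(32 / 9 / n)
        assert gammas.mean() == pytest.approx(8 / 3, abs=3 * se_mean)
        assert gammas.var() == pytest.approx(32 / 9, rel=0.05)
        assert a1.min() >= 16 and a1.max() <= 27
        assert span.min() >= 10 and span.max() <= 18

    def test_reproducible_given_seed(self):
        model = ReproductionModel()
        t1 = assign_birth_traits(np.random.default_rng(7), model)
        t2 = assign_birth_traits(np.random.default_rng(7), model)
        assert t1 == t2


class TestOnsetWait:
    def test_matches_exponential_under_constant_hazard(self, rng):
        lam = 0.05
        hz = constant_hazards(onset=lam, max_age=10_000.0)
        dm = DiseaseModel.from_population(hz, kappa=1.0, carrier_prob=0.0)
        waits = [draw_onset_wait(make_state(), dm, hz, rng) for _ in range(10_000)]
        assert sps.kstest(waits, "expon", args=(0, 1 / lam)).pvalue > 0.01

    def test_carrier_median_scales_by_kappa(self, rng):
        lam, kappa = 0.02, 4.0
        hz = constant_hazards(onset=lam, max_age=10_000.0)
        dm = DiseaseModel.from_population(hz, kappa=kappa, carrier_prob=0.0)
        carrier = np.median(
            [draw_onset_wait(make_state(carrier=True), dm, hz, rng) for _ in range(10_000)]
        )
        noncar = np.median(
            [draw_onset_wait(make_state(), dm, hz, rng) for _ in range(10_000)]
        )
        assert carrier == pytest.approx(noncar / kappa, rel=0.1)
        assert carrier == pytest.approx(math.log(2) / (kappa * lam), rel=0.1)

    def test_zero_onset_hazard_never_strikes(self, rng):
        hz = constant_hazards(onset=0.0)
        dm = DiseaseModel.from_population(hz, kappa=1.0, carrier_prob=0.0)
        assert math.isinf(draw_onset_wait(make_state(), dm, hz, rng))

    def test_rejects_already_affected(self, rng):
        hz = constant_hazards(onset=0.01)
        dm = DiseaseModel.from_population(hz, kappa=1.0, carrier_prob=0.0)
        with pytest.raises(ValueError, match="affected"):
            draw_onset_wait(make_state(affected=True), dm, hz, rng)


class TestDeathWait:
    def test_matches_exponential_when_unaffected(self, rng):
        lam = 0.04
        hz = constant_hazards(death_u=lam, max_age=10_000.0)
        waits = [draw_death_wait(make_state(), hz, rng) for _ in range(10_000)]
        assert sps.kstest(waits, "expon", args=(0, 1 / lam)).pvalue > 0.01

    def test_affected_hazard_doubling_halves_mean_wait(self, rng):
        hz = constant_hazards(death_u=0.02, death_a=0.04, max_age=10_000.0)
        mean_u = np.mean([draw_death_wait(make_state(), hz, rng) for _ in range(10_000)])
        mean_a = np.mean(
            [draw_death_wait(make_state(affected=True), hz, rng) for _ in range(10_000)]
        )
        assert mean_a == pytest.approx(mean_u / 2, rel=0.1)

    def test_zero_hazard_dies_at_max_age(self, rng):
        hz = constant_hazards(max_age=100.0)
        assert draw_death_wait(make_state(age=37.5), hz, rng) == pytest.approx(62.5)


class TestReproWait:
    def test_past_reproductive_span_is_infinite(self):
        model = ReproductionModel()
        state = make_state(age=40.0, gamma=3.0)
        assert math.isinf(draw_repro_wait(state, model, _FixedExp(0.01)))

    def test_before_span_shifts_clock_to_span_start(self):
        # t'=0, a1=20, a2=35, drawn w=5 -> reproduction at age 25, wait 25
        model = ReproductionModel()
        gamma = 3.0
        state = make_state(age=0.0, gamma=gamma, a1=20.0, a2=35.0)
        unit = 5.0 * gamma / (35.0 - 20.0)  # so w = unit / rate = 5
        assert draw_repro_wait(state, model, _FixedExp(unit)) == pytest.approx(25.0)

    def test_within_span_returns_residual_wait(self):
        model = ReproductionModel()
        gamma = 3.0
        state = make_state(age=22.0, gamma=gamma, a1=20.0, a2=35.0)
        unit = 5.0 * gamma / 15.0
        assert draw_repro_wait(state, model, _FixedExp(unit)) == pytest.approx(5.0)

    def test_draw_overshooting_span_end_is_infinite(self):
        model = ReproductionModel()
        gamma = 3.0
        state = make_state(age=22.0, gamma=gamma, a1=20.0, a2=35.0)
        unit = 14.0 * gamma / 15.0  # 22 + 14 >= 35
        assert math.isinf(draw_repro_wait(state, model, _FixedExp(unit)))

    def test_onset_with_unit_rescale_leaves_rate_unchanged(self, rng):
        model = ReproductionModel(onset_scale=1.0)
        s_aff = make_state(age=25.0, affected=True, gamma=3.0)
        s_un = make_state(age=25.0, affected=False, gamma=3.0)
        w1 = draw_repro_wait(s_aff, model, np.random.default_rng(5))
        w2 = draw_repro_wait(s_un, model, np.random.default_rng(5))
        assert w1 == w2


class TestSimulateLife:
    def test_no_hazards_no_birth_rate_gives_single_censoring(self, rng):
        hz = constant_hazards()
        dm = DiseaseModel.from_population(hz, kappa=1.0, carrier_prob=0.0)
        events = simulate_life(
            make_state(gamma=0.0, birth_year=1950), dm, hz, ReproductionModel(), 2017, rng
        )
        assert [e.kind for e in events] == [EventKind.CENSORED]
        assert events[0].year == 2017

    def test_enormous_death_hazard_kills_in_infancy(self, rng):
        hz = constant_hazards(death_u=1e6)
        dm = DiseaseModel.from_population(hz, kappa=1.0, carrier_prob=0.0)
        events = simulate_life(
            make_state(gamma=5.0, birth_year=1950), dm, hz, ReproductionModel(), 2017, rng
        )
        assert [e.kind for e in events] == [EventKind.DEATH]
        assert events[0].age < 0.01

    def test_competing_exponentials_onset_fraction(self, rng):
        lam_on, lam_d = 0.02, 0.03
        hz = constant_hazards(onset=lam_on, death_u=lam_d, death_a=lam_d, max_age=10_000.0)
        dm = DiseaseModel.from_population(hz, kappa=1.0, carrier_prob=0.0)
        n = 10_000
        onset_first = 0
        for _ in range(n):
            events = simulate_life(
                make_state(gamma=0.0, birth_year=0), dm, hz, ReproductionModel(), 10**7, rng
            )
            if events[0].kind is EventKind.ONSET:
                onset_first += 1
        p = lam_on / (lam_on + lam_d)
        se = math.sqrt(p * (1 - p) / n)
        assert onset_first / n == pytest.approx(p, abs=3 * se)

    def test_event_ordering_invariants(self, synthetic_hazards, rng):
        dm = DiseaseModel.from_population(synthetic_hazards, kappa=10.0, carrier_prob=0.002)
        repro = ReproductionModel()
        for _ in range(200):
            gamma, a1, a2 = assign_birth_traits(rng, repro)
            events = simulate_life(
                make_state(gamma=gamma, a1=a1, a2=a2, carrier=True, birth_year=1940),
                dm, synthetic_hazards, repro, 2017, rng,
            )
            ages = [e.age for e in events]
            assert ages == sorted(ages)
            kinds = [e.kind for e in events]
            assert kinds.count(EventKind.ONSET) <= 1
            assert kinds.count(EventKind.DEATH) <= 1
            if EventKind.DEATH in kinds or EventKind.CENSORED in kinds:
                assert kinds[-1] in (EventKind.DEATH, EventKind.CENSORED)

    def test_offspring_counts_match_poisson_gamma_mixture(self, rng):
        """Event-by-event offspring counts for unaffected survivors match the
        negative binomial implied by mixing Poisson(gamma) over
        Gamma(2, 4/3), i.e. NB(size 2, success 1/(1 + 4/3))."""
        hz = constant_hazards()  # no onset, death at max age 100 > a2
        dm = DiseaseModel.from_population(hz, kappa=1.0, carrier_prob=0.0)
        repro = ReproductionModel()
        n = 20_000
        counts = np.empty(n, dtype=int)
        for i in range(n):
            gamma, a1, a2 = assign_birth_traits(rng, repro)
            events = simulate_life(
                make_state(gamma=gamma, a1=a1, a2=a2, birth_year=0),
                dm, hz, repro, 10**7, rng,
            )
            counts[i] = sum(e.kind is EventKind.REPRODUCTION for e in events)
        size, p = 2, 1 / (1 + 4 / 3)
        kmax = 10
        observed = np.bincount(np.minimum(counts, kmax), minlength=kmax + 1)
        pmf = sps.nbinom.pmf(np.arange(kmax), size, p)
        expected = np.append(pmf, 1 - pmf.sum()) * n
        chi2 = ((observed - expected) ** 2 / expected).sum()
        assert sps.chi2.sf(chi2, df=kmax) > 0.01
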