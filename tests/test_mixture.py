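"""Gaussian-mixture fitting of blockage amplitudes: EM, BIC order selection,
species labeling and soft-count frequencies."""

import numpy as np
import pytest

from poreqc import (
    EventTable,
    amplitude_histogram,
    fit_mixture,
    label_components,
    select_components,
    simulate_event_table,
    species_frequencies,
)
from poreqc.errors import InvalidParameterError

TRUE_MEANS = (60.0, 150.0, 300.0)
TRUE_SDS = (5.0, 9.0, 15.0)


def three_component_sample(rng, counts=(4320, 3600, 3600)):
    parts = [
        rng.normal(m, s, size=n) for m, s, n in zip(TRUE_MEANS, TRUE_SDS, counts)
    ]
    return np.concatenate(parts)


class TestFitMixture:
    def test_single_normal_recovery(self, rng):
        n, mu, sd = 5000, 150.0, 9.0
        x = rng.normal(mu, sd, size=n)
        fit = fit_mixture(x, 1, seed=0)
        c = fit.components[0]
        assert abs(c.mean_pA - mu) < 3 * sd / np.sqrt(n)
        assert abs(c.sd_pA - sd) < 3 * sd / np.sqrt(2 * n)
        assert c.weight == pytest.approx(1.0)

    def test_soft_counts_recover_separable_truth(self, rng):
        counts = (4320, 3600, 3600)
        fit = fit_mixture(three_component_sample(rng, counts), 3, seed=0)
        for comp, truth in zip(fit.components, counts):
            assert comp.soft_count == pytest.approx(truth, rel=0.05)

    def test_soft_count_conservation(self, rng):
        x = three_component_sample(rng)
        fit = fit_mixture(x, 3, seed=0)
        assert sum(c.soft_count for c in fit.components) == pytest.approx(
            len(x), abs=1e-6
        )
        assert sum(c.weight for c in fit.components) == pytest.approx(1.0, abs=1e-9)

    def test_deterministic_given_data_and_seed(self, rng):
        x = three_component_sample(rng, (500, 400, 400))
        f1 = fit_mixture(x, 3, seed=5)
        f2 = fit_mixture(x, 3, seed=5)
        assert f1.components == f2.components
        assert f1.log_likelihood == f2.log_likelihood
        assert np.array_equal(f1.responsibilities, f2.responsibilities)

    def test_bic_definition(self, rng):
        # BIC = -2 logL + p ln n with p = 3K - 1 free parameters in 1-D
        x = three_component_sample(rng, (500, 400, 400))
        fit = fit_mixture(x, 3, seed=0)
        p = 3 * 3 - 1
        assert fit.bic == pytest.approx(
            -2 * fit.log_likelihood + p * np.log(len(x)), rel=1e-9
        )

    def test_too_few_events_rejected(self, rng):
        with pytest.raises(InvalidParameterError):
            fit_mixture(rng.normal(100, 5, size=25), 3, seed=0)

    def test_parameter_recovery_across_seeds(self):
        # averaged over 20 seeds: means within 2%, weights within 3 points
        mean_err = np.zeros(3)
        weight_err = np.zeros(3)
        n_seeds = 20
        for seed in range(n_seeds):
            r = np.random.default_rng(1000 + seed)
            x = three_component_sample(r, (1200, 1000, 800))
            fit = fit_mixture(x, 3, seed=seed)
            got_means = np.array([c.mean_pA for c in fit.components])
            got_weights = np.array([c.weight for c in fit.components])
            mean_err += np.abs(got_means / np.array(TRUE_MEANS) - 1.0)
            weight_err += np.abs(got_weights - np.array([1200, 1000, 800]) / 3000.0)
        assert np.all(mean_err / n_seeds < 0.02)
        assert np.all(weight_err / n_seeds < 0.03)


class TestSelectComponents:
    def test_single_normal_selects_k1(self, rng):
        fit = select_components(rng.normal(150.0, 9.0, size=2000), k_max=4, seed=0)
        assert fit.n_components == 1

    def test_three_species_mock_selects_k3(self, rng):
        fit = select_components(three_component_sample(rng), k_max=4, seed=0)
        assert fit.n_components == 3

    def test_bic_picks_true_order_reliably(self):
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            r = np.random.default_rng(7000 + seed)
            x = three_component_sample(r, (1200, 1000, 1000))
            if select_components(x, k_max=4, seed=seed).n_components == 3:
                hits += 1
        assert hits >= 0.95 * n_seeds

    def test_plasma_like_two_species_gives_full_percent(self, rng):
        # a plasma-like sample with no gDNA: K=2 selected, gDNA soft count 0,
        # hence %cfDNA = 100
        x = np.concatenate([rng.normal(60, 5, 2500), rng.normal(150, 9, 2000)])
        fit = select_components(x, k_max=4, seed=0)
        assert fit.n_components == 2
        fit = label_components(fit, marker_amplitude_hint_pA=150.0)
        freqs = species_frequencies(fit, EventTable.from_events([], 1800.0))
        assert freqs.f_gdna == 0.0
        from poreqc import estimate_percent_target

        assert estimate_percent_target(freqs) == 100.0


class TestLabeling:
    def test_k3_order_rule(self, rng):
        fit = fit_mixture(three_component_sample(rng, (900, 800, 700)), 3, seed=0)
        fit = label_components(fit)
        labels = [c.species_label for c in fit.components]
        assert labels == ["target", "marker", "gdna"]

    def test_k2_with_hint(self, rng):
        x = np.concatenate([rng.normal(40, 4, 1500), rng.normal(118, 8, 1200)])
        fit = label_components(fit_mixture(x, 2, seed=0), marker_amplitude_hint_pA=120.0)
        labels = [c.species_label for c in fit.components]
        assert labels == ["target", "marker"]
        assert fit.soft_count("gdna") == 0.0

    def test_k1_without_hint_is_an_error(self, rng):
        fit = fit_mixture(rng.normal(100, 5, 1000), 1, seed=0)
        with pytest.raises(InvalidParameterError, match="hint"):
            label_components(fit)

    def test_surplus_components_left_unassigned(self, rng):
        x = three_component_sample(rng, (1500, 1200, 1200))
        fit = fit_mixture(x, 4, seed=0)
        with pytest.warns(UserWarning, match="unassigned"):
            fit = label_components(fit)
        labels = [c.species_label for c in fit.components]
        assert labels.count("unassigned") == 1
        for lab in ("target", "marker", "gdna"):
            assert labels.count(lab) == 1


class TestFrequencies:
    def test_frequency_arithmetic(self, rng):
        fit = label_components(fit_mixture(three_component_sample(rng), 3, seed=0))
        table = EventTable.from_events([], 1800.0)
        freqs = species_frequencies(fit, table)
        assert freqs.f_target == pytest.approx(fit.soft_count("target") / 1800.0)

    def test_unlabelled_fit_rejected(self, rng):
        fit = fit_mixture(three_component_sample(rng), 3, seed=0)
        with pytest.raises(InvalidParameterError):
            species_frequencies(fit, EventTable.from_events([], 1800.0))

    def test_end_to_end_frequency_ratio(self, mock_spec_factory):
        # 120/100/100 pM mock: f_target / f_marker within 5% of 1.2
        table = simulate_event_table(mock_spec_factory(duration_s=1800.0, seed=17))
        fit = label_components(fit_mixture(table.amplitudes(), 3, seed=0))
        freqs = species_frequencies(fit, table)
        assert freqs.f_target / freqs.f_marker == pytest.approx(1.2, rel=0.05)
        # conservation through soft counts
        total = (freqs.f_target + freqs.f_marker + freqs.f_gdna) * 1800.0
        assert total == pytest.approx(table.n_events, abs=1e-6)


def test_histogram_is_for_reporting_only(rng):
    x = rng.normal(100, 10, size=3000)
    hist = amplitude_histogram(x)
    assert hist.counts.sum() == 3000
    assert np.all(np.diff(hist.bin_edges) > 0)
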