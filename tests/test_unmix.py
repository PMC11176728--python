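"""Compound-normal proportion estimation against EM and ground truth."""

from __future__ import annotations

import numpy as np
import pytest

from _oracles import em_weights
from pollensize.errors import GateError, InvalidInputError, UnsupportedError
from pollensize.reference import components_for_metric, load_reference_table
from pollensize.sizestats import PooledSeries
from pollensize.synthetic import MixtureSampleSpec, sample_sizes
from pollensize.unmix import (
    FitConfig,
    MixtureSpec,
    SpeciesComponent,
    fit_proportions,
    mixture_pdf,
    objective,
    unmix_record,
)

NANA = SpeciesComponent("B. nana", 20.54, 0.92)
PUBESCENS = SpeciesComponent("B. pubescens", 25.46, 1.11)
PENDULA = SpeciesComponent("B. pendula", 22.41, 0.88)


def draw(proportions, n, seed, comps=(NANA, PUBESCENS)):
    spec = MixtureSampleSpec(list(comps), np.asarray(proportions, float), n, seed=seed)
    return sample_sizes(spec)[0]


class TestMixturePdf:
    def test_single_standard_normal_peak(self):
        spec = MixtureSpec([SpeciesComponent("x", 20.0, 1.0)], np.array([1.0]))
        assert mixture_pdf(20.0, spec) == pytest.approx(1 / np.sqrt(2 * np.pi))

    def test_linearity_of_symmetric_pair(self):
        a = SpeciesComponent("a", 18.0, 1.0)
        b = SpeciesComponent("b", 22.0, 1.0)
        mix = MixtureSpec([a, b], np.array([0.5, 0.5]))
        x = 20.0  # midpoint
        single = mixture_pdf(x, MixtureSpec([a], np.array([1.0])))
        assert mixture_pdf(x, mix) == pytest.approx(single)

    def test_normalization(self):
        spec = MixtureSpec([NANA, PUBESCENS, PENDULA], np.array([0.2, 0.5, 0.3]))
        grid = np.linspace(20.54 - 8 * 1.2, 25.46 + 8 * 1.2, 4001)
        assert np.trapezoid(np.asarray(mixture_pdf(grid, spec)), grid) == pytest.approx(
            1.0, abs=1e-3
        )

    def test_invalid_proportions_rejected(self):
        with pytest.raises(InvalidInputError):
            MixtureSpec([NANA], np.array([0.7]))
        with pytest.raises(InvalidInputError):
            MixtureSpec([NANA, PUBESCENS], np.array([1.2, -0.2]))


class TestObjective:
    def test_closed_form_at_component_mean(self):
        sigma = 0.92
        spec = MixtureSpec([NANA], np.array([1.0]))
        obs = np.full(10, 20.54)
        assert objective(obs, spec) == pytest.approx(-np.log(1 / (sigma * np.sqrt(2 * np.pi))))

    def test_duplication_invariance(self):
        obs = draw([0.4, 0.6], 200, seed=1)
        spec = MixtureSpec([NANA, PUBESCENS], np.array([0.4, 0.6]))
        assert objective(obs, spec) == pytest.approx(objective(np.tile(obs, 2), spec))

    def test_far_observation_floored_not_fatal(self):
        spec = MixtureSpec([NANA], np.array([1.0]))
        val = objective(np.array([20.54, 1e6]), spec)
        assert np.isfinite(val)

    def test_true_proportions_beat_degenerate_at_large_n(self):
        obs = draw([0.5, 0.5], 2000, seed=3)
        comps = [NANA, PUBESCENS]
        true = MixtureSpec(comps, np.array([0.5, 0.5]))
        degenerate = MixtureSpec(comps, np.array([1.0, 0.0]))
        assert objective(obs, true) < objective(obs, degenerate)

    def test_hist_l2_prefers_true_proportions(self):
        obs = draw([0.5, 0.5], 2000, seed=4)
        comps = [NANA, PUBESCENS]
        true = MixtureSpec(comps, np.array([0.5, 0.5]))
        degenerate = MixtureSpec(comps, np.array([1.0, 0.0]))
        assert objective(obs, true, "hist_l2") < objective(obs, degenerate, "hist_l2")


class TestFitProportions:
    def test_single_component_is_exact(self):
        obs = draw([1.0, 0.0], 100, seed=0)
        res = fit_proportions(obs, [NANA], FitConfig(seed=0))
        assert res.proportions.tolist() == [1.0]
        assert res.generations == 0

    def test_recovers_even_split_and_matches_em(self):
        obs = draw([0.5, 0.5], 1000, seed=5)
        res = fit_proportions(obs, [NANA, PUBESCENS], FitConfig(seed=5))
        assert res.proportions[0] == pytest.approx(0.5, abs=0.07)
        em = em_weights(obs, [20.54, 25.46], [0.92, 1.11])
        np.testing.assert_allclose(res.proportions, em, atol=0.01)

    def test_single_species_sample_fitted_with_three_components(self):
        obs = draw([1.0], 1000, seed=6, comps=(PUBESCENS,))
        comps = [NANA, PENDULA, PUBESCENS]
        res = fit_proportions(obs, comps, FitConfig(seed=6))
        assert res.proportions[2] >= 0.9
        em = em_weights(obs, [c.mu for c in comps], [c.sigma for c in comps])
        np.testing.assert_allclose(res.proportions, em, atol=0.01)

    def test_permuting_components_permutes_proportions_identically(self):
        obs = draw([0.3, 0.7], 600, seed=7)
        comps = [NANA, PENDULA, PUBESCENS]
        res = fit_proportions(obs, comps, FitConfig(seed=7))
        perm = [2, 0, 1]
        res_p = fit_proportions(obs, [comps[i] for i in perm], FitConfig(seed=7))
        np.testing.assert_array_equal(res_p.proportions, res.proportions[perm])

    def test_deterministic_for_fixed_seed(self):
        obs = draw([0.4, 0.6], 500, seed=8)
        a = fit_proportions(obs, [NANA, PUBESCENS], FitConfig(seed=11))
        b = fit_proportions(obs, [NANA, PUBESCENS], FitConfig(seed=11))
        np.testing.assert_array_equal(a.proportions, b.proportions)
        assert a.objective == b.objective

    def test_gate_names_threshold(self):
        with pytest.raises(GateError, match="25"):
            fit_proportions(np.full(10, 21.0), [NANA, PUBESCENS], FitConfig())

    def test_more_than_four_components_unsupported(self):
        comps = [SpeciesComponent(f"c{i}", 20.0 + i, 1.0) for i in range(5)]
        with pytest.raises(UnsupportedError):
            fit_proportions(np.full(100, 22.0), comps, FitConfig())

    def test_degenerate_observations_flagged(self):
        res = fit_proportions(np.full(30, 21.0), [NANA, PUBESCENS], FitConfig(seed=0))
        assert not res.converged

    def test_shared_shift_absorbs_swelling_offset(self):
        obs = draw([0.5, 0.5], 1500, seed=9) + 1.0
        cfg = FitConfig(seed=9, allow_shift=True)
        res = fit_proportions(obs, [NANA, PUBESCENS], cfg)
        assert res.shift == pytest.approx(1.0, abs=0.25)
        assert res.proportions[0] == pytest.approx(0.5, abs=0.08)


class TestUnmixRecord:
    def test_gradient_recovered_monotonically(self):
        dwarf_shares = [0.9, 0.5, 0.1]
        pooled = [
            PooledSeries(member_sample_ids=[f"s{i}"],
                         values=draw([p, 1 - p], 500, seed=20 + i))
            for i, p in enumerate(dwarf_shares)
        ]
        table = unmix_record(pooled, [NANA, PUBESCENS], FitConfig(seed=1))
        rec = table["p_B. nana"].to_numpy()
        assert np.all(np.diff(rec) < 0)
        np.testing.assert_allclose(rec, dwarf_shares, atol=0.1)

    def test_small_sample_flagged_without_proportions(self):
        pooled = [PooledSeries(member_sample_ids=["s0"], values=draw([0.5, 0.5], 10, seed=1))]
        table = unmix_record(pooled, [NANA, PUBESCENS], FitConfig(seed=0))
        assert table.loc[0, "reason"] == "below_min_count"
        assert np.isnan(table.loc[0, "p_B. nana"])

    def test_empty_record(self):
        assert unmix_record([], [NANA, PUBESCENS]).empty


def test_packaged_reference_builds_components():
    table = load_reference_table()
    comps = components_for_metric("mean_width", ["B. nana", "B. pendula", "B. pubescens"])
    assert [c.name for c in comps] == ["B. nana", "B. pendula", "B. pubescens"]
    assert comps[0].mu == 20.54 and comps[0].sigma == 0.92
    area = components_for_metric("area", table=table)
    assert len(area) == 4
    assert {c.name for c in area} == set(table[table.metric == "area"].species)
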