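"""Posterior densities and highest-posterior-density ranges.

The waterline HPD extraction is cross-checked against an independent
brute-force oracle that sorts grid cells by density and accumulates mass.
"""

import numpy as np
import pytest

from bayesage import (DegeneratePosteriorError, PosteriorDensity,
                      TransitionParams, density, hpdr, hpdr_frame, hpdr_table,
                      posterior)


def brute_force_hpd(post, coverage):
    """Independent oracle: sort cells by density, accumulate mass to coverage."""
    step = post.grid[1] - post.grid[0]
    weights = np.full_like(post.grid, step)
    weights[[0, -1]] = step / 2  # trapezoid point masses
    cell_mass = post.density * weights
    order = np.argsort(post.density)[::-1]
    cum = np.cumsum(cell_mass[order])
    k = int(np.searchsorted(cum, coverage)) + 1
    chosen = order[:k]
    return float(post.grid[chosen.min()]), float(post.grid[chosen.max()])


class TestPosterior:
    def test_normalized_for_all_phases_and_priors(self, reference_priors,
                                                  default_transition):
        for prior in reference_priors.values():
            for phase in range(1, 9):
                post = posterior(prior, default_transition, phase)
                assert post.mass() == pytest.approx(1.0, abs=1e-6)
                assert np.all(post.density >= 0)
                assert post.grid[0] == prior.age_offset

    def test_constant_likelihood_returns_prior(self, donated_prior):
        single = TransitionParams(tau=(), sigma=0.3)
        post = posterior(donated_prior, single, phase=1)
        prior_dens = density(donated_prior, post.grid)
        prior_dens = prior_dens / np.trapezoid(prior_dens, post.grid)
        assert np.allclose(post.density, prior_dens, atol=1e-12)

    def test_posterior_mean_nondecreasing_in_phase(self, donated_prior,
                                                   default_transition):
        means = [posterior(donated_prior, default_transition, j).mean()
                 for j in range(1, 9)]
        assert np.all(np.diff(means) > 0)

    def test_degenerate_phase_raises_named_error(self, donated_prior):
        # transitions far below the adult floor: phase 1 impossible at 18+
        trans = TransitionParams(tau=(np.log(5.0), np.log(8.0)), sigma=0.01)
        with pytest.raises(DegeneratePosteriorError, match="phase 1"):
            posterior(donated_prior, trans, phase=1)

    def test_bad_grid_arguments(self, donated_prior, default_transition):
        with pytest.raises(ValueError):
            posterior(donated_prior, default_transition, 1, age_max=10.0)
        with pytest.raises(ValueError):
            posterior(donated_prior, default_transition, 1, grid_step=0.0)


class TestHPDR:
    def test_matches_brute_force_oracle(self, reference_priors, default_transition):
        step = 0.01
        for prior in (reference_priors["donated"], reference_priors["us"]):
            for phase in (1, 4, 8):
                post = posterior(prior, default_transition, phase, grid_step=step)
                rng = hpdr(post, 0.90)
                lo, hi = brute_force_hpd(post, 0.90)
                assert abs(rng.lower - lo) <= step + 1e-9
                assert abs(rng.upper - hi) <= step + 1e-9
                assert rng.achieved_mass >= 0.90 - 1e-9

    def test_young_phase_starts_at_age_floor(self, reference_priors,
                                             default_transition):
        for prior in reference_priors.values():
            post = posterior(prior, default_transition, 1)
            rng = hpdr(post, 0.90)
            assert rng.lower == 18.0
            assert rng.lower_2dp == 18.00

    def test_coverage_to_one_approaches_support(self, donated_prior,
                                                default_transition):
        post = posterior(donated_prior, default_transition, 4)
        wide = hpdr(post, 0.999)
        narrow = hpdr(post, 0.90)
        assert wide.lower <= narrow.lower and wide.upper >= narrow.upper
        assert post.interval_mass(wide.lower, wide.upper) >= 0.999 - 1e-6

    def test_interval_mass_matches_achieved(self, donated_prior, default_transition):
        post = posterior(donated_prior, default_transition, 5)
        rng = hpdr(post, 0.90)
        assert post.interval_mass(rng.lower, rng.upper) == pytest.approx(
            rng.achieved_mass, abs=1e-9)

    def test_disconnected_region_flagged(self):
        # hand-built bimodal density: two separated bumps
        grid = np.arange(18.0, 100.0, 0.01)
        dens = (np.exp(-0.5 * ((grid - 30) / 2) ** 2)
                + np.exp(-0.5 * ((grid - 80) / 2) ** 2))
        dens /= np.trapezoid(dens, grid)
        post = PosteriorDensity(phase=1, grid=grid, density=dens)
        rng = hpdr(post, 0.90)
        assert rng.disconnected
        assert rng.lower < 35 and rng.upper > 75  # bounding interval spans both

    def test_invalid_coverage_rejected(self, donated_prior, default_transition):
        post = posterior(donated_prior, default_transition, 2)
        for cov in (0.0, 1.0, 1.5):
            with pytest.raises(ValueError):
                hpdr(post, cov)


class TestHPDRTable:
    def test_bounds_monotone_across_phases(self, reference_priors,
                                           default_transition):
        for prior in reference_priors.values():
            ranges = hpdr_table(prior, default_transition, 0.90)
            lowers = [r.lower for r in ranges]
            uppers = [r.upper for r in ranges]
            assert len(ranges) == 8
            assert np.all(np.diff(lowers) >= 0)
            assert np.all(np.diff(uppers) >= 0)

    def test_late_phases_wider_than_phase_one(self, donated_prior,
                                              default_transition):
        ranges = hpdr_table(donated_prior, default_transition, 0.90)
        w1 = ranges[0].upper - ranges[0].lower
        assert all(r.upper - r.lower > w1 for r in ranges[4:])

    def test_flatter_prior_raises_late_upper_bounds(self, reference_priors,
                                                    default_transition):
        # national prior has higher old-age survivorship than the collection
        donated = hpdr_table(reference_priors["donated"], default_transition)
        us = hpdr_table(reference_priors["us"], default_transition)
        for j in (5, 6, 7):
            assert us[j].upper > donated[j].upper
        # and phase-I upper for the narrower prior never exceeds the flatter one
        assert donated[0].upper <= us[0].upper

    def test_display_frame_rounds_to_two_decimals(self, donated_prior,
                                                  default_transition):
        ranges = hpdr_table(donated_prior, default_transition)
        df = hpdr_frame(ranges)
        assert list(df.columns) == ["phase", "lower", "upper", "coverage",
                                    "achieved_mass", "disconnected"]
        assert df["lower"].iloc[0] == 18.00
        assert (df["lower"].round(2) == df["lower"]).all()
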