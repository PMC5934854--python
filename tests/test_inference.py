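"""Particle filter, exact Kalman oracle, resampling, and imagery mode."""

import numpy as np
import pytest

from vestibinfer import (
    InternalModel,
    KnowledgeParams,
    KnowledgeSignal,
    ParticleEnsemble,
    TrajectoryProfile,
    VelocitySeries,
    WorldModel,
    exact_filter,
    generate_knowledge,
    generate_observations,
    generate_trajectory,
    make_time_grid,
    particle_filter,
    run_imagery,
    systematic_resample,
)


def _zero_knowledge(grid):
    return KnowledgeSignal(grid=grid, values=np.zeros(grid.n_steps))


class TestSystematicResample:
    def test_uniform_weights_keep_every_particle_once(self):
        ens = ParticleEnsemble(np.arange(8.0), np.full(8, 1 / 8))
        out = systematic_resample(ens, 0.37)
        np.testing.assert_array_equal(np.sort(out.velocities), np.arange(8.0))
        np.testing.assert_allclose(out.weights, 1 / 8)

    def test_degenerate_weight_copies_one_particle(self):
        ens = ParticleEnsemble(np.array([1.0, 2.0, 3.0]), np.array([0.0, 1.0, 0.0]))
        out = systematic_resample(ens, 0.99)
        np.testing.assert_array_equal(out.velocities, [2.0, 2.0, 2.0])

    def test_enumerated_offspring_counts_three_particles(self):
        # w = (1/2, 1/4, 1/4), N = 4: one stratified sweep gives counts
        # (2, 1, 1) for every possible draw u, by enumeration of the sweep
        ens = ParticleEnsemble(
            np.array([10.0, 20.0, 30.0, 40.0]), np.array([0.5, 0.25, 0.25, 0.0])
        )
        for u in np.linspace(0.0, 0.999999, 97):
            out = systematic_resample(ens, u)
            counts = [np.sum(out.velocities == v) for v in (10.0, 20.0, 30.0, 40.0)]
            assert counts == [2, 1, 1, 0]

    def test_offspring_counts_within_one_of_expectation(self, rng):
        # stratification guarantee |count_i - N w_i| < 1 for random weights
        n = 64
        w = rng.dirichlet(np.ones(n))
        ens = ParticleEnsemble(np.arange(float(n)), w)
        out = systematic_resample(ens, rng.uniform())
        counts = np.bincount(out.velocities.astype(int), minlength=n)
        assert np.all(np.abs(counts - n * w) < 1.0)

    def test_invalid_ensembles_rejected(self):
        with pytest.raises(ValueError):
            ParticleEnsemble(np.array([1.0, 2.0]), np.array([0.6, 0.6]))
        with pytest.raises(ValueError):
            ParticleEnsemble(np.array([1.0, 2.0]), np.array([1.5, -0.5]))
        with pytest.raises(ValueError):
            ParticleEnsemble(np.array([1.0]), np.array([1.0]))


class TestExactFilter:
    def test_conjugate_normal_posterior_sd(self):
        # static case: decay=1, no knowledge pull, sigma_q=0, flat-ish prior;
        # after n observations of sd sigma_v the posterior sd is sigma_v/sqrt(n)
        sigma_v = 5.0
        grid = make_time_grid(dt=0.01, total_time=0.99)  # 100 observations
        truth = VelocitySeries(grid, np.full(grid.n_steps, 42.0))
        obs = generate_observations(
            truth, WorldModel(sensor_mode="healthy", sensor_noise_sd=sigma_v), seed=1
        )
        model = InternalModel(
            decay=1.0,
            process_noise_sd=0.0,
            knowledge_weight=0.0,
            assumed_sensor_noise_sd=sigma_v,
            initial_mean=0.0,
            initial_sd=1e3 * sigma_v,
        )
        trace = exact_filter(obs, _zero_knowledge(grid), False, model)
        expected_sd = sigma_v / np.sqrt(grid.n_steps)
        assert trace.sd[-1] == pytest.approx(expected_sd, rel=0.01)
        # and the posterior mean is the running sample mean
        assert trace.mean[-1] == pytest.approx(np.mean(obs.values), rel=1e-6)

    def test_noiseless_sensor_limit_tracks_observations(self, grid, truth):
        obs = generate_observations(
            truth, WorldModel(sensor_noise_sd=3.0), seed=2
        )
        model = InternalModel(assumed_sensor_noise_sd=0.0)
        trace = exact_filter(obs, _zero_knowledge(grid), False, model)
        np.testing.assert_allclose(trace.mean, obs.values)
        np.testing.assert_allclose(trace.sd, 0.0, atol=1e-12)

    def test_uninformative_likelihood_keeps_prior_at_zero(self, grid, truth):
        obs = generate_observations(truth, WorldModel(sensor_noise_sd=10.0), seed=3)
        model = InternalModel(assumed_sensor_noise_sd=1e6 * 6.0)
        trace = exact_filter(obs, _zero_knowledge(grid), False, model)
        assert np.max(np.abs(trace.mean)) < 1e-3

    def test_posterior_sd_positive(self, grid, truth, internal):
        obs = generate_observations(truth, WorldModel(sensor_mode="bvp"), seed=4)
        trace = exact_filter(obs, _zero_knowledge(grid), False, internal)
        assert np.all(trace.sd > 0)

    def test_bvp_passive_mean_is_sign_symmetric_in_noise(self, grid, truth, internal):
        # deviation from zero is entirely noise-driven: negating the sensor
        # noise negates the whole mean trace
        obs = generate_observations(truth, WorldModel(sensor_mode="bvp"), seed=5)
        flipped = VelocitySeries(grid, -obs.values)
        t_pos = exact_filter(obs, _zero_knowledge(grid), False, internal)
        t_neg = exact_filter(flipped, _zero_knowledge(grid), False, internal)
        np.testing.assert_allclose(t_neg.mean, -t_pos.mean, atol=1e-10)


class TestParticleFilter:
    def test_near_noiseless_likelihood_tracks_observations(self, grid, truth):
        obs = generate_observations(truth, WorldModel(sensor_noise_sd=0.0), seed=6)
        model = InternalModel(assumed_sensor_noise_sd=0.01)
        trace = particle_filter(
            obs, _zero_knowledge(grid), False, model, n_particles=2000, seed=7
        )
        assert np.max(np.abs(trace.mean[3:] - obs.values[3:])) < 0.02

    def test_matches_exact_filter(self, grid, truth, defaults):
        # SMC consistency against the closed-form oracle
        from vestibinfer import ConditionSpec, make_condition

        world, internal, switch, kp = make_condition(
            ConditionSpec("healthy", "active"), defaults
        )
        obs = generate_observations(truth, world, seed=8)
        knowledge = generate_knowledge(truth, kp, switch, seed=9)
        exact = exact_filter(obs, knowledge, switch, internal)
        pf = particle_filter(
            obs, knowledge, switch, internal, n_particles=20000, seed=10
        )
        rmse = np.sqrt(np.mean((pf.mean - exact.mean) ** 2))
        assert rmse < 0.02 * 60.0

    def test_trace_diagnostics_well_formed(self, grid, truth, internal):
        obs = generate_observations(truth, WorldModel(), seed=11)
        n = 500
        trace = particle_filter(
            obs, _zero_knowledge(grid), False, internal, n_particles=n, seed=12
        )
        assert np.all(trace.ess > 0) and np.all(trace.ess <= n + 1e-9)
        assert np.all(trace.sd >= 0)
        assert trace.resampled.any()  # default threshold does trigger

    def test_same_seed_identical_trace(self, grid, truth, internal):
        obs = generate_observations(truth, WorldModel(), seed=13)
        kw = dict(n_particles=500, seed=14)
        a = particle_filter(obs, _zero_knowledge(grid), False, internal, **kw)
        b = particle_filter(obs, _zero_knowledge(grid), False, internal, **kw)
        np.testing.assert_array_equal(a.mean, b.mean)
        np.testing.assert_array_equal(a.sd, b.sd)
        np.testing.assert_array_equal(a.ess, b.ess)

    def test_mismatched_grids_rejected(self, grid, truth, internal):
        other = make_time_grid(dt=0.01, total_time=1.0)
        obs = generate_observations(truth, WorldModel(), seed=15)
        with pytest.raises(ValueError):
            particle_filter(
                obs, _zero_knowledge(other), False, internal, n_particles=500, seed=0
            )

    def test_too_few_particles_rejected(self, grid, truth, internal):
        obs = generate_observations(truth, WorldModel(), seed=16)
        with pytest.raises(ValueError):
            particle_filter(obs, _zero_knowledge(grid), False, internal,
                            n_particles=50, seed=0)


class TestImagery:
    def test_null_imagery_stays_at_zero(self, grid, internal):
        trace = run_imagery(_zero_knowledge(grid), internal)
        np.testing.assert_allclose(trace.mean, 0.0)

    def test_full_knowledge_pull_reproduces_signal(self, grid, truth):
        params = KnowledgeParams(knowledge_gain=1.0, knowledge_noise_sd=0.0)
        knowledge = generate_knowledge(truth, params, switch_active=True, seed=0)
        model = InternalModel(knowledge_weight=1.0)
        trace = run_imagery(knowledge, model)
        np.testing.assert_allclose(trace.mean[1:], knowledge.values[1:])
        assert trace.mean[0] == model.initial_mean

    def test_variance_grows_without_updates(self, grid):
        # var' = var + sigma_q^2 when decay=1 and knowledge_weight=0
        model = InternalModel(decay=1.0, knowledge_weight=0.0, process_noise_sd=2.0)
        trace = run_imagery(_zero_knowledge(grid), model)
        assert np.all(np.diff(trace.sd) >= 0)
        expected_var = model.initial_sd**2 + np.arange(grid.n_steps) * 4.0
        np.testing.assert_allclose(trace.sd, np.sqrt(expected_var))
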