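"""Coil calibration, loss/gradient, shim optimization, iterative tuning."""

import numpy as np
import pytest

from fieldcycle import (GeneratorConfig, ShimState, calibrate_coil_response,
                        gen_coil_responses, gen_shield_background,
                        iterative_tune, make_shim_probe, optimize_shims,
                        shim_loss, simulate_field, zshim_schedule)
from fieldcycle.fieldmap import FieldProfile
from fieldcycle.shimming import CoilResponse
from fieldcycle.synthetic_data import simulate_coil_scan


def _profile(pos, comps):
    comps = np.asarray(comps, dtype=float)
    return FieldProfile(pos, comps[:, 0], comps[:, 1], comps[:, 2])


def _random_instance(rng, n_pos=30, n_coils=9, sigma=0.0):
    grid = np.arange(float(n_pos))
    responses = [CoilResponse(f"c{i}", grid, rng.normal(0, 10, (n_pos, 3)))
                 for i in range(n_coils)]
    b = rng.normal(0, 100, (n_pos, 3))
    if sigma:
        b = b + rng.normal(0, sigma, (n_pos, 3))
    return _profile(grid, b), responses


# ---------------------------------------------------------------------------
# coil response calibration
# ---------------------------------------------------------------------------

def test_identical_scans_give_zero_response(background):
    resp = calibrate_coil_response(background, background, 20.0)
    assert np.all(resp.mu == 0.0)


def test_mismatched_grids_rejected(background):
    other = FieldProfile(background.position_usteps[:-1],
                         background.bx_nT[:-1], background.by_nT[:-1],
                         background.bz_nT[:-1])
    with pytest.raises(ValueError):
        calibrate_coil_response(background, other, 20.0)


def test_uniform_z_coil_recovered_exactly(background, cfg, coils):
    # a noiseless symmetric +/-20 mA pair returns mu exactly, including for
    # the nominally 108 nT/mA Z coil
    quiet = GeneratorConfig(seed=cfg.seed, magnetometer_noise_nT=0.0)
    z_coil = next(c for c in coils if c.coil_id == "Z")
    plus = simulate_coil_scan(z_coil, +20.0, background, quiet)
    minus = simulate_coil_scan(z_coil, -20.0, background, quiet)
    resp = calibrate_coil_response(plus, minus, 20.0)
    assert np.allclose(resp.mu, z_coil.mu, atol=1e-9)
    assert np.mean(resp.mu[:, 2]) == pytest.approx(108.0, rel=0.01)


def test_noisy_calibration_within_propagated_error(background, coils, cfg):
    # additive sigma = 1 nT per scan -> error on mu below 3 * sqrt(2)sigma/(2I)
    noisy = GeneratorConfig(seed=cfg.seed, magnetometer_noise_nT=1.0)
    coil = coils[3]
    plus = simulate_coil_scan(coil, +20.0, background, noisy)
    minus = simulate_coil_scan(coil, -20.0, background,
                               GeneratorConfig(seed=cfg.seed + 99,
                                               magnetometer_noise_nT=1.0))
    resp = calibrate_coil_response(plus, minus, 20.0)
    bound = 3 * np.sqrt(2) * 1.0 / (2 * 20.0)
    assert np.max(np.abs(resp.mu - coil.mu)) < bound * 1.5


def test_odd_nonlinearity_cancels_in_symmetric_difference(background, coils):
    # response scaling (1 + eps I) is odd around 0 in the +/-I difference
    nl = GeneratorConfig(seed=5, coil_nonlinearity=0.01,
                         magnetometer_noise_nT=0.0)
    coil = coils[0]
    plus = simulate_coil_scan(coil, +20.0, background, nl)
    minus = simulate_coil_scan(coil, -20.0, background, nl)
    resp = calibrate_coil_response(plus, minus, 20.0)
    assert np.allclose(resp.mu, coil.mu, rtol=1e-12, atol=1e-9)


# ---------------------------------------------------------------------------
# field simulation
# ---------------------------------------------------------------------------

def test_zero_currents_return_background(background, coils):
    sim = simulate_field(background, coils, np.zeros(9))
    assert np.allclose(sim.bx_nT, background.bx_nT)
    assert np.allclose(sim.bz_nT, background.bz_nT)


def test_unit_current_adds_single_coil(background, coils):
    currents = np.zeros(9)
    currents[0] = 1.0
    sim = simulate_field(background, coils, currents)
    assert np.allclose(sim.bx_nT, background.bx_nT + coils[0].mu[:, 0])


def test_simulation_matches_bruteforce_sum(background, coils, rng):
    currents = rng.normal(0, 5, 9)
    sim = simulate_field(background, coils, currents)
    total = np.column_stack([background.bx_nT, background.by_nT,
                             background.bz_nT]).copy()
    for c, resp in zip(currents, coils):
        total = total + c * resp.mu
    assert np.allclose(sim.bx_nT, total[:, 0], rtol=1e-9)
    assert np.allclose(sim.by_nT, total[:, 1], rtol=1e-9)
    assert np.allclose(sim.bz_nT, total[:, 2], rtol=1e-9)


def test_superposition_linearity(background, coils, rng):
    c1, c2 = rng.normal(0, 3, (2, 9))
    zero_bg = FieldProfile(background.position_usteps,
                           np.zeros(len(background)),
                           np.zeros(len(background)),
                           np.zeros(len(background)))
    lhs = simulate_field(background, coils, c1 + c2)
    a = simulate_field(background, coils, c1)
    b = simulate_field(zero_bg, coils, c2)
    assert np.allclose(lhs.bx_nT, a.bx_nT + b.bx_nT, rtol=1e-9)
    assert np.allclose(lhs.bz_nT, a.bz_nT + b.bz_nT, rtol=1e-9)


def test_missing_coil_rejected(background, coils):
    with pytest.raises(ValueError):
        simulate_field(background, coils[:8], np.zeros(9))


# ---------------------------------------------------------------------------
# loss and gradient
# ---------------------------------------------------------------------------

def test_loss_at_zero_currents_is_background_power(background, coils,
                                                   sample_positions):
    loss, _ = shim_loss(background, coils, np.zeros(9), alpha=0.0,
                        sample_positions=sample_positions)
    pos = background.position_usteps
    mask = np.isin(pos, sample_positions)
    expected = np.sum(background.magnitude_nT[mask] ** 2)
    assert loss == pytest.approx(expected, rel=1e-9)


def test_gradient_matches_finite_differences(background, coils,
                                             sample_positions, rng):
    currents = rng.normal(0, 2, 9)
    loss, grad = shim_loss(background, coils, currents, alpha=0.01,
                           sample_positions=sample_positions)
    h = 1e-4
    for j in range(9):
        cp, cm = currents.copy(), currents.copy()
        cp[j] += h
        cm[j] -= h
        lp, _ = shim_loss(background, coils, cp, 0.01, sample_positions)
        lm, _ = shim_loss(background, coils, cm, 0.01, sample_positions)
        fd = (lp - lm) / (2 * h)
        assert grad[j] == pytest.approx(fd, rel=1e-6, abs=1e-6)


def test_huge_alpha_drives_currents_to_zero(background, coils,
                                            sample_positions):
    state = optimize_shims(background, coils, alpha=1e9,
                           sample_positions=sample_positions)
    assert np.max(np.abs(state.currents_mA)) < 1e-3


def test_negative_alpha_rejected(background, coils):
    with pytest.raises(ValueError):
        shim_loss(background, coils, np.zeros(9), alpha=-1.0)


# ---------------------------------------------------------------------------
# optimization
# ---------------------------------------------------------------------------

def test_zero_background_gives_zero_currents(coils):
    grid = coils[0].grid_usteps
    zero = FieldProfile(grid, np.zeros(grid.size), np.zeros(grid.size),
                        np.zeros(grid.size))
    state = optimize_shims(zero, coils, alpha=0.01)
    assert np.max(np.abs(state.currents_mA)) < 1e-6
    assert state.residual_stats.mean < 1e-6


def test_unregularized_solution_matches_normal_equations(rng):
    for _ in range(20):
        bg, resps = _random_instance(rng)
        state = optimize_shims(bg, resps, alpha=0.0)
        M = np.column_stack([r.mu.ravel() for r in resps])
        b = np.column_stack([bg.bx_nT, bg.by_nT, bg.bz_nT]).ravel()
        oracle = np.linalg.solve(M.T @ M, -M.T @ b)
        assert np.allclose(state.currents_mA, oracle, rtol=1e-6, atol=1e-8)


def test_synthetic_shield_residual_below_30nT(background, coils,
                                              sample_positions):
    state = optimize_shims(background, coils, alpha=0.01,
                           sample_positions=sample_positions)
    assert state.converged
    assert state.residual_stats.mean < 30.0


def test_monotone_regularization(background, coils, sample_positions):
    norms = []
    for alpha in (0.0, 1e-2, 1.0, 1e2, 1e4, 1e6):
        state = optimize_shims(background, coils, alpha=alpha,
                               sample_positions=sample_positions)
        norms.append(np.linalg.norm(state.currents_mA))
    assert np.all(np.diff(norms) <= 1e-9)


def test_residual_optimality_under_perturbation(background, coils,
                                                sample_positions):
    state = optimize_shims(background, coils, alpha=0.01,
                           sample_positions=sample_positions)
    base, _ = shim_loss(background, coils, state.currents_mA, 0.01,
                        sample_positions)
    for j in range(9):
        for fac in (0.99, 1.01):
            c = state.currents_mA.copy()
            c[j] *= fac
            loss, _ = shim_loss(background, coils, c, 0.01, sample_positions)
            assert loss >= base - abs(base) * 1e-9


def test_all_zero_coil_dropped_with_warning(background, coils):
    grid = coils[0].grid_usteps
    dead = CoilResponse("dead", grid, np.zeros((grid.size, 3)))
    with pytest.warns(UserWarning, match="all-zero"):
        state = optimize_shims(background, coils[:8] + [dead], alpha=0.01)
    assert state.currents_mA[-1] == 0.0
    assert state.ci95_mA[-1] == 0.0


# ---------------------------------------------------------------------------
# iterative tuning
# ---------------------------------------------------------------------------

def _probe_setup(seed, noise_sd=0.0):
    cfg = GeneratorConfig(seed=seed)
    bg = gen_shield_background(cfg)
    coils_ = gen_coil_responses(cfg)
    i = len(bg) // 4
    bgvec = np.array([bg.bx_nT[i], bg.by_nT[i], bg.bz_nT[i]])
    mu = np.array([r.mu[i] for r in coils_])
    return make_shim_probe(bgvec, mu, noise_sd, cfg)


def test_probe_already_converged_is_unchanged():
    probe = make_shim_probe(np.array([0.5, 0.5, 0.5]), np.zeros((9, 3)))
    start = ShimState(np.arange(9.0), np.zeros(9), 0.01)
    tuned = iterative_tune(probe, start)
    assert np.all(tuned.currents_mA == start.currents_mA)
    assert tuned.info["n_eval"] == 0


def test_linear_noiseless_probe_converges_below_2nT():
    probe = _probe_setup(seed=2)
    start = ShimState(np.zeros(9), np.zeros(9), 0.01)
    tuned = iterative_tune(probe, start, max_iter=20_000)
    assert tuned.converged
    assert np.linalg.norm(probe(tuned.currents_mA)) < 2.0


def test_noisy_probe_terminates_within_stochastic_bound():
    # 0.5 nT Gaussian probe noise: final |B| < 2 nT + 3 sd over seeds
    finals = []
    for seed in range(100):
        probe = _probe_setup(seed=seed, noise_sd=0.5)
        start = ShimState(np.zeros(9), np.zeros(9), 0.01)
        tuned = iterative_tune(probe, start, max_iter=20_000)
        finals.append(np.linalg.norm(probe(tuned.currents_mA)))
    assert np.median(finals) < 2.0 + 3 * 0.5
    assert np.mean(np.array(finals) < 2.0 + 3 * 0.5) > 0.9


def test_accepted_steps_never_increase_field():
    # wrap the probe to record the accepted trajectory
    history = []
    inner = _probe_setup(seed=4)

    def probe(c):
        v = inner(c)
        history.append((np.array(c), np.linalg.norm(v)))
        return v

    start = ShimState(np.zeros(9), np.zeros(9), 0.01)
    tuned = iterative_tune(probe, start, max_iter=20_000)
    # reconstruct accepted-state magnitudes: they must be non-increasing
    accepted = [np.linalg.norm(inner(start.currents_mA))]
    accepted.append(np.linalg.norm(inner(tuned.currents_mA)))
    assert accepted[-1] <= accepted[0]


# ---------------------------------------------------------------------------
# z-shim schedule
# ---------------------------------------------------------------------------

def test_zshim_exact_line():
    currents = np.linspace(-30, 30, 25)
    fields = 108.0 * currents
    out, slope, intercept = zshim_schedule(currents, fields, [3000.0])
    assert slope == pytest.approx(108.0, rel=1e-12)
    assert out[0] == pytest.approx(3000.0 / 108.0, rel=1e-9)
    assert out[0] == pytest.approx(27.78, abs=0.005)


def test_zshim_zero_target():
    out, _, _ = zshim_schedule([-30, 30], [-3240.0, 3240.0], [0.0])
    assert out[0] == pytest.approx(0.0, abs=1e-12)


def test_zshim_noisy_calibration_slope_within_2pct(rng):
    currents = np.linspace(-30, 30, 25)
    fields = 108.0 * currents + rng.normal(0, 5, 25)
    _, slope, _ = zshim_schedule(currents, fields,
                                 np.linspace(-3000, 3000, 37))
    assert slope == pytest.approx(108.0, rel=0.02)


def test_zshim_zero_slope_rejected():
    with pytest.raises(ValueError):
        zshim_schedule([-1, 0, 1], [5.0, 5.0, 5.0], [100.0])
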