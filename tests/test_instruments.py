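import numpy as np
import pytest
from scipy import stats

from colloidstat.instruments import (
    InstrumentConfig,
    Track,
    diameter_from_diffusion,
    estimate_from_tracks,
    simulate_dls,
    simulate_nta,
    simulate_tracks,
    stokes_einstein,
)
from colloidstat.synthetic import ParticlePopulation, make_population


def monodisperse(d_nm, n, conc_per_ml):
    return ParticlePopulation(
        np.full(n, float(d_nm)), suspension_volume_ml=n / conc_per_ml
    )


def test_stokes_einstein_value_and_round_trip():
    d_coef = stokes_einstein(100.0, 298.15, 8.9e-4)
    assert d_coef == pytest.approx(4.91e-12, rel=5e-3)
    assert diameter_from_diffusion(d_coef) == pytest.approx(100.0, rel=1e-12)
    assert stokes_einstein(200.0) == pytest.approx(d_coef / 2.0, rel=1e-12)
    with pytest.raises(ValueError):
        stokes_einstein(-1.0)


def test_step_variance_matches_brownian_scaling():
    cfg = InstrumentConfig(seed=1, track_length_mean=200.0, n_frames_observed=20000)
    pop = monodisperse(100.0, 1000, 2e9)
    tracks = simulate_tracks(pop, cfg)
    steps = np.concatenate([t.dx for t in tracks] + [t.dy for t in tracks])
    assert steps.size > 1e5
    expected = 2.0 * stokes_einstein(100.0) * cfg.frame_interval
    assert np.var(steps) == pytest.approx(expected, rel=0.05)


def test_zero_concentration_yields_no_tracks():
    pop = ParticlePopulation(np.array([]), suspension_volume_ml=1.0)
    cfg = InstrumentConfig(seed=2)
    assert simulate_tracks(pop, cfg) == []


def test_tracks_deterministic_given_seed():
    pop = monodisperse(150.0, 500, 5e8)
    a = simulate_tracks(pop, InstrumentConfig(seed=3))
    b = simulate_tracks(pop, InstrumentConfig(seed=3))
    assert len(a) == len(b)
    assert all(np.array_equal(x.dx, y.dx) for x, y in zip(a, b))


def test_single_planted_track_closed_form():
    """Constant-step track: the MSD estimator reduces to a closed form."""
    cfg = InstrumentConfig(seed=0, min_track_length=10, n_frames_observed=20)
    step = 1e-6  # metres per frame, both axes
    track = Track(dx=np.full(20, step), dy=np.full(20, step))
    res = estimate_from_tracks([track], cfg)
    d_hat = 2.0 * step**2 / (4.0 * cfg.frame_interval)
    assert res.estimated_diameters[0] == pytest.approx(
        diameter_from_diffusion(d_hat), rel=1e-12
    )


def test_nta_recovers_monodisperse_size_and_concentration():
    """~1500 tracks of 30 frames on a 100 nm sample: median size within 5%,
    and the counting error calibrated — the measured concentration falls in
    the 95% Poisson interval of truth at close to the nominal rate."""
    truth = 9.4e11
    pop = monodisperse(100.0, 4000, truth)
    lam_frames = (
        truth / 200.0 * InstrumentConfig().sampling_volume_ml * 128
    )  # expected particle-frames
    lo, hi = stats.poisson.interval(0.95, lam_frames)
    covered = 0
    n_seeds = 40
    for seed in range(n_seeds):
        cfg = InstrumentConfig(seed=seed, dilution_factor=200.0,
                               n_frames_observed=128)
        res = simulate_nta(pop, cfg)
        assert 1000 < res.n_tracks < 4000
        assert np.median(res.estimated_diameters) == pytest.approx(100.0, rel=0.05)
        measured_frames = (
            res.particles_per_ml
            / cfg.dilution_factor
            * cfg.sampling_volume_ml
            * cfg.n_frames_observed
        )
        covered += lo <= measured_frames <= hi
    # binomial(40, 0.95) puts >= 34 successes at > 99.9% probability
    assert covered >= 34


def test_concentration_estimator_unbiased_over_seeds():
    truth = 2e11
    pop = monodisperse(150.0, 2000, truth)
    estimates = []
    for seed in range(50):
        cfg = InstrumentConfig(seed=seed, dilution_factor=200.0, n_frames_observed=60)
        estimates.append(simulate_nta(pop, cfg).particles_per_ml)
    mean = np.mean(estimates)
    se = np.std(estimates, ddof=1) / np.sqrt(len(estimates))
    assert abs(mean - truth) <= 2 * se


def test_short_tracks_filtered_for_sizing():
    cfg = InstrumentConfig(seed=0, min_track_length=10, n_frames_observed=10)
    short = Track(dx=np.ones(3) * 1e-7, dy=np.ones(3) * 1e-7)
    with pytest.raises(ValueError):
        estimate_from_tracks([short], cfg)


def test_dls_monodisperse_and_noise():
    pop = monodisperse(100.0, 100, 1e11)
    cfg = InstrumentConfig(seed=5)
    z, pdi = simulate_dls(pop, cfg, noise_sd=0.0)
    assert (z, pdi) == (pytest.approx(100.0), pytest.approx(0.0, abs=1e-12))
    zs = []
    for seed in range(100):
        rng = np.random.default_rng(seed)
        zs.append(simulate_dls(pop, cfg, noise_sd=0.01, rng=rng)[0])
    assert np.mean(zs) == pytest.approx(100.0, rel=0.005)


def test_bimodal_population_dls_exceeds_nta_mean():
    """Intensity weighting drags DLS upward relative to the number-weighted
    NTA mean whenever a heavy tail is present (569 vs 301 nm style contrast)."""
    pop = make_population(
        6000, [(150.0, 1.2, 0.85), (600.0, 1.2, 0.15)], seed=6,
        suspension_volume_ml=6000 / 5e11,
    )
    cfg = InstrumentConfig(seed=7, dilution_factor=200.0, n_frames_observed=128)
    nta = simulate_nta(pop, cfg)
    z, _ = simulate_dls(pop, cfg)
    assert z > nta.mean_size
    assert z > np.mean(pop.diameters)
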