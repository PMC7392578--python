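import numpy as np
import pytest

import foveometrics as fm


@pytest.fixture(scope="session")
def asym_truth():
    """Asymmetric generating truth, continuous at the pit bottom
    (baseline + para - pit identical on both sides)."""
    return fm.ProfileTruth(
        baseline_height=200.0,
        nasal=fm.SideTruth(pit_amplitude=120.0, pit_sigma=400.0,
                           para_amplitude=-20.0, para_sigma=1500.0),
        temporal=fm.SideTruth(pit_amplitude=100.0, pit_sigma=350.0,
                              para_amplitude=-40.0, para_sigma=1300.0),
        noise_sd=0.0,
        n_points=500,
        lateral_extent=10000.0,
        seed=0,
    )


@pytest.fixture(scope="session")
def sym_truth():
    return fm.ProfileTruth(noise_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def noiseless_fit(asym_truth):
    prof = fm.gen_ilm_profile(asym_truth)
    return fm.DoGModel(prof).fit()


@pytest.fixture(scope="session")
def small_geometry():
    """Compact raster for image tests (keeps rendering and tracing cheap)."""
    return fm.ScanGeometry(n_cols=200, n_rows=256, lateral_um_per_px=50.0,
                           axial_depth_um=2000.0, bruch_row=200.0)


@pytest.fixture(scope="session")
def default_cohort():
    table, truth = fm.gen_cohort(fm.CohortSpec(n_infants=80, seed=1))
    return table, truth


def random_fits(n, seed=0):
    """Random well-separated DoG parameter draws for oracle comparisons."""
    rng = np.random.default_rng(seed)
    fits = []
    for _ in range(n):
        sides = {}
        for s in fm.SIDES:
            s_pit = rng.uniform(200, 600)
            sides[s] = fm.DoGSideParams(
                a_pit=rng.uniform(50, 200),
                sigma_pit=s_pit,
                a_para=rng.uniform(-80, 80),
                sigma_para=rng.uniform(3.0 * s_pit, 3000),
            )
        fits.append(fm.DoGFit(
            baseline=rng.uniform(150, 300), sides=sides,
            rss={s: 0.0 for s in fm.SIDES}, converged=True,
            n_points={s: 0 for s in fm.SIDES},
        ))
    return fits
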