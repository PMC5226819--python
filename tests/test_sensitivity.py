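"""Per-cell sensitivity fields and their rank-coupling structure."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from cawave import StimulusParams, build_dense_grid
from cawave.sensitivity import (NoiseLevels, Region, central_block,
                                field_deterministic, field_homogeneous,
                                field_random, field_random_with_center,
                                scaled_stimulus)


def test_homogeneous_field(grid_5x5):
    f = field_homogeneous(grid_5x5, StimulusParams(60.0, 1.8, 0.9))
    assert f.n_cells == 25
    assert np.all(f.t1 == 60.0) and np.all(f.i_ip3_max == 1.8)
    f2 = field_homogeneous(grid_5x5, StimulusParams(60.0, 1.8, 0.9))
    assert np.array_equal(f.i_jinf_max, f2.i_jinf_max)
    # degenerate deterministic field with no regions is identical
    f3 = field_deterministic(grid_5x5, StimulusParams(60.0, 1.8, 0.9), [])
    assert np.array_equal(f.t1, f3.t1)


def test_deterministic_regions(grid_25x25):
    i0, j0 = central_block(25, 25, 3, 3)
    center = Region(i0, j0, 3, 3, StimulusParams(72.0, 2.16, 1.08))
    with pytest.warns(UserWarning):  # this triple breaks rank pairing
        f = field_deterministic(grid_25x25, StimulusParams(), [center])
    assert int(np.sum(f.t1 != 60.0)) == 9
    assert int(np.sum(f.i_ip3_max == 2.16)) == 9


def test_overlapping_regions_rejected(grid_25x25):
    a = Region(4, 4, 3, 3, StimulusParams(50, 2.16, 1.08))
    b = Region(5, 5, 3, 3, StimulusParams(50, 2.16, 1.08))
    with pytest.raises(ValueError, match="overlap"):
        field_deterministic(grid_25x25, StimulusParams(), [a, b])
    out = Region(24, 24, 3, 3, StimulusParams(50, 2.16, 1.08))
    with pytest.raises(ValueError, match="outside"):
        field_deterministic(grid_25x25, StimulusParams(), [out])


def test_scaled_stimulus_ratio_convention():
    s = scaled_stimulus(StimulusParams(60.0, 1.8, 0.9), 1.2)
    assert (s.t1, s.i_ip3_max, s.i_jinf_max) == (50.0, pytest.approx(2.16),
                                                 pytest.approx(1.08))


def test_random_field_exact_rank_coupling(grid_25x25):
    f = field_random(grid_25x25, StimulusParams(), NoiseLevels.named("high"),
                     seed=5)
    rho_jinf = spearmanr(f.i_ip3_max, f.i_jinf_max).statistic
    rho_t1 = spearmanr(f.i_ip3_max, f.t1).statistic
    assert rho_jinf == pytest.approx(1.0, abs=1e-12)
    assert rho_t1 == pytest.approx(-1.0, abs=1e-12)
    # equivalently: sorting by one parameter sorts the others (oracle)
    order = np.argsort(f.i_ip3_max)
    assert np.all(np.diff(f.i_jinf_max[order]) > 0)
    assert np.all(np.diff(f.t1[order]) < 0)


def test_random_field_marginals_and_reproducibility():
    g = build_dense_grid(100, 100)
    f = field_random(g, StimulusParams(60.0, 1.8, 0.9),
                     NoiseLevels(0.6, 0.04, 10.0), seed=9)
    assert f.i_ip3_max.mean() == pytest.approx(1.8, abs=3 * 0.6 / 100)
    assert f.i_ip3_max.std() == pytest.approx(0.6, rel=0.06)
    assert f.t1.std() == pytest.approx(10.0, rel=0.06)
    f2 = field_random(g, StimulusParams(60.0, 1.8, 0.9),
                      NoiseLevels(0.6, 0.04, 10.0), seed=9)
    assert np.array_equal(f.t1, f2.t1)


def test_random_field_positivity_with_rank_preserved():
    """Noise sd comparable to the mean forces sub-floor draws; they are
    remapped to small positive values without creating rank ties."""
    g = build_dense_grid(60, 60)
    f = field_random(g, StimulusParams(60.0, 1.8, 0.108),
                     NoiseLevels.named("high"), seed=3)
    assert np.all(f.i_jinf_max > 0)
    assert f.meta.get("clipped_jinf", 0) > 0
    assert spearmanr(f.i_ip3_max, f.i_jinf_max).statistic == pytest.approx(1.0)


def test_central_zone_field(grid_25x25):
    f = field_random_with_center(
        grid_25x25, StimulusParams(60.0, 1.8, 0.6), NoiseLevels.named("low"),
        StimulusParams(60.0, 2.6, 0.7), NoiseLevels(0.01, 0.001, 0.0),
        (3, 3), seed=4)
    i0, j0 = central_block(25, 25, 3, 3)
    zone = {(i, j) for i in range(i0, i0 + 3) for j in range(j0, j0 + 3)}
    in_zone = np.array([v in zone for v in f.nodes])
    assert in_zone.sum() == 9
    assert f.i_ip3_max[in_zone].mean() == pytest.approx(2.6, abs=0.02)
    assert f.i_ip3_max[~in_zone].mean() == pytest.approx(1.8, abs=0.15)
    # central onset leads the network: mean t1 set to the minimal background t1
    assert np.all(f.t1[in_zone] == f.t1[~in_zone].min())


def test_central_zone_degenerate_noise_matches_deterministic(grid_25x25):
    f = field_random_with_center(
        grid_25x25, StimulusParams(60.0, 1.8, 0.6), NoiseLevels(0, 0, 0),
        StimulusParams(55.0, 2.6, 0.7), NoiseLevels(0, 0, 0),
        (3, 3), seed=0, center_t1=55.0)
    i0, j0 = central_block(25, 25, 3, 3)
    det = field_deterministic(
        grid_25x25, StimulusParams(60.0, 1.8, 0.6),
        [Region(i0, j0, 3, 3, StimulusParams(55.0, 2.6, 0.7))])
    assert np.allclose(f.t1, det.t1)
    assert np.allclose(f.i_ip3_max, det.i_ip3_max)
    assert np.allclose(f.i_jinf_max, det.i_jinf_max)


def test_noise_level_names():
    assert NoiseLevels.named("moderate") == NoiseLevels(0.4, 0.025, 10.0)
    with pytest.raises(ValueError):
        NoiseLevels.named("extreme")
    with pytest.raises(ValueError):
        NoiseLevels(-0.1, 0.0, 0.0)
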