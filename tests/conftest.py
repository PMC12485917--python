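import numpy as np
import pytest

from hicstats import (ContactMatrix, Genome, build_bin_table,
                      expected_contact_map, sample_contact_map, test_genome)
from hicstats.compartments import CompartmentTrack
from hicstats.simulate import SimParams


@pytest.fixture(scope="session")
def small_genome():
    """Three chromosomes (12/10/8 Mb) plus a mito contig; fast but non-trivial."""
    Mb = 1_000_000
    return Genome(("chrA", "chrB", "chrC", "chrM"),
                  (12 * Mb, 10 * Mb, 8 * Mb, 16_600),
                  (5 * Mb, 4 * Mb, 3 * Mb, None),
                  (False, False, False, True))


@pytest.fixture(scope="session")
def small_bins(small_genome):
    return build_bin_table(small_genome, 250_000, 1_000_000)


@pytest.fixture(scope="session")
def desk_genome():
    return test_genome()


@pytest.fixture(scope="session")
def desk_bins(desk_genome):
    return build_bin_table(desk_genome, 250_000, 1_000_000)


@pytest.fixture(scope="session")
def alternating_track(desk_bins):
    """Planted hard A/B labels in alternating 2 Mb domains."""
    ev = np.where((desk_bins.start // 2_000_000) % 2 == 0, 1.0, -1.0)
    ev[desk_bins.is_mito_bin] = 0.0
    return CompartmentTrack(desk_bins, ev)


def checkerboard_params(**kw):
    """Symmetric compartment model with no other structure."""
    base = dict(alpha1=1.0, alpha2=1.0, c_AA=2.0, c_BB=2.0, c_AB=1.0,
                t_AA=1.0, t_BB=1.0, t_AB=1.0, boundaries=[],
                w_tel=1.0, w_cen=1.0, lambda_mito=0.0, f_cis=0.7)
    base.update(kw)
    return SimParams(**base)


def as_matrix(bt, expected, scale=1e7):
    """Wrap a noise-free expected map as an (identity-balanced) ContactMatrix."""
    return ContactMatrix(bt, expected * scale, weights=np.ones(bt.n_bins))


@pytest.fixture(scope="session")
def checkerboard_matrix(desk_bins, alternating_track):
    E = expected_contact_map(desk_bins, alternating_track, checkerboard_params())
    return as_matrix(desk_bins, E)


@pytest.fixture(scope="session")
def sampled_checkerboard(desk_bins, alternating_track):
    """One balanced multinomial sample of the checkerboard model."""
    from hicstats import ic_balance, mask_low_coverage
    E = expected_contact_map(desk_bins, alternating_track, checkerboard_params())
    m = sample_contact_map(desk_bins, E, 2_000_000, seed=123)
    return ic_balance(mask_low_coverage(m))
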