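"""Shared synthetic scenes for the test suite.

Everything is generated at run time from the simulator; the default scene
is the desk-scale 64x64x8 grid with 8 coils used throughout, with a
smaller 32x32x4 scene for cheap unit tests.
"""

import numpy as np
import pytest

from refill import synthsim as ss


class Scene:
    """A simulated world: object, coils, metadata and a static field."""

    def __init__(self, grid=(64, 64, 8), n_coils=8, seed=1,
                 phi_g_flash=0.02, phi_g_epi=0.03):
        self.grid = grid
        self.obj = ss.layered_phantom(grid)
        self.sens, self.theta0 = ss.make_coil_sensitivities(
            grid, n_coils, seed=seed)
        self.meta_flash = ss.default_flash_meta()
        self.meta_epi = ss.default_epi_meta()
        self.phi_g_flash = phi_g_flash
        self.phi_g_epi = phi_g_epi
        # smooth field within +/- 2*pi*40 rad/s, near-zero median
        self.fieldspec = ss.FieldSpec(
            uniform=2 * np.pi * 5,
            linear=(2 * np.pi * 10, 2 * np.pi * 20, 0.0),
            quadratic=(2 * np.pi * 10, -2 * np.pi * 12, 0.0),
            blobs=(((0.3, 0.2, 0.0), 0.3, 2 * np.pi * 10),),
        )
        self.field = ss.static_field(grid, self.fieldspec)
        self.support = self.obj > 0.05

    def flash_reference(self, field=None, noise_sd=0.0, seed=0):
        return ss.simulate_flash_reference(
            self.obj, self.sens, self.field if field is None else field,
            self.meta_flash, phi_g_flash=self.phi_g_flash,
            noise_sd=noise_sd, seed=seed)

    def timeseries(self, n_volumes, fieldspec=None, noise_sd=0.0, seed=0):
        return ss.simulate_timeseries(
            self.obj, self.sens, fieldspec or self.fieldspec, self.meta_epi,
            n_volumes, phi_g_epi=self.phi_g_epi, noise_sd=noise_sd, seed=seed)

    def pair_series(self, field):
        """Reversed + regular EPI pair for a given static field, plus the
        true distorted-space field of the regular volume."""
        from refill.datamodel_io import CoilStack
        rev = ss.simulate_epi_volume(self.obj, self.sens, field,
                                     self.meta_epi, phi_g_epi=self.phi_g_epi,
                                     readout_polarity=-1)
        reg, field_d, vsm = ss.simulate_epi_volume(
            self.obj, self.sens, field, self.meta_epi,
            phi_g_epi=self.phi_g_epi, readout_polarity=1, return_truth=True)
        series = CoilStack(
            np.stack([rev.magnitude, reg.magnitude], axis=-1),
            np.stack([rev.phase, reg.phase], axis=-1), self.meta_epi, "time")
        return series, field_d, vsm


@pytest.fixture(scope="session")
def scene():
    return Scene()


@pytest.fixture(scope="session")
def small_scene():
    return Scene(grid=(32, 32, 4), n_coils=4, seed=3)


@pytest.fixture(scope="session")
def reference(scene):
    return scene.flash_reference()


@pytest.fixture(scope="session")
def offsets(scene, reference):
    from refill import compute_phase_offsets, estimate_theta_g_flash
    return compute_phase_offsets(reference, estimate_theta_g_flash(reference))


@pytest.fixture(scope="session")
def offsets_small(small_scene):
    """True offsets of the small scene, as a PhaseOffsetMap."""
    from refill.datamodel_io import PhaseOffsetMap
    return PhaseOffsetMap(small_scene.theta0)
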