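"""Shared fixtures: study-condition phantoms, cohorts and templates.

Heavy objects (the 20-control cohort and its normative templates) are
session-scoped so the whole suite builds them once.  Study conditions:
64 mm head phantoms at 1 mm isotropic spacing, noise SD = 2% of the WM
mean, 2% multiplicative geometric jitter across controls.
"""

import numpy as np
import pytest

import fcdkit as fk

NOISE_SD = 0.02 * 130.0   # 2% of the WM mean intensity
COHORT_SEED = 11
PATIENT_SEED = 999
LESION_RADIUS_MM = 8.0
BLUR_RAMP_MM = 4.0
THICKENING_MM = 3.0


def study_spec(seed):
    return fk.PhantomSpec(noise_sd=NOISE_SD, seed=seed)


@pytest.fixture(scope="session")
def control_cohort():
    return fk.make_cohort(20, study_spec(COHORT_SEED), jitter=0.02)


@pytest.fixture(scope="session")
def junction_template(control_cohort):
    return fk.build_cohort_template(control_cohort, "junction",
                                    fk.RunConfig(modality="junction"))


@pytest.fixture(scope="session")
def thickness_template(control_cohort):
    return fk.build_cohort_template(control_cohort, "thickness",
                                    fk.RunConfig(modality="thickness"))


@pytest.fixture(scope="session")
def blur_patient():
    """A patient phantom with a planted blurred-junction lesion."""
    base = fk.make_head_phantom(study_spec(PATIENT_SEED))
    center = base.gm_wm_boundary_point()
    lesioned, mask = fk.insert_fcd_lesion(
        base, fk.LesionSpec(center_mm=center, radius_mm=LESION_RADIUS_MM,
                            kind="junction_blur", blur_ramp_mm=BLUR_RAMP_MM))
    return lesioned, mask


@pytest.fixture(scope="session")
def thick_patient():
    """A patient phantom with a planted focal-thickening lesion."""
    base = fk.make_head_phantom(study_spec(PATIENT_SEED))
    center = base.gm_wm_boundary_point()
    lesioned, mask = fk.insert_fcd_lesion(
        base, fk.LesionSpec(center_mm=center, radius_mm=LESION_RADIUS_MM,
                            kind="thickening", thickening_mm=THICKENING_MM))
    return lesioned, mask


@pytest.fixture(scope="session")
def aged_cohort():
    """n=30 controls, ages 6-12 y, planted 0.05 mm/yr thickness slope."""
    ages = np.linspace(6.0, 12.0, 30)
    cohort = fk.make_cohort(30, fk.PhantomSpec(seed=21), jitter=0.02,
                            ages=ages, age_thickness_slope=0.05)
    return cohort, ages


@pytest.fixture(scope="session")
def aged_thickness_template(aged_cohort):
    cohort, ages = aged_cohort
    maps = [fk.thickness_map(p.labels) for p in cohort]
    return fk.build_template(maps, ages=ages), cohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def quick_volume(rng, shape=(16, 16, 16), spacing=(1.0, 1.0, 1.0)):
    return fk.Volume3D(data=rng.standard_normal(shape), spacing=spacing)
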