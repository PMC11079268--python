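import numpy as np
import pytest

from plaquemech.contours import circular_contours
from plaquemech.materials import MATERIAL_LIBRARY
from plaquemech.synthetic import (ImagingSpec, VesselSpec,
                                  generate_vessel_geometry, render_oct_phantom)


@pytest.fixture(scope="session")
def ring():
    """Concentric circular three-layer vessel (1.5/1.75/2.0/2.4 mm)."""
    return circular_contours()


@pytest.fixture(scope="session")
def materials():
    return MATERIAL_LIBRARY


@pytest.fixture(scope="session")
def wavy_vessel():
    """An irregular vessel with one lipid pool (ground-truth generator spec)."""
    from plaquemech.synthetic import ComponentSpec
    spec = VesselSpec(
        fourier_perturbation=(((2, 0.06, 0.3),), ((3, 0.05, 1.0),),
                              ((2, 0.04, 2.0),), ((2, 0.05, 0.5),)),
        components=(ComponentSpec("lipid", (np.deg2rad(60), np.deg2rad(120)),
                                  (0.2, 0.8), cap_thickness=0.1),),
    )
    return generate_vessel_geometry(spec)


@pytest.fixture(scope="session")
def wavy_wall():
    """Irregular vessel wall without plaque components (detection phantoms)."""
    spec = VesselSpec(
        fourier_perturbation=(((2, 0.06, 0.3),), ((3, 0.05, 1.0),),
                              ((2, 0.04, 2.0),), ((2, 0.05, 0.5),)),
    )
    return generate_vessel_geometry(spec)


@pytest.fixture(scope="session")
def clean_phantom(wavy_wall):
    """Noiseless phantom without shadow, plus its ground truth."""
    image, truth = render_oct_phantom(wavy_wall, ImagingSpec())
    return image, truth
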