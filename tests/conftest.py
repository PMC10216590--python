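import numpy as np
import pytest

from omlit.materials import MaterialLibrary, OpticalConstants, default_library


@pytest.fixture(scope="session")
def default_lib() -> MaterialLibrary:
    return default_library()


def flat_material(material_id: str, n: float, k: float = 0.0) -> OpticalConstants:
    """Dispersionless material covering the whole visible range."""
    return OpticalConstants(
        material_id,
        np.array([300.0, 800.0]),
        np.array([n, n]),
        np.array([k, k]),
        provenance="synthetic test material",
    )


@pytest.fixture(scope="session")
def synthetic_lib() -> MaterialLibrary:
    """Dispersionless library for closed-form optics checks."""
    return MaterialLibrary(
        [
            flat_material("air", 1.0, 0.0),
            flat_material("glass", 1.5, 0.0),
            flat_material("arc", 1.5**0.5, 0.0),  # quarter-wave AR index for air/glass
            flat_material("metal", 2.0, 3.0),
            flat_material("absorber", 1.7, 0.4),
            flat_material("highindex", 2.3, 0.0),
        ]
    )
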