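from pathlib import Path

import numpy as np
import pytest

from metalloscope import synthetic_scene as ss
from metalloscope import xrf_quant as xq

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def tubulin_fasta() -> Path:
    return DATA_DIR / "synthetic_tubulin_dimer.fasta"


@pytest.fixture(scope="session")
def default_scene() -> ss.SyntheticScene:
    return ss.generate_scene(ss.SceneConfig(seed=1))


@pytest.fixture(scope="session")
def noisy_atom_maps(default_scene) -> dict[str, np.ndarray]:
    """Noisy element maps for the default scene, in atoms/nm²."""
    maps = ss.render_element_maps(default_scene, noise=True)
    return {el: xq.areal_density_to_atoms(m) for el, m in maps.items()}
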