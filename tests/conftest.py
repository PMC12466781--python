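import numpy as np
import pytest

from somacount import (
    RenderSpec,
    SyntheticAtlasSpec,
    Volume3D,
    make_toy_atlas,
    render_illumination_pair,
    sample_ground_truth_cells,
)


@pytest.fixture(scope="session")
def toy_atlas():
    """Five-region cuboid atlas on a 48^3 grid with 3 composites / 2 majors."""
    spec = SyntheticAtlasSpec(
        grid_shape=(48, 48, 48),
        regions={
            1: (4, 20, 4, 20, 4, 22),
            2: (4, 20, 4, 20, 26, 44),
            3: (26, 44, 4, 20, 4, 22),
            4: (26, 44, 4, 20, 26, 44),
            5: (4, 20, 26, 44, 4, 44),
        },
        composites={101: [1, 2], 102: [3, 4], 103: [5]},
        majors={201: [101, 102], 202: [103]},
    )
    return make_toy_atlas(spec)


@pytest.fixture(scope="session")
def rendered_pair(toy_atlas):
    """Noiseless, attenuation-free dual-illumination pair with known cells."""
    labelmap, _ = toy_atlas
    counts = {1: 4, 2: 4, 3: 3, 4: 3, 5: 5}
    cells = sample_ground_truth_cells(
        labelmap, counts, radius_range=(2.0, 2.5), min_separation=8.0, seed=11
    )
    left, right = render_illumination_pair(
        cells, labelmap, RenderSpec(background_level=100.0), seed=11, animal_id="demo"
    )
    return cells, counts, left, right


def two_cube_volume():
    """Two disjoint 3x3x3 cubes at intensity 100 on zero background."""
    vox = np.zeros((16, 16, 16), dtype=np.uint16)
    vox[2:5, 2:5, 2:5] = 100
    vox[9:12, 9:12, 9:12] = 100
    return Volume3D(voxels=vox, animal_id="cubes")
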