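import numpy as np
import pytest

import spinedyn as sd


@pytest.fixture(scope="session")
def clean_scene():
    """Default 4-session scene with one gain and one loss per interval."""
    return sd.make_scene(seed=11)


@pytest.fixture(scope="session")
def clean_stack(clean_scene):
    return sd.render_session(clean_scene, "BL", sd.NoiseModel.clean())


@pytest.fixture(scope="session")
def clean_backbone(clean_scene, clean_stack):
    poly = clean_scene.backbone_polyline()
    return sd.trace_backbone(clean_stack, [poly[0], poly[-1]])


@pytest.fixture(scope="session")
def demo_clean():
    """One full noise-free pipeline run shared across tests."""
    return sd.run_demo(seed=5, config=sd.PipelineConfig(seed=5, noise="clean"))


def straight_tube_scene(radius_um=0.5, shape=(96, 64, 15)):
    """Straight dendrite along x, centred on a voxel row, no spines."""
    nx, ny, nz = shape
    y0 = (ny // 2) * 0.18
    z0 = float(nz // 2)
    return sd.GroundTruthScene(
        backbone_control_points=((1.5, y0, z0), (nx * 0.18 - 1.5, y0, z0)),
        backbone_radius_um=radius_um,
        sessions=("BL",),
        spines=(),
        stack_shape_vox=shape,
        seed=0,
    )


@pytest.fixture(scope="session")
def tube_scene():
    return straight_tube_scene()


@pytest.fixture(scope="session")
def tube_stack(tube_scene):
    return sd.render_session(tube_scene, "BL", sd.NoiseModel.clean())
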