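"""Shared fixtures: verification bar, small vertebra phantom, one solved case.

The expensive objects (meshes, the reference follower-load solve) are
session-scoped so every test module reuses them.
"""

import numpy as np
import pytest

import vertefem as vf
from vertefem.calibration import CalibrationLine, hu_to_density


@pytest.fixture(scope="session")
def bar():
    """10 mm tall, 4x4 mm uniform bar at 1 mm voxels: the analytic test case."""
    vol = vf.make_bar_phantom(10.0, 4.0, 1000.0, 1.0)
    rho = hu_to_density(vol, CalibrationLine())
    mesh = vf.voxels_to_tets(vol, rho)
    vf.label_surfaces(mesh)
    cards = vf.assign_materials(mesh.element_density)
    return {
        "volume": vol,
        "mesh": mesh,
        "cards": cards,
        "E": float(cards.E[0]),
        "sigma_y": float(cards.sigma_y[0]),
        "area": 16.0,
        "length": 10.0,
    }


@pytest.fixture(scope="session")
def vertebra():
    """Coarse (2 mm voxel) vertebral phantom with frame and materials."""
    spec = vf.PhantomSpec(height=18.0, semi_axis_ap=14.0, semi_axis_ml=11.0, voxel=2.0, seed=1)
    vol = vf.make_vertebra_phantom(spec)
    rho = hu_to_density(vol, CalibrationLine())
    mesh = vf.voxels_to_tets(vol, rho)
    vf.label_surfaces(mesh)
    frame = vf.build_frame(mesh)
    cards = vf.assign_materials(mesh.element_density)
    return {"spec": spec, "volume": vol, "density": rho, "mesh": mesh, "frame": frame, "cards": cards}


@pytest.fixture(scope="session")
def vertebra_solution(vertebra):
    """Follower-load solve of the vertebra phantom, compressed well past yield."""
    lc = vf.place_control_point(
        vertebra["frame"], vertebra["mesh"], total_displacement=0.9, n_increments=10
    )
    rec = vf.solve_quasistatic(vertebra["mesh"], vertebra["cards"], lc, record_fields=False)
    assert rec.converged
    return {"loadcase": lc, "record": rec, **vertebra}
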