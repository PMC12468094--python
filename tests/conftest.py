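import warnings

import numpy as np
import pytest

from cxlsim.constitutive import MaterialParams
from cxlsim.fields import weakening_field
from cxlsim.meshing import build_mesh, build_spherical_shell
from cxlsim.metrics import detect_cone, tangential_curvature
from cxlsim.solver import KrylovSolver, SolveConfig, find_stress_free
from cxlsim.synthetic import CorneaSpec, generate_cornea


@pytest.fixture(scope="session")
def kc_spec():
    return CorneaSpec()


@pytest.fixture(scope="session")
def kc_grid(kc_spec):
    return generate_cornea(kc_spec)


@pytest.fixture(scope="session")
def avg_spec():
    """Average cornea of the study population: no cone, central thickness 545 µm."""
    return CorneaSpec(cone_amplitude=0.0, cone_thinning=0.0)


@pytest.fixture(scope="session")
def avg_grid(avg_spec):
    return generate_cornea(avg_spec)


@pytest.fixture(scope="session")
def params():
    return MaterialParams()


@pytest.fixture(scope="session")
def coarse_mesh(kc_grid):
    return build_mesh(kc_grid, layers=3, edge_central=1.2, edge_peripheral=1.6)


@pytest.fixture(scope="session")
def avg_mesh(avg_grid):
    return build_mesh(avg_grid, layers=3, edge_central=1.0, edge_peripheral=1.4)


@pytest.fixture(scope="session")
def thin_shell():
    return build_spherical_shell(radius=7.7, thickness=0.55, subdiv=1, layers=2)


@pytest.fixture(scope="session")
def prestress_state(kc_grid, coarse_mesh, params):
    """Shared stress-free recovery of the default KC cornea at 15 mm Hg."""
    cmap = tangential_curvature(kc_grid.anterior_points())
    cone = detect_cone(cmap)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        weak = weakening_field(cone, 0.429)
    cfg = SolveConfig(iop_mmhg=15.0)
    linsolver = KrylovSolver()
    pres = find_stress_free(
        coarse_mesh, lambda m: m.material_field(params, weakening=weak),
        cfg, tol_um=1.0, max_iter=25, linsolver=linsolver)
    return {"cone": cone, "weak": weak, "config": cfg, "pres": pres,
            "linsolver": linsolver, "mesh": coarse_mesh}
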