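import numpy as np
import pytest

from ectplan.phantom import default_tissue_table
from ectplan.electrodes import rasterize
from ectplan.solver import SolverConfig, solve_schedule
from ectplan.fixtures import toy_slab_fixture, two_needle_fixture


@pytest.fixture(scope="session")
def tissue_table():
    return default_tissue_table()


@pytest.fixture(scope="session")
def toy_case(tissue_table):
    """Two-needle slab with a small central tumor, solved once (2 mm grid)."""
    phantom, array, schedule = toy_slab_fixture(spacing=2.0)
    masks = rasterize(array, phantom, min_radius=0.75 * float(np.max(phantom.spacing)))
    solutions = solve_schedule(
        phantom, tissue_table, array, schedule, SolverConfig(), electrode_masks=masks
    )
    return {
        "phantom": phantom,
        "array": array,
        "schedule": schedule,
        "masks": masks,
        "solutions": solutions,
    }


@pytest.fixture(scope="session")
def two_needle_coarse(tissue_table):
    """Two parallel needles in homogeneous tissue at 1 mm, linear solve."""
    from ectplan.solver import solve_pair

    phantom, array = two_needle_fixture(spacing=1.0)
    masks = rasterize(array, phantom)
    solution = solve_pair(
        phantom, tissue_table, masks, (1, 2), 1000.0,
        SolverConfig(electroporation=False), array=array,
    )
    return {"phantom": phantom, "array": array, "masks": masks, "solution": solution}
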