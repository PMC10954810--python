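import logging

import numpy as np
import pytest

from resprout import (
    ChangeLabel,
    Cylinder,
    QSM,
    generate_table_top_tree,
    recompute_branch_structure,
)

logging.getLogger("resprout").setLevel(logging.ERROR)


def make_chain(n=3, axis=(0.0, 0.0, 1.0), length=1.0, radius=0.05):
    """A straight chain of n cylinders with consistent topology."""
    axis = np.asarray(axis, float)
    cyls = []
    start = np.zeros(3)
    for i in range(n):
        cyls.append(
            Cylinder(
                cylinder_id=i + 1,
                parent_id=None if i == 0 else i,
                extension_id=None if i == n - 1 else i + 2,
                start=start.copy(),
                axis=axis.copy(),
                length=length,
                radius=radius,
                branch_id=0,
                position_in_branch=i + 1,
                branch_order=0,
            )
        )
        start = start + length * axis
    return QSM(tree_id="chain", scan_year="t1", cylinders=cyls)


@pytest.fixture(scope="session")
def default_scenario():
    """One synthetic tree under the default study conditions."""
    return generate_table_top_tree(seed=0)


@pytest.fixture
def chain3():
    return make_chain(3)
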