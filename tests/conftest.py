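import numpy as np
import pandas as pd
import pytest

from flybrain.regions import Region, RegionSet


def make_synapse_table(
    pre=None, post=None, pre_xyz=None, score=None, neuropil=None,
    nt_type=None, nt_prob=None, record_id=None,
):
    """Small synapse-table builder for hand-constructed cases."""
    n = len(pre)
    pre_xyz = np.asarray(pre_xyz if pre_xyz is not None else np.zeros((n, 3)), dtype=np.int64)
    return pd.DataFrame(
        {
            "record_id": record_id if record_id is not None else np.arange(1, n + 1),
            "pre_root_id": pre,
            "post_root_id": post,
            "pre_x": pre_xyz[:, 0],
            "pre_y": pre_xyz[:, 1],
            "pre_z": pre_xyz[:, 2],
            "post_x": pre_xyz[:, 0] + 100,
            "post_y": pre_xyz[:, 1],
            "post_z": pre_xyz[:, 2],
            "score": score if score is not None else np.full(n, 200),
            "neuropil": neuropil if neuropil is not None else [""] * n,
            "nt_type": nt_type if nt_type is not None else [""] * n,
            "nt_prob": nt_prob if nt_prob is not None else [np.nan] * n,
        }
    )


@pytest.fixture
def toy_regions():
    """Two left/right pairs plus one centre box, 10 um cubes, 4 um gaps."""
    s = 10_000
    regs = [
        Region("A_L", "left", (-2 * s, 0, 0), (-s, s, s)),
        Region("A_R", "right", (s, 0, 0), (2 * s, s, s)),
        Region("B_L", "left", (-2 * s, 2 * s, 0), (-s, 3 * s, s)),
        Region("B_R", "right", (s, 2 * s, 0), (2 * s, 3 * s, s)),
        Region("C", "centre", (-s // 2, 4 * s, 0), (s // 2, 5 * s, s)),
    ]
    groups = {"optic_lobe": ["B_L", "B_R"], "central_brain": ["A_L", "A_R", "C"]}
    return RegionSet(regions=regs, groups=groups)


def region_centre(region):
    return tuple((lo + hi) // 2 for lo, hi in zip(region.lo, region.hi))
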