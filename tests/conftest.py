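"""Shared fixtures: small synthetic systems reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

import foldsaxs as fs


PDB_3ATOM = """\
ATOM      1  C1  GLC A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  O2  GLC A   1       1.400   0.000   0.000  1.00  0.00           O
ATOM      3  H1  GLC A   1       0.000   1.000   0.000  1.00  0.00           H
END
"""


@pytest.fixture
def pdb_3atom(tmp_path):
    path = tmp_path / "three.pdb"
    path.write_text(PDB_3ATOM)
    return str(path)


@pytest.fixture(scope="session")
def two_state_system():
    """A 4000-frame two-state trajectory with assignment and state curves.

    Expensive enough to share: used by population-fit and synthetic-data
    tests that only need *some* realistic fc/uf basis curves.
    """
    spec = fs.TwoStateSpec(occupancy_folded=0.75, seed=11)
    traj, labels = fs.generate_two_state_trajectory(spec, 4000, 0.1)
    rg = fs.rg_series(traj)
    intervals = fs.partition_intervals(rg, 0.1, 1.0)
    threshold = fs.auto_threshold([iv.mean_rg for iv in intervals]).threshold
    assignment = fs.assign_states(intervals, threshold)
    q = np.linspace(0.01, 0.5, 80)
    curves = {
        state: fs.ensemble_intensity(
            fs.concatenate_state_frames(traj, assignment, state), q, stride=5
        )
        for state in ("fc", "uf")
    }
    return {
        "spec": spec,
        "traj": traj,
        "labels": labels,
        "rg": rg,
        "assignment": assignment,
        "q": q,
        "curves": curves,
    }
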