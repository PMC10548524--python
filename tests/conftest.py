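import numpy as np
import pandas as pd
import pytest

from oxytraj.synthgen import _place_by_torsion
from oxytraj.traj_io import EventTable, Trajectory


def make_chi1_trajectory(chi1_angles, resnum=101, chain="A"):
    """Trajectory of a single serine-like residue whose N-CA-CB-OG torsion
    is constructed exactly at the requested angle per frame."""
    n_pos = np.array([1.45, 0.0, 0.0])
    ca = np.zeros(3)
    cb = np.array([-0.55, 1.40, 0.0])
    frames = []
    for chi in chi1_angles:
        og = _place_by_torsion(n_pos, ca, cb, bond=1.42, angle_deg=110.0,
                               torsion_deg=chi)
        frames.append(np.vstack([n_pos, ca, cb, og]))
    atoms = pd.DataFrame(
        {
            "name": ["N", "CA", "CB", "OG"],
            "resname": ["SER"] * 4,
            "resnum": [resnum] * 4,
            "chain": [chain] * 4,
        }
    )
    times = np.arange(len(frames)) * 0.05
    return Trajectory(times=times, atoms=atoms, coords=np.stack(frames))


def make_event_table(durations, censored, cutoff=float("inf")):
    df = pd.DataFrame(
        {
            "run_id": np.arange(len(durations)),
            "duration_ns": np.asarray(durations, dtype=float),
            "censored": np.asarray(censored, dtype=bool),
        }
    )
    return EventTable(events=df, cutoff_ns=cutoff)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
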