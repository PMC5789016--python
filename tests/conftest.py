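"""Shared fixtures: small synthetic systems generated once per session."""

import numpy as np
import pytest

from cgleaflet import (
    GeneratorConfig,
    default_topology,
    generate_membrane,
    outer_membrane_config,
)


@pytest.fixture(scope="session")
def topo():
    return default_topology()


@pytest.fixture(scope="session")
def om_small():
    """Outer-membrane preset, 400 lipids/leaflet, 6 frames: (config, traj, truth)."""
    cfg = outer_membrane_config(lipids_per_leaflet=400, n_frames=6, seed=7)
    traj, truth = generate_membrane(cfg)
    return cfg, traj, truth


@pytest.fixture(scope="session")
def om_medium():
    """Outer-membrane preset at map-recovery scale: 1024 lipids, 24 frames."""
    cfg = outer_membrane_config(lipids_per_leaflet=1024, n_frames=24, seed=13)
    traj, truth = generate_membrane(cfg)
    return cfg, traj, truth


@pytest.fixture(scope="session")
def flat_bilayer():
    """Featureless flat bilayer: constant order, no voids/clusters."""
    cfg = GeneratorConfig(
        lipids_per_leaflet=200,
        composition_upper={"POPE": 1.0},
        composition_lower={"POPE": 1.0},
        order_field_upper=0.5,
        order_field_lower=0.5,
        n_frames=3,
        seed=21,
    )
    traj, truth = generate_membrane(cfg)
    return cfg, traj, truth


def tiny_frame_two_leaflets(topo, n_per_leaflet=4, box=(4.0, 4.0, 10.0), z=2.0):
    """Minimal hand-built frame: POPE reference beads only, one per quadrant."""
    from cgleaflet import Frame

    sp = topo["POPE"]
    centers = [(1.0, 1.0), (3.0, 1.0), (1.0, 3.0), (3.0, 3.0)][:n_per_leaflet]
    pos, names, resnames, resids = [], [], [], []
    rid = 0
    for sign in (+1, -1):
        for (x, y) in centers:
            rid += 1
            pos.append([x, y, 5.0 + sign * z])
            names.append(sp.ref_bead)
            resnames.append("POPE")
            resids.append(rid)
    return Frame(
        positions=np.array(pos),
        box=np.array(box),
        names=np.array(names, dtype=object),
        resnames=np.array(resnames, dtype=object),
        resids=np.array(resids),
    )
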