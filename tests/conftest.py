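import numpy as np
import pytest

from soltrack import (SphereSet, ToySystemSpec, build_scope, cluster_inlets,
                      detect_inlets, extract_paths, make_toy_system,
                      resolve_selection, trim_paths)
from soltrack.tracking import INCOMING, OBJECT, OUTGOING, REENTRY, RawPath


def path_from_pattern(pattern, path_id=0, molecule_id=1, frames=None,
                      entry="pending", exit_="pending"):
    """Build a RawPath from a label pattern string.

    Characters: i=incoming, o=object, r=reentry, g=outgoing.  Coordinates
    are placed along x at the frame index so geometry stays trivial.
    """
    codes = {"i": INCOMING, "o": OBJECT, "r": REENTRY, "g": OUTGOING}
    labels = np.array([codes[c] for c in pattern], dtype=np.int8)
    n = len(pattern)
    if frames is None:
        frames = np.arange(n)
    coords = np.zeros((n, 3))
    coords[:, 0] = frames
    return RawPath(path_id, molecule_id, frames, coords, labels,
                   entry_terminus=entry, exit_terminus=exit_)


def track_system(system, object_radius=4.0, eps=2.5, min_samples=3,
                 gap_tolerance=0):
    """Run the tracking chain (extract → trim → inlets → clusters) on a toy."""
    topo, frames = system.topology, system.frames
    solvent = resolve_selection(topo, "solvent", required=True)
    ca = resolve_selection(topo, "name CA", required=True)
    idx = topo.atom_indices(ca.atom_ids)
    scope = build_scope(frames.coords[0][idx].astype(float))
    obj = SphereSet(system.ground_truth.object_center[None, :],
                    np.array([object_radius]))
    paths = extract_paths(frames, solvent, scope, obj, topo, gap_tolerance)
    paths = [p for p in trim_paths(paths, frames, topo) if p.n_samples]
    inlets = detect_inlets(paths)
    clusters = cluster_inlets(inlets, eps=eps, min_samples=min_samples)
    return paths, inlets, clusters


@pytest.fixture(scope="session")
def one_channel_system():
    spec = ToySystemSpec(channels=[((0, 0, 1), 4.0)], n_particles=30,
                         n_frames=4000, seed=11)
    return make_toy_system(spec)


@pytest.fixture(scope="session")
def one_channel_tracking(one_channel_system):
    return track_system(one_channel_system)


@pytest.fixture(scope="session")
def closed_shell_system():
    spec = ToySystemSpec(channels=[], n_particles=40, n_frames=3000, seed=13)
    return make_toy_system(spec)
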