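"""Random dendritic trees with group-dependent geometry, emitted as SWC.

Each tree is a soma sphere with ``n_primary`` stems; every segment either
bifurcates (with probability ``bifurcation_prob``) or terminates, up to a
maximum of 6 branch orders.  Diameters taper linearly with path length.
"""

from __future__ import annotations

import numpy as np

from gpephys.morphology import Morphology, SOMA, DENDRITE
from gpephys.synth.cells import CellParams

MAX_ORDER = 6
_NODE_SPACING = 5.0  # um between consecutive SWC nodes along a segment
_MIN_RADIUS = 0.1  # um floor so radii stay positive under heavy taper


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def generate_swc(params: CellParams, rng_seed=0) -> Morphology:
    """Grow one random dendritic tree from a cell's geometry parameters."""
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    geom = params.dendrite_geometry
    ids, types, xyz, radii, parents = [1], [SOMA], [np.zeros(3)], [params.soma_radius], [-1]
    next_id = 2

    def grow(parent_id: int, origin: np.ndarray, direction: np.ndarray,
             radius: float, path_len: float, order: int) -> None:
        nonlocal next_id
        seg_len = max(_NODE_SPACING, rng.exponential(geom.mean_segment_len))
        n_nodes = max(1, int(round(seg_len / _NODE_SPACING)))
        pos = origin.copy()
        pid = parent_id
        r = radius
        for _ in range(n_nodes):
            step = _NODE_SPACING
            jitter = rng.normal(0.0, 0.25, 3)
            direction = _unit(direction + jitter)
            pos = pos + step * direction
            path_len += step
            r = max(_MIN_RADIUS, radius - geom.taper * path_len / 2.0)
            ids.append(next_id)
            types.append(DENDRITE)
            xyz.append(pos.copy())
            radii.append(r)
            parents.append(pid)
            pid = next_id
            next_id += 1
        if order < MAX_ORDER and rng.random() < geom.bifurcation_prob:
            for _ in range(2):
                child_dir = _unit(direction + rng.normal(0.0, 0.6, 3))
                grow(pid, pos, child_dir, radius, path_len, order + 1)
        # else: terminate

    for s in range(geom.n_primary):
        theta = 2 * np.pi * s / geom.n_primary + rng.uniform(-0.3, 0.3)
        phi = rng.uniform(0.3, np.pi - 0.3)
        direction = np.array([
            np.sin(phi) * np.cos(theta),
            np.sin(phi) * np.sin(theta),
            np.cos(phi),
        ])
        origin = params.soma_radius * direction
        grow(1, origin, direction, geom.base_diameter / 2.0, 0.0, 1)

    return Morphology(
        ids=np.array(ids), types=np.array(types),
        xyz=np.vstack(xyz), radii=np.array(radii),
        parents=np.array(parents), group=params.group,
    )


def expected_bifurcations(n_primary: int, p: float, max_order: int = MAX_ORDER) -> float:
    """Analytic expected bifurcation count of the depth-limited branching process.

    Segments at order 1 number ``n_primary``; each segment of order k < max_order
    bifurcates with probability p into two order-(k+1) segments.
    """
    total = 0.0
    n_k = float(n_primary)
    for _ in range(1, max_order):
        total += n_k * p
        n_k = 2.0 * p * n_k
    return total
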