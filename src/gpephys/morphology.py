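"""SWC neuronal reconstructions and dendritic morphometrics.

Covers the quantities compared across GPe populations: total dendritic
length, per-primary-dendrite length, bifurcation/termination counts, soma
and total surface area, Sholl intersection profiles, and branch-order
resolved dendritic diameters.  Axon nodes (SWC type 2) are ignored: slice
recordings truncate long-range axons and they are not quantified here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SOMA = 1
AXON = 2
DENDRITE = 3


class SwcError(ValueError):
    """Malformed SWC content; message carries the offending line number."""


@dataclass
class Morphology:
    """Validated SWC tree (ids, types, coordinates in um, radii, parents)."""

    ids: np.ndarray
    types: np.ndarray
    xyz: np.ndarray  # (n, 3) um
    radii: np.ndarray  # um
    parents: np.ndarray  # SWC parent ids, -1 for the root
    cell_id: str = ""
    group: str = ""
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------
    def validate(self) -> None:
        ids = self.ids
        if len(ids) == 0:
            raise SwcError("empty morphology")
        if len(np.unique(ids)) != len(ids):
            raise SwcError("duplicate node ids")
        if np.any(self.radii <= 0):
            bad = int(np.argmax(self.radii <= 0))
            raise SwcError(f"non-positive radius at node id {ids[bad]}")
        if not np.all(np.isfinite(self.xyz)):
            raise SwcError("non-finite coordinates")
        roots = np.flatnonzero(self.parents == -1)
        if roots.size != 1:
            raise SwcError(f"expected exactly one root, found {roots.size}")
        if self.types[roots[0]] != SOMA:
            raise SwcError("root node must be a soma node (type 1)")
        id_pos = {int(i): k for k, i in enumerate(ids)}
        for k, p in enumerate(self.parents):
            if p == -1:
                continue
            if int(p) not in id_pos:
                raise SwcError(f"node id {ids[k]} references undefined parent {p}")
            if id_pos[int(p)] >= k:
                raise SwcError(f"parent {p} does not precede child {ids[k]}")
        # parent-precedes-child on a finite node set implies acyclicity

    @property
    def n_nodes(self) -> int:
        return len(self.ids)

    def _index(self) -> dict[int, int]:
        return {int(i): k for k, i in enumerate(self.ids)}

    def children(self) -> dict[int, list[int]]:
        """Map node array-index -> list of child array-indices (axons skipped)."""
        idx = self._index()
        out: dict[int, list[int]] = {k: [] for k in range(self.n_nodes)}
        for k, p in enumerate(self.parents):
            if p == -1 or self.types[k] == AXON:
                continue
            out[idx[int(p)]].append(k)
        return out

    def dendrite_segments(self) -> np.ndarray:
        """(n_seg, 2) array of (parent_idx, child_idx) where the child is a dendrite."""
        idx = self._index()
        segs = [
            (idx[int(p)], k)
            for k, p in enumerate(self.parents)
            if p != -1 and self.types[k] == DENDRITE
        ]
        return np.array(segs, dtype=int).reshape(-1, 2)

    def soma_centroid(self) -> np.ndarray:
        """Radius-weighted centroid of the soma nodes."""
        mask = self.types == SOMA
        w = self.radii[mask]
        return (self.xyz[mask] * w[:, None]).sum(axis=0) / w.sum()


# ---------------------------------------------------------------------------
# SWC i/o
# ---------------------------------------------------------------------------

def read_swc(path) -> Morphology:
    """Parse and validate a 7-column SWC file ('#' comments allowed)."""
    path = Path(path)
    ids, types, xyz, radii, parents = [], [], [], [], []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise SwcError(f"{path.name}:{lineno}: expected 7 columns, got {len(parts)}")
        try:
            ids.append(int(parts[0]))
            types.append(int(parts[1]))
            xyz.append([float(parts[2]), float(parts[3]), float(parts[4])])
            radii.append(float(parts[5]))
            parents.append(int(parts[6]))
        except ValueError as exc:
            raise SwcError(f"{path.name}:{lineno}: {exc}") from exc
        if radii[-1] <= 0:
            raise SwcError(f"{path.name}:{lineno}: non-positive radius")
    try:
        return Morphology(
            ids=np.array(ids), types=np.array(types), xyz=np.array(xyz),
            radii=np.array(radii), parents=np.array(parents),
            cell_id=path.stem,
        )
    except SwcError as exc:
        raise SwcError(f"{path.name}: {exc}") from exc


def write_swc(m: Morphology, path) -> Path:
    """Write standard 7-column SWC; read_swc(write_swc(m)) is the identity."""
    path = Path(path)
    lines = ["# id type x y z radius parent"]
    for k in range(m.n_nodes):
        x, y, z = m.xyz[k]
        lines.append(
            f"{m.ids[k]} {m.types[k]} {x:.6g} {y:.6g} {z:.6g} {m.radii[k]:.6g} {m.parents[k]}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# Morphometrics
# ---------------------------------------------------------------------------

@dataclass
class MorphoMetrics:
    cell_id: str
    group: str
    total_dendritic_length: float  # um
    mean_dendrite_length: float  # um per primary-dendrite subtree
    bifurcation_count: int
    termination_count: int
    primary_dendrite_count: int
    soma_area: float  # um^2, projected disc
    total_surface_area: float  # um^2, soma sphere + dendritic frusta
    flags: list = field(default_factory=list)

    def to_row(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "flags"}
        d["flags"] = ";".join(self.flags)
        return d


def _segment_lengths(m: Morphology, segs: np.ndarray) -> np.ndarray:
    if segs.size == 0:
        return np.zeros(0)
    d = m.xyz[segs[:, 1]] - m.xyz[segs[:, 0]]
    return np.linalg.norm(d, axis=1)


def morpho_metrics(m: Morphology, soma_as_sphere_only: bool = False) -> MorphoMetrics:
    """Scalar dendritic morphometrics of one reconstruction.

    Soma area is reported as the projected disc pi*r^2 (r = largest soma-node
    radius); total surface area as the soma sphere 4*pi*r^2 plus the lateral
    frustum area of every dendritic segment (``soma_as_sphere_only`` drops
    the frusta).
    """
    flags: list[str] = []
    segs = m.dendrite_segments()
    kids = m.children()
    r_s = float(m.radii[m.types == SOMA].max())
    soma_area = np.pi * r_s**2
    sphere = 4.0 * np.pi * r_s**2
    if segs.size == 0:
        flags.append("no_dendrites")
        return MorphoMetrics(m.cell_id, m.group, 0.0, 0.0, 0, 0, 0,
                             soma_area, sphere, flags)
    lengths = _segment_lengths(m, segs)
    total = float(lengths.sum())
    soma_idx = set(np.flatnonzero(m.types == SOMA).tolist())
    primary = sum(
        1 for s in soma_idx for c in kids[s] if m.types[c] == DENDRITE
    )
    dend_idx = np.flatnonzero(m.types == DENDRITE)
    bif = 0
    term = 0
    for k in dend_idx:
        nc = len(kids[k])
        if nc == 0:
            term += 1
        elif nc >= 2:
            bif += nc - 1  # a trifurcation counts as two bifurcations
            if nc > 2:
                flags.append(f"multifurcation_at_{m.ids[k]}")
    # lateral (frustum) surface of every dendritic segment; a dendrite
    # emerges from the soma at its own caliber, so soma-attached segments
    # use the child radius at both ends
    r1 = np.where(m.types[segs[:, 0]] == SOMA,
                  m.radii[segs[:, 1]], m.radii[segs[:, 0]])
    r2 = m.radii[segs[:, 1]]
    slant = np.sqrt(lengths**2 + (r1 - r2) ** 2)
    lateral = float((np.pi * (r1 + r2) * slant).sum())
    surface = sphere + (0.0 if soma_as_sphere_only else lateral)
    mean_len = total / primary if primary else 0.0
    return MorphoMetrics(
        cell_id=m.cell_id, group=m.group,
        total_dendritic_length=total, mean_dendrite_length=mean_len,
        bifurcation_count=bif, termination_count=term,
        primary_dendrite_count=primary, soma_area=soma_area,
        total_surface_area=surface, flags=flags,
    )


# ---------------------------------------------------------------------------
# Sholl analysis
# ---------------------------------------------------------------------------

@dataclass
class ShollProfile:
    radii: np.ndarray  # um
    intersections: np.ndarray  # counts
    step: float

    def to_frame(self, cell_id: str = "") -> pd.DataFrame:
        return pd.DataFrame({
            "cell_id": cell_id,
            "radius_um": self.radii,
            "intersections": self.intersections,
        })


def sholl(m: Morphology, step: float = 10.0) -> ShollProfile:
    """Concentric-sphere intersection counts around the soma centroid.

    A dendritic segment whose endpoint distances straddle a sphere radius
    counts one crossing; an endpoint exactly on a sphere is resolved to the
    smaller radius (counted for the sphere it touches, i.e. min < r <= max).
    A segment that dips inside a sphere and exits again (both endpoints
    outside, interior minimum inside) counts two crossings; pure tangency
    counts zero.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    center = m.soma_centroid()
    segs = m.dendrite_segments()
    if segs.size == 0:
        return ShollProfile(np.array([step]), np.array([0]), step)
    a = m.xyz[segs[:, 0]] - center
    b = m.xyz[segs[:, 1]] - center
    d1 = np.linalg.norm(a, axis=1)
    d2 = np.linalg.norm(b, axis=1)
    lo = np.minimum(d1, d2)
    hi = np.maximum(d1, d2)
    # distance is a convex quadratic along the segment: interior minimum
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    t = np.clip(-np.einsum("ij,ij->i", a, ab) / np.where(denom == 0, 1.0, denom), 0.0, 1.0)
    d_min = np.linalg.norm(a + t[:, None] * ab, axis=1)
    r_max = float(hi.max())
    radii = np.arange(step, r_max + step, step)
    radii = radii[radii <= r_max + 1e-9]
    if radii.size == 0:
        radii = np.array([step])
    counts = np.empty(radii.size, dtype=int)
    for k, r in enumerate(radii):
        straddle = (lo < r) & (r <= hi)
        dip = (lo >= r) & (d_min < r)
        counts[k] = int(straddle.sum() + 2 * dip.sum())
    return ShollProfile(radii, counts, step)


# ---------------------------------------------------------------------------
# Branch-order diameters
# ---------------------------------------------------------------------------

@dataclass
class OrderDiameters:
    order1: float  # um, length-weighted mean diameter
    order2: float
    higher: float  # orders > 2
    profile: pd.DataFrame = field(default_factory=pd.DataFrame)  # path_um vs diameter
    flags: list = field(default_factory=list)


def branch_orders(m: Morphology) -> np.ndarray:
    """Branch order per node (0 for soma/axon nodes, 1 for primary segments)."""
    kids = m.children()
    idx_order = np.zeros(m.n_nodes, dtype=int)
    root = int(np.flatnonzero(m.parents == -1)[0])
    stack = [(root, 0)]
    while stack:
        k, order = stack.pop()
        if m.types[k] == DENDRITE:
            idx_order[k] = order
        ck = [c for c in kids[k] if m.types[c] != AXON]
        if m.types[k] == SOMA:
            for c in ck:
                stack.append((c, 1))
        else:
            bump = 1 if len(ck) >= 2 else 0
            for c in ck:
                stack.append((c, order + bump))
    return idx_order


def branch_order_diameters(m: Morphology) -> OrderDiameters:
    """Length-weighted mean dendritic diameter per branch-order class.

    Classes are 1st order (soma to first bifurcation), 2nd order, and >2nd
    order; each segment contributes its mean diameter weighted by its length.
    Also emits a diameter vs. path-distance profile.
    """
    flags: list[str] = []
    segs = m.dendrite_segments()
    orders = branch_orders(m)
    if segs.size == 0:
        return OrderDiameters(np.nan, np.nan, np.nan, pd.DataFrame(), ["no_dendrites"])
    lengths = _segment_lengths(m, segs)
    diam = 2.0 * m.radii[segs[:, 1]]  # node diameter, weighted by its segment
    seg_order = orders[segs[:, 1]]

    def weighted(mask: np.ndarray) -> float:
        if not mask.any():
            return float("nan")
        return float(np.average(diam[mask], weights=lengths[mask]))

    o1 = weighted(seg_order == 1)
    o2 = weighted(seg_order == 2)
    oh = weighted(seg_order > 2)
    for name, v in (("order2", o2), ("higher", oh)):
        if np.isnan(v):
            flags.append(f"{name}_empty")

    # path distance from the soma for the diameter profile
    idx = m._index()
    path = np.zeros(m.n_nodes)
    kids = m.children()
    root = int(np.flatnonzero(m.parents == -1)[0])
    stack = [root]
    while stack:
        k = stack.pop()
        for c in kids[k]:
            path[c] = path[k] + float(np.linalg.norm(m.xyz[c] - m.xyz[k]))
            stack.append(c)
    dend = np.flatnonzero(m.types == DENDRITE)
    profile = pd.DataFrame({
        "path_um": path[dend],
        "diameter_um": 2.0 * m.radii[dend],
        "order": orders[dend],
    }).sort_values("path_um", ignore_index=True)
    return OrderDiameters(o1, o2, oh, profile, flags)


def metrics_table(morphologies: list[Morphology], sholl_step: float = 10.0
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell metrics table and long-format Sholl table for a cohort."""
    rows, sholl_rows = [], []
    for m in morphologies:
        rows.append(morpho_metrics(m).to_row())
        sholl_rows.append(sholl(m, sholl_step).to_frame(m.cell_id))
    metrics = pd.DataFrame(rows)
    profiles = pd.concat(sholl_rows, ignore_index=True) if sholl_rows else pd.DataFrame()
    return metrics, profiles
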