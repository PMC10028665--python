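"""Random compact parcellation of a voxel mask.

Partitions a 3-D binary mask into contiguous (6-connected) parcels whose
sizes all lie in [min_size, 2 * min_size] voxels — the "largest parcel no
larger than twice the smallest" constraint of random compact parcellation.
The algorithm is randomised region growing: random seed voxels, then
smallest-parcel-first growth over 6-neighbours, followed by a repair loop
that merges undersized parcels into their smallest neighbour and splits
oversized parcels by farthest-point bisection.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .conditioning import RoiTimeSeries
from .networks import NETWORKS

__all__ = [
    "VoxelMask",
    "Parcellation",
    "NetworkAssignment",
    "grow_compact_parcellation",
    "assign_parcels_to_networks",
    "extract_roi_timeseries",
]

#: 6-connectivity structuring element (faces only).
STRUCTURE_6 = ndimage.generate_binary_structure(3, 1)

_OFFSETS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
)


@dataclass
class VoxelMask:
    """3-D boolean lattice with per-axis voxel size in mm."""

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3-D")
        if not self.data.any():
            raise ValueError("mask has no foreground voxel")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.voxel_size))


@dataclass
class Parcellation:
    """Integer label image (0 = background) partitioning a mask into
    contiguous, size-constrained parcels."""

    labels: np.ndarray
    voxel_size: tuple[float, float, float]
    min_size: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 3:
            raise ValueError("label image must be 3-D")

    @property
    def n_parcels(self) -> int:
        return int(self.labels.max())

    @property
    def parcel_ids(self) -> np.ndarray:
        return np.arange(1, self.n_parcels + 1)

    @property
    def sizes(self) -> np.ndarray:
        """Voxel counts per parcel, indexed by parcel id - 1."""
        return np.bincount(self.labels.ravel(), minlength=self.n_parcels + 1)[1:]

    @property
    def volumes(self) -> np.ndarray:
        """Parcel volumes in mm^3."""
        return self.sizes * float(np.prod(self.voxel_size))

    def voxels(self, parcel_id: int) -> np.ndarray:
        return np.argwhere(self.labels == parcel_id)


@dataclass
class NetworkAssignment:
    """Mapping from parcel id to one of the seven canonical networks."""

    mapping: dict[int, str]

    def labels_for(self, parcel_ids) -> np.ndarray:
        return np.array([self.mapping[int(p)] for p in parcel_ids], dtype=object)

    @property
    def n_parcels(self) -> int:
        return len(self.mapping)


def _neighbors(flat: int, shape: tuple[int, int, int]) -> list[int]:
    z, y, x = np.unravel_index(flat, shape)
    out = []
    for dz, dy, dx in _OFFSETS:
        nz, ny, nx = z + dz, y + dy, x + dx
        if 0 <= nz < shape[0] and 0 <= ny < shape[1] and 0 <= nx < shape[2]:
            out.append(int(np.ravel_multi_index((nz, ny, nx), shape)))
    return out


def _grow_from_seeds(
    voxels: set[int],
    seeds: list[int],
    shape: tuple[int, int, int],
    rng: np.random.Generator,
    neighbor_map: dict[int, list[int]],
) -> dict[int, list[int]]:
    """Smallest-first randomised region growing inside a voxel set."""
    assignment: dict[int, int] = {}
    members: dict[int, list[int]] = {}
    frontier: dict[int, set[int]] = {}
    for pid, s in enumerate(seeds, start=1):
        assignment[s] = pid
        members[pid] = [s]
        frontier[pid] = {v for v in neighbor_map[s] if v in voxels and v not in assignment}
    open_parcels = set(members)
    while open_parcels:
        pid = min(open_parcels, key=lambda p: (len(members[p]), p))
        cand = frontier[pid]
        cand.difference_update(assignment)
        if not cand:
            open_parcels.discard(pid)
            continue
        pick = int(rng.choice(sorted(cand)))
        cand.discard(pick)
        assignment[pick] = pid
        members[pid].append(pick)
        for v in neighbor_map[pick]:
            if v in voxels and v not in assignment:
                cand.add(v)
    return members


def _farthest_voxel(start: int, members: set[int], neighbor_map) -> int:
    """BFS within the parcel; returns the last voxel reached."""
    seen = {start}
    queue = deque([start])
    last = start
    while queue:
        v = queue.popleft()
        last = v
        for u in neighbor_map[v]:
            if u in members and u not in seen:
                seen.add(u)
                queue.append(u)
    return last


def _bisect_parcel(members: list[int], neighbor_map, rng) -> tuple[list[int], list[int]]:
    """Split a connected parcel into two balanced connected halves grown
    from a farthest-point pair."""
    mset = set(members)
    a = _farthest_voxel(members[0], mset, neighbor_map)
    b = _farthest_voxel(a, mset, neighbor_map)
    halves = _grow_from_seeds(mset, [a, b], None, rng, neighbor_map)
    return halves[1], halves[2]


def grow_compact_parcellation(
    mask: VoxelMask, min_size_voxels: int, seed: int | None = None
) -> Parcellation:
    """Randomly partition a mask into contiguous parcels with sizes in
    [min_size_voxels, 2 * min_size_voxels].

    Each 6-connected mask component is parcellated independently; a
    component smaller than the minimum size is an explicit error. The
    result is deterministic under (mask, min_size, seed).
    """
    if min_size_voxels < 1:
        raise ValueError("min_size_voxels must be at least 1")
    rng = np.random.default_rng(seed)
    shape = mask.data.shape
    comp_labels, n_comp = ndimage.label(mask.data, structure=STRUCTURE_6)
    labels = np.zeros(shape, dtype=int)
    next_id = 1
    flat_comp = comp_labels.ravel()
    for c in range(1, n_comp + 1):
        flat_voxels = np.flatnonzero(flat_comp == c)
        if flat_voxels.size < min_size_voxels:
            raise ValueError(
                f"mask component {c} has {flat_voxels.size} voxels, fewer than "
                f"the minimum parcel size {min_size_voxels}; the size bounds "
                "cannot be satisfied"
            )
        voxset = set(int(v) for v in flat_voxels)
        neighbor_map = {v: _neighbors(v, shape) for v in voxset}
        parcels = _parcellate_component(voxset, min_size_voxels, rng, neighbor_map)
        for members in parcels:
            flat_idx = np.array(sorted(members))
            labels.ravel()[flat_idx] = next_id
            next_id += 1
    # canonical relabeling by first flat occurrence for seed stability
    out = _relabel_by_first_occurrence(labels)
    return Parcellation(labels=out, voxel_size=mask.voxel_size, min_size=min_size_voxels)


def _relabel_by_first_occurrence(labels: np.ndarray) -> np.ndarray:
    flat = labels.ravel()
    order: dict[int, int] = {}
    for v in flat:
        if v and v not in order:
            order[v] = len(order) + 1
    lut = np.zeros(labels.max() + 1, dtype=int)
    for old, new in order.items():
        lut[old] = new
    return lut[labels]


def _parcellate_component(
    voxset: set[int],
    min_size: int,
    rng: np.random.Generator,
    neighbor_map: dict[int, list[int]],
    max_repair_rounds: int = 200,
) -> list[list[int]]:
    s = len(voxset)
    max_size = 2 * min_size
    target = 1.5 * min_size
    k = int(round(s / target))
    k = max(k, int(np.ceil(s / max_size)))
    k = min(k, s // min_size)
    k = max(k, 1)
    seeds = [int(v) for v in rng.choice(sorted(voxset), size=k, replace=False)]
    members = _grow_from_seeds(voxset, seeds, None, rng, neighbor_map)
    parcels: dict[int, list[int]] = dict(members)

    def adjacency(pid: int, assignment: dict[int, int]) -> set[int]:
        adj = set()
        for v in parcels[pid]:
            for u in neighbor_map[v]:
                other = assignment.get(u)
                if other is not None and other != pid:
                    adj.add(other)
        return adj

    for _ in range(max_repair_rounds):
        assignment = {v: pid for pid, vs in parcels.items() for v in vs}
        undersized = sorted(
            (pid for pid, vs in parcels.items() if len(vs) < min_size),
            key=lambda p: (len(parcels[p]), p),
        )
        if undersized:
            pid = undersized[0]
            adj = adjacency(pid, assignment)
            if not adj:
                raise ValueError(
                    f"parcel of size {len(parcels[pid])} is isolated and below "
                    f"the minimum size {min_size}"
                )
            # merge into the smallest neighbour (ties: lowest id)
            tgt = min(adj, key=lambda p: (len(parcels[p]), p))
            parcels[tgt] = parcels[tgt] + parcels.pop(pid)
            continue
        oversized = sorted(
            (pid for pid, vs in parcels.items() if len(vs) > max_size),
            key=lambda p: (-len(parcels[p]), p),
        )
        if oversized:
            pid = oversized[0]
            half_a, half_b = _bisect_parcel(parcels[pid], neighbor_map, rng)
            parcels[pid] = half_a
            new_pid = max(parcels) + 1
            parcels[new_pid] = half_b
            continue
        break
    else:
        raise RuntimeError(
            "compact parcellation did not converge to the size bounds; "
            "the mask geometry may be too thin for the requested minimum size"
        )
    return [parcels[pid] for pid in sorted(parcels)]


def assign_parcels_to_networks(
    parc: Parcellation, network_label_image: np.ndarray
) -> NetworkAssignment:
    """Assign each parcel to a network by majority vote over its voxels.

    The network image holds values in {0..7} on the same grid as the
    parcellation (0 = unlabelled). Ties break to the lowest network index;
    a parcel whose voxels are all unlabelled is an error.
    """
    img = np.asarray(network_label_image)
    if img.shape != parc.labels.shape:
        raise ValueError(
            f"network image shape {img.shape} does not match the parcellation "
            f"grid {parc.labels.shape}"
        )
    if img.min() < 0 or img.max() > len(NETWORKS):
        raise ValueError("network image values must lie in {0..7}")
    mapping: dict[int, str] = {}
    orphans = []
    for pid in parc.parcel_ids:
        votes = np.bincount(img[parc.labels == pid], minlength=len(NETWORKS) + 1)
        votes = votes[1:]  # drop background
        if votes.sum() == 0:
            orphans.append(int(pid))
            continue
        winner = int(np.argmax(votes))  # argmax takes the lowest index on ties
        mapping[int(pid)] = NETWORKS[winner]
    if orphans:
        raise ValueError(
            f"parcels entirely outside the network labels: {orphans}"
        )
    return NetworkAssignment(mapping=mapping)


def extract_roi_timeseries(
    voxel_timeseries: np.ndarray,
    parc: Parcellation,
    interval: float = 2.0,
    **labels,
) -> RoiTimeSeries:
    """Average voxel signals within each parcel.

    ``voxel_timeseries`` has shape (nx, ny, nz, T) (the NIfTI convention);
    the node signal of parcel p at time t is the mean over its voxels.
    """
    vts = np.asarray(voxel_timeseries, dtype=float)
    if vts.ndim != 4 or vts.shape[:3] != parc.labels.shape:
        raise ValueError(
            f"voxel time series grid {vts.shape[:3] if vts.ndim == 4 else vts.shape} "
            f"does not match the parcellation grid {parc.labels.shape}"
        )
    t = vts.shape[3]
    n = parc.n_parcels
    data = np.empty((t, n))
    for pid in range(1, n + 1):
        data[:, pid - 1] = vts[parc.labels == pid].mean(axis=0)
    return RoiTimeSeries(
        data=data,
        interval=interval,
        node_ids=[str(pid) for pid in range(1, n + 1)],
        **labels,
    )
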