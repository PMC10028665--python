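"""Synthetic study generator with planted gradient geometry.

Emulates a multi-site eyes-closed (EC) / eyes-open (EO) resting-state
study: each node of a synthetic connectome has latent coordinates in a
low-dimensional gradient space, organised around seven network centroids.
Node time series are generated by a linear factor model — node signal =
coordinates x latent factor series + noise — so the correlation structure
(and hence everything downstream: affinity, diffusion embedding, network
dispersion) is an analytic function of the planted geometry. Condition
effects are planted as per-network spread multipliers and centroid
displacements; test-retest reliability is planted as a between/within
subject variance ratio on a dispersion-controlling parameter.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .conditioning import CONFOUND_ROLES, ConfoundSet, RoiTimeSeries, compute_fd
from .networks import NETWORKS, N_NETWORKS, validate_network

__all__ = [
    "LatentGeometry",
    "ConditionEffect",
    "StudyDesign",
    "RetestSample",
    "make_latent_geometry",
    "apply_condition_effect",
    "simulate_timeseries",
    "simulate_retest",
    "simulate_confounds",
    "make_synthetic_mask",
    "DEFAULT_CONDITION_EFFECT",
]


@dataclass
class LatentGeometry:
    """Ground-truth node coordinates in gradient space.

    Attributes
    ----------
    coords
        (N, G) node coordinates.
    labels
        Length-N array of network names, one of the seven canonical networks.
    centroids
        (7, G) network centroids in canonical network order.
    spreads
        Per-network isotropic spread (standard deviation of node offsets
        around the centroid), all positive.
    """

    coords: np.ndarray
    labels: np.ndarray
    centroids: np.ndarray
    spreads: dict[str, float]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.coords.shape[0] != self.labels.shape[0]:
            raise ValueError("one network label per node is required")
        if self.centroids.shape != (N_NETWORKS, self.coords.shape[1]):
            raise ValueError("centroids must be 7 x G")
        for name in self.labels:
            validate_network(str(name))
        for name, s in self.spreads.items():
            validate_network(name)
            if not s > 0:
                raise ValueError(f"spread for {name} must be positive, got {s}")
        if self.n_nodes < 2 * N_NETWORKS:
            raise ValueError("need at least two nodes per network (N >= 14)")

    @property
    def n_nodes(self) -> int:
        return self.coords.shape[0]

    @property
    def n_dims(self) -> int:
        return self.coords.shape[1]

    def members(self, network: str) -> np.ndarray:
        validate_network(network)
        return np.flatnonzero(self.labels == network)


@dataclass
class ConditionEffect:
    """Planted condition contrast: per-network spread multipliers and
    centroid displacement vectors (both relative to the reference state)."""

    spread_multipliers: dict[str, float] = field(default_factory=dict)
    centroid_shifts: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, m in self.spread_multipliers.items():
            validate_network(name)
            if not m > 0:
                raise ValueError(f"spread multiplier for {name} must be > 0, got {m}")
        shifts = {}
        for name, v in self.centroid_shifts.items():
            validate_network(name)
            v = np.asarray(v, dtype=float)
            if not np.all(np.isfinite(v)):
                raise ValueError(f"centroid shift for {name} must be finite")
            shifts[name] = v
        self.centroid_shifts = shifts


#: Default EC-vs-EO contrast: the eyes-closed state compresses the visual
#: and sensorimotor networks (spread multipliers < 1) and pushes the
#: frontoparietal centroid outward from the grand centroid. Direction
#: mirrors the reported EC/EO findings; magnitudes are free parameters of
#: the generator (see docs/methods.md).
DEFAULT_CONDITION_EFFECT = ConditionEffect(
    spread_multipliers={"VN": 0.85, "SMN": 0.85}
)
#: Outward displacement of the FPN centroid (gradient units); the outward
#: direction depends on the centroid layout, so the geometry-aware effect
#: is built by :func:`default_condition_effect`.
DEFAULT_FPN_OUTWARD_SHIFT = 0.3


def default_condition_effect(geom: "LatentGeometry") -> ConditionEffect:
    """EC-relative-to-EO effect for *geom*: VN/SMN compression (x0.85) and
    an outward FPN centroid displacement of 0.3 gradient units."""
    grand = geom.centroids.mean(axis=0)
    fpn = geom.centroids[NETWORKS.index("FPN")]
    direction = fpn - grand
    norm = np.linalg.norm(direction)
    if norm == 0:
        direction = np.zeros(geom.n_dims)
        direction[0] = 1.0
    else:
        direction = direction / norm
    return ConditionEffect(
        spread_multipliers=dict(DEFAULT_CONDITION_EFFECT.spread_multipliers),
        centroid_shifts={"FPN": DEFAULT_FPN_OUTWARD_SHIFT * direction},
    )


@dataclass
class StudyDesign:
    """Acquisition design: subjects per site, two conditions, sessions,
    time points and sampling interval.

    Defaults emulate a single 21-subject site scanned for 8 minutes (240
    volumes at a 2 s interval) in both eye conditions.
    """

    n_subjects: int = 21
    sites: tuple[str, ...] = ("site1",)
    conditions: tuple[str, str] = ("EC", "EO")
    n_sessions: int = 1
    n_timepoints: int = 240
    interval: float = 2.0
    retest: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_timepoints < 8:
            raise ValueError("need at least 8 time points")
        if len(self.conditions) != 2:
            raise ValueError("the design is fixed to two conditions")
        if self.n_subjects < 2:
            raise ValueError("need at least two subjects")
        if self.interval <= 0:
            raise ValueError("sampling interval must be positive")

    @property
    def duration(self) -> float:
        return self.n_timepoints * self.interval


def _centroid_layout(g_dims: int) -> np.ndarray:
    """Fixed, distinct centroid positions: seven points evenly spaced on the
    unit circle in the first two gradient dimensions, zero elsewhere."""
    if g_dims < 2:
        raise ValueError("gradient space must have at least 2 dimensions")
    angles = 2 * np.pi * np.arange(N_NETWORKS) / N_NETWORKS
    centroids = np.zeros((N_NETWORKS, g_dims))
    centroids[:, 0] = np.cos(angles)
    centroids[:, 1] = np.sin(angles)
    return centroids


def make_latent_geometry(
    n_nodes: int,
    g_dims: int = 2,
    network_spreads: dict[str, float] | float = 0.4,
    seed: int | None = None,
) -> LatentGeometry:
    """Draw a ground-truth geometry: nodes scattered isotropically around
    seven fixed network centroids.

    ``network_spreads`` is either a single spread for all networks or a
    full per-network mapping; the spread is the standard deviation per
    coordinate of the node offsets. Deterministic under ``seed``.
    """
    if n_nodes < 2 * N_NETWORKS:
        raise ValueError("n_nodes must be at least 14 (two per network)")
    if isinstance(network_spreads, dict):
        spreads = {name: float(network_spreads[name]) for name in NETWORKS}
    else:
        spreads = {name: float(network_spreads) for name in NETWORKS}
    for name, s in spreads.items():
        if not s >= 0:
            raise ValueError(f"spread for {name} must be non-negative, got {s}")
    rng = np.random.default_rng(seed)
    centroids = _centroid_layout(g_dims)
    # distribute nodes as evenly as possible, canonical network order
    base, extra = divmod(n_nodes, N_NETWORKS)
    counts = [base + (1 if i < extra else 0) for i in range(N_NETWORKS)]
    labels = np.concatenate(
        [np.repeat(name, c) for name, c in zip(NETWORKS, counts)]
    ).astype(object)
    coords = np.empty((n_nodes, g_dims))
    start = 0
    for i, (name, c) in enumerate(zip(NETWORKS, counts)):
        offsets = rng.normal(0.0, 1.0, size=(c, g_dims)) * spreads[name]
        coords[start : start + c] = centroids[i] + offsets
        start += c
    # a zero spread is allowed for degenerate tests, but the stored spread
    # must stay positive per the geometry invariant
    stored = {k: max(v, np.finfo(float).tiny) for k, v in spreads.items()}
    return LatentGeometry(coords=coords, labels=labels, centroids=centroids, spreads=stored)


def apply_condition_effect(geom: LatentGeometry, effect: ConditionEffect) -> LatentGeometry:
    """Return a new geometry with the condition effect applied.

    Node offsets from their network centroid are scaled by the network's
    spread multiplier and the centroid is translated by its displacement;
    node count and labels are unchanged.
    """
    coords = geom.coords.copy()
    centroids = geom.centroids.copy()
    spreads = dict(geom.spreads)
    for i, name in enumerate(NETWORKS):
        mult = effect.spread_multipliers.get(name, 1.0)
        shift = effect.centroid_shifts.get(name)
        idx = geom.members(name)
        old_centroid = geom.centroids[i]
        new_centroid = old_centroid + (shift if shift is not None else 0.0)
        if shift is not None and shift.shape != (geom.n_dims,):
            raise ValueError(f"centroid shift for {name} must have length {geom.n_dims}")
        coords[idx] = new_centroid + mult * (geom.coords[idx] - old_centroid)
        centroids[i] = new_centroid
        spreads[name] = spreads[name] * mult
    return LatentGeometry(coords=coords, labels=geom.labels.copy(), centroids=centroids, spreads=spreads)


def _band_limited_factors(
    t: int, g: int, interval: float, rng: np.random.Generator,
    low_hz: float = 0.01, high_hz: float = 0.1,
) -> np.ndarray:
    """Latent factor series: Gaussian noise band-limited to [low, high] Hz,
    then sample-orthonormalised so the in-sample factor covariance is
    exactly the identity (columns mean-free, unit variance, uncorrelated)."""
    raw = rng.standard_normal((t, g))
    freqs = np.fft.rfftfreq(t, d=interval)
    spec = np.fft.rfft(raw, axis=0)
    keep = (freqs >= low_hz - 1e-12) & (freqs <= high_hz + 1e-12)
    if not np.any(keep):
        raise ValueError(
            f"no Fourier bin of a {t}-point, {interval}-s series falls in "
            f"[{low_hz}, {high_hz}] Hz"
        )
    spec[~keep, :] = 0.0
    smooth = np.fft.irfft(spec, n=t, axis=0)
    smooth -= smooth.mean(axis=0)
    q, r = np.linalg.qr(smooth)
    # keep orientation deterministic: flip columns so diag(r) > 0
    signs = np.sign(np.diag(r))
    signs[signs == 0] = 1.0
    return q * signs * math.sqrt(t)


def simulate_timeseries(
    geom: LatentGeometry,
    design: StudyDesign,
    noise_sd: float = 1.0,
    seed: int | None = None,
) -> RoiTimeSeries:
    """Generate one scan from the factor model.

    Each node's signal is the sum over gradient dimensions of its latent
    coordinate times a shared smooth factor series, plus independent white
    noise of standard deviation ``noise_sd``. Because the factors are
    sample-orthonormal, the noiseless correlation between nodes i and j is
    exactly cos(c_i, c_j) = c_i . c_j / (|c_i| |c_j|); with noise the
    analytic correlation is c_i . c_j / sqrt((|c_i|^2 + sd^2)(|c_j|^2 + sd^2)).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    t = design.n_timepoints
    rng = np.random.default_rng(seed)
    factors = _band_limited_factors(t, geom.n_dims, design.interval, rng)
    data = factors @ geom.coords.T
    if noise_sd > 0:
        data = data + noise_sd * rng.standard_normal((t, geom.n_nodes))
    return RoiTimeSeries(data=data, interval=design.interval)


def analytic_correlation(geom: LatentGeometry, noise_sd: float = 0.0) -> np.ndarray:
    """Closed-form node correlation matrix implied by the factor model."""
    c = geom.coords
    gram = c @ c.T
    power = np.diag(gram) + noise_sd**2
    denom = np.sqrt(np.outer(power, power))
    r = gram / denom
    np.fill_diagonal(r, 1.0)
    return r


@dataclass
class RetestSample:
    """Two sessions of per-subject geometries with a planted reliability.

    ``parameter`` holds the (n_subjects, 2) dispersion-controlling log
    spread scale whose variance decomposition fixes the planted intraclass
    correlation sigma_b^2 / (sigma_b^2 + sigma_w^2).
    """

    sessions: list[list[LatentGeometry]]
    parameter: np.ndarray
    between_subject_sd: float
    within_subject_sd: float

    @property
    def planted_icc(self) -> float:
        b2 = self.between_subject_sd**2
        w2 = self.within_subject_sd**2
        if b2 + w2 == 0:
            return 1.0
        return b2 / (b2 + w2)


def simulate_retest(
    geom: LatentGeometry,
    design: StudyDesign,
    between_subject_sd: float,
    within_subject_sd: float,
    seed: int | None = None,
) -> RetestSample:
    """Two-visit sample with planted test-retest reliability.

    Each subject's session geometry scales all node offsets (and hence all
    within-network spreads) by exp(theta_ij) with
    theta_ij = b_i + w_ij, b_i ~ N(0, between sd), w_ij ~ N(0, within sd),
    so the planted intraclass correlation of theta is
    sigma_b^2 / (sigma_b^2 + sigma_w^2).
    """
    if between_subject_sd < 0 or within_subject_sd < 0:
        raise ValueError("standard deviations must be non-negative")
    rng = np.random.default_rng(seed)
    n = design.n_subjects
    b = rng.normal(0.0, between_subject_sd, size=n) if between_subject_sd else np.zeros(n)
    w = (
        rng.normal(0.0, within_subject_sd, size=(n, 2))
        if within_subject_sd
        else np.zeros((n, 2))
    )
    theta = b[:, None] + w
    sessions: list[list[LatentGeometry]] = [[], []]
    for j in range(2):
        for i in range(n):
            scale = float(np.exp(theta[i, j]))
            effect = ConditionEffect(
                spread_multipliers={name: scale for name in NETWORKS}
            )
            sessions[j].append(apply_condition_effect(geom, effect))
    return RetestSample(
        sessions=sessions,
        parameter=theta,
        between_subject_sd=between_subject_sd,
        within_subject_sd=within_subject_sd,
    )


def _smooth_series(t: int, rng: np.random.Generator, window: int = 5) -> np.ndarray:
    x = rng.standard_normal(t + window)
    kernel = np.ones(window) / window
    return np.convolve(x, kernel, mode="valid")[:t]


def simulate_confounds(
    design: StudyDesign,
    fd_mean_by_condition: dict[str, float] | None = None,
    seed: int | None = None,
    motion_amplitude: float = 1.0,
    fd_sd_by_condition: dict[str, float] | None = None,
) -> dict[str, ConfoundSet]:
    """Per-condition confound tables for one subject, with condition-specific
    head motion.

    The subject's scan-mean frame-wise displacement is drawn as
    ``condition mean + z * condition sd`` where z is a single per-subject
    motion propensity shared by both conditions (high movers move more
    under either condition); motion parameters are smoothed random walks
    rescaled so the mean FD over frames 2..T equals that draw exactly
    (frame 1 is 0 by convention). Defaults mirror a typical
    eyes-closed/eyes-open contrast: mean (SD) of 0.053 (0.024) mm under EC
    and 0.044 (0.014) mm under EO. Tissue and global regressors are smooth
    unit-variance series. ``motion_amplitude = 0`` yields zero motion and
    an all-zero FD trace; ``fd_sd_by_condition`` of zero removes the
    between-subject FD spread.
    """
    if fd_mean_by_condition is None:
        fd_mean_by_condition = {"EC": 0.053, "EO": 0.044}
    if fd_sd_by_condition is None:
        fd_sd_by_condition = {"EC": 0.024, "EO": 0.014}
    for cond, m in fd_mean_by_condition.items():
        if not np.isfinite(m) or m <= 0:
            raise ValueError(f"FD mean for {cond} must be finite and positive")
    rng = np.random.default_rng(seed)
    t = design.n_timepoints
    propensity = rng.standard_normal()
    out: dict[str, ConfoundSet] = {}
    for cond in design.conditions:
        if cond not in fd_mean_by_condition:
            raise ValueError(f"no FD mean given for condition {cond!r}")
        mean = fd_mean_by_condition[cond]
        sd = fd_sd_by_condition.get(cond, 0.0)
        # truncate well above zero so the target stays a valid FD mean
        target = max(mean + propensity * sd, mean / 5.0)
        tissue = np.column_stack([_smooth_series(t, rng) for _ in range(3)])
        increments = 0.01 * np.column_stack(
            [_smooth_series(t - 1, rng, window=3) for _ in range(6)]
        )
        motion = np.vstack([np.zeros(6), np.cumsum(increments, axis=0)])
        if motion_amplitude == 0:
            motion[:] = 0.0
        else:
            motion *= motion_amplitude
            fd = compute_fd(motion)
            current = fd[1:].mean()
            if current > 0:
                motion *= target / current
        fd = compute_fd(motion)
        data = np.column_stack([tissue, motion, fd])
        out[cond] = ConfoundSet(data=data)
    return out


def make_synthetic_mask(
    dims: tuple[int, int, int],
    shape: str = "slab",
    voxel_size_mm: float | tuple[float, float, float] = 3.0,
):
    """Synthetic 3-D binary mask for parcellation tests.

    ``shape`` is ``"slab"`` (the full box) or ``"ellipsoid"`` (the
    inscribed ellipsoid). The result is a single 6-connected foreground
    component with the voxel size recorded.
    """
    from .parcellation import VoxelMask  # local import to avoid a cycle

    dims = tuple(int(d) for d in dims)
    if len(dims) != 3 or any(d < 4 for d in dims):
        raise ValueError("dims must be three axes, each at least 4")
    if np.isscalar(voxel_size_mm):
        voxel_size = (float(voxel_size_mm),) * 3
    else:
        voxel_size = tuple(float(v) for v in voxel_size_mm)
    if shape == "slab":
        data = np.ones(dims, dtype=bool)
    elif shape == "ellipsoid":
        grids = np.indices(dims).astype(float)
        centered = [
            (grids[a] - (dims[a] - 1) / 2) / (dims[a] / 2) for a in range(3)
        ]
        data = centered[0] ** 2 + centered[1] ** 2 + centered[2] ** 2 <= 1.0
    else:
        raise ValueError(f"unknown mask shape {shape!r}; use 'slab' or 'ellipsoid'")
    if not data.any():
        raise ValueError("synthetic mask is empty")
    return VoxelMask(data=data, voxel_size=voxel_size)
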