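"""Node-level signal conditioning: nuisance regression and band-pass filtering.

Operates on region-of-interest (ROI) time series, i.e. a T x N matrix of
node signals sampled at a fixed interval. Conditioning follows the usual
resting-state order: ordinary least-squares removal of nuisance regressors
(tissue means, head-motion parameters, frame-wise displacement), then an
ideal discrete-Fourier band-pass restricted to the 0.01-0.1 Hz band that
carries resting-state fluctuations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "RoiTimeSeries",
    "ConfoundSet",
    "CONFOUND_ROLES",
    "compute_fd",
    "regress_confounds",
    "bandpass_filter",
]

#: Fixed confound-table header: tissue means, six rigid-body motion
#: parameters (translations in mm, rotations in radians) and frame-wise
#: displacement.
CONFOUND_ROLES: tuple[str, ...] = (
    "white_matter",
    "csf",
    "global_signal",
    "trans_x",
    "trans_y",
    "trans_z",
    "rot_x",
    "rot_y",
    "rot_z",
    "fd",
)

MOTION_COLUMNS = CONFOUND_ROLES[3:9]


@dataclass
class RoiTimeSeries:
    """T x N matrix of node signals with acquisition metadata.

    Parameters
    ----------
    data
        Array of shape (T, N): rows are time points, columns are nodes.
    interval
        Sampling interval in seconds (the repetition time for fMRI).
    node_ids
        Optional node identifiers; defaults to ``n0001 ...``.
    subject, condition, session, site
        Scan labels; free-form strings.
    """

    data: np.ndarray
    interval: float
    node_ids: list[str] | None = None
    subject: str | None = None
    condition: str | None = None
    session: str | None = None
    site: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time-series data must be 2-D (T x N)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time-series data contains non-finite values")
        if self.interval <= 0:
            raise ValueError("sampling interval must be positive")
        if self.node_ids is None:
            self.node_ids = [f"n{i + 1:04d}" for i in range(self.data.shape[1])]
        if len(self.node_ids) != self.data.shape[1]:
            raise ValueError("node_ids length does not match number of nodes")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Total scan duration in seconds (T x interval)."""
        return self.n_timepoints * self.interval

    def with_data(self, data: np.ndarray) -> "RoiTimeSeries":
        return replace(self, data=np.asarray(data, dtype=float))


@dataclass
class ConfoundSet:
    """T x C nuisance-regressor table with fixed column roles.

    Columns follow :data:`CONFOUND_ROLES`; frame-wise displacement (FD) is
    non-negative with FD of the first frame 0 by convention.
    """

    data: np.ndarray
    columns: tuple[str, ...] = field(default=CONFOUND_ROLES)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("confound data must be 2-D (T x C)")
        if self.data.shape[1] != len(self.columns):
            raise ValueError("confound data width does not match column roles")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("confound data contains non-finite values")
        if "fd" in self.columns:
            fd = self.fd
            if np.any(fd < 0):
                raise ValueError("FD must be non-negative")
            if fd[0] != 0:
                raise ValueError("FD of the first frame must be 0 by convention")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    def column(self, role: str) -> np.ndarray:
        return self.data[:, self.columns.index(role)]

    @property
    def fd(self) -> np.ndarray:
        return self.column("fd")

    @property
    def motion(self) -> np.ndarray:
        idx = [self.columns.index(c) for c in MOTION_COLUMNS]
        return self.data[:, idx]


def compute_fd(motion_params: np.ndarray, rotation_radius_mm: float = 50.0) -> np.ndarray:
    """Frame-wise displacement from six rigid-body motion parameters.

    FD[t] is the sum of absolute frame-to-frame changes in the three
    translations (mm) plus the three rotations (radians) converted to arc
    length on a sphere of ``rotation_radius_mm``. FD[0] = 0 by convention.
    """
    motion = np.asarray(motion_params, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(
            f"motion parameters must be T x 6 (3 translations mm, 3 rotations rad); "
            f"got shape {motion.shape}"
        )
    delta = np.abs(np.diff(motion, axis=0))
    fd = np.zeros(motion.shape[0])
    fd[1:] = delta[:, :3].sum(axis=1) + rotation_radius_mm * delta[:, 3:].sum(axis=1)
    return fd


def _collinear_columns(design: np.ndarray, names: list[str]) -> list[str]:
    """Greedy scan naming columns that do not add rank to the design."""
    kept: list[int] = []
    bad: list[str] = []
    for j in range(design.shape[1]):
        cols = design[:, kept + [j]]
        if np.linalg.matrix_rank(cols) == len(kept) + 1:
            kept.append(j)
        else:
            bad.append(names[j])
    return bad


def regress_confounds(ts: RoiTimeSeries, conf: ConfoundSet | np.ndarray) -> RoiTimeSeries:
    """Remove nuisance regressors from every node signal by least squares.

    An intercept is always included, so residuals are mean-zero and exactly
    orthogonal to every confound column. Raises on rank deficiency, naming
    the collinear columns.
    """
    if isinstance(conf, ConfoundSet):
        cmat = conf.data
        names = list(conf.columns)
    else:
        cmat = np.asarray(conf, dtype=float)
        names = [f"confound_{i}" for i in range(cmat.shape[1])]
    if cmat.shape[0] != ts.n_timepoints:
        raise ValueError(
            f"confound rows ({cmat.shape[0]}) do not match time points ({ts.n_timepoints})"
        )
    design = np.column_stack([np.ones(ts.n_timepoints), cmat])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        bad = _collinear_columns(design, ["intercept"] + names)
        raise ValueError(f"confound design is rank deficient; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(design, ts.data, rcond=None)
    return ts.with_data(ts.data - design @ beta)


def bandpass_filter(
    ts: RoiTimeSeries, low_hz: float = 0.01, high_hz: float = 0.1
) -> RoiTimeSeries:
    """Ideal discrete-Fourier band-pass with inclusive edges.

    Frequency bins with ``low_hz <= |f| <= high_hz`` are retained and all
    others zeroed, so the filter is exactly idempotent and a sinusoid on
    the frequency grid passes with unit gain. The DC bin lies outside any
    positive band, so the output is mean-free.
    """
    nyquist = 0.5 / ts.interval
    if not 0 <= low_hz < high_hz:
        raise ValueError("need 0 <= low_hz < high_hz")
    if high_hz > nyquist + 1e-12:
        raise ValueError(f"high_hz={high_hz} exceeds the Nyquist frequency {nyquist}")
    t = ts.n_timepoints
    freqs = np.fft.rfftfreq(t, d=ts.interval)
    spectrum = np.fft.rfft(ts.data, axis=0)
    # inclusive edges, with a tiny relative tolerance for grid round-off
    tol = 1e-12
    keep = (freqs >= low_hz - tol) & (freqs <= high_hz + tol)
    spectrum[~keep, :] = 0.0
    return ts.with_data(np.fft.irfft(spectrum, n=t, axis=0))
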