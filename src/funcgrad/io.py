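"""Readers and writers for the package's canonical on-disk formats.

Tab-separated values are the canonical exchange format for time series,
confounds, connectivity matrices, embeddings and dispersion tables, each
with a JSON sidecar carrying provenance; masks and label images are NIfTI.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .conditioning import CONFOUND_ROLES, ConfoundSet, RoiTimeSeries
from .connectome import ConnectivityMatrix
from .embedding import EmbeddingConfig, GradientEmbedding
from .parcellation import NetworkAssignment, Parcellation, VoxelMask

__all__ = [
    "write_timeseries",
    "read_timeseries",
    "write_confounds",
    "read_confounds",
    "write_matrix",
    "read_matrix",
    "write_embedding",
    "read_embedding",
    "write_assignment",
    "read_assignment",
    "write_mask",
    "read_mask",
    "write_parcellation",
    "read_parcellation",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _write_sidecar(path: Path, payload: dict) -> None:
    _sidecar_path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _read_sidecar(path: Path) -> dict:
    p = _sidecar_path(path)
    return json.loads(p.read_text()) if p.exists() else {}


def write_timeseries(ts: RoiTimeSeries, path, seed: int | None = None) -> None:
    path = Path(path)
    pd.DataFrame(ts.data, columns=ts.node_ids).to_csv(path, sep="\t", index=False)
    _write_sidecar(
        path,
        {
            "subject": ts.subject,
            "condition": ts.condition,
            "session": ts.session,
            "site": ts.site,
            "interval_seconds": ts.interval,
            "seed": seed,
        },
    )


def read_timeseries(path) -> RoiTimeSeries:
    path = Path(path)
    frame = pd.read_csv(path, sep="\t")
    meta = _read_sidecar(path)
    return RoiTimeSeries(
        data=frame.to_numpy(),
        interval=float(meta.get("interval_seconds", 2.0)),
        node_ids=[str(c) for c in frame.columns],
        subject=meta.get("subject"),
        condition=meta.get("condition"),
        session=meta.get("session"),
        site=meta.get("site"),
    )


def write_confounds(conf: ConfoundSet, path) -> None:
    pd.DataFrame(conf.data, columns=list(conf.columns)).to_csv(
        Path(path), sep="\t", index=False
    )


def read_confounds(path) -> ConfoundSet:
    frame = pd.read_csv(Path(path), sep="\t")
    if tuple(frame.columns) != CONFOUND_ROLES:
        raise ValueError(
            f"confound table header {tuple(frame.columns)} does not match the "
            f"fixed roles {CONFOUND_ROLES}"
        )
    return ConfoundSet(data=frame.to_numpy())


def write_matrix(cm: ConnectivityMatrix, path) -> None:
    path = Path(path)
    pd.DataFrame(cm.values, columns=cm.node_ids).to_csv(path, sep="\t", index=False)
    _write_sidecar(path, {"state": cm.state, "sparsity": cm.sparsity, **cm.meta})


def read_matrix(path) -> ConnectivityMatrix:
    path = Path(path)
    frame = pd.read_csv(path, sep="\t")
    meta = _read_sidecar(path)
    return ConnectivityMatrix(
        values=frame.to_numpy(),
        state=meta.get("state", "pearson_r"),
        sparsity=meta.get("sparsity", "dense"),
        node_ids=[str(c) for c in frame.columns],
        meta={k: v for k, v in meta.items() if k not in ("state", "sparsity")},
    )


def write_embedding(emb: GradientEmbedding, path) -> None:
    path = Path(path)
    cols = {f"g{i + 1}": emb.coords[:, i] for i in range(emb.n_gradients)}
    frame = pd.DataFrame({"node_id": emb.node_ids, **cols})
    frame.to_csv(path, sep="\t", index=False)
    _write_sidecar(
        path,
        {
            "eigenvalues": emb.eigenvalues.tolist(),
            "variance_ratios": emb.variance_ratios.tolist(),
            "alignment": emb.alignment,
            "procrustes_residual": emb.procrustes_residual,
            "config": dataclasses.asdict(emb.config) if emb.config else None,
        },
    )


def read_embedding(path) -> GradientEmbedding:
    path = Path(path)
    frame = pd.read_csv(path, sep="\t")
    meta = _read_sidecar(path)
    grad_cols = [c for c in frame.columns if c.startswith("g")]
    cfg = meta.get("config")
    return GradientEmbedding(
        coords=frame[grad_cols].to_numpy(),
        eigenvalues=np.asarray(meta["eigenvalues"]),
        variance_ratios=np.asarray(meta["variance_ratios"]),
        alignment=meta.get("alignment", "unaligned"),
        node_ids=[str(n) for n in frame["node_id"]],
        procrustes_residual=meta.get("procrustes_residual"),
        config=EmbeddingConfig(**cfg) if cfg else None,
    )


def write_assignment(assign: NetworkAssignment, path) -> None:
    frame = pd.DataFrame(
        sorted(assign.mapping.items()), columns=["parcel_id", "network"]
    )
    frame.to_csv(Path(path), sep="\t", index=False)


def read_assignment(path) -> NetworkAssignment:
    frame = pd.read_csv(Path(path), sep="\t")
    return NetworkAssignment(
        mapping={int(r.parcel_id): str(r.network) for r in frame.itertuples()}
    )


def write_mask(mask: VoxelMask, path) -> None:
    affine = np.diag(list(mask.voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), affine), str(path))


def read_mask(path) -> VoxelMask:
    img = nib.load(str(path))
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VoxelMask(data=np.asarray(img.dataobj) > 0, voxel_size=voxel_size)


def write_parcellation(parc: Parcellation, path) -> None:
    affine = np.diag(list(parc.voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(parc.labels.astype(np.int32), affine), str(path))


def read_parcellation(path, min_size: int = 1) -> Parcellation:
    img = nib.load(str(path))
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Parcellation(
        labels=np.asarray(img.dataobj).astype(int),
        voxel_size=voxel_size,
        min_size=min_size,
    )
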