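"""Seed definition and seed-to-voxel functional connectivity.

A seed mask is split into head/body/tail slabs along the anterior-posterior
axis (a geometric stand-in for the manual, landmark-based subdivision used
with real anatomy), the seed's mean time series is correlated with every
in-mask voxel, and the Pearson map is Fisher r-to-z transformed. The z map
is the mediator entering the voxel-wise path model.
"""

from __future__ import annotations

import logging

import numpy as np

from .types import ConnectivityMap, SeedSet, Volume4D

__all__ = ["partition_seed_geometric", "seed_timeseries", "rsfc_map", "fisher_z", "subject_zmap"]

log = logging.getLogger(__name__)

R_CLIP = 1.0 - 1e-7


def partition_seed_geometric(seed_mask: np.ndarray, axis: int = 0) -> SeedSet:
    """Split a seed mask into three contiguous slabs along ``axis``.

    The occupied slices along the axis are divided into head/body/tail
    groups with as-equal-as-possible slice counts; when the count is not
    divisible by 3 the extra slices go to the anterior groups first
    (10 slices -> 4/3/3). Head is the lowest-index (most anterior) slab.
    """
    seed_mask = np.asarray(seed_mask, dtype=bool)
    occupied = np.flatnonzero(seed_mask.sum(axis=tuple(i for i in range(seed_mask.ndim) if i != axis)))
    if occupied.size < 3:
        raise ValueError(f"seed spans only {occupied.size} slices along axis {axis}; need >= 3")
    groups = np.array_split(occupied, 3)
    parts = []
    for sl in groups:
        part = np.zeros_like(seed_mask)
        idx = [slice(None)] * seed_mask.ndim
        for s in sl:
            idx[axis] = s
            part[tuple(idx)] = seed_mask[tuple(idx)]
        parts.append(part)
    return SeedSet(head=parts[0], body=parts[1], tail=parts[2])


def seed_timeseries(vol: Volume4D, voxels: np.ndarray) -> np.ndarray:
    """Unweighted mean time series over a voxel set (boolean mask)."""
    voxels = np.asarray(voxels, dtype=bool)
    if voxels.shape != vol.grid:
        raise ValueError("seed mask shape does not match image grid")
    if not voxels.any():
        raise ValueError("seed voxel set is empty")
    return vol.data[:, voxels].mean(axis=1)


def rsfc_map(vol: Volume4D, seed_ts: np.ndarray, brain_mask: np.ndarray) -> np.ndarray:
    """Pearson correlation between the seed series and every in-mask voxel.

    Voxels whose series has zero variance (possible after masking or
    filtering) are assigned r = 0; their count is logged. Values outside
    the mask are 0.
    """
    seed_ts = np.asarray(seed_ts, dtype=float).ravel()
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if brain_mask.shape != vol.grid:
        raise ValueError("brain mask shape does not match image grid")
    if seed_ts.size != vol.n_volumes:
        raise ValueError("seed series length does not match number of volumes")
    s = seed_ts - seed_ts.mean()
    s_norm = np.sqrt((s**2).sum())
    if s_norm == 0:
        raise ValueError("seed time series has zero variance")
    ts = vol.data[:, brain_mask]
    ts = ts - ts.mean(axis=0)
    norms = np.sqrt((ts**2).sum(axis=0))
    dead = norms == 0
    if dead.any():
        log.info("rsfc_map: %d zero-variance voxels set to r=0", int(dead.sum()))
    norms[dead] = 1.0
    r = (s @ ts) / (s_norm * norms)
    r[dead] = 0.0
    r = np.clip(r, -1.0, 1.0)
    out = np.zeros(vol.grid)
    out[brain_mask] = r
    return out


def fisher_z(r: np.ndarray) -> np.ndarray:
    """Fisher r-to-z transform, ``z = atanh(r)``, with |r| clipped to 1 - 1e-7."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1 + 1e-12):
        raise ValueError("correlations must satisfy |r| <= 1")
    return np.arctanh(np.clip(r, -R_CLIP, R_CLIP))


def subject_zmap(
    vol: Volume4D,
    seed_voxels: np.ndarray,
    brain_mask: np.ndarray,
    subject_id: str = "",
    seed_label: str = "",
) -> ConnectivityMap:
    """Seed-mean -> Pearson map -> Fisher z, excluding the seed's own voxels."""
    seed_voxels = np.asarray(seed_voxels, dtype=bool)
    target_mask = np.asarray(brain_mask, dtype=bool) & ~seed_voxels
    ts = seed_timeseries(vol, seed_voxels)
    r = rsfc_map(vol, ts, target_mask)
    z = np.zeros(vol.grid)
    z[target_mask] = fisher_z(r[target_mask])
    return ConnectivityMap(z=z, subject_id=subject_id, seed_label=seed_label, mask=target_mask)
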