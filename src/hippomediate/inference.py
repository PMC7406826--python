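"""Cluster-extent family-wise error correction of the indirect-effect map.

Voxels passing an uncorrected primary threshold (p < 0.001, two-tailed)
are grouped into sign-homogeneous connected clusters; a cluster is
declared significant when its extent exceeds what the permutation null
distribution of the *maximum* cluster size produces at the chosen
family-wise alpha. The null is built by permuting acceptance scores
across subjects under the Freedman-Lane scheme (covariate-fitted part of
X kept fixed, residuals permuted), recomputing the voxel-wise indirect
effect statistic for every permutation.

The default cluster-forming statistic is the joint-significance test of
the indirect effect — a voxel is supra-threshold when both the a-path and
the b-path t tests pass the primary threshold (voxel p = max(p_a, p_b)) —
the standard small-sample test of a*b, used identically in the observed
pass and every permutation pass so exchangeability is preserved while
keeping thousands of permutations tractable. A delta-method (Sobel) a*b
statistic and a bootstrap-p engine are selectable; the bootstrap engine
is far slower and requires a bootstrap count whose p-value floor clears
the primary threshold.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage

from .mediation import indirect_stat_batch, path_stats, voxelwise_mediation
from .types import ClusterResult, MediationInput, MediationMaps

__all__ = ["primary_threshold", "connected_components", "cluster_fwe"]

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def primary_threshold(p_map: np.ndarray, alpha: float = 0.001) -> np.ndarray:
    """Binary supra-threshold map: strictly ``p < alpha`` (p already two-tailed)."""
    p_map = np.asarray(p_map, dtype=float)
    return p_map < alpha


def connected_components(
    binary: np.ndarray, connectivity: int = 18
) -> tuple[np.ndarray, np.ndarray]:
    """Label maximal connected sets under a 6/18/26 neighbourhood.

    Labels are assigned deterministically: descending size, ties broken by
    the lexicographically smallest voxel index in the cluster. Returns
    ``(label_map, sizes)`` where ``sizes[k]`` is the voxel count of label
    ``k + 1``.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be one of 6/18/26, got {connectivity}")
    binary = np.asarray(binary, dtype=bool)
    raw, n = ndimage.label(binary, structure=_STRUCTURES[connectivity])
    if n == 0:
        return np.zeros(binary.shape, dtype=int), np.zeros(0, dtype=int)
    sizes = ndimage.sum_labels(binary, raw, index=np.arange(1, n + 1)).astype(int)
    first_voxel = []
    for lbl in range(1, n + 1):
        idx = np.argwhere(raw == lbl)
        first_voxel.append(tuple(idx[np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0]))[0]]))
    order = sorted(range(n), key=lambda i: (-sizes[i], first_voxel[i]))
    remap = np.zeros(n + 1, dtype=int)
    for new, old in enumerate(order, start=1):
        remap[old + 1] = new
    return remap[raw], sizes[order]


def _signed_clusters(p: np.ndarray, sign: np.ndarray, alpha: float, connectivity: int):
    """Cluster supra-threshold voxels separately per sign of the effect."""
    supra = primary_threshold(p, alpha)
    labels = np.zeros(p.shape, dtype=int)
    sizes: list[int] = []
    signs: list[int] = []
    offset = 0
    for s in (1, -1):
        part = supra & (np.sign(sign) == s)
        lab, sz = connected_components(part, connectivity)
        labels[lab > 0] = lab[lab > 0] + offset
        sizes.extend(sz.tolist())
        signs.extend([s] * len(sz))
        offset += len(sz)
    return labels, np.asarray(sizes, dtype=int), np.asarray(signs, dtype=int)


def _to_map(values: np.ndarray, voxel_index: np.ndarray, grid, fill: float = 0.0) -> np.ndarray:
    out = np.full(grid, fill)
    out[tuple(voxel_index.T)] = values
    return out


def _freedman_lane_xs(
    x: np.ndarray, cov: np.ndarray | None, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Permuted X vectors: fitted part on covariates kept, residuals shuffled."""
    n = x.size
    if cov is None or cov.size == 0:
        fitted = np.full(n, x.mean())
    else:
        W = np.hstack([cov, np.ones((n, 1))])
        fitted = W @ (np.linalg.pinv(W) @ x)
    resid = x - fitted
    xs = np.empty((n_perm, n))
    for p in range(n_perm):
        xs[p] = fitted + rng.permutation(resid)
    return xs


def cluster_fwe(
    inp: MediationInput,
    maps: MediationMaps | None = None,
    n_perm: int = 1000,
    rng_seed: int = 0,
    alpha_primary: float = 0.001,
    connectivity: int = 18,
    stat: str = "joint",
    B_null: int = 2000,
    perm_chunk: int = 64,
) -> ClusterResult:
    """Permutation max-cluster-size FWE correction for the indirect-effect map.

    Parameters
    ----------
    inp : MediationInput
        Must carry ``voxel_index`` and ``grid``.
    maps : MediationMaps, optional
        Precomputed voxel-wise bootstrap maps. Required for
        ``stat="bootstrap"`` (their p_ab map forms the observed clusters);
        ignored for the analytic statistics.
    stat : {"joint", "sobel", "bootstrap"}
        Cluster-forming statistic, applied identically to observed and
        permuted data.
    B_null : int
        Bootstrap draws per voxel in permutation passes when
        ``stat="bootstrap"``. Must satisfy 1/B_null < alpha_primary.

    Returns
    -------
    ClusterResult
        Sign-homogeneous clusters with ``corrected_p = (1 + #{perm max
        size >= observed size}) / (1 + n_perm)``.
    """
    if inp.voxel_index is None or inp.grid is None:
        raise ValueError("cluster_fwe needs voxel_index and grid on the input")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; corrected p-values are coarse", RuntimeWarning)
    rng = np.random.default_rng(np.random.SeedSequence(rng_seed, spawn_key=(0xC1,)))

    # --- observed pass -------------------------------------------------
    obs = path_stats(inp.x, inp.m, inp.y, inp.cov)
    if stat in ("joint", "sobel"):
        p_obs, ab_obs = indirect_stat_batch(inp.x[None, :], inp.m, inp.y, inp.cov, stat=stat)
        p_obs, ab_obs = p_obs[0], ab_obs[0]
    elif stat == "bootstrap":
        if 1.0 / B_null >= alpha_primary:
            raise ValueError(
                f"B_null={B_null} cannot reach the primary threshold {alpha_primary} "
                f"(bootstrap p-value floor 1/B)"
            )
        if maps is None:
            maps = voxelwise_mediation(inp, B=B_null, rng_seed=rng_seed)
        p_obs = maps.pval["ab"][tuple(inp.voxel_index.T)]
        ab_obs = maps.coef["ab"][tuple(inp.voxel_index.T)]
    else:
        raise ValueError(f"unknown cluster-forming statistic {stat!r}")

    p_map = _to_map(p_obs, inp.voxel_index, inp.grid, fill=1.0)
    ab_map = _to_map(ab_obs, inp.voxel_index, inp.grid)
    labels, sizes, signs = _signed_clusters(p_map, ab_map, alpha_primary, connectivity)

    # --- permutation null of the maximum cluster size -------------------
    xs = _freedman_lane_xs(inp.x, inp.cov, n_perm, rng)
    null_max = np.zeros(n_perm, dtype=int)
    if stat in ("joint", "sobel"):
        for start in range(0, n_perm, perm_chunk):
            chunk = xs[start : start + perm_chunk]
            p_c, ab_c = indirect_stat_batch(chunk, inp.m, inp.y, inp.cov, stat=stat)
            for j in range(chunk.shape[0]):
                pm = _to_map(p_c[j], inp.voxel_index, inp.grid, fill=1.0)
                am = _to_map(ab_c[j], inp.voxel_index, inp.grid)
                _, sz, _ = _signed_clusters(pm, am, alpha_primary, connectivity)
                null_max[start + j] = sz.max() if sz.size else 0
    else:
        for p_i in range(n_perm):
            perm_inp = MediationInput(
                x=xs[p_i], y=inp.y, m=inp.m, cov=inp.cov,
                voxel_index=inp.voxel_index, grid=inp.grid,
            )
            pm_maps = voxelwise_mediation(perm_inp, B=B_null, rng_seed=rng_seed + 1 + p_i)
            pmap = pm_maps.pval["ab"]
            amap = pm_maps.coef["ab"]
            _, sz, _ = _signed_clusters(pmap, amap, alpha_primary, connectivity)
            null_max[p_i] = sz.max() if sz.size else 0

    # --- cluster table ---------------------------------------------------
    rows = []
    a_map = _to_map(obs["a"], inp.voxel_index, inp.grid)
    b_map = _to_map(obs["b"], inp.voxel_index, inp.grid)
    for lbl in range(1, sizes.size + 1):
        members = labels == lbl
        size = int(sizes[lbl - 1])
        corrected = (1.0 + np.count_nonzero(null_max >= size)) / (1.0 + n_perm)
        mem_idx = np.argwhere(members)
        peak_pos = mem_idx[np.argmin(p_map[members])]
        rows.append(
            {
                "label": lbl,
                "size": size,
                "sign": int(signs[lbl - 1]),
                "peak_i": int(peak_pos[0]),
                "peak_j": int(peak_pos[1]),
                "peak_k": int(peak_pos[2]),
                "corrected_p": corrected,
                "mean_a": float(a_map[members].mean()),
                "mean_b": float(b_map[members].mean()),
                "mean_ab": float(ab_map[members].mean()),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "label", "size", "sign", "peak_i", "peak_j", "peak_k",
            "corrected_p", "mean_a", "mean_b", "mean_ab",
        ],
    )
    return ClusterResult(
        label_map=labels,
        table=table,
        n_perm=n_perm,
        alpha_primary=alpha_primary,
        connectivity=connectivity,
        null_max_sizes=null_max,
    )
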