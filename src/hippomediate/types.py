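"""Core in-memory containers shared across pipeline stages.

Conventions
-----------
* 4D functional data are stored time-first, ``(T, nx, ny, nz)``, so that a
  voxel's time series is a contiguous slice along axis 0 after reshaping.
  On disk (NIfTI) the spatial axes come first; :mod:`hippomediate.io`
  transposes at the boundary.
* Rigid-body motion parameters are ``(T, 6)``: three translations in mm
  followed by three rotations in radians.
* Voxel indices are 0-based; millimetre coordinates go through the affine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Volume4D",
    "MotionParams",
    "NuisanceMatrix",
    "QCReport",
    "SeedSet",
    "ConnectivityMap",
    "MediationInput",
    "PathFit",
    "MediationMaps",
    "ClusterResult",
    "validate_behavior",
    "BEHAVIOR_COLUMNS",
]

#: Required columns of a behavioral table: subject id, demographics,
#: acceptance (AAQ-II, the X of the mediation model), symptom severity
#: (CAPS-5, the Y) and the two symptom covariates (BDI-II, DES-II).
BEHAVIOR_COLUMNS = ("subject_id", "age", "sex", "aaq", "caps", "bdi", "des")


def _default_affine(voxel_size: Sequence[float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


@dataclass
class Volume4D:
    """A subject's 4D functional image.

    Parameters
    ----------
    data : ndarray, shape (T, nx, ny, nz)
        BOLD signal values; must be finite.
    voxel_size : tuple of float
        Voxel edge lengths in mm.
    tr : float
        Repetition time in seconds.
    affine : ndarray (4, 4), optional
        Voxel-index to mm mapping. Defaults to a diagonal scaling by
        ``voxel_size``.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 4.5)
    tr: float = 2.0
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"Volume4D data must be 4D (T,nx,ny,nz), got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume4D data contains non-finite values")
        if self.tr <= 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        if self.affine is None:
            self.affine = _default_affine(self.voxel_size)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def grid(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    def timeseries_matrix(self) -> np.ndarray:
        """Return the data flattened to ``(T, n_voxels)`` (C voxel order)."""
        return self.data.reshape(self.n_volumes, -1)

    def replace_data(self, data: np.ndarray) -> "Volume4D":
        return Volume4D(data=data, voxel_size=self.voxel_size, tr=self.tr, affine=self.affine.copy())

    def voxel_to_mm(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(ijk)
        hom = np.c_[ijk, np.ones(len(ijk))]
        return (self.affine @ hom.T).T[:, :3].squeeze()


@dataclass
class MotionParams:
    """Rigid-body realignment parameters, ``(T, 6)``.

    Columns 0-2 are translations in mm, columns 3-5 rotations in radians.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 6:
            raise ValueError(f"MotionParams must be (T, 6), got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("MotionParams contains non-finite values")

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]

    @property
    def translations(self) -> np.ndarray:
        return self.values[:, :3]

    @property
    def rotations(self) -> np.ndarray:
        return self.values[:, 3:]


@dataclass
class NuisanceMatrix:
    """Column-stacked nuisance design used in the single cleanup regression."""

    design: np.ndarray  # (T, K)
    labels: list[str]

    def __post_init__(self) -> None:
        self.design = np.asarray(self.design, dtype=float)
        if self.design.ndim != 2:
            raise ValueError("design must be 2D")
        if len(self.labels) != self.design.shape[1]:
            raise ValueError("label count does not match column count")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("nuisance column labels must be unique")
        if self.design.shape[1] >= self.design.shape[0]:
            raise ValueError("nuisance design has at least as many columns as rows")

    @property
    def n_columns(self) -> int:
        return self.design.shape[1]


@dataclass
class QCReport:
    """Per-subject motion quality-control summary."""

    subject_id: str
    max_abs_translation: float  # mm
    max_abs_rotation_deg: float  # degrees
    mean_fd: float  # mm
    excluded: bool
    reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.excluded != bool(self.reasons):
            raise ValueError("excluded flag must match presence of reasons")


@dataclass
class SeedSet:
    """Anterior-to-posterior seed subdivision: head, body and tail masks."""

    head: np.ndarray
    body: np.ndarray
    tail: np.ndarray

    def __post_init__(self) -> None:
        for name in ("head", "body", "tail"):
            m = np.asarray(getattr(self, name), dtype=bool)
            setattr(self, name, m)
            if not m.any():
                raise ValueError(f"seed subregion '{name}' is empty")
        if (self.head & self.body).any() or (self.head & self.tail).any() or (self.body & self.tail).any():
            raise ValueError("seed subregions overlap")

    def __getitem__(self, label: str) -> np.ndarray:
        return getattr(self, label)

    @property
    def labels(self) -> tuple[str, ...]:
        return ("head", "body", "tail")

    def union(self) -> np.ndarray:
        return self.head | self.body | self.tail


@dataclass
class ConnectivityMap:
    """Per-subject seed-to-voxel Fisher-z map (the mediator M at every voxel)."""

    z: np.ndarray  # 3D, zero outside mask
    subject_id: str
    seed_label: str
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.ndim != 3:
            raise ValueError("z map must be 3D")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if not np.all(np.isfinite(self.z[self.mask])):
                raise ValueError("z map non-finite inside mask")


@dataclass
class MediationInput:
    """Aligned inputs of the voxel-wise three-path model.

    ``x`` is the acceptance score (AAQ-II), ``y`` the symptom severity
    (CAPS-5), ``m`` the subjects x voxels mediator matrix of Fisher-z
    connectivity values, and ``cov`` the covariates of no interest
    (age, sex, BDI-II, DES-II). ``voxel_index`` carries each mediator
    column's (i, j, k) grid position so maps can be reassembled and
    per-voxel RNG streams stay tied to the voxel, not to column order.
    """

    x: np.ndarray
    y: np.ndarray
    m: np.ndarray  # (n, V)
    cov: np.ndarray | None = None  # (n, q)
    voxel_index: np.ndarray | None = None  # (V, 3) int
    grid: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float).ravel()
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.m = np.atleast_2d(np.asarray(self.m, dtype=float))
        n = self.x.size
        if self.y.size != n or self.m.shape[0] != n:
            raise ValueError("x, y, m must have an equal number of subjects")
        if self.cov is not None:
            self.cov = np.atleast_2d(np.asarray(self.cov, dtype=float))
            if self.cov.shape[0] != n:
                raise ValueError("covariate rows must match subjects")
        q = 0 if self.cov is None else self.cov.shape[1]
        if n <= q + 3:
            raise ValueError(f"need n > q + 3 subjects for identifiability (n={n}, q={q})")
        for name, arr in (("x", self.x), ("y", self.y), ("m", self.m)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains missing/non-finite values")
        if self.cov is not None and not np.all(np.isfinite(self.cov)):
            raise ValueError("cov contains missing/non-finite values")
        if self.voxel_index is not None:
            self.voxel_index = np.asarray(self.voxel_index, dtype=int)
            if self.voxel_index.shape != (self.m.shape[1], 3):
                raise ValueError("voxel_index must be (V, 3)")

    @property
    def n_subjects(self) -> int:
        return self.x.size

    @property
    def n_voxels(self) -> int:
        return self.m.shape[1]

    @property
    def n_covariates(self) -> int:
        return 0 if self.cov is None else self.cov.shape[1]


@dataclass
class PathFit:
    """Point estimates (and, after bootstrapping, p-values) of one voxel's paths."""

    a: float
    b: float
    c: float
    c_prime: float
    ab: float
    se_a: float
    se_b: float
    p_a: float | None = None
    p_b: float | None = None
    p_ab: float | None = None
    p_c_prime: float | None = None
    n_redraws: int = 0


@dataclass
class MediationMaps:
    """Voxel-wise coefficient and bootstrap p-value maps for one seed."""

    coef: dict  # name -> 3D map; names: a, b, ab, c_prime
    pval: dict  # name -> 3D map in (0, 1]
    mask: np.ndarray
    n_boot: int
    rng_seed: int
    covariate_labels: list[str] = field(default_factory=list)
    flavor: str = "bc"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        for name, mp in self.coef.items():
            if not np.all(np.isfinite(np.asarray(mp)[self.mask])):
                raise ValueError(f"coefficient map '{name}' non-finite inside mask")
        for name, mp in self.pval.items():
            vals = np.asarray(mp)[self.mask]
            if vals.size and (np.any(vals <= 0) or np.any(vals > 1)):
                raise ValueError(f"p-value map '{name}' outside (0, 1]")


@dataclass
class ClusterResult:
    """Cluster-extent inference output: label map plus a cluster table.

    The table has one row per cluster with columns
    ``label, size, sign, peak_i, peak_j, peak_k, peak_x_mm, peak_y_mm,
    peak_z_mm, corrected_p, mean_a, mean_b, mean_ab``.
    """

    label_map: np.ndarray
    table: pd.DataFrame
    n_perm: int
    alpha_primary: float
    connectivity: int
    null_max_sizes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.label_map = np.asarray(self.label_map, dtype=int)
        if len(self.table):
            p = self.table["corrected_p"].to_numpy()
            if np.any(p <= 0) or np.any(p > 1):
                raise ValueError("corrected p-values must lie in (0, 1]")

    @property
    def n_clusters(self) -> int:
        return len(self.table)

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["corrected_p"] < alpha]


def validate_behavior(table: pd.DataFrame, n_covariates: int = 4) -> pd.DataFrame:
    """Validate a behavioral table against the model's identifiability needs.

    Requires all of :data:`BEHAVIOR_COLUMNS`, no missing values, and at
    least ``4 + n_covariates`` rows so the three path regressions are
    identified.
    """
    missing = [c for c in BEHAVIOR_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"behavioral table missing columns: {missing}")
    if table[list(BEHAVIOR_COLUMNS)].isna().any().any():
        raise ValueError("behavioral table contains missing values")
    if len(table) < 4 + n_covariates:
        raise ValueError(
            f"behavioral table has {len(table)} rows; need at least {4 + n_covariates} "
            f"for a model with {n_covariates} covariates"
        )
    if not table["sex"].isin([0, 1]).all():
        raise ValueError("sex must be coded 0/1")
    return table
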