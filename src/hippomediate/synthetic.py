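"""Synthetic cohorts with planted mediation structure.

Generates everything the pipeline consumes for a trauma-survivor cohort of
the kind the analysis targets — behavioral table, per-subject rigid-body
motion traces, tissue/seed label masks and 4D functional images — from a
known structural model, so every downstream stage can be verified against
ground truth.

Structural model (standardized scale)
-------------------------------------
With x the standardized acceptance score and latent mediator noise
``eps ~ N(0, 1 - a^2)``:

    M_latent_i = z0 + a_true * x_i + eps_i                  (unit variance about z0)
    y_std_i    = b_true * (M_latent_i - z0) + c_prime_true * x_i
                 + gamma' * covariates_std_i + e_i

``M_latent`` is the per-subject Fisher-z connectivity between the seed and
the planted target region; the symptom score written to the behavioral
table is ``caps = 25.27 + 11.0 * y_std`` (Table-style marginals).

Imaging model
-------------
Every voxel carries white noise of sd ``noise_sd``; brain voxels add a
slow drift and a low-amplitude rank-``confound_rank`` structured signal;
noise-mask voxels carry the same structured signal at high amplitude
(giving the CompCor stage a recoverable target); seed voxels share a
band-limited latent signal s(t); voxels in the (dilated) target region add
``w_i * s(t)``.

The coupling ``w_i`` is calibrated so that the seed-target correlation
*after the default preprocessing* has Fisher z equal to ``M_latent_i``:
band-pass filtering keeps the in-band fraction ``f`` of white-noise
variance and Gaussian smoothing multiplies independent-noise variance by
``kappa`` (sum of squared kernel weights), while the band-limited signal
passes unchanged, so

    w_i = noise_sd * sqrt(kappa * f) * r_i / sqrt(1 - r_i^2),   r_i = tanh(M_latent_i).

The planted signal extends one voxel beyond the nominal target region so
that, after smoothing, every target voxel sees a homogeneous signal
neighbourhood and the calibration holds voxel-wise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from . import preprocess
from .types import MediationInput, MotionParams, Volume4D

__all__ = [
    "CohortSpec",
    "Cohort",
    "default_regions",
    "gen_behavior",
    "gen_motion",
    "gen_cohort",
    "gen_paths_dataset",
    "gen_mediation_grid",
]

# Cohort marginals (mean, sd) used for cosmetic realism of the behavioral table.
AAQ_MARGINAL = (39.89, 11.03)
CAPS_MARGINAL = (25.27, 11.0)
BDI_MARGINAL = (25.15, 13.62)
DES_MARGINAL = (17.08, 23.89)
AGE_MARGINAL = (40.36, 11.10)
FEMALE_PROP = 0.424

#: Standardized covariate effects on the outcome (age, sex, bdi, des).
COVARIATE_GAMMA = (0.05, 0.05, 0.15, 0.10)

Z0 = 0.25  # baseline seed-target Fisher z


def default_regions(grid: tuple[int, int, int]) -> dict[str, np.ndarray]:
    """Brain/seed/target/noise masks at fractional positions of the grid.

    The brain is the inscribed ellipsoid; seed, target and noise regions
    are disjoint boxes inside it (the seed box spans enough slices along
    axis 0 for a head/body/tail split).
    """
    nx, ny, nz = grid
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    brain = ((ii - cx) / cx) ** 2 + ((jj - cy) / cy) ** 2 + ((kk - cz) / cz) ** 2 <= 1.0

    def box(fr):
        m = np.zeros(grid, dtype=bool)
        (i0, i1), (j0, j1), (k0, k1) = (
            (int(fr[0][0] * nx), int(fr[0][1] * nx)),
            (int(fr[1][0] * ny), int(fr[1][1] * ny)),
            (int(fr[2][0] * nz), int(fr[2][1] * nz)),
        )
        m[i0:i1, j0:j1, k0:k1] = True
        return m

    seed = box(((0.15, 0.60), (0.40, 0.60), (0.30, 0.70))) & brain
    target = box(((0.65, 0.85), (0.20, 0.40), (0.30, 0.60))) & brain
    noise = box(((0.20, 0.50), (0.15, 0.35), (0.40, 0.70))) & brain
    return {"brain": brain, "seed": seed, "target": target, "noise": noise}


@dataclass
class CohortSpec:
    """Generator settings; defaults are the emulated acquisition protocol.

    ``a_true``, ``b_true``, ``c_prime_true`` are standardized path
    coefficients; the default signs follow the direction the analysis is
    designed to detect (acceptance lowers seed-target connectivity,
    connectivity raises symptom severity), and the default direct path is
    chosen so the implied total correlation corr(X, Y) = c' + a*b = -0.81.
    """

    n_subjects: int = 33
    n_volumes: int = 200  # pre-discard
    tr: float = 2.0
    grid: tuple[int, int, int] = (20, 20, 10)
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 4.5)
    seed_region: np.ndarray | None = None
    target_region: np.ndarray | None = None
    noise_region: np.ndarray | None = None
    brain_mask: np.ndarray | None = None
    a_true: float = -0.65
    b_true: float = 0.45
    c_prime_true: float = -0.52
    noise_sd: float = 1.0
    spike_prob: float = 0.02
    high_motion_subjects: tuple[int, ...] = ()
    high_motion_spike_prob: float = 0.6
    motion_noise: float = 1.0
    confound_rank: int = 3
    confound_amp_brain: float = 0.3
    drift_amp: float = 0.3
    signal_band: tuple[float, float] = (0.01, 0.08)
    # Analysis-protocol settings the coupling calibration assumes:
    n_discard: int = 4
    fwhm: float = 4.0
    band: tuple[float, float] = (0.01, 0.1)
    n_compcor: int = 5
    scrub_thr: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_volumes <= 4 or self.n_volumes <= self.n_discard:
            raise ValueError("n_volumes must exceed 4 and the discard count")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.n_subjects < 8:
            raise ValueError(
                f"n_subjects={self.n_subjects} too small: the path model with 4 covariates "
                "needs at least 8 subjects (4 + number of covariates)"
            )
        if not 0 <= self.spike_prob <= 1:
            raise ValueError("spike_prob must be a probability")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if any(g < 4 for g in self.grid):
            raise ValueError("grid dimensions must be at least 4")
        defaults = default_regions(self.grid)
        if self.brain_mask is None:
            self.brain_mask = defaults["brain"]
        if self.seed_region is None:
            self.seed_region = defaults["seed"]
        if self.target_region is None:
            self.target_region = defaults["target"]
        if self.noise_region is None:
            self.noise_region = defaults["noise"]
        for name in ("brain_mask", "seed_region", "target_region", "noise_region"):
            m = np.asarray(getattr(self, name), dtype=bool)
            setattr(self, name, m)
            if m.shape != tuple(self.grid):
                raise ValueError(f"{name} shape {m.shape} does not match grid {self.grid}")
            if not m.any():
                raise ValueError(f"{name} is empty")
        pairs = [("seed_region", "target_region"), ("seed_region", "noise_region"), ("target_region", "noise_region")]
        for n1, n2 in pairs:
            if (getattr(self, n1) & getattr(self, n2)).any():
                raise ValueError(f"regions overlap: {n1} and {n2} must be disjoint")
        for name in ("seed_region", "target_region", "noise_region"):
            if (getattr(self, name) & ~self.brain_mask).any():
                raise ValueError(f"{name} extends outside the brain mask")
        if any(not (0 <= i < self.n_subjects) for i in self.high_motion_subjects):
            raise ValueError("high_motion_subjects indices out of range")

    # -- derived quantities -------------------------------------------------
    @property
    def retained_volumes(self) -> int:
        return self.n_volumes - self.n_discard

    def noise_scale_after_cleanup(self) -> float:
        """sd multiplier of voxel white noise after smoothing + band-pass.

        Ignores the (small) extra variance the nuisance regression removes;
        :func:`_attenuation_factors` refines this per subject.
        """
        kappa = preprocess.smoothing_variance_factor(self.grid, self.voxel_size, self.fwhm)
        f = preprocess.band_variance_fraction(self.retained_volumes, self.tr, *self.band)
        return float(np.sqrt(kappa * f))

    def label_volume(self) -> np.ndarray:
        """Integer label mask: 1/2/3 seed head/body/tail, 10 noise, 20 other brain."""
        from .connectivity import partition_seed_geometric

        labels = np.zeros(self.grid, dtype=np.int16)
        labels[self.brain_mask] = 20
        labels[self.noise_region] = 10
        seeds = partition_seed_geometric(self.seed_region, axis=0)
        for val, name in ((1, "head"), (2, "body"), (3, "tail")):
            labels[seeds[name]] = val
        return labels


def _stream(spec: CohortSpec, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(spec.rng_seed, spawn_key=tuple(key)))


def _band_limited_signal(rng: np.random.Generator, T: int, tr: float, band: tuple[float, float], size: int = 1) -> np.ndarray:
    """Unit-variance signals with support restricted to a frequency band."""
    freqs = np.fft.rfftfreq(T, d=tr)
    keep = (freqs >= band[0]) & (freqs <= band[1])
    if not keep.any():
        raise ValueError("signal band contains no Fourier bins at this T and TR")
    spec = np.zeros((size, freqs.size), dtype=complex)
    n_keep = int(keep.sum())
    spec[:, keep] = rng.standard_normal((size, n_keep)) + 1j * rng.standard_normal((size, n_keep))
    sig = np.fft.irfft(spec, n=T, axis=1)
    sig /= sig.std(axis=1, keepdims=True)
    return sig


def _attenuation_factors(spec: CohortSpec, subject_index: int) -> tuple[float, float]:
    """Per-subject retention of planted signal and noise under the cleanup.

    The nuisance regression is not spectrally flat: motion expansions,
    spike indicators and the structured-noise components overlap the
    narrow signal band far more than white noise does, so the planted
    band-limited signal is attenuated more strongly. Both effects are
    computed exactly from the projector the analysis will use, which the
    generator can reconstruct: the subject's own motion trace (hence
    Friston-24, FD and spike columns), its confound time courses (which
    CompCor recovers almost perfectly), trend and intercept. CompCor
    components beyond the confound rank are treated as random directions.

    Returns ``(g_s, v_n)``: the expected *variance* fraction of the
    planted signal surviving regression, and the in-band white-noise
    variance fraction surviving regression followed by band-pass.
    """
    T = spec.retained_volumes
    motion = MotionParams(gen_motion(spec, subject_index).values[spec.n_discard:])
    fd = preprocess.compute_fd(motion)
    spikes, _ = preprocess.scrubbing_regressors(fd, thr=spec.scrub_thr)
    trend = np.arange(T, dtype=float) - (T - 1) / 2
    cols = [preprocess.friston24(motion), spikes]
    if spec.confound_rank > 0:
        rng = _stream(spec, 6, subject_index)
        U = _band_limited_signal(rng, spec.n_volumes, spec.tr, spec.signal_band, size=spec.confound_rank)
        cols.append(U[:, spec.n_discard:].T)
    cols.append(trend[:, None])
    cols.append(np.ones((T, 1)))
    W = np.hstack(cols)
    # Orthonormal basis of the nuisance span (rank-revealing via SVD).
    u, s, _ = np.linalg.svd(W, full_matrices=False)
    Q = u[:, s > s[0] * 1e-10]
    n_extra = max(0, spec.n_compcor - spec.confound_rank)

    freqs = np.fft.rfftfreq(T, d=spec.tr)
    d_sig = 2 * int(((freqs >= spec.signal_band[0]) & (freqs <= spec.signal_band[1])).sum())
    q_sig = preprocess.bandpass_series(Q, spec.tr, *spec.signal_band)
    tr_sig = float((q_sig**2).sum()) + n_extra * d_sig / T
    g_s = max(1.0 - tr_sig / d_sig, 0.05)

    f = preprocess.band_variance_fraction(T, spec.tr, *spec.band)
    q_bp = preprocess.bandpass_series(Q, spec.tr, *spec.band)
    tr_bp = float((q_bp**2).sum()) + n_extra * preprocess.band_variance_fraction(T, spec.tr, *spec.band)
    v_n = max(f - tr_bp / T, 1e-4)
    return g_s, v_n


def gen_behavior(spec: CohortSpec) -> pd.DataFrame:
    """Behavioral table with cohort-style marginals.

    Scores are continuous Gaussians at the configured means/SDs (age
    truncated to 18-65, sex Bernoulli at the cohort's female proportion).
    Deterministic given ``spec.rng_seed``. Note :func:`gen_cohort`
    regenerates the symptom score from the structural model; this
    stand-alone table is for behavioral-only analyses.
    """
    rng = _stream(spec, 1)
    n = spec.n_subjects
    age = AGE_MARGINAL[0] + AGE_MARGINAL[1] * rng.standard_normal(n)
    for _ in range(100):
        out = (age < 18) | (age > 65)
        if not out.any():
            break
        age[out] = AGE_MARGINAL[0] + AGE_MARGINAL[1] * rng.standard_normal(int(out.sum()))
    age = np.clip(age, 18, 65)
    sex = (rng.random(n) < FEMALE_PROP).astype(int)
    cols = {}
    for name, (mu, sd) in (("aaq", AAQ_MARGINAL), ("caps", CAPS_MARGINAL), ("bdi", BDI_MARGINAL), ("des", DES_MARGINAL)):
        cols[name] = mu + sd * rng.standard_normal(n)
    return pd.DataFrame(
        {
            "subject_id": [f"sub-{i + 1:03d}" for i in range(n)],
            "age": np.round(age, 1),
            "sex": sex,
            "aaq": np.round(cols["aaq"], 2),
            "caps": np.round(cols["caps"], 2),
            "bdi": np.round(cols["bdi"], 2),
            "des": np.round(cols["des"], 2),
        }
    )


def gen_motion(spec: CohortSpec, subject_index: int) -> MotionParams:
    """Rigid-body motion trace: a slow low-amplitude walk plus transient spikes.

    Spikes are one-volume displacements of ~0.7 mm with alternating sign,
    so every spiked volume (from volume 2 on) yields FD > 0.5 mm while the
    absolute-parameter exclusion bounds (1.5 mm / 1.5 deg) stay untouched;
    subjects listed in ``high_motion_subjects`` spike often enough to push
    mean FD over the 0.5 mm exclusion line.
    """
    if not 0 <= subject_index < spec.n_subjects:
        raise ValueError("subject_index out of range")
    rng = _stream(spec, 2, subject_index)
    T = spec.n_volumes
    steps = np.zeros((T, 6))
    steps[1:, :3] = 0.008 * spec.motion_noise * rng.standard_normal((T - 1, 3))
    steps[1:, 3:] = 0.00016 * spec.motion_noise * rng.standard_normal((T - 1, 3))
    trace = np.cumsum(steps, axis=0)
    p_spike = spec.high_motion_spike_prob if subject_index in spec.high_motion_subjects else spec.spike_prob
    spikes = np.flatnonzero(rng.random(T - 1) < p_spike) + 1  # volumes 1..T-1
    for s_i, t in enumerate(spikes):
        mag = 0.7 + 0.05 * abs(rng.standard_normal())
        trace[t, 0] += mag if s_i % 2 == 0 else -mag
    return MotionParams(trace)


@dataclass
class Cohort:
    """A generated cohort; images and motion are materialised lazily per subject.

    ``truth`` records the planted structure: standardized acceptance
    ``x_std``, latent mediator ``m_latent`` (Fisher-z scale), couplings
    ``w``, standardized outcome ``y_std``, the region masks and the
    calibration constants.
    """

    spec: CohortSpec
    behavior: pd.DataFrame
    truth: dict = field(default_factory=dict)

    @property
    def n_subjects(self) -> int:
        return self.spec.n_subjects

    def motion(self, i: int) -> MotionParams:
        return gen_motion(self.spec, i)

    def confound_signals(self, i: int) -> np.ndarray:
        """The subject's structured-noise time courses, shape (rank, T)."""
        spec = self.spec
        if spec.confound_rank == 0:
            return np.zeros((0, spec.n_volumes))
        rng = _stream(spec, 6, i)
        return _band_limited_signal(rng, spec.n_volumes, spec.tr, spec.signal_band, size=spec.confound_rank)

    def seed_signal(self, i: int) -> np.ndarray:
        rng = _stream(spec := self.spec, 7, i)
        return _band_limited_signal(rng, spec.n_volumes, spec.tr, spec.signal_band, size=1)[0]

    def volume(self, i: int) -> Volume4D:
        """Materialise subject ``i``'s 4D image (deterministic per seed)."""
        spec = self.spec
        if not 0 <= i < spec.n_subjects:
            raise ValueError("subject index out of range")
        T = spec.n_volumes
        rng = _stream(spec, 3, i)
        data = spec.noise_sd * rng.standard_normal((T,) + tuple(spec.grid))

        brain = spec.brain_mask
        trend = np.linspace(-0.5, 0.5, T)
        data[:, brain] += spec.drift_amp * trend[:, None]

        if spec.confound_rank > 0:
            U = self.confound_signals(i)  # (r, T)
            load_brain = spec.confound_amp_brain * rng.standard_normal((spec.confound_rank, int(brain.sum())))
            data[:, brain] += U.T @ load_brain
            load_noise = 1.0 + 0.2 * rng.standard_normal((spec.confound_rank, int(spec.noise_region.sum())))
            data[:, spec.noise_region] += U.T @ load_noise

        s = self.seed_signal(i)
        data[:, spec.seed_region] += s[:, None]
        support = self.truth["support_region"]
        data[:, support] += self.truth["w"][i] * s[:, None]
        return Volume4D(data=data, voxel_size=spec.voxel_size, tr=spec.tr)

    def volumes(self):
        for i in range(self.n_subjects):
            yield self.volume(i)

    def label_volume(self) -> np.ndarray:
        return self.spec.label_volume()

    def covariates(self) -> np.ndarray:
        return self.behavior[["age", "sex", "bdi", "des"]].to_numpy(dtype=float)


def _standardized_covariates(behavior: pd.DataFrame) -> np.ndarray:
    age = (behavior["age"].to_numpy() - AGE_MARGINAL[0]) / AGE_MARGINAL[1]
    sex = (behavior["sex"].to_numpy() - FEMALE_PROP) / np.sqrt(FEMALE_PROP * (1 - FEMALE_PROP))
    bdi = (behavior["bdi"].to_numpy() - BDI_MARGINAL[0]) / BDI_MARGINAL[1]
    des = (behavior["des"].to_numpy() - DES_MARGINAL[0]) / DES_MARGINAL[1]
    return np.column_stack([age, sex, bdi, des])


def gen_cohort(spec: CohortSpec) -> Cohort:
    """Generate a full cohort with planted path structure.

    The behavioral table's symptom score is rebuilt from the structural
    model so that the planted paths hold on the standardized scale; the
    ``truth`` dict carries everything a recovery analysis needs.
    """
    behavior = gen_behavior(spec)
    x_std = (behavior["aaq"].to_numpy() - AAQ_MARGINAL[0]) / AAQ_MARGINAL[1]

    rng_m = _stream(spec, 4)
    a = spec.a_true
    sd_eps = float(np.sqrt(max(1.0 - a**2, 0.05)))
    m_latent = Z0 + a * x_std + sd_eps * rng_m.standard_normal(spec.n_subjects)
    m_latent = np.clip(m_latent, Z0 - 2.8, Z0 + 2.8)
    r = np.tanh(m_latent)
    # Per-subject coupling calibrated for the post-cleanup scale: observed
    # r = sqrt(g_s) w / sqrt(g_s w^2 + kappa v_n sigma^2) must equal the
    # planted r (see _attenuation_factors for g_s and v_n).
    kappa = preprocess.smoothing_variance_factor(spec.grid, spec.voxel_size, spec.fwhm)
    gv = np.array([_attenuation_factors(spec, i) for i in range(spec.n_subjects)])
    g_s, v_n = gv[:, 0], gv[:, 1]
    sigma_eff = spec.noise_sd * np.sqrt(kappa * v_n / g_s)
    w = sigma_eff * r / np.sqrt(1.0 - r**2)

    rng_y = _stream(spec, 5)
    cov_std = _standardized_covariates(behavior)
    gamma = np.asarray(COVARIATE_GAMMA)
    b, cp = spec.b_true, spec.c_prime_true
    var_model = b**2 * (a**2 + sd_eps**2) + cp**2 + 2 * b * cp * a + float(gamma @ gamma)
    sd_e = float(np.sqrt(max(1.0 - var_model, 0.1)))
    y_std = b * (m_latent - Z0) + cp * x_std + cov_std @ gamma + sd_e * rng_y.standard_normal(spec.n_subjects)
    behavior = behavior.copy()
    behavior["caps"] = np.round(CAPS_MARGINAL[0] + CAPS_MARGINAL[1] * y_std, 2)

    support = ndimage.binary_dilation(
        spec.target_region, structure=ndimage.generate_binary_structure(3, 3), iterations=1
    )
    support &= ~spec.seed_region  # keep planted regions disjoint from the seed
    truth = {
        "x_std": x_std,
        "m_latent": m_latent,
        "w": w,
        "y_std": y_std,
        "sd_eps": sd_eps,
        "sd_e": sd_e,
        "z0": Z0,
        "a_true": a,
        "b_true": b,
        "c_prime_true": cp,
        "target_region": spec.target_region,
        "support_region": support,
        "signal_retention": g_s,
        "noise_retention": v_n,
        "kappa": kappa,
        "cov_std": cov_std,
    }
    return Cohort(spec=spec, behavior=behavior, truth=truth)


# ---------------------------------------------------------------------------
# Behavioral-level simulators (no imaging): used for bootstrap calibration
# and cluster-inference studies where the imaging stage is not under test.
# ---------------------------------------------------------------------------

def gen_paths_dataset(
    n: int,
    a_true: float,
    b_true: float,
    c_prime_true: float = 0.0,
    n_covariates: int = 4,
    rng_seed: int | np.random.Generator = 0,
    meas_sd: float = 0.0,
):
    """Single-voxel mediation dataset from the standardized structural model.

    Returns ``(x, m, y, cov)``. Covariates are independent standard
    normals with the default small effects on the outcome only, mirroring
    the cohort generator.
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    x = rng.standard_normal(n)
    cov = rng.standard_normal((n, n_covariates)) if n_covariates else None
    sd_eps = np.sqrt(max(1.0 - a_true**2, 0.05))
    m = a_true * x + sd_eps * rng.standard_normal(n)
    gamma = np.asarray(COVARIATE_GAMMA[:n_covariates]) if n_covariates else np.zeros(0)
    var_model = b_true**2 * (a_true**2 + sd_eps**2) + c_prime_true**2 + 2 * b_true * c_prime_true * a_true + float(gamma @ gamma)
    sd_e = np.sqrt(max(1.0 - var_model, 0.1))
    y = b_true * m + c_prime_true * x + (cov @ gamma if n_covariates else 0.0) + sd_e * rng.standard_normal(n)
    m_obs = m + meas_sd * rng.standard_normal(n) if meas_sd else m
    return x, m_obs, y, cov


def gen_mediation_grid(
    n: int = 33,
    grid: tuple[int, int, int] = (20, 20, 10),
    a_true: float = 0.0,
    b_true: float = 0.0,
    c_prime_true: float = 0.0,
    n_covariates: int = 4,
    rng_seed: int | np.random.Generator = 0,
    meas_sd: float = 0.12,
) -> MediationInput:
    """Whole-grid mediator matrix with (optionally) planted target structure.

    Background in-brain voxels get independent unit-variance z values;
    target voxels share the subject's latent mediator plus measurement
    noise of sd ``meas_sd`` (the Fisher-z sampling error scale at ~70
    effective in-band degrees of freedom). With ``a_true = b_true = 0``
    this is a fully null cohort for family-wise error calibration.
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    regions = default_regions(grid)
    brain, target = regions["brain"], regions["target"]
    voxel_index = np.argwhere(brain)
    V = len(voxel_index)
    x, m_target, y, cov = gen_paths_dataset(
        n, a_true, b_true, c_prime_true, n_covariates, rng_seed=rng, meas_sd=0.0
    )
    M = Z0 + rng.standard_normal((n, V))
    in_target = target[tuple(voxel_index.T)]
    M[:, in_target] = (Z0 + m_target)[:, None] + meas_sd * rng.standard_normal((n, int(in_target.sum())))
    return MediationInput(x=x, y=y, m=M, cov=cov, voxel_index=voxel_index, grid=grid)
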