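"""End-to-end orchestration from inputs to the cluster table.

A run directory is the unit of work: ``inputs/`` holds (or is populated
with) the per-subject 4D images, motion files, the label mask and the
behavioral table; each stage reads what the previous one wrote, so stages
can also be run individually from the command line. Subjects are always
joined by explicit id — never by file order.

Layout of a completed run::

    <out_dir>/
      config.yaml          provenance.json       qc.tsv
      inputs/              behavior.tsv, labels.nii.gz,
                           <id>_func.nii.gz, <id>_motion.txt, cohort.yaml
      cleaned/<id>.nii.gz
      zmaps/<id>_<seed>_z.nii.gz + manifest.tsv
      mediation/<path>_{coef,p}.nii.gz + mediation.json
      clusters.tsv         cluster_labels.nii.gz
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io, preprocess
from .connectivity import partition_seed_geometric, subject_zmap
from .inference import cluster_fwe
from .mediation import voxelwise_mediation
from .synthetic import CohortSpec, gen_cohort
from .types import ClusterResult, MediationInput, MediationMaps

__all__ = ["RunConfig", "run_pipeline", "stage_simulate", "stage_qc", "stage_preprocess",
           "stage_connect", "stage_mediate", "stage_report"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline settings; defaults reproduce the reference protocol."""

    out_dir: str = "run"
    mode: str = "synthetic"  # or "real"
    # real-mode input locations (ignored for synthetic):
    behavior_path: str | None = None
    func_dir: str | None = None
    motion_dir: str | None = None
    labels_path: str | None = None
    # synthetic cohort overrides (CohortSpec keyword arguments):
    cohort: dict = field(default_factory=dict)
    # preprocessing:
    n_discard: int = 4
    head_radius: float = 50.0
    max_translation: float = 1.5
    max_rotation_deg: float = 1.5
    max_mean_fd: float = 0.5
    scrub_thr: float = 0.5
    n_compcor: int = 5
    fwhm: float = 4.0
    band: tuple = (0.01, 0.1)
    bandpass_before_smoothing: bool = False
    # connectivity / mediation:
    seed_labels: tuple = ("head", "body", "tail")
    mediation_seed: str = "body"
    n_boot: int = 10000
    bootstrap_flavor: str = "bc"
    # cluster inference:
    alpha_primary: float = 0.001
    alpha_cluster: float = 0.05
    cluster_connectivity: int = 18
    cluster_stat: str = "joint"
    n_perm: int = 1000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.band = tuple(float(b) for b in self.band)
        self.seed_labels = tuple(self.seed_labels)
        if self.mode not in ("synthetic", "real"):
            raise ValueError(f"mode must be synthetic or real, got {self.mode!r}")
        if self.mediation_seed not in self.seed_labels:
            raise ValueError("mediation_seed must be among seed_labels")

    def to_yaml(self, path: str | Path) -> Path:
        d = dataclasses.asdict(self)
        d["band"] = list(self.band)
        d["seed_labels"] = list(self.seed_labels)
        return io.save_yaml(d, path)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**io.load_yaml(path))

    def digest(self) -> str:
        d = dataclasses.asdict(self)
        return hashlib.sha256(repr(sorted(d.items())).encode()).hexdigest()[:16]


def _paths(cfg: RunConfig) -> dict[str, Path]:
    out = Path(cfg.out_dir)
    return {
        "out": out,
        "inputs": out / "inputs",
        "cleaned": out / "cleaned",
        "zmaps": out / "zmaps",
        "mediation": out / "mediation",
    }


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: RunConfig) -> Path:
    """Generate a synthetic cohort and write it as pipeline inputs."""
    if cfg.mode != "synthetic":
        raise ValueError("stage_simulate only applies to synthetic mode")
    p = _paths(cfg)
    p["inputs"].mkdir(parents=True, exist_ok=True)
    spec = CohortSpec(
        n_discard=cfg.n_discard, fwhm=cfg.fwhm, band=cfg.band, **cfg.cohort
    )
    cohort = gen_cohort(spec)
    io.save_behavior(cohort.behavior, p["inputs"] / "behavior.tsv")
    affine = np.diag(list(spec.voxel_size) + [1.0])
    io.save_labels(cohort.label_volume(), p["inputs"] / "labels.nii.gz", affine)
    for i, sid in enumerate(cohort.behavior["subject_id"]):
        io.save_volume(cohort.volume(i), p["inputs"] / f"{sid}_func.nii.gz")
        io.save_motion(cohort.motion(i), p["inputs"] / f"{sid}_motion.txt")
    io.save_yaml(
        {
            "rng_seed": spec.rng_seed,
            "n_subjects": spec.n_subjects,
            "n_volumes": spec.n_volumes,
            "tr": spec.tr,
            "grid": list(spec.grid),
            "voxel_size": list(spec.voxel_size),
            "a_true": spec.a_true,
            "b_true": spec.b_true,
            "c_prime_true": spec.c_prime_true,
            "high_motion_subjects": list(spec.high_motion_subjects),
        },
        p["inputs"] / "cohort.yaml",
    )
    log.info("simulated cohort of %d subjects at %s", spec.n_subjects, p["inputs"])
    return p["inputs"]


def _input_locations(cfg: RunConfig) -> tuple[Path, Path, Path, Path]:
    if cfg.mode == "synthetic":
        inp = _paths(cfg)["inputs"]
        return inp / "behavior.tsv", inp, inp, inp / "labels.nii.gz"
    for name, val in (
        ("behavior_path", cfg.behavior_path),
        ("func_dir", cfg.func_dir),
        ("motion_dir", cfg.motion_dir),
        ("labels_path", cfg.labels_path),
    ):
        if val is None:
            raise ValueError(f"real mode requires {name}")
    return Path(cfg.behavior_path), Path(cfg.func_dir), Path(cfg.motion_dir), Path(cfg.labels_path)


def _load_inputs(cfg: RunConfig):
    behavior_path, func_dir, motion_dir, labels_path = _input_locations(cfg)
    for f in (behavior_path, labels_path):
        if not Path(f).exists():
            raise FileNotFoundError(f"missing input file: {f}")
    behavior = io.load_behavior(behavior_path)
    labels = io.load_labels(labels_path)
    ids = list(behavior["subject_id"])
    missing = [
        sid for sid in ids
        if not (func_dir / f"{sid}_func.nii.gz").exists() or not (motion_dir / f"{sid}_motion.txt").exists()
    ]
    if missing:
        raise FileNotFoundError(
            f"behavioral/image subject-id mismatch; no imaging inputs for: {missing}"
        )
    return behavior, labels, func_dir, motion_dir


def stage_qc(cfg: RunConfig) -> pd.DataFrame:
    """Motion QC: FD and exclusion decision per subject, written to qc.tsv."""
    behavior, _, _, motion_dir = _load_inputs(cfg)
    rows = []
    for sid in behavior["subject_id"]:
        motion = io.load_motion(motion_dir / f"{sid}_motion.txt")
        motion = preprocess.MotionParams(motion.values[cfg.n_discard:])
        fd = preprocess.compute_fd(motion, head_radius=cfg.head_radius)
        rep = preprocess.exclusion_decision(
            motion, fd,
            max_translation=cfg.max_translation,
            max_rotation_deg=cfg.max_rotation_deg,
            max_mean_fd=cfg.max_mean_fd,
            subject_id=sid,
        )
        rows.append(
            {
                "subject_id": rep.subject_id,
                "max_abs_translation": rep.max_abs_translation,
                "max_abs_rotation_deg": rep.max_abs_rotation_deg,
                "mean_fd": rep.mean_fd,
                "excluded": rep.excluded,
                "reasons": ";".join(rep.reasons),
            }
        )
    qc = pd.DataFrame(rows)
    out = _paths(cfg)["out"]
    out.mkdir(parents=True, exist_ok=True)
    qc.to_csv(out / "qc.tsv", sep="\t", index=False)
    n_exc = int(qc["excluded"].sum())
    log.info("QC: %d of %d subjects excluded", n_exc, len(qc))
    return qc


def _retained_ids(cfg: RunConfig) -> list[str]:
    qc_path = _paths(cfg)["out"] / "qc.tsv"
    if not qc_path.exists():
        raise FileNotFoundError("qc.tsv not found; run the qc stage first")
    qc = pd.read_csv(qc_path, sep="\t")
    return list(qc.loc[~qc["excluded"], "subject_id"])


def stage_preprocess(cfg: RunConfig) -> Path:
    """Discard, nuisance-regress, smooth and band-pass every retained subject."""
    behavior, labels, func_dir, motion_dir = _load_inputs(cfg)
    retained = _retained_ids(cfg)
    p = _paths(cfg)
    p["cleaned"].mkdir(parents=True, exist_ok=True)
    noise_mask = labels == 10
    for sid in retained:
        vol = io.load_volume(func_dir / f"{sid}_func.nii.gz")
        motion = io.load_motion(motion_dir / f"{sid}_motion.txt")
        if vol.n_volumes != motion.n_volumes:
            raise ValueError(
                f"{sid}: image has {vol.n_volumes} volumes but motion file has {motion.n_volumes}"
            )
        vol, motion = preprocess.discard_initial(vol, motion, k=cfg.n_discard)
        cleaned = preprocess.clean(
            vol, motion,
            noise_mask=noise_mask,
            n_compcor=cfg.n_compcor,
            fwhm=cfg.fwhm,
            band=cfg.band,
            head_radius=cfg.head_radius,
            scrub_thr=cfg.scrub_thr,
            bandpass_before_smoothing=cfg.bandpass_before_smoothing,
        )
        io.save_volume(cleaned, p["cleaned"] / f"{sid}.nii.gz")
    return p["cleaned"]


def stage_connect(cfg: RunConfig) -> pd.DataFrame:
    """Seed-to-voxel Fisher-z maps for every retained subject and seed label."""
    _, labels, _, _ = _load_inputs(cfg)
    retained = _retained_ids(cfg)
    p = _paths(cfg)
    p["zmaps"].mkdir(parents=True, exist_ok=True)
    seed_union = (labels >= 1) & (labels <= 3)
    brain_eff = (labels > 0) & ~seed_union
    seed_masks = {"head": labels == 1, "body": labels == 2, "tail": labels == 3}
    rows = []
    for sid in retained:
        vol = io.load_volume(p["cleaned"] / f"{sid}.nii.gz")
        for lab in cfg.seed_labels:
            cmap = subject_zmap(vol, seed_masks[lab], brain_eff, subject_id=sid, seed_label=lab)
            path = p["zmaps"] / f"{sid}_{lab}_z.nii.gz"
            io.save_map(cmap.z, path, vol.affine)
            rows.append({"subject_id": sid, "seed": lab, "path": path.name})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(p["zmaps"] / "manifest.tsv", sep="\t", index=False)
    return manifest


def _mediation_input(cfg: RunConfig) -> MediationInput:
    behavior, labels, _, _ = _load_inputs(cfg)
    retained = _retained_ids(cfg)
    p = _paths(cfg)
    seed_union = (labels >= 1) & (labels <= 3)
    mask = (labels > 0) & ~seed_union
    voxel_index = np.argwhere(mask)
    behavior = behavior.set_index("subject_id").loc[retained].reset_index()
    M = np.empty((len(retained), len(voxel_index)))
    for r, sid in enumerate(retained):
        z = io.load_map(p["zmaps"] / f"{sid}_{cfg.mediation_seed}_z.nii.gz")
        M[r] = z[mask]
    return MediationInput(
        x=behavior["aaq"].to_numpy(float),
        y=behavior["caps"].to_numpy(float),
        m=M,
        cov=behavior[["age", "sex", "bdi", "des"]].to_numpy(float),
        voxel_index=voxel_index,
        grid=labels.shape,
    )


def stage_mediate(cfg: RunConfig) -> MediationMaps:
    """Voxel-wise path fits with bootstrap p-values for the chosen seed."""
    inp = _mediation_input(cfg)
    maps = voxelwise_mediation(inp, B=cfg.n_boot, rng_seed=cfg.rng_seed, flavor=cfg.bootstrap_flavor)
    p = _paths(cfg)
    p["mediation"].mkdir(parents=True, exist_ok=True)
    for name in maps.coef:
        io.save_map(maps.coef[name], p["mediation"] / f"{name}_coef.nii.gz")
        io.save_map(maps.pval[name], p["mediation"] / f"{name}_p.nii.gz")
    io.save_json(
        {
            "n_boot": maps.n_boot,
            "rng_seed": maps.rng_seed,
            "flavor": maps.flavor,
            "seed_label": cfg.mediation_seed,
            "covariates": ["age", "sex", "bdi", "des"],
            "n_subjects": inp.n_subjects,
            "n_voxels": inp.n_voxels,
        },
        p["mediation"] / "mediation.json",
    )
    return maps


def stage_report(cfg: RunConfig) -> ClusterResult:
    """Cluster-extent FWE correction of the indirect-effect map."""
    inp = _mediation_input(cfg)
    result = cluster_fwe(
        inp,
        n_perm=cfg.n_perm,
        rng_seed=cfg.rng_seed,
        alpha_primary=cfg.alpha_primary,
        connectivity=cfg.cluster_connectivity,
        stat=cfg.cluster_stat,
    )
    p = _paths(cfg)
    table = result.table.copy()
    _, _, _, labels_file = _input_locations(cfg)
    import nibabel as nib

    affine = nib.load(str(labels_file)).affine
    if len(table):
        peaks = table[["peak_i", "peak_j", "peak_k"]].to_numpy()
        mm = (affine @ np.c_[peaks, np.ones(len(peaks))].T).T[:, :3]
        table[["peak_x_mm", "peak_y_mm", "peak_z_mm"]] = np.round(mm, 2)
    else:
        table[["peak_x_mm", "peak_y_mm", "peak_z_mm"]] = None
    table.to_csv(p["out"] / "clusters.tsv", sep="\t", index=False)
    io.save_labels(result.label_map, p["out"] / "cluster_labels.nii.gz", affine)
    return result


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage and write provenance; returns a summary dict."""
    p = _paths(cfg)
    p["out"].mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(p["out"] / "config.yaml")
    if cfg.mode == "synthetic":
        stage_simulate(cfg)
    qc = stage_qc(cfg)
    stage_preprocess(cfg)
    stage_connect(cfg)
    stage_mediate(cfg)
    result = stage_report(cfg)
    summary = {
        "config_digest": cfg.digest(),
        "version": __version__,
        "rng_seed": cfg.rng_seed,
        "n_subjects": int(len(qc)),
        "n_excluded": int(qc["excluded"].sum()),
        "excluded_ids": list(qc.loc[qc["excluded"], "subject_id"]),
        "n_clusters": result.n_clusters,
        "n_significant_clusters": int(len(result.significant(cfg.alpha_cluster))),
    }
    io.save_json(summary, p["out"] / "provenance.json")
    return summary
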