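"""Motion QC and nuisance cleanup of the simulated cohort.

Discards the first four volumes, computes frame-wise displacement, applies
the exclusion criteria (any parameter > 1.5 mm / 1.5 deg, mean FD > 0.5
mm), and runs the cleanup chain — Friston-24 + spike regressors + 5
CompCor components + trend in one regression, 4 mm FWHM smoothing, then
0.01-0.1 Hz band-pass — on every retained subject.

Writes results/qc.tsv; cleaned images go to scratch/run/cleaned/.
"""

import importlib.util
import shutil
import sys
from pathlib import Path

spec = importlib.util.spec_from_file_location("config00", Path(__file__).parent / "00_config.py")
config00 = importlib.util.module_from_spec(spec)
spec.loader.exec_module(config00)

from hippomediate.pipeline import stage_preprocess, stage_qc  # noqa: E402


def main() -> None:
    cfg = config00.get_config()
    qc = stage_qc(cfg)
    stage_preprocess(cfg)
    shutil.copy(Path(cfg.out_dir) / "qc.tsv", config00.RESULTS / "qc.tsv")

    excluded = qc[qc["excluded"]]
    print(f"{len(excluded)} of {len(qc)} subjects excluded for excessive head motion:")
    for _, row in excluded.iterrows():
        print(f"  {row.subject_id}: mean FD = {row.mean_fd:.2f} mm ({row.reasons})")
    print(f"{len(qc) - len(excluded)} subjects enter the connectivity analysis")


if __name__ == "__main__":
    sys.exit(main())
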