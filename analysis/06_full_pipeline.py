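#!/usr/bin/env python
"""End-to-end pipeline run with provenance.

Runs simulate -> extract -> metrics -> stats under one seed into a fresh
results/pipeline_run directory, writing the feature tables, the stats
report and the manifest (package version, config echo, output hashes).
Equivalent to `ephyskit run --seed 51 --out results/pipeline_run`.
"""

from pathlib import Path

from ephyskit.config import RunConfig
from ephyskit.pipeline import run_pipeline

OUT = Path(__file__).resolve().parents[1] / "results" / "pipeline_run"


def main() -> None:
    cfg = RunConfig(seed=51, output_dir=str(OUT), n_cells_per_group=2,
                    n_wells_per_group=3, mea_duration_s=120.0,
                    n_mea_electrodes=16)
    outdir = run_pipeline(cfg)
    print((outdir / "stats_report.txt").read_text())
    print(f"run complete: {outdir}")


if __name__ == "__main__":
    main()
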