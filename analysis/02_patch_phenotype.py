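#!/usr/bin/env python
"""Current-clamp phenotype of the synthetic cohort.

Simulates control and SK-upregulated ("variant") neurons at weeks 3-5,
extracts AP and AHP features (threshold, amplitude, half-width, fAHP,
post-train mAHP/sAHP, R_N, QC), and tests the genotype and genotype-by-week
effects with the two-way ANOVA.  Writes results/cell_features.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from ephyskit import stats
from ephyskit.config import RunConfig
from ephyskit.pipeline import _extract_cell_features

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cfg = RunConfig(seed=11, n_cells_per_group=4)
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for group in cfg.groups:
        for week in cfg.weeks:
            print(f"simulating {group} week {week} ...")
            rows.extend(_extract_cell_features(cfg, rng, group, week))
    df = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "cell_features.csv", index=False)

    print(f"\n{df.groupby(['group', 'week'])[['half_width_ms', 'mahp_mv', 'sahp_mv']].mean().round(3)}")
    print(f"\nQC pass rate: {df.qc_pass.mean():.0%}")
    for metric in ("mahp_mv", "sahp_mv", "half_width_ms"):
        sub = df.dropna(subset=[metric])
        res = stats.two_way_anova(sub, metric, "group", "week")
        print(f"{metric}: genotype {res.f_string('group')}; "
              f"interaction {res.f_string('group:week')}")
    print(f"wrote {OUT / 'cell_features.csv'}")


if __name__ == "__main__":
    main()
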