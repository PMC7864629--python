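#!/usr/bin/env python
"""Junction-potential correction for the whole-cell recordings.

Computes the stationary Henderson liquid junction potential between the
K-methyl-sulfate internal solution and the bicarbonate-buffered aCSF at
the 33 C bath temperature, and writes it to results/ljp.json.  This is
the correction added once to every reported membrane potential.
"""

import json
from pathlib import Path

from ephyskit.ljp import bicarbonate_acsf, compute_ljp, kmeso4_internal

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    pipette, bath = kmeso4_internal(), bicarbonate_acsf()
    corr = compute_ljp(pipette, bath)
    room = compute_ljp(kmeso4_internal(295.15), bicarbonate_acsf(295.15))
    print(f"LJP correction at 33 C: {corr:+.2f} mV "
          "(added to pipette-referenced potentials)")
    print(f"LJP correction at 22 C: {room:+.2f} mV")
    OUT.mkdir(exist_ok=True)
    (OUT / "ljp.json").write_text(json.dumps(
        {"ljp_correction_mv_33c": round(corr, 3),
         "ljp_correction_mv_22c": round(room, 3)}, indent=1))
    print(f"wrote {OUT / 'ljp.json'}")


if __name__ == "__main__":
    main()
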