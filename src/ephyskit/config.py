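"""Run configuration: YAML/JSON parameter files with strict validation.

Unknown keys are rejected (with their path) so typos never silently fall
back to defaults; every effective parameter is echoed into the run
manifest for provenance.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Parameters of one end-to-end pipeline run."""

    seed: int = 0
    output_dir: str = "results/run"
    log_level: str = "INFO"
    # cohort design
    n_cells_per_group: int = 4
    n_wells_per_group: int = 4
    groups: list = field(default_factory=lambda: ["control", "variant"])
    weeks: list = field(default_factory=lambda: [3, 4, 5])
    # analysis knobs
    burst_min_surprise: float = 10.0
    burst_seed_factor: float = 0.5
    burst_min_spikes: int = 3
    qc_max_rs_mohm: float = 30.0
    qc_min_rn_mohm: float = 200.0
    qc_max_vrest_mv: float = -45.0
    qc_min_ap_amplitude_mv: float = 80.0
    tau_fit_window_ms: list = field(default_factory=lambda: [50.0, 1000.0])
    mea_duration_s: float = 300.0
    n_mea_electrodes: int = 64
    # simulation knobs (effect sizes of the synthetic variant phenotype)
    variant_gsk_scale: float = 3.0
    variant_burst_rate_scale: float = 2.0
    train_pulse_amplitude_pa: float = 1200.0

    def as_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> RunConfig:
    """Load a YAML/JSON config file, apply overrides, reject unknown keys."""
    data: dict = {}
    if path is not None:
        path = Path(path)
        text = path.read_text()
        data = (json.loads(text) if path.suffix == ".json"
                else yaml.safe_load(text)) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a mapping")
    if overrides:
        data.update(overrides)
    valid = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - valid
    if unknown:
        raise ValueError(
            f"unknown config key(s): {sorted(unknown)}; valid keys are "
            f"{sorted(valid)}")
    return RunConfig(**data)
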