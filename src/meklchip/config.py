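"""Run configuration: one flat record of every tunable parameter.

Defaults follow the analysis conventions of the method: per-probe t-test
cutoff p < 0.005, regions require >= 3 probes, clustering gap and
smoothing / CpG-density windows of 300 bp (the typical sonication
fragment size), signal-score threshold 0.85, CpG-island O/E threshold
0.6, and QPCR fold-enrichment threshold 2.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    # global
    seed: int = 7
    outdir: str = "mekl_run"
    group1: str = "retina"
    group2: str = "brain"

    # simulation
    genome_length: int = 2_000_000
    island_fraction: float = 0.06
    island_length: int = 2000
    n_dmrs: int = 50
    meth_high: float = 0.9
    meth_low: float = 0.1
    baseline_methylation: float = 0.3
    spacing: int = 35
    probe_length: int = 50
    n_control: int = 2000
    n_antigenomic: int = 2000
    input_ng: float = 250
    replicates: int = 3
    low_input_ngs: tuple[float, ...] = (10, 25, 50)
    dye_bias_strength: float = 0.4

    # preprocessing
    span: float = 0.4
    background_quantile: float = 0.90
    signal_threshold: float = 0.85
    intensity_floor: float = 1.0
    dye_method: str = "spline"

    # calling
    p_cutoff: float = 0.005
    min_probes: int = 3
    max_gap: int = 300
    window: int = 300

    # annotation
    half_window: int = 300
    island_oe: float = 0.6

    # concordance
    n_perm: int = 1000

    # qpcr
    qpcr_threshold: float = 2.0

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["low_input_ngs"] = list(self.low_input_ngs)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "low_input_ngs" in d:
            d["low_input_ngs"] = tuple(d["low_input_ngs"])
        return cls(**d)

    def derive_seed(self, stage: int) -> int:
        """Deterministic sub-seed per pipeline stage, kept below 2**31."""
        return (self.seed * 1_000_003 + stage) % (2**31)
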