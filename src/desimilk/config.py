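"""Pipeline configuration: one structured file driving every stage.

Defaults equal the published acquisition/modelling settings wherever one
exists (mass region 100-2000, bin width 0.2 Da, intensity limit 1e6
counts, 20% holdout, 5 sigma outlier threshold, S-plot thresholds
0.5 / 0.05); everything else is this package's documented choice.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    seed: int = 0
    # binning grid
    mz_low: float = 100.0
    mz_high: float = 2000.0
    bin_width: float = 0.2
    intensity_limit: float = 1.0e6
    # preprocessing
    tic_normalise: bool = True  # classification pipelines; S-plot runs without
    scaling: str = "pareto"
    per_spectrum: bool = True  # spectrum-level CCR counting
    # PCA/LDA
    r2x_target: float = 0.95
    max_pcs: int = 60
    n_pcs: int | None = None
    outlier_sigma: float = 5.0
    holdout_fraction: float = 0.2
    bootstrap_repeats: int = 25
    # OPLS-DA
    n_orth: int = 1
    q2_folds: int = 7
    n_permutations: int = 100
    pcorr_min: float = 0.5
    p1_min: float = 0.05
    # annotation
    match_tol_ppm: float = 10.0
    # LOD
    lod_criterion: float = 0.8
    lod_repeats: int = 10
    # simulation
    sim_scale: float = 1.0  # fraction of the full study sample counts
    sim_mixture_samples_per_level: int = 6
    effect_size: float = 1.0

    def __post_init__(self) -> None:
        if self.scaling not in ("center", "pareto", "unit_variance"):
            raise ValueError(f"unknown scaling {self.scaling!r}")
        if not 0 < self.holdout_fraction < 1:
            raise ValueError("holdout_fraction must be in (0, 1)")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        if unknown := set(data) - known:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
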