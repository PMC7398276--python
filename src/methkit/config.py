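"""Run configuration: every calling threshold in one overridable place."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class Thresholds:
    hypo_margin: float = 0.3          # bulk-baseline hypomethylation margin
    event_delta: float = 0.1          # loss/gain event size per stage interval
    dms_max_gap: int = 250            # bp between mergeable DMSs
    dms_min_per_dmr: int = 3
    dms_fdr: float = 0.01
    dms_permutations: int = 1000
    dmv_threshold: float = 0.15       # 1-kb bin mCG below this joins a DMV run
    dmv_min_bins: int = 5
    pmd_min_length: int = 100_000
    pmd_trees: int = 1000
    mch_min_length: int = 15_000
    mch_min_bins: int = 3
    mch_elevation: float = 1.5        # chunk / neighbour level ratio
    mch_pseudo: float = 0.001
    enhancer_score_cutoff: float = 0.3
    extension_width: int = 400        # size-normalised region width (bp)
    permutations: int = 1000          # Monte-Carlo shuffle count

    def validate(self) -> None:
        checks = [
            (0 < self.hypo_margin <= 1, "hypo_margin must lie in (0, 1]"),
            (0 < self.event_delta <= 1, "event_delta must lie in (0, 1]"),
            (self.dms_max_gap > 0, "dms_max_gap must be positive"),
            (self.dms_min_per_dmr >= 1, "dms_min_per_dmr must be >= 1"),
            (0 < self.dms_fdr < 1, "dms_fdr must lie in (0, 1)"),
            (0 < self.dmv_threshold < 1, "dmv_threshold must lie in (0, 1)"),
            (self.dmv_min_bins >= 1, "dmv_min_bins must be >= 1"),
            (self.pmd_min_length > 0, "pmd_min_length must be positive"),
            (self.mch_elevation > 1, "mch_elevation must exceed 1"),
            (self.mch_pseudo > 0, "mch_pseudo must be positive"),
            (self.permutations >= 1, "permutations must be >= 1"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(msg)


@dataclass
class RunConfig:
    preset: str = "tiny"
    seed: int = 0
    outdir: str = "run"
    thresholds: Thresholds = field(default_factory=Thresholds)

    def validate(self) -> None:
        self.thresholds.validate()
        if self.seed < 0:
            raise ValueError("seed must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        thr = Thresholds(**raw.pop("thresholds", {}))
        cfg = cls(**{k: v for k, v in raw.items() if k in ("preset", "seed", "outdir")},
                  thresholds=thr)
        cfg.validate()
        return cfg
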