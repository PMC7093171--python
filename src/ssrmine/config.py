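"""Pipeline configuration: one serialisable object covering every stage.

Every option has a documented default; the effective configuration is
hashed (sha256 of its canonical JSON) and the hash is echoed into every
report header so mixed-config comparisons are detectable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .markers import ScreenConfig
from .mining import MiningThresholds

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Defaults for the whole mine -> regions -> stats -> markers -> popgen run.

    thresholds      minimum repeat copy number per unit length (mono..hexa)
    boundary_rule   region assignment rule for boundary-spanning loci
                    (only "start" is implemented: label by start coordinate)
    te_exclusive    if True, TE-resident loci are removed from base-class
                    tallies instead of being double-reported in the overlay
    sd_ddof         SD denominator for the CV statistic (1 = sample SD)
    table_decimals  rounding of displayed percentages / #/Mb / GC columns
    screen          tetranucleotide marker screen settings
    unbiased_he     use Nei's 2n/(2n-1) correction for He
    rarefaction_g   gene-copy count for allelic richness (None = min 2N)
    hwe_max_enum    exact-enumeration bound for the HWE test (arrays)
    hwe_mc_reps     Monte-Carlo replicates past that bound
    hwe_alpha       P threshold for flagging HWE deviation
    seed            seed for every stochastic step
    """

    thresholds: MiningThresholds = field(default_factory=MiningThresholds)
    boundary_rule: str = "start"
    te_exclusive: bool = False
    sd_ddof: int = 1
    table_decimals: int = 2
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    unbiased_he: bool = True
    rarefaction_g: int | None = None
    hwe_max_enum: int = 200_000
    hwe_mc_reps: int = 100_000
    hwe_alpha: float = 0.01
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["thresholds"] = {str(k): v for k, v in self.thresholds.min_rcn.items()}
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "thresholds" in d:
            d["thresholds"] = MiningThresholds({int(k): int(v) for k, v in d["thresholds"].items()})
        if "screen" in d and isinstance(d["screen"], dict):
            d["screen"] = ScreenConfig(**d["screen"])
        return cls(**d)

    @classmethod
    def from_json_file(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def config_hash(self) -> str:
        """Short sha256 digest of the canonical JSON form."""
        canon = json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(canon.encode()).hexdigest()[:12]
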