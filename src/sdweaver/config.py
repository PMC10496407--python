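"""Run configuration: every tunable in one serializable record.

A run always writes its fully-resolved configuration next to its
outputs so results can be reproduced exactly; loading rejects unknown
keys.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path


@dataclass
class RunConfig:
    """All assembler/simulator tunables with their defaults.

    The clustering floor is ``min_frac`` x the expected full-anchor-span
    coverage (derived from ``coverage``, ``read_mean`` and
    ``anchor_len``); ``min_f2`` of None selects the automatic
    depth-dependent cis-morphism threshold.
    """

    # recruitment
    k: int = 15
    w: int = 10
    min_cov_frac: float = 0.5
    # clustering
    min_f2: float | None = None
    max_sites: int = 200
    max_dist: float = 0.4
    min_shared: int = 3
    min_frac: float = 0.8
    n_sim: int = 100
    # assembly / extension
    flank: int | None = None        # default: read_mean / 2
    step_cap: int | None = None     # default: read_mean / 2
    anchor_len: int = 2000
    min_reads: int = 5
    max_iters: int = 500
    polish_rounds: int = 2
    trim_frac: float = 0.5
    q_cap: float = 60.0
    # data model
    coverage: float = 40.0
    error_rate: float = 0.15
    error_profile: str = "clr"      # 'clr' or 'hifi'
    read_mean: float = 5000.0
    read_sd: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.error_profile not in ("clr", "hifi"):
            raise ValueError("error_profile must be 'clr' or 'hifi'")

    @property
    def noise_fraction(self) -> float:
        """Expected frequency of one specific wrong base from sequencing
        error alone (substitution share of the error rate / 3 bases)."""
        return self.error_rate * 0.6 / 3.0

    @property
    def profile_min_f2(self) -> float:
        """Fixed per-technology threshold used when min_f2 is not None
        and not set explicitly: 0.25 for CLR-like, 0.10 for HiFi-like."""
        return 0.25 if self.error_profile == "clr" else 0.10

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for key, value in self.to_dict().items():
                fh.write(f"{key}={'' if value is None else value}\n")

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs: dict = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, raw = line.partition("=")
                if key not in fields:
                    raise KeyError(f"unknown config key: {key!r}")
                if raw == "":
                    kwargs[key] = None
                    continue
                ann = str(fields[key].type)
                if "int" in ann:
                    kwargs[key] = int(raw)
                elif "float" in ann:
                    kwargs[key] = float(raw)
                else:
                    kwargs[key] = raw
        return cls(**kwargs)
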