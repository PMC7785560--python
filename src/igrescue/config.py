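"""Run configuration: defaults, YAML/JSON loading, seed streams, hashing.

Every stage parameter has a default; the effective configuration is
echoed verbatim (JSON) into the output directory, and artifacts carry
its hash so any output can be traced to the exact parameter set.  All
randomness flows from the single top-level seed through named child
streams, so stages are individually reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml


@dataclass
class RunConfig:
    # paths
    germline_dir: str = ""
    reads: str = ""
    reads2: str = ""
    out_dir: str = "igrescue_out"
    sample_id: str = "sample"
    seed: int = 0
    # simulation
    n_clones: int = 51
    dominance: float = 0.6
    shm_rate: float = 0.02
    dominant_shm: int = 15  # nonsilent SHMs planted in the dominant clone
    n_igseq_reads: int = 20000
    n_fragments: int = 4000
    read_len: int = 150
    error_rate: float = 0.005
    damage_rate: float = 0.002
    # junction calling
    min_v_identity: float = 0.85
    min_aligned_nt: int = 30
    ratio_threshold: float = 20.0
    max_mismatches: int = 2
    # assembly
    filter_min_identity: float = 0.80
    filter_mode: str = "identity"
    min_overlap: int = 20
    min_overlap_identity: float = 0.95
    min_coverage: int = 2
    branch_ratio: float = 0.8
    max_iterations: int = 10000
    c_cap: int = 60

    @classmethod
    def load(cls, path: str | Path | None = None, **overrides) -> "RunConfig":
        data: dict = {}
        if path is not None:
            text = Path(path).read_text()
            data = yaml.safe_load(text) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    #: fields that locate files rather than parameterize the computation;
    #: excluded from the config hash so identical analyses hash identically
    _PATH_FIELDS = ("germline_dir", "reads", "reads2", "out_dir")

    @property
    def hash(self) -> str:
        payload = {
            k: v for k, v in self.to_dict().items() if k not in self._PATH_FIELDS
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def echo(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "config.json", "w") as fh:
            json.dump(
                {"config_hash": self.hash, **self.to_dict()},
                fh, indent=2, sort_keys=True,
            )
            fh.write("\n")

    def child_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the top-level seed."""
        ss = np.random.SeedSequence([self.seed, int.from_bytes(
            hashlib.sha256(stage.encode()).digest()[:4], "big")])
        return int(ss.generate_state(1)[0] % (2**31))
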