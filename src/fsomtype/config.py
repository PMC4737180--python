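"""Run configuration: defaults, flat key=value files, provenance stamps."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, fields
from pathlib import Path

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All pipeline defaults in one serializable place.

    Defaults follow the method's stated parameters where it states them
    (+/-200 bp flanks at 20 bp resolution, k scanned from 4, FDR 0.05,
    5% membership-sharing edge cutoff, 4 super-groups); the remaining
    knobs are this package's documented choices.
    """

    flank_bp: int = 200
    bin_size: int = 20
    max_gap: int = 2
    band_radius: float = 5.0
    rows: int = 3
    cols: int = 3
    epochs: int = 30
    alpha0: float = 0.5
    alphaT: float = 0.01
    sigmaT: float = 0.5
    theta: float = 1.0
    k_min: int = 4
    K: int = 8
    m: int = 50
    M: int = 16
    delta_min: float = 0.025
    fdr_level: float = 0.05
    min_members: int = 5
    min_edge: float = 0.05
    n_groups: int = 4
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Parse a flat key=value text file; unknown keys are rejected."""
        known = {f.name: f.type for f in fields(cls)}
        kwargs = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            typ = known[key]
            kwargs[key] = int(value) if typ == "int" else float(value)
        return cls(**kwargs)

    def to_file(self, path: str | Path) -> None:
        lines = [f"{k}={v}" for k, v in sorted(asdict(self).items())]
        Path(path).write_text("\n".join(lines) + "\n")

    def digest(self) -> str:
        """Short stable hash identifying this configuration."""
        payload = ";".join(f"{k}={v}" for k, v in sorted(asdict(self).items()))
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def stamp(self) -> str:
        return f"config_hash={self.digest()} seed={self.seed}"
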