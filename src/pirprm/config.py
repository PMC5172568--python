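"""Run configuration: linker constants, modes, tolerances, labels.

A ``RunConfig`` is fully serializable to YAML; every CLI command echoes the
effective configuration (and its hash) into the output directory so a run
can be reproduced from its outputs alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Tuple

import yaml

from .crosslink_model import PIRLinker
from .prm_quant import MatchOptions

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    # linker constants (Da; reporter is an m/z)
    linker_name: str = "BDP"
    stump_residual: float = 197.032
    longarm_residual: float = 948.444
    reporter_mz: float = 752.412
    intact_added_mass: Optional[float] = None  # defaults to stump + longarm

    # transition generation
    precursor_mode: str = "most_abundant"  # most_abundant | monoisotopic | observed
    released_charges: Tuple[int, ...] = (1,)
    longarm_charges: Tuple[int, ...] = (1,)
    by_charges: Tuple[int, ...] = (1,)
    include_reporter: bool = False
    carbamidomethyl_cys: bool = True
    molecule_list_name: Optional[str] = None

    # quantification tolerances
    isolation_window: float = 3.0
    ppm_tol: float = 10.0
    abs_floor: float = 0.005
    smooth: bool = False
    top_n: int = 3

    def linker(self) -> PIRLinker:
        return PIRLinker(
            name=self.linker_name,
            stump_residual=self.stump_residual,
            longarm_residual=self.longarm_residual,
            reporter_mz=self.reporter_mz,
            intact_added_mass=self.intact_added_mass,
        )

    def match_options(self) -> MatchOptions:
        return MatchOptions(
            isolation_window=self.isolation_window,
            ppm_tol=self.ppm_tol,
            abs_floor=self.abs_floor,
            smooth=self.smooth,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("released_charges", "longarm_charges", "by_charges"):
            d[key] = list(d[key])
        return d

    def digest(self) -> str:
        """Stable short hash of the effective configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def dump(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def load_config(path=None, **overrides) -> RunConfig:
    """Load a YAML config file (if given) and apply keyword overrides."""
    data = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    for key in ("released_charges", "longarm_charges", "by_charges"):
        if key in data:
            data[key] = tuple(data[key])
    return RunConfig(**data)
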