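"""YAML configuration loading for compound, partition and kinetic parameters.

Shipped defaults live under ``alpbpk/data/``; any loader accepts a path to a
user-supplied file with the same schema.  Validation is delegated to the
pydantic domain types.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Optional, Union

import yaml

from .compound import CompoundProperties
from .pbpk import PBPKParameterSet, TissuePartitionMap
from .physiology import PhysiologyProfile, build_physiology

__all__ = [
    "load_compound",
    "load_partition_map",
    "load_pbpk_params",
    "load_physiology",
]

PathLike = Union[str, Path]


def _read_yaml(name: str, path: Optional[PathLike]) -> dict:
    if path is not None:
        with open(path) as fh:
            return yaml.safe_load(fh)
    ref = resources.files("alpbpk").joinpath(f"data/{name}")
    return yaml.safe_load(ref.read_text())


def load_compound(path: Optional[PathLike] = None) -> CompoundProperties:
    """Compound properties from YAML (packaged atractylodin defaults)."""
    return CompoundProperties(**_read_yaml("compound.yaml", path))


def load_partition_map(path: Optional[PathLike] = None) -> TissuePartitionMap:
    """Per-tissue Kp values from YAML."""
    return TissuePartitionMap(kp=_read_yaml("kp.yaml", path))


def load_pbpk_params(path: Optional[PathLike] = None) -> PBPKParameterSet:
    """Calibrated kinetic parameters from YAML."""
    return PBPKParameterSet(**_read_yaml("pbpk_params.yaml", path))


def load_physiology(path: Optional[PathLike] = None) -> PhysiologyProfile:
    """Subject physiology from YAML (``body_weight``/``age``), scaled from
    the packaged reference tables."""
    data = _read_yaml("physiology.yaml", path)
    return build_physiology(body_weight=data.get("body_weight", 60.0),
                            age=data.get("age", 40.0))
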