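"""Schema-validated run configuration (YAML).

A run is fully determined by (config, global seed): every stochastic
operation derives its own seed deterministically from the global one, so
identical inputs give byte-identical numeric outputs on one platform.
Unknown keys are rejected and all schema violations are reported at once.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .params import FundamentalConstants

__all__ = ["RunConfig", "load_config", "dump_config", "derive_seed"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ModelBlock(_Strict):
    dimension: str = "2D"
    d_plus: float = Field(ge=0)
    d_minus: float = Field(ge=0)
    e_plus: float = Field(ge=0)
    e_minus: float = Field(ge=0)
    k_plus: float = Field(ge=0)
    k_minus: float = Field(ge=0)
    R_total: float = Field(default=1.0, ge=0)
    L_total: float = Field(default=1.0, ge=0)

    @model_validator(mode="after")
    def _check_dimension(self):
        if self.dimension not in ("2D", "3D"):
            raise ValueError("dimension must be '2D' or '3D'")
        return self

    def constants(self) -> FundamentalConstants:
        return FundamentalConstants(
            dimension=self.dimension,  # type: ignore[arg-type]
            d_plus=self.d_plus, d_minus=self.d_minus,
            e_plus=self.e_plus, e_minus=self.e_minus,
            k_plus=self.k_plus, k_minus=self.k_minus,
        )


class GeometryBlock(_Strict):
    D: float = Field(default=0.1, gt=0)
    b: float = Field(default=0.1, gt=0)
    a: float = Field(default=0.005, gt=0)
    v: float = Field(default=1.0e4, gt=0)
    h: float = Field(default=50.0, gt=0)
    L_cell: float = Field(default=1000.0, gt=0)


class PanelBlock(_Strict):
    n: int = Field(default=6, ge=2)
    fold_k_plus: float = Field(default=1e3, gt=0)
    fold_k_minus: float = Field(default=10.0, gt=0)
    k_plus_max: float = Field(default=1.0, gt=0)
    k_minus_max: float = Field(default=0.5, gt=0)
    coupling: str = "affinity"
    jitter: float = Field(default=0.0, ge=0)


class TFBlock(_Strict):
    n_lifetimes: int = Field(default=10_000, ge=1)


class AFBlock(_Strict):
    m_r: float = Field(default=50.0, gt=0)
    m_l: float = Field(default=50.0, gt=0)
    A_c: float = Field(default=3.0, gt=0)
    contact_times: list[float] = Field(
        default_factory=lambda: [0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0]
    )
    cycles: int = Field(default=2000, ge=1)


class SPRBlock(_Strict):
    concentration: float = Field(default=1e-6, ge=0)
    t_assoc_end: float = Field(default=60.0, gt=0)
    t_total: float = Field(default=180.0, gt=0)
    n_points: int = Field(default=500, ge=10)
    R_max: float = Field(default=100.0, gt=0)
    noise_sd: float = Field(default=1.0, ge=0)


class FretBlock(_Strict):
    t_max: float = Field(default=10.0, gt=0)
    n_points: int = Field(default=200, ge=10)
    noise_sd: float = Field(default=0.0, ge=0)


class AssayBlocks(_Strict):
    tf: TFBlock = TFBlock()
    af: AFBlock = AFBlock()
    spr: SPRBlock = SPRBlock()
    fret: FretBlock = FretBlock()


class RunConfig(_Strict):
    model: ModelBlock
    geometry: GeometryBlock = GeometryBlock()
    panel: PanelBlock = PanelBlock()
    assays: AssayBlocks = AssayBlocks()
    seed: int = Field(default=0, ge=0, lt=2**31)
    output_dir: str = "kinetrans-out"
    conservation_rtol: float = Field(default=1e-8, gt=0)
    timescale_threshold: float = Field(default=1e-2, gt=0)


def load_config(path) -> RunConfig:
    """Load and validate a YAML configuration.

    All schema violations are reported together in the raised error, not
    just the first.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    try:
        return RunConfig(**data)
    except ValidationError as exc:
        lines = [
            f"  {'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
            for err in exc.errors()
        ]
        raise ValueError("invalid configuration:\n" + "\n".join(lines)) from exc


def dump_config(config: RunConfig) -> str:
    """Serialize a configuration back to YAML (round-trip stable)."""
    return yaml.safe_dump(config.model_dump(), sort_keys=True)


def derive_seed(global_seed: int, label: str) -> int:
    """Deterministic per-operation seed below 2^31 from the global seed."""
    folded = int.from_bytes(label.encode()[:8].ljust(8, b"\0"), "little") % (2**31)
    ss = np.random.SeedSequence([global_seed, folded])
    return int(ss.generate_state(1)[0] % (2**31))
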