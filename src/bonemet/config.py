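"""Run configuration: one flat dataclass, YAML round-trip, CLI overrides."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Every stage parameter with a default; round-trips through YAML."""

    # inputs / outputs
    expression_tsv: str | None = None
    groups_tsv: str | None = None
    image_dir: str | None = None
    group_manifest: str | None = None
    variant_table: str | None = None
    times_csv: str | None = None
    output_dir: str = "bonemet_out"

    # expression axis
    from_group: str = "BMD"
    to_group: str = "TMD"
    k_per_end: int = 10

    # morphometrics
    threshold_method: str | float = "otsu"
    min_size: float = 50.0
    fill_holes: bool = True
    pixel_size: float = 1.0
    write_masks: bool = False

    # assays
    variance_window: int = 15
    spot_min_area: float = 5.0
    elapsed_hours: float = 24.0
    n_bins: int = 20

    # variants
    min_af: float = 0.0
    classes: list[str] = field(
        default_factory=lambda: ["stop_gain", "missense"]
    )

    # simulation
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)
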