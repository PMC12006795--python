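"""Pipeline configuration: every analysis threshold in one place.

Plain key=value text config with a fixed schema; unknown keys are errors
so threshold-name typos cannot silently fall back to defaults. CLI flags
override config values, which override defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from pathlib import Path


@dataclass(frozen=True)
class PipelineConfig:
    bin_size: int = 200
    end_trim: int = 200
    trim_both_ends: bool = False
    include_mito: bool = False
    fc_threshold: float = 2.0
    fdr_threshold: float = 0.01
    residual_threshold: float = 2.576
    min_peak_len: int = 100
    cds_cover_frac: float = 0.30
    subregion_cover_frac: float = 0.90
    upstream: int = 1000
    n_subregions: int = 5
    urs_window_lo: int = -600
    urs_window_hi: int = -100
    urs_tile_width: int = 100
    peak_q: float = 0.01
    local_halfwidth: int = 5
    spike_fraction_expected: float = 0.10
    use_spike_size_factors: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "fc_threshold",
            "fdr_threshold",
            "residual_threshold",
            "min_peak_len",
            "peak_q",
            "bin_size",
            "upstream",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("cds_cover_frac", "subregion_cover_frac"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")


_BOOL = {"true": True, "false": False, "1": True, "0": False, "yes": True, "no": False}


def load_config(path: str | Path | None, **overrides) -> PipelineConfig:
    """Load key=value config; unknown keys raise; overrides win."""
    cfg = PipelineConfig()
    valid = {f.name: f.type for f in fields(PipelineConfig)}
    values: dict = {}
    if path is not None:
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"config line {lineno}: expected key=value")
            key, raw = (s.strip() for s in line.split("=", 1))
            if key not in valid:
                raise ValueError(f"config line {lineno}: unknown key {key!r}")
            current = getattr(cfg, key)
            if isinstance(current, bool):
                if raw.lower() not in _BOOL:
                    raise ValueError(f"config line {lineno}: bad boolean {raw!r}")
                values[key] = _BOOL[raw.lower()]
            elif isinstance(current, int):
                values[key] = int(raw)
            else:
                values[key] = float(raw)
    values.update({k: v for k, v in overrides.items() if v is not None})
    bad = set(values) - set(valid)
    if bad:
        raise ValueError(f"unknown config keys: {sorted(bad)}")
    return replace(cfg, **values)


def dump_config(cfg: PipelineConfig, path: str | Path) -> None:
    lines = [f"{f.name} = {getattr(cfg, f.name)}" for f in fields(PipelineConfig)]
    Path(path).write_text("\n".join(lines) + "\n")
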