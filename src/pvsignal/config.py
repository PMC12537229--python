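"""Pipeline configuration: structured file in, validated dataclass out."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .contingency import load_pt_soc_map
from .disprop import SignalThresholds
from .faers_io import AnalysisConfig, read_table
from .synthetic import SyntheticConfig, generate

__all__ = ["PipelineConfig", "load_config", "load_tables"]


class ConfigurationError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Where the tables come from and how the analysis runs.

    Exactly one of ``input_dir`` (a directory holding DEMO/DRUG/REAC/THER
    ``.txt`` files) or ``synthetic`` (a generator spec) must be set.
    """

    input_dir: str | None = None
    synthetic: SyntheticConfig | None = None
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    thresholds: SignalThresholds | None = None
    pt_soc_map: str | None = None  # path to a pt<TAB>soc TSV; None = packaged map
    ic_mode: str = "fixed_offset"
    yates: bool = False
    top: int | None = None
    zero_day_value: float = 0.5
    out_dir: str | None = None

    def check(self) -> None:
        if (self.input_dir is None) == (self.synthetic is None):
            raise ConfigurationError(
                "exactly one of 'input_dir' or 'synthetic' must be configured"
            )
        if self.input_dir is not None and not Path(self.input_dir).is_dir():
            raise ConfigurationError(f"input_dir does not exist: {self.input_dir}")

    def resolve_pt_soc_map(self) -> dict[str, str]:
        if self.pt_soc_map:
            return load_pt_soc_map(self.pt_soc_map)
        from .synthetic import packaged_pt_soc_map

        return packaged_pt_soc_map()


def load_tables(config: PipelineConfig):
    """Materialise the four tables from disk or from the generator."""
    if config.synthetic is not None:
        tables = generate(config.synthetic)
        return tables.demo, tables.drug, tables.reac, tables.ther
    base = Path(config.input_dir)
    out = []
    for kind in ("DEMO", "DRUG", "REAC", "THER"):
        path = base / f"{kind}.txt"
        if not path.exists():
            gz = base / f"{kind}.txt.gz"
            if gz.exists():
                path = gz
            else:
                raise ConfigurationError(f"missing input table: {path}")
        out.append(read_table(path, kind))
    return tuple(out)


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML pipeline config.

    Top-level keys mirror :class:`PipelineConfig`; ``analysis``,
    ``thresholds`` and ``synthetic`` are nested mappings whose keys mirror
    the corresponding dataclasses.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs: dict = {}
    for key in ("input_dir", "pt_soc_map", "ic_mode", "yates", "top",
                "zero_day_value", "out_dir"):
        if key in raw:
            kwargs[key] = raw[key]
    if "analysis" in raw:
        a = dict(raw["analysis"])
        for setkey in ("synonyms", "roles"):
            if setkey in a:
                a[setkey] = set(a[setkey])
        kwargs["analysis"] = AnalysisConfig(**a)
    if "thresholds" in raw:
        kwargs["thresholds"] = SignalThresholds(**raw["thresholds"])
    if "synthetic" in raw:
        kwargs["synthetic"] = SyntheticConfig(**raw["synthetic"])
    unknown = set(raw) - {"input_dir", "pt_soc_map", "ic_mode", "yates", "top",
                          "zero_day_value", "out_dir", "analysis", "thresholds",
                          "synthetic"}
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**kwargs)
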