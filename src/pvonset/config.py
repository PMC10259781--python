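"""Pipeline configuration, loadable from YAML.

One file describes a whole run: where the four tables live and how their
columns map onto the schema, which term list defines the target event,
the study drug, the drug lists behind the covariates, the dose band edges,
and the time-to-onset settings. Everything has a default matching the
bundled synthetic dumps, so a minimal config only names the table paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .cohort import CohortConfig, bundled_drug_list, load_drug_list
from .errors import ConfigurationError


@dataclass
class PipelineConfig:
    tables_dir: Path = Path(".")
    table_files: dict[str, str] = field(
        default_factory=lambda: {
            "DEMO": "DEMO.csv", "DRUG": "DRUG.csv",
            "REAC": "REAC.csv", "HIST": "HIST.csv",
        }
    )
    column_mapping: dict[str, dict[str, str]] = field(default_factory=dict)
    delimiter: str = ","
    encoding: str = "utf-8"

    term_list: Optional[Path] = None  # None -> bundled demo list
    drug_name: str = "clozapine"
    antipsychotic_list: Optional[Path] = None
    antiepileptic_list: Optional[Path] = None

    dose_low_edge: float = 200.0
    dose_high_edge: float = 400.0
    lithium_edge: float = 600.0
    dose_rule: str = "max"
    sex_reference: str = "male"

    window_days: int = 1095
    day_convention: str = "plus_one"
    histogram_bin_days: float = 30.0

    out_dir: Path = Path("pvonset_out")
    seed: int = 0

    def table_path(self, kind: str) -> Path:
        return Path(self.tables_dir) / self.table_files[kind]

    def cohort_config(self) -> CohortConfig:
        aps = (
            load_drug_list(self.antipsychotic_list)
            if self.antipsychotic_list
            else bundled_drug_list("antipsychotics.txt")
        )
        aes = (
            load_drug_list(self.antiepileptic_list)
            if self.antiepileptic_list
            else bundled_drug_list("antiepileptics.txt")
        )
        return CohortConfig(
            drug_name=self.drug_name,
            dose_low_edge=self.dose_low_edge,
            dose_high_edge=self.dose_high_edge,
            lithium_edge=self.lithium_edge,
            antipsychotics=aps,
            antiepileptics=aes,
            dose_rule=self.dose_rule,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("tables_dir", "term_list", "antipsychotic_list",
                    "antiepileptic_list", "out_dir"):
            if key in raw and raw[key] is not None:
                raw[key] = Path(raw[key])
        cfg = cls(**raw)
        if not 0 < cfg.dose_low_edge <= cfg.dose_high_edge:
            raise ConfigurationError("dose band edges must be positive and ordered")
        if cfg.window_days <= 0:
            raise ConfigurationError("window_days must be positive")
        return cfg
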