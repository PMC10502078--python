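"""Run configuration: a single structured YAML/JSON file collecting every
analysis threshold and path, with the published defaults spelled out."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .items import PLANT_ITEMS, SWEET_TREAT_ITEMS

SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Either ``simulate_n`` is set (a synthetic study with the demo ground
    truth is generated) or the genotype/cohort input paths are given.
    Thresholds default to the published conventions: interaction claimed at
    p < 0.15 for whole-GRS screens and p < 0.2 for per-SNP screens, with a
    dichotomized-score refit for borderline whole-GRS p-values in
    [0.15, 0.25).
    """

    seed: int = 0
    simulate_n: int | None = 1142
    genotypes_path: str | None = None
    genotype_format: str | None = None  # 'vcf' | 'tsv' | None (infer)
    panel_path: str | None = None  # None -> packaged default panel
    cohort_path: str | None = None
    ffq_path: str | None = None  # optional separate FFQ ratings CSV
    lms_path: str | None = None  # optional LMS reference (needs bmi column)
    schemes: list[str] = field(
        default_factory=lambda: ["unweighted", "speliotes", "finhit", "ratio"]
    )
    alpha_grs: float = 0.15
    alpha_snp: float = 0.2
    borderline_band: tuple[float, float] = (0.15, 0.25)
    screening_covariates: list[str] = field(
        default_factory=lambda: ["sex", "ltpa", "sleep", "pc1", "pc2"]
    )
    validation_model1: list[str] = field(default_factory=lambda: ["sex"])
    validation_model2: list[str] = field(
        default_factory=lambda: ["sex", "ltpa", "sleep"]
    )
    recode_mapping: dict[int, float] | None = None  # None -> default
    sti_items: list[str] = field(default_factory=lambda: list(SWEET_TREAT_ITEMS))
    pci_items: list[str] = field(default_factory=lambda: list(PLANT_ITEMS))
    figures: bool = False

    def __post_init__(self):
        if not 0.0 < self.alpha_grs < 1.0:
            raise ConfigurationError("alpha_grs must be in (0, 1)")
        if not 0.0 <= self.alpha_snp <= 1.0:
            raise ConfigurationError("alpha_snp must be in [0, 1]")
        self.borderline_band = tuple(self.borderline_band)  # type: ignore
        if self.simulate_n is None and (
            self.genotypes_path is None or self.cohort_path is None
        ):
            raise ConfigurationError(
                "either simulate_n or genotype+cohort paths must be given"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        version = raw.pop("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise ConfigurationError(
                f"unsupported config schema_version {version}"
            )
        if "recode_mapping" in raw and raw["recode_mapping"] is not None:
            raw["recode_mapping"] = {
                int(k): float(v) for k, v in raw["recode_mapping"].items()
            }
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["borderline_band"] = list(self.borderline_band)
        d = {"schema_version": SCHEMA_VERSION, **d}
        Path(path).write_text(
            yaml.safe_dump(d, sort_keys=True, default_flow_style=False)
        )
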