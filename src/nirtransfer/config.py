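"""Run configuration: YAML-backed, strictly validated, fingerprintable.

A run config fixes everything needed to reproduce a simulation or study
bit-for-bit: the wavenumber grid, the generator settings (brand designs,
silk variants, domain shifts, seed) and the study hyperparameters.
Unknown keys are rejected so that typos fail fast, and every run writes
the resolved config plus its fingerprint next to the outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .simulate import (
    BrandDesign,
    DomainShift,
    default_brand_designs,
    default_brand_shifts,
    default_four_brand_study,
    make_component_library,
    synthesize_dataset,
    _DEFAULT_SILK_VARIANTS,
)
from .io import default_grid
from .study import StudyConfig

__all__ = ["RunConfig", "load_config", "config_fingerprint"]


class ConfigError(ValueError):
    """A run-config document is malformed."""


def _from_mapping(cls, doc: dict, path: str):
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: expected a mapping, got {type(doc).__name__}")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(doc) - names
    if unknown:
        raise ConfigError(f"{path}: unknown key(s) {sorted(unknown)}")
    return cls(**doc)


@dataclass
class GridSpec:
    start: float = 10_000.0
    end: float = 4_000.0
    step: float = 4.0


@dataclass
class GeneratorSpec:
    seed: int = 0
    distinct_silk: bool = True
    noise_sd: float | None = None
    silk_variants: dict | None = None
    brands: dict | None = None      # brand -> {n_samples, silk_variant, ranges}
    shifts: dict | None = None      # brand -> DomainShift fields


@dataclass
class RunConfig:
    grid: GridSpec = field(default_factory=GridSpec)
    generator: GeneratorSpec = field(default_factory=GeneratorSpec)
    study: StudyConfig = field(default_factory=StudyConfig)

    # -- construction -----------------------------------------------------
    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        doc = dict(doc or {})
        unknown = set(doc) - {"grid", "generator", "study"}
        if unknown:
            raise ConfigError(f"unknown top-level key(s) {sorted(unknown)}")
        grid = _from_mapping(GridSpec, doc.get("grid", {}), "grid")
        gen = _from_mapping(GeneratorSpec, doc.get("generator", {}), "generator")
        study_doc = dict(doc.get("study", {}))
        for key in ("sweep_fractions", "sweep_methods"):
            if key in study_doc:
                study_doc[key] = tuple(study_doc[key])
        if "sweep_pairs" in study_doc:
            study_doc["sweep_pairs"] = tuple(tuple(p) for p in study_doc["sweep_pairs"])
        study = _from_mapping(StudyConfig, study_doc, "study")
        return cls(grid=grid, generator=gen, study=study)

    def to_dict(self) -> dict:
        return {
            "grid": dataclasses.asdict(self.grid),
            "generator": dataclasses.asdict(self.generator),
            "study": self.study.to_dict(),
        }

    # -- realization ------------------------------------------------------
    def wavenumbers(self):
        return default_grid(self.grid.start, self.grid.end, self.grid.step)

    def brand_shifts(self) -> dict:
        shifts = default_brand_shifts()
        for brand, fields_ in (self.generator.shifts or {}).items():
            shifts[brand] = _from_mapping(DomainShift, fields_, f"generator.shifts.{brand}")
        return shifts

    def make_datasets(self) -> dict:
        """Generate the configured multi-brand study."""
        gen = self.generator
        grid = self.wavenumbers()
        if gen.brands is None:
            return default_four_brand_study(
                gen.seed,
                shifts=self.brand_shifts() if gen.shifts else None,
                noise_sd=gen.noise_sd,
                distinct_silk=gen.distinct_silk,
                grid=grid,
            )
        variants = gen.silk_variants or (_DEFAULT_SILK_VARIANTS if gen.distinct_silk else None)
        library = make_component_library(grid, gen.seed, silk_variants=variants)
        shifts = self.brand_shifts()
        out = {}
        for brand, spec in gen.brands.items():
            spec = dict(spec)
            ranges = {c: tuple(r) for c, r in spec.pop("ranges").items()}
            design = BrandDesign(
                brand=brand,
                n_samples=spec.pop("n_samples"),
                component_ranges=ranges,
                silk_variant=spec.pop("silk_variant", None),
            )
            if spec:
                raise ConfigError(f"generator.brands.{brand}: unknown key(s) {sorted(spec)}")
            shift = shifts.get(brand, DomainShift.identity())
            if gen.noise_sd is not None:
                shift = dataclasses.replace(shift, noise_sd=gen.noise_sd)
            out[brand] = synthesize_dataset(library, design, shift, gen.seed)
        return out


def load_config(path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return RunConfig.from_dict(doc)


def config_fingerprint(cfg: RunConfig) -> str:
    """sha256 over the canonical JSON of the resolved config."""
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()
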