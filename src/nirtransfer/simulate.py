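"""Synthetic multi-brand blended-spectra generator.

Real formulated-blend NIR archives are proprietary, so the pipeline is
exercised on simulated data with the same statistical structure: each
sample is a mixture of raw-material powders (tobacco silk, cut stem,
fermented cut stem, expanded tobacco silk) whose spectrum is modelled as
a Beer-Lambert linear combination of pure-component *endmember* spectra,
plus a brand-specific instrumental/material shift (baseline offset, tilt,
gain) and i.i.d. Gaussian measurement noise.

Endmembers are sums of Gaussian absorption bands on a descending
wavenumber grid.  The default band centers sit at the absorption peaks
characteristic of plant-material NIR spectra (6780, 5760, 5130, 4700,
4280 cm^-1, with troughs near 6055, 5360, 4950, 4500, 4160 cm^-1);
amplitudes differ per component so that the blend proportion is
spectrally identifiable.  The tobacco-silk endmember may carry per-brand
*variants* (perturbed band amplitudes), mirroring the fact that the silk
component differs between brands while the stem components are shared.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .io import SpectralDataset, default_grid

__all__ = [
    "COMPONENTS",
    "ANALYTE",
    "ComponentLibrary",
    "BrandDesign",
    "DomainShift",
    "make_component_library",
    "sample_blend_design",
    "synthesize_dataset",
    "default_brand_designs",
    "default_brand_shifts",
    "default_four_brand_study",
]

COMPONENTS = ("tobacco_silk", "cut_stem", "fermented_cut_stem", "expanded_tobacco_silk")
ANALYTE = "tobacco_silk"

# (center cm^-1, width cm^-1) of the Gaussian bands shared by all
# endmembers; the five principal peaks plus two auxiliary bands that shape
# the short- and long-wave ends of the grid.
_PEAK_BANDS = ((6780.0, 250.0), (5760.0, 180.0), (5130.0, 150.0), (4700.0, 120.0), (4280.0, 95.0))
_AUX_BANDS = ((8800.0, 900.0), (4050.0, 80.0))

#: Relative overall absorptivity per raw material: leaf-derived silk
#: absorbs most, stem material less, expanded (puffed) silk least.
_COMPONENT_ABSORPTIVITY = {
    "tobacco_silk": 1.00,
    "cut_stem": 0.70,
    "fermented_cut_stem": 0.72,
    "expanded_tobacco_silk": 0.68,
}

#: Relative per-band shape jitter distinguishing components beyond their
#: overall intensity.
_SHAPE_JITTER = 0.25

#: Within-domain nuisance structure: smooth random spectral modes shared
#: by all brands (moisture, particle size, temperature drifts...), with
#: per-sample Gaussian coefficients.  Real NIR spectra have dozens of
#: such variance directions; they are what makes a 30-dimensional
#: adaptation subspace selective.
_N_NUISANCE_MODES = 22
_DEFAULT_NUISANCE_SD = 0.2  # coefficient sd, unit-norm modes


@dataclass
class ComponentLibrary:
    """Pure-component endmember spectra on a common grid.

    ``endmembers`` maps component names to spectra; brand-specific
    tobacco-silk variants are stored under ``tobacco_silk@<variant>``.
    ``band_params`` maps each endmember name to ``(baseline, bands)``
    where ``bands`` is a list of ``(center, width, amplitude)``.
    """

    wavenumbers: np.ndarray
    endmembers: dict
    band_params: dict
    nuisance_modes: np.ndarray | None = None  # (k, d), unit-norm smooth rows

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        d = self.wavenumbers.size
        for name, spec in self.endmembers.items():
            spec = np.asarray(spec, dtype=float)
            if spec.shape != (d,):
                raise ValueError(f"endmember {name!r} is not on the library grid")
            if np.min(spec) <= 0:
                raise ValueError(f"endmember {name!r} is not strictly positive")
            self.endmembers[name] = spec

    def endmember_for(self, component: str, silk_variant: str | None = None) -> np.ndarray:
        """Spectrum for ``component``, honouring a silk variant if requested."""
        if component == ANALYTE and silk_variant is not None:
            key = f"{ANALYTE}@{silk_variant}"
            if key not in self.endmembers:
                raise KeyError(f"library has no tobacco-silk variant {silk_variant!r}")
            return self.endmembers[key]
        if component not in self.endmembers:
            raise KeyError(f"library has no endmember for component {component!r}")
        return self.endmembers[component]


@dataclass
class BrandDesign:
    """Sampling design for one brand: sample count and blend-ratio boxes.

    ``component_ranges`` maps component name to ``(min %, max %)``;
    components absent from the map are fixed at exactly 0 %.
    """

    brand: str
    n_samples: int
    component_ranges: dict
    silk_variant: str | None = None

    def __post_init__(self) -> None:
        if ANALYTE not in self.component_ranges:
            raise ValueError(f"design for {self.brand!r} must include the analyte {ANALYTE!r}")
        lo_sum = sum(lo for lo, _ in self.component_ranges.values())
        hi_sum = sum(hi for _, hi in self.component_ranges.values())
        if lo_sum > 100 + 1e-9 or hi_sum < 100 - 1e-9:
            raise ValueError(
                f"infeasible design for {self.brand!r}: range minima sum to {lo_sum}, "
                f"maxima to {hi_sum}; compositions must sum to 100"
            )
        for comp, (lo, hi) in self.component_ranges.items():
            if not (0 <= lo <= hi <= 100):
                raise ValueError(f"bad range for {comp!r} in {self.brand!r}: ({lo}, {hi})")


@dataclass
class DomainShift:
    """Brand-level spectral perturbation applied on top of the mixture.

    additive_offset : absorbance units, flat baseline shift
    slope : absorbance per cm^-1, linear tilt across the grid
    multiplicative_gain : unitless scaling of the mixture spectrum
    noise_sd : absorbance units, i.i.d. Gaussian noise per grid point
    """

    additive_offset: float = 0.0
    slope: float = 0.0
    multiplicative_gain: float = 1.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.multiplicative_gain <= 0:
            raise ValueError("multiplicative_gain must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @classmethod
    def identity(cls) -> "DomainShift":
        return cls()


def _gaussian_bands(grid: np.ndarray, baseline: float, bands) -> np.ndarray:
    spec = np.full(grid.shape, baseline, dtype=float)
    for center, width, amp in bands:
        spec += amp * np.exp(-0.5 * ((grid - center) / width) ** 2)
    return spec


def make_component_library(
    grid: np.ndarray,
    seed: int,
    silk_variants: dict | None = None,
    amplitude_scale: float = 1.0,
    n_nuisance_modes: int = _N_NUISANCE_MODES,
) -> ComponentLibrary:
    """Build a seeded endmember library on ``grid``.

    Band amplitudes are drawn per component; the fermented cut stem is a
    mild perturbation of the cut stem (both are stem material), while the
    expanded silk is drawn independently.  ``silk_variants`` maps variant
    identifiers to relative amplitude-perturbation scales; each variant is
    a tobacco-silk endmember whose band amplitudes are multiplied by
    ``1 + scale * u`` with ``u ~ Uniform(-1, 1)`` per band.
    ``amplitude_scale`` rescales every band amplitude (0 leaves only the
    baselines, mostly useful for degenerate-case testing).
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("grid must be non-empty")
    rng = np.random.default_rng(seed)
    bands_cw = _PEAK_BANDS + _AUX_BANDS

    # One shared band-amplitude pattern: the raw materials are all plant
    # matter with the same functional groups, so their spectra share the
    # band structure and differ chiefly in overall absorptivity
    # (_COMPONENT_ABSORPTIVITY) with a small per-component shape jitter.
    base_amps = np.concatenate([
        rng.uniform(0.15, 0.45, size=len(_PEAK_BANDS)),
        rng.uniform(0.10, 0.30, size=len(_AUX_BANDS)),
    ])
    base_baseline = rng.uniform(0.35, 0.45)
    baselines = {}
    amps: dict[str, np.ndarray] = {}
    for comp in COMPONENTS:
        alpha = _COMPONENT_ABSORPTIVITY[comp]
        jitter = 1.0 + _SHAPE_JITTER * rng.uniform(-1, 1, size=len(bands_cw))
        amps[comp] = alpha * base_amps * jitter
        baselines[comp] = alpha * base_baseline * (1.0 + 0.03 * rng.uniform(-1, 1))

    band_params: dict = {}
    endmembers: dict = {}
    for comp in COMPONENTS:
        bands = [
            (c, w, float(a) * amplitude_scale) for (c, w), a in zip(bands_cw, amps[comp])
        ]
        band_params[comp] = (baselines[comp], bands)
        endmembers[comp] = _gaussian_bands(grid, baselines[comp], bands)

    for variant, scale in (silk_variants or {}).items():
        u = rng.uniform(-1, 1, size=len(bands_cw))
        v_amps = amps["tobacco_silk"] * (1.0 + scale * u)
        bands = [
            (c, w, float(a) * amplitude_scale) for (c, w), a in zip(bands_cw, v_amps)
        ]
        name = f"{ANALYTE}@{variant}"
        band_params[name] = (baselines["tobacco_silk"], bands)
        endmembers[name] = _gaussian_bands(grid, baselines["tobacco_silk"], bands)

    # smooth random nuisance modes, shared across every brand that uses
    # this library (physical effects are instrument/material-wide)
    modes = None
    if n_nuisance_modes > 0:
        lo, hi = float(grid.min()), float(grid.max())
        modes = np.empty((n_nuisance_modes, grid.size))
        for j in range(n_nuisance_modes):
            center = rng.uniform(lo, hi)
            width = rng.uniform(150.0, 500.0)
            mode = np.exp(-0.5 * ((grid - center) / width) ** 2)
            modes[j] = mode / np.linalg.norm(mode)

    return ComponentLibrary(
        wavenumbers=grid, endmembers=endmembers, band_params=band_params,
        nuisance_modes=modes,
    )


def _design_fingerprint(design: BrandDesign) -> int:
    """Stable 31-bit seed derived from the design alone, so that blend
    compositions depend on the design, not on the noise seed."""
    parts = [design.brand, str(design.n_samples), str(design.silk_variant)]
    for comp in sorted(design.component_ranges):
        lo, hi = design.component_ranges[comp]
        parts.append(f"{comp}:{lo!r}:{hi!r}")
    return zlib.crc32("|".join(parts).encode()) % (2**31)


def sample_blend_design(design: BrandDesign, seed: int, max_tries: int = 100_000) -> list:
    """Draw ``n_samples`` compositions honouring the design's range boxes.

    Minor components are drawn uniformly within their ranges and the
    analyte takes the remainder to 100 %; draws with the analyte outside
    its own range are rejected.  Returns a list of dicts component -> %.
    """
    rng = np.random.default_rng(seed)
    minors = [c for c in design.component_ranges if c != ANALYTE]
    lo_a, hi_a = design.component_ranges[ANALYTE]
    out = []
    tries = 0
    while len(out) < design.n_samples:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"rejection sampling for {design.brand!r} exceeded {max_tries} draws; "
                "the range boxes leave almost no feasible volume"
            )
        comp = {}
        for c in minors:
            lo, hi = design.component_ranges[c]
            comp[c] = rng.uniform(lo, hi)
        analyte = 100.0 - sum(comp.values())
        if lo_a - 1e-12 <= analyte <= hi_a + 1e-12:
            comp[ANALYTE] = analyte
            out.append(comp)
    return out


def synthesize_dataset(
    library: ComponentLibrary,
    design: BrandDesign,
    shift: DomainShift,
    seed: int,
    id_prefix: str | None = None,
    nuisance_sd: float = 0.0,
) -> SpectralDataset:
    """Simulate one brand's dataset from the mixture model.

    spectrum_i = gain * sum_c (f_ic / 100) * endmember_c
                 + offset + slope * (w - mean(w))
                 + sum_j c_ij * mode_j + Normal(0, noise_sd^2)

    with nuisance coefficients ``c_ij ~ Normal(0, nuisance_sd^2)`` on the
    library's shared smooth modes.  ``seed`` drives the nuisance draws
    and measurement noise only; compositions are drawn from a seed
    derived from the design itself, so re-simulating with a different
    noise seed keeps the blend targets fixed.
    """
    grid = library.wavenumbers
    for comp in design.component_ranges:
        library.endmember_for(comp, design.silk_variant if comp == ANALYTE else None)
    compositions = sample_blend_design(design, _design_fingerprint(design))
    rng = np.random.default_rng(seed)
    tilt = shift.slope * (grid - grid.mean())
    X = np.empty((design.n_samples, grid.size))
    y = np.empty(design.n_samples)
    for i, comp in enumerate(compositions):
        mix = np.zeros(grid.size)
        for c, frac in comp.items():
            em = library.endmember_for(c, design.silk_variant if c == ANALYTE else None)
            mix += (frac / 100.0) * em
        X[i] = shift.multiplicative_gain * mix + shift.additive_offset + tilt
        y[i] = comp[ANALYTE]
    if nuisance_sd > 0 and library.nuisance_modes is not None:
        coeffs = rng.normal(0.0, nuisance_sd, size=(design.n_samples, library.nuisance_modes.shape[0]))
        X += coeffs @ library.nuisance_modes
    if shift.noise_sd > 0:
        X += rng.normal(0.0, shift.noise_sd, size=X.shape)
    prefix = id_prefix if id_prefix is not None else design.brand
    ids = np.array([f"{prefix}-{i:04d}" for i in range(design.n_samples)], dtype=object)
    return SpectralDataset(
        wavenumbers=grid.copy(),
        absorbance=X,
        target=y,
        brand=np.array([design.brand] * design.n_samples, dtype=object),
        sample_id=ids,
    )


# ---------------------------------------------------------------------------
# Default four-brand study

#: Blend-ratio boxes per brand (percent): analyte plus the minor
#: components present in each brand's formulation.
_TABLE_DESIGNS = {
    "#1": (210, {"tobacco_silk": (59, 100), "cut_stem": (0, 20),
                 "fermented_cut_stem": (0, 20), "expanded_tobacco_silk": (0, 25)}),
    "#2": (199, {"tobacco_silk": (75, 100), "fermented_cut_stem": (0, 25)}),
    "#3": (200, {"tobacco_silk": (75, 100), "cut_stem": (0, 25)}),
    "#4": (183, {"tobacco_silk": (75, 100), "cut_stem": (0, 25)}),
}

#: Silk-variant amplitude-perturbation scales.  Brands #2 and #3 use
#: near-identical silk; #1 and #4 use strongly perturbed, independent
#: variants, which (with the offsets below) makes them the divergent
#: domains of the study.
_DEFAULT_SILK_VARIANTS = {"v1": 0.05, "v2": 0.02, "v3": 0.02, "v4": 0.05}

_VARIANT_OF_BRAND = {"#1": "v1", "#2": "v2", "#3": "v3", "#4": "v4"}

#: Default domain shifts: #2/#3 nearly unshifted, #1/#4 shifted strongly
#: in opposite directions.  noise_sd ~ 1e-3 absorbance emulates averaged
#: FT-NIR scan noise.
_DEFAULT_SHIFTS = {
    "#1": DomainShift(additive_offset=+0.10, slope=+1.5e-5, noise_sd=1e-3),
    "#2": DomainShift(additive_offset=+0.006, slope=0.0, noise_sd=1e-3),
    "#3": DomainShift(additive_offset=-0.006, slope=0.0, noise_sd=1e-3),
    "#4": DomainShift(additive_offset=-0.10, slope=-1.5e-5, noise_sd=1e-3),
}


def default_brand_designs(distinct_silk: bool = True) -> dict:
    """The four brand designs (sample counts and ratio boxes)."""
    designs = {}
    for brand, (n, ranges) in _TABLE_DESIGNS.items():
        designs[brand] = BrandDesign(
            brand=brand,
            n_samples=n,
            component_ranges=dict(ranges),
            silk_variant=_VARIANT_OF_BRAND[brand] if distinct_silk else None,
        )
    return designs


def default_brand_shifts() -> dict:
    return {b: replace(s) for b, s in _DEFAULT_SHIFTS.items()}


def default_four_brand_study(
    seed: int,
    shifts: dict | None = None,
    noise_sd: float | None = None,
    nuisance_sd: float = _DEFAULT_NUISANCE_SD,
    distinct_silk: bool = True,
    grid: np.ndarray | None = None,
) -> dict:
    """Generate the default four-brand study: brand -> SpectralDataset.

    Defaults reproduce the study conditions: brand sizes 210/199/200/183,
    the per-brand blend-ratio boxes, near-identical #2/#3 domains and
    strongly (oppositely) shifted #1/#4 domains.  Overrides exist for the
    degenerate regimes used in testing: ``noise_sd`` replaces every
    brand's noise level, ``shifts`` replaces the shift map entirely, and
    ``distinct_silk=False`` gives all brands the same silk endmember.
    """
    if grid is None:
        grid = default_grid()
    lib_seed = np.random.SeedSequence([int(seed), 0xC0FFEE]).generate_state(1)[0] % (2**31)
    library = make_component_library(
        grid, lib_seed, silk_variants=_DEFAULT_SILK_VARIANTS if distinct_silk else None
    )
    designs = default_brand_designs(distinct_silk=distinct_silk)
    shift_map = default_brand_shifts() if shifts is None else dict(shifts)
    if noise_sd is not None:
        shift_map = {b: replace(s, noise_sd=noise_sd) for b, s in shift_map.items()}
    out = {}
    for k, brand in enumerate(sorted(designs)):
        noise_seed = np.random.SeedSequence([int(seed), 1, k]).generate_state(1)[0] % (2**31)
        out[brand] = synthesize_dataset(
            library, designs[brand], shift_map[brand], noise_seed, nuisance_sd=nuisance_sd
        )
    return out
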