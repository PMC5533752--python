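"""Synthetic multi-group 1H-NMR study generator.

Emulates the statistical structure of a three-group (control vs. two
treatment arms, here labelled SMFY and GMFS), four-matrix (serum, urine,
cortex, stomach extract) NMR metabolomics study: per-metabolite baseline
concentrations with multiplicative (log-normal) biological variation,
planted group effects on known metabolites, per-sample dilution factors,
and additive Gaussian spectral noise on a Lorentzian forward model.

The generator's ground truth (which metabolite changed, in which group and
matrix, and by how much) is what downstream marker-selection performance is
scored against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

SAMPLE_TYPES = ("serum", "urine", "cortex", "stomach")
GROUPS = ("control", "SMFY", "GMFS")
TREATED_GROUPS = ("SMFY", "GMFS")

#: Spectrometer frequency assumed throughout (1 ppm = 600 Hz).
SPECTROMETER_MHZ = 600.0

#: Default rendering grid. It extends below 0 ppm so that the TSP reference
#: singlet at 0.000 ppm is visible for chemical-shift referencing; the
#: analysed ranges all start at 0.5 ppm.
GRID_LO = -0.25
GRID_HI = 10.0
GRID_STEP = 0.0005

#: Log-scale SD of biological (concentration) variation.
CONC_LOG_SD = 0.15

#: Log-scale SD of per-sample dilution, per sample type. Urine is the
#: classic high-dilution-variance matrix.
DILUTION_LOG_SD = {"serum": 0.05, "urine": 0.30, "cortex": 0.05, "stomach": 0.05}

#: Default additive spectral noise SD (intensity units; peak heights for a
#: unit concentration are O(100)).
DEFAULT_NOISE_SD = 0.5


def default_grid() -> np.ndarray:
    n = int(round((GRID_HI - GRID_LO) / GRID_STEP)) + 1
    return np.linspace(GRID_LO, GRID_HI, n)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Peak:
    """One resonance of a metabolite.

    ``pattern`` holds the multiplet fine structure as (offset in Hz from
    ``center``, fractional weight) pairs; weights sum to 1.  ``area_share``
    is the fraction of the metabolite's total integral carried by this
    resonance.
    """

    center: float
    pattern: tuple[tuple[float, float], ...]
    linewidth_hz: float
    area_share: float

    def line_positions(self) -> tuple[float, ...]:
        return tuple(self.center + off / SPECTROMETER_MHZ for off, _ in self.pattern)


@dataclass(frozen=True)
class MetaboliteTemplate:
    name: str
    peaks: tuple[Peak, ...]
    matrices: frozenset
    baseline_level: float
    is_reference: bool = False

    def __post_init__(self):
        total = sum(p.area_share for p in self.peaks)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"{self.name}: area shares sum to {total}, expected 1")
        for p in self.peaks:
            w = sum(weight for _, weight in p.pattern)
            if abs(w - 1.0) > 1e-9:
                raise ValueError(f"{self.name}: pattern weights sum to {w}")
            for pos in p.line_positions():
                if not (GRID_LO <= pos <= GRID_HI):
                    raise ValueError(f"{self.name}: line at {pos} ppm off-grid")

    def line_positions(self) -> list[float]:
        return [pos for p in self.peaks for pos in p.line_positions()]


@dataclass(frozen=True)
class EffectSpec:
    """A planted group effect: ``metabolite`` is multiplied by
    ``2**log2_effect`` in ``comparison_group`` for every matrix listed."""

    metabolite: str
    comparison_group: str
    log2_effect: float
    matrices: frozenset

    def __post_init__(self):
        if not math.isfinite(self.log2_effect):
            raise ValueError("log2_effect must be finite")
        if self.comparison_group not in TREATED_GROUPS:
            raise ValueError(f"comparison_group must be one of {TREATED_GROUPS}")


@dataclass
class StudyDesign:
    groups: tuple[str, ...] = GROUPS
    n_per_group: int = 8
    sample_types: tuple[str, ...] = SAMPLE_TYPES

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ValueError("need at least 2 samples per group")


@dataclass
class SimulatedStudy:
    """Spectra, metadata, dilution factors and ground truth for one run."""

    spectra: dict  # sample_type -> list[Spectrum]
    metadata: pd.DataFrame  # sample_id, group, sample_type
    dilution: pd.Series  # indexed by sample_id
    ground_truth: pd.DataFrame  # metabolite, group, sample_type, log2_effect, is_marker
    concentrations: dict  # sample_type -> DataFrame (samples x metabolites)
    seed: int


# ---------------------------------------------------------------------------
# Template library
# ---------------------------------------------------------------------------

_ALL = frozenset(SAMPLE_TYPES)
_J = 7.0  # generic 3-bond coupling, Hz


def _s(center, share, lw=1.0):
    return Peak(center, ((0.0, 1.0),), lw, share)


def _d(center, share, j=_J, lw=1.0):
    return Peak(center, ((-j / 2, 0.5), (j / 2, 0.5)), lw, share)


def _t(center, share, j=_J, lw=1.0):
    return Peak(center, ((-j, 0.25), (0.0, 0.5), (j, 0.25)), lw, share)


def _q(center, share, j=_J, lw=1.0):
    return Peak(
        center,
        ((-1.5 * j, 0.125), (-0.5 * j, 0.375), (0.5 * j, 0.375), (1.5 * j, 0.125)),
        lw,
        share,
    )


def _m(center, share, lw=2.5):
    # unresolved multiplet modelled as a single broadened line
    return Peak(center, ((0.0, 1.0),), lw, share)


def _met(name, peaks, matrices, baseline, reference=False):
    return MetaboliteTemplate(name, tuple(peaks), frozenset(matrices), baseline, reference)


def build_default_library() -> list[MetaboliteTemplate]:
    """Bundled metabolite templates (73 compounds, 0.5-10 ppm).

    Positions follow standard 600 MHz aqueous-sample assignments: lactate's
    methyl doublet centred at 1.336 ppm, the TSP reference singlet at
    0.000 ppm, gut-microbial aromatics (hippurate, benzoate, urocanate)
    restricted to urine, the neurotransmitter GABA to cortex extract and a
    broad LDL lipid resonance to serum.
    """
    S, U, C, T = "serum", "urine", "cortex", "stomach"
    lib = [
        _met("TSP", [_s(0.000, 1.0)], _ALL, 2.0, reference=True),
        _met("LDL", [_s(0.86, 0.4, lw=8.0), _s(1.26, 0.6, lw=8.0)], {S}, 8.0),
        _met("2-hydroxybutyrate", [_t(0.90, 0.6), _m(3.99, 0.4)], _ALL, 1.0),
        _met("valine", [_d(0.99, 0.5), _d(1.04, 0.5)], _ALL, 1.5),
        _met("leucine", [_t(0.96, 0.6), _m(1.70, 0.4)], _ALL, 1.5),
        _met("isobutyrate", [_d(1.13, 1.0)], _ALL, 1.0),
        _met("3-hydroxybutyrate", [_d(1.20, 0.5), _m(2.31, 0.25), _m(4.16, 0.25)], _ALL, 2.0),
        _met("methylmalonate", [_d(1.26, 0.7), _q(3.16, 0.3)], {U}, 1.0),
        _met("threonine", [_d(1.32, 0.4), _d(3.58, 0.2), _m(4.25, 0.4)], _ALL, 1.5),
        _met("lactate", [_d(1.336, 0.75), _q(4.12, 0.25)], _ALL, 10.0),
        _met("alanine", [_d(1.48, 0.6), _q(3.78, 0.4)], _ALL, 3.0),
        _met("citrulline", [_m(1.55, 1.0)], _ALL, 1.0),
        _met("arginine", [_t(1.63, 0.6), _m(3.23, 0.4)], _ALL, 1.5),
        _met("lysine", [_m(1.72, 0.5), _t(3.02, 0.5)], _ALL, 2.0),
        _met("acetate", [_s(1.92, 1.0)], _ALL, 2.5),
        _met("GABA", [_m(1.90, 0.33), _t(2.29, 0.33), _t(3.01, 0.34)], {C}, 2.0),
        _met("N-acetylaspartate", [_s(2.01, 0.6), _m(2.49, 0.2), _m(4.38, 0.2)], _ALL, 3.0),
        _met("O-acetylglycoprotein", [_s(2.04, 1.0, lw=4.0)], {S}, 3.0),
        _met("glutamate", [_m(2.08, 0.3), _m(2.34, 0.4), _t(3.75, 0.3)], _ALL, 3.0),
        _met("methionine", [_s(2.13, 0.5), _t(2.64, 0.3), _t(3.86, 0.2)], _ALL, 1.5),
        _met("glutamine", [_m(2.16, 0.4), _m(2.45, 0.4), _t(3.77, 0.2)], {S, C, T}, 2.5),
        _met("glutarate", [_t(2.18, 0.6), _m(1.78, 0.4)], _ALL, 1.0),
        _met("acetone", [_s(2.22, 1.0)], _ALL, 1.0),
        _met("acetoacetate", [_s(2.27, 1.0)], _ALL, 1.0),
        _met("pyruvate", [_s(2.37, 1.0)], _ALL, 1.0),
        _met("succinate", [_s(2.41, 1.0)], _ALL, 1.5),
        _met("alpha-ketoglutarate", [_t(2.44, 0.5), _t(3.01, 0.5)], {U}, 2.0),
        _met("citrate", [_d(2.54, 0.5, j=15.0), _d(2.66, 0.5, j=15.0)], _ALL, 3.0),
        _met("methylamine", [_s(2.60, 1.0)], _ALL, 1.0),
        _met("aspartate", [_m(2.68, 0.35), _m(2.80, 0.35), _m(3.89, 0.3)], _ALL, 2.0),
        _met("dimethylamine", [_s(2.72, 1.0)], {U}, 1.5),
        _met("trimethylamine", [_s(2.88, 1.0)], _ALL, 1.0),
        _met("N,N-dimethylglycine", [_s(2.93, 1.0)], _ALL, 1.5),
        _met("creatine", [_s(3.03, 0.6), _s(3.93, 0.4)], _ALL, 3.0),
        _met("creatinine", [_s(3.06, 0.6), _s(4.06, 0.4)], _ALL, 4.0),
        _met("malonate", [_s(3.11, 1.0)], {U}, 1.0),
        _met("ethanolamine", [_t(3.15, 0.5), _t(3.82, 0.5)], {S, C, T}, 1.5),
        _met("choline", [_s(3.20, 1.0)], _ALL, 2.0),
        _met("phosphocholine", [_s(3.22, 0.7), _m(4.21, 0.3)], _ALL, 2.5),
        _met("taurine", [_t(3.26, 0.5), _t(3.42, 0.5)], _ALL, 3.0),
        _met("betaine", [_s(3.27, 0.75), _s(3.90, 0.25)], _ALL, 2.0),
        _met("scyllo-inositol", [_s(3.35, 1.0)], _ALL, 1.0),
        _met("beta-glucose", [_m(3.24, 0.3), _m(3.47, 0.4), _d(4.64, 0.3)], _ALL, 6.0),
        _met("glycine", [_s(3.56, 1.0)], _ALL, 2.5),
        _met("myo-inositol", [_m(3.53, 0.4), _t(3.62, 0.4), _t(4.06, 0.2)], _ALL, 3.0),
        _met("ortho-hydroxyphenylacetate", [_s(3.66, 0.4), _m(6.93, 0.3), _m(7.23, 0.3)], {U}, 1.0),
        _met("phenylacetylglycine", [_s(3.68, 0.4), _d(7.36, 0.3), _m(7.42, 0.3)], {U}, 2.0),
        _met("glycerol", [_m(3.65, 1.0)], {S}, 2.0),
        _met("alpha-glucose", [_m(3.53, 0.3), _m(3.82, 0.3), _d(5.23, 0.4, j=3.8)], _ALL, 4.0),
        _met("hippurate", [_d(3.97, 0.3), _t(7.55, 0.2), _t(7.64, 0.2), _d(7.83, 0.3)], {U}, 4.0),
        _met("aminohippurate", [_s(3.95, 0.2), _d(6.87, 0.4), _d(7.73, 0.4)], {U}, 1.5),
        _met("trigonelline", [_s(4.44, 0.4), _d(8.08, 0.3), _s(9.12, 0.3)], {U}, 1.0),
        _met("N-methylnicotinamide", [_s(4.48, 0.3), _d(8.90, 0.2), _d(8.97, 0.2), _s(9.28, 0.3)], {U}, 1.0),
        _met("ascorbate", [_d(4.52, 1.0)], _ALL, 1.5),
        _met("galactose", [_d(4.58, 1.0)], _ALL, 1.5),
        _met("mannose", [_d(5.18, 1.0)], _ALL, 1.0),
        _met("sucrose", [_d(5.41, 1.0)], _ALL, 1.0),
        _met("allantoin", [_s(5.39, 1.0)], _ALL, 2.0),
        _met("uracil", [_d(5.80, 0.5), _d(7.54, 0.5)], {S, C, T}, 1.0),
        _met("inosine", [_d(6.10, 0.4), _s(8.23, 0.3), _s(8.34, 0.3)], _ALL, 1.5),
        _met("urocanate", [_d(6.40, 0.4), _s(7.29, 0.3), _d(7.90, 0.3)], {U}, 1.5),
        _met("fumarate", [_s(6.52, 1.0)], _ALL, 1.0),
        _met("4-hydroxybenzoate", [_d(6.80, 1.0)], _ALL, 1.0),
        _met("tyrosine", [_d(6.90, 0.5), _d(7.19, 0.5)], _ALL, 1.0),
        _met("histidine", [_s(7.09, 0.5), _s(7.79, 0.5)], _ALL, 1.0),
        _met("1-methylhistidine", [_s(7.05, 0.5), _s(7.78, 0.5)], {U}, 1.0),
        _met("phenylalanine", [_m(7.33, 0.4), _m(7.38, 0.3), _m(7.43, 0.3)], _ALL, 2.0),
        _met("benzoate", [_t(7.48, 0.4), _d(7.87, 0.6)], {U}, 2.0),
        _met("xanthine", [_s(7.94, 1.0)], _ALL, 1.0),
        _met("hypoxanthine", [_s(8.19, 0.5), _s(8.21, 0.5)], _ALL, 1.0),
        _met("formate", [_s(8.46, 1.0)], _ALL, 1.0),
        _met("nicotinate", [_d(8.61, 1.0)], _ALL, 1.0),
        _met("nicotinamide", [_s(8.72, 1.0)], _ALL, 1.0),
    ]
    return lib


def library_index(library: Sequence[MetaboliteTemplate]) -> dict:
    return {m.name: m for m in library}


# ---------------------------------------------------------------------------
# Default planted effects
# ---------------------------------------------------------------------------

def default_effects(min_abs_log2: float | None = None) -> list[EffectSpec]:
    """Planted group effects for the default study.

    Per sample type, each treated group has 10 affected metabolites: a
    shared core changed in the same direction in both groups, group-specific
    changes, and one metabolite (methionine, serum) changed in opposite
    directions in the two groups.  Magnitudes lie in [0.5, 1.5] on the log2
    scale; ``min_abs_log2`` clamps weaker effects up to that magnitude
    (used to study the strong-effect regime).
    """
    S, U, C, T = "serum", "urine", "cortex", "stomach"
    both = TREATED_GROUPS

    def spread(metabolite, groups, log2, matrices):
        return [
            EffectSpec(metabolite, g, log2, frozenset(matrices)) for g in groups
        ]

    eff: list[EffectSpec] = []
    # serum: shared core
    eff += spread("lactate", both, +1.0, {S})
    eff += spread("glutamine", both, -0.8, {S})
    eff += spread("citrate", both, -0.7, {S})
    eff += spread("3-hydroxybutyrate", both, -0.9, {S})
    eff += spread("beta-glucose", both, -0.6, {S})
    eff += spread("N,N-dimethylglycine", both, -0.75, {S})
    eff += spread("LDL", both, -0.55, {S})
    # serum: group-specific, incl. the opposite-direction methionine pair
    eff += spread("2-hydroxybutyrate", ["SMFY"], +1.2, {S})
    eff += spread("creatine", ["SMFY"], +0.9, {S})
    eff += spread("methionine", ["SMFY"], -0.8, {S})
    eff += spread("methionine", ["GMFS"], +0.8, {S})
    eff += spread("O-acetylglycoprotein", ["GMFS"], -0.85, {S})
    eff += spread("glutamate", ["GMFS"], +0.7, {S})
    # urine
    eff += spread("hippurate", both, -1.0, {U})
    eff += spread("urocanate", both, -0.8, {U})
    eff += spread("benzoate", both, -0.9, {U})
    eff += spread("allantoin", both, -0.7, {U})
    eff += spread("alpha-ketoglutarate", both, -0.75, {U})
    eff += spread("phenylacetylglycine", both, -0.85, {U})
    eff += spread("ortho-hydroxyphenylacetate", both, -0.6, {U})
    eff += spread("methylmalonate", ["SMFY"], +1.1, {U})
    eff += spread("aminohippurate", ["SMFY"], -0.9, {U})
    eff += spread("2-hydroxybutyrate", ["SMFY"], +0.6, {U})
    eff += spread("N-methylnicotinamide", ["GMFS"], +0.8, {U})
    eff += spread("1-methylhistidine", ["GMFS"], +0.6, {U})
    eff += spread("malonate", ["GMFS"], -0.7, {U})
    # cortex: eight shared changes plus group-specific ones
    eff += spread("aspartate", both, -0.8, {C})
    eff += spread("phenylalanine", both, -0.7, {C})
    eff += spread("fumarate", both, -0.9, {C})
    eff += spread("GABA", both, -1.0, {C})
    eff += spread("phosphocholine", both, -0.6, {C})
    eff += spread("threonine", both, +0.8, {C})
    eff += spread("lysine", both, +0.7, {C})
    eff += spread("myo-inositol", both, +0.9, {C})
    eff += spread("acetate", ["SMFY"], -0.7, {C})
    eff += spread("ethanolamine", ["SMFY"], -0.8, {C})
    eff += spread("glutamate", ["GMFS"], +0.8, {C})
    eff += spread("N-acetylaspartate", ["GMFS"], +0.6, {C})
    # stomach
    eff += spread("alpha-glucose", both, +0.7, {T})
    eff += spread("lactate", both, +0.9, {T})
    eff += spread("alanine", both, +0.6, {T})
    eff += spread("glycine", both, -0.6, {T})
    eff += spread("taurine", both, -0.7, {T})
    eff += spread("succinate", both, -0.8, {T})
    eff += spread("creatine", ["SMFY"], +0.7, {T})
    eff += spread("acetate", ["SMFY"], -0.6, {T})
    eff += spread("uracil", ["SMFY"], +0.9, {T})
    eff += spread("choline", ["SMFY"], +0.5, {T})
    eff += spread("glutamate", ["GMFS"], +0.7, {T})
    eff += spread("glutamine", ["GMFS"], -0.6, {T})
    eff += spread("inosine", ["GMFS"], +0.8, {T})
    eff += spread("hypoxanthine", ["GMFS"], -0.7, {T})

    if min_abs_log2 is not None:
        eff = [
            EffectSpec(
                e.metabolite,
                e.comparison_group,
                math.copysign(max(abs(e.log2_effect), min_abs_log2), e.log2_effect),
                e.matrices,
            )
            for e in eff
        ]

    names = {m.name for m in build_default_library()}
    for e in eff:
        if e.metabolite not in names:
            raise ValueError(f"effect on unknown metabolite {e.metabolite!r}")
    return eff


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

_BASIS_CACHE: dict = {}


def _grid_key(grid: np.ndarray) -> tuple:
    return (len(grid), float(grid[0]), float(grid[-1]))


def metabolite_basis(library: Sequence[MetaboliteTemplate], grid: np.ndarray) -> np.ndarray:
    """Unit-concentration spectra, one row per library entry (cached)."""
    key = (tuple(m.name for m in library), tuple(library).__hash__(), _grid_key(grid))
    basis = _BASIS_CACHE.get(key)
    if basis is None:
        basis = np.zeros((len(library), len(grid)))
        for i, met in enumerate(library):
            for peak in met.peaks:
                hw = peak.linewidth_hz / 2.0 / SPECTROMETER_MHZ  # HWHM, ppm
                for off_hz, weight in peak.pattern:
                    c = peak.center + off_hz / SPECTROMETER_MHZ
                    basis[i] += (
                        peak.area_share
                        * weight
                        * hw
                        / (np.pi * ((grid - c) ** 2 + hw**2))
                    )
        _BASIS_CACHE[key] = basis
    return basis


def _check_uniform_grid(grid: np.ndarray) -> float:
    d = np.diff(grid)
    if len(d) == 0 or d[0] <= 0 or np.any(np.abs(d - d[0]) > 1e-9 * max(1.0, abs(d[0]))):
        raise ValueError("grid must be uniform and ascending")
    return float(d[0])


def render_spectrum(
    concentrations: Mapping[str, float],
    library: Sequence[MetaboliteTemplate],
    grid: np.ndarray | None = None,
    noise_sd: float = 0.0,
    dilution: float = 1.0,
    rng: np.random.Generator | None = None,
):
    """Render one spectrum from per-metabolite amounts.

    intensity = dilution * sum_m conc_m * (unit-area Lorentzian mixture)
    + N(0, noise_sd).  Linear in concentrations and in dilution.
    """
    from .preprocess import Spectrum  # local import to avoid a cycle

    if grid is None:
        grid = default_grid()
    _check_uniform_grid(grid)
    if dilution <= 0:
        raise ValueError("dilution must be positive")
    idx = library_index(library)
    for name, c in concentrations.items():
        if name not in idx:
            raise ValueError(f"unknown metabolite {name!r}")
        if c < 0:
            raise ValueError(f"negative concentration for {name!r}")
    basis = metabolite_basis(library, grid)
    conc = np.array([concentrations.get(m.name, 0.0) for m in library])
    intensity = dilution * (conc @ basis)
    if noise_sd > 0:
        rng = np.random.default_rng() if rng is None else rng
        intensity = intensity + rng.normal(0.0, noise_sd, size=len(grid))
    return Spectrum(ppm=grid.copy(), intensity=intensity, sample_id="", sample_type="")


# ---------------------------------------------------------------------------
# Study simulation
# ---------------------------------------------------------------------------

def _effect_table(
    effects: Sequence[EffectSpec], library: Sequence[MetaboliteTemplate]
) -> dict:
    """(sample_type, group, metabolite) -> log2 effect, validated."""
    idx = library_index(library)
    table: dict = {}
    for e in effects:
        met = idx.get(e.metabolite)
        if met is None:
            raise ValueError(f"effect on unknown metabolite {e.metabolite!r}")
        for st in e.matrices:
            if st not in met.matrices:
                raise ValueError(
                    f"effect on {e.metabolite!r} in {st!r}, but the template "
                    f"is only present in {sorted(met.matrices)}"
                )
            key = (st, e.comparison_group, e.metabolite)
            table[key] = table.get(key, 0.0) + e.log2_effect
    return table


def simulate_study(
    design: StudyDesign | None = None,
    library: Sequence[MetaboliteTemplate] | None = None,
    effects: Sequence[EffectSpec] | None = None,
    noise_sd: float = DEFAULT_NOISE_SD,
    dilution_sd: Mapping[str, float] | None = None,
    seed: int = 0,
    grid: np.ndarray | None = None,
) -> SimulatedStudy:
    """Simulate a full study; bit-identical for identical seeds.

    Control samples draw each metabolite concentration log-normally around
    its baseline (log-SD 0.15); treated groups multiply affected
    metabolites by 2**log2_effect; each sample gets a log-normal dilution
    factor (log-SD 0.3 for urine, 0.05 elsewhere) applied to the whole
    spectrum before additive Gaussian noise.
    """
    design = design or StudyDesign()
    library = list(library) if library is not None else build_default_library()
    effects = list(effects) if effects is not None else default_effects()
    dilution_sd = dict(DILUTION_LOG_SD if dilution_sd is None else dilution_sd)
    if grid is None:
        grid = default_grid()
    eff_table = _effect_table(effects, library)

    ss = np.random.SeedSequence(seed)
    children = {st: np.random.default_rng(s) for st, s in
                zip(design.sample_types, ss.spawn(len(design.sample_types)))}

    meta_rows, dil_rows = [], {}
    spectra: dict = {st: [] for st in design.sample_types}
    concentrations: dict = {}
    basis_cache: dict = {}

    for st in design.sample_types:
        rng = children[st]
        present = [m for m in library if st in m.matrices]
        sub_basis = basis_cache.get(st)
        if sub_basis is None:
            full = metabolite_basis(library, grid)
            rows = [i for i, m in enumerate(library) if st in m.matrices]
            sub_basis = full[rows]
            basis_cache[st] = sub_basis
        names = [m.name for m in present]
        sample_ids, groups_col = [], []
        conc_rows = []
        for g in design.groups:
            for k in range(design.n_per_group):
                sid = f"{st}_{g}_{k + 1:02d}"
                sample_ids.append(sid)
                groups_col.append(g)
        n_samples = len(sample_ids)
        # concentrations
        log_noise = rng.normal(0.0, CONC_LOG_SD, size=(n_samples, len(present)))
        conc = np.empty_like(log_noise)
        for j, m in enumerate(present):
            for i, g in enumerate(groups_col):
                shift = eff_table.get((st, g, m.name), 0.0)
                if m.is_reference:
                    conc[i, j] = m.baseline_level
                else:
                    conc[i, j] = m.baseline_level * (2.0**shift) * math.exp(log_noise[i, j])
        # dilution
        dsd = dilution_sd.get(st, 0.05)
        dil = np.exp(rng.normal(0.0, dsd, size=n_samples))
        # spectra
        raw = (conc @ sub_basis) * dil[:, None]
        if noise_sd > 0:
            raw = raw + rng.normal(0.0, noise_sd, size=raw.shape)
        from .preprocess import Spectrum

        for i, sid in enumerate(sample_ids):
            spectra[st].append(
                Spectrum(ppm=grid.copy(), intensity=raw[i], sample_id=sid, sample_type=st)
            )
            meta_rows.append({"sample_id": sid, "group": groups_col[i], "sample_type": st})
            dil_rows[sid] = dil[i]
        concentrations[st] = pd.DataFrame(conc, index=sample_ids, columns=names)

    gt_rows = []
    for st in design.sample_types:
        for g in TREATED_GROUPS:
            if g not in design.groups:
                continue
            for m in library:
                if st not in m.matrices or m.is_reference:
                    continue
                shift = eff_table.get((st, g, m.name), 0.0)
                gt_rows.append(
                    {
                        "metabolite": m.name,
                        "group": g,
                        "sample_type": st,
                        "log2_effect": shift,
                        "is_marker": shift != 0.0,
                    }
                )
    metadata = pd.DataFrame(meta_rows)
    return SimulatedStudy(
        spectra=spectra,
        metadata=metadata,
        dilution=pd.Series(dil_rows, name="dilution"),
        ground_truth=pd.DataFrame(gt_rows),
        concentrations=concentrations,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# TSV export
# ---------------------------------------------------------------------------

def write_spectra_tsv(spectra, path) -> None:
    """First column `ppm`, one column per sample id."""
    data = {"ppm": spectra[0].ppm}
    for sp in spectra:
        data[sp.sample_id] = sp.intensity
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_metadata_tsv(metadata: pd.DataFrame, path) -> None:
    metadata[["sample_id", "group", "sample_type"]].to_csv(path, sep="\t", index=False)


def write_ground_truth_tsv(ground_truth: pd.DataFrame, path) -> None:
    cols = ["metabolite", "group", "sample_type", "log2_effect", "is_marker"]
    ground_truth[cols].to_csv(path, sep="\t", index=False)
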