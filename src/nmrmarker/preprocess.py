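"""Spectral preprocessing: referencing, region exclusion, bucketing, PQN.

Turns a set of 1D spectra into the normalized bucket matrix consumed by the
chemometric models.  The conventions are the ones used throughout clinical
NMR metabolomics: fixed-width 0.004 ppm buckets (2.4 Hz at 600 MHz) laid
half-open and ascending from the start of the retained range, residual
water/urea windows excluded, constant-sum (total-area) normalization to
100, then probabilistic quotient normalization (PQN) against a
control-group median reference to remove per-sample dilution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .synthdata import SPECTROMETER_MHZ

DEFAULT_BUCKET_WIDTH = 0.004  # ppm

#: Retained chemical-shift range per sample type.
DEFAULT_RETAINED = {
    "serum": (0.5, 9.0),
    "urine": (0.5, 10.0),
    "cortex": (0.5, 8.5),
    "stomach": (0.5, 9.2),
}

#: Residual-water window per sample type, plus the urea window applied to
#: every matrix.
WATER_WINDOWS = {
    "serum": (4.7, 5.0),
    "urine": (4.76, 5.06),
    "cortex": (4.97, 5.02),
    "stomach": (4.95, 5.04),
}
UREA_WINDOW = (5.60, 6.35)

REFERENCE_WINDOWS = {"tsp": (-0.05, 0.05), "lactate": (1.30, 1.36)}
REFERENCE_TARGETS = {"tsp": 0.0, "lactate": 1.336}


def ppm_width_to_hz(width_ppm: float, spectrometer_mhz: float = SPECTROMETER_MHZ) -> float:
    """Bucket width in Hz for a given spectrometer frequency (0.004 ppm at
    600 MHz -> 2.4 Hz)."""
    return width_ppm * spectrometer_mhz


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Spectrum:
    ppm: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""
    sample_type: str = ""

    def __post_init__(self):
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.shape != self.intensity.shape:
            raise ValueError("ppm and intensity must have equal length")

    @property
    def step(self) -> float:
        """Grid step; for gapped spectra, the underlying acquisition step."""
        d = np.diff(self.ppm)
        return float(np.min(d)) if len(d) else 0.0


@dataclass
class ExclusionPlan:
    """Retained range and half-open excluded intervals per sample type."""

    retained: dict  # sample_type -> (lo, hi)
    excluded: dict  # sample_type -> list of (a, b), half-open [a, b)

    def __post_init__(self):
        for st, (lo, hi) in self.retained.items():
            for a, b in self.excluded.get(st, []):
                if not (lo <= a < b <= hi):
                    raise ValueError(
                        f"{st}: excluded interval [{a}, {b}) outside retained [{lo}, {hi}]"
                    )
        for st, ivals in self.excluded.items():
            s = sorted(ivals)
            for (a1, b1), (a2, b2) in zip(s, s[1:]):
                if a2 < b1:
                    raise ValueError(f"{st}: overlapping exclusions {s}")

    def is_excluded(self, sample_type: str, x: float) -> bool:
        lo, hi = self.retained[sample_type]
        if not (lo <= x <= hi):
            return True
        return any(a <= x < b for a, b in self.excluded.get(sample_type, []))


def default_exclusion_plan() -> ExclusionPlan:
    excluded = {st: [WATER_WINDOWS[st], UREA_WINDOW] for st in DEFAULT_RETAINED}
    return ExclusionPlan(retained=dict(DEFAULT_RETAINED), excluded=excluded)


@dataclass
class BucketMatrix:
    """samples x fixed-width buckets, with normalization bookkeeping.

    ``edges`` are bucket left edges; bucket b covers [edges[b], edges[b]+width).
    ``area_factors`` (raw row sum / 100) and ``quotients`` (PQN median
    quotients) are populated by the normalization steps; their product is
    the recovered per-sample dilution factor up to a common scale.
    """

    sample_ids: list
    sample_type: str
    edges: np.ndarray
    width: float
    values: np.ndarray
    state: str = "raw"  # raw | total_area | pqn
    area_factors: np.ndarray | None = None
    quotients: np.ndarray | None = None

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("bucket edges must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("bucket values must be finite")
        if self.values.shape != (len(self.sample_ids), len(self.edges)):
            raise ValueError("values shape inconsistent with ids/edges")

    @property
    def dilution_estimates(self) -> np.ndarray:
        """Per-sample overall normalization factor (area factor x PQN
        quotient); proportional to the physical dilution factor."""
        if self.area_factors is None or self.quotients is None:
            raise ValueError("dilution estimates require total-area + PQN states")
        return self.area_factors * self.quotients

    def to_frame(self) -> pd.DataFrame:
        cols = [f"b_{e:.4f}" for e in self.edges]
        return pd.DataFrame(self.values, index=self.sample_ids, columns=cols)

    def write_tsv(self, path, sidecar_path=None, extra: dict | None = None) -> None:
        df = self.to_frame()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t", float_format="%.8g")
        if sidecar_path is not None:
            meta = {
                "sample_type": self.sample_type,
                "width": self.width,
                "state": self.state,
                "edges_ppm": [round(float(e), 6) for e in self.edges[:1]],
                "n_buckets": int(len(self.edges)),
                "area_factors": None
                if self.area_factors is None
                else [float(x) for x in self.area_factors],
                "quotients": None
                if self.quotients is None
                else [float(x) for x in self.quotients],
            }
            if extra:
                meta.update(extra)
            with open(sidecar_path, "w") as fh:
                json.dump(meta, fh, indent=1)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def _noise_floor(intensity: np.ndarray) -> float:
    med = float(np.median(intensity))
    mad = float(np.median(np.abs(intensity - med)))
    return med + 10.0 * (mad if mad > 0 else 1e-12)


def reference_shift(spectrum: Spectrum, mode: str) -> Spectrum:
    """Translate the ppm axis (integer grid steps) so the reference apex
    sits on its nominal position.

    ``tsp``: singlet apex in -0.05..0.05 ppm moved to 0.000.
    ``lactate``: left (lower-ppm) split of the methyl doublet found in
    1.30..1.36 ppm moved to 1.336.
    """
    if mode not in REFERENCE_WINDOWS:
        raise ValueError(f"unknown reference mode {mode!r}")
    lo, hi = REFERENCE_WINDOWS[mode]
    ppm, y = spectrum.ppm, spectrum.intensity
    step = float(np.diff(ppm)[0])
    if ppm[0] > lo or ppm[-1] < hi:
        raise ValueError(f"search window [{lo}, {hi}] ppm not covered by the grid")
    win = (ppm >= lo) & (ppm <= hi)
    if not np.any(win):
        raise ValueError(f"search window [{lo}, {hi}] ppm contains no grid points")
    ywin = y[win]
    floor = _noise_floor(y)
    if float(np.max(ywin)) <= floor:
        raise ValueError(f"no peak above the noise floor in [{lo}, {hi}] ppm")
    pwin = ppm[win]
    apex = float(pwin[int(np.argmax(ywin))])
    if mode == "lactate":
        # the doublet has two lines; take the leftmost (lowest-ppm) local
        # maximum comparable in height to the apex
        apex_height = float(np.max(ywin))
        candidates = pwin[(ywin >= 0.5 * apex_height)]
        # cluster candidate points into lines separated by > 2 steps
        lines = []
        for p in candidates:
            if not lines or p - lines[-1][-1] > 2.5 * step:
                lines.append([p])
            else:
                lines[-1].append(p)
            lines[-1][-1] = p
        line_apexes = []
        for grp in lines:
            sel = (pwin >= grp[0]) & (pwin <= grp[-1])
            line_apexes.append(float(pwin[sel][int(np.argmax(ywin[sel]))]))
        apex = min(line_apexes)
    target = REFERENCE_TARGETS[mode]
    n_steps = int(round((target - apex) / step))
    return replace(spectrum, ppm=spectrum.ppm + n_steps * step)


def apply_exclusions(spectrum: Spectrum, plan: ExclusionPlan) -> Spectrum:
    """Drop grid points outside the retained range or inside an excluded
    half-open interval; returns a gapped spectrum."""
    st = spectrum.sample_type
    if st not in plan.retained:
        raise ValueError(f"no retained range defined for sample type {st!r}")
    lo, hi = plan.retained[st]
    keep = (spectrum.ppm >= lo) & (spectrum.ppm <= hi)
    for a, b in plan.excluded.get(st, []):
        keep &= ~((spectrum.ppm >= a) & (spectrum.ppm < b))
    if not np.any(keep):
        raise ValueError(f"exclusion plan removes every point of {spectrum.sample_id!r}")
    return replace(spectrum, ppm=spectrum.ppm[keep], intensity=spectrum.intensity[keep])


def bucket_spectra(
    spectra: Sequence[Spectrum], width: float = DEFAULT_BUCKET_WIDTH
) -> BucketMatrix:
    """Integrate exclusion-applied spectra into fixed-width buckets.

    Buckets are half-open [lo, lo + width) laid ascending from the start of
    the retained range; a bucket's value is the rectangle-rule integral
    (sum of intensities times the grid step) over its member points.
    Buckets that intersect an excluded gap are dropped entirely, as is a
    trailing partial bucket narrower than width/2.
    """
    if not spectra:
        raise ValueError("no spectra given")
    st = spectra[0].sample_type
    ref_ppm = spectra[0].ppm
    for sp in spectra[1:]:
        if sp.sample_type != st:
            raise ValueError("all spectra must share one sample type")
        if len(sp.ppm) != len(ref_ppm) or np.any(np.abs(sp.ppm - ref_ppm) > 1e-9):
            raise ValueError("all spectra must share one ppm grid")
    step = float(np.min(np.diff(ref_ppm)))
    start = float(ref_ppm[0])
    idx = np.floor((ref_ppm - start) / width + 1e-9).astype(int)
    n_per_full = int(round(width / step))
    counts = np.bincount(idx)
    last = int(idx[-1])

    keep_buckets = []
    for b in range(len(counts)):
        c = counts[b]
        if c == 0:
            continue
        member = idx == b
        pmin, pmax = ref_ppm[member][0], ref_ppm[member][-1]
        contiguous = abs((pmax - pmin) - (c - 1) * step) < 1e-9
        if c == n_per_full and contiguous:
            keep_buckets.append(b)
        elif b == last and contiguous and c * step >= width / 2 and abs(
            pmin - (start + b * width)
        ) < step:
            # trailing partial bucket at the end of the retained range
            keep_buckets.append(b)
    if not keep_buckets:
        raise ValueError("no complete bucket survives")
    keep_buckets = np.array(keep_buckets, dtype=int)

    values = np.empty((len(spectra), len(keep_buckets)))
    sums = np.zeros((len(spectra), len(counts)))
    for i, sp in enumerate(spectra):
        np.add.at(sums[i], idx, sp.intensity)
    values = sums[:, keep_buckets] * step
    edges = start + keep_buckets * width
    return BucketMatrix(
        sample_ids=[sp.sample_id for sp in spectra],
        sample_type=st,
        edges=edges,
        width=width,
        values=values,
    )


def total_area_normalize(matrix: BucketMatrix) -> BucketMatrix:
    """Scale every row to sum 100 (constant-sum normalization)."""
    if matrix.state != "raw":
        raise ValueError(f"expected raw state, got {matrix.state!r}")
    sums = matrix.values.sum(axis=1)
    for sid, s in zip(matrix.sample_ids, sums):
        if s <= 0:
            raise ValueError(f"sample {sid!r} has non-positive total area")
    values = matrix.values * (100.0 / sums[:, None])
    return replace(
        matrix, values=values, state="total_area", area_factors=sums / 100.0
    )


def pqn_normalize(
    matrix: BucketMatrix,
    groups: Sequence[str] | pd.Series | None = None,
    reference_group: str | None = None,
    floor_quantile: float = 0.05,
) -> BucketMatrix:
    """Probabilistic quotient normalization.

    The reference spectrum is the element-wise median over the
    reference-group rows (all rows when no group is given).  For each
    sample, quotients value/reference are computed over buckets where the
    reference exceeds its own 5th percentile; the row is divided by the
    median quotient, which is stored.  Applying PQN to an already
    PQN-normalized matrix is a no-op.
    """
    if matrix.state == "pqn":
        return matrix
    if matrix.state != "total_area":
        raise ValueError(f"expected total_area state, got {matrix.state!r}")
    if reference_group is not None:
        if groups is None:
            raise ValueError("reference_group given without group labels")
        groups = np.asarray(groups)
        if len(groups) != len(matrix.sample_ids):
            raise ValueError("group labels must align with samples")
        ref_rows = matrix.values[groups == reference_group]
        if len(ref_rows) == 0:
            raise ValueError(f"reference group {reference_group!r} absent")
    else:
        ref_rows = matrix.values
    reference = np.median(ref_rows, axis=0)
    if floor_quantile > 0:
        mask = reference > np.percentile(reference, 100.0 * floor_quantile)
    else:
        mask = reference > 0
    if not np.any(mask):
        raise ValueError("reference spectrum has no bucket above its 5th percentile")
    ratios = matrix.values[:, mask] / reference[mask]
    quotients = np.median(ratios, axis=1)
    if np.any(quotients <= 0):
        raise ValueError("non-positive PQN quotient")
    values = matrix.values / quotients[:, None]
    return replace(matrix, values=values, state="pqn", quotients=quotients)


# ---------------------------------------------------------------------------
# TSV import (the synthdata export formats)
# ---------------------------------------------------------------------------

def read_spectra_tsv(path, sample_type: str) -> list:
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "ppm":
        raise ValueError("first column must be 'ppm'")
    ppm = df["ppm"].to_numpy()
    return [
        Spectrum(ppm=ppm.copy(), intensity=df[c].to_numpy(), sample_id=c, sample_type=sample_type)
        for c in df.columns[1:]
    ]


def read_metadata_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"sample_id", "group", "sample_type"} - set(df.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    return df


def read_bucket_tsv(path, sample_type: str, width: float = DEFAULT_BUCKET_WIDTH,
                    state: str = "raw") -> BucketMatrix:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    edges = np.array([float(c[2:]) for c in df.columns])
    return BucketMatrix(
        sample_ids=list(df.index),
        sample_type=sample_type,
        edges=edges,
        width=width,
        values=df.to_numpy(),
        state=state,
    )
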