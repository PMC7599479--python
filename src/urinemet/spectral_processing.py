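"""Spectral preprocessing: TSP referencing, region exclusion, binning,
total-area normalization.

The fixed pipeline order is reference -> exclude -> bin -> normalize. Water
(4.62-5.15 ppm) is excluded before normalization so the dominant solvent
signal cannot swamp the total-area denominator; the TSP reference region
(default +-0.05 ppm around 0) is likewise dropped because the reference
compound is not biological signal. Bins are half-open [left, left+width)
intervals on an ascending ppm axis, anchored by default at the retained
axis minimum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_BIN_WIDTH = 0.0073
DEFAULT_WATER_REGION = (4.62, 5.15)
DEFAULT_TSP_REGION = (-0.05, 0.05)


@dataclass
class Spectrum:
    """One 1D spectrum: a strictly monotone ppm axis plus intensities."""

    ppm: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.shape != self.intensity.shape or self.ppm.ndim != 1:
            raise ValueError("ppm and intensity must be 1-D and equally long")
        d = np.diff(self.ppm)
        if self.ppm.size >= 2 and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("ppm axis must be strictly monotone")


@dataclass
class BinnedMatrix:
    """Samples x bins feature matrix with bin bookkeeping."""

    values: np.ndarray
    bin_edges: np.ndarray  # (n_bins, 2) ascending left edges
    sample_ids: list[str]
    excluded_regions: list[tuple[float, float]] = field(default_factory=list)
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        if self.values.ndim != 2 or self.bin_edges.shape != (self.values.shape[1], 2):
            raise ValueError("values must be samples x bins with matching bin_edges")
        if len(self.sample_ids) != self.values.shape[0]:
            raise ValueError("sample_ids length mismatch")
        if self.bin_edges.shape[0] > 1 and np.any(np.diff(self.bin_edges[:, 0]) <= 0):
            raise ValueError("bins must be ordered by ascending left edge")

    @property
    def bin_centers(self) -> np.ndarray:
        return self.bin_edges.mean(axis=1)


def reference_to_tsp(s: Spectrum, search_window: tuple[float, float] = (-0.2, 0.2)) -> Spectrum:
    """Shift the ppm axis so the tallest point inside ``search_window`` sits
    at exactly 0 ppm (TSP referencing). Intensities are unchanged."""
    lo, hi = min(search_window), max(search_window)
    mask = (s.ppm >= lo) & (s.ppm <= hi)
    if not mask.any():
        raise ValueError("TSP search window contains no points")
    seg = s.intensity[mask]
    if np.all(seg == 0):
        raise ValueError("no signal inside TSP search window")
    shift = s.ppm[mask][np.argmax(seg)]
    return Spectrum(ppm=s.ppm - shift, intensity=s.intensity.copy(), sample_id=s.sample_id)


def exclude_regions(
    s: Spectrum, regions: list[tuple[float, float]] | None = None
) -> Spectrum:
    """Remove all points whose ppm falls inside any closed interval.

    Default region list is the water band ``[(4.62, 5.15)]``.
    """
    if regions is None:
        regions = [DEFAULT_WATER_REGION]
    if not regions:
        return Spectrum(ppm=s.ppm.copy(), intensity=s.intensity.copy(), sample_id=s.sample_id)
    keep = np.ones(s.ppm.size, dtype=bool)
    for lo, hi in regions:
        lo, hi = min(lo, hi), max(lo, hi)
        keep &= ~((s.ppm >= lo) & (s.ppm <= hi))
    return Spectrum(ppm=s.ppm[keep], intensity=s.intensity[keep], sample_id=s.sample_id)


def _tile_edges(origin: float, axis_max: float, width: float) -> np.ndarray:
    span = axis_max - origin
    if span < width:
        raise ValueError("bin width larger than axis span")
    n_bins = int(np.ceil(span / width - 1e-12))
    lefts = origin + width * np.arange(n_bins)
    return np.column_stack([lefts, lefts + width])


def _bin_on_edges(
    ppm: np.ndarray, intensity: np.ndarray, edges: np.ndarray, width: float
) -> tuple[np.ndarray, np.ndarray]:
    """Sum intensities x grid spacing into a contiguous uniform tiling."""
    spacing = float(np.median(np.abs(np.diff(ppm))))
    idx = np.floor((ppm - edges[0, 0]) / width).astype(int)
    ok = (idx >= 0) & (idx < edges.shape[0]) & (ppm < edges[-1, 1])
    sums = np.bincount(idx[ok], weights=intensity[ok], minlength=edges.shape[0])
    counts = np.bincount(idx[ok], minlength=edges.shape[0])
    return sums * spacing, counts


def bin_spectrum(
    s: Spectrum,
    width: float = DEFAULT_BIN_WIDTH,
    origin: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Bucket a spectrum into fixed-width ppm bins.

    Bins tile ``[origin, axis_max)`` as half-open ``[left, left+width)``
    intervals; a bin's value is the sum of the intensities at the grid
    points inside it times the median grid spacing (an area, not a mean).
    Bins containing no grid points (e.g. those lying wholly inside an
    excluded region) are dropped.

    Returns ``(bin_values, bin_edges)`` with ``bin_edges`` of shape (n, 2).
    """
    if width <= 0:
        raise ValueError("bin width must be > 0")
    ppm, intensity = s.ppm, s.intensity
    if ppm.size >= 2 and ppm[0] > ppm[-1]:  # normalize to ascending
        ppm, intensity = ppm[::-1], intensity[::-1]
    if origin is None:
        origin = float(ppm.min())
    edges = _tile_edges(origin, float(ppm.max()), width)
    sums, counts = _bin_on_edges(ppm, intensity, edges, width)
    occupied = counts > 0
    return sums[occupied], edges[occupied]


def total_area_normalize(m: BinnedMatrix) -> BinnedMatrix:
    """Divide each row by its own total so row sums equal 1 (total-area
    normalization); relative within-row proportions are preserved."""
    sums = m.values.sum(axis=1)
    if np.any(sums <= 0):
        bad = [m.sample_ids[i] for i in np.flatnonzero(sums <= 0)]
        raise ValueError(f"nonpositive total area for samples: {bad}")
    return BinnedMatrix(
        values=m.values / sums[:, None],
        bin_edges=m.bin_edges.copy(),
        sample_ids=list(m.sample_ids),
        excluded_regions=list(m.excluded_regions),
        normalized=True,
    )


def preprocess_cohort(
    spectra: list[Spectrum],
    width: float = DEFAULT_BIN_WIDTH,
    water_region: tuple[float, float] = DEFAULT_WATER_REGION,
    tsp_region: tuple[float, float] | None = DEFAULT_TSP_REGION,
    reference: bool = True,
    normalize: bool = True,
    bin_origin: float | None = None,
) -> BinnedMatrix:
    """Full preprocessing pipeline: reference -> exclude -> bin -> normalize.

    All spectra are binned on a common edge layout derived from the first
    spectrum; a differing layout in any later spectrum is a hard error.
    """
    if not spectra:
        raise ValueError("no spectra to preprocess")
    regions = [water_region] + ([tsp_region] if tsp_region is not None else [])

    rows, full_edges, occupied = [], None, None
    for s in spectra:
        if reference:
            s = reference_to_tsp(s)
        s = exclude_regions(s, regions)
        ppm, intensity = s.ppm, s.intensity
        if ppm.size >= 2 and ppm[0] > ppm[-1]:
            ppm, intensity = ppm[::-1], intensity[::-1]
        if full_edges is None:
            origin = float(ppm.min()) if bin_origin is None else bin_origin
            full_edges = _tile_edges(origin, float(ppm.max()), width)
        vals, counts = _bin_on_edges(ppm, intensity, full_edges, width)
        occ = counts > 0
        if occupied is None:
            occupied = occ
        elif not np.array_equal(occ, occupied):
            raise ValueError(f"bin layout mismatch for sample {s.sample_id!r}")
        rows.append(vals)

    m = BinnedMatrix(
        values=np.vstack(rows)[:, occupied],
        bin_edges=full_edges[occupied],
        sample_ids=[s.sample_id for s in spectra],
        excluded_regions=[tuple(r) for r in regions],
    )
    return total_area_normalize(m) if normalize else m


# ---------------------------------------------------------------------------
# I/O

def read_spectra_csv(path: str | Path) -> list[Spectrum]:
    """Read wide-format spectra (``ppm`` column + one column per sample)."""
    df = pd.read_csv(path)
    if "ppm" not in df.columns:
        raise ValueError("wide spectra CSV needs a 'ppm' column")
    ppm = df["ppm"].to_numpy(float)
    return [
        Spectrum(ppm=ppm.copy(), intensity=df[c].to_numpy(float), sample_id=str(c))
        for c in df.columns
        if c != "ppm"
    ]


def read_binned_csv(path: str | Path, width: float = DEFAULT_BIN_WIDTH) -> BinnedMatrix:
    """Read a pre-binned samples x bins CSV whose header row holds bin centers
    and whose first column holds sample ids."""
    df = pd.read_csv(path, index_col=0)
    centers = np.array([float(c) for c in df.columns])
    edges = np.column_stack([centers - width / 2, centers + width / 2])
    return BinnedMatrix(
        values=df.to_numpy(float),
        bin_edges=edges,
        sample_ids=[str(i) for i in df.index],
    )


def write_binned_csv(m: BinnedMatrix, path: str | Path) -> None:
    """Write the matrix as CSV (bin centers as header) plus a JSON sidecar
    recording edges, exclusions and the normalization flag."""
    path = Path(path)
    df = pd.DataFrame(m.values, index=m.sample_ids,
                      columns=[f"{c:.6f}" for c in m.bin_centers])
    df.index.name = "sample_id"
    df.to_csv(path)
    sidecar = {
        "bin_edges": m.bin_edges.tolist(),
        "excluded_regions": [list(r) for r in m.excluded_regions],
        "normalized": m.normalized,
        "bin_convention": "half-open [left, right), ascending ppm",
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, sort_keys=True))
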