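"""Statistical total correlation spectroscopy (S-TOCSY).

Correlates every bin of the feature matrix against a driver signal — either
the OPLS predictive score (oriented so higher score means cancer) or a
chosen bin column — yielding the per-bin correlation P(corr)p and covariance
Pp profiles, then annotates which metabolite templates the correlated bins
belong to.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectral_processing import BinnedMatrix
from .synthetic_data import MetaboliteTemplate

DEFAULT_PPM_TOL = 0.02
DEFAULT_CORR_THRESHOLD = 0.3


@dataclass
class StocsyResult:
    p_corr: np.ndarray           # per-bin Pearson correlation with driver
    p_cov: np.ndarray            # per-bin covariance (1/(n-1))
    driver: str                  # description of the driver signal
    bin_edges: np.ndarray


@dataclass
class AnnotationHit:
    metabolite: str
    matched_peaks: int
    max_abs_corr: float
    direction_call: str          # up | down


def stocsy(
    m: BinnedMatrix | np.ndarray,
    driver,
    bin_edges: np.ndarray | None = None,
) -> StocsyResult:
    """Per-bin correlation and covariance against a driver.

    ``driver`` is either a score vector of length n_samples or an integer
    bin index (classic STOCSY mode). Constant columns are reported with a
    correlation of 0 rather than NaN.
    """
    if isinstance(m, BinnedMatrix):
        X, edges = m.values, m.bin_edges
    else:
        X = np.asarray(m, dtype=float)
        edges = bin_edges if bin_edges is not None else np.column_stack(
            [np.arange(X.shape[1]), np.arange(X.shape[1]) + 1.0]
        )
    if np.isscalar(driver) or isinstance(driver, (int, np.integer)):
        j = int(driver)
        desc = f"bin {j} [{edges[j, 0]:.4f}, {edges[j, 1]:.4f}] ppm"
        d = X[:, j].astype(float)
    else:
        d = np.asarray(driver, dtype=float)
        desc = "score vector"
    if d.size != X.shape[0]:
        raise ValueError("driver length must equal the number of samples")
    dc = d - d.mean()
    sd_d = float(np.sqrt((dc @ dc)))
    if sd_d == 0:
        raise ValueError("zero-variance driver")

    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    p_cov = (dc @ Xc) / (n - 1)
    col_ss = np.sqrt((Xc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        p_corr = (dc @ Xc) / (sd_d * col_ss)
    p_corr = np.where(col_ss == 0, 0.0, p_corr)
    p_corr = np.clip(p_corr, -1.0, 1.0)
    return StocsyResult(p_corr=p_corr, p_cov=p_cov, driver=desc, bin_edges=edges)


def annotate(
    result: StocsyResult,
    library: list[MetaboliteTemplate],
    ppm_tol: float = DEFAULT_PPM_TOL,
    corr_threshold: float = DEFAULT_CORR_THRESHOLD,
) -> list[AnnotationHit]:
    """Match correlated bins to metabolite template peaks.

    A template peak matches when some bin whose interval intersects
    ``[center - ppm_tol, center + ppm_tol]`` carries ``|p_corr| >=
    corr_threshold``. Hits are sorted by strongest correlation. The
    direction call for each matched peak comes from the passing bin nearest
    the peak centre — not the strongest bin in the window, which for
    near-degenerate resonances (creatine 3.04 vs creatinine 3.05) can belong
    to a neighbouring metabolite; with the driver oriented so that cancer
    scores higher, "up" reads as elevated in cancer.
    """
    if ppm_tol <= 0 or corr_threshold <= 0:
        raise ValueError("thresholds must be positive")
    lefts, rights = result.bin_edges[:, 0], result.bin_edges[:, 1]
    centers = result.bin_edges.mean(axis=1)
    hits: list[AnnotationHit] = []
    for tpl in library:
        max_corr, matched = 0.0, 0
        best_near_corr, best_near_cov = 0.0, 0.0
        for pk in tpl.peaks:
            sel = (rights > pk.center - ppm_tol) & (lefts < pk.center + ppm_tol)
            if not sel.any():
                continue
            corr = result.p_corr[sel]
            passing = np.abs(corr) >= corr_threshold
            if not passing.any():
                continue
            matched += 1
            max_corr = max(max_corr, float(np.abs(corr).max()))
            pass_idx = np.flatnonzero(sel)[passing]
            k = pass_idx[np.argmin(np.abs(centers[pass_idx] - pk.center))]
            if abs(result.p_corr[k]) > abs(best_near_corr):
                best_near_corr = float(result.p_corr[k])
                best_near_cov = float(result.p_cov[k])
        best_cov = best_near_cov
        if matched >= 1:
            hits.append(
                AnnotationHit(
                    metabolite=tpl.name,
                    matched_peaks=matched,
                    max_abs_corr=max_corr,
                    direction_call="up" if best_cov > 0 else "down",
                )
            )
    hits.sort(key=lambda h: -h.max_abs_corr)
    return hits
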