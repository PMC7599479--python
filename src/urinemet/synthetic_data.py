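"""Synthetic urine 1H-NMR cohort simulation.

Generates seeded two-group (control vs. gastric cancer) cohorts of 1D
frequency-domain urine spectra with the statistical structure the downstream
chemometrics assumes: Lorentzian multiplets for a panel of marker and
background metabolites, a TSP reference singlet at 0 ppm, a dominant broad
water band, lognormal inter-subject concentration variability, and
group-dependent mean shifts for the marker metabolites.

The nine marker metabolites (alanine, citrate, creatine, creatinine,
glycerol, hippurate, phenylalanine, taurine, 3-hydroxybutyrate) carry their
literature chemical shifts and multiplicities; cancer-group means are moved
up or down relative to controls according to each marker's direction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .spectral_processing import Spectrum

MULTIPLICITIES = ("singlet", "doublet", "triplet", "multiplet")

#: ppm interval occupied by the (simulated) residual water resonance.
WATER_REGION = (4.62, 5.15)

#: Default proton frequency of the simulated spectrometer, MHz.
SPECTROMETER_FREQ_MHZ = 500.13


@dataclass(frozen=True)
class MetabolitePeak:
    """One multiplet of a metabolite.

    Parameters
    ----------
    center : float
        Chemical shift of the multiplet centre, ppm.
    multiplicity : str
        One of ``singlet``, ``doublet``, ``triplet``, ``multiplet``.
    j_coupling : float
        Scalar coupling constant in Hz (ignored for singlets).
    relative_area : float
        Fraction of the metabolite's total integral carried by this
        multiplet; the peaks of one metabolite sum to 1.
    """

    center: float
    multiplicity: str
    j_coupling: float = 0.0
    relative_area: float = 1.0

    def __post_init__(self) -> None:
        if not -0.5 <= self.center <= 13.5:
            raise ValueError(f"peak center {self.center} ppm outside [-0.5, 13.5]")
        if self.multiplicity not in MULTIPLICITIES:
            raise ValueError(f"unknown multiplicity {self.multiplicity!r}")
        if not 0 < self.relative_area <= 1:
            raise ValueError("relative_area must lie in (0, 1]")
        if self.multiplicity != "singlet" and self.j_coupling <= 0:
            raise ValueError("non-singlet peaks need j_coupling > 0")


@dataclass(frozen=True)
class MetaboliteTemplate:
    """A metabolite: its multiplets and its direction of change in cancer."""

    name: str
    peaks: tuple[MetabolitePeak, ...]
    direction: str = "none"  # up | down | none

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down", "none"):
            raise ValueError(f"direction must be up/down/none, got {self.direction!r}")
        total = sum(p.relative_area for p in self.peaks)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"{self.name}: peak relative_areas sum to {total}, not 1")


def _mk(name, direction, *peaks):
    total = sum(a for _, _, _, a in peaks)
    return MetaboliteTemplate(
        name=name,
        direction=direction,
        peaks=tuple(
            MetabolitePeak(center=c, multiplicity=m, j_coupling=j, relative_area=a / total)
            for c, m, j, a in peaks
        ),
    )


def build_template_library() -> list[MetaboliteTemplate]:
    """Return the simulated urine metabolite panel.

    Nine marker metabolites with group-dependent directions, the TSP
    chemical-shift reference (singlet at 0.00 ppm), and four direction-free
    background urine metabolites whose peaks stay >= 0.02 ppm away from any
    marker peak centre.

    J-couplings are typical literature values; within the pipeline only the
    peak positions matter once spectra are binned at 0.0073 ppm.
    """
    lib = [
        # (center ppm, multiplicity, J Hz, raw area weight)
        _mk("alanine", "up", (1.49, "doublet", 7.2, 1.0)),
        _mk("citrate", "up",
            (2.54, "doublet", 15.1, 0.5), (2.68, "doublet", 15.1, 0.5)),
        _mk("creatine", "up", (3.04, "singlet", 0.0, 1.0)),
        _mk("creatinine", "down",
            (3.05, "singlet", 0.0, 0.6), (4.07, "singlet", 0.0, 0.4)),
        _mk("glycerol", "down",
            (3.57, "multiplet", 6.0, 0.25), (3.66, "multiplet", 6.0, 0.25),
            (3.78, "multiplet", 6.0, 0.5)),
        _mk("hippurate", "up",
            (3.98, "doublet", 6.0, 0.25), (7.55, "triplet", 7.8, 0.25),
            (7.64, "triplet", 7.8, 0.125), (7.83, "multiplet", 7.8, 0.375)),
        _mk("phenylalanine", "up",
            (7.32, "multiplet", 7.5, 0.4), (7.38, "multiplet", 7.5, 0.4),
            (7.42, "multiplet", 7.5, 0.2)),
        _mk("taurine", "up", (3.27, "triplet", 6.6, 0.5), (3.43, "triplet", 6.6, 0.5)),
        _mk("3-hydroxybutyrate", "down", (1.21, "doublet", 6.3, 1.0)),
        # chemical-shift / intensity reference
        _mk("tsp", "none", (0.00, "singlet", 0.0, 1.0)),
        # background urine metabolites, no group effect; urea dominates the
        # matrix as in real urine, so marker shifts perturb the total area
        # only mildly
        _mk("urea", "none", (5.78, "singlet", 0.0, 1.0)),
        _mk("acetate", "none", (1.92, "singlet", 0.0, 1.0)),
        _mk("succinate", "none", (2.41, "singlet", 0.0, 1.0)),
        _mk("dimethylglycine", "none", (2.93, "singlet", 0.0, 1.0)),
        _mk("histidine", "none", (7.07, "singlet", 0.0, 1.0)),
        _mk("trigonelline", "none", (4.43, "singlet", 0.0, 0.5), (9.12, "singlet", 0.0, 0.5)),
        _mk("formate", "none", (8.44, "singlet", 0.0, 1.0)),
    ]
    return lib


# offsets (in units of J) and area weights per multiplicity; the generic
# "multiplet" is rendered as 4 equal lines spanning 2 J, a symmetric cluster
# that stands in for unresolved higher-order patterns.
_LINE_PATTERNS = {
    "singlet": (np.array([0.0]), np.array([1.0])),
    "doublet": (np.array([-0.5, 0.5]), np.array([0.5, 0.5])),
    "triplet": (np.array([-1.0, 0.0, 1.0]), np.array([0.25, 0.5, 0.25])),
    "multiplet": (np.array([-1.0, -1.0 / 3, 1.0 / 3, 1.0]), np.array([0.25] * 4)),
}


def render_multiplet(
    peak: MetabolitePeak,
    amplitude: float,
    axis: np.ndarray,
    linewidth: float = 0.0015,
    spectrometer_freq: float = SPECTROMETER_FREQ_MHZ,
) -> np.ndarray:
    """Render one multiplet as a sum of Lorentzian lines on ``axis``.

    ``amplitude`` is the total integrated area (over an infinite axis) of the
    multiplet; ``linewidth`` is the Lorentzian full width at half maximum in
    ppm. Line splittings are ``j_coupling / spectrometer_freq`` ppm.
    """
    axis = np.asarray(axis, dtype=float)
    d = np.diff(axis)
    if axis.size < 2 or not (np.all(d > 0) or np.all(d < 0)):
        raise ValueError("axis must be strictly monotone")
    if linewidth <= 0:
        raise ValueError("linewidth must be > 0")
    offsets, weights = _LINE_PATTERNS[peak.multiplicity]
    j_ppm = peak.j_coupling / spectrometer_freq
    centers = peak.center + offsets * j_ppm
    hwhm = linewidth / 2.0
    out = np.zeros_like(axis)
    for c, wgt in zip(centers, weights):
        out += (amplitude * wgt / np.pi) * hwhm / ((axis - c) ** 2 + hwhm**2)
    return out


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one simulated two-group cohort."""

    n_control: int = 100
    n_case: int = 103
    effect_log2fc: float = 0.8
    subject_cv: float = 0.3
    linewidth: float = 0.0015
    noise_sd: float = 0.002
    axis_min: float = -0.5
    axis_max: float = 13.5
    n_points: int = 32768
    seed: int = 0
    tsp_amplitude: float = 1.0
    water_amplitude: float = 5000.0
    creatine_creatinine_anticorr: float = 0.6

    def __post_init__(self) -> None:
        if self.n_control < 2 or self.n_case < 2:
            raise ValueError("need at least 2 samples per group")
        if self.linewidth <= 0:
            raise ValueError("linewidth must be > 0")
        if not self.axis_min < 0 < self.axis_max:
            raise ValueError("axis must bracket 0 ppm (TSP reference)")
        if self.n_points < 16:
            raise ValueError("n_points too small")
        if self.subject_cv < 0 or self.noise_sd < 0:
            raise ValueError("variability parameters must be nonnegative")


#: baseline (control-group) mean concentrations, arbitrary units.  Values are
#: in a plausible urine dynamic range so that markers are visible but none
#: dominates the total area the way creatinine/urea do in real urine.
_DEFAULT_BASE_CONC = {
    "alanine": 0.30,
    "citrate": 0.80,
    "creatine": 0.40,
    "creatinine": 1.50,
    "glycerol": 0.35,
    "hippurate": 0.90,
    "phenylalanine": 0.20,
    "taurine": 0.60,
    "3-hydroxybutyrate": 0.25,
    "urea": 20.00,
    "acetate": 1.50,
    "succinate": 1.50,
    "dimethylglycine": 1.50,
    "histidine": 1.20,
    "trigonelline": 2.40,
    "formate": 0.90,
}

# stage composition of the simulated cancer group, mirroring an early-GC
# heavy clinical series (56 IA, 13 IB, 10 II, 15 III, 9 IV out of 103)
_STAGE_FRACTIONS = (("IA", 56 / 103), ("IB", 13 / 103), ("II", 10 / 103),
                    ("III", 15 / 103), ("IV", 9 / 103))


@dataclass
class SyntheticCohort:
    """Spectra plus ground truth for one simulated cohort."""

    spectra: list[Spectrum]
    labels: list[str]
    stages: list[str]
    true_concentrations: np.ndarray  # samples x metabolites
    metabolite_names: list[str]
    spec: CohortSpec
    library: list[MetaboliteTemplate] = field(repr=False, default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.spectra)
        if not (len(self.labels) == len(self.stages) == self.true_concentrations.shape[0] == n):
            raise ValueError("cohort component lengths disagree")
        if len(set(self.labels)) < 2:
            raise ValueError("cohort must contain both classes")


def _assign_stages(n_case: int) -> list[str]:
    counts = [int(round(f * n_case)) for _, f in _STAGE_FRACTIONS]
    # fix rounding drift on the largest stratum
    counts[0] += n_case - sum(counts)
    stages: list[str] = []
    for (name, _), c in zip(_STAGE_FRACTIONS, counts):
        stages.extend([name] * c)
    return stages[:n_case]


def _water_band(axis: np.ndarray, amplitude: float) -> np.ndarray:
    """Broad Gaussian residual-water resonance centred at 4.88 ppm."""
    fwhm = 0.2
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return amplitude * np.exp(-0.5 * ((axis - 4.88) / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))


def simulate_cohort(
    spec: CohortSpec,
    library: list[MetaboliteTemplate] | None = None,
) -> SyntheticCohort:
    """Simulate a seeded control/cancer urine NMR cohort.

    Per subject, each metabolite concentration is drawn lognormally around
    its group mean; cancer means are ``control_mean * 2**(+-effect_log2fc)``
    with the sign from the template direction. Creatine and creatinine share
    a latent subject factor with opposite signs, reproducing their inverse
    relationship within subjects. All multiplets, a fixed TSP singlet and a
    large water band are rendered on the ppm axis, and Gaussian baseline
    noise (scaled to the TSP peak height) is added. Identical seeds produce
    bit-identical cohorts.
    """
    if library is None:
        library = build_template_library()
    if not library:
        raise ValueError("empty template library")
    rng = np.random.default_rng(spec.seed)
    axis = np.linspace(spec.axis_min, spec.axis_max, spec.n_points)

    metabolites = [t for t in library if t.name != "tsp"]
    names = [t.name for t in metabolites]
    n_total = spec.n_control + spec.n_case
    labels = ["control"] * spec.n_control + ["case"] * spec.n_case
    stages = ["-"] * spec.n_control + _assign_stages(spec.n_case)

    # lognormal with mean mu and CV c: sigma_log = sqrt(ln(1+c^2)),
    # mu_log = ln(mu) - sigma_log^2/2
    cv = spec.subject_cv
    sigma_log = float(np.sqrt(np.log1p(cv * cv)))

    group_means = np.empty((n_total, len(metabolites)))
    for j, tpl in enumerate(metabolites):
        base = _DEFAULT_BASE_CONC.get(tpl.name, 0.3)
        case_mean = base
        if tpl.direction == "up":
            case_mean = base * 2.0**spec.effect_log2fc
        elif tpl.direction == "down":
            case_mean = base * 2.0**-spec.effect_log2fc
        group_means[: spec.n_control, j] = base
        group_means[spec.n_control :, j] = case_mean

    # standard-normal subject x metabolite innovations, with a shared latent
    # factor pushing creatine and creatinine in opposite directions
    z = rng.standard_normal((n_total, len(metabolites)))
    rho = spec.creatine_creatinine_anticorr
    if rho > 0 and "creatine" in names and "creatinine" in names:
        i_cr, i_crn = names.index("creatine"), names.index("creatinine")
        latent = rng.standard_normal(n_total)
        s = np.sqrt(1.0 - rho * rho)
        z[:, i_cr] = rho * latent + s * z[:, i_cr]
        z[:, i_crn] = -rho * latent + s * z[:, i_crn]

    conc = group_means * np.exp(sigma_log * z - 0.5 * sigma_log**2)

    tsp_peak = MetabolitePeak(center=0.0, multiplicity="singlet", j_coupling=0.0,
                              relative_area=1.0)
    # height of a unit-area Lorentzian at its centre
    tsp_height = spec.tsp_amplitude * 2.0 / (np.pi * spec.linewidth)
    water = _water_band(axis, spec.water_amplitude)

    spectra: list[Spectrum] = []
    for i in range(n_total):
        y = water.copy()
        for j, tpl in enumerate(metabolites):
            for pk in tpl.peaks:
                y += render_multiplet(pk, conc[i, j] * pk.relative_area, axis,
                                      spec.linewidth)
        y += render_multiplet(tsp_peak, spec.tsp_amplitude, axis, spec.linewidth)
        if spec.noise_sd > 0:
            y += rng.normal(0.0, spec.noise_sd * tsp_height, size=axis.size)
        spectra.append(Spectrum(ppm=axis.copy(), intensity=y, sample_id=f"S{i + 1:03d}"))

    return SyntheticCohort(
        spectra=spectra,
        labels=labels,
        stages=stages,
        true_concentrations=conc,
        metabolite_names=names,
        spec=spec,
        library=list(library),
    )


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write a cohort as wide CSV + metadata TSV + JSON sidecar.

    The wide CSV has one ``ppm`` column followed by one intensity column per
    sample; the TSV carries ``sample_id``, ``group`` and ``stage``; the
    sidecar records the generating :class:`CohortSpec` including the seed.
    """
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cols = {"ppm": cohort.spectra[0].ppm}
    for s in cohort.spectra:
        cols[s.sample_id] = s.intensity
    spectra_path = out / "spectra.csv"
    pd.DataFrame(cols).to_csv(spectra_path, index=False)

    meta_path = out / "metadata.tsv"
    pd.DataFrame({
        "sample_id": [s.sample_id for s in cohort.spectra],
        "group": cohort.labels,
        "stage": cohort.stages,
    }).to_csv(meta_path, sep="\t", index=False)

    sidecar_path = out / "cohort_spec.json"
    sidecar_path.write_text(json.dumps(asdict(cohort.spec), indent=2, sort_keys=True))
    return {"spectra": spectra_path, "metadata": meta_path, "spec": sidecar_path}
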