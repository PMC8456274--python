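"""Synthetic serum LDI-MS cohorts and laser-shot-resolved acquisitions.

The generator emulates nanoparticle-assisted LDI-MS of serum at the statistical
level needed by the downstream pipeline: a panel of metabolite m/z features
(a few of which are class-discriminating biomarkers), per-subject biological
variation, and per-replicate acquisition noise whose magnitude shrinks as the
number of averaged laser shots grows.

Model
-----
A single laser shot produces

    I_shot(m) = sum_i h_i * eps_i * G(m; mz_i, sigma) + chem(m) + b + e(m)

with ``h_i = 2**log2_abundance_i`` the subject's true peak height and
``eps_i = C * P_i`` a unit-mean multiplicative lognormal factor composed of a
shared per-shot ionization-yield part ``C`` (CV ``shot_cv_common``) and an
independent per-peak part ``P_i`` (CV ``shot_cv * ionization_cv_i``);
``G`` is a unit-height Gaussian line shape,
``chem`` sparse transient nuisance peaks, ``b`` a constant baseline and ``e``
additive Gaussian detector noise.  An ``n_shots`` acquisition is the mean of
``n_shots`` independent shots; peak-apex variance therefore decays as
``1/n_shots`` while the expectation is shot-count independent.  Because peak
shapes are linear in the per-shot heights, the mean spectrum is assembled from
shot-averaged heights and an exactly distributed ``N(0, sigma/sqrt(n))``
detector-noise term rather than by materialising every shot.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, NamedTuple, Sequence

import numpy as np

__all__ = [
    "MetabolitePanel",
    "AcquisitionConfig",
    "CohortSample",
    "Cohort",
    "Spectrum",
    "make_panel",
    "sample_cohort",
    "analytic_spectrum",
    "simulate_spectrum",
    "paired_acquisition",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class MetabolitePanel:
    """Ground-truth metabolite feature panel.

    ``mz`` centers are strictly increasing; abundances are log2 of the expected
    apex intensity in a healthy control; ``effect_log2fc`` is the signed case
    minus control difference in log2 abundance (zero for non-biomarkers).
    """

    mz: np.ndarray
    base_log_abundance: np.ndarray  # log2 apex intensity, control class
    ionization_cv: np.ndarray  # per-feature multiplier on the shot CV
    is_biomarker: np.ndarray  # bool
    effect_log2fc: np.ndarray  # signed; 0 where not a biomarker

    def __post_init__(self) -> None:
        n = len(self.mz)
        for name in ("base_log_abundance", "ionization_cv", "is_biomarker", "effect_log2fc"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"panel field {name!r} length mismatch")
        if n and np.any(np.diff(self.mz) <= 0):
            raise ValueError("panel mz centers must be strictly increasing")
        bad = self.is_biomarker & (self.effect_log2fc == 0)
        if np.any(bad):
            raise ValueError("every biomarker needs a nonzero effect_log2fc")
        if np.any(~self.is_biomarker & (self.effect_log2fc != 0)):
            raise ValueError("non-biomarkers must have zero effect_log2fc")

    @property
    def n_features(self) -> int:
        return len(self.mz)

    @property
    def direction(self) -> np.ndarray:
        """'up' / 'down' / '' per feature, consistent with effect sign."""
        out = np.full(self.n_features, "", dtype=object)
        out[self.is_biomarker & (self.effect_log2fc > 0)] = "up"
        out[self.is_biomarker & (self.effect_log2fc < 0)] = "down"
        return out

    def case_log_abundance(self) -> np.ndarray:
        return self.base_log_abundance + self.effect_log2fc


@dataclass(frozen=True)
class AcquisitionConfig:
    """Instrument/acquisition model parameters.

    ``n_points`` defaults to a desk-scale 8,000-point grid; the full-resolution
    ~80,000-point profile is available by configuration.  Per-shot peak-height
    noise is multiplicative lognormal with two components: a *common*
    ionization-yield factor shared by every peak in the shot (laser coupling;
    the reason TIC-style normalization exists) with CV ``shot_cv_common``, and
    an independent per-peak factor with CV ``shot_cv``.  The defaults put a
    native 1000-shot replicate at ~13.4% apex CV (~12.6% of it shared), the
    regime where replicate-to-replicate variation visibly perturbs diagnosis,
    while preserving the exact 1/n variance decay of shot averaging.
    """

    mz_min: float = 100.0
    mz_max: float = 1000.0
    n_points: int = 8000
    peak_sigma: float = 0.35  # Da
    baseline_level: float = 2.0
    chemical_noise_density: float = 0.08  # expected nuisance peaks per Da
    shot_cv: float = 0.35
    shot_cv_common: float = 4.0
    detector_noise_sigma: float = 6.0  # single-shot additive noise SD
    adduct_relative_height: float = 0.0  # optional +21.98/+37.96 Da satellites
    adduct_offsets: tuple[float, ...] = (21.98, 37.96)
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.mz_min < self.mz_max:
            raise ValueError("mz_min must be < mz_max")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if self.peak_sigma <= 0:
            raise ValueError("peak_sigma must be > 0")
        if self.shot_cv < 0:
            raise ValueError("shot_cv must be >= 0")

    def grid(self) -> np.ndarray:
        return np.linspace(self.mz_min, self.mz_max, self.n_points)


class CohortSample(NamedTuple):
    sample_id: str
    label: int  # 0 control, 1 case
    log_abundance: np.ndarray  # log2, over panel features


@dataclass(frozen=True)
class Cohort:
    samples: tuple[CohortSample, ...]
    cohort_tag: Literal["discovery", "validation"] = "discovery"

    def __post_init__(self) -> None:
        for s in self.samples:
            if s.label not in (0, 1):
                raise ValueError("labels must be binary 0/1")
        sizes = {len(s.log_abundance) for s in self.samples}
        if len(sizes) > 1:
            raise ValueError("abundance vectors must share the panel size")

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.samples])

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def __len__(self) -> int:
        return len(self.samples)


@dataclass(frozen=True)
class Spectrum:
    """One acquisition: ascending m/z grid, nonnegative intensities, metadata."""

    mz: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""
    replicate_id: str = ""
    n_shots: int = 1

    def __post_init__(self) -> None:
        if len(self.mz) != len(self.intensity):
            raise ValueError("mz and intensity lengths differ")
        if len(self.mz) > 1 and np.any(np.diff(self.mz) <= 0):
            raise ValueError("mz must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be nonnegative")

    def __len__(self) -> int:
        return len(self.mz)


# ---------------------------------------------------------------------------
# panel / cohort sampling


def make_panel(
    n_features: int,
    n_biomarkers: int,
    effect_log2fc: float | Sequence[float],
    n_up: int,
    seed: int,
    *,
    mz_min: float = 100.0,
    mz_max: float = 1000.0,
    min_spacing: float = 8.0,
    edge_margin: float = 2.0,
    base_log_abundance_mean: float = 6.0,
    base_log_abundance_sd: float = 0.7,
    ionization_cv_range: tuple[float, float] = (0.8, 1.2),
) -> MetabolitePanel:
    """Draw a metabolite panel with ``n_biomarkers`` class-discriminating features.

    ``n_up`` of the biomarkers are up-regulated in cases, the remainder
    down-regulated.  ``effect_log2fc`` is the magnitude of the case/control
    log2 fold change (scalar, or one value per biomarker).  Feature centers are
    uniform over the m/z range subject to a minimum spacing so peaks do not
    overlap at the default line width.
    """
    if n_biomarkers > n_features:
        raise ValueError("n_biomarkers cannot exceed n_features")
    if n_up > n_biomarkers:
        raise ValueError("n_up cannot exceed n_biomarkers")
    if n_features < 0:
        raise ValueError("n_features must be >= 0")
    rng = np.random.default_rng(seed)

    # rejection-free spaced uniform draw: order statistics + guaranteed gaps;
    # edge_margin keeps every line shape fully inside the scanned range
    lo, hi = mz_min + edge_margin, mz_max - edge_margin
    span = (hi - lo) - min_spacing * max(n_features - 1, 0)
    if span <= 0:
        raise ValueError("m/z range too small for requested spacing")
    u = np.sort(rng.uniform(0, span, size=n_features))
    mz = lo + u + min_spacing * np.arange(n_features)

    base = rng.normal(base_log_abundance_mean, base_log_abundance_sd, size=n_features)
    ion_cv = rng.uniform(*ionization_cv_range, size=n_features)

    is_bio = np.zeros(n_features, dtype=bool)
    effect = np.zeros(n_features)
    if n_biomarkers:
        idx = rng.choice(n_features, size=n_biomarkers, replace=False)
        is_bio[idx] = True
        mag = np.broadcast_to(np.atleast_1d(np.asarray(effect_log2fc, float)), (n_biomarkers,))
        if np.any(mag == 0):
            raise ValueError("biomarker effect_log2fc must be nonzero")
        sign = np.array([1.0] * n_up + [-1.0] * (n_biomarkers - n_up))
        effect[idx] = np.abs(mag) * sign
    return MetabolitePanel(mz, base, ion_cv, is_bio, effect)


def sample_cohort(
    panel: MetabolitePanel,
    n_control: int,
    n_case: int,
    between_subject_cv: float,
    seed: int,
    *,
    cohort_tag: Literal["discovery", "validation"] = "discovery",
) -> Cohort:
    """Draw per-subject true log2 abundances around the class means.

    Between-subject spread is lognormal on the linear intensity scale with the
    stated CV; ``between_subject_cv=0`` returns the class means exactly.
    """
    if n_control < 0 or n_case < 0:
        raise ValueError("cohort counts must be >= 0")
    rng = np.random.default_rng(seed)
    sigma_log2 = math.sqrt(math.log1p(between_subject_cv**2)) / math.log(2)
    samples = []
    for i in range(n_control + n_case):
        label = int(i >= n_control)
        mean = panel.case_log_abundance() if label else panel.base_log_abundance
        la = mean + rng.normal(0.0, sigma_log2, size=panel.n_features)
        samples.append(CohortSample(f"{cohort_tag[:4]}-{i:04d}", label, la))
    return Cohort(tuple(samples), cohort_tag)


# ---------------------------------------------------------------------------
# spectra


def _add_peaks(grid: np.ndarray, out: np.ndarray, centers: np.ndarray,
               heights: np.ndarray, sigma: float) -> None:
    """Accumulate unit-height-scaled Gaussians, evaluated within +-5 sigma."""
    if len(centers) == 0:
        return
    step = grid[1] - grid[0]
    half = max(int(math.ceil(5 * sigma / step)), 1)
    pos = np.searchsorted(grid, centers)
    for c, h, p in zip(centers, heights, pos):
        lo, hi = max(p - half, 0), min(p + half + 1, len(grid))
        if lo < hi:
            out[lo:hi] += h * np.exp(-0.5 * ((grid[lo:hi] - c) / sigma) ** 2)


def _peak_centers_heights(sample_log_abund: np.ndarray, panel: MetabolitePanel,
                          acq: AcquisitionConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Expand panel (+ optional adduct satellites) into centers/heights/cv arrays."""
    centers = panel.mz.copy()
    heights = 2.0 ** np.asarray(sample_log_abund, float)
    cvs = acq.shot_cv * panel.ionization_cv
    if acq.adduct_relative_height > 0:
        for off in acq.adduct_offsets:
            keep = panel.mz + off <= acq.mz_max
            centers = np.concatenate([centers, panel.mz[keep] + off])
            heights = np.concatenate([heights, heights[: panel.n_features][keep]
                                      * acq.adduct_relative_height])
            cvs = np.concatenate([cvs, acq.shot_cv * panel.ionization_cv[keep]])
    return centers, heights, cvs


def analytic_spectrum(sample_log_abund: np.ndarray, panel: MetabolitePanel,
                      acq: AcquisitionConfig) -> np.ndarray:
    """Noise-free expected spectrum (the acquisition's shot-count-free mean,
    excluding chemical noise whose expectation is documented separately)."""
    grid = acq.grid()
    out = np.full(acq.n_points, acq.baseline_level)
    centers, heights, _ = _peak_centers_heights(sample_log_abund, panel, acq)
    _add_peaks(grid, out, centers, heights, acq.peak_sigma)
    return out


def _mean_lognormal_factors(rng: np.random.Generator, cvs: np.ndarray,
                            n_shots: int, common_cv: float = 0.0) -> np.ndarray:
    """Mean over shots of unit-mean multiplicative factors.

    Each shot's factor is (shared lognormal with CV ``common_cv``) x
    (independent per-peak lognormal with CV ``cvs[i]``); both unit mean, so
    the product has unit mean and the mean over shots has variance ~ 1/n.
    """
    sig = np.sqrt(np.log1p(cvs**2))
    z = rng.standard_normal((len(cvs), n_shots)).astype(np.float32)
    per_peak = np.exp(sig[:, None] * z - 0.5 * sig[:, None] ** 2)
    if common_cv > 0:
        sc = math.sqrt(math.log1p(common_cv**2))
        c = np.exp(sc * rng.standard_normal(n_shots) - 0.5 * sc * sc)
        per_peak = per_peak * c[None, :]
    return per_peak.mean(axis=1)


def simulate_spectrum(
    sample: CohortSample | np.ndarray,
    panel: MetabolitePanel,
    acq: AcquisitionConfig,
    n_shots: int,
    seed: int | None = None,
    *,
    replicate_id: str = "r0",
) -> Spectrum:
    """Simulate one ``n_shots``-averaged acquisition of a subject.

    The returned intensity is the exact distributional mean over ``n_shots``
    single-shot draws: per-peak heights carry the mean of ``n_shots`` unit-mean
    lognormal factors, detector noise is drawn as N(0, sigma/sqrt(n_shots)),
    and transient chemical-noise peaks scale with the shot-averaged noise
    level.  Expectation is shot-count independent; apex variance ~ 1/n_shots.
    """
    if n_shots < 1:
        raise ValueError("n_shots must be >= 1")
    if seed is None:
        seed = acq.seed if acq.seed is not None else 0
    rng = np.random.default_rng(seed)
    if isinstance(sample, CohortSample):
        sample_id, log_abund = sample.sample_id, sample.log_abundance
    else:
        sample_id, log_abund = "", np.asarray(sample, float)

    grid = acq.grid()
    out = np.full(acq.n_points, acq.baseline_level)

    centers, heights, cvs = _peak_centers_heights(log_abund, panel, acq)
    if len(centers):
        heights = heights * _mean_lognormal_factors(rng, cvs, n_shots,
                                                    acq.shot_cv_common)
        _add_peaks(grid, out, centers, heights, acq.peak_sigma)

    noise_eff = acq.detector_noise_sigma / math.sqrt(n_shots)

    # transient chemical-noise peaks: Poisson-placed, heights at ~0.5-3.5x the
    # effective noise scale so the S/N<=3 screen has true negatives to remove
    n_chem = rng.poisson(acq.chemical_noise_density * (acq.mz_max - acq.mz_min))
    if n_chem and noise_eff > 0:
        chem_mz = np.sort(rng.uniform(acq.mz_min, acq.mz_max, size=n_chem))
        chem_h = rng.uniform(0.5, 3.5, size=n_chem) * noise_eff
        chem_h = chem_h * _mean_lognormal_factors(rng, np.full(n_chem, acq.shot_cv),
                                                  n_shots, acq.shot_cv_common)
        _add_peaks(grid, out, chem_mz, chem_h, acq.peak_sigma)

    if noise_eff > 0:
        out += rng.normal(0.0, noise_eff, size=acq.n_points)

    np.maximum(out, 0.0, out=out)
    return Spectrum(grid, out, sample_id=sample_id, replicate_id=replicate_id,
                    n_shots=n_shots)


def paired_acquisition(
    sample: CohortSample | np.ndarray,
    panel: MetabolitePanel,
    acq: AcquisitionConfig,
    low_shots: int,
    high_shots: int,
    n_pairs: int,
    seed: int,
) -> list[tuple[Spectrum, Spectrum]]:
    """Aligned (native low-shot, high-shot reference) training pairs.

    Both members of each pair share the subject's true abundances; the
    high-shot member is the stabilizer's reference target.
    """
    if low_shots >= high_shots:
        raise ValueError("low_shots must be < high_shots")
    ss = np.random.SeedSequence(seed).spawn(2 * n_pairs)
    pairs = []
    for k in range(n_pairs):
        lo = simulate_spectrum(sample, panel, acq, low_shots,
                               seed=int(ss[2 * k].generate_state(1)[0] % 2**31),
                               replicate_id=f"low{k}")
        hi = simulate_spectrum(sample, panel, acq, high_shots,
                               seed=int(ss[2 * k + 1].generate_state(1)[0] % 2**31),
                               replicate_id=f"high{k}")
        pairs.append((lo, hi))
    return pairs
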