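"""Synthetic DESI-like milk spectra for the five species and their
cow-milk mixtures.

The generator plants each species' marker peaks at the bundled table's
representative (measured) masses, so downstream ppm matching sees
realistic offsets from the theoretical masses.  Around the markers it
emulates the statistical structure the analysis assumes:

* shared matrix peaks common to every milk,
* species-private peaks (each milk has its own lipidome beyond the
  tabulated markers),
* a goat profile that is a shrunk copy of the cow marker pattern plus
  weak goat-private peaks — making goat, as in real data, the hardest
  species to separate from cow,
* multiplicative lognormal intensity noise per peak and scan
  (mean-corrected, so expected intensities are exact),
* Gaussian ppm-scale m/z jitter,
* Poisson-count background peaks at uniform random m/z,
* a per-scan lognormal TIC factor and occasional failed low-TIC scans,
* a per-source ("farm") multiplicative offset on marker intensities,
* v/v mixing: an alpha-mixture's expected peak intensities are
  (1-alpha) x base + alpha x cow.

Defaults reproduce the study design: 103/27/36/34/73 pure samples of
cow/goat/camel/oat/soya, 6-9 replicate scans each, 30 cow farms, and
the four published cow-into-other mixture series.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .adulteration import default_designs
from .annotation import MarkerRecord, load_marker_table
from .io import PeakList, SampleRecord

PURE_SPECIES = ("cow", "goat", "camel", "oat", "soya")


@dataclass(frozen=True)
class SpeciesProfile:
    """Expected (noise-free) peak pattern of one milk species."""

    species: str
    peaks: tuple  # ((mz, expected_intensity), ...) markers + private peaks
    shared: tuple  # shared matrix peaks, identical across species

    @property
    def all_peaks(self) -> np.ndarray:
        arr = np.array(list(self.peaks) + list(self.shared), dtype=float)
        return arr[np.argsort(arr[:, 0])]


@dataclass(frozen=True)
class SimulationConfig:
    """Free parameters of the generator.

    Sample counts, replicate range and source counts follow the study
    design; the noise laws and their magnitudes are the generator's own
    model of DESI spectra (see docs/methods.md).
    """

    seed: int
    samples_per_species: dict = field(default_factory=lambda: {
        "cow": 103, "goat": 27, "camel": 36, "oat": 34, "soya": 73})
    sources_per_species: dict = field(default_factory=lambda: {
        "cow": 30, "goat": 2, "camel": 2, "oat": 4, "soya": 5})
    replicates_min: int = 6
    replicates_max: int = 9
    marker_intensity: float = 4.0e5  # expected counts of a marker peak
    effect_size: float = 1.0  # multiplier on species-specific peak intensities
    goat_similarity: float = 0.85  # goat's cow-marker intensity relative to cow
    goat_private_scale: float = 0.15  # goat boost on a subset of shared peaks
    shared_peak_count: int = 60
    shared_intensity: float = 2.0e5
    private_peak_count: int = 12
    private_intensity: float = 2.5e5
    intensity_sigma: float = 0.35  # lognormal sigma of per-peak scan noise
    mz_jitter_ppm: float = 5.0
    background_peaks: float = 150.0  # Poisson mean per scan
    background_intensity: float = 5.0e3  # exponential mean
    tic_sigma: float = 0.10  # lognormal sigma of the per-scan TIC factor
    failed_scan_rate: float = 0.02  # scans acquired with ~1% of normal TIC
    mixture_samples_per_level: int = 6
    mz_low: float = 100.0
    mz_high: float = 2000.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 1 <= self.replicates_min <= self.replicates_max:
            raise ValueError("invalid replicate range")
        for name, v in self.samples_per_species.items():
            if v < 1:
                raise ValueError(f"samples for {name} must be >= 1")


def _source_rng(config: SimulationConfig, source_id: str) -> np.random.Generator:
    # per-source stream independent of call order
    return np.random.default_rng([config.seed, zlib.crc32(source_id.encode())])


def default_profiles(config: SimulationConfig,
                     table: list[MarkerRecord] | None = None) -> dict[str, SpeciesProfile]:
    """Species profiles built from the bundled marker table.

    Cow carries the 23 cow markers; camel/oat/soya their attributed
    table rows; goat carries the cow markers shrunk by the similarity
    factor.  Every species additionally gets private peaks and the
    shared matrix peaks, with all m/z inside [100, 2000).
    """
    table = table or load_marker_table()
    rng = np.random.default_rng([config.seed, 0x5F0F])  # profile stream
    shared_mz = np.sort(rng.uniform(config.mz_low + 10, 1100.0, config.shared_peak_count))
    shared_int = config.shared_intensity * rng.lognormal(0.0, 0.5, config.shared_peak_count)
    shared = tuple(zip(shared_mz.tolist(), shared_int.tolist()))

    eff = config.effect_size * config.marker_intensity
    by_species: dict[str, list[tuple[float, float]]] = {s: [] for s in PURE_SPECIES}
    cow_markers = [r for r in table if r.milk_type == "cow"]
    for r in cow_markers:
        by_species["cow"].append((r.representative_mass, eff))
        by_species["goat"].append((r.representative_mass, eff * config.goat_similarity))
    for r in table:
        if r.milk_type == "camel":
            by_species["camel"].append((r.representative_mass, eff))
        elif r.milk_type == "oat":
            by_species["oat"].append((r.representative_mass, eff))
        elif r.milk_type == "soya":
            by_species["soya"].append((r.representative_mass, eff))
        elif r.milk_type == "oat+soya":
            by_species["oat"].append((r.representative_mass, eff))
            by_species["soya"].append((r.representative_mass, eff))
    for sp in PURE_SPECIES:
        if sp == "goat":
            continue
        mz = rng.uniform(config.mz_low + 10, 1500.0, config.private_peak_count)
        inten = config.effect_size * config.private_intensity \
            * rng.lognormal(0.0, 0.3, config.private_peak_count)
        by_species[sp].extend(zip(mz.tolist(), inten.tolist()))
        if sp == "cow":
            # goat mirrors the whole cow-specific pattern (markers and
            # cow-private peaks alike) at shrunk intensity: goat and cow
            # share every peak position and differ only in intensity
            by_species["goat"].extend(
                (m, v * config.goat_similarity) for m, v in zip(mz.tolist(), inten.tolist())
            )
    # goat-private variation hides inside the shared matrix peaks:
    # intensity boosts at existing m/z, never new peaks
    pick = rng.choice(config.shared_peak_count, config.private_peak_count, replace=False)
    by_species["goat"].extend(
        (float(shared_mz[j]), config.goat_private_scale * float(shared_int[j])) for j in pick
    )
    return {
        sp: SpeciesProfile(species=sp, peaks=tuple(by_species[sp]), shared=shared)
        for sp in PURE_SPECIES
    }


def _mixture_expectation(base: SpeciesProfile, cow: SpeciesProfile,
                         alpha: float) -> list[tuple[float, float, bool]]:
    """Union of peaks with (1-alpha) base + alpha cow expected intensity.

    Returns (mz, expected, is_specific): shared peaks are flagged so the
    farm effect applies only to species-specific peaks.
    """
    exp: dict[float, float] = {}
    specific: dict[float, bool] = {}
    for mz, inten in base.peaks:
        exp[mz] = exp.get(mz, 0.0) + (1 - alpha) * inten
        specific[mz] = True
    for mz, inten in cow.peaks:
        exp[mz] = exp.get(mz, 0.0) + alpha * inten
        specific[mz] = True
    for mz, inten in base.shared:  # shared sets are identical across species
        exp[mz] = exp.get(mz, 0.0) + inten
        specific[mz] = False
    return [(mz, v, specific[mz]) for mz, v in exp.items() if v > 0]


def simulate_sample(
    profile: SpeciesProfile,
    config: SimulationConfig,
    rng: np.random.Generator,
    sample_id: str = "sample",
    source_id: str = "src0",
    alpha: float = 0.0,
    cow_profile: SpeciesProfile | None = None,
) -> SampleRecord:
    """Draw one sample's replicate scans.

    ``alpha`` is the v/v cow-milk fraction; for 0 < alpha < 1 a
    ``cow_profile`` must be supplied and the record's species becomes
    ``"mixture"``.  For pure samples the per-source farm offset is
    derived deterministically from (seed, source_id); mixtures draw
    per-sample offsets because base and cow milks are paired randomly.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha {alpha} outside [0, 1]")
    if 0.0 < alpha < 1.0 and cow_profile is None:
        raise ValueError("mixtures need a cow_profile")
    if alpha == 1.0 and cow_profile is not None:
        profile = cow_profile
    if 0.0 < alpha < 1.0:
        peaks = _mixture_expectation(profile, cow_profile, alpha)
        species = "mixture"
        farm_rng = rng
    else:
        peaks = [(mz, v, True) for mz, v in profile.peaks] + \
                [(mz, v, False) for mz, v in profile.shared]
        peaks = [p for p in peaks if p[1] > 0]
        species = "cow" if alpha == 1.0 else profile.species
        farm_rng = _source_rng(config, source_id)

    mz0 = np.array([p[0] for p in peaks])
    expected = np.array([p[1] for p in peaks])
    is_specific = np.array([p[2] for p in peaks])
    # farm effect: one multiplier per species-specific peak, mean-corrected
    fs = config.intensity_sigma * 0.45  # farm variation smaller than scan noise
    farm = np.ones_like(expected)
    if fs > 0:
        farm[is_specific] = np.exp(farm_rng.normal(-fs**2 / 2, fs, int(is_specific.sum())))
    expected = expected * farm

    n_scans = int(rng.integers(config.replicates_min, config.replicates_max + 1))
    scans = []
    sig = config.intensity_sigma
    for _ in range(n_scans):
        tic_factor = np.exp(rng.normal(-config.tic_sigma**2 / 2, config.tic_sigma)) \
            if config.tic_sigma > 0 else 1.0
        if config.failed_scan_rate > 0 and rng.random() < config.failed_scan_rate:
            tic_factor *= 0.01
        noise = np.exp(rng.normal(-sig**2 / 2, sig, len(expected))) if sig > 0 else 1.0
        inten = expected * noise * tic_factor
        mz = mz0.copy()
        if config.mz_jitter_ppm > 0:
            mz = mz * (1.0 + rng.normal(0.0, config.mz_jitter_ppm, len(mz)) * 1e-6)
        if config.background_peaks > 0:
            n_bg = rng.poisson(config.background_peaks)
            bg_mz = rng.uniform(config.mz_low, config.mz_high, n_bg)
            bg_int = rng.exponential(config.background_intensity, n_bg) * tic_factor
            mz = np.concatenate([mz, bg_mz])
            inten = np.concatenate([inten, bg_int])
        order = np.argsort(mz, kind="stable")
        mz, inten = mz[order], inten[order]
        # merge exact m/z collisions to keep the axis strictly ascending
        uniq, inverse = np.unique(mz, return_inverse=True)
        if len(uniq) < len(mz):
            inten = np.bincount(inverse, weights=inten)
            mz = uniq
        scans.append(PeakList(mz=mz, intensity=inten))
    return SampleRecord(
        sample_id=sample_id, species=species, adulteration_fraction=float(alpha),
        source_id=source_id, scans=scans,
    )


def simulate_study(config: SimulationConfig) -> tuple[list[SampleRecord], pd.DataFrame]:
    """The full five-species study plus the four adulteration series.

    Returns the sample records and a truth table (sample_id, species,
    adulteration_fraction, source_id, n_scans).  Fully reproducible from
    ``config.seed``.
    """
    rng = np.random.default_rng([config.seed, 1])
    profiles = default_profiles(config)
    records: list[SampleRecord] = []
    for sp in PURE_SPECIES:
        n = config.samples_per_species[sp]
        n_src = config.sources_per_species.get(sp, 1)
        for i in range(n):
            src = f"{sp}_src{i % n_src:02d}"
            records.append(simulate_sample(
                profiles[sp], config, rng,
                sample_id=f"{sp}_{i:03d}", source_id=src,
                alpha=1.0 if sp == "cow" else 0.0,
                cow_profile=profiles["cow"] if sp == "cow" else None,
            ))
    for base_sp, design in default_designs(
            samples_per_level=config.mixture_samples_per_level).items():
        for level in design.levels:
            for j in range(design.samples_per_level):
                sid = f"mix_{base_sp}_{level:g}_{j}"
                records.append(simulate_sample(
                    profiles[base_sp], config, rng,
                    sample_id=sid, source_id=f"mix_{base_sp}",
                    alpha=level, cow_profile=profiles["cow"],
                ))
    truth = pd.DataFrame({
        "sample_id": [r.sample_id for r in records],
        "species": [r.species for r in records],
        "adulteration_fraction": [r.adulteration_fraction for r in records],
        "source_id": [r.source_id for r in records],
        "n_scans": [len(r.scans) for r in records],
    })
    return records, truth


def pure_study_config(seed: int, scale: float = 1.0, **overrides) -> SimulationConfig:
    """A study config whose per-species sample counts are the design
    counts scaled by ``scale`` (minimum 4 samples per species)."""
    base = SimulationConfig(seed=seed)
    counts = {sp: max(4, int(round(n * scale))) for sp, n in base.samples_per_species.items()}
    return replace(base, samples_per_species=counts, **overrides)
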