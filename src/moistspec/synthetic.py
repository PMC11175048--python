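"""Synthetic vis-NIR soil spectra with known chemistry.

The generator emulates the field study this package models: agricultural
topsoil samples scanned (a) in situ while field moist, (b) after drying and
sieving to <2 mm, and (c) after additional fine grinding, with a
research-grade full-range spectrometer (350-2500 nm at 1 nm) and a
consumer-grade short-range instrument (1350-2500 nm, coarse grid reported
in wavenumbers).

The physical model is deliberately simple and linear in absorbance:

    A(lam) = baseline(lam) + sum_bands amplitude * driver + moisture(lam)
             + multiplicative scatter + additive noise

with Gaussian absorption bands for clay (kaolinite/metal-OH near 1400 and
2200 nm), organic carbon (broad visible darkening plus C-H/C-O overtones),
nitrogen (protein/amine combination band) and water (O-H bands near
1415-1455, 1915 and 2200 nm plus a broad darkening of moist soil).
Reflectance is then R = 10^(-A).  Chemistry drivers enter linearly, so
band-doubling and rank arguments used in the tests hold by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datatypes import SpectraSet, validate_reference_table

# Summary statistics of the emulated study's laboratory analyses
# (percent by mass): [min, Q1, median, Q3, max].
CHEMISTRY_RANGES = {
    "water_content": (8.54, 37.31),
    "soc": (0.74, 3.67),
    "ntot": (0.07, 0.40),
    "clay": (11.35, 55.46),
}

#: Mean soil C:N ratio used to couple total nitrogen to organic carbon.
MEAN_CN_RATIO = 9.2

FULL_RANGE_NM = (350.0, 2500.0)
SHORT_RANGE_NM = (1350.0, 2500.0)


@dataclass(frozen=True)
class AbsorptionBand:
    """One Gaussian absorption feature tied to a chemistry driver.

    ``amplitude_per_unit`` is absorbance per unit of the driver (percent by
    mass for clay/soc/ntot/water).
    """

    center: float  # nm
    width: float  # Gaussian sigma, nm
    amplitude_per_unit: float
    driver: str  # one of clay, soc, ntot, water

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("band width must be positive")
        if not (FULL_RANGE_NM[0] <= self.center <= FULL_RANGE_NM[1]):
            raise ValueError("band center outside 350-2500 nm")
        if self.driver not in ("clay", "soc", "ntot", "water"):
            raise ValueError(f"unknown band driver {self.driver!r}")

    def profile(self, grid: np.ndarray) -> np.ndarray:
        z = (grid - self.center) / self.width
        return np.exp(-0.5 * z * z)


def default_bands() -> list[AbsorptionBand]:
    """Band inventory: clay at 1400/2200 nm, SOC at 600/1730/2100 nm,
    Ntot at 2050 nm, water at 1440/1915/2200 nm."""
    return [
        AbsorptionBand(1400.0, 30.0, 0.004, "clay"),
        AbsorptionBand(2200.0, 25.0, 0.003, "clay"),
        AbsorptionBand(600.0, 150.0, 0.050, "soc"),
        AbsorptionBand(1730.0, 20.0, 0.020, "soc"),
        AbsorptionBand(2100.0, 25.0, 0.020, "soc"),
        AbsorptionBand(2050.0, 25.0, 0.150, "ntot"),
        AbsorptionBand(1440.0, 45.0, 0.010, "water"),
        AbsorptionBand(1915.0, 35.0, 0.015, "water"),
        AbsorptionBand(2200.0, 30.0, 0.004, "water"),
    ]


#: chemistry-independent mineralogy/colour nuisance features (center, sigma)
#: in nm: iron-oxide and electronic-transition bands in the visible/short
#: NIR, a carbonate combination band, and broad colour structure.  Each
#: sample carries its own random amplitude on every feature, identical in
#: all three sample states.
NUISANCE_BANDS = (
    (450.0, 120.0),
    (870.0, 60.0),
    (1000.0, 80.0),
    (1260.0, 40.0),
    (1600.0, 100.0),
    (2340.0, 30.0),
)


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study.

    Defaults reproduce the emulated study's design: 134 sampled points,
    5 field replicates, 3 laboratory replicates, multiplicative scatter
    decreasing from field-moist to finely ground sample states.
    """

    n_samples: int = 134
    bands: list[AbsorptionBand] = field(default_factory=default_bands)
    #: global gain on the water bands, per % gravimetric water.
    moisture_coupling: float = 1.0
    #: broad baseline darkening of moist soil, absorbance per % water.
    moisture_darkening: float = 0.004
    #: sd of the per-sample amplitudes on the mineralogy nuisance features
    #: (absorbance units); identical across the three sample states.
    nuisance_sd: float = 0.03
    #: per-state sd of the multiplicative scatter factor on absorbance.
    scatter_sd_by_state: dict = field(
        default_factory=lambda: {
            "field_moist": 0.030,
            "lab_sieved": 0.015,
            "lab_fine": 0.005,
        }
    )
    baseline_offset_sd: float = 0.01  # additive absorbance offset per replicate
    noise_sd: float = 0.004  # iid absorbance noise per grid point
    #: per-replicate sd of gravimetric water (%) across a field core -
    #: replicate scans of a heterogeneous moist core can see slightly
    #: different moisture (off by default: the core is treated as
    #: homogeneous over the scanned face).
    moisture_jitter_sd: float = 0.0
    replicates_field: int = 5
    replicates_lab: int = 3
    #: probability a field replicate gets a spurious bump.  Field bundles in
    #: the emulated study carried 0-1 outliers each; laboratory bundles none.
    outlier_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 12:
            raise ValueError("need n_samples >= 12 for the EPO subset and split")
        for name in ("baseline_offset_sd", "noise_sd", "moisture_darkening",
                     "nuisance_sd", "moisture_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(v < 0 for v in self.scatter_sd_by_state.values()):
            raise ValueError("scatter sds must be >= 0")
        if not (0 <= self.outlier_rate < 1):
            raise ValueError("outlier_rate must lie in [0, 1)")
        if self.replicates_field < 1 or self.replicates_lab < 1:
            raise ValueError("replicate counts must be >= 1")


def _scaled_beta(rng: np.random.Generator, n: int, a: float, b: float,
                 lo: float, hi: float) -> np.ndarray:
    return lo + (hi - lo) * rng.beta(a, b, size=n)


def sample_reference_chemistry(n: int, seed: int) -> pd.DataFrame:
    """Draw ``n`` samples of (clay, soc, ntot, water_content).

    Clay, water and SOC follow scaled Beta distributions matched to the
    emulated study's quartiles (clay strongly right-skewed); Ntot is coupled
    to SOC through a mean C:N ratio plus noise, giving the agronomic C-N
    correlation (Pearson r >= 0.8 at large n).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    clay = _scaled_beta(rng, n, 0.9, 2.8, *CHEMISTRY_RANGES["clay"])
    water = _scaled_beta(rng, n, 2.0, 2.4, *CHEMISTRY_RANGES["water_content"])
    soc = _scaled_beta(rng, n, 1.2, 2.5, *CHEMISTRY_RANGES["soc"])
    lo_n, hi_n = CHEMISTRY_RANGES["ntot"]
    ntot = np.clip(soc / MEAN_CN_RATIO + rng.normal(0.0, 0.02, size=n), lo_n, hi_n)
    table = pd.DataFrame(
        {
            "sample_id": [f"S{i:03d}" for i in range(n)],
            "clay": clay,
            "soc": soc,
            "ntot": ntot,
            "water_content": water,
        }
    )
    return validate_reference_table(table)


def _baseline(grid: np.ndarray) -> np.ndarray:
    # smooth dry-soil absorbance baseline rising into the visible
    x = (grid - FULL_RANGE_NM[0]) / (FULL_RANGE_NM[1] - FULL_RANGE_NM[0])
    return 0.30 + 0.20 * x

#: extra brightening of finely ground soil (smaller particles scatter more).
STATE_BASELINE_OFFSET = {"lab_sieved": 0.0, "lab_fine": -0.05}


def _dry_absorbance(chem, grid: np.ndarray, state: str,
                    config: SyntheticConfig) -> np.ndarray:
    drivers = {
        "clay": float(chem["clay"]),
        "soc": float(chem["soc"]),
        "ntot": float(chem["ntot"]),
        "water": 0.0,
    }
    absorb = _baseline(grid) + STATE_BASELINE_OFFSET[state]
    for band in config.bands:
        amount = drivers[band.driver]
        if amount != 0.0:
            absorb = absorb + band.amplitude_per_unit * amount * band.profile(grid)
    return absorb


def water_signature(grid: np.ndarray, config: SyntheticConfig) -> np.ndarray:
    """Absorbance added per % gravimetric water (the shared moisture
    direction: O-H bands plus broad darkening)."""
    sig = np.full_like(grid, config.moisture_darkening, dtype=float)
    for band in config.bands:
        if band.driver == "water":
            sig = sig + (
                config.moisture_coupling * band.amplitude_per_unit * band.profile(grid)
            )
    return sig


def _check_grid(grid: np.ndarray) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or len(grid) < 2 or not np.all(np.diff(grid) > 0):
        raise ValueError("grid must be 1-D and strictly increasing")
    if grid[0] < FULL_RANGE_NM[0] - 1e-9 or grid[-1] > FULL_RANGE_NM[1] + 1e-9:
        raise ValueError("grid outside the 350-2500 nm instrument range")
    return grid


def _to_reflectance(absorb: np.ndarray) -> np.ndarray:
    return np.clip(10.0 ** (-absorb), 1e-6, 1.0)


def generate_dry_spectrum(
    chem,
    grid: np.ndarray,
    state: str,
    config: SyntheticConfig,
    seed: int | None = None,
) -> np.ndarray:
    """Reflectance of one dried sample in the given state.

    With ``noise_sd``, ``baseline_offset_sd`` and the state's scatter sd all
    zero the result is a deterministic function of the chemistry row.
    """
    if state not in ("lab_sieved", "lab_fine"):
        raise ValueError(f"dry state must be lab_sieved or lab_fine, got {state!r}")
    grid = _check_grid(grid)
    absorb = _dry_absorbance(chem, grid, state, config)
    scatter_sd = config.scatter_sd_by_state.get(state, 0.0)
    if seed is not None and (scatter_sd or config.baseline_offset_sd or config.noise_sd):
        rng = np.random.default_rng(seed)
        absorb = _apply_scatter_and_noise(absorb, scatter_sd, config, rng)
    return _to_reflectance(absorb)


def _apply_scatter_and_noise(absorb, scatter_sd, config, rng):
    alpha = rng.normal(0.0, scatter_sd) if scatter_sd else 0.0
    beta = rng.normal(0.0, config.baseline_offset_sd) if config.baseline_offset_sd else 0.0
    out = (1.0 + alpha) * absorb + beta
    if config.noise_sd:
        out = out + rng.normal(0.0, config.noise_sd, size=absorb.shape)
    return out


def add_moisture_effect(
    dry: np.ndarray,
    grid: np.ndarray,
    water_content: float,
    config: SyntheticConfig,
) -> np.ndarray:
    """Superimpose the water absorption bands and moist-soil darkening on a
    dry reflectance spectrum.  ``water_content = 0`` returns the input
    unchanged; absorbance at the 1915 nm band grows strictly with water.
    """
    if water_content < 0:
        raise ValueError("water_content must be >= 0")
    if water_content == 0:
        return np.asarray(dry, dtype=float)
    grid = np.asarray(grid, dtype=float)
    absorb = -np.log10(np.asarray(dry, dtype=float))
    absorb = absorb + water_content * water_signature(grid, config)
    return _to_reflectance(absorb)


def instrument_grid(instrument: str) -> tuple[np.ndarray, str]:
    """Native acquisition grid: full_range at 1 nm in nm; short_range at
    8 nm spacing, stored as ascending wavenumbers (cm^-1)."""
    if instrument == "full_range":
        return np.arange(FULL_RANGE_NM[0], FULL_RANGE_NM[1] + 0.5, 1.0), "nm"
    if instrument == "short_range":
        lam = np.arange(SHORT_RANGE_NM[0], SHORT_RANGE_NM[1] + 0.5, 8.0)
        return np.sort(1e7 / lam), "cm-1"
    raise ValueError(f"unknown instrument {instrument!r}")


def generate_dataset(
    config: SyntheticConfig,
    instrument: str = "full_range",
) -> tuple[SpectraSet, pd.DataFrame]:
    """Full synthetic acquisition campaign for one instrument.

    Returns a replicate-level reflectance :class:`SpectraSet` covering all
    three treatments (field_moist with ``replicates_field`` rows per sample,
    lab_sieved and lab_fine with ``replicates_lab`` each) and the matching
    reference-chemistry table.  Output is a pure function of ``config`` and
    the instrument choice.
    """
    stored_grid, xunit = instrument_grid(instrument)
    if xunit == "nm":
        lam = stored_grid
    else:  # simulate on the wavelength axis, store on the wavenumber axis
        lam = np.sort(1e7 / stored_grid)
    chem_seed = int(np.random.default_rng(config.seed).integers(2**31))
    table = sample_reference_chemistry(config.n_samples, chem_seed)
    rng = np.random.default_rng(
        np.random.SeedSequence((config.seed, 0 if instrument == "full_range" else 1))
    )

    rows, ids, treatments, reps = [], [], [], []
    wsig = water_signature(lam, config)
    # per-sample mineralogy nuisance, identical in every sample state so it
    # cancels in the moist-minus-dry difference matrix
    profiles = np.stack(
        [np.exp(-0.5 * ((lam - c) / w) ** 2) for c, w in NUISANCE_BANDS]
    )
    amps = rng.normal(0.0, config.nuisance_sd, size=(config.n_samples, len(NUISANCE_BANDS)))
    for k, (_, chem) in enumerate(table.iterrows()):
        nuisance = amps[k] @ profiles
        dry_sieved = _dry_absorbance(chem, lam, "lab_sieved", config) + nuisance
        dry_fine = _dry_absorbance(chem, lam, "lab_fine", config) + nuisance
        wc = float(chem["water_content"])
        plan = [
            ("field_moist", dry_sieved, config.replicates_field),
            ("lab_sieved", dry_sieved, config.replicates_lab),
            ("lab_fine", dry_fine, config.replicates_lab),
        ]
        for treatment, absorb, n_rep in plan:
            scatter_sd = config.scatter_sd_by_state.get(treatment, 0.0)
            for r in range(n_rep):
                if treatment == "field_moist":
                    wc_rep = wc + (
                        rng.normal(0.0, config.moisture_jitter_sd)
                        if config.moisture_jitter_sd
                        else 0.0
                    )
                    absorb_rep = absorb + max(wc_rep, 0.0) * wsig
                else:
                    absorb_rep = absorb
                a = _apply_scatter_and_noise(absorb_rep, scatter_sd, config, rng)
                refl = _to_reflectance(a)
                if (
                    treatment == "field_moist"
                    and config.outlier_rate
                    and rng.random() < config.outlier_rate
                ):
                    refl = _inject_outlier_bump(refl, lam, rng)
                if xunit == "cm-1":
                    refl = refl[::-1]  # ascending-wavenumber storage order
                rows.append(refl)
                ids.append(str(chem["sample_id"]))
                treatments.append(treatment)
                reps.append(r)
    return (
        SpectraSet(
            ids=np.array(ids, dtype=object),
            grid=stored_grid,
            values=np.vstack(rows),
            xunit=xunit,
            yunit="reflectance",
            treatment=np.array(treatments, dtype=object),
            instrument=instrument,
            replicate=np.array(reps, dtype=int),
        ),
        table,
    )


def _inject_outlier_bump(refl: np.ndarray, lam: np.ndarray,
                         rng: np.random.Generator) -> np.ndarray:
    """Localized spurious reflectance bump (a corrupted replicate).

    A localized (non-uniform) artefact is used because the replicate screen
    is the sd-over-wavelengths of the per-wavelength replicate sd, which a
    uniform offset cannot trigger.
    """
    center = rng.uniform(lam[0] + 100, lam[-1] - 100)
    sigma = rng.uniform(20.0, 50.0)
    amp = rng.uniform(0.10, 0.20)
    bump = amp * np.exp(-0.5 * ((lam - center) / sigma) ** 2)
    return np.clip(refl + bump, 1e-6, 1.0)
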