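"""Spectra processing chain.

The canonical order, applied by :func:`preprocess_pipeline`, is:

1. replicate outlier screening (sd-of-sds statistic, iterative removal),
2. replicate averaging,
3. short-range instrument only: wavenumber-to-wavelength conversion and
   cubic-spline resampling to a 2 nm grid,
4. reflectance-to-absorbance transform, A = log10(1/R),
5. Savitzky-Golay smoothing,
6. standard normal variate (SNV) row normalization.

Each stage appends a record to the returned stage log, so the applied order
is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import savgol_filter

from .datatypes import SpectraSet
from .exceptions import DegenerateInputError


@dataclass
class PreprocessParams:
    """Tunables of the processing chain.

    ``outlier_threshold`` is in reflectance units (the screen runs before
    the absorbance transform).  Savitzky-Golay defaults are window 11 /
    order 2 on the dense full-range grid and window 5 / order 2 on coarse
    short-range grids.
    """

    outlier_threshold: float = 0.01
    sg_window: int = 11
    sg_polyorder: int = 2
    target_spacing_nm: float = 2.0

    def __post_init__(self) -> None:
        if self.outlier_threshold <= 0:
            raise ValueError("outlier_threshold must be > 0")
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
            raise ValueError("sg_window must be odd and > sg_polyorder")
        if self.target_spacing_nm <= 0:
            raise ValueError("target_spacing_nm must be > 0")

    @classmethod
    def for_instrument(cls, instrument: str) -> "PreprocessParams":
        if instrument == "short_range":
            return cls(sg_window=5)
        return cls()


def write_stage_log(log: list[dict], path) -> None:
    """Persist a pipeline stage log as JSON lines (one stage per line)."""
    import json

    with open(path, "w") as fh:
        for record in log:
            fh.write(json.dumps(record, default=str) + "\n")


def replicate_spread_statistic(values: np.ndarray) -> float:
    """Spread of a replicate bundle: the standard deviation over wavelengths
    of the per-wavelength standard deviation across replicates.

    Invariant to a uniform offset between replicates (the per-wavelength
    sds are then all equal).
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] < 2:
        raise ValueError("need at least 2 replicates")
    per_wavelength_sd = np.std(values, axis=0, ddof=1)
    return float(np.std(per_wavelength_sd, ddof=1))


def screen_replicates(
    values: np.ndarray,
    params: PreprocessParams | None = None,
) -> tuple[np.ndarray, list[dict]]:
    """Iteratively drop outlying replicates while the spread statistic
    exceeds the threshold.

    The replicate with the largest mean absolute deviation from the
    replicate mean is removed at each step; never fewer than 2 replicates
    remain (a warning is emitted if the threshold is still exceeded then).
    Returns (indices of kept replicates, removal log).
    """
    params = params or PreprocessParams()
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] < 2:
        raise ValueError("need at least 2 replicates")
    kept = list(range(values.shape[0]))
    log: list[dict] = []
    while True:
        stat = replicate_spread_statistic(values[kept])
        if stat <= params.outlier_threshold:
            break
        if len(kept) <= 2:
            warnings.warn(
                f"replicate spread {stat:.4g} still above threshold "
                f"{params.outlier_threshold} with only 2 replicates left",
                stacklevel=2,
            )
            break
        mean = values[kept].mean(axis=0)
        mad = np.abs(values[kept] - mean).mean(axis=1)
        worst = int(np.argmax(mad))
        log.append(
            {
                "removed_replicate": kept[worst],
                "statistic_before": stat,
                "mean_abs_deviation": float(mad[worst]),
            }
        )
        kept.pop(worst)
    return np.array(kept, dtype=int), log


def average_replicates(values: np.ndarray) -> np.ndarray:
    """Arithmetic per-wavelength mean of the kept replicates."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] < 1:
        raise ValueError("need at least 1 replicate to average")
    return values.mean(axis=0)


def wavenumber_to_wavelength(spectra: SpectraSet) -> SpectraSet:
    """Convert a wavenumber-gridded set to wavelengths: lambda = 1e7 / nu.

    The converted grid is re-sorted ascending with columns re-ordered
    accordingly.
    """
    if spectra.xunit != "cm-1":
        raise ValueError("spectra are not on a wavenumber grid")
    if np.any(spectra.grid <= 0):
        raise ValueError("wavenumbers must be strictly positive")
    lam = 1e7 / spectra.grid
    order = np.argsort(lam)
    out = spectra.with_values(spectra.values[:, order])
    out.grid = lam[order]
    out.xunit = "nm"
    out.validate()
    return out


def resample(spectra: SpectraSet, target_grid: np.ndarray) -> SpectraSet:
    """Natural-cubic-spline interpolation of every spectrum onto
    ``target_grid`` (which must lie inside the source span); exact at the
    source knots."""
    target_grid = np.asarray(target_grid, dtype=float)
    if target_grid[0] < spectra.grid[0] - 1e-9 or target_grid[-1] > spectra.grid[-1] + 1e-9:
        raise ValueError("target grid requires extrapolation beyond the source span")
    spline = CubicSpline(spectra.grid, spectra.values, axis=1, bc_type="natural")
    values = spline(target_grid)
    # spline overshoot can nudge reflectance past its bounds; clamp softly
    if spectra.yunit == "reflectance":
        values = np.clip(values, 1e-9, 1.0)
    return SpectraSet(
        ids=spectra.ids.copy(),
        grid=target_grid,
        values=values,
        xunit=spectra.xunit,
        yunit=spectra.yunit,
        treatment=None if spectra.treatment is None else spectra.treatment.copy(),
        instrument=spectra.instrument,
        replicate=None if spectra.replicate is None else spectra.replicate.copy(),
    )


def to_absorbance(spectra: SpectraSet) -> SpectraSet:
    """Reflectance to absorbance, A = log10(1/R)."""
    if spectra.yunit != "reflectance":
        raise ValueError("spectra are already absorbance")
    if np.any(spectra.values <= 0):
        raise ValueError("reflectance must be strictly positive")
    return spectra.with_values(-np.log10(spectra.values), yunit="absorbance")


def savitzky_golay(spectra: SpectraSet, params: PreprocessParams) -> SpectraSet:
    """Savitzky-Golay smoothing (order-0 output): every interior point is the
    centre of a local least-squares polynomial fit; edges use the polynomial
    fitted to the terminal window."""
    if params.sg_window % 2 == 0:
        raise ValueError("sg_window must be odd")
    if params.sg_window > len(spectra.grid):
        raise ValueError("sg_window exceeds grid length")
    smoothed = savgol_filter(
        spectra.values, params.sg_window, params.sg_polyorder, axis=1, mode="interp"
    )
    return spectra.with_values(smoothed)


def snv(spectra: SpectraSet) -> SpectraSet:
    """Standard normal variate: centre each spectrum to mean 0 and scale to
    sample sd 1 (n-1 denominator)."""
    if spectra.values.shape[1] < 2:
        raise ValueError("need at least 2 grid points per spectrum")
    mean = spectra.values.mean(axis=1, keepdims=True)
    sd = spectra.values.std(axis=1, ddof=1, keepdims=True)
    flat = np.flatnonzero(sd.ravel() == 0)
    if flat.size:
        raise DegenerateInputError(
            f"constant spectrum, SNV undefined for sample(s) "
            f"{list(spectra.ids[flat])}"
        )
    return spectra.with_values((spectra.values - mean) / sd)


def _default_target_grid(grid: np.ndarray, spacing: float) -> np.ndarray:
    start = np.ceil(grid[0] / spacing) * spacing
    stop = np.floor(grid[-1] / spacing) * spacing
    return np.arange(start, stop + spacing / 2, spacing)


def preprocess_pipeline(
    raw: SpectraSet,
    params: PreprocessParams | None = None,
) -> tuple[SpectraSet, list[dict]]:
    """Run the full chain on a replicate-level reflectance set.

    Screening and averaging operate per (sample, treatment) replicate
    bundle.  Returns one processed absorbance spectrum per sample x
    treatment and the stage log.
    """
    params = params or PreprocessParams.for_instrument(raw.instrument)
    if raw.yunit != "reflectance":
        raise ValueError("pipeline expects raw reflectance replicates")
    log: list[dict] = []

    treatments = (
        raw.treatment if raw.treatment is not None else np.array([""] * raw.n_spectra)
    )
    keys = list(dict.fromkeys(zip(raw.ids, treatments)))  # stable order
    averaged, ids, treats = [], [], []
    removals = []
    for sid, treat in keys:
        mask = (raw.ids == sid) & (treatments == treat)
        bundle = raw.values[mask]
        if bundle.shape[0] >= 2:
            kept, rlog = screen_replicates(bundle, params)
            for entry in rlog:
                entry.update(sample_id=sid, treatment=treat)
            removals.extend(rlog)
            bundle = bundle[kept]
        averaged.append(average_replicates(bundle))
        ids.append(sid)
        treats.append(treat)
    spectra = SpectraSet(
        ids=np.array(ids, dtype=object),
        grid=raw.grid.copy(),
        values=np.vstack(averaged),
        xunit=raw.xunit,
        yunit="reflectance",
        treatment=np.array(treats, dtype=object),
        instrument=raw.instrument,
    )
    log.append(
        {
            "stage": "screen_and_average",
            "threshold": params.outlier_threshold,
            "rows_in": int(raw.n_spectra),
            "rows_out": int(spectra.n_spectra),
            "removals": removals,
        }
    )

    if spectra.xunit == "cm-1":
        spectra = wavenumber_to_wavelength(spectra)
        log.append({"stage": "wavenumber_to_wavelength", "rows": int(spectra.n_spectra)})
        target = _default_target_grid(spectra.grid, params.target_spacing_nm)
        spectra = resample(spectra, target)
        log.append(
            {
                "stage": "resample",
                "spacing_nm": params.target_spacing_nm,
                "grid_span": [float(target[0]), float(target[-1])],
            }
        )

    spectra = to_absorbance(spectra)
    log.append({"stage": "to_absorbance"})
    spectra = savitzky_golay(spectra, params)
    log.append(
        {"stage": "savitzky_golay", "window": params.sg_window,
         "polyorder": params.sg_polyorder}
    )
    spectra = snv(spectra)
    log.append({"stage": "snv"})
    return spectra, log
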