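"""Core containers for spectra and reference chemistry.

A :class:`SpectraSet` is a thin, validated wrapper around a 2-D value matrix
(rows = spectra, columns = grid points) plus per-row metadata (sample id,
replicate index, treatment) and set-level metadata (instrument, axis unit,
value unit).  The wide-CSV dialect used on disk has one metadata block
(``sample_id, replicate, treatment, instrument, unit``) followed by one
column per grid point, named ``wl_<nm>`` for wavelength grids and
``wn_<cm-1>`` for wavenumber grids.

A reference table is an ordinary :class:`pandas.DataFrame` with columns
``sample_id, clay, soc, ntot, water_content`` (all percentages by mass);
:func:`validate_reference_table` enforces its invariants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import GridMismatchError, MissingSampleError

TREATMENTS = ("field_moist", "lab_sieved", "lab_fine")
INSTRUMENTS = ("full_range", "short_range")

REFERENCE_COLUMNS = ("sample_id", "clay", "soc", "ntot", "water_content")


@dataclass
class SpectraSet:
    """Wavelength- (or wavenumber-) gridded spectra with metadata.

    Parameters
    ----------
    ids : array of str, one per row.
    grid : strictly increasing axis values, nm or cm^-1 depending on
        ``xunit``.
    values : 2-D array, shape ``(len(ids), len(grid))``.
    xunit : ``"nm"`` or ``"cm-1"``.
    yunit : ``"reflectance"`` or ``"absorbance"``.
    treatment : per-row treatment labels.
    instrument : set-level instrument label.
    replicate : optional per-row replicate index.
    """

    ids: np.ndarray
    grid: np.ndarray
    values: np.ndarray
    xunit: str = "nm"
    yunit: str = "reflectance"
    treatment: np.ndarray | None = None
    instrument: str = "full_range"
    replicate: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.treatment is not None:
            self.treatment = np.asarray(self.treatment, dtype=object)
        if self.replicate is not None:
            self.replicate = np.asarray(self.replicate, dtype=int)
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        n, p = self.values.shape
        if len(self.ids) != n:
            raise ValueError(f"ids length {len(self.ids)} != row count {n}")
        if len(self.grid) != p:
            raise ValueError(f"grid length {len(self.grid)} != column count {p}")
        if p >= 2 and not np.all(np.diff(self.grid) > 0):
            raise ValueError("grid must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectra contain NaN or Inf")
        if self.xunit not in ("nm", "cm-1"):
            raise ValueError(f"unknown axis unit {self.xunit!r}")
        if self.yunit not in ("reflectance", "absorbance"):
            raise ValueError(f"unknown value unit {self.yunit!r}")
        if self.yunit == "reflectance":
            if np.any(self.values <= 0) or np.any(self.values > 1):
                raise ValueError("reflectance values must lie in (0, 1]")
        if self.treatment is not None and len(self.treatment) != n:
            raise ValueError("treatment length mismatch")
        if self.replicate is not None and len(self.replicate) != n:
            raise ValueError("replicate length mismatch")

    # -- basic views ----------------------------------------------------
    @property
    def n_spectra(self) -> int:
        return self.values.shape[0]

    def select(
        self,
        treatment: str | None = None,
        ids: Sequence[str] | None = None,
    ) -> "SpectraSet":
        """Row subset by treatment and/or sample id (order preserved)."""
        mask = np.ones(self.n_spectra, dtype=bool)
        if treatment is not None:
            if self.treatment is None:
                raise ValueError("set carries no treatment metadata")
            mask &= self.treatment == treatment
        if ids is not None:
            wanted = set(ids)
            missing = wanted - set(self.ids[mask])
            if missing:
                raise MissingSampleError(
                    f"sample ids not present: {sorted(missing)}"
                )
            mask &= np.isin(self.ids, list(wanted))
        return self._take(np.flatnonzero(mask))

    def reorder_by_ids(self, order: Sequence[str]) -> "SpectraSet":
        """Reorder rows to follow ``order`` (ids must be unique in the set)."""
        lookup = {}
        for i, sid in enumerate(self.ids):
            if sid in lookup:
                raise ValueError(f"duplicate sample id {sid!r}; reduce replicates first")
            lookup[sid] = i
        try:
            idx = np.array([lookup[s] for s in order], dtype=int)
        except KeyError as exc:
            raise MissingSampleError(f"sample id not present: {exc.args[0]!r}") from exc
        return self._take(idx)

    def _take(self, idx: np.ndarray) -> "SpectraSet":
        return SpectraSet(
            ids=self.ids[idx],
            grid=self.grid.copy(),
            values=self.values[idx],
            xunit=self.xunit,
            yunit=self.yunit,
            treatment=None if self.treatment is None else self.treatment[idx],
            instrument=self.instrument,
            replicate=None if self.replicate is None else self.replicate[idx],
        )

    def with_values(self, values: np.ndarray, yunit: str | None = None) -> "SpectraSet":
        """Same metadata, new value matrix (and optionally unit)."""
        return SpectraSet(
            ids=self.ids.copy(),
            grid=self.grid.copy(),
            values=values,
            xunit=self.xunit,
            yunit=self.yunit if yunit is None else yunit,
            treatment=None if self.treatment is None else self.treatment.copy(),
            instrument=self.instrument,
            replicate=None if self.replicate is None else self.replicate.copy(),
        )

    def same_grid(self, other: "SpectraSet", atol: float = 1e-9) -> bool:
        return (
            self.xunit == other.xunit
            and len(self.grid) == len(other.grid)
            and np.allclose(self.grid, other.grid, atol=atol)
        )

    def require_same_grid(self, other: "SpectraSet") -> None:
        if not self.same_grid(other):
            raise GridMismatchError("spectra sets are not on a common grid")

    # -- wide CSV dialect ----------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        prefix = "wl" if self.xunit == "nm" else "wn"
        cols = [f"{prefix}_{g:.6g}" for g in self.grid]
        df = pd.DataFrame(self.values, columns=cols)
        df.insert(0, "unit", self.yunit)
        df.insert(0, "instrument", self.instrument)
        df.insert(
            0,
            "treatment",
            self.treatment if self.treatment is not None else [""] * self.n_spectra,
        )
        df.insert(
            0,
            "replicate",
            self.replicate if self.replicate is not None else [0] * self.n_spectra,
        )
        df.insert(0, "sample_id", self.ids)
        return df

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SpectraSet":
        meta = ["sample_id", "replicate", "treatment", "instrument", "unit"]
        spectral = [c for c in df.columns if c not in meta]
        if not spectral:
            raise ValueError("no spectral columns found")
        prefix = spectral[0].split("_", 1)[0]
        xunit = {"wl": "nm", "wn": "cm-1"}[prefix]
        grid = np.array([float(c.split("_", 1)[1]) for c in spectral])
        order = np.argsort(grid)
        treatment = df["treatment"].to_numpy(dtype=object)
        has_treatment = bool(np.any(treatment != ""))
        return cls(
            ids=df["sample_id"].astype(str).to_numpy(dtype=object),
            grid=grid[order],
            values=df[spectral].to_numpy(dtype=float)[:, order],
            xunit=xunit,
            yunit=str(df["unit"].iloc[0]),
            treatment=treatment if has_treatment else None,
            instrument=str(df["instrument"].iloc[0]),
            replicate=df["replicate"].to_numpy(dtype=int),
        )

    @classmethod
    def read_csv(cls, path) -> "SpectraSet":
        return cls.from_frame(pd.read_csv(path))


def validate_reference_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the reference-chemistry invariants and return the table.

    All concentrations are percentages by mass; ``water_content`` is
    gravimetric.  Raises ``ValueError`` on violation.
    """
    missing = set(REFERENCE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"reference table missing columns: {sorted(missing)}")
    if table["sample_id"].duplicated().any():
        raise ValueError("sample_id values must be unique")
    numeric = table[["clay", "soc", "ntot", "water_content"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(numeric)):
        raise ValueError("reference values must be finite")
    if np.any(numeric < 0):
        raise ValueError("reference values must be non-negative")
    if np.any(table["clay"].to_numpy(dtype=float) > 100):
        raise ValueError("clay content cannot exceed 100 %")
    return table


def reference_row(table: pd.DataFrame, sample_id: str) -> pd.Series:
    hit = table.loc[table["sample_id"] == sample_id]
    if hit.empty:
        raise MissingSampleError(f"sample id not in reference table: {sample_id!r}")
    return hit.iloc[0]
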