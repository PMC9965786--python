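"""Shared in-memory containers for spectra, CHC profiles and feature tables.

A :class:`Spectrum` is one ATR-FTIR measurement (wavenumber grid +
absorbance vector); a :class:`SpectraSet` is a collection sharing one grid.
A :class:`CHCProfile` holds the percent-of-total-peak-area composition of
one pupa. A :class:`FeatureTable` is the samples × features matrix (plus
age/temperature metadata) that every model consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

META_COLUMNS = ("sample_id", "temperature_C", "age_days", "replicate")


@dataclass
class Spectrum:
    """One absorbance spectrum on a strictly monotone wavenumber grid.

    The canonical orientation is descending wavenumber (FTIR convention,
    4000 → 900 cm⁻¹); ascending inputs are re-oriented on construction.
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavenumbers.ndim != 1 or self.absorbance.ndim != 1:
            raise ValueError("wavenumbers and absorbance must be 1-D")
        if self.wavenumbers.size != self.absorbance.size:
            raise ValueError(
                f"length mismatch: {self.wavenumbers.size} wavenumbers vs "
                f"{self.absorbance.size} absorbance values"
            )
        if self.wavenumbers.size < 2:
            raise ValueError("a spectrum needs at least 2 points")
        if not (np.isfinite(self.wavenumbers).all() and np.isfinite(self.absorbance).all()):
            raise ValueError("spectrum contains non-finite values")
        d = np.diff(self.wavenumbers)
        if np.all(d > 0):  # ascending input: flip to canonical descending
            self.wavenumbers = self.wavenumbers[::-1].copy()
            self.absorbance = self.absorbance[::-1].copy()
        elif not np.all(d < 0):
            raise ValueError("wavenumbers must be strictly monotone")

    @property
    def sample_id(self) -> str | None:
        return self.meta.get("sample_id")

    def replace(self, absorbance: np.ndarray | None = None,
                wavenumbers: np.ndarray | None = None,
                **meta_updates) -> "Spectrum":
        """Return a copy with new data and/or updated metadata."""
        meta = dict(self.meta)
        meta.update(meta_updates)
        return Spectrum(
            wavenumbers=self.wavenumbers if wavenumbers is None else wavenumbers,
            absorbance=self.absorbance if absorbance is None else absorbance,
            meta=meta,
        )


class SpectraSet:
    """A list of spectra constrained to share one wavenumber grid."""

    def __init__(self, spectra: Iterable[Spectrum]):
        self.spectra: list[Spectrum] = list(spectra)
        if self.spectra:
            grid = self.spectra[0].wavenumbers
            bad = [s.sample_id for s in self.spectra
                   if s.wavenumbers.shape != grid.shape
                   or not np.array_equal(s.wavenumbers, grid)]
            if bad:
                raise ValueError(f"spectra on mismatched grids: {bad}")
            self.grid = grid
        else:
            self.grid = np.empty(0)

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    def __getitem__(self, i: int) -> Spectrum:
        return self.spectra[i]

    def absorbance_matrix(self) -> np.ndarray:
        """Stack absorbances into an (n_spectra, n_points) array."""
        if not self.spectra:
            return np.empty((0, self.grid.size))
        return np.vstack([s.absorbance for s in self.spectra])

    def meta_frame(self) -> pd.DataFrame:
        return pd.DataFrame([s.meta for s in self.spectra])


@dataclass
class CHCProfile:
    """Percent-of-total-peak-area cuticular hydrocarbon composition of one pupa."""

    percents: "pd.Series | Mapping[str, float]"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.percents, pd.Series):
            self.percents = pd.Series(dict(self.percents), dtype=float)
        else:
            self.percents = self.percents.astype(float)
        if (self.percents < 0).any():
            raise ValueError("negative percent in CHC profile")

    @property
    def sample_id(self) -> str | None:
        return self.meta.get("sample_id")

    @property
    def compounds(self) -> list[str]:
        return list(self.percents.index)

    def total(self) -> float:
        return float(self.percents.sum())

    def replace(self, percents=None, **meta_updates) -> "CHCProfile":
        meta = dict(self.meta)
        meta.update(meta_updates)
        return CHCProfile(
            percents=self.percents if percents is None else percents,
            meta=meta,
        )


class FeatureTable:
    """Samples × features matrix with sample metadata, the X/y of all models.

    ``data`` holds the numeric features (index = sample_id); ``meta`` holds
    temperature_C, age_days and replicate on the same index.
    """

    def __init__(self, data: pd.DataFrame, meta: pd.DataFrame):
        if data.index.has_duplicates:
            dupes = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample_ids: {dupes}")
        if not data.index.equals(meta.index):
            meta = meta.loc[data.index]
        if data.isna().any().any():
            raise ValueError("feature table contains missing values")
        if len(data) < 1 or data.shape[1] < 1:
            raise ValueError("feature table needs >= 1 sample and >= 1 feature")
        self.data = data
        self.meta = meta

    @property
    def X(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def feature_ids(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    @property
    def sample_ids(self) -> list[str]:
        return [str(i) for i in self.data.index]

    @property
    def ages(self) -> np.ndarray:
        return self.meta["age_days"].to_numpy(dtype=float)

    @property
    def temperatures(self) -> np.ndarray:
        return self.meta["temperature_C"].to_numpy()

    def __len__(self) -> int:
        return len(self.data)

    def subset_temperature(self, temperature_C: int) -> "FeatureTable":
        mask = self.meta["temperature_C"] == temperature_C
        if not mask.any():
            raise ValueError(f"no samples at {temperature_C} C")
        return FeatureTable(self.data.loc[mask.to_numpy()],
                            self.meta.loc[mask.to_numpy()])

    def to_frame(self) -> pd.DataFrame:
        """Single DataFrame with metadata columns ahead of features."""
        return pd.concat([self.meta, self.data], axis=1)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="sample_id")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame,
                   meta_columns: Sequence[str] = ("temperature_C", "age_days", "replicate"),
                   ) -> "FeatureTable":
        meta_cols = [c for c in meta_columns if c in frame.columns]
        meta = frame[meta_cols]
        data = frame.drop(columns=meta_cols)
        return cls(data, meta)

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        frame = pd.read_csv(path, index_col="sample_id")
        return cls.from_frame(frame)
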