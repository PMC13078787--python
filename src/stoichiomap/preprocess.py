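"""Single-cell Raman spectra containers and preprocessing.

The preprocessing chain mirrors common practice for cellular Raman
spectroscopy: background subtraction, cropping to the informative
wavenumber window, Savitzky-Golay smoothing, per-spectrum standardization
(zero mean, unit standard deviation, which removes laser-power variation),
and finally selection of the 700-1800 cm^-1 fingerprint band where
biomolecular signals concentrate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

__all__ = [
    "SpectraSet",
    "SpectraPreprocessor",
    "subtract_background",
    "crop",
    "savitzky_golay",
    "standardize",
]


@dataclass
class SpectraSet:
    """Cells x channels intensity matrix with a wavenumber axis and labels.

    Parameters
    ----------
    intensities : ndarray of shape (n_cells, n_channels)
    wavenumbers : ndarray of shape (n_channels,)
        Strictly increasing, in cm^-1.
    condition : ndarray of shape (n_cells,)
        Condition label per cell.
    replicate : ndarray of shape (n_cells,)
        Biological replicate label per cell.
    cell_id : ndarray of shape (n_cells,), optional
    """

    intensities: np.ndarray
    wavenumbers: np.ndarray
    condition: np.ndarray
    replicate: np.ndarray
    cell_id: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.condition = np.asarray(self.condition)
        self.replicate = np.asarray(self.replicate)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be a 2-D cells x channels matrix")
        n_cells, n_channels = self.intensities.shape
        if self.wavenumbers.shape != (n_channels,):
            raise ValueError(
                f"wavenumber axis length {self.wavenumbers.size} does not match "
                f"channel count {n_channels}"
            )
        if np.any(np.diff(self.wavenumbers) <= 0):
            raise ValueError("wavenumbers must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensity matrix contains non-finite values")
        for name, arr in (("condition", self.condition), ("replicate", self.replicate)):
            if arr.shape != (n_cells,):
                raise ValueError(f"{name} labels must match the cell count {n_cells}")
        if self.cell_id is None:
            self.cell_id = np.array([f"cell{i:05d}" for i in range(n_cells)])
        else:
            self.cell_id = np.asarray(self.cell_id)
            if self.cell_id.shape != (n_cells,):
                raise ValueError("cell_id must match the cell count")

    @property
    def n_cells(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """One row per cell; wavenumbers are encoded in the column names."""
        cols = [f"wn_{w:.6g}" for w in self.wavenumbers]
        df = pd.DataFrame(self.intensities, columns=cols)
        df.insert(0, "replicate", self.replicate)
        df.insert(0, "condition", self.condition)
        df.insert(0, "cell_id", self.cell_id)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SpectraSet":
        wn_cols = [c for c in df.columns if c.startswith("wn_")]
        if not wn_cols:
            raise ValueError("no wavenumber columns (prefix 'wn_') found")
        wavenumbers = np.array([float(c[3:]) for c in wn_cols])
        return cls(
            intensities=df[wn_cols].to_numpy(dtype=float),
            wavenumbers=wavenumbers,
            condition=df["condition"].to_numpy(),
            replicate=df["replicate"].to_numpy(),
            cell_id=df["cell_id"].to_numpy() if "cell_id" in df else None,
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SpectraSet":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


def subtract_background(
    spectra: SpectraSet | np.ndarray,
    background: np.ndarray,
    background_wavenumbers: np.ndarray | None = None,
) -> SpectraSet | np.ndarray:
    """Element-wise subtraction of a background spectrum.

    ``background`` may be a single spectrum (broadcast over cells) or a
    per-cell matrix. When a wavenumber axis is supplied for the background
    it must match the axis of the spectra exactly.
    """
    background = np.asarray(background, dtype=float)
    if isinstance(spectra, SpectraSet):
        if background_wavenumbers is not None and not np.array_equal(
            np.asarray(background_wavenumbers, dtype=float), spectra.wavenumbers
        ):
            raise ValueError("background wavenumber axis does not match the spectra")
        if background.shape[-1] != spectra.n_channels:
            raise ValueError(
                f"background has {background.shape[-1]} channels, spectra have "
                f"{spectra.n_channels}"
            )
        return replace(spectra, intensities=spectra.intensities - background)
    spectra = np.asarray(spectra, dtype=float)
    if spectra.shape[-1] != background.shape[-1]:
        raise ValueError("channel counts of spectrum and background differ")
    return spectra - background


def crop(spectra: SpectraSet, lo: float, hi: float) -> SpectraSet:
    """Keep channels with lo <= wavenumber <= hi (closed interval)."""
    if not lo < hi:
        raise ValueError(f"crop bounds must satisfy lo < hi, got ({lo}, {hi})")
    mask = (spectra.wavenumbers >= lo) & (spectra.wavenumbers <= hi)
    if not mask.any():
        raise ValueError(
            f"crop window [{lo}, {hi}] does not overlap the wavenumber axis "
            f"[{spectra.wavenumbers[0]}, {spectra.wavenumbers[-1]}]"
        )
    return replace(
        spectra,
        intensities=spectra.intensities[:, mask],
        wavenumbers=spectra.wavenumbers[mask],
    )


def savitzky_golay(spectra: SpectraSet, window: int = 11, polyorder: int = 3) -> SpectraSet:
    """Savitzky-Golay smoothing of every spectrum.

    Local least-squares polynomial smoothing; a spectrum that is exactly a
    polynomial of degree <= ``polyorder`` passes through unchanged in the
    window interior.
    """
    if window % 2 != 1 or window < 3:
        raise ValueError(f"window must be an odd integer >= 3, got {window}")
    if polyorder >= window:
        raise ValueError(f"polyorder ({polyorder}) must be smaller than window ({window})")
    if window > spectra.n_channels:
        raise ValueError(
            f"window ({window}) exceeds the channel count ({spectra.n_channels})"
        )
    smoothed = savgol_filter(spectra.intensities, window, polyorder, axis=1)
    return replace(spectra, intensities=smoothed)


def standardize(spectra: SpectraSet | np.ndarray) -> SpectraSet | np.ndarray:
    """Per-spectrum standardization to mean 0 and (sample) standard deviation 1."""
    if isinstance(spectra, SpectraSet):
        return replace(spectra, intensities=standardize(spectra.intensities))
    x = np.atleast_2d(np.asarray(spectra, dtype=float))
    if x.shape[1] < 2:
        raise ValueError("standardization needs at least 2 channels")
    sd = x.std(axis=1, ddof=1)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"spectrum {bad} is constant; standard deviation is zero")
    out = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    return out if np.asarray(spectra).ndim == 2 else out[0]


@dataclass
class SpectraPreprocessor:
    """Deterministic preprocessing chain for cellular Raman spectra.

    Order: background subtraction -> crop to ``crop_range`` -> Savitzky-Golay
    -> per-spectrum standardization -> selection of the fingerprint ``band``.
    Standardizing on the wider crop before selecting the fingerprint band is
    the default; set ``standardize_after_band`` to standardize on the band
    itself instead.
    """

    sg_window: int = 11
    sg_polyorder: int = 3
    crop_range: tuple[float, float] = (632.0, 1862.0)
    band: tuple[float, float] = (700.0, 1800.0)
    standardize_after_band: bool = False

    def transform(
        self, spectra: SpectraSet, background: np.ndarray | None = None
    ) -> SpectraSet:
        out = spectra
        if background is not None:
            out = subtract_background(out, background)
        out = crop(out, *self.crop_range)
        out = savitzky_golay(out, self.sg_window, self.sg_polyorder)
        if self.standardize_after_band:
            out = crop(out, *self.band)
            out = standardize(out)
        else:
            out = standardize(out)
            out = crop(out, *self.band)
        return out

    __call__ = transform
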