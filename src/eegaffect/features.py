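"""Wavelet band-power features.

Each 1 s window is decomposed by a 4-level dyadic discrete wavelet transform
into five subbands that at 128 Hz coincide with the classical EEG bands:
approximation A4 = delta (0-4 Hz) and details D4..D1 = theta (4-8), alpha
(8-16), beta (16-32), gamma (32-64).  The per-band feature is the mean squared
subband coefficient (wavelet band power, the "PSD" of the pipeline); with 14
channels and 5 bands a window yields 70 features.  Features are min-max
normalized to [0, 1] per participant.

The default wavelet is db4 (orthogonal, the standard choice for EEG band
work) with periodized boundary handling, which makes the transform exactly
orthogonal: subband energies sum to the window's time-domain energy and the
coefficient counts are exactly dyadic (64/32/16/8/8 for 128 samples).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pywt

from .preprocessing import WindowSet
from .synthetic import BAND_NAMES

__all__ = [
    "Band",
    "BandScheme",
    "dyadic_scheme",
    "dwt_band_decompose",
    "band_power",
    "welch_band_power",
    "FeatureMatrix",
    "assemble_features",
    "minmax_normalize",
    "apply_norm_params",
    "normalize_per_subject",
]


@dataclass(frozen=True)
class Band:
    name: str
    subband_code: str  # A4, D4, D3, D2, D1
    f_low: float
    f_high: float


@dataclass(frozen=True)
class BandScheme:
    """Dyadic decomposition scheme mapping DWT subbands to named bands."""

    levels: int
    bands: tuple[Band, ...]  # ordered low to high frequency

    def __post_init__(self) -> None:
        if len(self.bands) != self.levels + 1:
            raise ValueError("a k-level dyadic decomposition yields k+1 subbands")
        for a, b in zip(self.bands, self.bands[1:]):
            if a.f_high != b.f_low:
                raise ValueError("bands must partition the spectrum contiguously")

    @property
    def band_names(self) -> tuple[str, ...]:
        return tuple(b.name for b in self.bands)

    def band(self, name: str) -> Band:
        for b in self.bands:
            if b.name == name:
                return b
        raise KeyError(name)


def dyadic_scheme(
    sampling_rate: float = 128.0,
    levels: int = 4,
    names: Sequence[str] = BAND_NAMES,
) -> BandScheme:
    """Band edges from recursive halving of [0, Nyquist].

    At 128 Hz with 4 levels: delta/A4 0-4, theta/D4 4-8, alpha/D3 8-16,
    beta/D2 16-32, gamma/D1 32-64 Hz.
    """
    if len(names) != levels + 1:
        raise ValueError("need one name per subband (levels + 1)")
    nyq = sampling_rate / 2.0
    bands = []
    # approximation first: [0, nyq / 2**levels]
    edges = [0.0] + [nyq / 2 ** k for k in range(levels, -1, -1)]
    codes = [f"A{levels}"] + [f"D{k}" for k in range(levels, 0, -1)]
    for name, code, lo, hi in zip(names, codes, edges[:-1], edges[1:]):
        bands.append(Band(name=name, subband_code=code, f_low=lo, f_high=hi))
    return BandScheme(levels=levels, bands=tuple(bands))


def dwt_band_decompose(
    window: np.ndarray,
    scheme: BandScheme | None = None,
    wavelet: str = "db4",
    mode: str = "periodization",
) -> dict[str, np.ndarray]:
    """Decompose a (channels x samples) window into named subbands.

    Returns a map band name -> (channels x n_coefficients) array, ordered
    low to high frequency (A4 first, then D4..D1).
    """
    window = np.atleast_2d(np.asarray(window, dtype=float))
    scheme = scheme or dyadic_scheme()
    if window.shape[-1] < 2 ** scheme.levels:
        raise ValueError(
            f"window of {window.shape[-1]} samples is too short for a "
            f"{scheme.levels}-level decomposition"
        )
    coeffs = pywt.wavedec(window, wavelet, level=scheme.levels, mode=mode, axis=-1)
    # wavedec returns [A_levels, D_levels, ..., D1]: already low -> high.
    return {band.name: c for band, c in zip(scheme.bands, coeffs)}


def band_power(coeffs: np.ndarray) -> np.ndarray | float:
    """Mean squared coefficient: power per subband coefficient.

    Accepts a single coefficient vector (returns a scalar) or a
    (channels x n) array (returns per-channel powers).
    """
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.shape[-1] == 0:
        raise ValueError("empty coefficient vector")
    out = np.mean(coeffs ** 2, axis=-1)
    return float(out) if out.ndim == 0 else out


def welch_band_power(
    window: np.ndarray, scheme: BandScheme, sampling_rate: float
) -> dict[str, np.ndarray]:
    """Fourier alternative: mean Welch PSD inside each nominal band.

    Provided for comparison with the wavelet band power; not used by the
    default pipeline.
    """
    from scipy import signal as sps

    window = np.atleast_2d(np.asarray(window, dtype=float))
    f, pxx = sps.welch(window, fs=sampling_rate, nperseg=min(window.shape[-1], 128))
    out = {}
    for band in scheme.bands:
        sel = (f >= band.f_low) & (f < band.f_high)
        out[band.name] = pxx[:, sel].mean(axis=-1)
    return out


# ---------------------------------------------------------------------------
# Feature matrix
# ---------------------------------------------------------------------------

_META_COLS = ("subject_id", "trial_id", "window_index", "label")


@dataclass
class FeatureMatrix:
    """Per-window band-power features with labels and provenance.

    Columns are ordered channel-major, band-minor: for each channel in montage
    order, the five bands low to high (delta..gamma).  Column names are
    ``"<channel>:<band>"``.
    """

    values: np.ndarray  # (n_windows, n_channels * n_bands)
    columns: list[tuple[str, str]]  # (channel, band)
    labels: np.ndarray  # str array, per row
    subject_ids: np.ndarray
    trial_ids: np.ndarray
    window_indices: np.ndarray
    normalized: bool = False
    norm_params: pd.DataFrame | None = None  # index = column names, cols x_min/x_max

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.columns):
            raise ValueError("values shape inconsistent with column list")
        n = self.values.shape[0]
        for arr in (self.labels, self.subject_ids, self.trial_ids, self.window_indices):
            if len(arr) != n:
                raise ValueError("metadata length inconsistent with row count")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def column_names(self) -> list[str]:
        return [f"{ch}:{band}" for ch, band in self.columns]

    def subset_rows(self, mask: np.ndarray) -> "FeatureMatrix":
        mask = np.asarray(mask)
        return replace(
            self,
            values=self.values[mask],
            labels=self.labels[mask],
            subject_ids=self.subject_ids[mask],
            trial_ids=self.trial_ids[mask],
            window_indices=self.window_indices[mask],
            norm_params=self.norm_params,
        )

    def select_channels(self, channels: Sequence[str]) -> "FeatureMatrix":
        keep = [i for i, (ch, _) in enumerate(self.columns) if ch in set(channels)]
        missing = set(channels) - {ch for ch, _ in self.columns}
        if missing:
            raise KeyError(f"unknown channels {sorted(missing)}")
        return self._select_cols(keep)

    def select_bands(self, bands: Sequence[str]) -> "FeatureMatrix":
        keep = [i for i, (_, b) in enumerate(self.columns) if b in set(bands)]
        missing = set(bands) - {b for _, b in self.columns}
        if missing:
            raise KeyError(f"unknown bands {sorted(missing)}")
        return self._select_cols(keep)

    def _select_cols(self, idx: list[int]) -> "FeatureMatrix":
        np_sel = None
        if self.norm_params is not None:
            names = [f"{self.columns[i][0]}:{self.columns[i][1]}" for i in idx]
            np_sel = self.norm_params.loc[names]
        return replace(
            self,
            values=self.values[:, idx],
            columns=[self.columns[i] for i in idx],
            norm_params=np_sel,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.column_names)
        df.insert(0, "subject_id", self.subject_ids)
        df.insert(1, "trial_id", self.trial_ids)
        df.insert(2, "window_index", self.window_indices)
        df.insert(3, "label", self.labels)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)
        if self.norm_params is not None:
            sidecar = Path(path).with_suffix(".norm.json")
            sidecar.write_text(json.dumps(self.norm_params.to_dict(orient="index")))

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        feat_cols = [c for c in df.columns if c not in _META_COLS]
        columns = [tuple(c.split(":", 1)) for c in feat_cols]
        norm_params = None
        sidecar = Path(path).with_suffix(".norm.json")
        if sidecar.exists():
            norm_params = pd.DataFrame.from_dict(
                json.loads(sidecar.read_text()), orient="index"
            )
        values = df[feat_cols].to_numpy(dtype=float)
        return cls(
            values=values,
            columns=columns,  # type: ignore[arg-type]
            labels=df["label"].to_numpy(dtype=str),
            subject_ids=df["subject_id"].to_numpy(dtype=int),
            trial_ids=df["trial_id"].to_numpy(dtype=int),
            window_indices=df["window_index"].to_numpy(dtype=int),
            normalized=bool(norm_params is not None),
            norm_params=norm_params,
        )


def assemble_features(
    ws: WindowSet,
    scheme: BandScheme | None = None,
    wavelet: str = "db4",
    channels: Sequence[str] | None = None,
    mode: str = "periodization",
) -> FeatureMatrix:
    """One row of (channel, band) powers per window, unnormalized."""
    scheme = scheme or dyadic_scheme(ws.sampling_rate)
    all_channels = list(ws.channel_names)
    channels = list(channels) if channels is not None else all_channels
    missing = set(channels) - set(all_channels)
    if missing:
        raise KeyError(f"unknown channels {sorted(missing)}")
    ch_idx = [all_channels.index(c) for c in channels]
    columns = [(ch, band.name) for ch in channels for band in scheme.bands]

    rows = np.empty((len(ws.windows), len(columns)))
    for r, w in enumerate(ws.windows):
        sub = dwt_band_decompose(w.data[ch_idx], scheme, wavelet, mode)
        powers = np.column_stack([band_power(sub[b.name]) for b in scheme.bands])
        rows[r] = powers.ravel()  # channel-major, band-minor

    return FeatureMatrix(
        values=rows,
        columns=columns,
        labels=np.array([w.label for w in ws.windows]),
        subject_ids=np.array([w.subject_id for w in ws.windows]),
        trial_ids=np.array([w.trial_id for w in ws.windows]),
        window_indices=np.array([w.window_index for w in ws.windows]),
    )


def _fit_minmax(values: np.ndarray, col_names: list[str]) -> pd.DataFrame:
    return pd.DataFrame(
        {"x_min": values.min(axis=0), "x_max": values.max(axis=0)}, index=col_names
    )


def _transform_minmax(values: np.ndarray, params: pd.DataFrame) -> np.ndarray:
    x_min = params["x_min"].to_numpy()
    x_max = params["x_max"].to_numpy()
    span = x_max - x_min
    degenerate = span == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} constant feature column(s) mapped to 0 "
            "during min-max normalization",
            stacklevel=3,
        )
    safe = np.where(degenerate, 1.0, span)
    out = (values - x_min) / safe
    out[:, degenerate] = 0.0
    return np.clip(out, 0.0, 1.0)


def minmax_normalize(
    fm: FeatureMatrix, fit_rows: np.ndarray | None = None
) -> FeatureMatrix:
    """Scale every feature to [0, 1] by ``(x - x_min) / (x_max - x_min)``.

    ``x_min``/``x_max`` are computed over ``fit_rows`` (default: all rows);
    all rows are transformed and clipped to [0, 1], so rows outside the fit
    set cannot escape the unit interval.  Constant columns map to 0 with a
    warning.
    """
    if fm.normalized:
        raise ValueError("feature matrix is already normalized")
    if fit_rows is None:
        fit = fm.values
    else:
        fit = fm.values[np.asarray(fit_rows)]
        if fit.shape[0] == 0:
            raise ValueError("fit_rows selects no rows")
    params = _fit_minmax(fit, fm.column_names)
    return replace(
        fm,
        values=_transform_minmax(fm.values, params),
        normalized=True,
        norm_params=params,
    )


def apply_norm_params(fm: FeatureMatrix, norm_params: pd.DataFrame) -> FeatureMatrix:
    """Re-apply stored min/max (inference path); values clipped to [0, 1]."""
    params = norm_params.loc[fm.column_names]
    return replace(
        fm,
        values=_transform_minmax(fm.values, params),
        normalized=True,
        norm_params=params,
    )


def normalize_per_subject(fm: FeatureMatrix) -> FeatureMatrix:
    """Min-max normalize each subject on its own rows (self-contained).

    This is the per-participant normalization of the study protocol and the
    one used for the subject-independent (LOSO) analysis, where each held-out
    subject is scaled by its own min/max only.
    """
    if fm.normalized:
        raise ValueError("feature matrix is already normalized")
    out = fm.values.copy()
    for sid in np.unique(fm.subject_ids):
        mask = fm.subject_ids == sid
        params = _fit_minmax(fm.values[mask], fm.column_names)
        out[mask] = _transform_minmax(fm.values[mask], params)
    return replace(fm, values=out, normalized=True, norm_params=None)
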