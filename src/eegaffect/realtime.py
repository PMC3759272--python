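"""Streaming happiness detection.

Incoming samples are tiled into 1 s windows; each window is classified
happy/unhappy by a previously trained subject-dependent model, and every 5
windows a majority vote over the 5 predictions emits a discrete happiness
level:

    happy votes   5   4   3   2   1   0
    output        H3  H2  H1  U1  U2  U3   (H = happy, U = unhappy)

The vote window is odd, so ties are impossible.  Vote blocks do not overlap:
one level is emitted every 5 seconds of signal.

The whole-recording baseline of the offline pipeline is unavailable online;
the streaming default subtracts a causal running mean with a 10 s half-life.
``baseline="window"`` (subtract each window's own mean) and ``"none"`` are
also available — the window mode makes a stream replay bit-identical to the
batch pipeline on the same file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Literal, Sequence

import numpy as np
from scipy import signal as sps

from .classification import load_model
from .features import (
    BandScheme,
    FeatureMatrix,
    apply_norm_params,
    band_power,
    dwt_band_decompose,
    dyadic_scheme,
)

__all__ = [
    "HappinessLevel",
    "DetectorState",
    "vote",
    "classify_window",
    "run_stream",
    "detector_from_file",
]

logger = logging.getLogger(__name__)

HAPPY = "happy"
UNHAPPY = "unhappy"

VOTE_WINDOW = 5

#: happy-vote count -> (polarity, level)
_LEVEL_TABLE: dict[int, tuple[str, int]] = {
    0: (UNHAPPY, 3),
    1: (UNHAPPY, 2),
    2: (UNHAPPY, 1),
    3: (HAPPY, 1),
    4: (HAPPY, 2),
    5: (HAPPY, 3),
}


@dataclass(frozen=True)
class HappinessLevel:
    polarity: str  # happy | unhappy
    level: int  # 1..3
    happy_votes: int  # 0..5


def vote(predictions: Sequence[str]) -> HappinessLevel:
    """Majority vote over exactly 5 per-second predictions."""
    if len(predictions) != VOTE_WINDOW:
        raise ValueError(f"vote requires exactly {VOTE_WINDOW} predictions")
    unknown = set(predictions) - {HAPPY, UNHAPPY}
    if unknown:
        raise ValueError(f"unknown predictions {sorted(unknown)}")
    happy_votes = sum(p == HAPPY for p in predictions)
    polarity, level = _LEVEL_TABLE[happy_votes]
    return HappinessLevel(polarity=polarity, level=level, happy_votes=happy_votes)


@dataclass
class DetectorState:
    """A loaded model plus the rolling prediction buffer of the detector."""

    model: object
    norm_params: object  # per-feature min/max DataFrame from training
    channels: tuple[str, ...]
    sampling_rate: float = 128.0
    scheme: BandScheme | None = None
    wavelet: str = "db4"
    window_length: float = 1.0
    vote_window: int = VOTE_WINDOW
    baseline: Literal["running", "window", "none"] = "running"
    baseline_half_life: float = 10.0  # seconds

    buffer: list[str] = field(default_factory=list)
    emitted: list[tuple[float, int, HappinessLevel]] = field(default_factory=list)
    _ema_state: np.ndarray | None = None
    _n_windows_seen: int = 0

    def __post_init__(self) -> None:
        self.channels = tuple(self.channels)
        if self.scheme is None:
            self.scheme = dyadic_scheme(self.sampling_rate)
        if self.vote_window % 2 == 0:
            raise ValueError("vote window must be odd so ties are impossible")

    @property
    def n_window_samples(self) -> int:
        return round(self.window_length * self.sampling_rate)

    def reset(self) -> None:
        self.buffer.clear()
        self.emitted.clear()
        self._ema_state = None
        self._n_windows_seen = 0

    # -- baseline ----------------------------------------------------------
    def _apply_baseline(self, window: np.ndarray) -> np.ndarray:
        if self.baseline == "none":
            return window
        if self.baseline == "window":
            return window - window.mean(axis=1, keepdims=True)
        # causal exponential running mean, per channel
        d = 0.5 ** (1.0 / (self.baseline_half_life * self.sampling_rate))
        if self._ema_state is None:
            self._ema_state = window[:, :1].copy()
        b, a = [1.0 - d], [1.0, -d]
        zi = self._ema_state * 1.0  # lfilter zi for this 1st-order recursion
        ema = np.empty_like(window)
        for c in range(window.shape[0]):
            ema[c], zf = sps.lfilter(b, a, window[c], zi=[d * zi[c, 0]])
            self._ema_state[c, 0] = ema[c, -1]
        return window - ema


def classify_window(state: DetectorState, window: np.ndarray) -> str:
    """Classify one raw 1 s window; the prediction joins the vote buffer."""
    if state.model is None:
        raise ValueError("detector has no loaded model")
    window = np.asarray(window, dtype=float)
    expected = (len(state.channels), state.n_window_samples)
    if window.shape != expected:
        raise ValueError(f"window shape {window.shape} != expected {expected}")

    window = state._apply_baseline(window)
    sub = dwt_band_decompose(window, state.scheme, state.wavelet)
    powers = np.column_stack(
        [band_power(sub[b.name]) for b in state.scheme.bands]
    ).ravel()  # channel-major, band-minor — same order as training
    columns = [(ch, b.name) for ch in state.channels for b in state.scheme.bands]
    fm = FeatureMatrix(
        values=powers[None, :],
        columns=columns,
        labels=np.array(["?"]),
        subject_ids=np.array([-1]),
        trial_ids=np.array([-1]),
        window_indices=np.array([state._n_windows_seen]),
    )
    fm = apply_norm_params(fm, state.norm_params)
    pred = str(state.model.predict(fm.values)[0])
    state.buffer.append(pred)
    state._n_windows_seen += 1
    return pred


def _iter_windows(
    source: Iterable[np.ndarray] | np.ndarray, n_channels: int, n_samples: int
) -> Iterator[np.ndarray]:
    """Tile a sample stream (array or iterable of sample vectors/chunks)."""
    if isinstance(source, np.ndarray):
        if source.ndim != 2 or source.shape[0] != n_channels:
            raise ValueError(f"stream array must be ({n_channels}, n_samples)")
        n_full = source.shape[1] // n_samples
        if source.shape[1] % n_samples:
            logger.warning(
                "stream ends mid-window: dropping %d trailing samples",
                source.shape[1] % n_samples,
            )
        for k in range(n_full):
            yield source[:, k * n_samples:(k + 1) * n_samples]
        return
    # iterable of per-sample vectors or (n_channels, chunk) blocks
    buf: list[np.ndarray] = []
    held = 0
    for item in source:
        arr = np.asarray(item, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        if arr.shape[0] != n_channels:
            raise ValueError(f"stream item has {arr.shape[0]} channels, expected {n_channels}")
        buf.append(arr)
        held += arr.shape[1]
        while held >= n_samples:
            block = np.concatenate(buf, axis=1)
            yield block[:, :n_samples]
            rest = block[:, n_samples:]
            buf = [rest] if rest.size else []
            held = rest.shape[1] if rest.size else 0
    if held:
        logger.warning("stream ends mid-window: dropping %d trailing samples", held)


def run_stream(
    state: DetectorState, source: Iterable[np.ndarray] | np.ndarray
) -> list[tuple[float, int, HappinessLevel]]:
    """Replay a sample stream; one happiness level per 5 classified windows.

    Returns the emitted events as (timestamp_s, happy_votes, level); the
    timestamp marks the end of each 5 s vote block.  Events are also appended
    to ``state.emitted`` and logged.
    """
    emitted_here: list[tuple[float, int, HappinessLevel]] = []
    for window in _iter_windows(source, len(state.channels), state.n_window_samples):
        classify_window(state, window)
        if len(state.buffer) == state.vote_window:
            level = vote(state.buffer)
            t = state._n_windows_seen * state.window_length
            event = (t, level.happy_votes, level)
            state.emitted.append(event)
            emitted_here.append(event)
            logger.info(
                "emit t=%.0fs happy_votes=%d -> %s level %d",
                t, level.happy_votes, level.polarity, level.level,
            )
            state.buffer.clear()
    return emitted_here


def detector_from_file(path, **overrides) -> DetectorState:
    """Build a DetectorState from a persisted model file."""
    payload = load_model(path)
    kwargs = dict(
        model=payload["model"],
        norm_params=payload["norm_params"],
        channels=tuple(payload["channels"]),
        sampling_rate=payload["sampling_rate"],
        wavelet=payload["wavelet"],
    )
    kwargs.update(overrides)
    return DetectorState(**kwargs)
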