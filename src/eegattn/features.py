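"""The ten per-channel features and feature-vector assembly.

Per channel: six time-domain descriptors (F1-F6), sample entropy (F7), and
three wavelet-packet band-energy ratios (F8 E_theta/E_all, F9 E_alpha/E_all,
F10 E_beta/E_all).  Vectors are feature-major: F1 over all channels, then F2,
and so on — 100 values for the default 10-channel montage.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._wpd import leaf_energies
from .io import feature_column_names
from .preprocess import Epoch

logger = logging.getLogger(__name__)

GROUP_IDS = tuple(f"F{i}" for i in range(1, 11))

FEATURE_DESCRIPTIONS = {
    "F1": "rectified average",
    "F2": "maximum",
    "F3": "peak difference",
    "F4": "root mean square",
    "F5": "standard deviation",
    "F6": "margin factor",
    "F7": "sample entropy",
    "F8": "theta energy ratio",
    "F9": "alpha energy ratio",
    "F10": "beta energy ratio",
}


@dataclass(frozen=True)
class SampEnParams:
    m: int = 2
    r_factor: float = 0.2

    def __post_init__(self):
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if not self.r_factor > 0:
            raise ValueError("r_factor must be positive")


def _default_band_map(level: int, fs: float) -> dict[str, tuple[int, ...]]:
    """Assign leaves to theta/alpha/beta by leaf centre frequency.

    At the default level 7 and 512 Hz each leaf spans 2 Hz; the dyadic grid
    cannot realize a 13 Hz band edge, so the alpha/beta boundary falls at
    14 Hz (leaf centres 9/11/13 -> alpha, 15..29 -> beta).
    """
    width = (fs / 2.0) / (1 << level)
    edges = {"theta": (4.0, 8.0), "alpha": (8.0, 14.0), "beta": (14.0, 30.0)}
    band_map: dict[str, tuple[int, ...]] = {}
    for band, (lo, hi) in edges.items():
        leaves = [
            i for i in range(1 << level)
            if lo <= (i + 0.5) * width < hi
        ]
        band_map[band] = tuple(leaves)
    return band_map


@dataclass(frozen=True)
class WpdParams:
    wavelet: str = "db8"
    level: int = 7
    fs: float = 512.0
    band_map: Mapping[str, tuple[int, ...]] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.level < 1:
            raise ValueError("level must be >= 1")
        band_map = self.band_map
        if band_map is None:
            band_map = _default_band_map(self.level, self.fs)
            object.__setattr__(self, "band_map", band_map)
        seen: set[int] = set()
        for band, leaves in band_map.items():
            for leaf in leaves:
                if leaf in seen:
                    raise ValueError(f"leaf {leaf} assigned to two bands")
                if not 0 <= leaf < (1 << self.level):
                    raise ValueError(f"leaf {leaf} out of range for level {self.level}")
                seen.add(leaf)


# ---------------------------------------------------------------------------
# F1-F6: time-domain descriptors
# ---------------------------------------------------------------------------


def time_domain_features(x: np.ndarray) -> tuple[float, float, float, float, float, float]:
    """Return (F1..F6) for one window.

    F1 mean |x|; F2 max x (signed, as printed); F3 max-min; F4 RMS;
    F5 population standard deviation; F6 margin factor
    max |x| / (mean sqrt|x|)^2.  F6 is NaN for an all-zero window.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite samples")
    abs_x = np.abs(x)
    f1 = float(abs_x.mean())
    f2 = float(x.max())
    f3 = float(x.max() - x.min())
    f4 = float(np.sqrt(np.mean(x * x)))
    f5 = float(x.std())  # population (1/N) normalization
    sqrt_amp = float(np.mean(np.sqrt(abs_x))) ** 2
    if sqrt_amp == 0.0:
        logger.warning("all-zero window: margin factor undefined")
        f6 = math.nan
    else:
        f6 = float(abs_x.max()) / sqrt_amp
    return f1, f2, f3, f4, f5, f6


# ---------------------------------------------------------------------------
# F7: sample entropy
# ---------------------------------------------------------------------------


def _sampen_counts_numpy(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    n = x.shape[0] - m
    tm = np.lib.stride_tricks.sliding_window_view(x, m)[:n]
    tm1 = np.lib.stride_tricks.sliding_window_view(x, m + 1)[:n]
    b = a = 0
    chunk = 512
    for i0 in range(0, n, chunk):
        d = np.abs(tm[i0 : i0 + chunk, None, :] - tm[None, :, :]).max(axis=-1)
        b += int((d < r).sum())
        d1 = np.abs(tm1[i0 : i0 + chunk, None, :] - tm1[None, :, :]).max(axis=-1)
        a += int((d1 < r).sum())
    # remove self-matches (distance 0 < r always)
    return (b - n) // 2, (a - n) // 2


def _make_numba_counts():
    try:
        import numba
    except ImportError:  # pragma: no cover - env-dependent
        return None

    @numba.njit(cache=True)
    def counts(x, m, r):  # pragma: no cover - compiled
        n = x.shape[0] - m
        b = 0
        a = 0
        for i in range(n - 1):
            for j in range(i + 1, n):
                d = 0.0
                for k in range(m):
                    t = abs(x[i + k] - x[j + k])
                    if t > d:
                        d = t
                if d < r:
                    b += 1
                    t = abs(x[i + m] - x[j + m])
                    if t > d:
                        d = t
                    if d < r:
                        a += 1
        return b, a

    return counts


_numba_counts = _make_numba_counts()


def _sampen_counts(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    """Matched template-pair counts at lengths m and m+1 (i < j, D < r)."""
    if _numba_counts is not None:
        b, a = _numba_counts(np.ascontiguousarray(x, dtype=np.float64), m, float(r))
        return int(b), int(a)
    return _sampen_counts_numpy(np.asarray(x, dtype=np.float64), m, r)


def sample_entropy(x: np.ndarray, params: SampEnParams = SampEnParams()) -> float:
    """SampEn(m, r) = -ln(A/B) with Chebyshev distance and strict ``D < r``.

    Follows the Richman-Moorman convention: N - m templates are formed at
    both lengths m and m+1, self-matches are excluded and matched pairs are
    counted symmetrically.  The tolerance is ``r_factor`` times the window's
    population standard deviation.  Returns NaN (logged) when no template
    pair matches at length m + 1.
    """
    x = np.asarray(x, dtype=np.float64)
    n = x.shape[0]
    if n <= params.m + 1:
        raise ValueError(f"need more than m+1={params.m + 1} samples, got {n}")
    sd = float(x.std())
    if sd == 0.0:
        raise ValueError("zero-variance window: tolerance r would be 0")
    r = params.r_factor * sd
    b, a = _sampen_counts(x, params.m, r)
    if b == 0 or a == 0:
        logger.warning("sample entropy undefined (B=%d, A=%d)", b, a)
        return math.nan
    return float(-np.log(a / b))


# ---------------------------------------------------------------------------
# F8-F10: wavelet-packet band-energy ratios
# ---------------------------------------------------------------------------


def wpd_band_ratios(
    x: np.ndarray, fs: float, params: WpdParams | None = None
) -> tuple[float, float, float]:
    """(E_theta, E_alpha, E_beta) / E_all from a full wavelet-packet tree.

    Leaf energies are sums of squared coefficients in natural frequency
    order; E_all is the total over all leaves.  Input shorter than a
    multiple of ``2**level`` is zero-padded (pad contributes no energy).
    """
    if params is None:
        params = WpdParams(fs=fs)
    x = np.asarray(x, dtype=np.float64)
    block = 1 << params.level
    if x.shape[0] < block:
        raise ValueError(f"need at least 2**level={block} samples, got {x.shape[0]}")
    if x.shape[0] % block:
        pad = block - x.shape[0] % block
        x = np.concatenate([x, np.zeros(pad)])
    energies = leaf_energies(x, params.level, params.wavelet)
    e_all = float(energies.sum())
    if e_all == 0.0:
        raise ValueError("zero-energy window: band ratios undefined")
    ratios = tuple(
        float(energies[list(params.band_map[band])].sum()) / e_all
        for band in ("theta", "alpha", "beta")
    )
    return ratios  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


@dataclass
class FeatureVector:
    """One epoch's features in feature-major order plus metadata."""

    values: np.ndarray
    channel_labels: tuple[str, ...]
    label: int
    subject_id: str
    session_id: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (10 * len(self.channel_labels),):
            raise ValueError(
                f"expected {10 * len(self.channel_labels)} values, "
                f"got {self.values.shape}"
            )

    @property
    def column_names(self) -> list[str]:
        return feature_column_names(self.channel_labels)


def extract_features(
    epoch: Epoch,
    se: SampEnParams = SampEnParams(),
    wpd: WpdParams | None = None,
) -> FeatureVector:
    """Compute F1..F10 for every channel of one epoch."""
    if wpd is None:
        wpd = WpdParams(fs=epoch.fs)
    n_ch = epoch.data.shape[0]
    per_channel = np.empty((10, n_ch))
    for c in range(n_ch):
        x = epoch.data[c]
        try:
            per_channel[0:6, c] = time_domain_features(x)
            per_channel[6, c] = sample_entropy(x, se)
            per_channel[7:10, c] = wpd_band_ratios(x, epoch.fs, wpd)
        except ValueError as exc:
            raise ValueError(
                f"feature extraction failed on channel "
                f"{epoch.channel_labels[c]!r}: {exc}"
            ) from exc
    return FeatureVector(
        values=per_channel.reshape(-1),  # feature-major
        channel_labels=epoch.channel_labels,
        label=epoch.label,
        subject_id=epoch.subject_id,
        session_id=epoch.session_id,
    )


def extract_batch(
    epochs: Sequence[Epoch],
    se: SampEnParams = SampEnParams(),
    wpd: WpdParams | None = None,
) -> pd.DataFrame:
    """Feature table for a batch of epochs: metadata columns + one column per
    (feature, channel) pair in feature-major order."""
    if not epochs:
        raise ValueError("no epochs to extract")
    vectors = [extract_features(ep, se, wpd) for ep in epochs]
    columns = vectors[0].column_names
    data = np.stack([v.values for v in vectors])
    df = pd.DataFrame(data, columns=columns)
    df.insert(0, "session", [v.session_id for v in vectors])
    df.insert(0, "subject", [v.subject_id for v in vectors])
    df.insert(0, "label", [v.label for v in vectors])
    return df
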