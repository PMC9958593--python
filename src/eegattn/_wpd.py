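"""Periodized orthogonal wavelet-packet decomposition.

Implements the full binary filter-bank tree with circular (periodized)
convolution, which keeps the transform exactly orthogonal so leaf energies
partition signal energy.  Leaves are returned in natural frequency order:
because decimating the high-pass branch mirrors its spectrum, the low/high
outputs of a node swap frequency position whenever the node sits at an odd
frequency index (the standard Gray-code reordering).
"""

from __future__ import annotations

import numpy as np

# Orthonormal Daubechies scaling filters (reconstruction low-pass), keyed by
# vanishing moments.  Values are the standard published coefficients.
_SCALING_FILTERS: dict[str, np.ndarray] = {
    "db1": np.array([0.7071067811865476, 0.7071067811865476]),
    "db2": np.array([
        0.4829629131445342, 0.8365163037378079,
        0.22414386804201342, -0.1294095225512604,
    ]),
    "db4": np.array([
        0.23037781330889645, 0.7148465705529156,
        0.630880767929859, -0.027983769416859487,
        -0.18703481171909303, 0.030841381835560646,
        0.03288301166688516, -0.010597401785069016,
    ]),
    "db8": np.array([
        0.054415842243104015, 0.3128715909143001,
        0.6756307362972899, 0.5853546836542067,
        -0.01582910525634809, -0.28401554296154685,
        0.00047248457391295385, 0.12874742662047886,
        -0.01736930100180782, -0.04408825393079466,
        0.013981027917398279, 0.008746094047405756,
        -0.004870352993451565, -0.0003917403733769486,
        0.0006754494064505691, -0.00011747678412476947,
    ]),
}


def wavelet_filters(name: str) -> tuple[np.ndarray, np.ndarray]:
    """Return the (low-pass, high-pass) orthonormal analysis pair."""
    try:
        h = _SCALING_FILTERS[name]
    except KeyError:
        raise ValueError(
            f"unknown wavelet {name!r}; available: {sorted(_SCALING_FILTERS)}"
        ) from None
    g = (h[::-1] * np.power(-1.0, np.arange(len(h)))).copy()
    return h, g


def _analysis_step(v: np.ndarray, h: np.ndarray, g: np.ndarray):
    """One periodized decomposition step: v (even length) -> (approx, detail)."""
    n = v.shape[0]
    L = h.shape[0]
    idx = (2 * np.arange(n // 2)[:, None] + np.arange(L)[None, :]) % n
    windows = v[idx]
    return windows @ h, windows @ g


def wpd_leaves(x: np.ndarray, level: int, wavelet: str = "db4") -> list[np.ndarray]:
    """Full wavelet-packet decomposition; returns 2**level leaf coefficient
    arrays ordered by increasing frequency.

    The input length must be a multiple of ``2**level`` (callers zero-pad).
    """
    if level < 1:
        raise ValueError("level must be >= 1")
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("expected a 1-D signal")
    if x.shape[0] % (1 << level) != 0:
        raise ValueError(
            f"signal length {x.shape[0]} not divisible by 2**level={1 << level}"
        )
    h, g = wavelet_filters(wavelet)

    nodes: dict[int, np.ndarray] = {0: x}  # freq position -> coefficients
    for _ in range(level):
        next_nodes: dict[int, np.ndarray] = {}
        for pos, v in nodes.items():
            lo, hi = _analysis_step(v, h, g)
            if pos % 2 == 0:
                next_nodes[2 * pos] = lo
                next_nodes[2 * pos + 1] = hi
            else:  # spectrum of this node is mirrored: swap children
                next_nodes[2 * pos] = hi
                next_nodes[2 * pos + 1] = lo
        nodes = next_nodes
    return [nodes[p] for p in range(1 << level)]


def leaf_energies(x: np.ndarray, level: int, wavelet: str = "db4") -> np.ndarray:
    """Energy (sum of squared coefficients) of each frequency-ordered leaf."""
    return np.array([float(np.sum(c * c)) for c in wpd_leaves(x, level, wavelet)])
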