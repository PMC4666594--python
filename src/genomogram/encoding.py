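"""Numeric encodings of DNA: Voss indicators, affine reductions, power spectra.

A DNA string over {A, C, G, T} is first expanded into the Voss representation
``u``: four binary indicator rows (ordered A, C, G, T), one per base, with
``u[b, n] = 1`` iff the base at position ``n`` is ``b``. The 4-row indicator
matrix is redundant (columns are one-hot) and is reduced to three real
channels ``(x_r, x_g, x_b)`` by one of two affine transforms:

* **Z-curve** — the classic purine/pyrimidine, amino/keto and strong/weak
  axes::

      x_r[n] = u_A[n] - u_C[n] + u_G[n] - u_T[n]
      x_g[n] = u_A[n] + u_C[n] - u_G[n] - u_T[n]
      x_b[n] = u_A[n] - u_C[n] - u_G[n] + u_T[n]

  so each base maps to a corner of the cube {-1, +1}^3.

* **Tetrahedron** — each base maps to a unit vector from the centre of a
  regular tetrahedron to one of its vertices (the "rgb" mapping)::

      A -> (0, 0, 1)
      T -> (2*sqrt(2)/3,  0,          -1/3)
      C -> (-sqrt(2)/3,   sqrt(6)/3,  -1/3)
      G -> (-sqrt(2)/3,  -sqrt(6)/3,  -1/3)

Both transforms are applied per position (non-cumulative), so the channels
are piecewise-constant base indicators rather than a running walk; a
cumulative variant is available via ``cumulative=True`` for users who want
the classic Z-curve trajectory. Per-position channels are what produce the
salt-and-pepper image textures downstream.

The power spectrum sums squared DFT magnitudes over the three channels,
excluding the DC term — the standard genomic-signal view in which protein
coding regions show the period-3 peak at k = N/3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sequences import ALPHABET, DnaSequence

__all__ = [
    "VossMatrix",
    "AffineSignal",
    "Spectrum",
    "voss_encode",
    "voss_decode",
    "zcurve_transform",
    "tetrahedron_transform",
    "affine_transform",
    "decode_affine",
    "power_spectrum",
    "ZCURVE_BASE_VECTORS",
    "TETRAHEDRON_BASE_VECTORS",
]

_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}

# Columns of the affine maps, keyed by base, rows (x_r, x_g, x_b).
ZCURVE_BASE_VECTORS: dict[str, np.ndarray] = {
    "A": np.array([1.0, 1.0, 1.0]),
    "C": np.array([-1.0, 1.0, -1.0]),
    "G": np.array([1.0, -1.0, -1.0]),
    "T": np.array([-1.0, -1.0, 1.0]),
}

_S2, _S6 = np.sqrt(2.0), np.sqrt(6.0)
TETRAHEDRON_BASE_VECTORS: dict[str, np.ndarray] = {
    "A": np.array([0.0, 0.0, 1.0]),
    "C": np.array([-_S2 / 3, _S6 / 3, -1.0 / 3]),
    "G": np.array([-_S2 / 3, -_S6 / 3, -1.0 / 3]),
    "T": np.array([2 * _S2 / 3, 0.0, -1.0 / 3]),
}


@dataclass(frozen=True)
class VossMatrix:
    """4xN binary indicator matrix, rows ordered (A, C, G, T)."""

    u: np.ndarray

    def __post_init__(self) -> None:
        u = np.asarray(self.u)
        if u.ndim != 2 or u.shape[0] != 4:
            raise ValueError("Voss matrix must be 4xN")
        if not np.isin(u, (0, 1)).all():
            raise ValueError("Voss entries must be 0 or 1")
        if not (u.sum(axis=0) == 1).all():
            raise ValueError("Voss columns must be one-hot")
        object.__setattr__(self, "u", u.astype(np.int8))

    @property
    def n(self) -> int:
        return self.u.shape[1]


@dataclass(frozen=True)
class AffineSignal:
    """3xN real channel matrix (x_r, x_g, x_b) tagged with its transform."""

    channels: np.ndarray
    transform: str  # "zcurve" | "tetrahedron"

    def __post_init__(self) -> None:
        c = np.asarray(self.channels, dtype=float)
        if c.ndim != 2 or c.shape[0] != 3:
            raise ValueError("AffineSignal needs a 3xN channel matrix")
        if self.transform not in ("zcurve", "tetrahedron"):
            raise ValueError(f"unknown transform {self.transform!r}")
        object.__setattr__(self, "channels", c)

    @property
    def n(self) -> int:
        return self.channels.shape[1]


@dataclass(frozen=True)
class Spectrum:
    """One-sided power spectrum, DC excluded: indices k = 1..floor(N/2)."""

    k: np.ndarray
    power: np.ndarray

    @property
    def peak_k(self) -> int:
        return int(self.k[np.argmax(self.power)])


def voss_encode(seq: DnaSequence) -> VossMatrix:
    """Expand a DNA sequence into its 4xN one-hot indicator matrix."""
    idx = np.fromiter((_BASE_INDEX[b] for b in seq.bases), dtype=np.intp, count=seq.n)
    u = np.zeros((4, seq.n), dtype=np.int8)
    u[idx, np.arange(seq.n)] = 1
    return VossMatrix(u)


def voss_decode(v: VossMatrix, id: str = "decoded") -> DnaSequence:
    idx = np.argmax(v.u, axis=0)
    return DnaSequence(id=id, bases="".join(ALPHABET[i] for i in idx))


def _apply_base_map(v: VossMatrix, vectors: dict[str, np.ndarray]) -> np.ndarray:
    m = np.column_stack([vectors[b] for b in ALPHABET])  # 3x4, columns A,C,G,T
    return m @ v.u.astype(float)


def zcurve_transform(v: VossMatrix, cumulative: bool = False) -> AffineSignal:
    """Reduce a Voss matrix to the three Z-curve channels (values in {-1, +1})."""
    c = _apply_base_map(v, ZCURVE_BASE_VECTORS)
    if cumulative:
        c = np.cumsum(c, axis=1)
    return AffineSignal(c, "zcurve")


def tetrahedron_transform(v: VossMatrix, cumulative: bool = False) -> AffineSignal:
    """Reduce a Voss matrix to tetrahedron-vertex channels (unit columns)."""
    c = _apply_base_map(v, TETRAHEDRON_BASE_VECTORS)
    if cumulative:
        c = np.cumsum(c, axis=1)
    return AffineSignal(c, "tetrahedron")


_TRANSFORMS = {"zcurve": zcurve_transform, "tetrahedron": tetrahedron_transform}


def affine_transform(v: VossMatrix, kind: str, cumulative: bool = False) -> AffineSignal:
    try:
        fn = _TRANSFORMS[kind]
    except KeyError:
        raise ValueError(f"unknown transform {kind!r}") from None
    return fn(v, cumulative=cumulative)


def decode_affine(s: AffineSignal, id: str = "decoded") -> DnaSequence:
    """Invert a per-position affine signal back to its DNA sequence.

    Both base maps are injective, so each column is matched to the nearest
    base vector; exact for non-cumulative signals.
    """
    vectors = (
        ZCURVE_BASE_VECTORS if s.transform == "zcurve" else TETRAHEDRON_BASE_VECTORS
    )
    m = np.column_stack([vectors[b] for b in ALPHABET])  # 3x4
    d2 = (
        np.sum(s.channels**2, axis=0)[None, :]
        - 2 * m.T @ s.channels
        + np.sum(m**2, axis=0)[:, None]
    )
    idx = np.argmin(d2, axis=0)
    return DnaSequence(id=id, bases="".join(ALPHABET[i] for i in idx))


def power_spectrum(s: AffineSignal) -> Spectrum:
    """Channel-summed one-sided power spectrum, DC term excluded."""
    n = s.n
    if n < 2:
        raise ValueError("power spectrum needs N >= 2")
    f = np.fft.rfft(s.channels, axis=1)  # full-resolution DFT of each channel
    power = np.sum(np.abs(f) ** 2, axis=0)
    kmax = n // 2
    return Spectrum(k=np.arange(1, kmax + 1), power=power[1 : kmax + 1])
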