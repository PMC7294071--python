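"""Real even-order spherical harmonics and Funk-Hecke convolution.

Basis convention (documented once, here): real, orthonormal, antipodally
symmetric.  Coefficients are ordered l ascending (even only), m from -l
to +l within each l, giving (l_max+1)(l_max+2)/2 coefficients.  For a
complex harmonic Y_lm (scipy convention, Condon-Shortley phase):

    m < 0 :  sqrt(2) * Im(Y_l|m|)
    m = 0 :  Y_l0 (real)
    m > 0 :  sqrt(2) * Re(Y_lm)

A fibre orientation distribution (FOD) expanded in this basis integrates
over the sphere to c_00 * sqrt(4π) — the apparent fibre density read-out.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import sph_harm_y

from .biophysics import ResponseFunction

__all__ = [
    "SHSeries",
    "n_coefficients",
    "lm_pairs",
    "sh_basis",
    "sh_fit",
    "sh_eval",
    "funk_hecke_convolve",
    "delta_series",
    "fibonacci_hemisphere",
]

log = logging.getLogger(__name__)


def n_coefficients(l_max: int) -> int:
    """Number of even-order real SH coefficients up to l_max."""
    return (l_max + 1) * (l_max + 2) // 2


def lm_pairs(l_max: int) -> list[tuple[int, int]]:
    return [(l, m) for l in range(0, l_max + 1, 2) for m in range(-l, l + 1)]


@dataclass(frozen=True)
class SHSeries:
    """Even-order real spherical-harmonic series."""

    l_max: int
    coeffs: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.coeffs, dtype=float)
        if c.shape != (n_coefficients(self.l_max),):
            raise ValueError(
                f"l_max={self.l_max} needs {n_coefficients(self.l_max)} "
                f"coefficients, got {c.shape}"
            )
        if not np.all(np.isfinite(c)):
            raise ValueError("non-finite SH coefficients")
        object.__setattr__(self, "coeffs", c)

    @property
    def integral(self) -> float:
        """Integral of the function over the sphere: c_00 * sqrt(4π)."""
        return float(self.coeffs[0] * np.sqrt(4 * np.pi))

    def pad_to(self, l_max: int) -> "SHSeries":
        if l_max < self.l_max:
            raise ValueError("cannot pad to a lower order")
        out = np.zeros(n_coefficients(l_max))
        out[: self.coeffs.size] = self.coeffs
        return SHSeries(l_max, out)


def sh_basis(directions: np.ndarray, l_max: int) -> np.ndarray:
    """Design matrix of real even SH values: rows directions, cols (l, m)."""
    if l_max % 2 or l_max < 0:
        raise ValueError(f"l_max must be even and >= 0, got {l_max}")
    d = np.atleast_2d(np.asarray(directions, dtype=float))
    theta = np.arccos(np.clip(d[:, 2], -1.0, 1.0))
    phi = np.arctan2(d[:, 1], d[:, 0])
    cols = []
    for l in range(0, l_max + 1, 2):
        for m in range(-l, l + 1):
            y = sph_harm_y(l, abs(m), theta, phi)
            if m < 0:
                cols.append(np.sqrt(2.0) * y.imag)
            elif m == 0:
                cols.append(y.real)
            else:
                cols.append(np.sqrt(2.0) * y.real)
    return np.column_stack(cols)


def sh_eval(series: SHSeries, directions: np.ndarray) -> np.ndarray:
    return sh_basis(directions, series.l_max) @ series.coeffs


def sh_fit(values: np.ndarray, directions: np.ndarray, l_max: int) -> SHSeries:
    """Ordinary least-squares SH fit of sampled amplitudes."""
    v = np.asarray(values, dtype=float)
    d = np.atleast_2d(np.asarray(directions, dtype=float))
    need = n_coefficients(l_max)
    if d.shape[0] < need:
        raise ValueError(
            f"underdetermined SH fit: l_max={l_max} has {need} coefficients "
            f"but only {d.shape[0]} directions were given (need >= {need})"
        )
    basis = sh_basis(d, l_max)
    cond = np.linalg.cond(basis)
    if cond > 1e6:
        log.warning("ill-conditioned SH design matrix (cond=%.3g)", cond)
    coeffs, *_ = np.linalg.lstsq(basis, v, rcond=None)
    return SHSeries(l_max, coeffs)


def funk_hecke_multipliers(response: ResponseFunction, b_value: float,
                           l_max: int) -> np.ndarray:
    """Per-coefficient convolution factors r_l * sqrt(4π/(2l+1))."""
    r_l = response.zonal(b_value)
    if l_max > response.l_max:
        raise ValueError(
            f"FOD l_max={l_max} exceeds response l_max={response.l_max}"
        )
    mult = np.empty(n_coefficients(l_max))
    i = 0
    for l in range(0, l_max + 1, 2):
        factor = r_l[l // 2] * np.sqrt(4 * np.pi / (2 * l + 1))
        for _ in range(-l, l + 1):
            mult[i] = factor
            i += 1
    return mult


def funk_hecke_convolve(fod: SHSeries, response: ResponseFunction,
                        b_value: float) -> SHSeries:
    """Predicted signal harmonics of an FOD under the single-fibre kernel.

    Funk-Hecke: each (l, m) coefficient is scaled by
    r_l(b) * sqrt(4π/(2l+1)); the l=0 factor equals the kernel's spherical
    (powder) average times sqrt(4π).
    """
    mult = funk_hecke_multipliers(response, b_value, fod.l_max)
    return SHSeries(fod.l_max, fod.coeffs * mult)


def delta_series(axis: np.ndarray, l_max: int) -> SHSeries:
    """Band-limited unit-integral delta FOD at ``axis``.

    The spherical delta has coefficients f_lm = Y_lm(axis); its integral
    is Y_00 * sqrt(4π) = 1.
    """
    coeffs = sh_basis(np.asarray(axis, dtype=float)[None, :], l_max)[0]
    return SHSeries(l_max, coeffs)


def fibonacci_hemisphere(n: int) -> np.ndarray:
    """Deterministic near-uniform directions on the upper hemisphere.

    Used for constraint/evaluation grids where antipodal duplicates are
    redundant (even-order functions are symmetric).
    """
    i = np.arange(n) + 0.5
    z = i / n  # upper hemisphere only
    phi = np.pi * (1 + np.sqrt(5.0)) * i
    r = np.sqrt(1 - z**2)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
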