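"""Two-compartment single-fibre diffusion signal model.

The voxel signal is a weighted sum of a "stick" (intra-axonal: axially
symmetric tensor with zero perpendicular diffusivity) and a "zeppelin"
(extra-axonal: same parallel diffusivity, non-zero perpendicular
diffusivity).  With b in ms/μm², unit gradient g, fibre axis n and
c = g·n:

    S(b, g) = f exp(-b d∥ c²) + (1-f) exp(-b [D_e⊥ + (d∥ - D_e⊥) c²])

Signals are S0-normalised (b=0 gives exactly 1).  Rician noise replaces S
by sqrt((S+e1)² + e2²) with e1, e2 ~ N(0, σ²), σ = 1/SNR on the b=0
signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.special import eval_legendre

from .acquisition import AcquisitionScheme

__all__ = [
    "CompartmentParams",
    "FibreConfig",
    "SignalSet",
    "NoiseModel",
    "NOISELESS",
    "compartment_signal",
    "add_rician_noise",
    "analytic_response",
    "ResponseFunction",
    "KERNEL_PARAMS",
]

#: parallel diffusivity of both compartments, μm²/ms
DEFAULT_D_PAR = 1.9


@dataclass(frozen=True)
class CompartmentParams:
    """Stick-zeppelin parameters.

    f : intra-axonal signal fraction, in [0, 1]
    d_par : parallel diffusivity of both compartments, μm²/ms
    d_e_perp : extra-axonal perpendicular diffusivity, μm²/ms
    """

    f: float
    d_par: float = DEFAULT_D_PAR
    d_e_perp: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 <= self.f <= 1.0:
            raise ValueError(f"f={self.f} outside [0, 1]")
        if self.d_par <= 0:
            raise ValueError(f"d_par={self.d_par} must be > 0")
        if not 0.0 <= self.d_e_perp <= self.d_par:
            raise ValueError(
                f"d_e_perp={self.d_e_perp} outside [0, d_par={self.d_par}]"
            )


#: the fixed deconvolution kernel: response-function parameters
KERNEL_PARAMS = CompartmentParams(f=0.3, d_par=DEFAULT_D_PAR, d_e_perp=0.8)


@dataclass(frozen=True)
class FibreConfig:
    """One or more coherent fibre populations (orientation, weight)."""

    components: tuple[tuple[np.ndarray, float], ...]

    def __post_init__(self) -> None:
        comps = []
        total = 0.0
        for orient, w in self.components:
            v = np.asarray(orient, dtype=float)
            nrm = np.linalg.norm(v)
            if nrm < 1e-12:
                raise ValueError("zero-norm fibre orientation")
            if w < 0:
                raise ValueError("negative fibre weight")
            comps.append((v / nrm, float(w)))
            total += w
        if not comps:
            raise ValueError("at least one fibre component required")
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fibre weights sum to {total}, expected 1")
        object.__setattr__(self, "components", tuple(comps))

    @classmethod
    def single(cls, orientation=(0.0, 0.0, 1.0)) -> "FibreConfig":
        return cls(((np.asarray(orientation, dtype=float), 1.0),))


@dataclass(frozen=True)
class SignalSet:
    """S0-normalised amplitudes in the scheme's measurement order."""

    scheme: AcquisitionScheme
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.scheme.n_measurements,):
            raise ValueError(
                f"{v.shape[0] if v.ndim else 0} values for a scheme with "
                f"{self.scheme.n_measurements} measurements"
            )
        object.__setattr__(self, "values", v)

    def shell_values(self, b_value: float) -> np.ndarray:
        return self.values[self.scheme.measurement_slices()[b_value]]


_NOISELESS_SENTINEL = "noiseless"


@dataclass(frozen=True)
class NoiseModel:
    """Rician noise at a given SNR (σ = 1/snr on the S0 = 1 scale)."""

    snr: float | str
    seed: int = 0

    def __post_init__(self) -> None:
        if self.snr != _NOISELESS_SENTINEL:
            if not (isinstance(self.snr, (int, float)) and self.snr > 0):
                raise ValueError(
                    f"snr must be > 0 or {_NOISELESS_SENTINEL!r}, got {self.snr!r}"
                )

    @property
    def is_noiseless(self) -> bool:
        return self.snr == _NOISELESS_SENTINEL


NOISELESS = NoiseModel(_NOISELESS_SENTINEL)


def stick_zeppelin(params: CompartmentParams, b_ms_um2, cos_angle) -> np.ndarray:
    """Signal of the two-compartment model at b (ms/μm²), c = g·n."""
    b = np.asarray(b_ms_um2, dtype=float)
    c2 = np.square(np.asarray(cos_angle, dtype=float))
    intra = np.exp(-b * params.d_par * c2)
    extra = np.exp(-b * (params.d_e_perp + (params.d_par - params.d_e_perp) * c2))
    return params.f * intra + (1.0 - params.f) * extra


def compartment_signal(params: CompartmentParams, fibre: FibreConfig,
                       scheme: AcquisitionScheme) -> SignalSet:
    """Noise-free voxel signal over every measurement of ``scheme``."""
    values = [np.ones(scheme.n_b0)]
    for shell in scheme.shells:
        s = np.zeros(shell.n_directions)
        for axis, w in fibre.components:
            c = shell.directions @ axis
            s += w * stick_zeppelin(params, shell.b_ms_um2, c)
        values.append(s)
    return SignalSet(scheme, np.concatenate(values))


def add_rician_noise(signals: SignalSet, noise: NoiseModel) -> SignalSet:
    """Corrupt with Rician noise; the noiseless sentinel is a no-op."""
    if noise.is_noiseless:
        return signals
    rng = np.random.default_rng(noise.seed)
    sigma = 1.0 / float(noise.snr)
    e1, e2 = rng.normal(scale=sigma, size=(2, signals.values.shape[0]))
    noisy = np.hypot(signals.values + e1, e2)
    return SignalSet(signals.scheme, noisy)


# ---------------------------------------------------------------------------
# analytic response function


@dataclass(frozen=True)
class ResponseFunction:
    """Per-shell zonal (m=0) spherical-harmonic coefficients of the kernel.

    ``shells`` maps b-value (s/mm²) to the even-l coefficient vector
    (r_0, r_2, ..., r_lmax) of the axially symmetric single-fibre signal
    about its axis.
    """

    l_max: int
    shells: dict[float, np.ndarray]
    kernel_params: CompartmentParams | None = None

    def __post_init__(self) -> None:
        for b, r in self.shells.items():
            r = np.asarray(r, dtype=float)
            if r.shape != (self.l_max // 2 + 1,):
                raise ValueError(f"shell b={b}: expected {self.l_max // 2 + 1} "
                                 f"zonal coefficients, got {r.shape}")
            if not np.all(np.isfinite(r)):
                raise ValueError(f"shell b={b}: non-finite coefficients")
            if r[0] <= 0:
                raise ValueError(f"shell b={b}: r_0 must be positive")

    def zonal(self, b_value: float) -> np.ndarray:
        try:
            return np.asarray(self.shells[b_value])
        except KeyError:
            raise KeyError(
                f"no response for shell b={b_value}; "
                f"available: {sorted(self.shells)}"
            ) from None


_GL_ORDER = 64
_GL_NODES, _GL_WEIGHTS = leggauss(_GL_ORDER)


def zonal_coefficients(func, l_max: int) -> np.ndarray:
    """Even-l m=0 SH coefficients of an axially symmetric function.

    ``func`` maps cosθ to amplitude.  r_l = 2π ∫ f(c) Y_l0(c) dc with
    Y_l0(c) = sqrt((2l+1)/4π) P_l(c), by 64-point Gauss-Legendre
    quadrature (exact for polynomial integrands far beyond l=8).
    """
    if l_max % 2 or l_max < 0:
        raise ValueError(f"l_max must be even and >= 0, got {l_max}")
    vals = func(_GL_NODES)
    out = np.empty(l_max // 2 + 1)
    for i, l in enumerate(range(0, l_max + 1, 2)):
        y_l0 = np.sqrt((2 * l + 1) / (4 * np.pi)) * eval_legendre(l, _GL_NODES)
        out[i] = 2 * np.pi * np.sum(_GL_WEIGHTS * vals * y_l0)
    return out


def zonal_eval(r_l: np.ndarray, cos_angle) -> np.ndarray:
    """Evaluate a zonal series at cosθ: sum_l r_l Y_l0(θ)."""
    c = np.asarray(cos_angle, dtype=float)
    out = np.zeros_like(c)
    for i, r in enumerate(np.asarray(r_l)):
        l = 2 * i
        out += r * np.sqrt((2 * l + 1) / (4 * np.pi)) * eval_legendre(l, c)
    return out


def analytic_response(params: CompartmentParams, scheme: AcquisitionScheme,
                      l_max: int = 8) -> ResponseFunction:
    """Zonal response of the stick-zeppelin kernel on every shell."""
    if l_max % 2:
        raise ValueError(f"l_max must be even, got {l_max}")
    shells = {}
    for shell in scheme.shells:
        b = shell.b_ms_um2
        shells[shell.b_value] = zonal_coefficients(
            lambda c: stick_zeppelin(params, b, c), l_max
        )
    return ResponseFunction(l_max, shells, params)
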