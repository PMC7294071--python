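"""The b-value simulation study: AFD over a grid of fibre geometries.

42 combinations of intra-axonal signal fraction f (7 values) and
extra-axonal perpendicular diffusivity D_e,⊥ (6 values) are pushed
through the two-compartment simulator and deconvolved with the fixed
mismatched kernel (f=0.3, D_e,⊥=0.8) under each sampling scheme, with
optional Rician noise.  The scheme comparison is an OLS model with the
full factorial expansion f * D_e,⊥ * scheme (continuous predictors
uncentred, scheme treatment-coded); the three-way coefficients quantify
how much more the AFD-f relationship depends on D_e,⊥ in a scheme than
in the reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .acquisition import AcquisitionScheme, make_paper_scheme
from .biophysics import (KERNEL_PARAMS, CompartmentParams, FibreConfig,
                         NoiseModel, add_rician_noise, analytic_response,
                         compartment_signal)
from .csd import CSDOptions, afd_total, csd_fit

__all__ = ["SimulationGrid", "run_grid", "fit_interaction", "InteractionFit",
           "count_degenerate", "deperp_eta_squared", "DEFAULT_SCHEMES"]

DEFAULT_SCHEMES = ("ss_1200", "ss_2400", "ss_4000", "ss_6000", "ms_all")

DEFAULT_F = (0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8)
DEFAULT_DE_PERP = (0.2, 0.4, 0.6, 0.8, 1.0, 1.2)
DEFAULT_SNR = (50.0, 35.0, 20.0)


@dataclass(frozen=True)
class SimulationGrid:
    """Parameter grid of the simulation study.

    Defaults give the 7 x 6 = 42 combinations; ``snr_values=()`` means
    noiseless only, otherwise ``n_realizations`` Rician draws are added
    per (cell, scheme, SNR).
    """

    f_values: tuple[float, ...] = DEFAULT_F
    de_perp_values: tuple[float, ...] = DEFAULT_DE_PERP
    snr_values: tuple[float, ...] = ()
    n_realizations: int = 100
    d_par: float = KERNEL_PARAMS.d_par

    @property
    def n_combinations(self) -> int:
        return len(self.f_values) * len(self.de_perp_values)

    def cells(self):
        for f in self.f_values:
            for de in self.de_perp_values:
                yield CompartmentParams(f=f, d_par=self.d_par, d_e_perp=de)


def run_grid(grid: SimulationGrid | None = None,
             schemes: tuple[str, ...] = DEFAULT_SCHEMES,
             seed: int = 0,
             scheme: AcquisitionScheme | None = None,
             options: CSDOptions | None = None) -> pd.DataFrame:
    """Simulate every grid cell and estimate AFD per sampling scheme.

    Returns a long table (scheme, f, de_perp, snr, realization, afd,
    converged); the noiseless row of each cell has snr = inf and
    realization 0.  Fibre orientation is fixed at +z (AFD is orientation
    independent up to sampling tolerance).  Fully reproducible from
    ``seed``.
    """
    grid = grid or SimulationGrid()
    if not schemes:
        raise ValueError("at least one scheme required")
    scheme = scheme or make_paper_scheme()
    response = analytic_response(KERNEL_PARAMS, scheme, l_max=8)
    fibre = FibreConfig.single((0.0, 0.0, 1.0))
    n_noise_draws = grid.n_combinations * len(grid.snr_values) * grid.n_realizations
    seeds = np.random.SeedSequence(seed).generate_state(
        max(1, n_noise_draws)) >> 1  # keep below 2^31
    rows = []
    k = 0
    for params in grid.cells():
        clean = compartment_signal(params, fibre, scheme)
        variants = [(np.inf, 0, clean)]
        for snr in grid.snr_values:
            for r in range(1, grid.n_realizations + 1):
                noisy = add_rician_noise(clean, NoiseModel(snr, int(seeds[k])))
                k += 1
                variants.append((snr, r, noisy))
        for snr, realization, sig in variants:
            for label in schemes:
                fod = csd_fit(sig, label, response, options)
                rows.append((label, params.f, params.d_e_perp, snr,
                             realization, afd_total(fod).value, fod.converged))
    return pd.DataFrame(
        rows, columns=["scheme", "f", "de_perp", "snr", "realization",
                       "afd", "converged"],
    )


@dataclass(frozen=True)
class InteractionFit:
    """Three-way f x D_e,⊥ x scheme coefficients against a reference."""

    reference: str
    coefficients: dict[str, tuple[float, float, float]]  # est, lo, hi
    r_squared: float
    n_obs: int
    model: object = field(repr=False, compare=False, default=None)

    def estimate(self, scheme: str) -> float:
        return self.coefficients[scheme][0]

    def interval(self, scheme: str) -> tuple[float, float]:
        return self.coefficients[scheme][1:]

    def to_frame(self) -> pd.DataFrame:
        rows = [(s, *v) for s, v in self.coefficients.items()]
        return pd.DataFrame(rows, columns=["scheme", "estimate", "ci_low",
                                           "ci_high"])


def fit_interaction(table: pd.DataFrame, reference: str = "ss_6000",
                    noiseless_only: bool = True) -> InteractionFit:
    """OLS of afd on the factorial expansion f * de_perp * scheme.

    Continuous f and D_e,⊥ enter uncentred; scheme is treatment-coded
    with ``reference``.  By default only the noiseless rows are used;
    ``noiseless_only=False`` fits on every (noisy) realization row.
    """
    schemes = set(table["scheme"])
    if reference not in schemes:
        raise KeyError(f"reference {reference!r} not in table")
    if len(schemes) < 2:
        raise ValueError("interaction model needs at least two schemes")
    if noiseless_only:
        data = table[np.isinf(table["snr"])]
    else:
        noisy = table[~np.isinf(table["snr"])]
        data = noisy if len(noisy) else table
    if data.empty:
        raise ValueError("no rows left after noiseless filter")
    formula = f"afd ~ f * de_perp * C(scheme, Treatment(reference='{reference}'))"
    res = smf.ols(formula, data=data).fit()
    ci = res.conf_int()
    coeffs = {}
    for s in sorted(schemes - {reference}):
        key = f"f:de_perp:C(scheme, Treatment(reference='{reference}'))[T.{s}]"
        coeffs[s] = (float(res.params[key]), float(ci.loc[key, 0]),
                     float(ci.loc[key, 1]))
    return InteractionFit(reference, coeffs, float(res.rsquared),
                          int(res.nobs), res)


def count_degenerate(table: pd.DataFrame, scheme: str, target_afd: float,
                     tol: float = 0.05) -> int:
    """Number of noiseless (f, D_e,⊥) cells with AFD within tol of target."""
    sub = table[(table["scheme"] == scheme) & np.isinf(table["snr"])]
    if sub.empty:
        raise KeyError(f"no noiseless rows for scheme {scheme!r}")
    return int((np.abs(sub["afd"] - target_afd) <= tol).sum())


def deperp_eta_squared(table: pd.DataFrame, scheme: str) -> float:
    """Share of noiseless AFD variance attributable to D_e,⊥ (eta²).

    Two-way factorial decomposition with f and D_e,⊥ categorical:
    eta² = SS(D_e,⊥) / SS(total).
    """
    sub = table[(table["scheme"] == scheme) & np.isinf(table["snr"])]
    if sub.empty:
        raise KeyError(f"no noiseless rows for scheme {scheme!r}")
    afd = sub["afd"].to_numpy()
    grand = afd.mean()
    ss_tot = float(np.sum((afd - grand) ** 2))
    ss_de = float(sum(
        len(g) * (g["afd"].mean() - grand) ** 2
        for _, g in sub.groupby("de_perp")
    ))
    return ss_de / ss_tot
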