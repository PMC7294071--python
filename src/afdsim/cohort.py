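"""Synthetic developmental cohort generation.

Two generators produce the long-format subject x tract x scheme AFD
table that the statistics stage consumes:

* :func:`generate_cohort` — statistical mode: per tract and scheme an
  AFD column is planted with a target age-R² (default: the shipped
  38-tract x 4-scheme reference matrix), by mixing standardised age with
  independent Gaussian noise and mapping to a plausible AFD scale.
* :func:`mechanistic_cohort` — mechanistic mode: an age-dependent
  intra-axonal fraction f (optionally with age-dependent D_e,⊥) is
  pushed through the full simulator + CSD per scheme, so b-value
  dependence of age sensitivity emerges from the physics instead of
  being planted.

The emulated cohort: 78 children aged 8-18 (uniform; mean 13, sd ≈ 2.89
— within rounding of the reference population's 12.4 ± 2.9), 45 female,
log-normal head-motion summary (median 0.5 mm RMS displacement).
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .acquisition import make_paper_scheme
from .biophysics import (KERNEL_PARAMS, CompartmentParams, FibreConfig,
                         NoiseModel, add_rician_noise, analytic_response,
                         compartment_signal)
from .csd import CSDOptions, afd_total, csd_fit

__all__ = ["CohortSpec", "load_table1", "table1_matrix", "generate_cohort",
           "generate_subjects", "mechanistic_cohort", "COHORT_SCHEMES"]

COHORT_SCHEMES = ("ss_6000", "ss_4000", "ss_2400", "ss_1200")


def load_table1() -> pd.DataFrame:
    """The shipped per-tract age-R² reference matrix (38 tracts x 4 schemes).

    Columns: tract, hemisphere, label and one r2_<scheme> column per
    single-shell scheme; label joins tract and hemisphere (e.g. AF_L,
    CA, CC_Full).
    """
    ref = importlib.resources.files("afdsim") / "data" / "table1.tsv"
    df = pd.read_csv(ref, sep="\t", dtype={"hemisphere": str})
    df["label"] = [
        t if h == "-" else f"{t}_{h}"
        for t, h in zip(df["tract"], df["hemisphere"])
    ]
    return df


def table1_matrix() -> pd.DataFrame:
    """R² matrix indexed by tract label, one column per scheme."""
    df = load_table1().set_index("label")
    mat = df[[f"r2_{s.replace('_', '')}" for s in COHORT_SCHEMES]]
    mat.columns = list(COHORT_SCHEMES)
    return mat


@dataclass(frozen=True)
class CohortSpec:
    """Synthetic cohort description.

    ``target_r2`` is a tract x scheme DataFrame of age-R² targets
    (default: the shipped reference matrix); ``sex_effect`` and
    ``motion_effect`` add standardised-covariate contributions to AFD
    (default 0: all planted variance is on age).
    """

    n_subjects: int = 78
    age_range: tuple[float, float] = (8.0, 18.0)
    n_female: int = 45
    motion_median_mm: float = 0.5
    motion_sigma: float = 0.4  # log-scale sd of the log-normal
    schemes: tuple[str, ...] = COHORT_SCHEMES
    target_r2: pd.DataFrame | None = None
    afd_mean: float = 1.0
    afd_sd: float = 0.1
    sex_effect: float = 0.0
    motion_effect: float = 0.0
    calibrate: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_female > self.n_subjects:
            raise ValueError("n_female cannot exceed n_subjects")
        if self.target_r2 is not None:
            vals = self.target_r2.to_numpy(dtype=float)
            if np.any(vals < 0) or np.any(vals >= 1):
                raise ValueError("target R² entries must lie in [0, 1)")

    def resolved_targets(self) -> pd.DataFrame:
        mat = self.target_r2 if self.target_r2 is not None else table1_matrix()
        missing = [s for s in self.schemes if s not in mat.columns]
        if missing:
            raise KeyError(f"target_r2 lacks scheme columns {missing}")
        return mat[list(self.schemes)]


def generate_subjects(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Subject table: id, age (years), sex (female=1), motion (mm)."""
    lo, hi = spec.age_range
    age = rng.uniform(lo, hi, size=spec.n_subjects)
    sex = np.zeros(spec.n_subjects, dtype=int)
    sex[: spec.n_female] = 1
    rng.shuffle(sex)
    motion = rng.lognormal(np.log(spec.motion_median_mm), spec.motion_sigma,
                           size=spec.n_subjects)
    return pd.DataFrame({
        "subject_id": [f"sub-{i + 1:03d}" for i in range(spec.n_subjects)],
        "age": age, "sex": sex, "motion": motion,
    })


def generate_cohort(spec: CohortSpec | None = None) -> pd.DataFrame:
    """Statistical-mode cohort with planted per-cell age-R².

    Per tract t and scheme s the subject AFD is

        afd_i = sqrt(R²_ts) z(age_i) + sqrt(1 - R²_ts) ε_i  (+ covariate
        terms), then mapped to mean ``afd_mean``, sd ``afd_sd``.

    With ``spec.calibrate`` (default) the planted R² is first shrunk by
    the expected chance-fit of the p = 3 predictors,
    max(0, t - p (1 - t) / (n - 1)), so that the FITTED multiple R²
    recovers the target in expectation (the fitted R² of an
    uncalibrated plant is biased upward by the chance fit; a target of
    zero plants zero and recovers the null expectation p/(n-1)).
    Targets below the null floor p/(n-1) cannot be recovered by any
    generator.

    Returns the long table (subject_id, age, sex, motion, tract, scheme,
    afd) with a complete crossing; reproducible from ``spec.seed``.
    """
    spec = spec or CohortSpec()
    targets = spec.resolved_targets()
    rng = np.random.default_rng(spec.seed)
    subjects = generate_subjects(spec, rng)
    z_age = (subjects["age"] - subjects["age"].mean()) / subjects["age"].std()
    z_sex = (subjects["sex"] - subjects["sex"].mean()) / subjects["sex"].std()
    z_mot = (subjects["motion"] - subjects["motion"].mean()) / subjects["motion"].std()
    frames = []
    p_predictors = 3  # age + sex + motion
    shrink = p_predictors / (spec.n_subjects - 1)
    for tract, row in targets.iterrows():
        for s in spec.schemes:
            r2 = float(row[s])
            if spec.calibrate:
                r2 = max(0.0, r2 - shrink * (1.0 - r2))
            eps = rng.standard_normal(spec.n_subjects)
            core = np.sqrt(r2) * z_age + np.sqrt(1.0 - r2) * eps
            core = core + spec.sex_effect * z_sex + spec.motion_effect * z_mot
            afd = spec.afd_mean + spec.afd_sd * core
            frames.append(pd.DataFrame({
                "subject_id": subjects["subject_id"],
                "age": subjects["age"], "sex": subjects["sex"],
                "motion": subjects["motion"],
                "tract": tract, "scheme": s, "afd": afd,
            }))
    return pd.concat(frames, ignore_index=True)


def mechanistic_cohort(spec: CohortSpec | None = None,
                       f_base: float = 0.45,
                       f_slope_per_year: float = 0.012,
                       f_sd: float = 0.01,
                       de_base: float = 0.8,
                       de_slope_per_year: float = -0.02,
                       de_sd: float = 0.15,
                       snr: float | None = 50.0,
                       tracts: tuple[str, ...] | None = None,
                       seed: int | None = None) -> pd.DataFrame:
    """Mechanistic-mode cohort: age-dependent microstructure through CSD.

    Per subject and tract, f = f_base + f_slope_per_year*(age - 12.4) +
    noise (clipped to [0.2, 0.8] with a warning) and optionally
    D_e,⊥ = de_base + de_slope_per_year*(age - 12.4) + noise (clipped to
    [0.2, 1.2]); the voxel is simulated on the full multi-shell scheme,
    Rician noise at ``snr`` added (None = noiseless), and AFD estimated
    per requested scheme.  Default noise levels put the dominant
    non-developmental variance on D_e,⊥ (f_sd << de_sd): the regime in
    which extra-axonal contamination camouflages intra-axonal change at
    low b-values, which is the mechanism this mode exists to exhibit.
    Slow relative to the statistical mode: one CSD fit per subject x
    tract x scheme.
    """
    spec = spec or CohortSpec()
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    subjects = generate_subjects(spec, rng)
    if tracts is None:
        tracts = tuple(spec.resolved_targets().index)
    scheme = make_paper_scheme()
    response = analytic_response(KERNEL_PARAMS, scheme, l_max=8)
    fibre = FibreConfig.single((0.0, 0.0, 1.0))
    age_c = subjects["age"].to_numpy() - 12.4

    n_clip = 0
    rows = []
    for tract in tracts:
        f_i = f_base + f_slope_per_year * age_c + rng.normal(0, f_sd, len(age_c))
        de_i = de_base + de_slope_per_year * age_c + rng.normal(0, de_sd, len(age_c))
        clipped = (f_i < 0.2) | (f_i > 0.8) | (de_i < 0.2) | (de_i > 1.2)
        n_clip += int(clipped.sum())
        f_i = np.clip(f_i, 0.2, 0.8)
        de_i = np.clip(de_i, 0.2, 1.2)
        for j, subj in subjects.iterrows():
            params = CompartmentParams(f=float(f_i[j]),
                                       d_e_perp=float(de_i[j]))
            sig = compartment_signal(params, fibre, scheme)
            if snr is not None:
                sig = add_rician_noise(
                    sig, NoiseModel(snr, int(rng.integers(2**31))))
            for s in spec.schemes:
                fod = csd_fit(sig, s, response)
                rows.append((subj["subject_id"], subj["age"], subj["sex"],
                             subj["motion"], tract, s, afd_total(fod).value))
    if n_clip:
        warnings.warn(f"{n_clip} subject x tract parameter draws clipped "
                      "to the valid (f, D_e,⊥) box", stacklevel=2)
    return pd.DataFrame(rows, columns=["subject_id", "age", "sex", "motion",
                                       "tract", "scheme", "afd"])
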