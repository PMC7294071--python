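"""End-to-end orchestration of the two studies.

Each run writes delimited tables plus a ``manifest.json`` that echoes
the effective configuration, the seed, package versions and row counts,
so a run is self-describing.  A single global seed deterministically
derives per-stage sub-seeds via ``numpy.random.SeedSequence(seed).spawn``
in a fixed order (simulation grid, cohort, bootstrap), so stages can be
re-run in isolation.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import statsmodels

import afdsim

from .cohort import COHORT_SCHEMES, CohortSpec, generate_cohort
from .devstats import (bonferroni_alpha, cluster_matrix, column_median,
                       export_dendrogram_newick, r2_difference_bca, r2_matrix,
                       r2_table)
from .simstudy import (DEFAULT_SCHEMES, SimulationGrid, count_degenerate,
                       fit_interaction, run_grid)

__all__ = ["run_simulation_study", "run_cohort_study", "stage_seeds"]


def stage_seeds(seed: int) -> dict[str, int]:
    """Named per-stage sub-seeds derived from one global seed."""
    children = np.random.SeedSequence(seed).spawn(3)
    names = ("simulation", "cohort", "bootstrap")
    return {n: int(c.generate_state(1)[0] >> 1) for n, c in zip(names, children)}


def _manifest(path: Path, **fields) -> None:
    fields["written_at"] = datetime.now(timezone.utc).isoformat()
    fields["versions"] = {
        "afdsim": afdsim.__version__, "numpy": np.__version__,
        "scipy": scipy.__version__, "pandas": pd.__version__,
        "statsmodels": statsmodels.__version__,
        "python": platform.python_version(),
    }
    path.write_text(json.dumps(fields, indent=2, default=str) + "\n")


def run_simulation_study(out_dir: str | Path, seed: int = 0,
                         grid: SimulationGrid | None = None,
                         schemes: tuple[str, ...] = DEFAULT_SCHEMES,
                         reference: str = "ss_6000",
                         degeneracy_target: float = 1.2,
                         degeneracy_tol: float = 0.05) -> Path:
    """Simulate the grid, fit the interaction model, count degeneracies."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid = grid or SimulationGrid()
    sim_seed = stage_seeds(seed)["simulation"]
    table = run_grid(grid, schemes, seed=sim_seed)
    table.to_csv(out / "sim_table.tsv", sep="\t", index=False)

    fit = fit_interaction(table, reference=reference)
    fit.to_frame().to_csv(out / "interaction.tsv", sep="\t", index=False)

    degeneracy = {
        s: count_degenerate(table, s, degeneracy_target, degeneracy_tol)
        for s in schemes
    }
    pd.DataFrame(sorted(degeneracy.items()),
                 columns=["scheme", "n_combinations"]).to_csv(
        out / "degeneracy.tsv", sep="\t", index=False)

    _manifest(out / "manifest.json", study="simulation", seed=seed,
              stage_seed=sim_seed, grid=asdict(grid), schemes=list(schemes),
              reference=reference, n_rows=len(table),
              n_noiseless_rows=int(np.isinf(table["snr"]).sum()),
              degeneracy_target=degeneracy_target,
              degeneracy_tol=degeneracy_tol)
    return out


def run_cohort_study(out_dir: str | Path, seed: int = 0,
                     spec: CohortSpec | None = None,
                     bootstrap_samples: int = 10_000,
                     family_alpha: float = 0.05,
                     reference: str = "ss_6000") -> Path:
    """Generate the cohort; R² per cell, BCa differences, clustering."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(seed)
    spec = spec or CohortSpec(seed=seeds["cohort"])
    cohort = generate_cohort(spec)
    cohort.to_csv(out / "cohort.tsv", sep="\t", index=False)

    tab = r2_table(cohort)
    tab.to_csv(out / "r2_table.tsv", sep="\t", index=False)
    mat = r2_matrix(cohort)
    mat.to_csv(out / "r2_matrix.tsv", sep="\t")

    alpha = bonferroni_alpha(mat.shape[0], mat.shape[1], family_alpha)
    boot_rng = np.random.default_rng(seeds["bootstrap"])
    rows = []
    others = [s for s in spec.schemes if s != reference]
    for tract in mat.index:
        for other in others:
            b = r2_difference_bca(cohort, tract, reference, other,
                                  B=bootstrap_samples,
                                  seed=int(boot_rng.integers(2**31)))
            rows.append((tract, f"{reference}>{other}", b.estimate, b.lo,
                         b.hi, not (b.lo <= 0.0 <= b.hi)))
    bca = pd.DataFrame(rows, columns=["tract", "comparison", "estimate",
                                      "ci_low", "ci_high", "excludes_zero"])
    bca.to_csv(out / "bca_differences.tsv", sep="\t", index=False)

    cl = cluster_matrix(mat)
    (out / "dendrogram_tracts.nwk").write_text(
        export_dendrogram_newick(cl.row_linkage, list(mat.index)) + "\n")
    (out / "dendrogram_schemes.nwk").write_text(
        export_dendrogram_newick(cl.col_linkage, list(mat.columns)) + "\n")
    ordered = mat.loc[list(cl.row_order), list(cl.col_order)]
    ordered.to_csv(out / "heatmap_matrix.tsv", sep="\t")

    medians = {s: column_median(mat, s) for s in mat.columns}
    _manifest(out / "manifest.json", study="cohort", seed=seed,
              stage_seeds=seeds, n_subjects=spec.n_subjects,
              n_tracts=mat.shape[0], n_schemes=mat.shape[1],
              bootstrap_samples=bootstrap_samples,
              bonferroni_alpha=alpha, column_medians=medians,
              scheme_clusters_k2=cluster_matrix(mat).cut_cols(2))
    return out
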