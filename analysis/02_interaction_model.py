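#!/usr/bin/env python
"""Fit the f x D_e,⊥ x scheme interaction model on the simulated grid.

Reads results/simulation/sim_table.tsv (run 01 first), prints the
three-way coefficients against the ss_6000 reference next to the values
published for this design, and reports the multi-shell degeneracy count
(AFD = 1.2 ± 0.05).
"""

import argparse

import pandas as pd

from afdsim.simstudy import count_degenerate, fit_interaction

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--table", default="results/simulation/sim_table.tsv")
args = parser.parse_args()

table = pd.read_csv(args.table, sep="\t")
fit = fit_interaction(table, reference="ss_6000")

published = {"ss_1200": (0.80, 0.44, 1.2), "ss_2400": (0.55, 0.19, 0.91),
             "ms_all": (0.83, 0.47, 1.2), "ss_4000": None}
print(f"{'scheme':8} {'beta':>8} {'95% CI':>18}   published")
for scheme, (est, lo, hi) in fit.coefficients.items():
    pub = published.get(scheme)
    pub_s = f"{pub[0]:.2f} [{pub[1]}, {pub[2]}]" if pub else "n.s."
    print(f"{scheme:8} {est:8.3f} [{lo:7.3f}, {hi:6.3f}]   {pub_s}")
print()
print("Note: the recomputed coefficients do not reproduce the published "
      "pattern; under a kernel-relative read-out the f x D_e,⊥ coupling "
      "peaks at b = 2400-4000 rather than decreasing monotonically with "
      "b (see docs/methods.md, 'Known limitations').")

n = count_degenerate(table, "ms_all", 1.2, tol=0.05)
print(f"\nms_all degeneracy: {n} of 42 (f, D_e,⊥) combinations give "
      "AFD within 0.05 of 1.2 (published: at least six).")
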