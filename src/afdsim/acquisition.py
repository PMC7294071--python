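"""Multi-shell diffusion acquisition schemes.

A scheme is a set of b-value shells, each carrying a set of unit gradient
directions, plus a number of b=0 measurements.  b-values are stored in
s/mm² at the interface; physics modules divide by 1000 so that they combine
directly with diffusivities in μm²/ms.

The flat measurement layout used throughout the package is: all b=0
measurements first, then each weighted shell in ascending b-value order,
directions in stored order.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np

__all__ = [
    "Shell",
    "AcquisitionScheme",
    "SCHEME_SELECTORS",
    "resolve_selector",
    "generate_directions",
    "electrostatic_energy",
    "make_paper_scheme",
    "read_gradient_table",
    "write_gradient_table",
]

#: b-values (s/mm²) below this are pooled into the b=0 group when reading
#: gradient tables; scanners often report small nonzero b for "b0" volumes.
B0_THRESHOLD = 50.0
#: measured b-values within this tolerance of each other form one shell
SHELL_TOLERANCE = 100.0

# Named sub-scheme selectors: label -> b-values (s/mm²) retained.
SCHEME_SELECTORS = {
    "ss_1200": (1200.0,),
    "ss_2400": (2400.0,),
    "ss_4000": (4000.0,),
    "ss_6000": (6000.0,),
    "ms_all": (500.0, 1200.0, 2400.0, 4000.0, 6000.0),
}


class GradientTableError(ValueError):
    """Malformed bval/bvec input."""


@dataclass(frozen=True)
class Shell:
    """One b-value shell: diffusion weighting plus unit directions."""

    b_value: float  # s/mm²
    directions: np.ndarray  # (n, 3), unit norm

    def __post_init__(self) -> None:
        if self.b_value < 0:
            raise ValueError(f"negative b-value {self.b_value}")
        d = np.atleast_2d(np.asarray(self.directions, dtype=float))
        if d.ndim != 2 or d.shape[1] != 3:
            raise ValueError("directions must be (n, 3)")
        if self.b_value > 0 and d.shape[0] < 1:
            raise ValueError("a weighted shell needs at least one direction")
        norms = np.linalg.norm(d, axis=1)
        if d.shape[0] and not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("directions must have unit norm (tol 1e-6)")
        object.__setattr__(self, "directions", d)

    @property
    def n_directions(self) -> int:
        return self.directions.shape[0]

    @property
    def b_ms_um2(self) -> float:
        """b in ms/μm² — the unit all signal formulas use."""
        return self.b_value / 1000.0


@dataclass(frozen=True)
class AcquisitionScheme:
    """Ordered set of shells plus a count of b=0 measurements."""

    name: str
    shells: tuple[Shell, ...]
    n_b0: int = 0

    def __post_init__(self) -> None:
        shells = tuple(sorted(self.shells, key=lambda s: s.b_value))
        bvals = [s.b_value for s in shells]
        if len(set(bvals)) != len(bvals):
            raise ValueError(f"duplicate shell b-values: {bvals}")
        if not any(s.b_value > 0 for s in shells):
            raise ValueError("a scheme needs at least one b > 0 shell")
        if self.n_b0 < 0:
            raise ValueError("n_b0 must be non-negative")
        object.__setattr__(self, "shells", shells)

    @property
    def b_values(self) -> tuple[float, ...]:
        return tuple(s.b_value for s in self.shells)

    @property
    def n_measurements(self) -> int:
        return self.n_b0 + sum(s.n_directions for s in self.shells)

    def shell(self, b_value: float) -> Shell:
        for s in self.shells:
            if s.b_value == b_value:
                return s
        raise KeyError(f"no shell with b={b_value} in scheme {self.name!r}")

    def select(self, selector: str | Sequence[float]) -> "AcquisitionScheme":
        """Return the sub-scheme keeping only the selected shells.

        ``selector`` is a label from :data:`SCHEME_SELECTORS` or an explicit
        list of b-values.  b=0 measurements are always retained.  The parent
        scheme is never mutated.
        """
        bvals = resolve_selector(selector)
        missing = [b for b in bvals if b not in self.b_values]
        if missing:
            raise KeyError(
                f"selector requests b-values {missing} absent from scheme "
                f"{self.name!r} (has {list(self.b_values)})"
            )
        label = selector if isinstance(selector, str) else "custom"
        shells = tuple(s for s in self.shells if s.b_value in bvals)
        return AcquisitionScheme(f"{self.name}:{label}", shells, self.n_b0)

    def measurement_table(self) -> tuple[np.ndarray, np.ndarray]:
        """Flat (bvals, bvecs) arrays in package measurement order."""
        bvals = np.concatenate(
            [np.zeros(self.n_b0)]
            + [np.full(s.n_directions, s.b_value) for s in self.shells]
        )
        bvecs = np.vstack(
            [np.zeros((self.n_b0, 3))] + [s.directions for s in self.shells]
        )
        return bvals, bvecs

    def measurement_slices(self) -> dict[float, slice]:
        """Slice into the flat measurement vector for each weighted shell."""
        out: dict[float, slice] = {}
        i = self.n_b0
        for s in self.shells:
            out[s.b_value] = slice(i, i + s.n_directions)
            i += s.n_directions
        return out


def resolve_selector(selector: str | Sequence[float]) -> tuple[float, ...]:
    if isinstance(selector, str):
        try:
            return SCHEME_SELECTORS[selector]
        except KeyError:
            raise KeyError(
                f"unknown scheme selector {selector!r}; "
                f"known labels: {sorted(SCHEME_SELECTORS)}"
            ) from None
    return tuple(float(b) for b in selector)


# ---------------------------------------------------------------------------
# direction generation: antipodally symmetric electrostatic repulsion


def electrostatic_energy(points: np.ndarray) -> float:
    """Symmetric Coulomb energy sum_{i<j} 1/|xi-xj| + 1/|xi+xj|."""
    x = np.asarray(points, dtype=float)
    if x.shape[0] < 2:
        return 0.0
    diff = x[:, None, :] - x[None, :, :]
    summ = x[:, None, :] + x[None, :, :]
    dd = np.linalg.norm(diff, axis=-1)
    ds = np.linalg.norm(summ, axis=-1)
    iu = np.triu_indices(x.shape[0], k=1)
    return float(np.sum(1.0 / dd[iu]) + np.sum(1.0 / ds[iu]))


def _energy_gradient(x: np.ndarray) -> np.ndarray:
    diff = x[:, None, :] - x[None, :, :]
    summ = x[:, None, :] + x[None, :, :]
    dd = np.linalg.norm(diff, axis=-1)
    ds = np.linalg.norm(summ, axis=-1)
    np.fill_diagonal(dd, np.inf)
    grad = -(diff / dd[..., None] ** 3).sum(axis=1)
    grad += -(summ / ds[..., None] ** 3).sum(axis=1)
    return grad


def generate_directions(n: int, seed: int = 0, *, max_iter: int = 10_000,
                        tol: float = 1e-9) -> np.ndarray:
    """Generate ``n`` unit directions by antipodal electrostatic repulsion.

    Projected gradient descent from a random start: step along the
    negative tangential gradient, renormalize, accept only energy
    decreases (backtracking step control).  Stops when the energy
    decrease falls below ``tol`` or after ``max_iter`` iterations.
    Deterministic given ``seed``; different seeds reach different local
    optima of near-identical energy.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, 3))
    x /= np.linalg.norm(x, axis=1, keepdims=True)
    if n == 1:
        return x
    energy = electrostatic_energy(x)
    step = 1e-2
    for _ in range(max_iter):
        g = _energy_gradient(x)
        # tangential component only: radial motion is removed by renorm
        g -= (g * x).sum(axis=1, keepdims=True) * x
        gmax = np.abs(g).max()
        if gmax == 0:
            break
        trial = x - step * g / gmax
        trial /= np.linalg.norm(trial, axis=1, keepdims=True)
        e_trial = electrostatic_energy(trial)
        if e_trial < energy:
            if energy - e_trial < tol:
                x, energy = trial, e_trial
                break
            x, energy = trial, e_trial
            step *= 1.2
        else:
            step *= 0.5
            if step < 1e-14:
                break
    return x


@lru_cache(maxsize=8)
def _cached_shell_directions(n: int, seed: int) -> np.ndarray:
    d = generate_directions(n, seed)
    d.setflags(write=False)
    return d


#: seed used for the built-in scheme's direction sets (arbitrary, documented)
PAPER_SCHEME_SEED = 20200326

_PAPER_SHELLS = ((500.0, 30), (1200.0, 30), (2400.0, 60), (4000.0, 60),
                 (6000.0, 60))
_PAPER_N_B0 = 14


def make_paper_scheme(seed: int = PAPER_SCHEME_SEED) -> AcquisitionScheme:
    """The built-in 6-shell Connectom-style scheme.

    b = 0 (14 volumes), 500 (30 dirs), 1200 (30), 2400 (60), 4000 (60),
    6000 (60) s/mm² — 254 measurements.  Directions come from per-shell
    electrostatic repulsion with shell-specific sub-seeds derived from
    ``seed``.
    """
    shells = tuple(
        Shell(b, _cached_shell_directions(n, seed + i))
        for i, (b, n) in enumerate(_PAPER_SHELLS)
    )
    return AcquisitionScheme("connectom_multishell", shells, _PAPER_N_B0)


# ---------------------------------------------------------------------------
# FSL-style gradient tables


def _parse_rows(text: str, what: str) -> list[list[float]]:
    rows = []
    for line in text.strip().splitlines():
        if not line.strip():
            continue
        try:
            rows.append([float(tok) for tok in line.split()])
        except ValueError as exc:
            raise GradientTableError(f"non-numeric token in {what}: {exc}") from None
    return rows


def read_gradient_table(bval_text: str, bvec_text: str,
                        name: str = "from_table") -> AcquisitionScheme:
    """Build a scheme from FSL-dialect bval/bvec text.

    One row of b-values; three rows (x, y, z) of gradient components.
    b below :data:`B0_THRESHOLD` is pooled as b=0; remaining b-values are
    clustered into shells within :data:`SHELL_TOLERANCE` and each shell is
    labelled with the mean b of its cluster.
    """
    bval_rows = _parse_rows(bval_text, "bvals")
    bvec_rows = _parse_rows(bvec_text, "bvecs")
    if len(bval_rows) != 1:
        raise GradientTableError(f"expected 1 bval row, got {len(bval_rows)}")
    if len(bvec_rows) != 3:
        raise GradientTableError(f"expected 3 bvec rows, got {len(bvec_rows)}")
    bvals = np.asarray(bval_rows[0])
    lens = {len(r) for r in bvec_rows} | {len(bvals)}
    if len(lens) != 1:
        raise GradientTableError(f"ragged rows: lengths {sorted(lens)}")
    bvecs = np.asarray(bvec_rows).T  # (n, 3)

    weighted = bvals >= B0_THRESHOLD
    n_b0 = int((~weighted).sum())
    norms = np.linalg.norm(bvecs[weighted], axis=1)
    if np.any(norms < 1e-12):
        raise GradientTableError("zero-norm direction with b > 0")

    # cluster weighted b-values into shells
    shells: list[Shell] = []
    bw = bvals[weighted]
    vw = bvecs[weighted] / norms[:, None]
    order = np.argsort(bw)
    groups: list[list[int]] = []
    for idx in order:
        if groups and bw[idx] - bw[groups[-1][0]] <= SHELL_TOLERANCE:
            groups[-1].append(idx)
        else:
            groups.append([idx])
    for grp in groups:
        shells.append(Shell(float(np.mean(bw[grp])), vw[grp]))
    return AcquisitionScheme(name, tuple(shells), n_b0)


def write_gradient_table(scheme: AcquisitionScheme) -> tuple[str, str]:
    """Serialize a scheme to FSL bval/bvec text (measurement order)."""
    bvals, bvecs = scheme.measurement_table()
    buf = io.StringIO()
    print(" ".join(f"{b:.6g}" for b in bvals), file=buf)
    bval_text = buf.getvalue()
    lines = []
    for axis in range(3):
        lines.append(" ".join(f"{v:.10f}" for v in bvecs[:, axis]))
    return bval_text, "\n".join(lines) + "\n"
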