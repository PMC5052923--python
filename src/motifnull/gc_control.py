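"""Joint control of mean IC and mean GC-content.

The two-constraint MaxEnt density over motifs is
P(M) ∝ exp(lambda IC(M) + mu' GC(M)).  Because the entropy of a column
depends only on its count multiset while its GC fraction depends only on
which counts are assigned to G and C, the class marginal is governed by
lambda alone and the assignment stage by the GC tilt alone.  lambda is
therefore fit first (exactly as without GC control), and the GC conjugate
parameter mu is fit afterwards by one-dimensional root-finding on the
exact expected GC:

    <GC> = sum_classes P(class) * sum_g g * u(g|class) e^{-mu g} / Z(class, mu),

where g ranges over the GC fractions realizable by assigning the count
multiset to bases and u(g|class) is the fraction of distinct assignments
with that g.  The tilt convention e^{-mu g} means negative mu raises GC;
the user-facing API works in terms of the target fraction and hides the
sign.  Sampling replaces only stage 2 of the column sampler (assignment
drawn with probability proportional to e^{-mu g}); stages 1 and 3 are
untouched, so the entropy-class distribution is exactly preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
from scipy.optimize import brentq

from . import count_classes as cc
from .errors import FeasibilityError, ParameterError
from .maxent import MaxEntModel, _per_motif_seeds
from .motif_core import Motif

DEFAULT_GC_TOL = 1e-10

# Base order A, C, G, T: indices 1 and 2 are the GC pair.
_GC_SLOTS = (1, 2)


def _class_assignments(rep: tuple[int, ...]) -> tuple[np.ndarray, np.ndarray]:
    """Distinct assignments of a count multiset to (A, C, G, T).

    Returns (assignments, g): an (m, 4) array of count tuples and the GC
    fraction of each.  m <= 4! = 24.
    """
    N = sum(rep)
    distinct = sorted(set(permutations(rep)))
    arr = np.array(distinct, dtype=np.int64)
    g = (arr[:, _GC_SLOTS[0]] + arr[:, _GC_SLOTS[1]]) / float(N)
    return arr, g


@dataclass
class GCModel:
    """A MaxEnt model with an additional GC-content tilt."""

    base: MaxEntModel
    mu: float
    target_gc: float
    achieved_mean_gc: float

    # per-class assignment tables, aligned with base.class_table rows
    _assignments: list[np.ndarray] = field(default_factory=list, repr=False)
    _gcs: list[np.ndarray] = field(default_factory=list, repr=False)
    _cdfs: list[np.ndarray] = field(default_factory=list, repr=False)


def _assignment_tables(table: cc.ClassTable) -> tuple[list[np.ndarray], list[np.ndarray]]:
    assignments, gcs = [], []
    for k in range(table.class_count):
        arr, g = _class_assignments(tuple(int(c) for c in table.counts[k]))
        assignments.append(arr)
        gcs.append(g)
    return assignments, gcs


def expected_gc(base: MaxEntModel, mu: float, gcs: list[np.ndarray] | None = None) -> float:
    """Exact mean GC fraction of a column under (lambda, mu)."""
    table = base.class_table
    if gcs is None:
        _, gcs = _assignment_tables(table)
    p = cc.class_probs(table, base.lam)
    total = 0.0
    for k in range(table.class_count):
        g = gcs[k]
        w = np.exp(-mu * (g - g.mean()))  # shift for stability; cancels in ratio
        total += p[k] * float((g * w).sum() / w.sum())
    return total


def feasible_gc_range(base: MaxEntModel) -> tuple[float, float]:
    """Closed interval of mean GC attainable at the model's lambda.

    Endpoints weight each class's extreme realizable GC (two smallest /
    two largest counts assigned to the GC pair) by the lambda-tilted class
    probabilities.  A fully conserved ensemble spans [0, 1]; a maximally
    balanced one collapses toward 0.5.
    """
    table = base.class_table
    p = cc.class_probs(table, base.lam)
    srt = np.sort(table.counts, axis=1)  # ascending
    g_min = (srt[:, 0] + srt[:, 1]) / float(base.N)
    g_max = (srt[:, -1] + srt[:, -2]) / float(base.N)
    return float(p @ g_min), float(p @ g_max)


def fit_mu(
    base: MaxEntModel, target_gc: float, tol: float = DEFAULT_GC_TOL
) -> GCModel:
    """Tune mu so the expected GC fraction equals target_gc; lambda untouched.

    Mean GC is strictly decreasing in mu (Boltzmann monotonicity), so a
    doubling bracket plus Brent's method suffices.  Targets outside the
    feasible interval raise FeasibilityError naming the interval.
    """
    lo, hi = feasible_gc_range(base)
    if not (lo < target_gc < hi):
        raise FeasibilityError(
            f"target mean GC {target_gc} is not attainable at this IC",
            feasible=(lo, hi),
        )
    assignments, gcs = _assignment_tables(base.class_table)

    def f(mu: float) -> float:
        return expected_gc(base, mu, gcs) - target_gc

    a, b = -1.0, 1.0
    while f(a) < 0:  # mean GC decreasing in mu: need f(a) >= 0
        a *= 2.0
    while f(b) > 0:
        b *= 2.0
    mu = brentq(f, a, b, xtol=1e-13, rtol=8.9e-16, maxiter=200)
    achieved = expected_gc(base, mu, gcs)
    if abs(achieved - target_gc) > max(tol, 1e-9):
        raise ParameterError(
            f"mu tuning did not converge: achieved {achieved} vs {target_gc}"
        )
    model = GCModel(
        base=base, mu=float(mu), target_gc=float(target_gc),
        achieved_mean_gc=float(achieved),
    )
    model._assignments = assignments
    model._gcs = gcs
    model._cdfs = [
        _assignment_cdf(g, model.mu) for g in gcs
    ]
    return model


def _assignment_cdf(g: np.ndarray, mu: float) -> np.ndarray:
    w = np.exp(-mu * (g - g.min()))
    cdf = np.cumsum(w / w.sum())
    cdf[-1] = 1.0
    return cdf


def sample_gc(model: GCModel, n: int, seed=None) -> list[Motif]:
    """Draw n motifs matching both mean IC and mean GC.

    Stage 1 (class) and stage 3 (row arrangement) are identical to plain
    MaxEnt sampling; stage 2 draws the base assignment with probability
    proportional to e^{-mu g} among the distinct assignments.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    base = model.base
    table = base.class_table
    out = []
    for ss in _per_motif_seeds(seed, n):
        rng = np.random.default_rng(ss)
        idx = cc.sample_class_indices(base.sampling_cdf, base.L, rng)
        counts = np.empty((base.L, 4), dtype=np.int64)
        u = rng.random(base.L)
        for j, k in enumerate(idx):
            a = np.searchsorted(model._cdfs[k], u[j], side="right")
            counts[j] = model._assignments[k][a]
        cols = cc.arrange_letters(counts, base.N, rng)
        out.append(Motif.from_array(cols.T))
    return out
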