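"""Maximum-entropy motif sampling given mean information content.

The MaxEnt distribution over N x L motifs subject to a mean-entropy
constraint is a Boltzmann distribution P(M) = exp(-lambda H(M)) / Z with
Shannon entropy in place of energy.  Because positional entropy is additive
over columns, the distribution factors column-wise and Z = Z_c(lambda)^L.
Constraining mean IC is equivalent (IC = 2L - H), and the user-facing API
takes a target mean IC in bits.

lambda is tuned by bracketed Brent root-finding on the exactly computable
mean (the tilted class sums), to a tolerance stated in bits of mean IC.
Sampling then draws L independent columns per motif via the exact
three-stage column sampler.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from . import count_classes as cc
from .errors import FeasibilityError, ParameterError
from .motif_core import Motif

DEFAULT_IC_TOL = 1e-10  # bits


def achievable_ic_range(N: int, L: int, table: cc.ClassTable | None = None) -> tuple[float, float]:
    """Open interval of mean ICs attainable by some finite lambda.

    The upper endpoint 2L is the lambda -> +inf limit (all columns
    monomorphic); the lower endpoint L*(2 - H_max(N)) is the lambda -> -inf
    limit, where H_max is the entropy of the most balanced count class.
    Both are approached but never attained.
    """
    if N < 1 or L < 1:
        raise ParameterError("N and L must be >= 1")
    if table is None:
        q, r = divmod(N, 4)
        balanced = tuple([q + 1] * r + [q] * (4 - r))
        h_max = cc.class_entropy(balanced)
    else:
        h_max = float(table.entropy.max())
    return (L * (2.0 - h_max), 2.0 * L)


@dataclass
class MaxEntModel:
    """A tuned MaxEnt motif distribution: dimensions, lambda and its table."""

    N: int
    L: int
    lam: float
    target_ic: float  # bits
    class_table: cc.ClassTable
    achieved_mean_ic: float  # bits

    _cdf: np.ndarray | None = field(default=None, repr=False)

    @property
    def sampling_cdf(self) -> np.ndarray:
        if self._cdf is None:
            self._cdf = cc.class_sampling_cdf(self.class_table, self.lam)
        return self._cdf

    def mean_var_ic(self) -> tuple[float, float]:
        """Mean and variance of motif IC (bits, bits^2) under the model."""
        mean_h, var_h = cc.tilted_moments(self.class_table, self.lam)
        return 2.0 * self.L - self.L * mean_h, self.L * var_h

    def ic_of_class_matrix(self, idx: np.ndarray) -> np.ndarray:
        """IC of motifs given their (n, L) matrix of column class indices."""
        return 2.0 * self.L - self.class_table.entropy[idx].sum(axis=-1)


def mean_ic_at(table: cc.ClassTable, lam: float, L: int) -> float:
    """Exact mean motif IC at a given lambda (monotone increasing in lambda)."""
    mean_h, _ = cc.tilted_moments(table, lam)
    return 2.0 * L - L * mean_h


def fit_lambda(
    N: int,
    L: int,
    target_ic: float,
    tol: float = DEFAULT_IC_TOL,
    table: cc.ClassTable | None = None,
) -> MaxEntModel:
    """Tune lambda so the MaxEnt mean IC equals target_ic (bits).

    The bracket [-1, 1] is doubled geometrically until it straddles the
    root (guaranteed for feasible targets, by monotonicity), then Brent's
    method finishes.  Raises FeasibilityError for targets outside the open
    achievable interval.
    """
    if table is None:
        table = cc.enumerate_classes(N)
    lo, hi = achievable_ic_range(N, L, table)
    if not (lo < target_ic < hi):
        raise FeasibilityError(
            f"target mean IC {target_ic} bits is not attainable for N={N}, L={L}",
            feasible=(lo, hi),
        )

    def f(lam: float) -> float:
        return mean_ic_at(table, lam, L) - target_ic

    a, b = -1.0, 1.0
    fa, fb = f(a), f(b)
    while fa > 0:  # root below a
        a *= 2.0
        fa = f(a)
    while fb < 0:  # root above b
        b *= 2.0
        fb = f(b)
    if fa == 0.0:
        lam = a
    elif fb == 0.0:
        lam = b
    else:
        lam = brentq(f, a, b, xtol=1e-13, rtol=8.9e-16, maxiter=200)
    achieved = mean_ic_at(table, lam, L)
    if abs(achieved - target_ic) > max(tol, 1e-9):
        raise ParameterError(
            f"lambda tuning did not converge: achieved mean IC {achieved!r} "
            f"vs target {target_ic!r}"
        )
    return MaxEntModel(
        N=N, L=L, lam=float(lam), target_ic=float(target_ic),
        class_table=table, achieved_mean_ic=float(achieved),
    )


def _seed_sequence(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def _per_motif_seeds(seed, n: int) -> list[np.random.SeedSequence]:
    """One independent stream per motif: output i is the same regardless of n."""
    return _seed_sequence(seed).spawn(n)


def sample_motif_array(model: MaxEntModel, rng: np.random.Generator) -> np.ndarray:
    """One motif as an (N, L) int8 array, drawn with the three-stage sampler."""
    cols = cc.sample_columns(
        model.class_table, model.lam, model.L, rng, cdf=model.sampling_cdf
    )  # (L, N)
    return cols.T


def sample_maxent(model: MaxEntModel, n: int, seed=None) -> list[Motif]:
    """Draw n i.i.d. motifs from the tuned MaxEnt distribution.

    A single user seed spawns one independent substream per motif, so the
    i-th motif is reproducible and independent of n.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    out = []
    for ss in _per_motif_seeds(seed, n):
        rng = np.random.default_rng(ss)
        out.append(Motif.from_array(sample_motif_array(model, rng)))
    return out


def sample_maxent_ics(model: MaxEntModel, n: int, seed=None) -> np.ndarray:
    """ICs of n i.i.d. MaxEnt motifs, without materializing letters.

    Motif IC depends only on the column classes, so this draws stage-1 class
    indices in one vectorized stream.  Intended for importance sampling and
    large validation runs; uses a single stream rather than per-motif
    substreams.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    rng = np.random.default_rng(_seed_sequence(seed))
    idx = cc.sample_class_indices(model.sampling_cdf, (n, model.L), rng)
    return model.ic_of_class_matrix(idx)
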