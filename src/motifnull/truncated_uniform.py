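"""Truncated-uniform motif sampling: uniform over all motifs with IC in I +/- eps.

A rejection sampler with the MaxEnt distribution (tuned so its mean IC is
the interval center I) as the proposal.  Written in terms of IC, the
proposal is Q(M) = exp(lambda IC(M)) / Z_Q, and the unnormalized density
ratio P/Q is proportional to exp(-lambda IC(M)).  For lambda > 0 this is
maximized at the lower interval endpoint I_min = I - eps, giving acceptance
ratio AR(M) = exp(lambda (I_min - IC(M))) >= exp(-2 lambda eps); for
lambda < 0 the maximizer is the upper endpoint I_max, symmetrically.
Proposals falling outside the interval are rejected outright (target
density zero) and counted toward the acceptance rate.

The runtime-optimal tolerance is eps = 1/(2 lambda); we cap it at 0.5 bits
when |lambda| < 1, where the heuristic degenerates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import count_classes as cc
from .errors import FeasibilityError, ParameterError, ProposalBudgetError
from .maxent import MaxEntModel, fit_lambda, _per_motif_seeds
from .motif_core import Motif

EPSILON_CAP = 0.5  # bits; applied when |lambda| < 1
DEFAULT_PROPOSAL_BUDGET = 10**6  # proposals per requested motif


def default_epsilon(lam: float) -> float:
    """Runtime-optimal half-width 1/(2|lambda|), capped at 0.5 bits.

    The 1/(2 lambda) rule comes from minimizing (proposal cost) x (mean
    trials); it diverges as lambda -> 0, where any eps is cheap, so the cap
    applies for |lambda| < 1.
    """
    if lam == 0.0:
        warnings.warn(
            "lambda = 0: eps heuristic undefined, returning the 0.5-bit cap",
            RuntimeWarning,
            stacklevel=2,
        )
        return EPSILON_CAP
    return min(1.0 / (2.0 * abs(lam)), EPSILON_CAP)


@dataclass
class TUModel:
    """Truncated-uniform target with its MaxEnt proposal."""

    N: int
    L: int
    center_ic: float  # I, bits
    epsilon: float  # bits
    proposal: MaxEntModel

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ParameterError("epsilon must be positive")

    @property
    def i_min(self) -> float:
        return self.center_ic - self.epsilon

    @property
    def i_max(self) -> float:
        return self.center_ic + self.epsilon


@dataclass
class TUSampleReport:
    """Accepted motifs plus rejection bookkeeping.

    Two rates are reported because proposals are rejected for two distinct
    reasons.  `acceptance_rate` counts every proposal (out-of-band draws
    have target density zero and are rejected outright); it governs the
    runtime and is bounded above by the proposal mass of the IC band, so it
    falls with N.  `ratio_test_rate` conditions on landing in the band; it
    is bounded below by roughly (1 - e^{-2 lambda eps}) / (2 lambda eps)
    and stays above 1e-2 across practical parameter ranges.
    """

    motifs: list[Motif]
    proposals_used: int
    in_band_proposals: int

    @property
    def acceptance_rate(self) -> float:
        return len(self.motifs) / self.proposals_used

    @property
    def ratio_test_rate(self) -> float:
        if self.in_band_proposals == 0:
            return float("nan")
        return len(self.motifs) / self.in_band_proposals


def build_tu_model(
    N: int, L: int, I: float, epsilon: float | None = None,
    table: cc.ClassTable | None = None,
) -> TUModel:
    """Fit the proposal (mean IC = I) and resolve epsilon (None -> heuristic)."""
    proposal = fit_lambda(N, L, I, table=table)
    if epsilon is None:
        epsilon = default_epsilon(proposal.lam)
    return TUModel(N=N, L=L, center_ic=I, epsilon=float(epsilon), proposal=proposal)


def acceptance_ratio(model: TUModel, ic) -> np.ndarray:
    """AR for in-band ICs: 1 at the maximizing endpoint, >= exp(-2|lambda|eps).

    Only meaningful for ic within [I-eps, I+eps]; out-of-band proposals are
    rejected before this ratio is evaluated.
    """
    lam = model.proposal.lam
    ic = np.asarray(ic, dtype=float)
    if lam >= 0:
        return np.exp(lam * (model.i_min - ic))
    return np.exp(lam * (model.i_max - ic))


def _sample_one(
    model: TUModel, rng: np.random.Generator, budget: int
) -> tuple[Motif, int, int]:
    """Rejection-sample a single motif from its own stream.

    Proposals are drawn in growing batches; only class indices and IC are
    computed until acceptance, at which point the accepted class row is
    materialized into letters.  Returns (motif, proposals used, in-band
    proposals seen among them).
    """
    prop = model.proposal
    used = 0
    band_seen = 0
    batch = 16
    while used < budget:
        batch = min(batch, budget - used)
        idx = cc.sample_class_indices(prop.sampling_cdf, (batch, model.L), rng)
        ics = prop.ic_of_class_matrix(idx)
        r = rng.random(batch)
        in_band = (ics >= model.i_min) & (ics <= model.i_max)
        # clip keeps the exp argument <= 0 for out-of-band draws (discarded anyway)
        ar = acceptance_ratio(model, np.clip(ics, model.i_min, model.i_max))
        ok = in_band & (r <= ar)
        hits = np.flatnonzero(ok)
        if hits.size:
            j = int(hits[0])
            used += j + 1
            band_seen += int(in_band[: j + 1].sum())
            counts = cc.assign_counts_to_bases(prop.class_table, idx[j], rng)
            cols = cc.arrange_letters(counts, model.N, rng)  # (L, N)
            return Motif.from_array(cols.T), used, band_seen
        used += batch
        band_seen += int(in_band.sum())
        batch = min(batch * 2, 4096)
    raise ProposalBudgetError(
        f"no acceptance within {budget} proposals for IC band "
        f"{model.i_min:.4g}..{model.i_max:.4g} (N={model.N}, L={model.L})"
    )


def sample_tu_from_model(
    model: TUModel, n: int, seed=None, budget: int = DEFAULT_PROPOSAL_BUDGET
) -> TUSampleReport:
    """Draw n motifs from a prepared TU model, one substream per motif."""
    if n < 1:
        raise ParameterError("n must be >= 1")
    motifs, used, band = [], 0, 0
    for ss in _per_motif_seeds(seed, n):
        rng = np.random.default_rng(ss)
        m, u, b = _sample_one(model, rng, budget)
        motifs.append(m)
        used += u
        band += b
    return TUSampleReport(motifs=motifs, proposals_used=used, in_band_proposals=band)


def sample_tu(
    N: int, L: int, I: float, epsilon: float | None = None, n: int = 1,
    seed=None, budget: int = DEFAULT_PROPOSAL_BUDGET,
    table: cc.ClassTable | None = None,
) -> TUSampleReport:
    """Sample n motifs uniformly from {M : |IC(M) - I| <= eps}.

    epsilon=None applies the 1/(2 lambda) heuristic.  Every returned motif
    satisfies the hard interval constraint; conditional on the interval all
    motifs are equiprobable.  Raises FeasibilityError when the proposal
    cannot be tuned (I outside the achievable mean-IC range).
    """
    model = build_tu_model(N, L, I, epsilon, table=table)
    return sample_tu_from_model(model, n, seed=seed, budget=budget)
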