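"""Equivalence classes of single-column base-count vectors.

A column of N letters over a 4-letter alphabet is summarized by its count
vector (n_A, n_C, n_G, n_T).  Two columns have equal entropy iff their count
vectors are permutations of one another, so the 4^N columns collapse into
equivalence classes indexed by the integer partitions of N into at most 4
parts.  Each class carries:

  * a canonical representative: the counts sorted in non-increasing order,
  * its plug-in entropy in bits,
  * its weight w = (4!/prod m_v!) * (N!/prod n_b!): the number of distinct
    columns in the class (distinct assignments of counts to bases, times
    arrangements of the letter multiset over the N rows).

All tilted sums (partition function, moments) and the exact three-stage
column sampler live here.  The Boltzmann tilt is exp(-lambda * H) with H in
bits throughout; users comparing against natural-log implementations must
rescale lambda by ln 2.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
from scipy.special import gammaln, logsumexp

from .errors import ParameterError


def _partitions_at_most(n: int, parts: int, largest: int | None = None) -> Iterator[tuple[int, ...]]:
    """Yield partitions of n into at most `parts` non-increasing parts."""
    if n == 0:
        yield ()
        return
    if parts == 0:
        return
    if largest is None:
        largest = n
    for first in range(min(n, largest), 0, -1):
        for rest in _partitions_at_most(n - first, parts - 1, first):
            yield (first,) + rest


def class_count_closed_form(N: int) -> int:
    """Number of integer partitions of N into at most 4 parts (closed form)."""
    if N < 1:
        raise ParameterError("N must be >= 1")
    M = N + 4
    return round((M**3 + 3 * M**2 - 9 * M * (M % 2)) / 144)


@dataclass(frozen=True)
class CountVector:
    """Canonical representative of a count-vector class: sorted non-increasing."""

    counts: tuple[int, ...]

    def __post_init__(self):
        if any(c < 0 for c in self.counts):
            raise ParameterError("counts must be non-negative")
        if list(self.counts) != sorted(self.counts, reverse=True):
            object.__setattr__(self, "counts", tuple(sorted(self.counts, reverse=True)))

    @property
    def N(self) -> int:
        return sum(self.counts)


def class_entropy(v: CountVector | tuple[int, ...]) -> float:
    """Plug-in entropy of a count vector, in bits (0*log 0 = 0)."""
    counts = v.counts if isinstance(v, CountVector) else tuple(v)
    N = sum(counts)
    h = 0.0
    for c in counts:
        if c > 0:
            h -= (c / N) * math.log2(c / N)
    return h


def class_weight(v: CountVector | tuple[int, ...]) -> tuple[int, float]:
    """Exact class weight and its natural log.

    weight = (A!/prod multiplicities!) * (N!/prod counts!), where the
    multiplicities count how many entries of the tuple share each value.
    The exact path uses Python big integers; the log path uses log-gamma.
    The two agree to 1e-9 relative for all N.
    """
    counts = v.counts if isinstance(v, CountVector) else tuple(v)
    A = len(counts)
    N = sum(counts)
    mult: dict[int, int] = {}
    for c in counts:
        mult[c] = mult.get(c, 0) + 1
    perm = math.factorial(A)
    for mv in mult.values():
        perm //= math.factorial(mv)
    arr = math.factorial(N)
    for c in counts:
        arr //= math.factorial(c)
    exact = perm * arr
    log_w = (
        gammaln(A + 1)
        - sum(gammaln(mv + 1) for mv in mult.values())
        + gammaln(N + 1)
        - sum(gammaln(c + 1) for c in counts)
    )
    return exact, float(log_w)


@dataclass
class ClassTable:
    """All count-vector classes for N sites over an alphabet, with weights.

    Arrays are aligned: row k of `counts` is the canonical representative of
    class k, with entropy `entropy[k]` (bits) and natural-log weight
    `log_weight[k]`.
    """

    N: int
    alphabet_size: int
    counts: np.ndarray  # (K, alphabet_size) int64, rows sorted non-increasing
    entropy: np.ndarray  # (K,) bits
    log_weight: np.ndarray  # (K,) natural log

    @property
    def class_count(self) -> int:
        return self.counts.shape[0]

    def exact_weight(self, k: int) -> int:
        """Big-integer weight of class k."""
        return class_weight(tuple(int(c) for c in self.counts[k]))[0]

    def total_weight_exact(self) -> int:
        """Sum of exact weights over all classes; equals alphabet_size**N."""
        return sum(self.exact_weight(k) for k in range(self.class_count))

    # -- serialization -----------------------------------------------------

    def to_text(self, sink) -> None:
        """Write a tab-separated cache: counts, entropy_bits, log_weight."""
        if isinstance(sink, (str, Path)):
            with open(sink, "w") as fh:
                self.to_text(fh)
            return
        sink.write(f"# class_table N={self.N} alphabet_size={self.alphabet_size}\n")
        cols = "\t".join(f"n{i}" for i in range(self.alphabet_size))
        sink.write(f"# {cols}\tentropy_bits\tlog_weight\n")
        for k in range(self.class_count):
            row = "\t".join(str(int(c)) for c in self.counts[k])
            sink.write(f"{row}\t{self.entropy[k]:.17g}\t{self.log_weight[k]:.17g}\n")

    @classmethod
    def from_text(cls, source) -> "ClassTable":
        if isinstance(source, (str, Path)):
            with open(source) as fh:
                return cls.from_text(fh)
        header = source.readline()
        m = [int(x) for x in re.findall(r"\d+", header)]
        N, A = m[0], m[1]
        counts, ent, logw = [], [], []
        for line in source:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.split()
            counts.append([int(x) for x in parts[:A]])
            ent.append(float(parts[A]))
            logw.append(float(parts[A + 1]))
        return cls(
            N=N,
            alphabet_size=A,
            counts=np.array(counts, dtype=np.int64),
            entropy=np.array(ent),
            log_weight=np.array(logw),
        )


def enumerate_classes(N: int, alphabet_size: int = 4) -> ClassTable:
    """Enumerate all count-vector classes for N sites.

    One entry per integer partition of N into at most `alphabet_size` parts,
    zero-padded and sorted non-increasing.  Partition counts grow as
    O(N^(alphabet_size-1)); a warning is emitted for alphabets larger than 6.
    """
    if N < 1:
        raise ParameterError("N must be >= 1")
    if not (2 <= alphabet_size <= 20):
        raise ParameterError("alphabet_size must be between 2 and 20")
    if alphabet_size > 6:
        warnings.warn(
            f"alphabet_size={alphabet_size}: class enumeration is "
            f"O(N^{alphabet_size - 1}) and may be very slow for large N",
            RuntimeWarning,
            stacklevel=2,
        )
    reps = []
    for part in _partitions_at_most(N, alphabet_size):
        reps.append(tuple(part) + (0,) * (alphabet_size - len(part)))
    counts = np.array(reps, dtype=np.int64)
    K = counts.shape[0]
    # Entropy, vectorized, in bits.
    with np.errstate(divide="ignore", invalid="ignore"):
        p = counts / float(N)
        terms = np.where(counts > 0, p * np.log2(np.where(counts > 0, p, 1.0)), 0.0)
    entropy = -terms.sum(axis=1)
    # log weight = log(A!/prod m_v!) + log(N!/prod n_b!)
    log_w = np.full(K, gammaln(alphabet_size + 1) + gammaln(N + 1))
    log_w -= gammaln(counts + 1).sum(axis=1)
    # multiplicity correction: counts rows are sorted, so equal values are adjacent
    sorted_counts = counts  # already non-increasing
    for k in range(K):
        row = sorted_counts[k]
        run = 1
        for i in range(1, alphabet_size):
            if row[i] == row[i - 1]:
                run += 1
            else:
                log_w[k] -= gammaln(run + 1)
                run = 1
        log_w[k] -= gammaln(run + 1)
    return ClassTable(
        N=N,
        alphabet_size=alphabet_size,
        counts=counts,
        entropy=entropy,
        log_weight=log_w,
    )


def load_or_build(N: int, alphabet_size: int = 4, cache_dir=None) -> ClassTable:
    """Return the class table for (N, alphabet_size), using a text cache if given."""
    if cache_dir is None:
        return enumerate_classes(N, alphabet_size)
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    path = cache_dir / f"classes_N{N}_A{alphabet_size}.tsv"
    if path.exists():
        return ClassTable.from_text(path)
    table = enumerate_classes(N, alphabet_size)
    table.to_text(path)
    return table


# ---------------------------------------------------------------------------
# Tilted sums
# ---------------------------------------------------------------------------

def log_partition_column(table: ClassTable, lam: float) -> float:
    """log Z_c(lambda) = log sum_k w_k exp(-lambda H_k), H in bits.

    Computed by log-sum-exp; safe for any |lambda| that fits in a float.
    """
    return float(logsumexp(table.log_weight - lam * table.entropy))


def class_log_probs(table: ClassTable, lam: float) -> np.ndarray:
    """Log probability of each class under the tilted distribution."""
    a = table.log_weight - lam * table.entropy
    return a - logsumexp(a)


def class_probs(table: ClassTable, lam: float) -> np.ndarray:
    return np.exp(class_log_probs(table, lam))


def tilted_moments(table: ClassTable, lam: float) -> tuple[float, float]:
    """Mean and variance of the column entropy (bits, bits^2) under the tilt."""
    p = class_probs(table, lam)
    mean = float(p @ table.entropy)
    var = float(p @ table.entropy**2 - mean**2)
    return mean, max(var, 0.0)


def tilted_central_moment(table: ClassTable, lam: float, order: int) -> float:
    """Central moment of column entropy of the given order under the tilt."""
    p = class_probs(table, lam)
    mean = float(p @ table.entropy)
    return float(p @ (table.entropy - mean) ** order)


# ---------------------------------------------------------------------------
# Exact column sampling
#
# Stage 1: class k with probability proportional to w_k exp(-lambda H_k).
# Stage 2: uniform choice among the distinct assignments of the count
#          multiset to bases (a uniform random permutation of the counts --
#          every distinct assignment arises from the same number of
#          permutations).
# Stage 3: uniform random arrangement of the letter multiset over rows.
# Every column within a class is therefore equiprobable.
# ---------------------------------------------------------------------------

def class_sampling_cdf(table: ClassTable, lam: float) -> np.ndarray:
    """Cumulative class probabilities for inverse-CDF sampling."""
    cdf = np.cumsum(class_probs(table, lam))
    cdf[-1] = 1.0
    return cdf


def sample_class_indices(cdf: np.ndarray, size, rng: np.random.Generator) -> np.ndarray:
    return np.searchsorted(cdf, rng.random(size), side="right")


def assign_counts_to_bases(
    table: ClassTable, class_idx: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Stage 2 for a batch of columns: (n, A) counts after random assignment."""
    reps = table.counts[class_idx]  # (n, A)
    keys = rng.random(reps.shape)
    perm = np.argsort(keys, axis=1)
    return np.take_along_axis(reps, perm, axis=1)


def arrange_letters(counts: np.ndarray, N: int, rng: np.random.Generator) -> np.ndarray:
    """Stage 3 for a batch: (n, N) int8 letter indices, rows shuffled uniformly."""
    n, A = counts.shape
    cum = np.cumsum(counts, axis=1)
    pos = np.arange(N)
    letters = np.zeros((n, N), dtype=np.int8)
    for b in range(A - 1):
        letters += (pos[None, :] >= cum[:, b : b + 1]).astype(np.int8)
    keys = rng.random((n, N))
    order = np.argsort(keys, axis=1)
    return np.take_along_axis(letters, order, axis=1)


def sample_columns(
    table: ClassTable, lam: float, n: int, rng: np.random.Generator,
    cdf: np.ndarray | None = None,
) -> np.ndarray:
    """Draw n i.i.d. columns from the tilted distribution: (n, N) int8."""
    if cdf is None:
        cdf = class_sampling_cdf(table, lam)
    idx = sample_class_indices(cdf, n, rng)
    counts = assign_counts_to_bases(table, idx, rng)
    return arrange_letters(counts, table.N, rng)


def sample_column(table: ClassTable, lam: float, rng: np.random.Generator) -> str:
    """Draw a single column as a string of N letters."""
    from .motif_core import DNA_ALPHABET

    letters = sample_columns(table, lam, 1, rng)[0]
    return "".join(DNA_ALPHABET[int(b)] for b in letters)
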