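"""Motif representation, I/O, and information statistics.

A motif is treated extensionally: a gapless alignment of N DNA sequences of
common length L, not a probability matrix.  All statistics are computed from
plug-in (maximum-likelihood) column base frequencies with no pseudocounts,
in bits (log base 2), against a uniform mononucleotide background of
2 bits/base.
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence, TextIO

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlphabetError, DimensionError, EmptyInputError, ParameterError

DNA_ALPHABET = "ACGT"
_BASE_TO_INDEX = {b: i for i, b in enumerate(DNA_ALPHABET)}
_INDEX_TO_BASE = np.array(list(DNA_ALPHABET))
_VALID = re.compile(r"^[ACGT]+$")


@dataclass(frozen=True)
class Motif:
    """A gapless alignment of N equal-length DNA sequences.

    Sequences are stored uppercased, in input order; all statistics in this
    package are invariant under reordering of the rows.
    """

    sequences: tuple[str, ...]

    def __post_init__(self):
        if len(self.sequences) == 0:
            raise EmptyInputError("a motif needs at least one sequence")
        seqs = tuple(s.upper() for s in self.sequences)
        L = len(seqs[0])
        if L < 1:
            raise DimensionError("motif width must be at least 1")
        for i, s in enumerate(seqs):
            if len(s) != L:
                raise DimensionError(
                    f"sequence {i} has length {len(s)}, expected {L}"
                )
            if not _VALID.match(s):
                bad = sorted(set(s) - set(DNA_ALPHABET))
                raise AlphabetError(
                    f"sequence {i} contains characters outside ACGT: {bad}"
                )
        object.__setattr__(self, "sequences", seqs)

    @property
    def N(self) -> int:
        """Number of sites (rows)."""
        return len(self.sequences)

    @property
    def L(self) -> int:
        """Motif width in bp (columns)."""
        return len(self.sequences[0])

    def to_array(self) -> np.ndarray:
        """(N, L) int8 array with A,C,G,T -> 0,1,2,3."""
        flat = np.frombuffer("".join(self.sequences).encode(), dtype=np.uint8)
        out = np.empty(flat.shape, dtype=np.int8)
        for base, idx in _BASE_TO_INDEX.items():
            out[flat == ord(base)] = idx
        return out.reshape(self.N, self.L)

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "Motif":
        """Inverse of :meth:`to_array`."""
        arr = np.asarray(arr)
        if arr.ndim != 2:
            raise DimensionError("expected a 2-D (N, L) array")
        rows = _INDEX_TO_BASE[arr]
        return cls(tuple("".join(row) for row in rows))

    def column_counts(self) -> np.ndarray:
        """(L, 4) matrix of per-column base counts."""
        arr = self.to_array()
        counts = np.zeros((self.L, 4), dtype=np.int64)
        for b in range(4):
            counts[:, b] = (arr == b).sum(axis=0)
        return counts


@dataclass(frozen=True)
class MotifStatistic:
    """A named, deterministic real-valued function of a motif."""

    name: str
    evaluator: Callable[[Motif], float]

    def __call__(self, m: Motif) -> float:
        return float(self.evaluator(m))


@dataclass(frozen=True)
class PositionalProfile:
    """Per-column information content plus motif-level totals."""

    column_ic: np.ndarray  # bits, length L
    total_ic: float  # bits
    total_entropy: float  # bits
    gc_fraction: float  # in [0, 1]


def column_entropies_from_counts(counts: np.ndarray, N: int) -> np.ndarray:
    """Plug-in Shannon entropy (bits) of each row of an (L, 4) count matrix."""
    p = counts / float(N)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return -terms.sum(axis=1)


def motif_entropy(m: Motif) -> float:
    """Total positional entropy H(M) in bits (sum of column entropies)."""
    return float(column_entropies_from_counts(m.column_counts(), m.N).sum())


def motif_ic(m: Motif) -> float:
    """Information content IC(M) = 2L - H(M), in bits, under a uniform background."""
    return 2.0 * m.L - motif_entropy(m)


def motif_gc(m: Motif) -> float:
    """Fraction of G+C letters over all N*L positions."""
    counts = m.column_counts()
    gc = counts[:, _BASE_TO_INDEX["G"]].sum() + counts[:, _BASE_TO_INDEX["C"]].sum()
    return float(gc) / (m.N * m.L)


def positional_ic(m: Motif) -> PositionalProfile:
    """Per-column IC (2 - column entropy) and consistent motif totals."""
    H = column_entropies_from_counts(m.column_counts(), m.N)
    col_ic = 2.0 - H
    return PositionalProfile(
        column_ic=col_ic,
        total_ic=float(col_ic.sum()),
        total_entropy=float(H.sum()),
        gc_fraction=motif_gc(m),
    )


def gini(values: np.ndarray) -> float:
    """Gini coefficient of a vector of non-negative values.

    With c_1 <= ... <= c_L the sorted values, returns
    2*sum(j*c_j)/(L*sum(c_j)) - (L+1)/L.  Undefined (0/0) when all values
    are zero; we return 0 with a warning (the all-zero vector is maximally
    even).
    """
    c = np.sort(np.asarray(values, dtype=float))
    L = c.size
    total = c.sum()
    if total <= 0:
        warnings.warn(
            "Gini coefficient undefined for an all-zero vector; returning 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    j = np.arange(1, L + 1)
    return float(2.0 * (j * c).sum() / (L * total) - (L + 1) / L)


def igc(m: Motif) -> float:
    """Informational Gini coefficient: Gini of the per-column IC vector.

    0 means information is spread evenly across columns; values near 1 mean
    it is concentrated in few columns.  For finite L the maximum is
    (L-1)/L.  A zero-IC motif returns 0 with a warning.
    """
    return gini(positional_ic(m).column_ic)


# ---------------------------------------------------------------------------
# I/O
#
# Two plain-text formats:
#   * "fasta": standard multi-FASTA; on write, headers are
#     >motif{i}_site{j} and sequences wrap at 80 columns.
#   * "lines": one site per line; '#' lines are comments; blank lines
#     separate motifs.
# read_motif treats the whole input as one motif; read_motifs splits it
# into the motifs write_motifs produced.
# ---------------------------------------------------------------------------

_HEADER_RE = re.compile(r"^motif(\d+)_site(\d+)$")


def _as_text_handle(source) -> tuple[TextIO, bool]:
    if isinstance(source, (str, Path)):
        return open(source, "r"), True
    if isinstance(source, bytes):
        return io.StringIO(source.decode()), False
    if isinstance(source, io.BytesIO):
        return io.TextIOWrapper(source), False
    return source, False


def read_motifs(source, format: str = "fasta") -> list[Motif]:
    """Read one or more motifs from a stream or path.

    FASTA records whose headers all match ``motif{i}_site{j}`` are grouped by
    motif index; otherwise all records form a single motif.  In "lines"
    format, blank lines separate motifs.
    """
    handle, close = _as_text_handle(source)
    try:
        if format == "fasta":
            records = list(SeqIO.parse(handle, "fasta"))
            if not records:
                raise EmptyInputError("no FASTA records found")
            ids = [r.id for r in records]
            matches = [_HEADER_RE.match(i) for i in ids]
            if all(matches):
                groups: dict[int, list[str]] = {}
                for rec, mt in zip(records, matches):
                    groups.setdefault(int(mt.group(1)), []).append(str(rec.seq))
                return [Motif(tuple(groups[k])) for k in sorted(groups)]
            return [Motif(tuple(str(r.seq) for r in records))]
        elif format == "lines":
            blocks: list[list[str]] = [[]]
            for raw in handle:
                line = raw.strip()
                if line.startswith("#"):
                    continue
                if not line:
                    if blocks[-1]:
                        blocks.append([])
                    continue
                blocks[-1].append(line)
            blocks = [b for b in blocks if b]
            if not blocks:
                raise EmptyInputError("no sites found in input")
            return [Motif(tuple(b)) for b in blocks]
        else:
            raise ParameterError(f"unknown motif format: {format!r}")
    finally:
        if close:
            handle.close()


def read_motif(source, format: str = "fasta") -> Motif:
    """Read a single motif; the entire input is taken as one alignment."""
    motifs = read_motifs(source, format=format)
    if len(motifs) == 1:
        return motifs[0]
    # Collapse grouped input back into a single alignment, preserving order.
    return Motif(tuple(s for m in motifs for s in m.sequences))


def write_motifs(motifs: Sequence[Motif], sink, format: str = "fasta") -> None:
    """Write motifs to a path or text handle; round-trips with read_motifs."""
    if len(motifs) == 0:
        raise EmptyInputError("no motifs to write")
    if isinstance(sink, (str, Path)):
        with open(sink, "w") as fh:
            write_motifs(motifs, fh, format=format)
        return
    if format == "fasta":
        records = [
            SeqRecord(Seq(seq), id=f"motif{i}_site{j}", description="")
            for i, m in enumerate(motifs)
            for j, seq in enumerate(m.sequences)
        ]
        writer = SeqIO.FastaIO.FastaWriter(sink, wrap=80)
        writer.write_file(records)
    elif format == "lines":
        for i, m in enumerate(motifs):
            if i:
                sink.write("\n")
            sink.write(f"# motif{i}\n")
            for seq in m.sequences:
                sink.write(seq + "\n")
    else:
        raise ParameterError(f"unknown motif format: {format!r}")


# Shipped statistics, usable anywhere a MotifStatistic is accepted.
IC_STATISTIC = MotifStatistic("ic", motif_ic)
IGC_STATISTIC = MotifStatistic("igc", igc)
GC_STATISTIC = MotifStatistic("gc", motif_gc)
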