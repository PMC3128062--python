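"""Order-k finite-context model: counts, pseudocount estimator, IR updates.

This is the clear reference implementation of a single adaptive model.
Probability estimates use the symmetric-pseudocount estimator

    P(s | c) = (n(s|c) + alpha) / (N(c) + 4 * alpha)

which interpolates between the maximum-likelihood estimate and the
uniform distribution with weight lambda = N / (N + 4*alpha).  Besides the
direct counter n(s|c), the model can also bump the counter addressed by
the reverse complement of the (k+1)-mer ``context + symbol`` so that
inverted repeats contribute statistics.

Large-scale scanning uses the compiled kernels in ``dnafcm._kernels``;
this module is the ground truth they are tested against.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Union

import numpy as np

AlphaLike = Union[int, float, str, Fraction, tuple]

#: complement of a 2-bit code (A<->T, C<->G)
def complement_code(s: int) -> int:
    return 3 - s


def as_alpha(value: AlphaLike) -> Fraction:
    """Normalize a pseudocount given as int/float/"1/16"/Fraction/tuple."""
    if isinstance(value, tuple):
        frac = Fraction(int(value[0]), int(value[1]))
    elif isinstance(value, str):
        frac = Fraction(value)
    elif isinstance(value, float):
        frac = Fraction(value).limit_denominator(1 << 16)
    else:
        frac = Fraction(value)
    if frac <= 0:
        raise ValueError(f"pseudocount must be > 0, got {value!r}")
    return frac


def pack_context(codes) -> int:
    """Pack symbol codes (oldest first) into an integer, newest in low bits."""
    packed = 0
    for s in codes:
        packed = (packed << 2) | int(s)
    return packed


def unpack_context(packed: int, k: int) -> list[int]:
    """Inverse of :func:`pack_context`: codes oldest first."""
    return [(packed >> (2 * (k - 1 - i))) & 3 for i in range(k)]


def shift_context(packed: int, s: int, k: int) -> int:
    """Push symbol ``s`` as the most recent; the oldest symbol falls off."""
    return ((packed << 2) | int(s)) & ((1 << (2 * k)) - 1)


def ir_counterpart(packed: int, s: int, k: int) -> tuple[int, int]:
    """Context/symbol pair addressed by the inverted-repeat update.

    Take the (k+1)-mer ``context + s``, reverse it, complement it; the
    first k symbols of the result are the counterpart context and the
    last one the counterpart symbol.  The map is an involution.
    """
    mask = (1 << (2 * k)) - 1
    w_comp = ((packed << 2) | int(s)) ^ ((mask << 2) | 3)  # complement all k+1
    # reverse base-4 digits of the complemented (k+1)-mer
    rev = 0
    tmp = w_comp
    for _ in range(k + 1):
        rev = (rev << 2) | (tmp & 3)
        tmp >>= 2
    return (rev >> 2) & mask, rev & 3


@dataclass
class InfoAccumulator:
    """Running total of code lengths; ``average`` is bits per base (bpb)."""

    total_bits: float = 0.0
    n_symbols: int = 0

    def add(self, bits: float) -> None:
        self.total_bits += bits
        self.n_symbols += 1

    @property
    def average(self) -> float:
        return self.total_bits / self.n_symbols if self.n_symbols else 0.0


class CountTable:
    """Per-context symbol counters n(s|c) with N(c) = sum_s n(s|c).

    Two interchangeable backends: a dense ``(4**k, 4)`` array (small k)
    and a dict keyed by the packed context (deep, sparse k).  Unvisited
    contexts read as all-zero in both.
    """

    DENSE_MAX_ORDER = 10

    def __init__(self, k: int, backend: str = "auto"):
        if k < 1:
            raise ValueError("model order must be >= 1")
        if backend == "auto":
            backend = "dense" if k <= self.DENSE_MAX_ORDER else "hash"
        if backend not in ("dense", "hash"):
            raise ValueError(f"unknown backend {backend!r}")
        self.k = k
        self.backend = backend
        if backend == "dense":
            self._dense = np.zeros((4**k, 4), dtype=np.int64)
            self._map: dict[int, np.ndarray] = {}
        else:
            self._dense = None
            self._map = {}

    def counts(self, context: int) -> np.ndarray:
        """The four counters for ``context`` (a copy-safe view)."""
        if self.backend == "dense":
            return self._dense[context]
        row = self._map.get(context)
        if row is None:
            return np.zeros(4, dtype=np.int64)
        return row

    def total(self, context: int) -> int:
        return int(self.counts(context).sum())

    def increment(self, context: int, s: int, by: int = 1) -> None:
        if self.backend == "dense":
            self._dense[context, s] += by
        else:
            row = self._map.get(context)
            if row is None:
                row = np.zeros(4, dtype=np.int64)
                self._map[context] = row
            row[s] += by

    def check(self) -> None:
        """On-demand consistency check: counters non-negative."""
        if self.backend == "dense":
            assert (self._dense >= 0).all()
        else:
            for row in self._map.values():
                assert (row >= 0).all()

    @property
    def n_contexts_seen(self) -> int:
        if self.backend == "dense":
            return int((self._dense.sum(axis=1) > 0).sum())
        return len(self._map)


class FCModel:
    """One adaptive order-k finite-context model.

    The context register starts as all-A at construction (and after
    :meth:`reset`), matching the warm-up convention shared by the
    scanning kernels and the codec.
    """

    def __init__(
        self,
        k: int,
        alpha: AlphaLike = 1,
        use_ir: bool = True,
        backend: str = "auto",
    ):
        self.k = k
        self.alpha = as_alpha(alpha)
        self.use_ir = use_ir
        self.counts = CountTable(k, backend=backend)
        self.reset()

    def reset(self) -> None:
        self.context = 0  # all-A warm-up

    # -- estimation -----------------------------------------------------

    def estimate(self, context: int | None = None) -> np.ndarray:
        """Probability vector over A,C,G,T for the given (or current) context."""
        c = self.context if context is None else context
        row = self.counts.counts(c)
        a_num = self.alpha.numerator
        a_den = self.alpha.denominator
        num = a_den * row + a_num
        den = a_den * int(row.sum()) + 4 * a_num
        return num / float(den)

    def info(self, s: int, context: int | None = None) -> float:
        """Code length, in bits, of symbol ``s`` under the current estimate."""
        return info_content(self.estimate(context), s)

    # -- adaptation -----------------------------------------------------

    def update(self, s: int, context: int | None = None) -> None:
        """Account one observed symbol (direct and, optionally, IR counter).

        Both increments are applied unconditionally, so when the IR
        address coincides with the direct one the counter rises by 2.
        Advances the context register only when ``context`` is None.
        """
        c = self.context if context is None else context
        self.counts.increment(c, s)
        if self.use_ir:
            ir_c, ir_s = ir_counterpart(c, s, self.k)
            self.counts.increment(ir_c, ir_s)
        if context is None:
            self.context = shift_context(c, s, self.k)

    def scan(self, codes, accumulate: InfoAccumulator | None = None) -> np.ndarray:
        """Process a code sequence, returning per-symbol bits.

        Estimate-then-update for every symbol; this is the reference
        single-model pass the fast kernels must agree with bit for bit.
        """
        out = np.empty(len(codes), dtype=np.float64)
        for i, s in enumerate(np.asarray(codes, dtype=np.int64)):
            out[i] = self.info(int(s))
            self.update(int(s))
            if accumulate is not None:
                accumulate.add(out[i])
        return out


def info_content(p: np.ndarray, s: int) -> float:
    """Negative log2 probability of symbol ``s`` (bits)."""
    return float(-np.log2(p[s]))
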