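"""Seeded generators for test sequences with known statistical structure.

Fixtures are built from ordered segments: iid background, order-k Markov
sources with a known transition table (whose entropy rate is computable
analytically and serves as an oracle), exact copies of earlier segments
(direct repeats) and reverse-complemented copies (inverted repeats).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from dnafcm.seqio import COMPLEMENT, FilteredSequence

KINDS = ("iid", "markov", "repeat_copy", "inverted_repeat_copy")


@dataclass(frozen=True)
class SegmentSpec:
    """One building block of a fixture.

    kind = "iid":    optional ``probs`` (4 floats, default uniform)
    kind = "markov": ``order`` and ``transition`` of shape (4**order, 4)
    kind = "repeat_copy" / "inverted_repeat_copy": ``source`` = index of
        an earlier segment; the copy is tiled/truncated to ``length``.
        Inverted copies are the reverse complement of the source.
    """

    kind: str
    length: int
    probs: Optional[tuple] = None
    order: Optional[int] = None
    transition: Optional[tuple] = None  # nested tuples for hashability
    source: Optional[int] = None

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if self.length < 1:
            raise ValueError("segment length must be >= 1")
        if self.kind == "markov":
            if self.order is None or self.transition is None:
                raise ValueError("markov segment needs order and transition")
            table = np.asarray(self.transition, dtype=np.float64)
            if table.shape != (4**self.order, 4):
                raise ValueError("transition table must have shape (4**order, 4)")
            if np.any(table < 0) or not np.allclose(table.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("transition rows must be probability distributions")
        if self.kind in ("repeat_copy", "inverted_repeat_copy") and self.source is None:
            raise ValueError("copy segment needs a source index")


@dataclass(frozen=True)
class FixtureSpec:
    segments: tuple[SegmentSpec, ...]
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "segments", tuple(self.segments))
        for i, seg in enumerate(self.segments):
            if seg.kind in ("repeat_copy", "inverted_repeat_copy"):
                if not (0 <= seg.source < i):
                    raise ValueError(
                        f"segment {i} must reference an earlier segment, got {seg.source}"
                    )


@dataclass
class SegmentAnnotation:
    """Ground truth for one generated segment (1-based inclusive span)."""

    index: int
    kind: str
    start: int
    end: int
    entropy_rate: Optional[float] = None  # analytic, for iid/markov
    source: Optional[int] = None


def generate(spec: FixtureSpec) -> tuple[FilteredSequence, list[SegmentAnnotation]]:
    """Deterministically generate the fixture sequence and its annotation."""
    rng = np.random.default_rng(spec.seed)
    chunks: list[np.ndarray] = []
    annotations: list[SegmentAnnotation] = []
    pos = 0
    for i, seg in enumerate(spec.segments):
        if seg.kind == "iid":
            probs = np.full(4, 0.25) if seg.probs is None else np.asarray(seg.probs)
            chunk = rng.choice(4, size=seg.length, p=probs).astype(np.int8)
            h = float(-np.sum(probs[probs > 0] * np.log2(probs[probs > 0])))
        elif seg.kind == "markov":
            table = np.asarray(seg.transition, dtype=np.float64)
            prior = np.concatenate(chunks) if chunks else np.zeros(0, dtype=np.int8)
            chunk = _gen_markov(rng, seg.length, seg.order, table, prior)
            h = entropy_rate(table, seg.order)
        else:
            src = annotations[seg.source]
            source_codes = np.concatenate(chunks)[src.start - 1 : src.end]
            if seg.kind == "inverted_repeat_copy":
                source_codes = COMPLEMENT[source_codes][::-1]
            reps = -(-seg.length // len(source_codes))
            chunk = np.tile(source_codes, reps)[: seg.length].astype(np.int8)
            h = None
        chunks.append(chunk)
        annotations.append(
            SegmentAnnotation(
                index=i,
                kind=seg.kind,
                start=pos + 1,
                end=pos + seg.length,
                entropy_rate=h,
                source=seg.source,
            )
        )
        pos += seg.length
    codes = np.concatenate(chunks).astype(np.int8) if chunks else np.zeros(0, np.int8)
    seq = FilteredSequence(
        record_id=f"fixture-seed{spec.seed}",
        codes=codes,
        positions=np.arange(1, len(codes) + 1, dtype=np.int64),
        original_length=len(codes),
    )
    return seq, annotations


def _gen_markov(rng, length, order, table, prior) -> np.ndarray:
    """Sequential draw from an order-k chain; context warm-up pads with A."""
    out = np.empty(length, dtype=np.int8)
    mask = 4**order
    ctx = 0
    warm = prior[-order:] if len(prior) else np.zeros(0, dtype=np.int8)
    for s in warm:
        ctx = (ctx * 4 + int(s)) % mask
    # draw all uniforms up front: deterministic and fast
    u = rng.random(length)
    cdf = np.cumsum(table, axis=1)
    cdf[:, 3] = 1.0
    for i in range(length):
        s = int(np.searchsorted(cdf[ctx], u[i], side="right"))
        s = min(s, 3)
        out[i] = s
        ctx = (ctx * 4 + s) % mask
    return out


def entropy_rate(transition, order: int) -> float:
    """Entropy rate (bits/symbol) of a stationary order-k chain.

    Computes the stationary distribution over the 4**order contexts by
    power iteration of the induced context chain, then averages the
    conditional entropies: h = -sum_c pi(c) sum_s p(s|c) log2 p(s|c).
    """
    table = np.asarray(transition, dtype=np.float64)
    n_ctx = 4**order
    if table.shape != (n_ctx, 4):
        raise ValueError("transition table must have shape (4**order, 4)")
    if np.any(table < 0) or not np.allclose(table.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("transition rows must be probability distributions")
    # context transition: c -> (4c + s) mod 4**order with prob p(s|c)
    pi = np.full(n_ctx, 1.0 / n_ctx)
    for _ in range(10000):
        nxt = np.zeros(n_ctx)
        for s in range(4):
            targets = (np.arange(n_ctx) * 4 + s) % n_ctx
            np.add.at(nxt, targets, pi * table[:, s])
        if np.abs(nxt - pi).sum() < 1e-14:
            pi = nxt
            break
        pi = nxt
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(table > 0, np.log2(np.where(table > 0, table, 1.0)), 0.0)
    cond_h = -(table * logp).sum(axis=1)
    return float((pi * cond_h).sum())


def random_transition_table(order: int, rng, concentration: float = 0.5) -> np.ndarray:
    """Dirichlet-random stochastic table, skewed for small concentration."""
    return rng.dirichlet(np.full(4, concentration), size=4**order)


# -- convenience fixtures used across the test-suite and docs --------------


def iid_fixture(n: int, seed: int = 0, probs=None) -> FilteredSequence:
    spec = FixtureSpec(
        segments=(SegmentSpec(kind="iid", length=n, probs=tuple(probs) if probs else None),),
        seed=seed,
    )
    return generate(spec)[0]


def markov_fixture(n: int, order: int, seed: int = 0, concentration: float = 0.5):
    """(sequence, analytic entropy rate) for a random order-k source."""
    rng = np.random.default_rng(seed + 7919)
    table = random_transition_table(order, rng, concentration)
    spec = FixtureSpec(
        segments=(
            SegmentSpec(
                kind="markov",
                length=n,
                order=order,
                transition=tuple(map(tuple, table)),
            ),
        ),
        seed=seed,
    )
    seq, ann = generate(spec)
    return seq, ann[0].entropy_rate


def planted_repeat_fixture(
    background: int, repeat: int, seed: int = 0, inverted: bool = False
):
    """iid background with a planted (direct or inverted) repeat:
    [iid background][iid repeat-unit][copy of the unit][iid tail]."""
    kind = "inverted_repeat_copy" if inverted else "repeat_copy"
    spec = FixtureSpec(
        segments=(
            SegmentSpec(kind="iid", length=background),
            SegmentSpec(kind="iid", length=repeat),
            SegmentSpec(kind=kind, length=repeat, source=1),
            SegmentSpec(kind="iid", length=max(background // 2, 1)),
        ),
        seed=seed,
    )
    return generate(spec)


def rc_halves_fixture(half: int, seed: int = 0) -> FilteredSequence:
    """Second half is the reverse complement of the first half."""
    spec = FixtureSpec(
        segments=(
            SegmentSpec(kind="iid", length=half),
            SegmentSpec(kind="inverted_repeat_copy", length=half, source=0),
        ),
        seed=seed,
    )
    return generate(spec)[0]


def annotations_to_tsv(annotations: Sequence[SegmentAnnotation]) -> str:
    """BED-like TSV (1-based inclusive spans) of the ground-truth segments."""
    lines = ["index\tkind\tstart\tend\tentropy_rate\tsource"]
    for a in annotations:
        er = "" if a.entropy_rate is None else f"{a.entropy_rate:.6f}"
        src = "" if a.source is None else str(a.source)
        lines.append(f"{a.index}\t{a.kind}\t{a.start}\t{a.end}\t{er}\t{src}")
    return "\n".join(lines) + "\n"
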