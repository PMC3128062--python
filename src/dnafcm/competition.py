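"""Block-wise competition among finite-context models of different orders.

All configured models scan the sequence in a single left-to-right pass.
Every model estimates and then updates its counts at every symbol, so
adaptation never depends on which model wins; at each block boundary the
model with the smallest accumulated block cost is selected, its
per-symbol code lengths become the information profile for the block,
and the choice index is charged to an adaptive low-order side model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np

from dnafcm import _kernels
from dnafcm.fcm import AlphaLike, as_alpha
from dnafcm.seqio import FilteredSequence

DEFAULT_DEPTHS = (2, 4, 6, 8, 10, 12, 14, 16)


@dataclass(frozen=True)
class CompetitionConfig:
    """Everything that determines encoder/decoder behavior.

    ``alpha_low`` applies to orders below ``alpha_threshold`` (Laplace's
    estimator by default), ``alpha_high`` to the deeper models, where a
    small pseudocount sharpens estimates built from few observations.
    """

    depths: tuple[int, ...] = DEFAULT_DEPTHS
    block_size: int = 200
    alpha_low: Fraction = Fraction(1)
    alpha_high: Fraction = Fraction(1, 16)
    alpha_threshold: int = 12
    side_order: int = 4
    side_alpha: Fraction = Fraction(1)
    use_ir: bool = True
    hash_min_order: int = 11
    reset_per_record: bool = True

    def __post_init__(self):
        object.__setattr__(self, "depths", tuple(int(d) for d in self.depths))
        for name in ("alpha_low", "alpha_high", "side_alpha"):
            object.__setattr__(self, name, as_alpha(getattr(self, name)))
        if not self.depths:
            raise ValueError("depths must be non-empty")
        if any(d < 1 for d in self.depths):
            raise ValueError("model orders must be >= 1")
        if list(self.depths) != sorted(set(self.depths)):
            raise ValueError("depths must be strictly increasing")
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")
        if self.side_order < 0:
            raise ValueError("side_order must be >= 0")

    def alpha_for(self, depth: int) -> Fraction:
        return self.alpha_high if depth >= self.alpha_threshold else self.alpha_low

    def to_dict(self) -> dict:
        return {
            "depths": list(self.depths),
            "block_size": self.block_size,
            "alpha_low": str(self.alpha_low),
            "alpha_high": str(self.alpha_high),
            "alpha_threshold": self.alpha_threshold,
            "side_order": self.side_order,
            "side_alpha": str(self.side_alpha),
            "use_ir": self.use_ir,
            "hash_min_order": self.hash_min_order,
            "reset_per_record": self.reset_per_record,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CompetitionConfig":
        return cls(**{**d, "depths": tuple(d["depths"])})


@dataclass
class BlockRecord:
    """Outcome of the competition for one block."""

    block_index: int
    model_costs: np.ndarray  # bits per configured depth
    chosen: int  # index into cfg.depths
    symbol_bits: float  # winning model's cost for this block


@dataclass
class InformationProfile:
    """Per-retained-base code length with original 1-based coordinates."""

    positions: np.ndarray  # int64
    bits: np.ndarray  # float64
    chosen_depth: np.ndarray  # int64, winning model order per base


@dataclass
class RecordResult:
    record_id: str
    blocks: list[BlockRecord]
    profile: InformationProfile
    symbol_bits: float
    side_bits: float
    modeled_bases: int

    @property
    def bpb(self) -> float:
        if self.modeled_bases == 0:
            return 0.0
        return (self.symbol_bits + self.side_bits) / self.modeled_bases

    def depth_histogram(self, depths: Sequence[int]) -> dict[int, int]:
        hist = {int(d): 0 for d in depths}
        for blk in self.blocks:
            hist[int(depths[blk.chosen])] += 1
        return hist


@dataclass
class RunResult:
    """Aggregate of one or more per-record competition runs."""

    config: CompetitionConfig
    records: list[RecordResult] = field(default_factory=list)

    @property
    def symbol_bits(self) -> float:
        return sum(r.symbol_bits for r in self.records)

    @property
    def side_bits(self) -> float:
        return sum(r.side_bits for r in self.records)

    @property
    def modeled_bases(self) -> int:
        return sum(r.modeled_bases for r in self.records)

    @property
    def bpb(self) -> float:
        if self.modeled_bases == 0:
            return 0.0
        return (self.symbol_bits + self.side_bits) / self.modeled_bases

    def depth_histogram(self) -> dict[int, int]:
        hist = {int(d): 0 for d in self.config.depths}
        for rec in self.records:
            for d, c in rec.depth_histogram(self.config.depths).items():
                hist[d] += c
        return hist

    def summary(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "records": [
                {
                    "id": r.record_id,
                    "modeled_bases": r.modeled_bases,
                    "symbol_bits": r.symbol_bits,
                    "side_bits": r.side_bits,
                    "bpb": r.bpb,
                }
                for r in self.records
            ],
            "totals": {
                "modeled_bases": self.modeled_bases,
                "symbol_bits": self.symbol_bits,
                "side_bits": self.side_bits,
                "bpb": self.bpb,
            },
            "depth_histogram": self.depth_histogram(),
        }


def _kernel_args(cfg: CompetitionConfig, depths: Sequence[int], alphas) -> dict:
    ks = np.asarray(depths, dtype=np.int64)
    a_num = np.array([a.numerator for a in alphas], dtype=np.int64)
    a_den = np.array([a.denominator for a in alphas], dtype=np.int64)
    backend, dense, hmaps, hrows, hlens = _kernels.make_bank(ks, cfg.hash_min_order)
    m = len(ks)
    side_states = m ** cfg.side_order if cfg.side_order > 0 else 1
    side_counts = np.zeros((side_states, m), dtype=np.int64)
    return {
        "ks": ks,
        "a_num": a_num,
        "a_den": a_den,
        "backend": backend,
        "dense": dense,
        "hmaps": hmaps,
        "hrows": hrows,
        "hlens": hlens,
        "side_counts": side_counts,
    }


class _Engine:
    """Reusable kernel state, so counts can optionally persist across records."""

    def __init__(self, cfg: CompetitionConfig):
        self.cfg = cfg
        self.depths = cfg.depths
        self.alphas = [cfg.alpha_for(d) for d in cfg.depths]
        self.reset()

    def reset(self) -> None:
        self.bank = _kernel_args(self.cfg, self.depths, self.alphas)
        self.side_ctx = 0

    def run_record(self, seq: FilteredSequence) -> RecordResult:
        cfg = self.cfg
        b = self.bank
        codes = np.ascontiguousarray(seq.codes, dtype=np.int8)
        profile, chosen, model_costs, model_totals, side_bits, side_ctx = (
            _kernels.run_engine(
                codes,
                b["ks"],
                b["a_num"],
                b["a_den"],
                b["backend"],
                b["dense"],
                b["hmaps"],
                b["hrows"],
                b["hlens"],
                cfg.use_ir,
                cfg.block_size,
                np.int64(cfg.side_alpha.numerator),
                np.int64(cfg.side_alpha.denominator),
                b["side_counts"],
                np.int64(self.side_ctx),
            )
        )
        self.side_ctx = int(side_ctx)
        blocks = [
            BlockRecord(
                block_index=i,
                model_costs=model_costs[i],
                chosen=int(chosen[i]),
                symbol_bits=float(model_costs[i, chosen[i]]),
            )
            for i in range(len(chosen))
        ]
        depth_arr = np.asarray(self.depths, dtype=np.int64)
        per_base_depth = (
            depth_arr[chosen][np.arange(len(codes)) // cfg.block_size]
            if len(codes)
            else np.zeros(0, dtype=np.int64)
        )
        return RecordResult(
            record_id=seq.record_id,
            blocks=blocks,
            profile=InformationProfile(
                positions=seq.positions.copy(),
                bits=profile,
                chosen_depth=per_base_depth,
            ),
            symbol_bits=float(profile.sum()),
            side_bits=float(side_bits),
            modeled_bases=len(codes),
        )


def run_multi(seq: FilteredSequence, cfg: Optional[CompetitionConfig] = None) -> RunResult:
    """Competing-models pass over a single record."""
    cfg = cfg or CompetitionConfig()
    engine = _Engine(cfg)
    return RunResult(config=cfg, records=[engine.run_record(seq)])


def run_records(
    seqs: Sequence[FilteredSequence], cfg: Optional[CompetitionConfig] = None
) -> RunResult:
    """Competing-models pass over several records (e.g. chromosomes).

    Models restart at each record boundary unless ``cfg.reset_per_record``
    is False, in which case counts and the side context carry over.
    """
    cfg = cfg or CompetitionConfig()
    engine = _Engine(cfg)
    result = RunResult(config=cfg)
    for seq in seqs:
        if cfg.reset_per_record and result.records:
            engine.reset()
        result.records.append(engine.run_record(seq))
    return result


def run_single(
    seq: FilteredSequence,
    depth: int,
    alpha: AlphaLike = 1,
    use_ir: bool = True,
    hash_min_order: int = 11,
) -> RunResult:
    """One model over the whole record: no blocks, no side channel.

    The reported bpb is the plain average of the per-symbol code lengths.
    """
    cfg = CompetitionConfig(
        depths=(int(depth),),
        block_size=max(len(seq), 1),
        alpha_low=as_alpha(alpha),
        alpha_high=as_alpha(alpha),
        alpha_threshold=int(depth) + 1,
        side_order=0,
        use_ir=use_ir,
        hash_min_order=hash_min_order,
    )
    result = run_multi(seq, cfg)
    # a single-model run carries no side information at all
    for rec in result.records:
        rec.side_bits = 0.0
    return result


def best_single(
    seq: FilteredSequence, cfg: Optional[CompetitionConfig] = None
) -> tuple[int, RunResult]:
    """Best fixed-order model for one record (ties to the lowest depth).

    Each depth runs with its pseudocount from the config policy; the
    winner is the depth with minimum bpb.
    """
    cfg = cfg or CompetitionConfig()
    best_depth, best_result = None, None
    for d in cfg.depths:
        res = run_single(
            seq,
            d,
            alpha=cfg.alpha_for(d),
            use_ir=cfg.use_ir,
            hash_min_order=cfg.hash_min_order,
        )
        if best_result is None or res.bpb < best_result.bpb:
            best_depth, best_result = d, res
    return best_depth, best_result


def side_channel_bits(choices: Sequence[int], cfg: Optional[CompetitionConfig] = None) -> float:
    """Code length of a depth-choice sequence under the adaptive side model.

    Order-``side_order`` finite-context model over the index alphabet
    {0..len(depths)-1}, pseudocount ``side_alpha``, context warmed up at
    index 0.  This is the plain-Python mirror of what the scan kernel
    accumulates; the two are tested for exact agreement.
    """
    cfg = cfg or CompetitionConfig()
    m = len(cfg.depths)
    choices = np.asarray(choices, dtype=np.int64)
    if choices.size and (choices.min() < 0 or choices.max() >= m):
        raise ValueError("choice index out of range for the configured depth set")
    n_states = m ** cfg.side_order if cfg.side_order > 0 else 1
    counts = np.zeros((n_states, m), dtype=np.int64)
    a_num = cfg.side_alpha.numerator
    a_den = cfg.side_alpha.denominator
    ctx = 0
    bits = 0.0
    for c in choices:
        row = counts[ctx]
        p = (a_den * row[c] + a_num) / (a_den * int(row.sum()) + m * a_num)
        bits += -math.log2(p)
        counts[ctx, c] += 1
        ctx = (ctx * m + int(c)) % n_states
    return bits


def single_model_scan(
    seq: FilteredSequence, cfg: Optional[CompetitionConfig] = None
) -> dict[int, float]:
    """bpb of every configured depth run singly (the fixed-order table)."""
    cfg = cfg or CompetitionConfig()
    return {
        d: run_single(
            seq, d, alpha=cfg.alpha_for(d), use_ir=cfg.use_ir,
            hash_min_order=cfg.hash_min_order,
        ).bpb
        for d in cfg.depths
    }
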