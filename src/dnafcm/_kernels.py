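"""Numba kernels for the multi-model scan and the range coder.

All kernels share the same model machinery so that the ideal-bits scan,
the encoder and the decoder see bit-identical count tables:

* per-model context register ``ctx`` (2 bits/symbol, newest in low bits)
  initialized to all-A at the start of every record;
* an inverted-repeat register ``irr`` holding the reverse complement of
  the current context, updated incrementally: shifting symbol ``s`` into
  ``ctx`` maps ``irr -> (comp(s) << 2(k-1)) | (irr >> 2)``, which is
  exactly the IR counterpart context of ``(ctx, s)``, while ``irr & 3``
  is the IR counterpart symbol;
* count storage that is either a dense ``(4**k, 4)`` array or an open
  hash (packed context -> row index into a growable array), selected per
  model; both produce identical arithmetic.

Probabilities are the rational (b*n + a) / (b*N + 4a) with the
pseudocount alpha = a/b; the float used for ideal bits and the integer
frequencies used by the coder are derived from the same counts.

The range coder is a classic byte-wise 32-bit coder with carry handling
(LZMA style).  Frequencies are deterministically down-scaled to keep
totals below 2**16, on both sides identically.
"""

from __future__ import annotations

import numpy as np
from numba import njit, types
from numba.typed import Dict, List

DENSE = 0
HASH = 1

_TOP = np.uint64(1) << np.uint64(32)
_BOT = np.uint64(1) << np.uint64(24)
_FREQ_LIMIT = 1 << 16


def make_bank(ks, hash_min_order):
    """Allocate count storage for a set of model orders.

    Returns (backend, dense, hmaps, hrows, hlens); dense models get their
    full table, hash models a seed row store that the kernels grow.
    """
    backend = np.empty(len(ks), dtype=np.int64)
    dense = List()
    hmaps = List()
    hrows = List()
    hlens = np.zeros(len(ks), dtype=np.int64)
    for i, k in enumerate(ks):
        if k < hash_min_order:
            backend[i] = DENSE
            dense.append(np.zeros((4**int(k), 4), dtype=np.int64))
            hrows.append(np.zeros((1, 4), dtype=np.int64))
        else:
            backend[i] = HASH
            dense.append(np.zeros((1, 4), dtype=np.int64))
            hrows.append(np.zeros((1 << 12, 4), dtype=np.int64))
        hmaps.append(Dict.empty(types.int64, types.int64))
    return backend, dense, hmaps, hrows, hlens


@njit(cache=True)
def _row_for_update(backend_m, dense_m, hmap_m, hrows, hlens, m, ctx):
    """Row index for (model m, context ctx), creating a hash row if needed.

    Returns -1 for dense models (caller indexes the dense table directly).
    May grow ``hrows[m]`` in place via list setitem.
    """
    if backend_m == DENSE:
        return np.int64(-1)
    if ctx in hmap_m:
        return hmap_m[ctx]
    idx = hlens[m]
    rows = hrows[m]
    if idx >= rows.shape[0]:
        grown = np.zeros((rows.shape[0] * 2, 4), dtype=np.int64)
        grown[:idx] = rows
        hrows[m] = grown
    hmap_m[ctx] = idx
    hlens[m] = idx + 1
    return idx


@njit(cache=True, inline="always")
def _counts_of(backend_m, dense_m, hmap_m, hrows_m, ctx):
    """Four counters of a context without creating storage (n0,n1,n2,n3)."""
    if backend_m == DENSE:
        return dense_m[ctx, 0], dense_m[ctx, 1], dense_m[ctx, 2], dense_m[ctx, 3]
    if ctx in hmap_m:
        i = hmap_m[ctx]
        return hrows_m[i, 0], hrows_m[i, 1], hrows_m[i, 2], hrows_m[i, 3]
    return np.int64(0), np.int64(0), np.int64(0), np.int64(0)


@njit(cache=True)
def _update_models(
    s, M, ks, backend, dense, hmaps, hrows, hlens, ctx, irr, masks, use_ir
):
    """Direct (+ optional IR) count updates and context shifts, all models."""
    for m in range(M):
        c = ctx[m]
        ridx = _row_for_update(backend[m], dense[m], hmaps[m], hrows, hlens, m, c)
        if ridx < 0:
            dense[m][c, s] += 1
        else:
            hrows[m][ridx, s] += 1
        if use_ir:
            irc = ((3 - s) << (2 * (ks[m] - 1))) | (irr[m] >> 2)
            irs = irr[m] & 3
            ridx = _row_for_update(
                backend[m], dense[m], hmaps[m], hrows, hlens, m, irc
            )
            if ridx < 0:
                dense[m][irc, irs] += 1
            else:
                hrows[m][ridx, irs] += 1
            irr[m] = irc
        ctx[m] = ((c << 2) | s) & masks[m]


@njit(cache=True)
def run_engine(
    codes,
    ks,
    a_num,
    a_den,
    backend,
    dense,
    hmaps,
    hrows,
    hlens,
    use_ir,
    block_size,
    side_a_num,
    side_a_den,
    side_counts,
    side_ctx0,
):
    """Single left-to-right competing-models pass (ideal code lengths).

    Every model estimates then updates at every symbol; the per-block
    winner is the model with the smallest accumulated block cost (ties
    to the lowest index).  Returns per-base profile bits of the winning
    models, per-block choices and costs, per-model totals, side-channel
    bits, and the final side context (for cross-record continuation).
    """
    n = codes.shape[0]
    M = ks.shape[0]
    nblocks = (n + block_size - 1) // block_size
    S = side_counts.shape[0]

    ctx = np.zeros(M, dtype=np.int64)
    irr = np.empty(M, dtype=np.int64)
    masks = np.empty(M, dtype=np.int64)
    for m in range(M):
        masks[m] = (np.int64(1) << (2 * ks[m])) - 1
        irr[m] = masks[m]  # reverse complement of all-A warm-up

    profile = np.empty(n, dtype=np.float64)
    chosen = np.zeros(nblocks, dtype=np.int64)
    model_costs = np.zeros((nblocks, M), dtype=np.float64)
    model_totals = np.zeros(M, dtype=np.float64)
    block_cost = np.zeros(M, dtype=np.float64)
    bits_buf = np.empty((M, block_size), dtype=np.float64)

    side_bits = 0.0
    side_ctx = side_ctx0
    bi = 0
    b = 0
    for i in range(n):
        s = np.int64(codes[i])
        for m in range(M):
            n0, n1, n2, n3 = _counts_of(backend[m], dense[m], hmaps[m], hrows[m], ctx[m])
            if s == 0:
                ns = n0
            elif s == 1:
                ns = n1
            elif s == 2:
                ns = n2
            else:
                ns = n3
            ntot = n0 + n1 + n2 + n3
            p = (a_den[m] * ns + a_num[m]) / (a_den[m] * ntot + 4 * a_num[m])
            bits = -np.log2(p)
            block_cost[m] += bits
            bits_buf[m, bi] = bits
            model_totals[m] += bits
        _update_models(
            s, M, ks, backend, dense, hmaps, hrows, hlens, ctx, irr, masks, use_ir
        )
        bi += 1
        if bi == block_size or i == n - 1:
            best = 0
            for m in range(1, M):
                if block_cost[m] < block_cost[best]:
                    best = m
            chosen[b] = best
            start = i + 1 - bi
            for j in range(bi):
                profile[start + j] = bits_buf[best, j]
            for m in range(M):
                model_costs[b, m] = block_cost[m]
                block_cost[m] = 0.0
            nside = np.int64(0)
            for m in range(M):
                nside += side_counts[side_ctx, m]
            ps = (side_a_den * side_counts[side_ctx, best] + side_a_num) / (
                side_a_den * nside + M * side_a_num
            )
            side_bits += -np.log2(ps)
            side_counts[side_ctx, best] += 1
            side_ctx = (side_ctx * M + best) % S
            bi = 0
            b += 1
    return profile, chosen, model_costs, model_totals, side_bits, side_ctx


# ---------------------------------------------------------------------------
# range coder primitives
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _scale4(f0, f1, f2, f3):
    """Deterministically scale four frequencies so the total is < 2**16."""
    tot = f0 + f1 + f2 + f3
    while tot >= _FREQ_LIMIT:
        f0 = max(f0 >> 1, np.int64(1))
        f1 = max(f1 >> 1, np.int64(1))
        f2 = max(f2 >> 1, np.int64(1))
        f3 = max(f3 >> 1, np.int64(1))
        tot = f0 + f1 + f2 + f3
    return f0, f1, f2, f3, tot


@njit(cache=True)
def _symbol_freqs(backend_m, dense_m, hmap_m, hrows_m, ctx, a_num_m, a_den_m):
    n0, n1, n2, n3 = _counts_of(backend_m, dense_m, hmap_m, hrows_m, ctx)
    return _scale4(
        a_den_m * n0 + a_num_m,
        a_den_m * n1 + a_num_m,
        a_den_m * n2 + a_num_m,
        a_den_m * n3 + a_num_m,
    )


@njit(cache=True)
def _side_freqs(side_counts, side_ctx, M, sa_num, sa_den, out):
    tot = np.int64(0)
    for m in range(M):
        out[m] = sa_den * side_counts[side_ctx, m] + sa_num
        tot += out[m]
    while tot >= _FREQ_LIMIT:
        tot = 0
        for m in range(M):
            out[m] = max(out[m] >> 1, np.int64(1))
            tot += out[m]
    return tot


@njit(cache=True)
def _enc_put(buf, pos, byte):
    if pos >= buf.shape[0]:
        grown = np.empty(buf.shape[0] * 2, dtype=np.uint8)
        grown[: buf.shape[0]] = buf
        buf = grown
    buf[pos] = byte
    return buf, pos + 1


@njit(cache=True)
def _enc_shift_low(low, cache, cache_size, buf, pos):
    if low < np.uint64(0xFF000000) or low >= _TOP:
        carry = low >> np.uint64(32)
        temp = cache
        while True:
            buf, pos = _enc_put(buf, pos, np.uint8((temp + carry) & np.uint64(0xFF)))
            temp = np.uint64(0xFF)
            cache_size -= 1
            if cache_size == 0:
                break
        cache = (low >> np.uint64(24)) & np.uint64(0xFF)
        cache_size = 0
    cache_size += 1
    low = (low << np.uint64(8)) & (_TOP - np.uint64(1))
    return low, cache, cache_size, buf, pos


@njit(cache=True)
def _enc_freq(low, rng, cache, cache_size, buf, pos, cum, freq, tot):
    r = rng // np.uint64(tot)
    low = low + r * np.uint64(cum)
    rng = r * np.uint64(freq)
    while rng < _BOT:
        rng = rng << np.uint64(8)
        low, cache, cache_size, buf, pos = _enc_shift_low(low, cache, cache_size, buf, pos)
    return low, rng, cache, cache_size, buf, pos


@njit(cache=True, inline="always")
def _dec_byte(payload, ptr):
    if ptr < payload.shape[0]:
        return np.uint64(payload[ptr]), ptr + 1
    return np.uint64(0), ptr + 1  # zero padding past the flushed tail


@njit(cache=True)
def _dec_freq_value(code, rng, tot):
    r = rng // np.uint64(tot)
    v = code // r
    if v >= np.uint64(tot):
        v = np.uint64(tot - 1)
    return v


@njit(cache=True)
def _dec_update(code, rng, payload, ptr, cum, freq, tot):
    r = rng // np.uint64(tot)
    code = code - r * np.uint64(cum)
    rng = r * np.uint64(freq)
    while rng < _BOT:
        nb, ptr = _dec_byte(payload, ptr)
        code = (code << np.uint64(8)) | nb
        rng = rng << np.uint64(8)
    return code, rng, ptr


# ---------------------------------------------------------------------------
# payload encode / decode
# ---------------------------------------------------------------------------


@njit(cache=True)
def _digest_mix(digest, ctx, s):
    return (digest * np.uint64(1000003)) ^ (np.uint64(ctx) * np.uint64(4) + np.uint64(s))


@njit(cache=True)
def _state_digest(M, ctx, irr, hlens, side_ctx, backend, dense, hmaps, hrows, digest):
    """Digest of the adaptive state: registers, row allocation, and the
    count row under each model's current context."""
    for m in range(M):
        digest = _digest_mix(digest, ctx[m], 0)
        digest = _digest_mix(digest, irr[m], 1)
        digest = _digest_mix(digest, hlens[m], 2)
        n0, n1, n2, n3 = _counts_of(backend[m], dense[m], hmaps[m], hrows[m], ctx[m])
        digest = _digest_mix(digest, n0 * 4 + n1, 0)
        digest = _digest_mix(digest, n2 * 4 + n3, 1)
    return _digest_mix(digest, side_ctx, 3)


@njit(cache=True)
def encode_payload(
    codes,
    chosen,
    ks,
    a_num,
    a_den,
    backend,
    dense,
    hmaps,
    hrows,
    hlens,
    use_ir,
    block_size,
    side_a_num,
    side_a_den,
    side_counts,
    side_ctx0,
):
    """Range-encode one record given the per-block winning model indices.

    Per block: the winner's index is coded with the adaptive side model,
    then the block symbols with the winner's count-derived frequencies.
    Model updates mirror :func:`run_engine` exactly.  Returns the payload
    bytes, the final side context, and per-block model-state digests.
    """
    n = codes.shape[0]
    M = ks.shape[0]
    nblocks = (n + block_size - 1) // block_size
    S = side_counts.shape[0]

    ctx = np.zeros(M, dtype=np.int64)
    irr = np.empty(M, dtype=np.int64)
    masks = np.empty(M, dtype=np.int64)
    for m in range(M):
        masks[m] = (np.int64(1) << (2 * ks[m])) - 1
        irr[m] = masks[m]

    buf = np.empty(1 << 12, dtype=np.uint8)
    pos = 0
    low = np.uint64(0)
    rng = _TOP - np.uint64(1)
    cache = np.uint64(0)
    cache_size = np.int64(1)

    sfreq = np.empty(M, dtype=np.int64)
    digests = np.empty(nblocks, dtype=np.uint64)
    side_ctx = side_ctx0

    i = 0
    for b in range(nblocks):
        best = chosen[b]
        # side channel first
        stot = _side_freqs(side_counts, side_ctx, M, side_a_num, side_a_den, sfreq)
        cum = np.int64(0)
        for m in range(best):
            cum += sfreq[m]
        low, rng, cache, cache_size, buf, pos = _enc_freq(
            low, rng, cache, cache_size, buf, pos, cum, sfreq[best], stot
        )
        side_counts[side_ctx, best] += 1
        side_ctx = (side_ctx * M + best) % S

        blen = min(block_size, n - i)
        for _ in range(blen):
            s = np.int64(codes[i])
            f0, f1, f2, f3, tot = _symbol_freqs(
                backend[best],
                dense[best],
                hmaps[best],
                hrows[best],
                ctx[best],
                a_num[best],
                a_den[best],
            )
            if s == 0:
                cum, freq = np.int64(0), f0
            elif s == 1:
                cum, freq = f0, f1
            elif s == 2:
                cum, freq = f0 + f1, f2
            else:
                cum, freq = f0 + f1 + f2, f3
            low, rng, cache, cache_size, buf, pos = _enc_freq(
                low, rng, cache, cache_size, buf, pos, cum, freq, tot
            )
            _update_models(
                s, M, ks, backend, dense, hmaps, hrows, hlens, ctx, irr, masks, use_ir
            )
            i += 1
        digests[b] = _state_digest(
            M, ctx, irr, hlens, side_ctx, backend, dense, hmaps, hrows, np.uint64(b + 1)
        )

    if nblocks > 0:
        for _ in range(5):
            low, cache, cache_size, buf, pos = _enc_shift_low(
                low, cache, cache_size, buf, pos
            )
    return buf[:pos].copy(), side_ctx, digests


@njit(cache=True)
def decode_payload(
    payload,
    n,
    ks,
    a_num,
    a_den,
    backend,
    dense,
    hmaps,
    hrows,
    hlens,
    use_ir,
    block_size,
    side_a_num,
    side_a_den,
    side_counts,
    side_ctx0,
):
    """Inverse of :func:`encode_payload`; returns (codes, side_ctx, digests)."""
    M = ks.shape[0]
    nblocks = (n + block_size - 1) // block_size
    S = side_counts.shape[0]

    ctx = np.zeros(M, dtype=np.int64)
    irr = np.empty(M, dtype=np.int64)
    masks = np.empty(M, dtype=np.int64)
    for m in range(M):
        masks[m] = (np.int64(1) << (2 * ks[m])) - 1
        irr[m] = masks[m]

    codes = np.empty(n, dtype=np.int8)
    sfreq = np.empty(M, dtype=np.int64)
    digests = np.empty(nblocks, dtype=np.uint64)

    rng = _TOP - np.uint64(1)
    code = np.uint64(0)
    ptr = 0
    if nblocks > 0:
        _, ptr = _dec_byte(payload, ptr)  # encoder's initial zero cache byte
        for _ in range(4):
            nb, ptr = _dec_byte(payload, ptr)
            code = (code << np.uint64(8)) | nb

    side_ctx = side_ctx0
    i = 0
    for b in range(nblocks):
        stot = _side_freqs(side_counts, side_ctx, M, side_a_num, side_a_den, sfreq)
        v = _dec_freq_value(code, rng, stot)
        best = 0
        cum = np.int64(0)
        for m in range(M):
            if np.uint64(cum + sfreq[m]) > v:
                best = m
                break
            cum += sfreq[m]
        code, rng, ptr = _dec_update(code, rng, payload, ptr, cum, sfreq[best], stot)
        side_counts[side_ctx, best] += 1
        side_ctx = (side_ctx * M + best) % S

        blen = min(block_size, n - i)
        for _ in range(blen):
            f0, f1, f2, f3, tot = _symbol_freqs(
                backend[best],
                dense[best],
                hmaps[best],
                hrows[best],
                ctx[best],
                a_num[best],
                a_den[best],
            )
            v = _dec_freq_value(code, rng, tot)
            if v < np.uint64(f0):
                s, cum, freq = np.int64(0), np.int64(0), f0
            elif v < np.uint64(f0 + f1):
                s, cum, freq = np.int64(1), f0, f1
            elif v < np.uint64(f0 + f1 + f2):
                s, cum, freq = np.int64(2), f0 + f1, f2
            else:
                s, cum, freq = np.int64(3), f0 + f1 + f2, f3
            code, rng, ptr = _dec_update(code, rng, payload, ptr, cum, freq, tot)
            codes[i] = np.int8(s)
            _update_models(
                s, M, ks, backend, dense, hmaps, hrows, hlens, ctx, irr, masks, use_ir
            )
            i += 1
        digests[b] = _state_digest(
            M, ctx, irr, hlens, side_ctx, backend, dense, hmaps, hrows, np.uint64(b + 1)
        )
    return codes, side_ctx, digests
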