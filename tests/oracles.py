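"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (exhaustive enumeration, per-position
regex probing) and shares no code with the implementation paths it checks.
"""

from __future__ import annotations

import itertools
import math
import re

import numpy as np

from protevo.profilehmm import ProfileModel, encode

LN2 = math.log(2.0)


# ---------------------------------------------------------------------------
# Profile-HMM path enumeration

def _core_paths(p: ProfileModel, sub: np.ndarray):
    """Yield log-odds of every core path consuming exactly ``sub``.

    A core path starts with an entry into some match state and ends with an
    exit from a match state; entry and exit each contribute log2(1/M)
    (added by the caller for local mode).
    """
    M = p.M
    em = p._em_lo
    t = p._ln_t
    n = len(sub)

    def walk(kind: str, j: int, consumed: int, score: float):
        # completion: exit only from a match state with everything consumed
        if kind == "M" and consumed == n:
            yield score
        if kind == "M":
            if j < M - 1:
                if consumed < n:
                    yield from walk("M", j + 1,
                                    consumed + 1,
                                    score + t["t_mm"][j] + em[j + 1, sub[consumed]])
                    yield from walk("I", j, consumed + 1,
                                    score + t["t_mi"][j])
                yield from walk("D", j + 1, consumed,
                                score + t["t_md"][j])
        elif kind == "I":
            if consumed < n:
                yield from walk("I", j, consumed + 1, score + t["t_ii"][j])
                yield from walk("M", j + 1, consumed + 1,
                                score + t["t_im"][j] + em[j + 1, sub[consumed]])
            else:
                return
        else:  # D
            if j < M - 1:
                if consumed < n:
                    yield from walk("M", j + 1, consumed + 1,
                                    score + t["t_dm"][j] + em[j + 1, sub[consumed]])
                yield from walk("D", j + 1, consumed, score + t["t_dd"][j])

    if n == 0:
        return
    for j0 in range(M):
        yield from walk("M", j0, 1, em[j0, sub[0]])


def _glocal_paths(p: ProfileModel, codes: np.ndarray):
    M = p.M
    em = p._em_lo
    t = p._ln_t
    n = len(codes)
    ln_bm = math.log(max(p.t_bm, 1e-300))
    ln_bd = math.log(max(p.t_bd, 1e-300))

    def walk(kind: str, j: int, consumed: int, score: float):
        if j == M - 1 and consumed == n and kind in ("M", "D"):
            yield score
        if kind in ("M", "D"):
            if j < M - 1:
                key_m = "t_mm" if kind == "M" else "t_dm"
                key_d = "t_md" if kind == "M" else "t_dd"
                if consumed < n:
                    yield from walk("M", j + 1, consumed + 1,
                                    score + t[key_m][j] + em[j + 1, codes[consumed]])
                yield from walk("D", j + 1, consumed, score + t[key_d][j])
                if kind == "M" and consumed < n:
                    yield from walk("I", j, consumed + 1, score + t["t_mi"][j])
        else:  # I
            if consumed < n:
                yield from walk("I", j, consumed + 1, score + t["t_ii"][j])
                yield from walk("M", j + 1, consumed + 1,
                                score + t["t_im"][j] + em[j + 1, codes[consumed]])

    if n >= 1:
        yield from walk("M", 0, 1, ln_bm + em[0, codes[0]])
    yield from walk("D", 0, 0, ln_bd)


def enum_path_scores(p: ProfileModel, s: str, mode: str = "local") -> list[float]:
    """Log-odds (natural log) of every admissible state path."""
    codes = encode(s)
    if mode == "glocal":
        return list(_glocal_paths(p, codes))
    entry_exit = -2.0 * math.log(p.M)
    out = []
    L = len(codes)
    for i0 in range(L):
        for i1 in range(i0, L):
            for sc in _core_paths(p, codes[i0:i1 + 1]):
                out.append(sc + entry_exit)
    return out


def enum_forward_bits(p: ProfileModel, s: str, mode: str = "local") -> float:
    scores = enum_path_scores(p, s, mode)
    if not scores:
        return -math.inf
    m = max(scores)
    return (m + math.log(sum(math.exp(x - m) for x in scores))) / LN2


def enum_viterbi_bits(p: ProfileModel, s: str, mode: str = "local") -> float:
    scores = enum_path_scores(p, s, mode)
    return max(scores) / LN2 if scores else -math.inf


def random_profile(rng: np.random.Generator, M: int,
                   profile_id: str = "rand") -> ProfileModel:
    """A random valid profile (Dirichlet emissions/transitions)."""
    from protevo.profilehmm import blosum62_background

    emit = rng.dirichlet(np.full(20, 0.5), size=M)
    if M > 1:
        t_m = rng.dirichlet([4.0, 1.0, 1.0], size=M - 1)
        t_i = rng.dirichlet([2.0, 1.0], size=M - 1)
        t_d = rng.dirichlet([2.0, 1.0], size=M - 1)
    else:
        t_m = np.zeros((0, 3)); t_i = np.zeros((0, 2)); t_d = np.zeros((0, 2))
    b = rng.dirichlet([4.0, 1.0])
    return ProfileModel(
        id=profile_id, match_emit=emit,
        t_mm=t_m[:, 0], t_mi=t_m[:, 1], t_md=t_m[:, 2],
        t_im=t_i[:, 0], t_ii=t_i[:, 1],
        t_dm=t_d[:, 0], t_dd=t_d[:, 1],
        t_bm=float(b[0]), t_bd=float(b[1]),
        background=blosum62_background(),
    )


# ---------------------------------------------------------------------------
# Pairwise alignment enumeration

def enum_global_score(a: str, b: str, score_fn, gap_open: int,
                      gap_extend: int) -> float:
    """Best global alignment score by exhaustive enumeration of alignments.

    An alignment is a sequence of column operations (match, gap-in-a,
    gap-in-b); runs of gaps cost ``gap_open + k * gap_extend``.
    """
    best = [-math.inf]

    def walk(i: int, j: int, score: float, gap_state: str):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            walk(i + 1, j + 1, score + score_fn(a[i], b[j]), "")
        if i < len(a):  # a[i] against a gap
            cost = gap_extend if gap_state == "a" else gap_open + gap_extend
            walk(i + 1, j, score - cost, "a")
        if j < len(b):
            cost = gap_extend if gap_state == "b" else gap_open + gap_extend
            walk(i, j + 1, score - cost, "b")

    walk(0, 0, 0.0, "")
    return best[0]


def enum_local_score(a: str, b: str, score_fn, gap_open: int,
                     gap_extend: int) -> float:
    """Best local alignment score: best global score over all substring
    pairs, floored at 0 (empty alignment)."""
    best = 0.0
    for i0 in range(len(a)):
        for i1 in range(i0, len(a)):
            for j0 in range(len(b)):
                for j1 in range(j0, len(b)):
                    s = enum_global_score(a[i0:i1 + 1], b[j0:j1 + 1],
                                          score_fn, gap_open, gap_extend)
                    best = max(best, s)
    return best


# ---------------------------------------------------------------------------
# Motif scanning

def enum_motif_positions(region: str, pattern: str) -> list[int]:
    """1-based start positions: probe every position against each
    alternative of the pattern independently."""
    alternatives = pattern.split("|")
    hits = []
    for i in range(len(region)):
        for alt in alternatives:
            if re.match(alt, region[i:]):
                hits.append(i + 1)
                break
    return hits
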