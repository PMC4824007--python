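"""Position-specific profile models: building, scoring, e-value calibration,
proteome scanning and domain-architecture annotation.

Model architecture
------------------
A simplified single-hit Plan7 profile: M match states with position-specific
emissions, insert states I_1..I_{M-1} emitting the background distribution,
delete states D_1..D_M, and begin/end wrapping. Two scoring modes:

``local`` (default, the search mode)
    The aligned core may start at any match state and end at any match
    state; entry and exit each carry a uniform probability 1/M. Sequence
    residues outside the core are emitted by the background and contribute
    zero log-odds, as do insert emissions. The reported bit score is
    ``log2`` of the summed (forward) or maximal (Viterbi) path odds.

``glocal`` (test/verification mode)
    The path enters through begin (B->M1 or B->D1) at the first residue and
    must consume the whole sequence, ending at M_M or D_M. In this mode the
    model is a proper HMM: summing ``P(seq) = 2**bits * prod(q[residue])``
    over all sequences yields exactly 1, which the test suite exploits.

``X`` residues emit the background at every state (log-odds contribution 0).

E-values
--------
The null score distribution of i.i.d. background sequences is fitted with a
Gumbel (extreme-value) law; ``E = db_size * (1 - CDF(score))`` with
``db_size`` the number of sequences in the scanned proteome.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import stats

from .seqio import AMINO_ACIDS, Alignment, GAP_CHARS, Proteome, ProteinRecord, ungap

LN2 = math.log(2.0)
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
_AA_INDEX["X"] = 20
NEG_INF = -np.inf

# BLOSUM62 marginal residue frequencies (Robinson-Robinson style background
# used by BLAST/HMMER), normalized at import.
_BG = {
    "A": 0.0742, "R": 0.0516, "N": 0.0446, "D": 0.0536, "C": 0.0246,
    "Q": 0.0342, "E": 0.0543, "G": 0.0741, "H": 0.0262, "I": 0.0679,
    "L": 0.0989, "K": 0.0582, "M": 0.0247, "F": 0.0474, "P": 0.0388,
    "S": 0.0572, "T": 0.0509, "W": 0.0131, "Y": 0.0321, "V": 0.0729,
}


def blosum62_background() -> np.ndarray:
    q = np.array([_BG[a] for a in AMINO_ACIDS], dtype=float)
    return q / q.sum()


def encode(seq: str) -> np.ndarray:
    """Map a protein sequence to integer codes 0..19 (X -> 20)."""
    try:
        return np.array([_AA_INDEX[c] for c in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"illegal residue {exc.args[0]!r}") from None


class ProfileError(ValueError):
    pass


@dataclass
class ProfileModel:
    """A profile built from a seed alignment.

    Transition arrays are indexed by 0-based source position ``j`` and
    describe the move to position ``j+1`` (length M-1); ``t_bm``/``t_bd``
    are the begin-state transitions. All stored distributions are
    normalized; the local-mode 1/M entry/exit factors are scoring-mode
    constants, not stored transitions.
    """

    id: str
    match_emit: np.ndarray          # (M, 20) probabilities
    t_mm: np.ndarray                # (M-1,)
    t_mi: np.ndarray
    t_md: np.ndarray
    t_im: np.ndarray
    t_ii: np.ndarray
    t_dm: np.ndarray
    t_dd: np.ndarray
    t_bm: float
    t_bd: float
    background: np.ndarray          # (20,)
    source_alignment: str = ""
    match_columns: list[int] = field(default_factory=list)  # 0-based seed cols

    def __post_init__(self) -> None:
        self.match_emit = np.asarray(self.match_emit, dtype=float)
        if self.match_emit.ndim != 2 or self.match_emit.shape[1] != 20:
            raise ProfileError("match emissions must be (M, 20)")
        if self.M < 1:
            raise ProfileError("profile needs at least one match state")
        self.validate()
        # cached log-odds emission table, X column = 0
        lo = np.zeros((self.M, 21))
        lo[:, :20] = np.log(self.match_emit) - np.log(self.background)[None, :]
        self._em_lo = lo
        self._ln_t = {
            name: np.log(np.maximum(getattr(self, name), 1e-300))
            for name in ("t_mm", "t_mi", "t_md", "t_im", "t_ii", "t_dm", "t_dd")
        }

    @property
    def M(self) -> int:
        return self.match_emit.shape[0]

    def validate(self, tol: float = 1e-9) -> None:
        if not np.allclose(self.match_emit.sum(axis=1), 1.0, atol=tol):
            raise ProfileError("match emissions do not sum to 1")
        if not math.isclose(self.t_bm + self.t_bd, 1.0, abs_tol=tol):
            raise ProfileError("begin transitions do not sum to 1")
        if self.M > 1:
            for trio, names in ((("t_mm", "t_mi", "t_md"), "M"),
                                (("t_im", "t_ii"), "I"),
                                (("t_dm", "t_dd"), "D")):
                s = sum(np.asarray(getattr(self, n), dtype=float) for n in trio)
                if not np.allclose(s, 1.0, atol=tol):
                    raise ProfileError(f"{names}-state transitions do not sum to 1")
        if not math.isclose(float(self.background.sum()), 1.0, abs_tol=1e-6):
            raise ProfileError("background does not sum to 1")

    @property
    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[k] for k in np.argmax(self.match_emit, axis=1))

    # -- serialization ----------------------------------------------------
    def to_text(self) -> str:
        buf = io.StringIO()
        buf.write(f"PROFILE\t{self.id}\t{self.M}\t{self.source_alignment}\n")
        buf.write("BG\t" + "\t".join(f"{v:.10g}" for v in self.background) + "\n")
        buf.write(f"BEGIN\t{self.t_bm:.10g}\t{self.t_bd:.10g}\n")
        for j in range(self.M):
            buf.write(f"EMIT\t{j + 1}\t"
                      + "\t".join(f"{v:.10g}" for v in self.match_emit[j]) + "\n")
        for j in range(self.M - 1):
            vals = [self.t_mm[j], self.t_mi[j], self.t_md[j],
                    self.t_im[j], self.t_ii[j], self.t_dm[j], self.t_dd[j]]
            buf.write(f"TRANS\t{j + 1}\t"
                      + "\t".join(f"{v:.10g}" for v in vals) + "\n")
        buf.write("END\n")
        return buf.getvalue()

    @classmethod
    def from_text(cls, text: str) -> "ProfileModel":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        header = lines[0].split("\t")
        if header[0] != "PROFILE":
            raise ProfileError("not a profile text block")
        pid, M = header[1], int(header[2])
        src = header[3] if len(header) > 3 else ""
        bg = t_b = None
        emit = np.zeros((M, 20))
        trans = np.zeros((max(M - 1, 0), 7))
        for ln in lines[1:]:
            parts = ln.split("\t")
            if parts[0] == "BG":
                bg = np.array([float(v) for v in parts[1:]])
            elif parts[0] == "BEGIN":
                t_b = (float(parts[1]), float(parts[2]))
            elif parts[0] == "EMIT":
                emit[int(parts[1]) - 1] = [float(v) for v in parts[2:]]
            elif parts[0] == "TRANS":
                trans[int(parts[1]) - 1] = [float(v) for v in parts[2:]]
        if bg is None or t_b is None:
            raise ProfileError("incomplete profile block")
        return cls(id=pid, match_emit=emit,
                   t_mm=trans[:, 0], t_mi=trans[:, 1], t_md=trans[:, 2],
                   t_im=trans[:, 3], t_ii=trans[:, 4],
                   t_dm=trans[:, 5], t_dd=trans[:, 6],
                   t_bm=t_b[0], t_bd=t_b[1], background=bg,
                   source_alignment=src)


def build_profile(aln: Alignment, pseudo_total: float = 1.0,
                  trans_pseudo: float = 0.1,
                  gap_threshold: float = 0.5,
                  profile_id: str | None = None) -> ProfileModel:
    """Estimate a profile from a seed alignment.

    Columns with a gap fraction strictly below ``gap_threshold`` become
    match states (exactly at the threshold -> insert). Match emissions use
    background-proportional pseudocounts of total mass ``pseudo_total``;
    transitions use Laplace ``trans_pseudo`` smoothing. ``X`` residues are
    uninformative and excluded from emission counts.
    """
    if aln.n_rows < 2:
        raise ProfileError("seed alignment needs at least 2 rows")
    q = blosum62_background()
    n_cols = aln.n_columns
    cols = [aln.column(i) for i in range(n_cols)]
    gap_frac = [sum(c in GAP_CHARS for c in col) / len(col) for col in cols]
    match_cols = [i for i in range(n_cols) if gap_frac[i] < gap_threshold]
    M = len(match_cols)
    if M == 0:
        raise ProfileError("alignment has zero match columns")

    emit = np.zeros((M, 20))
    for j, ci in enumerate(match_cols):
        counts = np.zeros(20)
        n_obs = 0.0
        for c in cols[ci]:
            if c in GAP_CHARS or c == "X":
                continue
            counts[_AA_INDEX[c]] += 1.0
            n_obs += 1.0
        emit[j] = (counts + q * pseudo_total) / (n_obs + pseudo_total)
        emit[j] /= emit[j].sum()

    # transition counting: walk each row through the column classification
    is_match = [False] * n_cols
    for ci in match_cols:
        is_match[ci] = True
    col_pos = {}  # column index -> 0-based match position
    for j, ci in enumerate(match_cols):
        col_pos[ci] = j

    # counts[j] = dict of transition label -> count for moves leaving slot j
    c_m = np.zeros((max(M - 1, 0), 3))   # MM, MI, MD
    c_i = np.zeros((max(M - 1, 0), 2))   # IM, II
    c_d = np.zeros((max(M - 1, 0), 2))   # DM, DD
    c_b = np.zeros(2)                    # BM, BD
    first_ci, last_ci = match_cols[0], match_cols[-1]
    for _, row in aln.rows:
        state = "B"
        pos = -1  # current match position of the state (I_j sits at j)
        for ci in range(first_ci, last_ci + 1):
            ch = row[ci]
            if is_match[ci]:
                j = col_pos[ci]
                nxt = "D" if ch in GAP_CHARS else "M"
                if state == "B":
                    c_b[0 if nxt == "M" else 1] += 1
                elif state == "M":
                    c_m[pos][0 if nxt == "M" else 2] += 1
                elif state == "I":
                    # I->D is not representable in Plan7; folded into I->M
                    c_i[pos][0] += 1
                elif state == "D":
                    c_d[pos][0 if nxt == "M" else 1] += 1
                state, pos = nxt, j
            else:
                if ch in GAP_CHARS:
                    continue
                # residue in an insert column between match positions
                if state == "M":
                    c_m[pos][1] += 1
                    state = "I"
                elif state == "I":
                    c_i[pos][1] += 1
                elif state in ("B", "D"):
                    # leading inserts / inserts after deletes are dropped
                    continue
    if M > 1:
        t_m = (c_m + trans_pseudo) / (c_m + trans_pseudo).sum(axis=1, keepdims=True)
        t_i = (c_i + trans_pseudo) / (c_i + trans_pseudo).sum(axis=1, keepdims=True)
        t_d = (c_d + trans_pseudo) / (c_d + trans_pseudo).sum(axis=1, keepdims=True)
    else:
        t_m = np.zeros((0, 3)); t_i = np.zeros((0, 2)); t_d = np.zeros((0, 2))
    b = (c_b + trans_pseudo) / (c_b + trans_pseudo).sum()

    return ProfileModel(
        id=profile_id or aln.id, match_emit=emit,
        t_mm=t_m[:, 0], t_mi=t_m[:, 1], t_md=t_m[:, 2],
        t_im=t_i[:, 0], t_ii=t_i[:, 1],
        t_dm=t_d[:, 0], t_dd=t_d[:, 1],
        t_bm=float(b[0]), t_bd=float(b[1]),
        background=q, source_alignment=aln.id, match_columns=match_cols,
    )


# ---------------------------------------------------------------------------
# Forward scoring (batched)

def _glocal_delete_init(p: ProfileModel) -> np.ndarray:
    """log-odds of B -> D_1 -> ... -> D_{j+1} chains (consumes nothing)."""
    vd = np.full(p.M, NEG_INF)
    vd[0] = math.log(max(p.t_bd, 1e-300))
    for j in range(1, p.M):
        vd[j] = vd[j - 1] + p._ln_t["t_dd"][j - 1]
    return vd


def forward_score_batch(p: ProfileModel, seqs: Sequence[str],
                        mode: str = "local") -> np.ndarray:
    """Forward bit scores for a batch of sequences.

    The DP runs in scaled linear (odds) space: state values are renormalized
    by their running maximum each step and the log of the scale accumulated
    per sequence, so only cheap multiply/adds appear in the inner loop.
    """
    if mode not in ("local", "glocal"):
        raise ValueError(f"unknown mode {mode!r}")
    B = len(seqs)
    if B == 0:
        return np.zeros(0)
    lengths = np.array([len(s) for s in seqs])
    if (lengths == 0).any():
        raise ValueError("empty sequence")
    Lmax = int(lengths.max())
    codes = np.full((B, Lmax), 20, dtype=np.int64)
    for b, s in enumerate(seqs):
        codes[b, :len(s)] = encode(s)

    M = p.M
    em_lin = np.exp(p._em_lo)          # (M, 21) odds ratios
    t_mm = np.exp(p._ln_t["t_mm"]); t_mi = np.exp(p._ln_t["t_mi"])
    t_md = np.exp(p._ln_t["t_md"]); t_im = np.exp(p._ln_t["t_im"])
    t_ii = np.exp(p._ln_t["t_ii"]); t_dm = np.exp(p._ln_t["t_dm"])
    t_dd = np.exp(p._ln_t["t_dd"])
    entry_lin = 1.0 / M
    exit_lin = 1.0 / M
    # cumulative delete-chain products, floored to avoid division blowup;
    # chains that improbable carry no usable probability mass anyway
    if M > 1:
        dd_cum = np.concatenate([[1.0], np.cumprod(np.maximum(t_dd, 0.0))])
        dd_cum = np.maximum(dd_cum, 1e-250)
    else:
        dd_cum = np.ones(1)

    vm = np.zeros((B, M))
    vi = np.zeros((B, max(M - 1, 1)))
    vd = np.zeros((B, M))
    if mode == "glocal":
        vd[:] = np.exp(np.clip(_glocal_delete_init(p), -690.0, 0.0))[None, :]
    log_scale = np.zeros(B)
    end_acc = np.full(B, NEG_INF)
    fin_log = np.full(B, NEG_INF)

    for i in range(Lmax):
        e_i = em_lin[:, codes[:, i]].T     # (B, M)
        prev = np.zeros((B, M))
        if M > 1:
            prev[:, 1:] = (vm[:, :-1] * t_mm + vi[:, :M - 1] * t_im
                           + vd[:, :-1] * t_dm)
        if mode == "local":
            prev += entry_lin * np.exp(-np.clip(log_scale, -690.0, 690.0))[:, None]
        elif i == 0:
            prev[:, 0] += p.t_bm
        vm_new = e_i * prev

        if M > 1:
            vi_new = vm[:, :-1] * t_mi + vi[:, :M - 1] * t_ii
        else:
            vi_new = vi
        vd_new = np.zeros((B, M))
        if M > 1:
            src = vm_new[:, :-1] * t_md / dd_cum[1:M]
            vd_new[:, 1:] = np.cumsum(src, axis=1) * dd_cum[1:M]

        if mode == "local":
            alive = i < lengths
            row_sum = vm_new.sum(axis=1) * exit_lin
            with np.errstate(divide="ignore"):
                row_log = np.log(row_sum) + log_scale
            end_acc = np.where(alive, np.logaddexp(end_acc, row_log), end_acc)
        else:
            at_last = i == lengths - 1
            if at_last.any():
                fin = vm_new[:, M - 1] + vd_new[:, M - 1]
                with np.errstate(divide="ignore"):
                    fin_log = np.where(at_last, np.log(fin) + log_scale,
                                       fin_log)
        # rescale
        m = vm_new.max(axis=1)
        if M > 1:
            m = np.maximum(m, vi_new.max(axis=1))
        m = np.maximum(np.maximum(m, vd_new.max(axis=1)), 1e-300)
        inv = 1.0 / m
        vm = vm_new * inv[:, None]
        vi = vi_new * inv[:, None] if M > 1 else vi_new
        vd = vd_new * inv[:, None]
        log_scale = log_scale + np.log(m)

    out = end_acc if mode == "local" else fin_log
    return out / LN2


def forward_score(p: ProfileModel, s: str, mode: str = "local") -> float:
    """Forward log-odds bit score of one sequence."""
    return float(forward_score_batch(p, [s], mode=mode)[0])


def sequence_probability(p: ProfileModel, s: str) -> float:
    """P(s | profile) in glocal mode (used for normalization checks)."""
    bits = forward_score(p, s, mode="glocal")
    q = p.background
    log_bg = float(np.sum(np.log(q[encode(s)])))
    return math.exp(bits * LN2 + log_bg)


# ---------------------------------------------------------------------------
# Viterbi

@dataclass
class ViterbiResult:
    bits: float
    path: list[tuple[str, int, int | None]]  # (state, model pos 1-based, seq pos 1-based)
    env_start: int   # 1-based first residue consumed by the core
    env_end: int


def viterbi(p: ProfileModel, s: str, mode: str = "local") -> ViterbiResult:
    """Best single state path and its log-odds bit score."""
    if not s:
        raise ValueError("empty sequence")
    codes = encode(s)
    L, M = len(s), p.M
    em = p._em_lo
    t = p._ln_t
    entry = -math.log(M)
    exit_lo = -math.log(M)
    ln_t_bm = math.log(max(p.t_bm, 1e-300))

    VM = np.full((L, M), NEG_INF)
    VI = np.full((L, max(M - 1, 1)), NEG_INF)
    VD = np.full((L, M), NEG_INF)
    vd_init = _glocal_delete_init(p) if mode == "glocal" else np.full(M, NEG_INF)

    for i in range(L):
        e_i = em[:, codes[i]]
        vm_prev = VM[i - 1] if i > 0 else np.full(M, NEG_INF)
        vi_prev = VI[i - 1] if i > 0 else np.full(max(M - 1, 1), NEG_INF)
        vd_prev = VD[i - 1] if i > 0 else vd_init
        prev = np.full(M, NEG_INF)
        if M > 1:
            prev[1:] = np.maximum.reduce([
                vm_prev[:-1] + t["t_mm"],
                vi_prev[:M - 1] + t["t_im"],
                vd_prev[:-1] + t["t_dm"],
            ])
        if mode == "local":
            prev = np.maximum(prev, entry)
        elif i == 0:
            prev[0] = max(prev[0], ln_t_bm)
        VM[i] = e_i + prev
        if M > 1:
            VI[i, :M - 1] = np.maximum(vm_prev[:-1] + t["t_mi"],
                                       vi_prev[:M - 1] + t["t_ii"])
            # delete chains M_k -> D_{k+1} -> ... -> D_j via a max-scan
            dd_cum = np.concatenate([[0.0], np.cumsum(t["t_dd"])])  # (M,)
            src = VM[i, :-1] + t["t_md"] - dd_cum[1:M]
            VD[i, 1:] = np.maximum.accumulate(src) + dd_cum[1:M]

    if mode == "local":
        flat = np.argmax(VM)
        best_i, best_j = divmod(int(flat), M)
        bits = (VM[best_i, best_j] + exit_lo) / LN2
        end_state = ("M", best_i, best_j)
    else:
        best_i = L - 1
        if VM[best_i, M - 1] >= VD[best_i, M - 1]:
            end_state = ("M", best_i, M - 1)
            bits = VM[best_i, M - 1] / LN2
        else:
            end_state = ("D", best_i, M - 1)
            bits = VD[best_i, M - 1] / LN2

    if not math.isfinite(bits):
        return ViterbiResult(bits=float(bits), path=[], env_start=0, env_end=0)
    path = _traceback(p, codes, VM, VI, VD, vd_init, end_state, mode,
                      entry, ln_t_bm)
    consumed = [sp for st, _, sp in path if st in ("M", "I") and sp is not None]
    if consumed:
        env_start, env_end = min(consumed), max(consumed)
    else:
        env_start = env_end = 0
    return ViterbiResult(bits=float(bits), path=path,
                         env_start=env_start, env_end=env_end)


def _close(a: float, b: float) -> bool:
    if a == b:
        return True
    return math.isclose(a, b, rel_tol=1e-9, abs_tol=1e-9)


def _traceback(p, codes, VM, VI, VD, vd_init, end_state, mode, entry, ln_t_bm):
    t = p._ln_t
    M = p.M
    em = p._em_lo
    path: list[tuple[str, int, int | None]] = []
    state, i, j = end_state
    while True:
        if state == "M":
            path.append(("M", j + 1, i + 1))
            target = VM[i, j] - em[j, codes[i]]
            vm_prev = VM[i - 1] if i > 0 else None
            vi_prev = VI[i - 1] if i > 0 else None
            vd_prev = VD[i - 1] if i > 0 else (vd_init if mode == "glocal" else None)
            if j > 0 and vm_prev is not None and _close(target, vm_prev[j - 1] + t["t_mm"][j - 1]):
                state, i, j = "M", i - 1, j - 1
            elif j > 0 and vi_prev is not None and _close(target, vi_prev[j - 1] + t["t_im"][j - 1]):
                state, i, j = "I", i - 1, j - 1
            elif j > 0 and vd_prev is not None and _close(target, vd_prev[j - 1] + t["t_dm"][j - 1]):
                if i == 0 and mode == "glocal":
                    # chain of begin-deletes
                    k = j - 1
                    while k >= 0:
                        path.append(("D", k + 1, None))
                        k -= 1
                    break
                state, i, j = "D", i - 1, j - 1
            elif mode == "local" and _close(target, entry):
                break
            elif mode == "glocal" and i == 0 and j == 0 and _close(target, ln_t_bm):
                break
            else:  # numerical fallback: prefer entry in local mode
                if mode == "local":
                    break
                raise RuntimeError("viterbi traceback failed at M state")
        elif state == "I":
            path.append(("I", j + 1, i + 1))
            target = VI[i, j]
            vm_prev = VM[i - 1] if i > 0 else None
            vi_prev = VI[i - 1] if i > 0 else None
            if vm_prev is not None and _close(target, vm_prev[j] + t["t_mi"][j]):
                state, i = "M", i - 1
            elif vi_prev is not None and _close(target, vi_prev[j] + t["t_ii"][j]):
                state, i = "I", i - 1
            else:
                raise RuntimeError("viterbi traceback failed at I state")
        else:  # D
            path.append(("D", j + 1, None))
            target = VD[i, j] if i >= 0 else vd_init[j]
            if j > 0 and _close(target, VM[i, j - 1] + t["t_md"][j - 1]):
                state, j = "M", j - 1
            elif j > 0 and _close(target, VD[i, j - 1] + t["t_dd"][j - 1]):
                state, j = "D", j - 1
            else:
                raise RuntimeError("viterbi traceback failed at D state")
    path.reverse()
    return path


def viterbi_score(p: ProfileModel, s: str, mode: str = "local") -> float:
    return viterbi(p, s, mode=mode).bits


# ---------------------------------------------------------------------------
# Calibration and e-values

@dataclass(frozen=True)
class EvalueCalibration:
    """Gumbel fit (location mu, scale beta > 0) to a null score sample."""

    mu: float
    beta: float
    n_null: int
    seed: int

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ProfileError("Gumbel scale must be positive")
        if self.n_null < 100:
            raise ProfileError("calibration needs at least 100 null samples")

    def pvalue(self, score_bits: float | np.ndarray) -> float | np.ndarray:
        return stats.gumbel_r.sf(score_bits, loc=self.mu, scale=self.beta)


def sample_null_sequences(rng: np.random.Generator, n: int,
                          len_dist, q: np.ndarray) -> list[str]:
    """Draw i.i.d. background sequences with lengths from ``len_dist``.

    ``len_dist`` may be an int (fixed length), a (lo, hi) tuple (uniform
    inclusive), a sequence of lengths to resample from, or a callable
    ``f(rng, n) -> array``.
    """
    if isinstance(len_dist, int):
        lengths = np.full(n, len_dist)
    elif isinstance(len_dist, tuple) and len(len_dist) == 2:
        lengths = rng.integers(len_dist[0], len_dist[1] + 1, size=n)
    elif callable(len_dist):
        lengths = np.asarray(len_dist(rng, n), dtype=int)
    else:
        pool = np.asarray(list(len_dist), dtype=int)
        lengths = rng.choice(pool, size=n, replace=True)
    if (lengths < 1).any():
        raise ValueError("null sequence lengths must be >= 1")
    out = []
    for L in lengths:
        out.append("".join(AMINO_ACIDS[k]
                           for k in rng.choice(20, size=int(L), p=q)))
    return out


def _censored_gumbel_mle(scores: np.ndarray,
                         tail_fraction: float) -> tuple[float, float]:
    """Left-censored maximum-likelihood Gumbel fit.

    Only the upper ``tail_fraction`` of the sample is observed; the rest
    contribute the censored term ``n_cens * log F(c)``. E-values only ever
    query the right tail, and a full-sample fit is dominated by the bulk,
    whose shape differs enough from the Gumbel law to bias the tail; the
    censored fit concentrates the likelihood where the statistic is used.
    Method-of-moments fallback on optimizer failure.
    """
    from scipy.optimize import minimize

    srt = np.sort(scores)
    n = len(srt)
    k = min(max(int(round(n * tail_fraction)), 20), n)
    obs = srt[n - k:]
    c = srt[n - k]
    n_cens = n - k

    sd = float(np.std(srt, ddof=1))
    beta0 = sd * math.sqrt(6.0) / math.pi
    mu0 = float(np.mean(srt)) - 0.5772156649015329 * beta0

    def nll(params) -> float:
        mu, log_beta = params
        beta = math.exp(log_beta)
        z = (obs - mu) / beta
        ll = float(np.sum(-z - np.exp(-z))) - k * log_beta
        if n_cens:
            ll += n_cens * float(stats.gumbel_r.logcdf(c, loc=mu, scale=beta))
        return -ll

    res = minimize(nll, x0=[mu0, math.log(max(beta0, 1e-6))],
                   method="Nelder-Mead",
                   options={"xatol": 1e-9, "fatol": 1e-10, "maxiter": 4000})
    mu, beta = float(res.x[0]), float(math.exp(res.x[1]))
    if not (math.isfinite(mu) and math.isfinite(beta) and beta > 0):
        return mu0, beta0
    return mu, beta


def calibrate(p: ProfileModel, n_null: int, len_dist, seed: int,
              mode: str = "local", tail_fraction: float = 0.05
              ) -> EvalueCalibration:
    """Fit the null (background-sequence) forward-score distribution.

    Gumbel location and scale come from a left-censored maximum-likelihood
    fit to the upper ``tail_fraction`` of the null scores. Deterministic
    given ``seed``.
    """
    if n_null < 100:
        raise ProfileError("n_null must be >= 100")
    rng = np.random.default_rng(seed)
    seqs = sample_null_sequences(rng, n_null, len_dist, p.background)
    scores = np.asarray(forward_score_batch(p, seqs, mode=mode))
    if float(np.std(scores)) < 1e-12:
        raise ProfileError("degenerate null score variance")
    mu, beta = _censored_gumbel_mle(scores, tail_fraction)
    return EvalueCalibration(mu=mu, beta=beta, n_null=n_null, seed=seed)


def evalue(score_bits: float, cal: EvalueCalibration, db_size: int) -> float:
    """Expected number of >= score hits in ``db_size`` null sequences."""
    return float(db_size) * float(cal.pvalue(score_bits))


# ---------------------------------------------------------------------------
# Scanning

@dataclass(frozen=True)
class SearchHit:
    profile_id: str
    sequence_id: str
    bits: float
    evalue: float
    env_start: int
    env_end: int


def scan_proteome(p: ProfileModel, prot: Proteome, cal: EvalueCalibration,
                  threshold: float = 0.01) -> list[SearchHit]:
    """Forward-search a proteome; keep hits with E <= threshold.

    ``db_size`` is the number of sequences in the proteome. Hits are sorted
    ascending by e-value (ties: descending bits, then id) and envelopes come
    from the Viterbi path.
    """
    if len(prot) == 0:
        return []
    db_size = len(prot)
    seqs = [rec.sequence for rec in prot]
    bits = forward_score_batch(p, seqs)
    pvals = np.asarray(cal.pvalue(bits))
    evals = db_size * pvals
    hits: list[SearchHit] = []
    for rec, b, E in zip(prot, bits, evals):
        if E <= threshold:
            vr = viterbi(p, rec.sequence)
            hits.append(SearchHit(profile_id=p.id, sequence_id=rec.id,
                                  bits=float(b), evalue=float(E),
                                  env_start=vr.env_start, env_end=vr.env_end))
    hits.sort(key=lambda h: (h.evalue, -h.bits, h.sequence_id))
    return hits


@dataclass(frozen=True)
class DomainHit:
    domain_id: str
    start: int   # 1-based inclusive envelope
    end: int
    evalue: float


@dataclass
class DomainArchitecture:
    hits: list[DomainHit]

    @property
    def domain_ids(self) -> list[str]:
        return [h.domain_id for h in self.hits]

    def __iter__(self):
        return iter(self.hits)

    def __len__(self) -> int:
        return len(self.hits)


def annotate_domains(rec: ProteinRecord | str,
                     domain_profiles: Iterable[ProfileModel],
                     cals: dict[str, EvalueCalibration],
                     threshold: float = 0.01,
                     max_hits_per_domain: int = 8) -> DomainArchitecture:
    """Annotate the ordered domain architecture of one sequence.

    Each domain profile is searched iteratively: after each accepted hit the
    envelope is masked with ``X`` and the scan repeats, so tandem repeats of
    the same domain are all recovered. E-values use ``db_size = 1`` (a
    per-sequence domain test). Overlapping hits (any shared residue) are
    resolved greedily by ascending e-value; survivors are sorted by start.
    """
    seq = rec.sequence if isinstance(rec, ProteinRecord) else rec
    raw: list[DomainHit] = []
    for dp in domain_profiles:
        cal = cals[dp.id]
        work = seq
        for _ in range(max_hits_per_domain):
            bits = forward_score(dp, work)
            E = evalue(bits, cal, db_size=1)
            if E > threshold:
                break
            vr = viterbi(dp, work)
            s, e = vr.env_start, vr.env_end
            if s == 0 or e < s:
                break
            raw.append(DomainHit(domain_id=dp.id, start=s, end=e, evalue=E))
            work = work[:s - 1] + "X" * (e - s + 1) + work[e:]
    raw.sort(key=lambda h: (h.evalue, h.start, h.domain_id))
    kept: list[DomainHit] = []
    for h in raw:
        if all(h.end < k.start or h.start > k.end for k in kept):
            kept.append(h)
    kept.sort(key=lambda h: h.start)
    return DomainArchitecture(hits=kept)
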