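"""Explicit-duration HMM segmentation of fold-change tracks.

The model has one background state (B) and ``n_sub`` identical CUT sub-states
(C1..Cn) traversed unidirectionally: B->B, B->C1, Ci->Ci, Ci->Ci+1, Cn->Cn,
Cn->B.  The chain of sub-states gives CUT dwell times a negative-binomial
(n_sub, a) distribution instead of the geometric dwell of a plain 2-state
HMM, approximating a hidden semi-Markov model, and makes n_sub the minimum
decodable CUT length.  With the default n_sub = 9 the model has 10 states.

Emissions are over a small discrete alphabet obtained by binning per-
nucleotide log2(rrp6-delta/WT) fold change.  Decoding is Viterbi in log
space (posterior decoding available for comparison); no parameters are
re-estimated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from numba import njit

from .genomic_io import Annotation
from .coverage import FoldChangeTrack

# Default discretization (log2 fold-change cut points) and emissions.  The
# per-symbol log-likelihood ratio favors the CUT state only from the
# (0.5, 1.0] bin upward, i.e. for fold changes approaching 2x and above.
DEFAULT_BIN_EDGES = (-0.5, 0.5, 1.0, 2.0)
DEFAULT_BACKGROUND_EMISSION = (0.10, 0.72, 0.12, 0.05, 0.01)
DEFAULT_CUT_EMISSION = (0.02, 0.09, 0.16, 0.43, 0.30)
DEFAULT_N_SUB = 9
DEFAULT_Q = 0.9998    # background self-loop: mean background run 5 kb
DEFAULT_A = 2e-4      # sub-state advance: mean CUT run n_sub/a = 45 kb


@dataclass(frozen=True)
class Discretizer:
    """Right-closed binning of log2 fold change: symbol k <=> value in
    (edge_{k-1}, edge_k]; K = len(edges) + 1 symbols."""

    bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES

    def __post_init__(self):
        edges = np.asarray(self.bin_edges, dtype=float)
        if edges.ndim != 1 or len(edges) == 0 or not np.all(np.diff(edges) > 0):
            raise ValueError("bin edges must be strictly ascending and nonempty")

    @property
    def n_symbols(self) -> int:
        return len(self.bin_edges) + 1

    def symbols(self, fold_values: np.ndarray) -> np.ndarray:
        f = np.asarray(fold_values, dtype=float)
        if not np.all(np.isfinite(f)) or np.any(f <= 0):
            raise ValueError("fold-change values must be finite and positive")
        return np.searchsorted(
            np.asarray(self.bin_edges), np.log2(f), side="left"
        ).astype(np.int64)


def discretize(fc: FoldChangeTrack, d: Discretizer) -> dict[tuple[str, str], np.ndarray]:
    """Per-(chrom, strand) symbol arrays for HMM decoding."""
    return {k: d.symbols(v) for k, v in fc.data.items()}


@dataclass
class ExpandedHMM:
    """1 + n_sub state chain HMM with shared CUT emissions."""

    n_sub: int
    A: np.ndarray          # (n_states, n_states)
    E: np.ndarray          # (n_states, K)
    pi: np.ndarray         # (n_states,)

    _TOL = 1e-12

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=float)
        self.E = np.asarray(self.E, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        self.validate()

    @property
    def n_states(self) -> int:
        return self.n_sub + 1

    @property
    def q(self) -> float:
        """Background self-loop probability."""
        return float(self.A[0, 0])

    @property
    def a(self) -> float:
        """Sub-state advance probability (shared by all CUT sub-states)."""
        return float(self.A[1, 2]) if self.n_sub > 1 else float(self.A[1, 0])

    @property
    def expected_cut_length(self) -> float:
        """Mean decoded-state CUT run length, n_sub / a (negative binomial)."""
        return self.n_sub / self.a

    def allowed_transitions(self) -> np.ndarray:
        n = self.n_states
        allowed = np.zeros((n, n), dtype=bool)
        allowed[0, 0] = allowed[0, 1] = True
        for i in range(1, n):
            allowed[i, i] = True
            allowed[i, i + 1 if i < n - 1 else 0] = True
        return allowed

    def validate(self) -> None:
        n = self.n_states
        if self.n_sub < 1:
            raise ValueError("n_sub must be >= 1")
        if self.A.shape != (n, n) or self.E.shape[0] != n or self.pi.shape != (n,):
            raise ValueError("A/E/pi shapes inconsistent with n_sub")
        if np.any(self.A < 0) or np.any(self.E < 0) or np.any(self.pi < 0):
            raise ValueError("probabilities must be non-negative")
        for name, rows in (("A", self.A), ("E", self.E), ("pi", self.pi[None, :])):
            sums = rows.sum(axis=1)
            if np.any(np.abs(sums - 1.0) > 1e-9):
                raise ValueError(f"{name} rows must sum to 1 (got {sums})")
        if np.any(self.A[~self.allowed_transitions()] > self._TOL):
            raise ValueError("nonzero probability on a disallowed transition")
        # all CUT sub-states identical: one emission row, one (self, advance) pair
        for i in range(2, n):
            if not np.allclose(self.E[i], self.E[1], atol=self._TOL):
                raise ValueError("CUT sub-states must share one emission row")
            if not np.isclose(self.A[i, i], self.A[1, 1], atol=self._TOL):
                raise ValueError("CUT sub-states must share one self-loop probability")

    def stationary(self) -> np.ndarray:
        """Stationary distribution of A (left eigenvector for eigenvalue 1)."""
        n = self.n_states
        M = np.vstack([self.A.T - np.eye(n), np.ones(n)])
        b = np.concatenate([np.zeros(n), [1.0]])
        pi, *_ = np.linalg.lstsq(M, b, rcond=None)
        return np.clip(pi, 0, None) / pi.sum()


def build_model(
    n_sub: int = DEFAULT_N_SUB,
    q: float = DEFAULT_Q,
    a: float = DEFAULT_A,
    background_emission: Sequence[float] = DEFAULT_BACKGROUND_EMISSION,
    cut_emission: Sequence[float] = DEFAULT_CUT_EMISSION,
    pi: Sequence[float] | None = None,
) -> ExpandedHMM:
    """Assemble the expanded chain model; defaults give the 10-state model.

    ``pi`` defaults to the stationary distribution of A, so decoding restarts
    each chromosome from the model's long-run state frequencies.
    """
    if not (0.0 < q <= 1.0 and 0.0 < a <= 1.0):
        raise ValueError("q and a must be probabilities in (0, 1]")
    n = n_sub + 1
    A = np.zeros((n, n))
    A[0, 0], A[0, 1] = q, 1.0 - q
    for i in range(1, n):
        nxt = i + 1 if i < n - 1 else 0
        A[i, i], A[i, nxt] = 1.0 - a, a
    bg = np.asarray(background_emission, dtype=float)
    cut = np.asarray(cut_emission, dtype=float)
    if bg.shape != cut.shape:
        raise ValueError("background and CUT emission rows must have equal length")
    E = np.vstack([bg] + [cut] * n_sub)
    model = ExpandedHMM(n_sub, A, E, np.full(n, 1.0 / n))
    model.pi = model.stationary() if pi is None else np.asarray(pi, dtype=float)
    model.validate()
    return model


def model_to_dict(model: ExpandedHMM, d: Discretizer | None = None) -> dict:
    out = {
        "n_sub": model.n_sub,
        "A": model.A.tolist(),
        "E": model.E.tolist(),
        "pi": model.pi.tolist(),
    }
    if d is not None:
        out["bin_edges"] = list(d.bin_edges)
    return out


def model_from_dict(cfg: Mapping) -> tuple[ExpandedHMM, Discretizer]:
    if "A" in cfg:
        model = ExpandedHMM(
            int(cfg["n_sub"]), np.asarray(cfg["A"]), np.asarray(cfg["E"]), np.asarray(cfg["pi"])
        )
    else:
        model = build_model(
            n_sub=int(cfg.get("n_sub", DEFAULT_N_SUB)),
            q=float(cfg.get("q", DEFAULT_Q)),
            a=float(cfg.get("a", DEFAULT_A)),
            background_emission=cfg.get("background_emission", DEFAULT_BACKGROUND_EMISSION),
            cut_emission=cfg.get("cut_emission", DEFAULT_CUT_EMISSION),
        )
    disc = Discretizer(tuple(cfg.get("bin_edges", DEFAULT_BIN_EDGES)))
    return model, disc


# ---------------------------------------------------------------------------
# decoding kernels
# ---------------------------------------------------------------------------

def _log(x: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log(x)


@njit(cache=True)
def _viterbi_kernel(sym, logA, logE, logpi, preds):  # pragma: no cover - numba
    T = sym.shape[0]
    S = logE.shape[0]
    delta = np.empty((T, S))
    ptr = np.empty((T, S), np.int8)
    for s in range(S):
        delta[0, s] = logpi[s] + logE[s, sym[0]]
        ptr[0, s] = -1
    for t in range(1, T):
        for s in range(S):
            p0 = preds[s, 0]
            p1 = preds[s, 1]
            v0 = delta[t - 1, p0] + logA[p0, s]
            v1 = delta[t - 1, p1] + logA[p1, s]
            # ties resolved toward the lower-indexed (background-side) state
            if v0 >= v1:
                delta[t, s] = v0 + logE[s, sym[t]]
                ptr[t, s] = 0
            else:
                delta[t, s] = v1 + logE[s, sym[t]]
                ptr[t, s] = 1
    path = np.empty(T, np.int16)
    best = 0
    for s in range(1, S):
        if delta[T - 1, s] > delta[T - 1, best]:
            best = s
    path[T - 1] = best
    for t in range(T - 1, 0, -1):
        s = path[t]
        path[t - 1] = preds[s, ptr[t, s]]
    return path, delta[T - 1, best]


@njit(cache=True)
def _forward_backward_kernel(sym, A, E, pi, preds, succs):  # pragma: no cover
    T = sym.shape[0]
    S = E.shape[0]
    alpha = np.empty((T, S))
    scale = np.empty(T)
    for s in range(S):
        alpha[0, s] = pi[s] * E[s, sym[0]]
    scale[0] = alpha[0].sum()
    alpha[0] /= scale[0]
    for t in range(1, T):
        for s in range(S):
            acc = 0.0
            for j in range(2):
                p = preds[s, j]
                acc += alpha[t - 1, p] * A[p, s]
            alpha[t, s] = acc * E[s, sym[t]]
        scale[t] = alpha[t].sum()
        alpha[t] /= scale[t]
    beta = np.empty((T, S))
    for s in range(S):
        beta[T - 1, s] = 1.0
    for t in range(T - 2, -1, -1):
        for s in range(S):
            acc = 0.0
            for j in range(2):
                nxt = succs[s, j]
                acc += A[s, nxt] * E[nxt, sym[t + 1]] * beta[t + 1, nxt]
            beta[t, s] = acc / scale[t + 1]
    post = alpha * beta
    for t in range(T):
        post[t] /= post[t].sum()
    loglik = np.log(scale).sum()
    return post, loglik


@njit(cache=True)
def _pick(cum, u):  # pragma: no cover - numba
    for i in range(cum.shape[0]):
        if u < cum[i]:
            return i
    return cum.shape[0] - 1


@njit(cache=True)
def _sample_kernel(length, A_cum, E_cum, pi_cum, rand):  # pragma: no cover
    # rand: pre-drawn uniforms (2 per position) to keep sampling reproducible
    path = np.empty(length, np.int16)
    sym = np.empty(length, np.int64)
    state = _pick(pi_cum, rand[0, 0])
    for t in range(length):
        if t > 0:
            state = _pick(A_cum[state], rand[0, t])
        path[t] = state
        sym[t] = _pick(E_cum[state], rand[1, t])
    return sym, path


def _pred_succ(model: ExpandedHMM) -> tuple[np.ndarray, np.ndarray]:
    n = model.n_states
    allowed = model.allowed_transitions()
    preds = np.zeros((n, 2), dtype=np.int64)
    succs = np.zeros((n, 2), dtype=np.int64)
    for s in range(n):
        p = sorted(j for j in range(n) if allowed[j, s])
        preds[s] = p[:2] if len(p) >= 2 else [p[0], p[0]]
        q = sorted(j for j in range(n) if allowed[s, j])
        succs[s] = q[:2] if len(q) >= 2 else [q[0], q[0]]
    return preds, succs


def viterbi(symbols: np.ndarray, model: ExpandedHMM) -> np.ndarray:
    """Maximum-probability state path (log space, deterministic tie-break
    toward the background state)."""
    sym = np.asarray(symbols, dtype=np.int64)
    if sym.size == 0:
        return np.zeros(0, dtype=np.int16)
    if sym.min() < 0 or sym.max() >= model.E.shape[1]:
        raise ValueError("symbol outside the model alphabet")
    preds, _ = _pred_succ(model)
    path, _ = _viterbi_kernel(sym, _log(model.A), _log(model.E), _log(model.pi), preds)
    return path


def viterbi_score(symbols: np.ndarray, model: ExpandedHMM) -> tuple[np.ndarray, float]:
    """Viterbi path together with its log joint probability."""
    sym = np.asarray(symbols, dtype=np.int64)
    preds, _ = _pred_succ(model)
    path, score = _viterbi_kernel(sym, _log(model.A), _log(model.E), _log(model.pi), preds)
    return path, float(score)


def posterior(symbols: np.ndarray, model: ExpandedHMM) -> tuple[np.ndarray, float]:
    """Scaled forward-backward: per-position state posteriors and the data
    log-likelihood.  ``posterior(...)[0].argmax(1)`` is posterior decoding."""
    sym = np.asarray(symbols, dtype=np.int64)
    if sym.size == 0:
        return np.zeros((0, model.n_states)), 0.0
    preds, succs = _pred_succ(model)
    post, loglik = _forward_backward_kernel(sym, model.A, model.E, model.pi, preds, succs)
    return post, float(loglik)


def decode(
    fc: FoldChangeTrack, model: ExpandedHMM, d: Discretizer | None = None
) -> dict[tuple[str, str], np.ndarray]:
    """Viterbi-decode every (chromosome, strand) of a fold-change track."""
    d = d or Discretizer()
    return {k: viterbi(sym, model) for k, sym in discretize(fc, d).items()}


def segments_from_path(
    paths: Mapping[tuple[str, str], np.ndarray], feature_class: str = "rawCUT"
) -> list[Annotation]:
    """Maximal runs of CUT sub-states become raw CUT intervals (each at
    least n_sub long by construction of the chain)."""
    out = []
    for (chrom, strand), path in sorted(paths.items()):
        in_cut = np.asarray(path) > 0
        if in_cut.size == 0:
            continue
        d = np.diff(in_cut.astype(np.int8))
        starts = np.flatnonzero(d == 1) + 1
        ends = np.flatnonzero(d == -1) + 1
        if in_cut[0]:
            starts = np.concatenate(([0], starts))
        if in_cut[-1]:
            ends = np.concatenate((ends, [in_cut.size]))
        for i, (s, e) in enumerate(zip(starts, ends)):
            out.append(
                Annotation(
                    chrom, int(s), int(e), strand,
                    name=f"{feature_class}_{chrom}{strand}_{i}",
                    feature_class=feature_class,
                )
            )
    return sorted(out, key=lambda a: (a.chrom, a.start, a.end, a.strand))


def generate(
    model: ExpandedHMM, length: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Sample (symbols, state path) of the given length; reproducible from
    the seed.  Used to characterize the duration distribution of the model."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    rand = rng.random((2, length))
    A_cum = np.cumsum(model.A, axis=1)
    E_cum = np.cumsum(model.E, axis=1)
    pi_cum = np.cumsum(model.pi)
    sym, path = _sample_kernel(length, A_cum, E_cum, pi_cum, rand)
    return sym, path


def cut_run_lengths(path: np.ndarray, complete_only: bool = True) -> np.ndarray:
    """Lengths of maximal CUT-state runs in a path; ``complete_only`` drops
    runs truncated by the sequence ends."""
    in_cut = np.asarray(path) > 0
    if in_cut.size == 0:
        return np.zeros(0, dtype=np.int64)
    d = np.diff(in_cut.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    open_start = in_cut[0]
    open_end = in_cut[-1]
    if open_start:
        starts = np.concatenate(([0], starts))
    if open_end:
        ends = np.concatenate((ends, [in_cut.size]))
    lengths = ends - starts
    if complete_only:
        if open_end and lengths.size:
            lengths = lengths[:-1]
        if open_start and lengths.size:
            lengths = lengths[1:]
    return lengths
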