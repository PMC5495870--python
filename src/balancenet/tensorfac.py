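"""4-mode PARAFAC decomposition of the PDC connectivity tensor.

The per-subject PDC time–frequency maps of all directed channel pairs
form a 4th-order tensor with modes space (directed pair), time,
frequency and subject.  PARAFAC decomposes it into a sum of M rank-1
outer products

    X ≈ Σ_{r=1..M}  a_r ∘ b_r ∘ c_r ∘ d_r ,

yielding M spatial interaction patterns, time courses, frequency
profiles and subject loadings.  Because PDC values are nonnegative, the
default solver constrains all loadings to be nonnegative
(hierarchical alternating least squares, HALS); plain unconstrained ALS
is available as an option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import khatri_rao

from .connectivity import PDCTensor

__all__ = [
    "PDC4Tensor",
    "Parafac",
    "ParafacResults",
    "build_tensor",
    "factor_congruence",
]

MODE_NAMES = ("space", "time", "frequency", "subject")


@dataclass
class PDC4Tensor:
    """PDC values vectorized over directed pairs: pairs × time × freq × subject.

    Pair order is row-major (source-major) over the alphabetically
    sorted electrode subset, self-pairs skipped; ``pair_labels`` records
    it as ``"SRC->TGT"`` strings.
    """

    values: np.ndarray
    pair_labels: list[str]
    times: np.ndarray
    freqs: np.ndarray
    subjects: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 4:
            raise ValueError("values must be 4-dimensional (pairs, time, freq, subject)")
        if self.values.shape[0] != len(self.pair_labels):
            raise ValueError("pair axis does not match pair_labels")
        if self.values.min() < 0:
            raise ValueError("PDC tensor values must be nonnegative")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    def unvectorize(self, pair_values: np.ndarray) -> tuple[np.ndarray, list[str]]:
        """Map a vector over pairs back to a (target, source) matrix."""
        chans = sorted({lbl.split("->")[0] for lbl in self.pair_labels})
        idx = {c: i for i, c in enumerate(chans)}
        M = np.zeros((len(chans), len(chans)))
        for lbl, v in zip(self.pair_labels, np.asarray(pair_values)):
            src, tgt = lbl.split("->")
            M[idx[tgt], idx[src]] = v
        return M, chans


def build_tensor(
    pdcs: list[PDCTensor],
    electrode_subset: list[str] | None = None,
    subjects: list | None = None,
) -> PDC4Tensor:
    """Stack per-subject PDC tensors into the 4-mode PARAFAC input.

    All subjects must share time and frequency axes; the electrode
    subset defaults to all channels of the first tensor.
    """
    ref = pdcs[0]
    subset = sorted(electrode_subset if electrode_subset is not None else ref.channel_names)
    for p in pdcs[1:]:
        if p.values.shape[2:] != ref.values.shape[2:] or not (
            np.allclose(p.times, ref.times) and np.allclose(p.freqs, ref.freqs)
        ):
            raise ValueError("subjects have mismatching time/frequency axes")
    missing = [c for c in subset if c not in ref.channel_names]
    if missing:
        raise ValueError(f"subset channels not present: {missing}")

    pair_labels = [f"{s}->{t}" for s in subset for t in subset if t != s]
    idx = [ref.channel_names.index(c) for c in subset]
    slabs = []
    for p in pdcs:
        off = p.offdiagonal()
        rows = [
            off[idx[ti], idx[si]]
            for si in range(len(subset))
            for ti in range(len(subset))
            if ti != si
        ]
        slabs.append(np.stack(rows))  # (pairs, time, freq)
    values = np.stack(slabs, axis=-1)
    return PDC4Tensor(
        values=values,
        pair_labels=pair_labels,
        times=ref.times,
        freqs=ref.freqs,
        subjects=list(subjects) if subjects is not None else list(range(len(pdcs))),
    )


# --------------------------------------------------------------------------
# PARAFAC solver
# --------------------------------------------------------------------------

def _unfold(X: np.ndarray, mode: int) -> np.ndarray:
    return np.moveaxis(X, mode, 0).reshape(X.shape[mode], -1)


def _kr_excluding(factors: list[np.ndarray], mode: int) -> np.ndarray:
    mats = [f for i, f in enumerate(factors) if i != mode]
    out = mats[0]
    for m in mats[1:]:
        out = khatri_rao(out, m)
    return out


def _reconstruct(factors: list[np.ndarray]) -> np.ndarray:
    shape = tuple(f.shape[0] for f in factors)
    full = factors[0] @ _kr_excluding(factors, 0).T
    return full.reshape(shape)


class Parafac:
    """PARAFAC model of a nonnegative 4-mode (or N-mode) tensor.

    Parameters
    ----------
    tensor
        A :class:`PDC4Tensor` or a plain ndarray.
    rank
        Number of factors M (the balancing study uses 5).
    nonnegative
        Constrain all loadings to be ≥ 0 (default; HALS updates).  With
        ``False`` plain alternating least squares is used.
    n_restarts, max_iter, tol, seed
        Multi-start optimization controls; the best-fit restart is
        returned and everything is deterministic given ``seed``.
    """

    def __init__(
        self,
        tensor: PDC4Tensor | np.ndarray,
        rank: int = 5,
        nonnegative: bool = True,
        n_restarts: int = 10,
        max_iter: int = 500,
        tol: float = 1e-8,
        seed: int = 0,
    ) -> None:
        self.tensor = tensor
        self.X = tensor.values if isinstance(tensor, PDC4Tensor) else np.asarray(tensor, float)
        if rank < 1:
            raise ValueError("rank must be >= 1")
        if self.X.size == 0 or not np.isfinite(self.X).all():
            raise ValueError("tensor must be non-empty and finite")
        self.rank = rank
        self.nonnegative = nonnegative
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.seed = seed

    # -- single ALS run ----------------------------------------------------
    def _run(self, rng: np.random.Generator) -> tuple[list[np.ndarray], list[float], bool]:
        X = self.X
        N = X.ndim
        M = self.rank
        norm_x = np.linalg.norm(X)
        if norm_x == 0:
            raise ValueError("tensor is identically zero")
        scale = (norm_x**2 / X.size) ** 0.5
        factors = [np.abs(rng.standard_normal((X.shape[n], M))) * scale ** (2 / N) for n in range(N)]
        unfolds = [_unfold(X, n) for n in range(N)]
        grams = [f.T @ f for f in factors]

        errors: list[float] = []
        converged = False
        prev = np.inf
        for _ in range(self.max_iter):
            for n in range(N):
                kr = _kr_excluding(factors, n)
                W = unfolds[n] @ kr  # (I_n, M)
                H = np.ones((M, M))
                for m in range(N):
                    if m != n:
                        H *= grams[m]
                U = factors[n]
                if self.nonnegative:
                    for r in range(M):
                        h = H[r, r]
                        if h <= 1e-300:
                            # dead component: reseed its column
                            U[:, r] = np.abs(rng.standard_normal(U.shape[0])) * 1e-10
                            continue
                        u = U[:, r] + (W[:, r] - U @ H[:, r]) / h
                        U[:, r] = np.maximum(u, 0.0)
                else:
                    U = np.linalg.solve(H.T, W.T).T if np.linalg.cond(H) < 1e12 else W @ np.linalg.pinv(H)
                    factors[n] = U
                grams[n] = U.T @ U
            # relative reconstruction error via the last-updated mode
            H_all = np.ones((M, M))
            for m in range(N):
                H_all *= grams[m]
            cross = float(np.sum(W * factors[N - 1]))
            err2 = max(norm_x**2 - 2 * cross + float(H_all.sum()), 0.0)
            err = np.sqrt(err2) / norm_x
            errors.append(err)
            if abs(prev - err) < self.tol:
                converged = True
                break
            prev = err
        return factors, errors, converged

    def fit(self) -> "ParafacResults":
        """Run the multi-start (nonnegative) ALS and return the best fit."""
        best = None
        rng_root = np.random.default_rng(self.seed)
        for _ in range(self.n_restarts):
            rng = np.random.default_rng(rng_root.integers(0, 2**31 - 1))
            factors, errors, converged = self._run(rng)
            if best is None or errors[-1] < best[1][-1]:
                best = (factors, errors, converged)
        factors, errors, converged = best
        if not converged:
            warnings.warn("PARAFAC did not converge; returning best iterate")
        factors = self._normalize(factors)
        return ParafacResults(self, factors, errors, converged)

    @staticmethod
    def _normalize(factors: list[np.ndarray]) -> list[np.ndarray]:
        """Unit-normalize modes 1..N−1, absorbing all scale into mode 0."""
        out = [f.copy() for f in factors]
        for n in range(1, len(out)):
            norms = np.linalg.norm(out[n], axis=0)
            norms = np.where(norms == 0, 1.0, norms)
            out[n] /= norms
            out[0] *= norms
        return out


class ParafacResults:
    """Fitted PARAFAC factors with diagnostics.

    ``loadings`` maps mode names (space, time, frequency, subject for a
    4-mode PDC tensor) to (dim × M) loading matrices; the scale of each
    factor is carried by the first mode.
    """

    def __init__(
        self,
        model: Parafac,
        factors: list[np.ndarray],
        error_history: list[float],
        converged: bool,
    ) -> None:
        self.model = model
        self.factors = factors
        self.error_history = np.asarray(error_history)
        self.converged = converged
        self.rank = model.rank
        names = MODE_NAMES if len(factors) == 4 else tuple(f"mode{i}" for i in range(len(factors)))
        self.loadings = dict(zip(names, factors))

    @property
    def fit(self) -> float:
        """Explained-variation fraction 1 − ‖X − X̂‖/‖X‖ ∈ [0, 1]."""
        return float(np.clip(1.0 - self.error_history[-1], 0.0, 1.0))

    def reconstruct(self) -> np.ndarray:
        return _reconstruct(self.factors)

    def core_consistency(self) -> float:
        """Core-consistency diagnostic (100 = perfectly trilinear).

        Regresses the data onto the Tucker core implied by the PARAFAC
        factors and measures how close it is to the identity superdiagonal.
        """
        G = self.model.X
        for n, U in enumerate(self.factors):
            pinv = np.linalg.pinv(U)
            G = np.moveaxis(np.tensordot(pinv, G, axes=(1, n)), 0, n)
        M = self.rank
        ideal = np.zeros((M,) * G.ndim)
        ideal[tuple(np.arange(M) for _ in range(G.ndim))] = 1.0
        denom = max(float((ideal**2).sum()), 1e-300)
        return float(100.0 * (1.0 - ((G - ideal) ** 2).sum() / denom))

    def plot(self, axes=None):
        """One row of loading profiles per mode, one line per factor."""
        import matplotlib.pyplot as plt

        if axes is None:
            _, axes = plt.subplots(len(self.factors), 1, figsize=(7, 2.2 * len(self.factors)))
        for ax, (name, U) in zip(np.atleast_1d(axes), self.loadings.items()):
            for r in range(self.rank):
                ax.plot(U[:, r], label=f"factor {r + 1}")
            ax.set_ylabel(name)
        np.atleast_1d(axes)[0].legend(fontsize="small", ncol=min(self.rank, 5))
        return axes

    def summary(self) -> str:
        shape = "×".join(str(s) for s in self.model.X.shape)
        lines = [
            f"PARAFAC decomposition, M={self.rank} factors",
            "=" * 44,
            f"tensor:        {shape} ({', '.join(self.loadings)})",
            f"constraint:    {'nonnegative (HALS)' if self.model.nonnegative else 'unconstrained ALS'}",
            f"fit:           {self.fit:.4f}",
            f"iterations:    {self.error_history.size} (converged={self.converged})",
            f"restarts:      {self.model.n_restarts}",
        ]
        for name, U in self.loadings.items():
            peaks = ", ".join(str(int(np.argmax(U[:, r]))) for r in range(self.rank))
            lines.append(f"{name:>10} peak index per factor: {peaks}")
        return "\n".join(lines)


# --------------------------------------------------------------------------
# Factor comparison
# --------------------------------------------------------------------------

def _tucker_phi(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def factor_congruence(
    factors_a: list[np.ndarray] | ParafacResults,
    factors_b: list[np.ndarray] | ParafacResults,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Greedy-matched factor congruence between two decompositions.

    The similarity of factor r (in A) and s (in B) is the product over
    modes of Tucker's congruence coefficient of the corresponding
    loading columns; factors are matched greedily on |similarity|.

    Returns ``(scores, matching)`` where ``scores[k]`` is the congruence
    of the k-th matched pair ``matching[k] = (r_a, r_b)``.
    """
    fa = factors_a.factors if isinstance(factors_a, ParafacResults) else list(factors_a)
    fb = factors_b.factors if isinstance(factors_b, ParafacResults) else list(factors_b)
    if len(fa) != len(fb) or any(a.shape[0] != b.shape[0] for a, b in zip(fa, fb)):
        raise ValueError("decompositions have mismatching modes")
    Ma, Mb = fa[0].shape[1], fb[0].shape[1]
    sim = np.ones((Ma, Mb))
    for A, B in zip(fa, fb):
        phi = np.zeros((Ma, Mb))
        for r in range(Ma):
            for s in range(Mb):
                phi[r, s] = _tucker_phi(A[:, r], B[:, s])
        sim *= phi

    scores = []
    matching = []
    avail_a, avail_b = set(range(Ma)), set(range(Mb))
    masked = np.abs(sim)
    while avail_a and avail_b:
        r, s = max(((r, s) for r in avail_a for s in avail_b), key=lambda rs: masked[rs])
        scores.append(sim[r, s])
        matching.append((r, s))
        avail_a.discard(r)
        avail_b.discard(s)
    return np.asarray(scores), matching
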