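"""Krylov-accelerated inexact Newton (KAIN) mixing for fixed-point loops.

Given a fixed-point map x -> F(x) with update f(x) = F(x) - x, the plain
iteration x_{n+1} = x_n + f_n converges at the contraction rate of the
map.  KAIN accelerates it, in the spirit of DIIS/Anderson mixing, by a
constrained linear combination over a short history of iterates:
approximating the Jacobian of f on the secant subspace
span{x_j - x_n} through J (x_j - x_n) ~ f_j - f_n and taking an inexact
Newton step projected on that subspace,

    sum_j <x_i - x_n, f_j - f_n> c_j = -<x_i - x_n, f_n>,
    x_{n+1} = x_n + f_n + sum_j c_j [(x_j - x_n) + (f_j - f_n)].

For an exactly linear map on a d-dimensional space, the accelerated
iteration terminates in at most d + 1 steps once the history is long
enough (Krylov exactness) — the property the unit tests pin down.

The accelerator is generic: it works on any iterate objects supported
by the supplied ``axpy``-style arithmetic; here plain numpy arrays with
a caller-chosen inner product.
"""

from __future__ import annotations

from collections import deque
from typing import Callable

import numpy as np

__all__ = ["KainAccelerator"]


class KainAccelerator:
    """History-limited KAIN mixer over numpy arrays.

    Parameters
    ----------
    history:
        Maximum number of stored (iterate, update) pairs, >= 0.
        0 disables acceleration (plain, optionally damped, iteration).
    dot:
        Inner product on iterates; defaults to the Euclidean dot.
    damping:
        Step scale in (0, 1] used for the *plain* step when no history
        is available (and with history length 0).
    """

    #: condition-number ceiling above which the secant system is treated
    #: as singular and the oldest history entry is evicted
    COND_LIMIT = 1e12

    def __init__(
        self,
        history: int = 5,
        dot: Callable[[np.ndarray, np.ndarray], float] | None = None,
        damping: float = 1.0,
    ):
        if history < 0:
            raise ValueError("history must be >= 0")
        if not 0.0 < damping <= 1.0:
            raise ValueError("damping must be in (0, 1]")
        self.history = history
        self.damping = damping
        self._dot = dot or (lambda a, b: float(np.dot(np.ravel(a), np.ravel(b))))
        self._x: deque[np.ndarray] = deque()
        self._f: deque[np.ndarray] = deque()

    def __len__(self) -> int:
        return len(self._x)

    def reset(self) -> None:
        self._x.clear()
        self._f.clear()

    def step(self, x: np.ndarray, f: np.ndarray) -> np.ndarray:
        """Next iterate from the current iterate ``x`` and update ``f``.

        Falls back to the plain (damped) step when the history is empty
        or the secant system is degenerate; evicts the oldest entry and
        retries when the system is merely ill-conditioned.
        """
        x = np.asarray(x, dtype=float)
        f = np.asarray(f, dtype=float)
        nxt = None
        if self.history > 0 and self._x:
            while self._x:
                nxt = self._try_accelerated(x, f)
                if nxt is not None:
                    break
                self._x.popleft()  # evict oldest and retry
                self._f.popleft()
        if nxt is None:
            nxt = x + self.damping * f
        if self.history > 0:
            self._x.append(x.copy())
            self._f.append(f.copy())
            while len(self._x) > self.history:
                self._x.popleft()
                self._f.popleft()
        return nxt

    def _try_accelerated(self, x: np.ndarray, f: np.ndarray) -> np.ndarray | None:
        m = len(self._x)
        dx = [xi - x for xi in self._x]
        df = [fi - f for fi in self._f]
        A = np.empty((m, m))
        b = np.empty(m)
        for i in range(m):
            for j in range(m):
                A[i, j] = self._dot(dx[i], df[j])
            b[i] = -self._dot(dx[i], f)
        try:
            cond = np.linalg.cond(A)
            if not np.isfinite(cond) or cond > self.COND_LIMIT:
                return None
            c = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            return None
        if not np.isfinite(c).all():
            return None
        nxt = x + f
        for j in range(m):
            nxt = nxt + c[j] * (dx[j] + df[j])
        return nxt
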