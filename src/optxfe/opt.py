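"""Operational Transformer: channel-identity transformation of multichannel signals.

The transform walks a signal row by row, pairing each time sample with its
successor, pushes the pair through a small bank of element-wise binary
operators (max, min, sum, absolute difference, ratio), and records for each
operator the channel order obtained by sorting the operator output in
descending value.  The result is, per operator, a flat sequence of channel
identities in which every block of ``cn`` consecutive entries is a
permutation of ``1..cn``.  These identity sequences are the raw material for
transition-table feature extraction and, downstream, for lobe-level symbolic
interpretation — channel identity is preserved end to end.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "OperatorBank",
    "IdentitySignal",
    "operator_outputs",
    "descending_identities",
    "opt_transform",
]


def _ratio_with_epsilon(a: np.ndarray, b: np.ndarray, eps: float) -> np.ndarray:
    # Guard the denominator: b + eps can still be ~0 when b ≈ -eps, so any
    # denominator smaller in magnitude than eps is replaced by a
    # sign-preserving eps (zero maps to +eps).
    denom = b + eps
    tiny = np.abs(denom) < eps
    if np.any(tiny):
        denom = denom.copy()
        denom[tiny] = np.where(denom[tiny] < 0.0, -eps, eps)
    return a / denom


@dataclass(frozen=True)
class OperatorBank:
    """Ordered bank of element-wise binary operators.

    The default bank holds exactly five operators — max, min, addition,
    absolute difference and ratio — in that order; the position of an
    operator is meaningful downstream because each operator contributes a
    contiguous ``cn**2`` slice of the final feature vector.

    Parameters
    ----------
    epsilon
        Small positive constant added to the denominator of the ratio
        operator so that division stays finite.  The default 1e-12 is
        negligible at typical EEG amplitude scales.
    extra_operators
        Optional additional ``(name, f(a, b) -> vector)`` pairs appended
        after the default five; the bank is extensible by design.
    """

    epsilon: float = 1e-12
    extra_operators: tuple[tuple[str, Callable[[np.ndarray, np.ndarray], np.ndarray]], ...] = ()

    def __post_init__(self) -> None:
        if not self.epsilon > 0:
            raise ValueError(f"epsilon must be positive, got {self.epsilon}")

    @property
    def names(self) -> tuple[str, ...]:
        return ("max", "min", "add", "absdiff", "ratio") + tuple(n for n, _ in self.extra_operators)

    def __len__(self) -> int:
        return 5 + len(self.extra_operators)

    def apply(self, a: np.ndarray, b: np.ndarray) -> list[np.ndarray]:
        """Apply every operator to a pair of equal-length vectors (or stacks)."""
        outs = [
            np.maximum(a, b),
            np.minimum(a, b),
            a + b,
            np.abs(a - b),
            _ratio_with_epsilon(a, b, self.epsilon),
        ]
        outs.extend(f(a, b) for _, f in self.extra_operators)
        return outs


@dataclass(frozen=True)
class IdentitySignal:
    """Flat channel-identity sequence produced by one operator.

    ``identities`` holds ``(len - 1)`` consecutive blocks of length ``cn``;
    each block is the permutation of ``1..cn`` ranking the channels by
    descending operator output for one consecutive-sample pair.
    """

    operator_index: int  # 1-based position in the bank
    identities: np.ndarray  # int array, values in 1..cn
    cn: int

    def __post_init__(self) -> None:
        ids = np.asarray(self.identities)
        if ids.ndim != 1 or ids.size % self.cn != 0:
            raise ValueError("identities must be a flat array of whole cn-blocks")
        if ids.size and (ids.min() < 1 or ids.max() > self.cn):
            raise ValueError("identity values must lie in 1..cn")

    @property
    def n_blocks(self) -> int:
        return self.identities.size // self.cn

    def blocks(self) -> np.ndarray:
        """Identities reshaped to (n_blocks, cn)."""
        return np.asarray(self.identities).reshape(-1, self.cn)


def _validate_pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if a.ndim != 1 or a.size < 2:
        raise ValueError("inputs must be 1-D vectors of length >= 2")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("inputs must be finite")
    return a, b


def operator_outputs(a: Sequence[float], b: Sequence[float], bank: OperatorBank | None = None) -> list[np.ndarray]:
    """Apply the operator bank to one pair of channel vectors.

    Returns one output vector per operator, in bank order.
    """
    bank = bank or OperatorBank()
    a, b = _validate_pair(a, b)
    return bank.apply(a, b)


def descending_identities(v: Sequence[float]) -> np.ndarray:
    """Rank channels by descending value; ties go to the smaller channel index.

    Returns a permutation of ``1..cn`` (1-based channel identities).
    """
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("input must be finite")
    # Stable sort of -v: equal values keep ascending index order.
    return np.argsort(-v, kind="stable") + 1


def opt_transform(data: np.ndarray, bank: OperatorBank | None = None) -> list[IdentitySignal]:
    """Transform a (samples x channels) matrix into per-operator identity signals.

    For each consecutive row pair ``(row i, row i+1)`` and each operator in
    the bank, the descending channel ranking of the operator output is
    appended as the next ``cn``-block.  A signal of ``len`` samples yields
    ``len - 1`` blocks per operator.
    """
    bank = bank or OperatorBank()
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError("data must be 2-D with at least 2 channels")
    if data.shape[0] < 2:
        raise ValueError("signal must have at least 2 time samples")
    if not np.all(np.isfinite(data)):
        raise ValueError("signal must be finite")

    cn = data.shape[1]
    a, b = data[:-1], data[1:]
    signals = []
    for x, out in enumerate(bank.apply(a, b), start=1):
        # argsort each row of -out; stable kind breaks ties toward the
        # smaller channel index.
        ids = np.argsort(-out, axis=1, kind="stable") + 1
        signals.append(IdentitySignal(operator_index=x, identities=ids.ravel(), cn=cn))
    return signals
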