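"""Transition-table feature extraction from channel-identity signals.

Each operator's identity sequence is summarised by a ``cn x cn`` matrix of
adjacent-identity transition counts (a first-order symbolic-dynamics
statistic).  Flattening the five tables and concatenating them yields the
final feature vector of length ``5 * cn**2`` — 6125 features for a
35-channel recording.

The flattening order is load-bearing: feature ``u`` of one table maps to
cell ``(q, w)`` via ``u = (w - 1) * cn + q`` (row index fastest).  The
symbolic-interpretation stage inverts exactly this layout to recover the
channel pair behind a selected feature, so the layout must not change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .opt import IdentitySignal, OperatorBank, opt_transform

__all__ = [
    "TransitionTable",
    "transition_table",
    "flatten_table",
    "extract_features",
    "extract_feature_matrix",
]


@dataclass(frozen=True)
class TransitionTable:
    """Square count matrix of identity transitions; ``counts[q-1, w-1]`` is
    the number of times identity ``q`` is immediately followed by ``w``."""

    counts: np.ndarray  # (cn, cn) non-negative ints
    cn: int
    source_operator: int

    def total(self) -> int:
        return int(self.counts.sum())


def transition_table(t: IdentitySignal, include_cross_block: bool = True) -> TransitionTable:
    """Count adjacent-identity transitions in a flat identity sequence.

    By default transitions are counted over the entire flattened sequence,
    including the pairs spanning consecutive blocks, giving a total count of
    ``len(t) - 1``.  With ``include_cross_block=False`` the pairs bridging
    block boundaries are skipped and the total is ``n_blocks * (cn - 1)``.
    """
    ids = np.asarray(t.identities, dtype=np.int64)
    if ids.size < 2:
        raise ValueError("identity sequence must have at least 2 entries")
    if ids.min() < 1 or ids.max() > t.cn:
        raise ValueError("identities out of range 1..cn")
    cn = t.cn
    src, dst = ids[:-1], ids[1:]
    if not include_cross_block:
        keep = (np.arange(ids.size - 1) % cn) != cn - 1
        src, dst = src[keep], dst[keep]
    flat = (src - 1) * cn + (dst - 1)
    counts = np.bincount(flat, minlength=cn * cn).reshape(cn, cn)
    return TransitionTable(counts=counts, cn=cn, source_operator=t.operator_index)


def flatten_table(trt: TransitionTable) -> np.ndarray:
    """Linearise a transition table with the row index varying fastest.

    ``f[u-1] = counts[q-1, w-1]`` with ``u = (w - 1) * cn + q``, i.e. a
    column-major read of the matrix.
    """
    return np.asarray(trt.counts).ravel(order="F")


def extract_features(
    data: np.ndarray,
    bank: OperatorBank | None = None,
    include_cross_block: bool = True,
) -> np.ndarray:
    """Full feature vector of one segment: concatenated flattened tables.

    The output has length ``n_operators * cn**2`` (5 * cn**2 with the
    default bank), with operator ``a`` occupying entries
    ``(a-1)*cn**2 .. a*cn**2 - 1``.
    """
    signals = opt_transform(data, bank)
    return np.concatenate(
        [flatten_table(transition_table(t, include_cross_block)) for t in signals]
    )


def extract_feature_matrix(
    segments,
    bank: OperatorBank | None = None,
    include_cross_block: bool = True,
) -> pd.DataFrame:
    """Feature matrix over a collection of segments.

    Parameters
    ----------
    segments
        Iterable of objects with ``data``, ``label`` and ``subject_id``
        attributes (e.g. :class:`optxfe.synthetic.EegSegment`).

    Returns
    -------
    DataFrame with one row per segment, columns ``f0001..fNNNN`` plus the
    trailing ``label`` and ``subject_id`` columns.
    """
    rows, labels, subjects = [], [], []
    for seg in segments:
        rows.append(extract_features(seg.data, bank, include_cross_block))
        labels.append(seg.label)
        subjects.append(seg.subject_id)
    if not rows:
        raise ValueError("no segments provided")
    X = np.vstack(rows)
    width = len(str(X.shape[1]))
    df = pd.DataFrame(X, columns=[f"f{i:0{width}d}" for i in range(1, X.shape[1] + 1)])
    df["label"] = labels
    df["subject_id"] = subjects
    return df


def split_feature_frame(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split a feature frame into (X, y, subjects) arrays."""
    meta = [c for c in ("label", "subject_id") if c in df.columns]
    X = df.drop(columns=meta).to_numpy(dtype=float)
    y = df["label"].to_numpy()
    subjects = df["subject_id"].to_numpy() if "subject_id" in df.columns else np.arange(len(df))
    return X, y, subjects
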