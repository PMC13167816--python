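"""On-disk formats: segment CSVs, manifests, feature matrices, EDF recordings.

Channel indexing is 1-based at every public boundary, and channels are kept
in stored column order because the lobe look-up table is positional.  CSV
round-trips are lossless; EDF round-trips are lossy only by the format's
16-bit quantisation.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import EegSegment

__all__ = [
    "read_segment_csv",
    "write_segment_csv",
    "read_manifest",
    "read_edf",
    "write_edf",
    "write_feature_matrix",
    "read_feature_matrix",
]


def read_segment_csv(
    path: str | Path, subject_id: str = "?", label: int = 0, sampling_rate: float = 500.0
) -> EegSegment:
    """Load one segment from a delimited numeric matrix (optional header row).

    Fails loudly, with the line number, on ragged or non-numeric rows.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty file")
    sep = "," if "," in lines[0] else None
    first = lines[0].split(sep)
    has_header = not _all_numeric(first)
    names = [c.strip() for c in first] if has_header else None
    rows = []
    width = None
    for lineno, ln in enumerate(lines[1 if has_header else 0 :], start=2 if has_header else 1):
        cells = ln.split(sep)
        if width is None:
            width = len(cells)
        if len(cells) != width:
            raise ValueError(f"{path}:{lineno}: ragged row ({len(cells)} cells, expected {width})")
        try:
            rows.append([float(c) for c in cells])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric cell") from exc
    data = np.asarray(rows, dtype=float)
    seg = EegSegment(data=data, subject_id=subject_id, label=label, sampling_rate=sampling_rate)
    if names is not None:
        object.__setattr__(seg, "_channel_names", tuple(names))
    return seg


def _all_numeric(cells) -> bool:
    try:
        [float(c) for c in cells]
        return True
    except ValueError:
        return False


def write_segment_csv(seg: EegSegment, path: str | Path) -> Path:
    path = Path(path)
    cols = getattr(seg, "_channel_names", None) or [f"ch{i}" for i in range(1, seg.n_channels + 1)]
    pd.DataFrame(seg.data, columns=list(cols)).to_csv(path, index=False)
    return path


def read_manifest(path: str | Path, sampling_rate: float = 500.0) -> list[EegSegment]:
    """Load all segments listed in a manifest CSV (segment_file, subject_id, label).

    Segment paths are resolved relative to the manifest.  All segments must
    agree in channel count; offenders are reported together.
    """
    path = Path(path)
    table = pd.read_csv(path)
    required = {"segment_file", "subject_id", "label"}
    if not required.issubset(table.columns):
        raise ValueError(f"{path}: manifest must have columns {sorted(required)}")
    if table["segment_file"].duplicated().any():
        raise ValueError(f"{path}: duplicate segment_file entries")
    segments = []
    for _, row in table.iterrows():
        seg_path = path.parent / str(row["segment_file"])
        if not seg_path.exists():
            raise FileNotFoundError(f"{path}: listed segment missing: {seg_path}")
        segments.append(
            read_segment_csv(
                seg_path,
                subject_id=str(row["subject_id"]),
                label=int(row["label"]),
                sampling_rate=sampling_rate,
            )
        )
    counts = {seg.n_channels for seg in segments}
    if len(counts) > 1:
        offenders = [
            (str(t.segment_file), s.n_channels)
            for t, s in zip(table.itertuples(), segments)
            if s.n_channels != segments[0].n_channels
        ]
        raise ValueError(f"{path}: inconsistent channel counts: {offenders}")
    return segments


def read_edf(
    path: str | Path,
    segment_seconds: float = 15.0,
    subject_id: str = "?",
    label: int = 0,
) -> list[EegSegment]:
    """Read an EDF recording and cut it into non-overlapping fixed windows.

    All channels must share one sampling rate (no silent resampling); the
    trailing partial window is dropped.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    fs = raw.info["sfreq"]
    data = raw.get_data().T  # (samples, channels)
    win = int(round(segment_seconds * fs))
    if win < 2:
        raise ValueError("segment window shorter than 2 samples")
    n_win = data.shape[0] // win
    if n_win == 0:
        raise ValueError(f"{path}: recording shorter than one {segment_seconds}s window")
    return [
        EegSegment(
            data=data[i * win : (i + 1) * win],
            subject_id=subject_id,
            label=label,
            sampling_rate=fs,
        )
        for i in range(n_win)
    ]


def write_edf(seg: EegSegment, path: str | Path, physical_range: tuple[float, float] | None = None) -> Path:
    """Write one segment as a minimal EDF file (16-bit, one data record).

    A small writer for round-trip testing: single sampling rate, one record
    holding the whole segment.  Quantisation to the EDF 16-bit digital range
    is the only loss.
    """
    path = Path(path)
    data = np.asarray(seg.data, dtype=float)
    n, cn = data.shape
    if physical_range is None:
        span = max(np.abs(data).max(), 1e-9)
        physical_range = (-span, span)
    pmin, pmax = physical_range
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.clip(np.round((data - pmin) * scale) + dmin, dmin, dmax).astype("<i2")

    duration = n / seg.sampling_rate

    def f(text: str, width: int) -> bytes:
        return text.ljust(width)[:width].encode("ascii")

    header = b"".join([
        f("0", 8),
        f("X X X X", 80),  # patient id
        f("Startdate X X X X", 80),  # recording id
        f("01.01.00", 8), f("00.00.00", 8),
        f(str(256 * (1 + cn)), 8),
        f("", 44),
        f("1", 8),  # number of data records
        f(f"{duration:g}", 8),
        f(str(cn), 4),  # ns field is 4 ascii chars
    ])
    labels = getattr(seg, "_channel_names", None) or [f"ch{i}" for i in range(1, cn + 1)]
    sig = b"".join([
        b"".join(f(lbl, 16) for lbl in labels),
        b"".join(f("", 80) for _ in range(cn)),  # transducer
        b"".join(f("uV", 8) for _ in range(cn)),
        b"".join(f(f"{pmin:.6g}", 8) for _ in range(cn)),
        b"".join(f(f"{pmax:.6g}", 8) for _ in range(cn)),
        b"".join(f(str(dmin), 8) for _ in range(cn)),
        b"".join(f(str(dmax), 8) for _ in range(cn)),
        b"".join(f("", 80) for _ in range(cn)),  # prefiltering
        b"".join(f(str(n), 8) for _ in range(cn)),
        b"".join(f("", 32) for _ in range(cn)),
    ])
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        fh.write(digital.T.tobytes())  # record: all samples of ch1, then ch2, ...
    return path


def write_feature_matrix(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_feature_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
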