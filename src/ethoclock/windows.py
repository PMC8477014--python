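"""Frame-rate reduction and overlapping-window construction.

The preprocessing flow mirrors how raw per-frame behavior labels become
classifier input: frames are grouped into 3-s samples of 100 consecutive
frames, each sample is encoded as a per-behavior composition vector (time
fractions, summing to 1) plus a dominant (longest-duration) label, and
overlapping fixed-length windows of samples — 100 steps of 3 s, i.e. 5 min —
are labeled day or night from the phase schedule.  Windows that straddle a
phase transition are dropped.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np

from .core import BehaviorCatalog, EthogramStream, PhaseSchedule, frame_labels, phase_of

__all__ = [
    "NO_DOMINANT",
    "SampleSeries",
    "WindowSet",
    "aggregate_samples",
    "build_windows",
    "flatten_windows",
    "drop_behaviors",
]

#: Reserved dominant label for samples with no activity among kept behaviors.
NO_DOMINANT = -1


@dataclass
class SampleSeries:
    """Sequence of fixed-duration samples with composition encodings.

    ``composition[i, b]`` is the fraction of sample ``i``'s frames labeled
    behavior ``b``; rows sum to 1 for a freshly aggregated series and to
    <= 1 after :func:`drop_behaviors`.  ``first_frame[i, b]`` records the
    within-sample index of behavior ``b``'s first frame (used to break
    dominant-label ties toward the bout that starts earlier) or a sentinel
    when absent.
    """

    catalog: BehaviorCatalog
    start_s: np.ndarray
    composition: np.ndarray
    dominant: np.ndarray
    first_frame: np.ndarray
    sample_s: float = 3.0
    frames_per_sample: int = 100

    @property
    def n_samples(self) -> int:
        return int(self.composition.shape[0])


@dataclass
class WindowSet:
    """Overlapping windows of samples with day/night ground truth."""

    catalog: BehaviorCatalog
    sequential: np.ndarray  # (n_windows, window_len, catalog.size)
    labels: np.ndarray      # int8 phase codes, one per window
    start_s: np.ndarray
    window_len: int
    stride: int
    sample_s: float
    n_candidates: int       # windows before straddler dropping
    encoding: str = "composition"

    @property
    def n_windows(self) -> int:
        return int(self.sequential.shape[0])

    @property
    def flattened(self) -> np.ndarray:
        """Step-major flattening: (n_windows, window_len * catalog.size)."""
        return flatten_windows(self)

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.sequential).tobytes())
        h.update(np.ascontiguousarray(self.labels).tobytes())
        return h.hexdigest()[:16]

    def save(self, path, provenance: dict | None = None) -> None:
        """Persist as .npz plus a JSON provenance sidecar."""
        np.savez_compressed(
            path,
            sequential=self.sequential,
            labels=self.labels,
            start_s=self.start_s,
        )
        meta = {
            "catalog": list(self.catalog.names),
            "window_len": self.window_len,
            "stride": self.stride,
            "sample_s": self.sample_s,
            "n_candidates": self.n_candidates,
            "encoding": self.encoding,
            "content_hash": self.content_hash(),
        }
        if provenance:
            meta.update(provenance)
        with open(str(path) + ".json", "w", encoding="utf-8") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, path) -> "WindowSet":
        with np.load(path) as z:
            seq, labels, start_s = z["sequential"], z["labels"], z["start_s"]
        with open(str(path) + ".json", "r", encoding="utf-8") as fh:
            meta = json.load(fh)
        return cls(
            catalog=BehaviorCatalog(tuple(meta["catalog"])),
            sequential=seq, labels=labels, start_s=start_s,
            window_len=meta["window_len"], stride=meta["stride"],
            sample_s=meta["sample_s"], n_candidates=meta["n_candidates"],
            encoding=meta.get("encoding", "composition"),
        )


def aggregate_samples(
    stream: EthogramStream,
    fps: float,
    frames_per_sample: int = 100,
) -> SampleSeries:
    """Reduce a stream to fixed-length samples of consecutive frames.

    Each sample covers ``frames_per_sample`` frames; the trailing partial
    sample is discarded.  The dominant label is the behavior occupying the
    most frames, ties broken toward the behavior appearing earliest in the
    sample.
    """
    labels = frame_labels(stream, fps)
    n_samples = labels.size // frames_per_sample
    if n_samples < 1:
        raise ValueError("stream shorter than one sample")
    nb = stream.catalog.size
    lab2d = labels[: n_samples * frames_per_sample].reshape(n_samples, frames_per_sample)

    flat = lab2d.astype(np.int64) + np.arange(n_samples)[:, None] * nb
    counts = np.bincount(flat.ravel(), minlength=n_samples * nb).reshape(n_samples, nb)
    composition = counts.astype(np.float64) / frames_per_sample

    sentinel = frames_per_sample  # larger than any real frame index
    first = np.full((n_samples, nb), sentinel, dtype=np.int32)
    frame_idx = np.broadcast_to(
        np.arange(frames_per_sample, dtype=np.int32), lab2d.shape
    )
    np.minimum.at(first.reshape(-1), flat.ravel(), frame_idx.ravel())

    dominant = _dominant_from(counts, first)
    start_s = np.arange(n_samples, dtype=np.float64) * frames_per_sample / fps
    return SampleSeries(
        catalog=stream.catalog,
        start_s=start_s,
        composition=composition,
        dominant=dominant,
        first_frame=first,
        sample_s=frames_per_sample / fps,
        frames_per_sample=frames_per_sample,
    )


def _dominant_from(counts: np.ndarray, first: np.ndarray) -> np.ndarray:
    """Argmax of counts with ties broken by earliest first occurrence."""
    best = counts.max(axis=1, keepdims=True)
    # Rank candidates by (is-not-max, first_frame, behavior index).
    sentinel = first.max() + 1
    key = np.where(counts == best, first, sentinel)
    dominant = np.argmin(key, axis=1).astype(np.int32)
    dominant[best[:, 0] == 0] = NO_DOMINANT
    return dominant


def build_windows(
    samples: SampleSeries,
    schedule: PhaseSchedule,
    window_len: int = 100,
    stride: int = 1,
    *,
    encoding: str = "composition",
) -> WindowSet:
    """Assemble phase-pure overlapping windows from a sample series.

    Candidate windows start at samples 0, stride, 2*stride, ...; a window is
    kept only when the phase is constant at every constituent sample start,
    and its label is that phase.  ``encoding`` selects per-step features:
    the composition vector (default) or a one-hot of the dominant label.
    """
    if window_len < 1 or stride < 1:
        raise ValueError("window_len and stride must be >= 1")
    n = samples.n_samples
    if n < window_len:
        raise ValueError(f"need at least window_len={window_len} samples, have {n}")
    if encoding not in ("composition", "onehot"):
        raise ValueError(f"unknown encoding {encoding!r}")

    phases = phase_of(samples.start_s, schedule)
    changes = np.flatnonzero(np.diff(phases.astype(np.int8)) != 0)  # change after index c
    change_marker = np.zeros(n, dtype=np.int32)
    change_marker[changes + 1] = 1
    cum_changes = np.concatenate(([0], np.cumsum(change_marker)))

    starts = np.arange(0, n - window_len + 1, stride)
    n_candidates = starts.size
    # window [s, s+L) is phase-pure iff no change marker in (s, s+L)
    pure = (cum_changes[starts + window_len] - cum_changes[starts + 1]) == 0
    kept = starts[pure]

    if encoding == "composition":
        feats = samples.composition
    else:
        nb = samples.catalog.size
        feats = np.zeros((n, nb), dtype=np.float64)
        valid = samples.dominant >= 0
        feats[np.flatnonzero(valid), samples.dominant[valid]] = 1.0

    sw = np.lib.stride_tricks.sliding_window_view(feats, window_len, axis=0)
    # sw shape: (n - L + 1, nb, L) -> select kept, reorder to (w, L, nb)
    sequential = np.ascontiguousarray(sw[kept].transpose(0, 2, 1), dtype=np.float32)
    labels = phases[kept].astype(np.int8)
    return WindowSet(
        catalog=samples.catalog,
        sequential=sequential,
        labels=labels,
        start_s=samples.start_s[kept],
        window_len=window_len,
        stride=stride,
        sample_s=samples.sample_s,
        n_candidates=n_candidates,
        encoding=encoding,
    )


def flatten_windows(ws: WindowSet) -> np.ndarray:
    """Step-major flattening of the sequential array.

    Row ``w``, column ``t * catalog.size + b`` equals
    ``sequential[w, t, b]``; reshaping back is the exact inverse.
    """
    n, L, nb = ws.sequential.shape
    return ws.sequential.reshape(n, L * nb)


def drop_behaviors(samples: SampleSeries, keep) -> SampleSeries:
    """Restrict a sample series to a subset of behaviors, pre-windowing.

    Composition columns are restricted to ``keep`` (names or indices)
    without renormalization — time spent in a dropped behavior reads as
    absent activity, not redistributed.  The dominant label is recomputed
    over the kept behaviors; a sample fully occupied by dropped behaviors
    gets the reserved :data:`NO_DOMINANT` label.
    """
    keep_idx = [samples.catalog.index(b) if isinstance(b, str) else int(b) for b in keep]
    if not keep_idx:
        raise ValueError("keep must be a non-empty subset of the catalog")
    if len(set(keep_idx)) != len(keep_idx):
        raise ValueError("keep contains duplicates")
    for b in keep_idx:
        if not 0 <= b < samples.catalog.size:
            raise ValueError(f"behavior index {b} out of range")
    keep_idx = sorted(keep_idx)
    new_catalog = BehaviorCatalog(tuple(samples.catalog.names[b] for b in keep_idx))
    comp = samples.composition[:, keep_idx]
    first = samples.first_frame[:, keep_idx]
    counts = np.rint(comp * samples.frames_per_sample).astype(np.int64)
    dominant = _dominant_from(counts, first)
    return SampleSeries(
        catalog=new_catalog,
        start_s=samples.start_s,
        composition=comp,
        dominant=dominant,
        first_frame=first,
        sample_s=samples.sample_s,
        frames_per_sample=samples.frames_per_sample,
    )
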