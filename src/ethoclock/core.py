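"""Core domain types for home-cage ethogram streams.

A recording is modeled as an *ethogram stream*: a gapless, non-overlapping
sequence of behavior bouts drawn from a fixed catalog of activities, together
with a circadian phase schedule (the day/night ground truth of the light
cycle in the animal facility).  Everything downstream — frame-rate reduction,
windowing, classification — consumes these types.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DEFAULT_BEHAVIORS",
    "DAY",
    "NIGHT",
    "PHASE_NAMES",
    "BehaviorCatalog",
    "Bout",
    "EthogramStream",
    "PhaseSchedule",
    "StreamValidationError",
    "EthogramParseError",
    "validate_stream",
    "phase_of",
    "frame_labels",
    "read_ethogram_csv",
    "write_ethogram_csv",
    "read_catalog_txt",
]

# Integer phase codes used throughout; night is the positive class for
# classification because mice are nocturnal and night is the active phase.
DAY = 0
NIGHT = 1
PHASE_NAMES = ("day", "night")

SECONDS_PER_DAY = 86400.0

#: Default 37-activity catalog in the style of automated home-cage scoring
#: vocabularies.  The subset of names that matter scientifically (Sleep, the
#: exploratory repertoire, the hang/rear postures) is fixed; the remaining
#: entries are plausible home-cage activities chosen to fill the catalog.
DEFAULT_BEHAVIORS = (
    "Sleep",
    "Twitch",
    "Awaken",
    "Groom",
    "Eat",
    "Drink",
    "Forage",
    "Dig",
    "Walk.Left",
    "Walk.Right",
    "Walk.Slow",
    "Turn",
    "Circle",
    "Sniff",
    "Chew",
    "Jump",
    "Repeated.Jumping",
    "Rear.Up",
    "Remain.Rear.Up",
    "Come.Down",
    "Land.Vertical",
    "Hang.Cuddled",
    "remain.Hang.Cuddled",
    "Hang.Vertical",
    "Remain.Hang.Vertical",
    "Stretch",
    "Stretch.Body",
    "Pause",
    "Remain.Low",
    "Stationary",
    "Urinate",
    "Come.Down.To.Partially.Reared",
    "Rear.Up.From.Partially.Reared",
    "Remain.Partially.Reared",
    "Unknown.Behavior",
    "Sniff.Object",
    "Run",
)


class StreamValidationError(ValueError):
    """An ethogram stream violates a structural invariant."""


class EthogramParseError(ValueError):
    """An ethogram CSV file could not be parsed."""


@dataclass(frozen=True)
class BehaviorCatalog:
    """Ordered catalog of mutually exclusive behavioral activities."""

    names: tuple[str, ...] = DEFAULT_BEHAVIORS

    def __post_init__(self) -> None:
        names = tuple(self.names)
        object.__setattr__(self, "names", names)
        if not names:
            raise ValueError("catalog must contain at least one behavior")
        if any(not n for n in names):
            raise ValueError("behavior names must be non-empty")
        if len(set(names)) != len(names):
            raise ValueError("behavior names must be unique")

    @property
    def size(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown behavior name: {name!r}") from None

    def __len__(self) -> int:  # convenience, mirrors size
        return len(self.names)


@dataclass(frozen=True)
class Bout:
    """One maximal contiguous interval of a single behavior."""

    behavior: int
    start_s: float
    dur_s: float


@dataclass(frozen=True)
class PhaseSchedule:
    """Light-cycle ground truth: alternating day and night phases.

    Defaults follow a 10-h day / 14-h night regime with the first day onset
    at t = 0.
    """

    day_len_s: float = 36000.0
    night_len_s: float = 50400.0
    day_start_s: float = 0.0

    def __post_init__(self) -> None:
        if self.day_len_s <= 0 or self.night_len_s <= 0:
            raise ValueError("phase lengths must be positive")

    @property
    def period_s(self) -> float:
        return self.day_len_s + self.night_len_s


class EthogramStream:
    """Gapless run-length encoding of a behavioral recording.

    Bouts are stored as parallel numpy arrays (behavior index, start, and
    duration in seconds) so that multi-day recordings with hundreds of
    thousands of bouts stay cheap.  Consecutive bouts of the same behavior
    are merged on construction: a behavior change is what delimits a bout,
    so bout counts are well defined.
    """

    def __init__(
        self,
        catalog: BehaviorCatalog,
        behavior: np.ndarray,
        start_s: np.ndarray,
        dur_s: np.ndarray,
        total_s: float | None = None,
        *,
        merge: bool = True,
        validate: bool = True,
    ) -> None:
        behavior = np.asarray(behavior, dtype=np.int64)
        start_s = np.asarray(start_s, dtype=np.float64)
        dur_s = np.asarray(dur_s, dtype=np.float64)
        if not (behavior.shape == start_s.shape == dur_s.shape) or behavior.ndim != 1:
            raise ValueError("behavior, start_s and dur_s must be equal-length 1-D arrays")
        if behavior.size == 0:
            raise StreamValidationError("a stream must contain at least one bout")
        if merge and behavior.size > 1:
            keep = np.empty(behavior.size, dtype=bool)
            keep[0] = True
            np.not_equal(behavior[1:], behavior[:-1], out=keep[1:])
            if not keep.all():
                seg = np.flatnonzero(keep)
                merged_dur = np.add.reduceat(dur_s, seg)
                behavior, start_s, dur_s = behavior[seg], start_s[seg], merged_dur
        self.catalog = catalog
        self.behavior = behavior
        self.start_s = start_s
        self.dur_s = dur_s
        self.total_s = float(total_s) if total_s is not None else float(start_s[-1] + dur_s[-1])
        if validate:
            validate_stream(self)

    @classmethod
    def from_bouts(
        cls,
        catalog: BehaviorCatalog,
        bouts: list[Bout] | list[tuple],
        total_s: float | None = None,
        **kw,
    ) -> "EthogramStream":
        rows = [(b.behavior, b.start_s, b.dur_s) if isinstance(b, Bout) else tuple(b) for b in bouts]
        if not rows:
            raise StreamValidationError("a stream must contain at least one bout")
        beh, start, dur = (np.array(col) for col in zip(*rows))
        return cls(catalog, beh, start, dur, total_s, **kw)

    @property
    def n_bouts(self) -> int:
        return int(self.behavior.size)

    @property
    def end_s(self) -> np.ndarray:
        return self.start_s + self.dur_s

    def bouts(self) -> list[Bout]:
        """Materialize bouts as objects (intended for small streams)."""
        return [
            Bout(int(b), float(s), float(d))
            for b, s, d in zip(self.behavior, self.start_s, self.dur_s)
        ]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EthogramStream):
            return NotImplemented
        return (
            self.catalog == other.catalog
            and self.total_s == other.total_s
            and np.array_equal(self.behavior, other.behavior)
            and np.array_equal(self.start_s, other.start_s)
            and np.array_equal(self.dur_s, other.dur_s)
        )

    def __repr__(self) -> str:
        return (
            f"EthogramStream({self.n_bouts} bouts, {self.total_s:.1f} s, "
            f"{self.catalog.size} behaviors)"
        )


def validate_stream(stream: EthogramStream, atol_per_bout: float = 1e-9) -> EthogramStream:
    """Check all structural invariants of a stream, returning it unchanged.

    Raises :class:`StreamValidationError` naming the first offending bout
    index: non-positive durations, out-of-range behavior indices, a nonzero
    first start, gaps/overlaps between consecutive bouts, or a last bout not
    ending at ``total_s``.
    """
    beh, start, dur = stream.behavior, stream.start_s, stream.dur_s
    tol = atol_per_bout * max(stream.n_bouts, 1)
    bad = np.flatnonzero(dur <= 0)
    if bad.size:
        raise StreamValidationError(f"non-positive duration at bout {bad[0]} (dur_s={dur[bad[0]]})")
    bad = np.flatnonzero((beh < 0) | (beh >= stream.catalog.size))
    if bad.size:
        raise StreamValidationError(
            f"behavior index out of range at bout {bad[0]} (behavior={beh[bad[0]]})"
        )
    if abs(start[0]) > tol:
        raise StreamValidationError(f"first bout starts at {start[0]}, expected 0")
    if stream.n_bouts > 1:
        gap = start[1:] - (start[:-1] + dur[:-1])
        bad = np.flatnonzero(np.abs(gap) > tol)
        if bad.size:
            i = int(bad[0]) + 1
            kind = "gap" if gap[bad[0]] > 0 else "overlap"
            raise StreamValidationError(f"{kind} of {gap[bad[0]]:.6g} s before bout {i}")
    end = start[-1] + dur[-1]
    if abs(end - stream.total_s) > tol:
        raise StreamValidationError(
            f"last bout ends at {end:.6g} s but total_s is {stream.total_s:.6g}"
        )
    return stream


def phase_of(t_s, schedule: PhaseSchedule):
    """Phase code (DAY or NIGHT) at time ``t_s`` seconds; vectorized.

    Day iff ``(t_s - day_start_s) mod period < day_len_s``.  Negative times
    are rejected.
    """
    t = np.asarray(t_s, dtype=np.float64)
    if np.any(t < 0):
        raise ValueError("t_s must be nonnegative")
    in_cycle = np.mod(t - schedule.day_start_s, schedule.period_s)
    phase = np.where(in_cycle < schedule.day_len_s, DAY, NIGHT)
    if np.isscalar(t_s) or np.ndim(t_s) == 0:
        return int(phase)
    return phase.astype(np.int8)


def frame_labels(stream: EthogramStream, fps: float, *, chunk: int = 4_000_000) -> np.ndarray:
    """Per-frame behavior indices at a nominal frame rate.

    Frame ``i`` carries the behavior of the bout containing its midpoint
    time ``(i + 0.5) / fps`` (a frame whose midpoint falls exactly on a bout
    boundary belongs to the later bout).  Output length is
    ``floor(total_s * fps)``.
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    n_frames = int(np.floor(stream.total_s * fps))
    out = np.empty(n_frames, dtype=np.int16)
    starts = stream.start_s
    beh = stream.behavior.astype(np.int16)
    for lo in range(0, n_frames, chunk):
        hi = min(lo + chunk, n_frames)
        mid = (np.arange(lo, hi, dtype=np.float64) + 0.5) / fps
        idx = np.searchsorted(starts, mid, side="right") - 1
        out[lo:hi] = beh[idx]
    return out


# ---------------------------------------------------------------------------
# Plain-text interchange: ethogram CSV dialect
#
#   # catalog: name1,name2,...      (optional commented header block)
#   behavior,start_s,dur_s
#   Sleep,0.000,12.400
#
# Catalog may instead be supplied separately (one name per line).


def write_ethogram_csv(stream: EthogramStream, path, *, embed_catalog: bool = True) -> None:
    """Write a stream in the ethogram CSV dialect (UTF-8, embedded catalog)."""
    buf = io.StringIO()
    if embed_catalog:
        buf.write("# catalog: " + ",".join(stream.catalog.names) + "\n")
    buf.write(f"# total_s: {stream.total_s:.6f}\n")
    buf.write("behavior,start_s,dur_s\n")
    names = stream.catalog.names
    for b, s, d in zip(stream.behavior, stream.start_s, stream.dur_s):
        buf.write(f"{names[b]},{s:.6f},{d:.6f}\n")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(buf.getvalue())


def read_ethogram_csv(path, catalog: BehaviorCatalog | None = None) -> EthogramStream:
    """Read a stream from the ethogram CSV dialect.

    The catalog comes from the ``# catalog:`` header block unless supplied
    explicitly.  Malformed rows raise :class:`EthogramParseError` with the
    1-based line number.  Empty files are an error, not an empty stream.
    """
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.readlines()
    total_s = None
    header_seen = False
    beh_names: list[str] = []
    starts: list[float] = []
    durs: list[float] = []
    for ln, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("catalog:"):
                names = tuple(n.strip() for n in body[len("catalog:"):].split(","))
                file_catalog = BehaviorCatalog(names)
                if catalog is None:
                    catalog = file_catalog
                elif catalog.names != file_catalog.names:
                    raise EthogramParseError(
                        f"line {ln}: embedded catalog differs from the supplied catalog"
                    )
            elif body.startswith("total_s:"):
                total_s = float(body[len("total_s:"):])
            continue
        if not header_seen:
            if line != "behavior,start_s,dur_s":
                raise EthogramParseError(f"line {ln}: expected header 'behavior,start_s,dur_s'")
            header_seen = True
            continue
        parts = line.split(",")
        if len(parts) != 3:
            raise EthogramParseError(f"line {ln}: expected 3 columns, got {len(parts)}")
        if catalog is None:
            raise EthogramParseError("no catalog: supply one or embed a '# catalog:' header")
        name, s_str, d_str = parts
        try:
            b = catalog.index(name)
        except KeyError:
            raise EthogramParseError(f"line {ln}: unknown behavior name {name!r}") from None
        try:
            starts.append(float(s_str))
            durs.append(float(d_str))
        except ValueError:
            raise EthogramParseError(f"line {ln}: non-numeric time field") from None
        beh_names.append(b)
    if not header_seen or not beh_names:
        raise EthogramParseError("file contains no bout rows")
    return EthogramStream(
        catalog,
        np.array(beh_names),
        np.array(starts),
        np.array(durs),
        total_s,
    )


def read_catalog_txt(path) -> BehaviorCatalog:
    """Read a catalog from a one-name-per-line text file."""
    with open(path, "r", encoding="utf-8") as fh:
        names = tuple(line.strip() for line in fh if line.strip() and not line.startswith("#"))
    return BehaviorCatalog(names)
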