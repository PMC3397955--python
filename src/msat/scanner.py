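"""Detection of maximal perfect tandem-repeat tracks in read sequences.

A track is a maximal run with period ``u`` (no one-base extension left or
right preserves the periodicity) whose repeated unit is primitive and whose
number of complete units reaches the configured threshold: by default twelve
for homopolymers (u=1) and five for di- to hexanucleotide units.  Any
non-ACGT character hard-breaks tracks.  Coordinates are 0-based, half-open.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Iterable, Iterator, Mapping

import numpy as np

from msat.motifs import MAX_UNIT_LENGTH, canonical_name, is_primitive

logger = logging.getLogger(__name__)

DEFAULT_MIN_REPETITIONS: Mapping[int, int] = MappingProxyType(
    {1: 12, 2: 5, 3: 5, 4: 5, 5: 5, 6: 5}
)

_SEGMENT_RE = re.compile(r"[ACGT]+")


class ScanConfigError(ValueError):
    """Raised for invalid thresholds or unit lengths in a :class:`ScanConfig`."""


@dataclass(frozen=True)
class ScanConfig:
    """Scanner thresholds.

    ``min_repetitions`` maps unit length to the minimum number of complete
    units a run must contain; ``count_partial_units`` controls whether a
    trailing partial unit contributes to reported track length (qualification
    always uses complete units only).
    """

    min_repetitions: Mapping[int, int] = field(
        default_factory=lambda: dict(DEFAULT_MIN_REPETITIONS)
    )
    unit_lengths: frozenset[int] = frozenset(range(1, MAX_UNIT_LENGTH + 1))
    count_partial_units: bool = True

    def __post_init__(self) -> None:
        units = frozenset(self.unit_lengths)
        if not units:
            raise ScanConfigError("unit_lengths must be non-empty")
        if not units <= frozenset(range(1, MAX_UNIT_LENGTH + 1)):
            raise ScanConfigError(f"unit lengths must be within 1..{MAX_UNIT_LENGTH}")
        object.__setattr__(self, "unit_lengths", units)
        for u in units:
            if u not in self.min_repetitions:
                raise ScanConfigError(f"no threshold for unit length {u}")
            if self.min_repetitions[u] < 2:
                raise ScanConfigError(
                    f"threshold for unit length {u} must be >= 2, "
                    f"got {self.min_repetitions[u]}"
                )


@dataclass(frozen=True)
class RepeatTrack:
    """One maximal perfect tandem run in one read (0-based, half-open)."""

    seq_id: str
    start: int
    end: int
    unit_length: int
    canonical_motif: str
    n_full_units: int

    @property
    def track_len(self) -> int:
        return self.end - self.start


def _scan_segment(
    seq_id: str, segment: str, offset: int, cfg: ScanConfig, out: list[RepeatTrack]
) -> None:
    n = len(segment)
    arr = np.frombuffer(segment.encode("ascii"), dtype=np.uint8)
    for u in sorted(cfg.unit_lengths):
        min_rep = cfg.min_repetitions[u]
        if n < u * min_rep:
            continue
        match = arr[:-u] == arr[u:]
        # maximal runs of consecutive matches: run [a, b) in match space is
        # a maximal period-u substring [a, b + u) of the segment
        padded = np.empty(match.size + 2, dtype=bool)
        padded[0] = padded[-1] = False
        padded[1:-1] = match
        diff = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)
        for a, b in zip(starts.tolist(), ends.tolist()):
            track_len = b - a + u
            n_full = track_len // u
            if n_full < min_rep:
                continue
            unit = segment[a : a + u]
            if u > 1 and not is_primitive(unit):
                continue  # reported at its fundamental period instead
            end = b + u if cfg.count_partial_units else a + n_full * u
            out.append(
                RepeatTrack(
                    seq_id=seq_id,
                    start=offset + a,
                    end=offset + end,
                    unit_length=u,
                    canonical_motif=canonical_name(unit),
                    n_full_units=n_full,
                )
            )


def scan_sequence(
    seq_id: str, seq: str, cfg: ScanConfig | None = None
) -> list[RepeatTrack]:
    """All qualifying maximal perfect repeat tracks in one sequence.

    Tracks are sorted by start position, then unit length.  Lowercase input is
    upper-cased; non-ACGT characters terminate tracks.
    """
    if cfg is None:
        cfg = ScanConfig()
    tracks: list[RepeatTrack] = []
    seq = seq.upper()
    for m in _SEGMENT_RE.finditer(seq):
        _scan_segment(seq_id, m.group(), m.start(), cfg, tracks)
    tracks.sort(key=lambda t: (t.start, t.unit_length))
    return tracks


def scan_reads(
    reads: Iterable[tuple[str, str]], cfg: ScanConfig | None = None
) -> tuple[list[RepeatTrack], int, int]:
    """Scan a stream of ``(seq_id, sequence)`` pairs.

    Returns ``(tracks, total_bases, gc_count)`` where ``total_bases`` is the
    sum of read lengths and ``gc_count`` the number of G/C bases.  Unreadable
    records are skipped with a logged warning.
    """
    if cfg is None:
        cfg = ScanConfig()
    tracks: list[RepeatTrack] = []
    total_bases = 0
    gc_count = 0
    for record in reads:
        try:
            seq_id, seq = record
            seq = seq.upper()
            total_bases += len(seq)
            gc_count += seq.count("G") + seq.count("C")
        except (TypeError, ValueError) as exc:
            logger.warning("skipping unreadable record %r: %s", record, exc)
            continue
        tracks.extend(scan_sequence(seq_id, seq, cfg))
    return tracks, total_bases, gc_count


TRACK_COLUMNS = ("seq_id", "start", "end", "unit_length", "canonical_motif", "n_full_units")


def write_tracks_tsv(tracks: Iterable[RepeatTrack], path) -> None:
    """BED-like TSV of tracks; coordinates 0-based, half-open."""
    with open(path, "w") as fh:
        fh.write("# coordinates: 0-based, half-open\n")
        fh.write("\t".join(TRACK_COLUMNS) + "\n")
        for t in tracks:
            fh.write(
                f"{t.seq_id}\t{t.start}\t{t.end}\t{t.unit_length}"
                f"\t{t.canonical_motif}\t{t.n_full_units}\n"
            )


def read_tracks_tsv(path) -> Iterator[RepeatTrack]:
    with open(path) as fh:
        header_seen = False
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if not header_seen:
                if tuple(line.split("\t")) != TRACK_COLUMNS:
                    raise ValueError(f"unexpected track header in {path}: {line!r}")
                header_seen = True
                continue
            seq_id, start, end, u, motif, n_full = line.split("\t")
            yield RepeatTrack(seq_id, int(start), int(end), int(u), motif, int(n_full))
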