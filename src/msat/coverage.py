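"""Per-species microsatellite coverage and composition statistics.

Coverage is reported in bases of repeat track per Mb (1e6 bases) of sequence.
Homopolymer (unit length 1) tracks are tallied separately and excluded from
total microsatellite coverage unless explicitly included.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from msat.motifs import MAX_UNIT_LENGTH, canonical_name
from msat.scanner import RepeatTrack

logger = logging.getLogger(__name__)

MB = 1_000_000


class ProfileError(ValueError):
    """Raised for invalid species profile contents."""


@dataclass
class SpeciesProfile:
    """Per-species totals: sequence length, GC, and repeat bases by motif class."""

    species_id: str
    taxonomy: tuple[str, ...]
    total_bases: int
    gc_fraction: float
    bases_by_motif: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.total_bases <= 0:
            raise ProfileError(f"{self.species_id}: total_bases must be positive")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ProfileError(f"{self.species_id}: gc_fraction outside [0, 1]")
        for motif, count in self.bases_by_motif.items():
            if count < 0:
                raise ProfileError(f"{self.species_id}: negative count for {motif}")
            if canonical_name(motif) != motif:
                raise ProfileError(
                    f"{self.species_id}: {motif!r} is not a canonical motif name"
                )

    def bases_by_unit_length(self) -> dict[int, int]:
        out = {k: 0 for k in range(1, MAX_UNIT_LENGTH + 1)}
        for motif, count in self.bases_by_motif.items():
            out[len(motif)] += count
        return out


def build_profile(
    tracks: Iterable[RepeatTrack],
    total_bases: int,
    gc_count: int,
    species_id: str,
    taxonomy: Iterable[str] = (),
) -> SpeciesProfile:
    """Aggregate scanner tracks into a species profile."""
    if total_bases <= 0:
        raise ProfileError("total_bases must be positive")
    bases: dict[str, int] = {}
    for t in tracks:
        bases[t.canonical_motif] = bases.get(t.canonical_motif, 0) + t.track_len
    return SpeciesProfile(
        species_id=species_id,
        taxonomy=tuple(taxonomy),
        total_bases=total_bases,
        gc_fraction=gc_count / total_bases,
        bases_by_motif=bases,
    )


def total_coverage(p: SpeciesProfile, include_homopolymers: bool = False) -> float:
    """Microsatellite bases per Mb; unit lengths 2-6 unless homopolymers included."""
    by_len = p.bases_by_unit_length()
    lo = 1 if include_homopolymers else 2
    bases = sum(by_len[u] for u in range(lo, MAX_UNIT_LENGTH + 1))
    return bases / p.total_bases * MB


def homopolymer_coverage(p: SpeciesProfile) -> float:
    """Homopolymer bases per Mb."""
    return p.bases_by_unit_length()[1] / p.total_bases * MB


def composition_by_unit_length(p: SpeciesProfile) -> dict[int, float]:
    """Share of each unit length (1-6) in all repeat bases, homopolymers included.

    Sums to 1; an all-zero profile yields an empty map with a warning.
    """
    by_len = p.bases_by_unit_length()
    total = sum(by_len.values())
    if total == 0:
        logger.warning("%s: no repeat bases; composition undefined", p.species_id)
        return {}
    return {u: by_len[u] / total for u in by_len}


def motif_proportions(p: SpeciesProfile, k: int) -> dict[str, float]:
    """Share of each canonical motif within the unit-length-k repeat bases.

    Covers every class of length ``k`` (absent motifs get 0); sums to 1.  A
    zero denominator yields an empty map with a warning.
    """
    from msat.motifs import enumerate_classes

    classes = enumerate_classes(k)
    denom = sum(p.bases_by_motif.get(m, 0) for m in classes)
    if denom == 0:
        logger.warning(
            "%s: no unit-length-%d repeat bases; proportions undefined",
            p.species_id,
            k,
        )
        return {}
    return {m: p.bases_by_motif.get(m, 0) / denom for m in classes}


def gc_percent(gc_count: int, total_acgt_bases: int) -> float:
    """(G+C) / (A+C+G+T) as a proportion in [0, 1]."""
    if total_acgt_bases <= 0:
        raise ProfileError("total_acgt_bases must be positive")
    return gc_count / total_acgt_bases
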