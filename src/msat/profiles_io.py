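"""Species-profile CSV in the published survey-table layout.

One row per species: species name, free-text taxonomy columns, optional
contact, total sequence length, GC proportion, and one base-count column per
canonical motif (ordered by unit length, then alphabetically).  The reader
tolerates layout variation through a column-mapping override and ignorable
columns (e.g. per-unit-length aggregate counts, which are derivable).
"""

from __future__ import annotations

import re
from typing import Iterable, Mapping, Sequence

import pandas as pd

from msat.coverage import SpeciesProfile
from msat.motifs import MAX_UNIT_LENGTH, all_canonical_motifs, canonical_name

SPECIES_COL = "species"
TOTAL_BASES_COL = "total_bases"
GC_COL = "gc_fraction"
_TAXONOMY_PREFIX = "taxonomy"
_MOTIF_LIKE = re.compile(r"[ACGT]{1,6}", re.IGNORECASE)


class ProfileSchemaError(ValueError):
    """Raised when a profile CSV is missing mandatory columns."""


class UnknownMotifColumnError(ProfileSchemaError):
    """Raised when a motif-like column is not a canonical class name."""


def write_profiles_csv(
    profiles: Iterable[SpeciesProfile],
    path,
    max_unit_length: int = MAX_UNIT_LENGTH,
) -> None:
    profiles = list(profiles)
    n_tax = max((len(p.taxonomy) for p in profiles), default=0)
    tax_cols = [f"{_TAXONOMY_PREFIX}{i + 1}" for i in range(n_tax)]
    motifs = all_canonical_motifs(max_unit_length)
    rows = []
    for p in profiles:
        row: dict[str, object] = {SPECIES_COL: p.species_id}
        for col, label in zip(tax_cols, p.taxonomy):
            row[col] = label
        row[TOTAL_BASES_COL] = p.total_bases
        row[GC_COL] = p.gc_fraction
        for m in motifs:
            row[m] = p.bases_by_motif.get(m, 0)
        rows.append(row)
    columns = [SPECIES_COL, *tax_cols, TOTAL_BASES_COL, GC_COL, *motifs]
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


def read_profiles_csv(
    path,
    column_map: Mapping[str, str] | None = None,
    taxonomy_cols: Sequence[str] | None = None,
    ignore_cols: Sequence[str] = (),
) -> list[SpeciesProfile]:
    """Parse a profile CSV into :class:`SpeciesProfile` objects.

    ``column_map`` renames the mandatory columns, e.g.
    ``{"species": "Species name", "total_bases": "Total length", "gc_fraction": "GC"}``.
    ``taxonomy_cols`` names the taxonomy columns explicitly (default: every
    column starting with ``taxonomy``); ``ignore_cols`` are dropped unread.
    ``path`` may also be an already-parsed DataFrame.
    """
    df = path.copy() if isinstance(path, pd.DataFrame) else pd.read_csv(path)
    df = df.drop(columns=list(ignore_cols), errors="ignore")
    column_map = dict(column_map or {})
    rename = {v: k for k, v in column_map.items()}
    df = df.rename(columns=rename)

    for col in (SPECIES_COL, TOTAL_BASES_COL, GC_COL):
        if col not in df.columns:
            raise ProfileSchemaError(f"missing mandatory column {col!r} in {path}")
    if taxonomy_cols is None:
        tax_cols = [c for c in df.columns if c.lower().startswith(_TAXONOMY_PREFIX)]
    else:
        missing = [c for c in taxonomy_cols if c not in df.columns]
        if missing:
            raise ProfileSchemaError(f"taxonomy columns not found: {missing}")
        tax_cols = list(taxonomy_cols)

    known = {SPECIES_COL, TOTAL_BASES_COL, GC_COL, "contact", *tax_cols}
    motif_cols: list[str] = []
    for col in df.columns:
        if col in known:
            continue
        if _MOTIF_LIKE.fullmatch(col):
            name = col.upper()
            if canonical_name(name) != name:
                raise UnknownMotifColumnError(
                    f"column {col!r} is not a canonical motif name "
                    f"(expected e.g. {canonical_name(name)!r})"
                )
            motif_cols.append(col)
        else:
            raise ProfileSchemaError(
                f"unrecognized column {col!r}; rename it via column_map, list it "
                f"in taxonomy_cols, or drop it via ignore_cols"
            )

    profiles: list[SpeciesProfile] = []
    for _, row in df.iterrows():
        counts: dict[str, int] = {}
        for col in motif_cols:
            value = row[col]
            count = 0 if pd.isna(value) else int(value)
            if count < 0:
                raise ProfileSchemaError(
                    f"negative count for motif {col!r}, species {row[SPECIES_COL]!r}"
                )
            if count:
                counts[col.upper()] = count
        taxonomy = tuple(
            "" if pd.isna(row[c]) else str(row[c]) for c in tax_cols
        )
        profiles.append(
            SpeciesProfile(
                species_id=str(row[SPECIES_COL]),
                taxonomy=taxonomy,
                total_bases=int(row[TOTAL_BASES_COL]),
                gc_fraction=float(row[GC_COL]),
                bases_by_motif=counts,
            )
        )
    return profiles


def matches_taxon(profile: SpeciesProfile, *labels: str) -> bool:
    """True if any taxonomy field (case-insensitive) equals one of ``labels``."""
    wanted = {label.strip().lower() for label in labels}
    return any(t.strip().lower() in wanted for t in profile.taxonomy)


def select_profiles(
    profiles: Iterable[SpeciesProfile],
    include: Sequence[str],
    exclude: Sequence[str] = (),
) -> list[SpeciesProfile]:
    """Profiles whose taxonomy matches any ``include`` label and no ``exclude``."""
    return [
        p
        for p in profiles
        if matches_taxon(p, *include) and not (exclude and matches_taxon(p, *exclude))
    ]
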