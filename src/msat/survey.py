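"""Cross-species survey workflows over profile tables.

Thin compositions of :mod:`msat.coverage` and :mod:`msat.phylo` used to
compare taxonomic groups in a multi-species profile table: rank-sum tests of
coverage between groups, motif-share vs GC correlations, composition counts,
and Moran's I on a label-defined clade partition.
"""

from __future__ import annotations

import math
import re
from typing import Iterable, Sequence

import pandas as pd

from msat.coverage import SpeciesProfile, total_coverage
from msat.phylo import CladePartition, CorrelogramPoint, morans_i, spearman_rho, wilcoxon_rank_sum
from msat.profiles_io import matches_taxon, select_profiles

def load_survey_table(path) -> list[SpeciesProfile]:
    """Load a published-style survey table with heuristic column mapping.

    Expected layout: species name first, free-text taxonomy columns, optional
    contact column, a total-sequence-length column (header containing
    "length" or "total"), a GC-proportion column (header containing "gc"),
    canonical-motif base-count columns, and optional per-unit-length
    aggregate count columns (numeric, non-motif headers), which are ignored
    because they are derivable.
    """
    from msat.profiles_io import read_profiles_csv

    df = pd.read_csv(path)
    df.columns = [str(c).strip() for c in df.columns]
    cols = list(df.columns)
    species_col = cols[0]
    gc_col = next((c for c in cols if "gc" in c.lower()), None)
    total_col = next(
        (c for c in cols[1:] if "length" in c.lower() or "total" in c.lower()), None
    )
    if gc_col is None or total_col is None:
        raise ValueError(f"{path}: could not locate GC / total-length columns")
    if df[gc_col].max() > 1.0:  # table prints GC as percent
        df[gc_col] = df[gc_col] / 100.0

    motif_like = re.compile(r"[ACGT]{1,6}")
    taxonomy_cols, ignore_cols = [], []
    for c in cols:
        if c in (species_col, gc_col, total_col) or motif_like.fullmatch(c.upper()):
            continue
        if "contact" in c.lower():
            ignore_cols.append(c)
        elif pd.api.types.is_numeric_dtype(df[c]):
            ignore_cols.append(c)  # derivable aggregate counts
        else:
            taxonomy_cols.append(c)
    return read_profiles_csv(
        df,
        column_map={
            "species": species_col,
            "total_bases": total_col,
            "gc_fraction": gc_col,
        },
        taxonomy_cols=taxonomy_cols,
        ignore_cols=ignore_cols,
    )


# common label groups for taxonomy-column selection
METAZOAN_PHYLA = (
    "Metazoa", "Cnidaria", "Arthropoda", "Onychophora", "Bryozoa",
    "Mollusca", "Echinodermata", "Chordata",
)
PLANT_PHYLA = ("Streptophyta", "Spermatophyta")
RAY_FINNED_FISH = ("Actinopterygii", "Actinopterigii")
TETRAPOD_LABELS = (
    "Tetrapoda", "Amphibia", "Aves", "Mammalia", "Reptilia",
    "Squamata", "Testudines", "Crocodylia", "Sphenodontia",
)
FLOWERING_PLANTS = ("Magnoliophyta", "Angiospermae")
NON_FLOWERING_SEED_PLANTS = (
    "Coniferophyta", "Cycadophyta", "Pinophyta", "Coniferopsida", "Cycadopsida",
)


def coverage_values(
    profiles: Iterable[SpeciesProfile], include_homopolymers: bool = False
) -> list[float]:
    return [total_coverage(p, include_homopolymers) for p in profiles]


def wilcoxon_between_groups(
    profiles: Sequence[SpeciesProfile],
    labels1: Sequence[str],
    labels2: Sequence[str],
    include_homopolymers: bool = False,
) -> tuple[float, float, int, int]:
    """Rank-sum W (group 1 first) and p for total coverage between label groups."""
    g1 = select_profiles(profiles, labels1)
    g2 = select_profiles(profiles, labels2)
    w, p = wilcoxon_rank_sum(
        coverage_values(g1, include_homopolymers),
        coverage_values(g2, include_homopolymers),
    )
    return w, p, len(g1), len(g2)


def _share(p: SpeciesProfile, numerator: Sequence[str], pool: Sequence[str]) -> float | None:
    denom = sum(p.bases_by_motif.get(m, 0) for m in pool)
    if denom == 0:
        return None
    return sum(p.bases_by_motif.get(m, 0) for m in numerator) / denom


def motif_share_vs_gc(
    profiles: Sequence[SpeciesProfile],
    numerator: Sequence[str],
    pool: Sequence[str],
) -> tuple[float, float, int]:
    """Spearman rho/p of a motif-share (within ``pool``) against GC fraction.

    Species with an empty pool are dropped; returns the n actually used.
    """
    shares, gcs = [], []
    for p in profiles:
        share = _share(p, numerator, pool)
        if share is not None:
            shares.append(share)
            gcs.append(p.gc_fraction)
    rho, pval = spearman_rho(shares, gcs)
    return rho, pval, len(shares)


def count_unit_length_dominant(
    profiles: Sequence[SpeciesProfile], unit_length: int = 2
) -> int:
    """Species where one unit-length class holds the strictly largest base count
    (homopolymers take part in the comparison)."""
    n = 0
    for p in profiles:
        by_len = p.bases_by_unit_length()
        target = by_len[unit_length]
        if all(target > v for u, v in by_len.items() if u != unit_length):
            n += 1
    return n


def count_unit_length_majority(
    profiles: Sequence[SpeciesProfile], unit_length: int = 2
) -> int:
    """Species where one di-hexa class exceeds the sum of the other di-hexa classes."""
    n = 0
    for p in profiles:
        by_len = p.bases_by_unit_length()
        others = sum(v for u, v in by_len.items() if u >= 2 and u != unit_length)
        if by_len[unit_length] > others:
            n += 1
    return n


def count_motif_share_above(
    profiles: Sequence[SpeciesProfile],
    motif: str,
    pool: Sequence[str],
    threshold: float,
) -> int:
    """Species whose ``motif`` share of the ``pool`` bases exceeds ``threshold``."""
    n = 0
    for p in profiles:
        share = _share(p, [motif], pool)
        if share is not None and share > threshold:
            n += 1
    return n


def labeled_partition(
    profiles: Sequence[SpeciesProfile],
    clade_labels: Sequence[Sequence[str]],
    cutoff_mya: float,
) -> CladePartition:
    """Clade partition defined by taxonomy labels instead of a tree.

    ``clade_labels[i]`` lists the labels whose species form clade ``i``; every
    profile must match exactly one group.
    """
    clade_of: dict[str, int] = {}
    for p in profiles:
        hits = [i for i, labels in enumerate(clade_labels) if matches_taxon(p, *labels)]
        if len(hits) != 1:
            raise ValueError(
                f"{p.species_id}: matches {len(hits)} clade label groups, expected 1"
            )
        clade_of[p.species_id] = hits[0]
    return CladePartition(
        cutoff_mya=cutoff_mya, clade_of=clade_of, n_clades=len(clade_labels)
    )


def morans_i_log_coverage(
    profiles: Sequence[SpeciesProfile],
    part: CladePartition,
    include_homopolymers: bool = False,
) -> CorrelogramPoint:
    """Moran's I of natural-log total coverage under a clade partition."""
    values = {
        p.species_id: math.log(total_coverage(p, include_homopolymers))
        for p in profiles
        if p.species_id in part.clade_of
    }
    return morans_i(values, part)
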