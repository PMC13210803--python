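"""Barcode species-support layer for two-species alignments.

The barcode question is whether two nominal species are separable by a
"barcode gap": the maximum within-species p-distance falling below the
minimum between-species p-distance.  The workflow here mirrors standard
ITS barcoding practice on a pre-aligned matrix:

1. extract the shared gap-free core (drop every column in which any sequence
   carries ``-``);
2. compute uncorrected p-distances on the core with pairwise deletion of
   ``N`` sites;
3. collapse haplotypes per species, locate fixed diagnostic sites, and check
   the gap.

Coordinates are 0-based half-open internally; reports print 1-based
positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .io import SeqAlignment, ValidationError

__all__ = [
    "extract_gapfree_core",
    "p_distance",
    "collapse_haplotypes",
    "diagnostic_sites",
    "species_summary",
    "SpeciesDistanceSummary",
]


@dataclass(frozen=True)
class SpeciesDistanceSummary:
    """Distance-based species-support summary for a two-species comparison.

    ``within_range`` maps each species to its (min, max) within-species
    p-distance; a species with fewer than two sequences is reported as
    ``(0.0, 0.0)`` and listed in ``degenerate_within``.
    ``barcode_gap_present`` is true when the largest within-species distance
    is strictly below the smallest between-species distance.
    """

    core_length: int
    n_per_species: dict[str, int]
    haplotypes_per_species: dict[str, int]
    within_range: dict[str, tuple[float, float]]
    between_range: tuple[float, float]
    diagnostic_sites: tuple[int, ...]
    barcode_gap_present: bool
    degenerate_within: frozenset[str] = frozenset()


def extract_gapfree_core(a: SeqAlignment) -> SeqAlignment:
    """Keep exactly the columns in which no sequence has a gap.

    Column order is preserved; the 0-based indices of the removed columns are
    recorded in ``provenance``.  Raises if every column contains a gap
    somewhere.
    """
    arr = a.as_array()
    keep = ~(arr == "-").any(axis=0)
    if not keep.any():
        raise ValidationError("gap-free core is empty: every column has a gap")
    removed = np.flatnonzero(~keep)
    rows = tuple("".join(r) for r in arr[:, keep])
    note = "removed_gap_columns=" + ",".join(map(str, removed.tolist()))
    return SeqAlignment(a.names, a.species_labels, rows,
                        provenance=a.provenance + (note,))


def p_distance(s1: str, s2: str) -> float:
    """Uncorrected proportion of differing sites between two core sequences.

    Sites where either sequence is ``N`` are dropped from numerator and
    denominator (pairwise deletion).  Sequences must be equal-length and
    gap-free (run :func:`extract_gapfree_core` first).
    """
    if len(s1) != len(s2):
        raise ValidationError(f"length mismatch: {len(s1)} vs {len(s2)}")
    a = np.frombuffer(s1.upper().encode(), dtype="S1")
    b = np.frombuffer(s2.upper().encode(), dtype="S1")
    if b"-" in a.tobytes() or b"-" in b.tobytes():
        raise ValidationError("p_distance requires gap-free sequences")
    comparable = (a != b"N") & (b != b"N")
    n = int(comparable.sum())
    if n == 0:
        raise ValidationError("no comparable (non-N) sites")
    return float(np.sum(a[comparable] != b[comparable]) / n)


def collapse_haplotypes(a: SeqAlignment, species: str) -> int:
    """Number of distinct core sequences among members of one species."""
    return len(set(a.rows_of(species)))


def diagnostic_sites(a: SeqAlignment, sp_a: str, sp_b: str) -> list[int]:
    """0-based columns fixed within each species and different between them.

    A column qualifies when every ``sp_a`` sequence shares one state, every
    ``sp_b`` sequence shares another state, and the two states differ.  An
    ``N`` in any sequence of either species disqualifies the column.
    """
    rows_a = np.array([list(r) for r in a.rows_of(sp_a)], dtype="U1")
    rows_b = np.array([list(r) for r in a.rows_of(sp_b)], dtype="U1")
    fixed_a = (rows_a == rows_a[0]).all(axis=0)
    fixed_b = (rows_b == rows_b[0]).all(axis=0)
    no_n = ~((rows_a == "N").any(axis=0) | (rows_b == "N").any(axis=0))
    diff = rows_a[0] != rows_b[0]
    return np.flatnonzero(fixed_a & fixed_b & no_n & diff).tolist()


def _range(values: list[float]) -> tuple[float, float]:
    return (min(values), max(values))


def species_summary(a: SeqAlignment, sp_a: str, sp_b: str) -> SpeciesDistanceSummary:
    """Full barcode-gap summary for the ``sp_a`` vs ``sp_b`` comparison.

    The alignment must already be core-extracted (gap-free).  Within-species
    ranges cover all within-species pairs; the between range covers all
    cross-species pairs.
    """
    if sp_a == sp_b:
        raise ValidationError("species_summary needs two distinct species labels")
    groups = {sp: a.rows_of(sp) for sp in (sp_a, sp_b)}
    within: dict[str, tuple[float, float]] = {}
    degenerate: set[str] = set()
    for sp, rows in groups.items():
        if len(rows) < 2:
            within[sp] = (0.0, 0.0)
            degenerate.add(sp)
        else:
            within[sp] = _range([p_distance(x, y) for x, y in combinations(rows, 2)])
    between = _range(
        [p_distance(x, y) for x in groups[sp_a] for y in groups[sp_b]]
    )
    sites = diagnostic_sites(a, sp_a, sp_b)
    max_within = max(hi for _, hi in within.values())
    return SpeciesDistanceSummary(
        core_length=a.column_count,
        n_per_species={sp: len(rows) for sp, rows in groups.items()},
        haplotypes_per_species={sp: collapse_haplotypes(a, sp) for sp in groups},
        within_range=within,
        between_range=between,
        diagnostic_sites=tuple(sites),
        barcode_gap_present=max_within < between[0],
        degenerate_within=frozenset(degenerate),
    )
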