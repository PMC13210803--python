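"""Readers, writers and validated containers for band matrices and alignments.

Two container types carry everything downstream:

* :class:`BandMatrix` — an individuals x loci 0/1 presence/absence matrix with
  population labels and an optional locus -> primer map.  This is the universe
  of the dominant-marker (ISSR-style) population layer.
* :class:`SeqAlignment` — species-labelled, equal-length aligned sequences over
  ``{A, C, G, T, N, -}``.  This is the universe of the barcode layer.

Band matrices are stored on disk as a "long" CSV
(``sample_id,population,<locus_1>,...``); a second reader dialect tolerates a
GenAlEx-style binary export (two numeric/title header lines before the column
header), since dominant-marker matrices are commonly curated for GenAlEx.
Missing data are rejected rather than imputed: only unambiguous 0/1 calls are
modelled.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "BandMatrix",
    "SeqAlignment",
    "ValidationError",
    "read_band_matrix",
    "write_band_matrix",
    "read_alignment",
    "write_alignment",
    "read_primer_map",
    "write_primer_map",
    "subset_samples",
]

#: characters allowed in an aligned sequence (no IUPAC ambiguity expansion)
ALIGNMENT_ALPHABET = frozenset("ACGTN-")


class ValidationError(ValueError):
    """Raised when an input file or container violates its invariants."""


@dataclass(frozen=True)
class BandMatrix:
    """Individuals x loci binary band matrix with population labels.

    Parameters
    ----------
    sample_ids
        Unique identifier per row.
    population_labels
        One population label per row (same order as ``sample_ids``).
    locus_ids
        Unique identifier per column.
    values
        ``(n_samples, n_loci)`` array of exactly 0/1.
    primer_of_locus
        Optional map ``locus_id -> primer name`` covering every locus.
    """

    sample_ids: tuple[str, ...]
    population_labels: tuple[str, ...]
    locus_ids: tuple[str, ...]
    values: np.ndarray
    primer_of_locus: dict[str, str] | None = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.ndim != 2:
            raise ValidationError("values must be a 2-D sample x locus matrix")
        object.__setattr__(self, "values", vals.astype(np.int8, copy=False))
        n, L = vals.shape
        if len(self.sample_ids) != n:
            raise ValidationError(
                f"{len(self.sample_ids)} sample ids for {n} matrix rows"
            )
        if len(self.population_labels) != n:
            raise ValidationError(
                f"{len(self.population_labels)} population labels for {n} rows"
            )
        if len(self.locus_ids) != L:
            raise ValidationError(f"{len(self.locus_ids)} locus ids for {L} columns")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample ids")
        if len(set(self.locus_ids)) != L:
            raise ValidationError("duplicate locus ids")
        if any(not str(p).strip() for p in self.population_labels):
            raise ValidationError("missing population label")
        bad = np.argwhere((vals != 0) & (vals != 1))
        if bad.size:
            i, j = bad[0]
            raise ValidationError(
                f"non-binary cell at sample {self.sample_ids[i]!r}, "
                f"locus {self.locus_ids[j]!r}: {vals[i, j]!r}"
            )
        if self.primer_of_locus is not None:
            missing = [l for l in self.locus_ids if l not in self.primer_of_locus]
            if missing:
                raise ValidationError(f"loci without a primer assignment: {missing[:5]}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_loci(self) -> int:
        return self.values.shape[1]

    @property
    def populations(self) -> tuple[str, ...]:
        """Distinct population labels in first-appearance order."""
        seen: dict[str, None] = {}
        for p in self.population_labels:
            seen.setdefault(p, None)
        return tuple(seen)

    def rows_of(self, population: str) -> np.ndarray:
        """Boolean row mask for one population label."""
        if population not in self.population_labels:
            raise KeyError(f"unknown population {population!r}")
        return np.asarray([p == population for p in self.population_labels])

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.locus_ids))
        df.insert(0, "population", list(self.population_labels))
        df.insert(0, "sample_id", list(self.sample_ids))
        return df


@dataclass(frozen=True)
class SeqAlignment:
    """Equal-length aligned sequences with one species label per sequence."""

    names: tuple[str, ...]
    species_labels: tuple[str, ...]
    rows: tuple[str, ...]
    provenance: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValidationError("empty alignment")
        if len({len(r) for r in self.rows}) != 1:
            lengths = sorted({len(r) for r in self.rows})
            raise ValidationError(f"ragged alignment: row lengths {lengths}")
        if len(self.names) != len(self.rows) or len(self.species_labels) != len(self.rows):
            raise ValidationError("names/species_labels/rows length mismatch")
        rows = tuple(r.upper() for r in self.rows)
        for name, row in zip(self.names, rows):
            bad = set(row) - ALIGNMENT_ALPHABET
            if bad:
                raise ValidationError(
                    f"sequence {name!r} contains characters outside "
                    f"{{A,C,G,T,N,-}}: {sorted(bad)}"
                )
        object.__setattr__(self, "rows", rows)

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    @property
    def column_count(self) -> int:
        return len(self.rows[0])

    @property
    def species(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for s in self.species_labels:
            seen.setdefault(s, None)
        return tuple(seen)

    def rows_of(self, species: str) -> tuple[str, ...]:
        if species not in self.species_labels:
            raise KeyError(f"unknown species label {species!r}")
        return tuple(r for r, s in zip(self.rows, self.species_labels) if s == species)

    def as_array(self) -> np.ndarray:
        """View as a (n_sequences, column_count) character array."""
        return np.array([list(r) for r in self.rows], dtype="U1")


# ---------------------------------------------------------------------------
# band-matrix CSV dialects
# ---------------------------------------------------------------------------

def _frame_to_matrix(df: pd.DataFrame, primer_of_locus=None) -> BandMatrix:
    if df.shape[1] < 3:
        raise ValidationError("band matrix needs sample_id, population and >=1 locus")
    sample_ids = tuple(str(s) for s in df.iloc[:, 0])
    populations = tuple("" if pd.isna(p) else str(p) for p in df.iloc[:, 1])
    locus_ids = tuple(str(c) for c in df.columns[2:])
    body = df.iloc[:, 2:]
    try:
        vals = body.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-numeric cell in band matrix: {exc}") from exc
    if np.isnan(vals).any():
        i, j = np.argwhere(np.isnan(vals))[0]
        raise ValidationError(
            f"missing value at sample {sample_ids[i]!r}, locus {locus_ids[j]!r}"
        )
    return BandMatrix(sample_ids, populations, locus_ids, vals,
                      primer_of_locus=primer_of_locus)


def read_band_matrix(
    path: str | Path,
    dialect: str = "long_csv",
    primer_of_locus: Mapping[str, str] | None = None,
) -> BandMatrix:
    """Read a 0/1 band matrix.

    ``dialect`` is one of:

    ``"long_csv"``
        Header ``sample_id,population,<locus>...``, one row per individual.
    ``"genalex_like"``
        Two extra leading header lines (counts line, then title/population
        line) before the same column header, as produced by GenAlEx binary
        exports.
    ``"auto"``
        Try ``long_csv`` first, then ``genalex_like``.
    """
    path = Path(path)
    primers = dict(primer_of_locus) if primer_of_locus is not None else None
    if dialect == "auto":
        try:
            return read_band_matrix(path, "long_csv", primers)
        except (ValidationError, ValueError):
            return read_band_matrix(path, "genalex_like", primers)
    text = path.read_text()
    if not text.strip():
        raise ValidationError(f"empty band-matrix file: {path}")
    if dialect == "long_csv":
        df = pd.read_csv(_stdio.StringIO(text))
    elif dialect == "genalex_like":
        lines = text.splitlines()
        if len(lines) < 4:
            raise ValidationError("genalex_like file needs 2 header lines + table")
        df = pd.read_csv(_stdio.StringIO("\n".join(lines[2:])))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return _frame_to_matrix(df, primers)


def write_band_matrix(m: BandMatrix, path: str | Path, dialect: str = "long_csv") -> None:
    """Write ``m`` in the given dialect (inverse of :func:`read_band_matrix`)."""
    path = Path(path)
    df = m.to_dataframe()
    if dialect == "long_csv":
        df.to_csv(path, index=False)
    elif dialect == "genalex_like":
        sizes = [int(np.sum(m.rows_of(p))) for p in m.populations]
        counts = [m.n_loci, m.n_samples, len(m.populations), *sizes]
        width = df.shape[1]
        line1 = ",".join(str(c) for c in counts[:width]).ljust(0)
        line2 = ",".join(["band matrix", ""] + list(m.populations))[: 10_000]
        body = df.to_csv(index=False)
        path.write_text(f"{line1}\n{line2}\n{body}")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_primer_map(path: str | Path) -> dict[str, str]:
    """Read a two-column ``locus_id,primer`` CSV into a dict."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValidationError("primer map needs locus_id and primer columns")
    return {str(l): str(p) for l, p in zip(df.iloc[:, 0], df.iloc[:, 1])}


def write_primer_map(primer_of_locus: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"locus_id": list(primer_of_locus), "primer": list(primer_of_locus.values())}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

def _species_from_header(name: str) -> str:
    """Default label parser: last '|'-separated field of the FASTA id."""
    return name.rsplit("|", 1)[-1] if "|" in name else name


def read_alignment(
    path: str | Path,
    species_map: Mapping[str, str] | None = None,
    label_parser: Callable[[str], str] | None = None,
) -> SeqAlignment:
    """Read an aligned FASTA file into a :class:`SeqAlignment`.

    Species labels come from ``species_map`` (sequence id -> species) when
    given, else from ``label_parser`` applied to each id, else from the last
    ``|``-separated field of the id.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) < 2:
        raise ValidationError(f"alignment {path} has {len(records)} record(s); need >=2")
    names = tuple(r.id for r in records)
    rows = tuple(str(r.seq).upper() for r in records)
    if species_map is not None:
        missing = [n for n in names if n not in species_map]
        if missing:
            raise ValidationError(f"no species label for sequences: {missing[:5]}")
        labels = tuple(species_map[n] for n in names)
    else:
        parse = label_parser or _species_from_header
        labels = tuple(parse(n) for n in names)
    return SeqAlignment(names, labels, rows)


def write_alignment(a: SeqAlignment, path: str | Path) -> None:
    """Write a FASTA with ``id|species`` headers (re-readable by default)."""
    with open(path, "w") as fh:
        for name, sp, row in zip(a.names, a.species_labels, a.rows):
            header = name if name.endswith(f"|{sp}") else f"{name}|{sp}"
            fh.write(f">{header}\n{row}\n")


def subset_samples(m: BandMatrix, keep) -> BandMatrix:
    """Filter rows by population label; loci are untouched.

    ``keep`` is either a predicate on the population label or an iterable of
    labels to retain.  Used to drop interspecific reference rows before every
    population-level analysis.
    """
    if callable(keep):
        pred = keep
    else:
        wanted = set(keep)
        pred = lambda p: p in wanted  # noqa: E731
    mask = np.asarray([bool(pred(p)) for p in m.population_labels])
    if not mask.any():
        raise ValidationError("subset_samples would retain no samples")
    return BandMatrix(
        tuple(s for s, k in zip(m.sample_ids, mask) if k),
        tuple(p for p, k in zip(m.population_labels, mask) if k),
        m.locus_ids,
        m.values[mask],
        primer_of_locus=m.primer_of_locus,
    )
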