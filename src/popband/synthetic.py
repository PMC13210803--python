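"""Synthetic data generators for the band-matrix and barcode layers.

Two generators make every pipeline stage testable without any external data:

* :func:`simulate_band_matrix` draws multi-population dominant-marker band
  matrices under the Balding-Nichols construction.  Each locus has an
  ancestral null-allele frequency q0 ~ Beta(a, b); each population draws its
  own q_g ~ Beta(q0 (1-F)/F, (1-q0)(1-F)/F), where F is a single
  differentiation knob comparable to Phi_PT (F = 0 means q_g = q0).  Under
  Hardy-Weinberg equilibrium a dominant band is present with probability
  1 - q_g^2.  The true q_g matrix is returned for parameter-recovery tests.

* :func:`simulate_barcode_alignment` builds two-species ITS-like alignments
  with an exact number of fixed diagnostic sites, optional non-diagnostic
  within-species variant sequences, and a chosen number of gap-containing
  columns, so core extraction, diagnostic-site counting and p-distances have
  analytically known outputs.

The default band-matrix configuration mirrors a realistic regional survey of
a fragmented mangrove species: four populations (CG/DN/PQ/CD) of 30/30/30/20
individuals, 81 loci spread over a 12-primer panel with loci-per-primer
counts (8,9,8,8,7,5,3,6,6,9,11,1), differentiation F = 0.25 and ancestral
q0 ~ Beta(2,2) (pooled expected gene diversity around 0.4).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import BandMatrix, SeqAlignment

__all__ = [
    "SyntheticPopGenConfig",
    "SyntheticBarcodeConfig",
    "simulate_band_matrix",
    "simulate_barcode_alignment",
    "write_truth",
    "STUDY_PRIMER_COUNTS",
]

#: loci-per-primer counts of the default 12-primer panel
STUDY_PRIMER_COUNTS: dict[str, int] = {
    "808": 8, "823": 9, "836": 8, "840": 8, "841": 7, "842": 5,
    "844": 3, "845": 6, "868": 6, "873": 9, "874": 11, "876": 1,
}

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SyntheticPopGenConfig:
    """Configuration for a Balding-Nichols dominant-marker simulation."""

    population_names: tuple[str, ...] = ("CG", "DN", "PQ", "CD")
    n_per_population: tuple[int, ...] = (30, 30, 30, 20)
    n_loci: int = 81
    primer_counts: dict[str, int] = field(
        default_factory=lambda: dict(STUDY_PRIMER_COUNTS))
    ancestral_beta: tuple[float, float] = (2.0, 2.0)
    fst: float = 0.25
    n_reference: int = 0            # extra off-target reference rows
    reference_label: str = "CT"
    seed: int = 20260510

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if len(self.population_names) != len(self.n_per_population):
            raise ValueError("population names/sizes length mismatch")
        if any(n < 2 for n in self.n_per_population):
            raise ValueError("every population needs >= 2 samples")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError("fst must be in [0, 1)")
        a, b = self.ancestral_beta
        if a <= 0 or b <= 0:
            raise ValueError("degenerate beta parameters")
        if self.primer_counts is not None and sum(self.primer_counts.values()) != self.n_loci:
            raise ValueError("primer_counts must sum to n_loci")


@dataclass(frozen=True)
class SyntheticBarcodeConfig:
    """Configuration for a two-species alignment with known structure."""

    n_species_a: int = 14
    n_species_b: int = 2
    label_a: str = "littorea"
    label_b: str = "racemosa"
    core_length: int = 697
    n_diagnostic: int = 32
    n_gap_columns: int = 17
    n_variants_a: int = 0           # within-species variant sequences
    n_variants_b: int = 0
    subs_per_variant: int = 0
    seed: int = 20260510

    def __post_init__(self) -> None:
        if self.n_species_a < 1 or self.n_species_b < 1:
            raise ValueError("need >= 1 sequence per species")
        if self.n_diagnostic > self.core_length:
            raise ValueError("n_diagnostic exceeds core_length")
        if self.n_variants_a > self.n_species_a or self.n_variants_b > self.n_species_b:
            raise ValueError("more variant sequences than sequences")


def simulate_band_matrix(cfg: SyntheticPopGenConfig) -> tuple[BandMatrix, dict]:
    """Draw a band matrix; returns ``(matrix, truth)``.

    ``truth`` holds the ancestral ``q0`` (per locus), the per-population
    null-allele frequencies ``q`` (populations x loci) and band-presence
    probabilities ``band_prob``.  Deterministic per ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    a, b = cfg.ancestral_beta
    L = cfg.n_loci
    q0 = rng.beta(a, b, size=L)
    # keep the Balding-Nichols beta parameters finite
    q0 = np.clip(q0, 1e-6, 1 - 1e-6)
    k = len(cfg.population_names)
    if cfg.fst == 0.0:
        q = np.tile(q0, (k, 1))
    else:
        c = (1.0 - cfg.fst) / cfg.fst
        q = rng.beta(q0 * c, (1.0 - q0) * c, size=(k, L))
    band_prob = 1.0 - q ** 2

    rows, sample_ids, pop_labels = [], [], []
    for g, (name, n_g) in enumerate(zip(cfg.population_names, cfg.n_per_population)):
        rows.append((rng.random((n_g, L)) < band_prob[g]).astype(np.int8))
        sample_ids += [f"{name}{i + 1}" for i in range(n_g)]
        pop_labels += [name] * n_g
    if cfg.n_reference > 0:
        # reference rows from an independent ancestral draw (off-target taxon)
        q_ref = np.clip(rng.beta(a, b, size=L), 1e-6, 1 - 1e-6)
        rows.append((rng.random((cfg.n_reference, L)) < 1.0 - q_ref ** 2).astype(np.int8))
        sample_ids += [f"{cfg.reference_label}{i + 1}" for i in range(cfg.n_reference)]
        pop_labels += [cfg.reference_label] * cfg.n_reference

    locus_ids = []
    primer_map: dict[str, str] | None = None
    if cfg.primer_counts:
        primer_map = {}
        for primer, cnt in cfg.primer_counts.items():
            for i in range(cnt):
                lid = f"P{primer}_L{i + 1}"
                locus_ids.append(lid)
                primer_map[lid] = primer
    else:
        locus_ids = [f"L{j + 1}" for j in range(L)]

    m = BandMatrix(tuple(sample_ids), tuple(pop_labels), tuple(locus_ids),
                   np.vstack(rows), primer_of_locus=primer_map)
    truth = {
        "q0": q0, "q": q, "band_prob": band_prob,
        "fst": cfg.fst, "populations": list(cfg.population_names),
    }
    return m, truth


def simulate_barcode_alignment(cfg: SyntheticBarcodeConfig) -> SeqAlignment:
    """Build a two-species alignment with exactly known structure.

    Species A's consensus is uniform random over {A,C,G,T}; species B's
    consensus differs at exactly ``n_diagnostic`` core positions.  Variant
    sequences carry ``subs_per_variant`` private substitutions at
    non-diagnostic positions.  ``n_gap_columns`` extra columns each receive a
    gap in at least one sequence; the remaining entries of a gap column are
    random bases.  Deterministic per ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    Lc = cfg.core_length
    cons_a = rng.choice(_BASES, size=Lc)
    diag = rng.choice(Lc, size=cfg.n_diagnostic, replace=False)
    cons_b = cons_a.copy()
    for pos in diag:
        alts = [x for x in "ACGT" if x != cons_a[pos]]
        cons_b[pos] = alts[rng.integers(len(alts))]

    n_total = cfg.n_species_a + cfg.n_species_b
    core = np.empty((n_total, Lc), dtype="U1")
    names, labels = [], []
    non_diag = np.setdiff1d(np.arange(Lc), diag)
    r = 0
    for sp_n, sp_label, cons, n_var in (
        (cfg.n_species_a, cfg.label_a, cons_a, cfg.n_variants_a),
        (cfg.n_species_b, cfg.label_b, cons_b, cfg.n_variants_b),
    ):
        for i in range(sp_n):
            row = cons.copy()
            if i < n_var and cfg.subs_per_variant > 0:
                sites = rng.choice(non_diag, size=cfg.subs_per_variant, replace=False)
                for pos in sites:
                    alts = [x for x in "ACGT" if x != cons[pos]]
                    row[pos] = alts[rng.integers(len(alts))]
            core[r] = row
            names.append(f"{sp_label.upper()[:2]}{i + 1}|{sp_label}")
            labels.append(sp_label)
            r += 1

    width = Lc + cfg.n_gap_columns
    gap_cols = np.sort(rng.choice(width, size=cfg.n_gap_columns, replace=False))
    full = np.empty((n_total, width), dtype="U1")
    core_cols = np.setdiff1d(np.arange(width), gap_cols)
    full[:, core_cols] = core
    for col in gap_cols:
        full[:, col] = rng.choice(_BASES, size=n_total)
        n_gapped = int(rng.integers(1, n_total + 1))
        who = rng.choice(n_total, size=n_gapped, replace=False)
        full[who, col] = "-"

    rows = tuple("".join(r_) for r_ in full)
    return SeqAlignment(tuple(names), tuple(labels), rows)


def write_truth(truth: dict, path: str | Path) -> None:
    """Dump a simulation truth record as JSON (arrays become lists)."""
    out = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
           for k, v in truth.items()}
    Path(path).write_text(json.dumps(out, indent=1))
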