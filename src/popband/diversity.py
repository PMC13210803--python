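"""Band-based diversity indices for dominant markers (ISSR/RAPD/AFLP).

A dominant marker scores only the band phenotype: presence (1) covers both
the dominant homozygote and the heterozygote.  Under Hardy-Weinberg
equilibrium the null-allele frequency is estimated from the band frequency
``f`` by the square-root estimator

    q = sqrt(1 - f),        p = 1 - q,

with no small-sample (Lynch-Milligan) correction.  Per-locus indices derive
from (p, q):

    Na = number of observed band states (2 iff 0 < f < 1, else 1)
    Ne = 1 / (p^2 + q^2)                  effective number of alleles
    He = 2 p q                            Nei's gene diversity (<= 0.5)
    I  = -(p ln p + q ln q)               Shannon's index (<= ln 2)
    PIC = He                              for a biallelic dominant locus

Summaries (per population, per primer, or pooled) average the per-locus
indices and count polymorphic loci by the strict criterion 0 < f < 1, so
PPB = 100 * P / L and mean Na = (2P + (L - P)) / L hold exactly.  All
indices are band-based comparative summaries, not allele-resolved
heterozygosity estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import BandMatrix

__all__ = [
    "LocusDiversity",
    "DiversitySummary",
    "band_frequency",
    "locus_diversity",
    "population_summary",
    "primer_summary",
    "pooled_summary",
]


@dataclass(frozen=True)
class LocusDiversity:
    """Per-locus dominant-marker indices derived from a band frequency."""

    locus_id: str
    f: float          # band frequency
    q: float          # null-allele frequency estimate, sqrt(1 - f)
    p: float          # band-allele frequency, 1 - q
    na: int           # observed band states (1 or 2)
    ne: float         # effective number of alleles, in [1, 2]
    he: float         # Nei's gene diversity, in [0, 0.5]
    i_shannon: float  # Shannon's information index, in [0, ln 2]
    pic: float        # polymorphism information content (== he here)


@dataclass(frozen=True)
class DiversitySummary:
    """Aggregated indices over a set of loci for one analysis unit."""

    unit_id: str
    n_samples: int
    n_loci: int
    n_polymorphic: int
    ppb_percent: float
    mean_na: float
    mean_ne: float
    mean_he: float
    mean_i: float

    def as_dict(self) -> dict:
        return {
            "unit": self.unit_id,
            "n": self.n_samples,
            "n_loci": self.n_loci,
            "polymorphic_loci": self.n_polymorphic,
            "ppb_percent": round(self.ppb_percent, 1),
            "mean_na": round(self.mean_na, 3),
            "mean_ne": round(self.mean_ne, 3),
            "mean_he": round(self.mean_he, 3),
            "mean_i": round(self.mean_i, 3),
        }


def band_frequency(m: BandMatrix, locus: str, samples: np.ndarray | None = None) -> float:
    """Fraction of (selected) samples showing the band at ``locus``."""
    try:
        j = m.locus_ids.index(locus)
    except ValueError:
        raise KeyError(f"unknown locus {locus!r}") from None
    col = m.values[:, j] if samples is None else m.values[samples, j]
    if col.size == 0:
        raise ValueError("empty sample subset")
    return float(col.mean())


def locus_diversity(f: float, locus_id: str = "") -> LocusDiversity:
    """All per-locus indices from a band frequency ``f`` in [0, 1]."""
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"band frequency {f} outside [0, 1]")
    q = float(np.sqrt(1.0 - f))
    p = 1.0 - q
    he = 2.0 * p * q
    ne = 1.0 / (p * p + q * q)
    # 0 * ln 0 == 0 by convention
    i = -sum(x * np.log(x) for x in (p, q) if x > 0.0)
    na = 2 if 0.0 < f < 1.0 else 1
    return LocusDiversity(locus_id, f, q, p, na, ne, he, float(i), he)


def _summary_from_freqs(unit_id: str, n_samples: int, freqs: np.ndarray,
                        locus_ids) -> DiversitySummary:
    per_locus = [locus_diversity(f, l) for f, l in zip(freqs, locus_ids)]
    L = len(per_locus)
    P = sum(1 for d in per_locus if d.na == 2)
    return DiversitySummary(
        unit_id=unit_id,
        n_samples=n_samples,
        n_loci=L,
        n_polymorphic=P,
        ppb_percent=100.0 * P / L,
        mean_na=float(np.mean([d.na for d in per_locus])),
        mean_ne=float(np.mean([d.ne for d in per_locus])),
        mean_he=float(np.mean([d.he for d in per_locus])),
        mean_i=float(np.mean([d.i_shannon for d in per_locus])),
    )


def population_summary(m: BandMatrix, pop: str) -> DiversitySummary:
    """Diversity summary over all loci, using one population's frequencies.

    Polymorphism is judged within the population: a locus fixed in this
    population but variable elsewhere counts as monomorphic here.
    """
    mask = m.rows_of(pop)  # KeyError for unknown population
    freqs = m.values[mask].mean(axis=0)
    return _summary_from_freqs(pop, int(mask.sum()), freqs, m.locus_ids)


def pooled_summary(m: BandMatrix, unit_id: str = "all") -> DiversitySummary:
    """Summary over all loci using frequencies pooled across all samples."""
    freqs = m.values.mean(axis=0)
    return _summary_from_freqs(unit_id, m.n_samples, freqs, m.locus_ids)


def primer_summary(m: BandMatrix, primer: str,
                   samples: np.ndarray | None = None) -> DiversitySummary:
    """Summary restricted to one primer's loci over the given sample subset."""
    if m.primer_of_locus is None:
        raise ValueError("band matrix has no locus -> primer map")
    cols = [j for j, l in enumerate(m.locus_ids) if m.primer_of_locus[l] == primer]
    if not cols:
        raise KeyError(f"unknown primer {primer!r}")
    vals = m.values if samples is None else m.values[samples]
    freqs = vals[:, cols].mean(axis=0)
    locus_ids = [m.locus_ids[j] for j in cols]
    return _summary_from_freqs(primer, vals.shape[0], freqs, locus_ids)
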