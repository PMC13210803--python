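"""Two-level AMOVA with Phi_PT for binary (dominant-marker) phenotypes.

AMOVA partitions the squared inter-individual distances into among- and
within-population components.  For 0/1 band profiles the squared Euclidean
distance equals the mismatching-locus count, the standard treatment of
dominant data.  With N individuals in k populations of sizes n_g:

    SS_total  = (1/N) * sum over all pairs of d^2
    SS_within = sum over groups g of (1/n_g) * sum over pairs within g of d^2
    SS_among  = SS_total - SS_within
    df_among = k - 1,  df_within = N - k
    Vw = SS_within / df_within
    Va = (SS_among/df_among - Vw) / n0,  n0 = (N - sum n_g^2 / N) / (k - 1)

Phi_PT = Va / (Va + Vw) after truncating a negative Va at zero; the
among-population percentage is 100 * Phi_PT.  Significance is assessed by
permuting whole individuals among populations (sizes fixed, loci never
permuted) with the "+1" convention p = (#{perm >= obs} + 1) / (n_perm + 1),
so 999 permutations give a minimum attainable p of 0.001.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .io import BandMatrix

__all__ = [
    "AmovaResult",
    "squared_distance",
    "amova_two_level",
    "permutation_test",
    "pairwise_phi_pt",
    "grouped_amova",
]


@dataclass(frozen=True)
class AmovaResult:
    df_among: int
    df_within: int
    ss_among: float
    ss_within: float
    va: float
    vw: float
    phi_pt: float
    pct_among: float
    pct_within: float
    p_value: float | None = None
    n_permutations: int = 0
    degenerate: bool = False  # zero total variance

    def as_dict(self) -> dict:
        d = {
            "df_among": self.df_among, "df_within": self.df_within,
            "ss_among": self.ss_among, "ss_within": self.ss_within,
            "va": self.va, "vw": self.vw,
            "phi_pt": self.phi_pt,
            "pct_among": self.pct_among, "pct_within": self.pct_within,
        }
        if self.p_value is not None:
            d["p_value"] = self.p_value
            d["n_permutations"] = self.n_permutations
        return d


def squared_distance(x, y) -> int:
    """Squared Euclidean distance between 0/1 vectors = mismatch count."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    return int(np.sum(x != y))


def _squared_distance_matrix(values: np.ndarray) -> np.ndarray:
    """Full N x N matrix of pairwise mismatch counts (float for speed)."""
    v = values.astype(np.float64)
    # for binary data |x - y|^2 over loci == mismatch count
    g = v @ v.T
    sq = np.diag(g)
    return sq[:, None] + sq[None, :] - 2.0 * g


def _label_codes(partition) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(list(partition))
    uniq, codes = np.unique(labels, return_inverse=True)
    return uniq, codes


def _ss_within(d2: np.ndarray, codes: np.ndarray, k: int) -> float:
    ss = 0.0
    for g in range(k):
        idx = np.flatnonzero(codes == g)
        block = d2[np.ix_(idx, idx)]
        ss += block.sum() / (2.0 * idx.size)
    return ss


def _amova_from_d2(d2: np.ndarray, codes: np.ndarray, k: int) -> AmovaResult:
    n = d2.shape[0]
    sizes = np.bincount(codes, minlength=k)
    if k < 2:
        raise ValueError("AMOVA needs at least 2 populations")
    if (sizes < 2).any():
        small = np.flatnonzero(sizes < 2)
        raise ValueError(f"population(s) with < 2 samples: group index {small.tolist()}")
    ss_total = d2.sum() / (2.0 * n)
    ss_within = _ss_within(d2, codes, k)
    ss_among = ss_total - ss_within
    df_among = k - 1
    df_within = n - k
    vw = ss_within / df_within
    n0 = (n - (sizes.astype(float) ** 2).sum() / n) / df_among
    va = (ss_among / df_among - vw) / n0
    if ss_total <= 1e-12:
        return AmovaResult(df_among, df_within, 0.0, 0.0, 0.0, 0.0,
                           0.0, 0.0, 100.0, degenerate=True)
    va = max(va, 0.0)
    phi = va / (va + vw) if (va + vw) > 0 else 0.0
    return AmovaResult(df_among, df_within, ss_among, ss_within, va, vw,
                       phi, 100.0 * phi, 100.0 * (1.0 - phi))


def amova_two_level(m: BandMatrix, partition=None) -> AmovaResult:
    """Two-level AMOVA of a band matrix under a population partition.

    ``partition`` defaults to the matrix's own population labels; pass any
    same-length label sequence to regroup.  Requires >= 2 populations, each
    with >= 2 samples.
    """
    labels = m.population_labels if partition is None else partition
    if len(labels) != m.n_samples:
        raise ValueError("partition length != number of samples")
    uniq, codes = _label_codes(labels)
    d2 = _squared_distance_matrix(m.values)
    return _amova_from_d2(d2, codes, len(uniq))


def _phi_only(d2: np.ndarray, codes: np.ndarray, k: int,
              const: tuple[float, float, int, int, float]) -> float:
    """Phi_PT for permuted codes, reusing invariants of the partition sizes."""
    ss_total, n0, df_among, df_within, _ = const
    ss_within = _ss_within(d2, codes, k)
    vw = ss_within / df_within
    va = max(((ss_total - ss_within) / df_among - vw) / n0, 0.0)
    return va / (va + vw) if (va + vw) > 0 else 0.0


def permutation_test(m: BandMatrix, partition=None, n_perm: int = 999,
                     seed: int | np.random.Generator = 0) -> AmovaResult:
    """AMOVA plus a permutation p-value for Phi_PT.

    Individuals are reassigned at random among populations with sample sizes
    preserved; p = (#{permuted Phi_PT >= observed} + 1) / (n_perm + 1).
    Deterministic for a given integer seed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = m.population_labels if partition is None else partition
    uniq, codes = _label_codes(labels)
    k = len(uniq)
    d2 = _squared_distance_matrix(m.values)
    obs = _amova_from_d2(d2, codes, k)
    n = m.n_samples
    sizes = np.bincount(codes, minlength=k)
    n0 = (n - (sizes.astype(float) ** 2).sum() / n) / (k - 1)
    ss_total = d2.sum() / (2.0 * n)
    const = (ss_total, n0, k - 1, n - k, 0.0)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        if _phi_only(d2, perm, k, const) >= obs.phi_pt - 1e-12:
            exceed += 1
    p = (exceed + 1) / (n_perm + 1)
    return AmovaResult(obs.df_among, obs.df_within, obs.ss_among, obs.ss_within,
                       obs.va, obs.vw, obs.phi_pt, obs.pct_among, obs.pct_within,
                       p_value=p, n_permutations=n_perm, degenerate=obs.degenerate)


def _pair_seed(seed: int, a: str, b: str) -> int:
    """Stable sub-seed for one population pair, independent of pair order."""
    key = "|".join(sorted((a, b))).encode()
    h = int.from_bytes(hashlib.sha256(key).digest()[:4], "big")
    return int(np.random.SeedSequence([seed & 0x7FFFFFFF, h]).generate_state(1)[0] % (2**31))


def pairwise_phi_pt(m: BandMatrix, partition=None, n_perm: int = 999,
                    seed: int = 0) -> dict[tuple[str, str], AmovaResult]:
    """Pairwise Phi_PT with permutation p for every population pair.

    Returns a dict keyed by ordered pairs (both orders present, symmetric).
    Each pair gets its own deterministic sub-seed derived from ``seed`` and
    the pair's labels, so population order cannot change results.
    """
    labels = tuple(m.population_labels if partition is None else partition)
    uniq = list(dict.fromkeys(labels))
    if len(uniq) < 2:
        raise ValueError("need >= 2 populations for pairwise Phi_PT")
    out: dict[tuple[str, str], AmovaResult] = {}
    for i, a in enumerate(uniq):
        for b in uniq[i + 1:]:
            mask = np.asarray([l in (a, b) for l in labels])
            sub = BandMatrix(
                tuple(s for s, kp in zip(m.sample_ids, mask) if kp),
                tuple(l for l, kp in zip(labels, mask) if kp),
                m.locus_ids, m.values[mask], primer_of_locus=m.primer_of_locus,
            )
            res = permutation_test(sub, n_perm=n_perm, seed=_pair_seed(seed, a, b))
            out[(a, b)] = out[(b, a)] = res
    return out


def grouped_amova(m: BandMatrix, grouping: dict[str, str], n_perm: int | None = None,
                  seed: int = 0) -> AmovaResult:
    """Two-level AMOVA after pooling populations into named groups.

    ``grouping`` maps each population label to a group label (e.g. mainland /
    island); the pooled groups become the partition units.  With ``n_perm``
    set, a permutation p-value is attached.
    """
    missing = [p for p in m.populations if p not in grouping]
    if missing:
        raise ValueError(f"grouping lacks population(s): {missing}")
    pooled = tuple(grouping[p] for p in m.population_labels)
    if len(set(pooled)) < 2:
        raise ValueError("grouping yields a single group")
    if n_perm is None:
        return amova_two_level(m, pooled)
    return permutation_test(m, pooled, n_perm=n_perm, seed=seed)
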