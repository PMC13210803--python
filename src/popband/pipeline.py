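"""End-to-end orchestration: species-support and population reports.

`run_species_support` turns an aligned two-species FASTA into a
barcode-gap report (haplotype counts, within/between p-distance ranges,
diagnostic sites, gap verdict).  `run_population_analysis` turns a band
matrix into the full population-layer report set: per-primer and
per-population diversity tables, AMOVA under the population partition and
an optional grouping scenario, pairwise Phi_PT, PCoA coordinates with
population centroids, and the subsampling sensitivity summary.  Every
report number is produced by the underlying module operations; nothing is
computed report-side.  A JSON manifest records seeds, permutation counts
and input checksums so a run is fully reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import amova as _amova
from . import diversity as _div
from . import ordination as _ord
from . import resampling as _res
from .io import (BandMatrix, read_alignment, read_band_matrix,
                 read_primer_map, subset_samples)
from .barcode import extract_gapfree_core, species_summary

__all__ = ["RunConfig", "run_species_support", "run_population_analysis"]


@dataclass
class RunConfig:
    """Inputs and knobs of one full analysis run."""

    band_matrix_path: str | None = None
    band_matrix_dialect: str = "auto"
    primer_map_path: str | None = None
    alignment_path: str | None = None
    species_pair: tuple[str, str] | None = None     # (focal, reference) labels
    focal_populations: tuple[str, ...] | None = None  # analytical-set filter
    grouping: dict[str, str] | None = None          # population -> group scenario
    n_permutations: int = 999
    resample_target_n: int = 20
    resample_iterations: int = 1000
    seed: int = 20260510
    out_dir: str = "results"
    species_map: dict[str, str] | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for key, val in raw.items():
            if not hasattr(cfg, key):
                raise KeyError(f"unknown config key {key!r}")
            if key in ("species_pair", "focal_populations") and val is not None:
                val = tuple(val)
            setattr(cfg, key, val)
        return cfg


def _checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _write_manifest(out: Path, cfg: RunConfig, extra: dict) -> None:
    manifest = {
        "seed": cfg.seed,
        "n_permutations": cfg.n_permutations,
        "resample_target_n": cfg.resample_target_n,
        "resample_iterations": cfg.resample_iterations,
        "inputs": {},
        **extra,
    }
    for label, p in (("band_matrix", cfg.band_matrix_path),
                     ("alignment", cfg.alignment_path)):
        if p is not None:
            manifest["inputs"][label] = {"path": str(p), "sha256_16": _checksum(p)}
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))


def run_species_support(cfg: RunConfig) -> dict[str, Path]:
    """Barcode-gap species-support report from an aligned FASTA."""
    if cfg.alignment_path is None:
        raise ValueError("config lacks alignment_path")
    aln = read_alignment(cfg.alignment_path, species_map=cfg.species_map)
    if cfg.species_pair is not None:
        sp_a, sp_b = cfg.species_pair
    else:
        species = aln.species
        if len(species) < 2:
            raise ValueError(
                f"need two species labels; alignment has only {species}")
        sp_a, sp_b = species[:2]
    for sp in (sp_a, sp_b):
        if sp not in aln.species_labels:
            raise ValueError(f"species label {sp!r} absent from alignment")
    core = extract_gapfree_core(aln)
    s = species_summary(core, sp_a, sp_b)

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    row = {
        "n_" + sp_a: s.n_per_species[sp_a],
        "n_" + sp_b: s.n_per_species[sp_b],
        "alignment_columns": aln.column_count,
        "core_length": s.core_length,
        "haplotypes_" + sp_a: s.haplotypes_per_species[sp_a],
        "haplotypes_" + sp_b: s.haplotypes_per_species[sp_b],
        "within_min_" + sp_a: round(s.within_range[sp_a][0], 4),
        "within_max_" + sp_a: round(s.within_range[sp_a][1], 4),
        "within_min_" + sp_b: round(s.within_range[sp_b][0], 4),
        "within_max_" + sp_b: round(s.within_range[sp_b][1], 4),
        "between_min": round(s.between_range[0], 4),
        "between_max": round(s.between_range[1], 4),
        "n_diagnostic_sites": len(s.diagnostic_sites),
        "barcode_gap_present": s.barcode_gap_present,
    }
    table = out / "species_support.csv"
    pd.DataFrame([row]).to_csv(table, index=False)
    detail = out / "species_support.json"
    detail.write_text(json.dumps({
        **row,
        # report 1-based positions on the core
        "diagnostic_sites_1based": [i + 1 for i in s.diagnostic_sites],
        "degenerate_within": sorted(s.degenerate_within),
    }, indent=1))
    _write_manifest(out, cfg, {"analysis": "species_support"})
    return {"table": table, "detail": detail}


def _focal(m: BandMatrix, cfg: RunConfig) -> BandMatrix:
    if cfg.focal_populations is None:
        return m
    return subset_samples(m, set(cfg.focal_populations))


def run_population_analysis(cfg: RunConfig) -> dict[str, Path]:
    """Full population-layer report set from a band matrix."""
    if cfg.band_matrix_path is None:
        raise ValueError("config lacks band_matrix_path")
    primer_map = (read_primer_map(cfg.primer_map_path)
                  if cfg.primer_map_path else None)
    full = read_band_matrix(cfg.band_matrix_path, dialect=cfg.band_matrix_dialect,
                            primer_of_locus=primer_map)
    m = _focal(full, cfg)
    pops = m.populations
    if len(pops) < 2:
        raise ValueError(f"need >= 2 focal populations, have {pops}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    # --- per-population and pooled diversity (Table-3 style) ---------------
    rows = [_div.population_summary(m, p).as_dict() for p in pops]
    rows.append(_div.pooled_summary(m, "all").as_dict())
    paths["population_diversity"] = out / "population_diversity.csv"
    pd.DataFrame(rows).to_csv(paths["population_diversity"], index=False)

    # --- per-primer diversity (Table-2 style) ------------------------------
    if m.primer_of_locus is not None:
        primers = list(dict.fromkeys(m.primer_of_locus[l] for l in m.locus_ids))
        prows = [_div.primer_summary(m, pr).as_dict() for pr in primers]
        paths["primer_diversity"] = out / "primer_diversity.csv"
        pd.DataFrame(prows).to_csv(paths["primer_diversity"], index=False)

    # --- AMOVA scenarios (Table-4 style) -----------------------------------
    scen_rows = []
    res = _amova.permutation_test(m, n_perm=cfg.n_permutations, seed=cfg.seed)
    scen_rows.append({"scenario": "populations", **{k: round(v, 4) if isinstance(v, float) else v
                                                    for k, v in res.as_dict().items()}})
    if cfg.grouping is not None:
        gres = _amova.grouped_amova(m, cfg.grouping,
                                    n_perm=cfg.n_permutations, seed=cfg.seed + 1)
        scen_rows.append({"scenario": "grouped", **{k: round(v, 4) if isinstance(v, float) else v
                                                    for k, v in gres.as_dict().items()}})
    paths["amova"] = out / "amova.csv"
    pd.DataFrame(scen_rows).to_csv(paths["amova"], index=False)

    # --- pairwise Phi_PT (Table-5 style) ------------------------------------
    pw = _amova.pairwise_phi_pt(m, n_perm=cfg.n_permutations, seed=cfg.seed)
    pw_rows = [{"population_1": a, "population_2": b,
                "phi_pt": round(pw[(a, b)].phi_pt, 3),
                "p_value": round(pw[(a, b)].p_value, 3)}
               for i, a in enumerate(pops) for b in pops[i + 1:]]
    paths["pairwise_phi_pt"] = out / "pairwise_phi_pt.csv"
    pd.DataFrame(pw_rows).to_csv(paths["pairwise_phi_pt"], index=False)

    # --- PCoA on Sokal-Michener dissimilarities -----------------------------
    dm = _ord.sokal_michener_matrix(m)
    pc = _ord.pcoa(dm, n_axes=2)
    coords = pd.DataFrame(pc.coordinates, columns=["axis_1", "axis_2"][:pc.coordinates.shape[1]])
    coords.insert(0, "population", list(m.population_labels))
    coords.insert(0, "sample_id", list(m.sample_ids))
    paths["pcoa_coordinates"] = out / "pcoa_coordinates.csv"
    coords.to_csv(paths["pcoa_coordinates"], index=False)
    cents = _ord.centroids(pc, m.population_labels)
    crows = [{"population": p, **{f"axis_{i+1}": c for i, c in enumerate(xy)}}
             for p, xy in cents.items()]
    paths["pcoa_centroids"] = out / "pcoa_centroids.csv"
    pd.DataFrame(crows).to_csv(paths["pcoa_centroids"], index=False)
    (out / "pcoa_variance.json").write_text(json.dumps({
        "pct_variance": [round(float(x), 1) for x in pc.pct_variance],
        "eigenvalues": [float(x) for x in pc.eigenvalues],
    }, indent=1))
    paths["pcoa_variance"] = out / "pcoa_variance.json"

    # --- subsampling sensitivity --------------------------------------------
    rrows = []
    for p in pops:
        n_p = int(np.sum(m.rows_of(p)))
        if n_p < cfg.resample_target_n:
            continue
        r = _res.resample_population(m, p, cfg.resample_target_n,
                                     n_iter=cfg.resample_iterations, seed=cfg.seed)
        for idx, (mean, lo, hi) in r.summary.items():
            rrows.append({"population": p, "index": idx,
                          "mean": round(mean, 3), "lo": round(lo, 3),
                          "hi": round(hi, 3),
                          "status": "resampled" if r.resampled
                                    else "observed, not resampled"})
    paths["resampling"] = out / "resampling_summary.csv"
    pd.DataFrame(rrows).to_csv(paths["resampling"], index=False)

    _write_manifest(out, cfg, {
        "analysis": "population",
        "n_focal_samples": m.n_samples,
        "focal_populations": list(pops),
    })
    return paths
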