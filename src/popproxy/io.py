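"""Readers, writers, run configuration, and the end-to-end pipeline.

File formats are deliberately plain text: labelled square CSV for distance
matrices, FASTA for haplotypes, Esri ASCII grid for the conductance raster,
JSON for reports.  ``run_pipeline`` chains the stages (simulate -> traits ->
screen -> distances -> infer -> prioritise) and stamps every output with a
hash of the configuration so runs are attributable and reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import inference
from .prioritise import prioritise as _prioritise
from .distances import (
    ConductanceRaster,
    HaplotypeSet,
    euclidean_trait_distance,
    great_circle_distance,
    habitat_divergence,
    phi_st,
    resistance_distance,
)
from .matrices import DistanceMatrix
from .screen import screen_traits
from .traits import trait_table_from_cohorts

logger = logging.getLogger(__name__)

PROXIES = ("genetic", "habitat", "geographic", "hydrologic")


# --------------------------------------------------------------------------
# FASTA
# --------------------------------------------------------------------------


def read_fasta(path: str | Path, population: str | None = None) -> HaplotypeSet:
    """Read one population's aligned haplotypes from FASTA."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        offender = next(r.id for r in records if len(r.seq) != len(records[0].seq))
        raise ValueError(f"ragged alignment in {path}: record {offender!r}")
    if population is None:
        population = path.stem.removeprefix("haplotypes_")
    return HaplotypeSet(population, [str(r.seq).upper() for r in records])


def write_fasta(hs: HaplotypeSet, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s), id=f"{hs.population}_{i + 1}", description="")
        for i, s in enumerate(hs.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


# --------------------------------------------------------------------------
# Esri ASCII grid
# --------------------------------------------------------------------------

_ASC_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "NODATA_value")


def read_ascii_grid(path: str | Path,
                    site_cells: dict[str, tuple[int, int]] | None = None,
                    k: float | None = None) -> ConductanceRaster:
    """Read an Esri ASCII grid; NODATA cells become NaN barrier cells."""
    path = Path(path)
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and parts[0].lower() in {k.lower() for k in _ASC_HEADER_KEYS}:
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(x) for x in parts])
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: missing header field {key!r}")
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    grid = np.array(rows, dtype=float)
    if grid.shape != (nrows, ncols):
        raise ValueError(
            f"{path}: header says {nrows}x{ncols} but data is "
            f"{grid.shape[0]}x{grid.shape[1]}"
        )
    nodata = header.get("nodata_value")
    if nodata is not None:
        grid[grid == nodata] = np.nan
    return ConductanceRaster(
        grid, site_cells or {}, cellsize=header["cellsize"],
        xllcorner=header.get("xllcorner", 0.0), yllcorner=header.get("yllcorner", 0.0),
        k=k,
    )


def write_ascii_grid(raster: ConductanceRaster, path: str | Path,
                     nodata: float = -9999.0) -> None:
    grid = raster.grid
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.shape[1]}\n")
        fh.write(f"nrows {grid.shape[0]}\n")
        fh.write(f"xllcorner {raster.xllcorner:g}\n")
        fh.write(f"yllcorner {raster.yllcorner:g}\n")
        fh.write(f"cellsize {raster.cellsize:g}\n")
        fh.write(f"NODATA_value {nodata:g}\n")
        out = np.where(np.isfinite(grid), grid, nodata)
        for row in out:
            fh.write(" ".join(f"{v:.12g}" for v in row) + "\n")


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------


@dataclass
class RunConfig:
    """End-to-end run settings; defaults match the published analysis.

    1000 permutations for MRDM, 9999 for Mantel, alpha = 0.05, unique
    contribution threshold 5%, river conductance bonus k = 100.
    """

    input_dir: str = "."
    output_dir: str = "results"
    proxies: tuple[str, ...] = PROXIES
    k: float = 100.0
    n_perm_mrdm: int = 1000
    n_perm_mantel: int = 9999
    alpha: float = 0.05
    u_threshold: float = 0.05
    seed: int = 0
    bray_curtis_mode: str = "shifted"
    standardise_first: bool = True
    simulate: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.proxies) - set(PROXIES)
        if unknown:
            raise ValueError(f"unknown proxies: {sorted(unknown)}")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
        if "proxies" in data:
            data["proxies"] = tuple(data["proxies"])
        return cls(**data)

    def config_hash(self) -> str:
        """Fingerprint of the analysis settings (paths excluded)."""
        data = dataclasses.asdict(self)
        data.pop("input_dir", None)
        data.pop("output_dir", None)
        payload = json.dumps(data, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


# --------------------------------------------------------------------------
# pipeline
# --------------------------------------------------------------------------


def _load_inputs(config: RunConfig):
    from .synthetic import SyntheticStudyConfig, generate_study

    if config.simulate:
        study = generate_study(SyntheticStudyConfig(seed=config.seed,
                                                    river_conductance_k=config.k))
        return (study.trait_table, study.coordinates, study.environment_table,
                study.haplotypes, study.raster, study.replicate_map)
    indir = Path(config.input_dir)
    trait_table = pd.read_csv(indir / "trait_table.csv", index_col=[0, 1])
    cohorts_path = indir / "cohort_counts.csv"
    if cohorts_path.exists():
        cohorts = pd.read_csv(cohorts_path)
        rates = trait_table_from_cohorts(cohorts)
        for col in rates.columns:
            if col not in trait_table.columns:
                trait_table[col] = rates[col]
    coords = pd.read_csv(indir / "coords.csv", index_col=0)
    env = pd.read_csv(indir / "environment.csv", index_col=0)
    haplotypes = None
    if "genetic" in config.proxies:
        fastas = sorted(indir.glob("haplotypes_*.fasta"))
        if not fastas:
            raise FileNotFoundError(
                f"genetic proxy enabled but no haplotypes_<POP>.fasta files in {indir}"
            )
        haplotypes = [read_fasta(p) for p in fastas]
    raster = None
    if "hydrologic" in config.proxies:
        asc = indir / "raster.asc"
        if not asc.exists():
            raise FileNotFoundError(f"hydrologic proxy enabled but {asc} is missing")
        cells_file = indir / "site_cells.json"
        site_cells = (
            {k: tuple(v) for k, v in json.loads(cells_file.read_text()).items()}
            if cells_file.exists() else {}
        )
        raster = read_ascii_grid(asc, site_cells=site_cells, k=config.k)
    replicate_map = {
        f"{p}::{t}": p for p, t in trait_table.index
    }
    return trait_table, coords, env, haplotypes, raster, replicate_map


def build_proxies(config: RunConfig, coords, env, haplotypes, raster,
                  replicate_map) -> dict[str, DistanceMatrix]:
    out: dict[str, DistanceMatrix] = {}
    if "genetic" in config.proxies:
        out["genetic"] = phi_st(haplotypes)
    if "habitat" in config.proxies:
        out["habitat"] = habitat_divergence(env, mode=config.bray_curtis_mode)
    if "geographic" in config.proxies:
        out["geographic"] = great_circle_distance(coords)
    if "hydrologic" in config.proxies:
        out["hydrologic"] = resistance_distance(raster)
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write the report bundle.

    Writes per-trait and per-proxy distance CSVs, screen_report.json,
    infer_report.json, prioritisation.csv and run_meta.json under
    ``config.output_dir``; returns the inference report as a dict.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    logger.info("pipeline start (config hash %s, seed %d)", chash, config.seed)

    trait_table, coords, env, haplotypes, raster, replicate_map = _load_inputs(config)

    logger.info("stage: differentiation screen")
    screen = screen_traits(trait_table, alpha=config.alpha)
    (outdir / "screen_report.json").write_text(
        json.dumps({"config_hash": chash, "traits": screen.to_records()}, indent=2) + "\n"
    )
    retained = screen.retained
    if not retained:
        raise RuntimeError("screen retained no traits; nothing to analyse")

    logger.info("stage: distance matrices (traits: %s)", ", ".join(retained))
    kta_matrices = {}
    for trait in retained:
        m = euclidean_trait_distance(trait_table[trait])
        kta_matrices[trait] = m
        m.to_csv(outdir / f"distance_kta_{trait}.csv", config_hash=chash)
    proxies_pop = build_proxies(config, coords, env, haplotypes, raster, replicate_map)
    rep_map_keys = {f"{p}::{t}": p for p, t in trait_table.index}
    proxies_rep = {
        name: (m.expand(rep_map_keys) if m.level == "population" else m)
        for name, m in proxies_pop.items()
    }
    for name, m in proxies_pop.items():
        m.to_csv(outdir / f"distance_proxy_{name}.csv", config_hash=chash)

    logger.info("stage: MRDM-CA and Mantel inference")
    reports = {}
    for i, trait in enumerate(retained):
        report = inference.mrdm_ca_loop(
            kta_matrices[trait], proxies_rep,
            n_perm=config.n_perm_mrdm, seed=config.seed + 1000 + i,
            u_threshold=config.u_threshold, alpha=config.alpha,
        )
        mantels = {
            name: inference.mantel(kta_matrices[trait], proxies_rep[name],
                                   n_perm=config.n_perm_mantel, seed=config.seed + 2000 + i)
            for name in proxies_rep
        }
        reports[trait] = (report, mantels)
    raw_p = [rep.mrdm.p_r_squared if rep.mrdm else 1.0 for rep, _ in reports.values()]
    adj_p = inference.bh_adjust(raw_p)

    infer_report = {"config_hash": chash, "seed": config.seed, "models": {}}
    for (trait, (rep, mantels)), p_adj in zip(reports.items(), adj_p):
        significant = [
            name for name in rep.predictors
            if p_adj < config.alpha and rep.commonality.unique[name] > config.u_threshold
        ] if rep.mrdm else []
        infer_report["models"][trait] = {
            "r_squared": rep.mrdm.r_squared if rep.mrdm else None,
            "p_r_squared": rep.mrdm.p_r_squared if rep.mrdm else None,
            "p_adjusted": p_adj,
            "predictors": {
                name: {
                    "r": rep.mrdm.r[name],
                    "beta": rep.mrdm.beta[name],
                    "U": rep.commonality.unique[name],
                    "C": rep.commonality.common[name],
                } for name in rep.predictors
            } if rep.mrdm else {},
            "significant_proxies": significant,
            "suppressor_rounds": [
                {"predictors": rnd.predictors,
                 "removed": [{"proxy": n, "reason": r} for n, r in rnd.removed]}
                for rnd in rep.trace.rounds
            ],
            "mantel": {name: {"r": m.r, "p": m.p} for name, m in mantels.items()},
        }
    (outdir / "infer_report.json").write_text(json.dumps(infer_report, indent=2) + "\n")

    logger.info("stage: prioritisation")
    proxy_table = _prioritise(
        proxies_rep, population_map=rep_map_keys, seed=config.seed,
        letters=True, standardise_first=config.standardise_first,
    )
    kta_table = _prioritise(
        kta_matrices, population_map=rep_map_keys, seed=config.seed,
        letters=False, standardise_first=config.standardise_first,
    )
    merged = proxy_table.rename(columns={"sum": "proxy_sum", "cluster": "proxy_cluster"})
    merged["kta_sum"] = kta_table["sum"]
    merged["kta_cluster"] = kta_table["cluster"]
    with open(outdir / "prioritisation.csv", "w") as fh:
        fh.write(f"# config_hash={chash}\n")
        merged.to_csv(fh, index_label="pair", float_format="%.6g")

    meta = {"config": dataclasses.asdict(config), "config_hash": chash,
            "retained_traits": retained}
    (outdir / "run_meta.json").write_text(json.dumps(meta, indent=2, default=str) + "\n")
    logger.info("pipeline complete; outputs in %s", outdir)
    return infer_report
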