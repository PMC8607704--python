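"""Synthetic common-garden studies with known proxy-trait couplings.

Emulates the design of a 7-lake, 3-tank-per-population larval rearing study:
site coordinates, an environmental table, per-population haplotype sets, a
river conductance raster, per-tank trait values and cohort censuses.  The
proxy-trait coupling is controlled: a coupled trait's population-level value
follows the first principal coordinate of the chosen proxy distance matrix,
so its Euclidean trait distances correlate with that proxy by construction
(weight 1, no noise gives Mantel r = 1).  Sites sit on a common meridian — a
single geodesic — so geographic distances are exactly 1-D embeddable and the
principal-coordinate construction is exact for the geographic proxy too.

Every draw derives from the master seed through fixed per-component
substreams (traits, sequences, raster, census, sites, environment), so
adding or ignoring a component never perturbs the others and the same seed
reproduces the study byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .distances import (
    ConductanceRaster,
    HaplotypeSet,
    great_circle_distance,
    habitat_divergence,
    phi_st,
    resistance_distance,
)
from .matrices import DistanceMatrix

logger = logging.getLogger(__name__)

PROXY_NAMES = ("genetic", "habitat", "geographic", "hydrologic")

_ENV_VARIABLES = [f"BIO{i}" for i in range(1, 20)] + [
    "srad", "wind", "vapr", "lake_area", "catchment_area", "mean_depth", "altitude",
]

# realistic display scales per trait: (baseline mean, scale); affine, so they
# do not alter any correlation structure
_TRAIT_SCALES = {
    "survival_rate": (50.0, 10.0),
    "specific_growth_rate": (3.5, 0.5),
    "swim_bladder_rate": (60.0, 12.0),
    "deformity_rate": (15.0, 5.0),
    "activity": (5.0, 1.0),
    "inter_individual_distance": (40.0, 8.0),
    "initial_length": (6.0, 0.4),
    "final_length": (12.0, 1.0),
}

_STREAMS = {"traits": 0, "sequences": 1, "raster": 2, "census": 3, "sites": 4, "environment": 5}


def _rng(seed: int, component: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), _STREAMS[component])))


def default_divergence_steps(populations: list[str]) -> dict[tuple[str, str], int]:
    """Star-shaped divergence: each population carries private mutations.

    Per-population counts are spread with a fixed stride so genetic
    divergence is decoupled from the latitudinal site order.
    """
    n = len(populations)
    m = {p: (i * 3) % n for i, p in enumerate(populations)}
    steps = {}
    for i, a in enumerate(populations):
        for b in populations[:i]:
            steps[(b, a)] = m[a] + m[b]
    return steps


@dataclass
class SyntheticStudyConfig:
    """Parameters of a simulated study; defaults mirror the 7-lake design."""

    n_populations: int = 7
    n_tanks_per_population: int = 3
    n_individuals_per_tank: int = 500
    trait_names: list[str] = field(
        default_factory=lambda: [
            "survival_rate", "specific_growth_rate", "activity", "final_length",
        ]
    )
    coupling: dict[str, tuple[str, float]] = field(
        default_factory=lambda: {
            "survival_rate": ("genetic", 0.8),
            "specific_growth_rate": ("hydrologic", 0.8),
            "activity": ("habitat", 0.8),
        }
    )
    noise_sd: float = 0.3
    haplotype_length: int = 1200
    n_sequences_per_population: int = 10
    within_variation: float = 0.5
    divergence_steps: dict[tuple[str, str], int] | None = None
    raster_shape: tuple[int, int] = (30, 40)
    river_conductance_k: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_populations", "n_tanks_per_population", "n_individuals_per_tank",
                     "n_sequences_per_population", "haplotype_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 <= self.within_variation <= 1):
            raise ValueError("within_variation must lie in [0, 1]")
        if self.raster_shape[0] < 3 or self.raster_shape[1] < 3:
            raise ValueError("raster_shape must be at least (3, 3)")
        if self.river_conductance_k < 0:
            raise ValueError("river_conductance_k must be >= 0")
        for trait, (proxy, weight) in self.coupling.items():
            if proxy not in PROXY_NAMES:
                raise ValueError(
                    f"coupling for {trait!r} references unknown proxy {proxy!r}; "
                    f"choose one of {PROXY_NAMES}"
                )
            if not (0 <= weight <= 1):
                raise ValueError(f"coupling weight for {trait!r} must lie in [0, 1]")
            if trait not in self.trait_names:
                raise ValueError(f"coupled trait {trait!r} not in trait_names")

    @property
    def populations(self) -> list[str]:
        return [f"P{i + 1}" for i in range(self.n_populations)]


@dataclass
class SyntheticStudy:
    """A complete simulated study bundle with its ground truth."""

    config: SyntheticStudyConfig
    trait_table: pd.DataFrame          # (population, tank) x trait
    cohort_counts: pd.DataFrame        # per-tank census integers
    environment_table: pd.DataFrame    # sites x variables
    coordinates: pd.DataFrame          # site latitude/longitude (WGS84)
    haplotypes: list[HaplotypeSet]
    raster: ConductanceRaster
    proxies: dict[str, DistanceMatrix]  # population-level proxy matrices
    truth: dict[str, tuple[str, float]]

    @property
    def replicate_map(self) -> dict[str, str]:
        return {
            f"{p}::T{t + 1}": p
            for p in self.config.populations
            for t in range(self.config.n_tanks_per_population)
        }


# --------------------------------------------------------------------------
# component generators
# --------------------------------------------------------------------------


def generate_coordinates(config: SyntheticStudyConfig) -> pd.DataFrame:
    """Sites on a common meridian with irregular latitudinal spacing."""
    rng = _rng(config.seed, "sites")
    lat = np.sort(rng.uniform(45.0, 62.0, size=config.n_populations))
    # enforce a minimal separation so no two sites coincide
    lat = 45.0 + (lat - lat.min()) * (17.0 / max(lat.max() - lat.min(), 1e-9))
    df = pd.DataFrame(
        {"latitude": lat, "longitude": np.full(config.n_populations, 15.0)},
        index=pd.Index(config.populations, name="population"),
    )
    return df


def generate_environment(config: SyntheticStudyConfig) -> pd.DataFrame:
    """Sites x 26 environmental variables with a low-rank latent structure."""
    rng = _rng(config.seed, "environment")
    n, p = config.n_populations, len(_ENV_VARIABLES)
    factors = rng.normal(size=(n, 3))
    loadings = rng.normal(size=(p, 3))
    env = factors @ loadings.T + 0.3 * rng.normal(size=(n, p))
    return pd.DataFrame(env, index=pd.Index(config.populations, name="population"),
                        columns=_ENV_VARIABLES)


def generate_haplotypes(config: SyntheticStudyConfig) -> list[HaplotypeSet]:
    """Aligned haplotypes whose between-population differences track the
    configured divergence steps.

    Pairwise step counts are fitted by a star model (non-negative least
    squares for per-population private mutation counts); each individual may
    additionally carry one private mutation, so within-population haplotypes
    are identical or one step apart.
    """
    rng = _rng(config.seed, "sequences")
    pops = config.populations
    steps = config.divergence_steps or default_divergence_steps(pops)
    pairs = {tuple(sorted(k)): v for k, v in steps.items()}
    want = {tuple(sorted((a, b))) for i, a in enumerate(pops) for b in pops[:i]}
    missing = want - set(pairs)
    if missing:
        raise ValueError(f"divergence_steps missing pairs: {sorted(missing)}")
    # star model: steps(a, b) ~ m_a + m_b, solved by NNLS
    pair_list = sorted(pairs)
    a_mat = np.zeros((len(pair_list), len(pops)))
    b_vec = np.zeros(len(pair_list))
    pop_idx = {p: i for i, p in enumerate(pops)}
    for r, (pa, pb) in enumerate(pair_list):
        a_mat[r, pop_idx[pa]] = 1.0
        a_mat[r, pop_idx[pb]] = 1.0
        b_vec[r] = pairs[(pa, pb)]
    m_counts = np.rint(nnls(a_mat, b_vec)[0]).astype(int)
    total_fixed = int(m_counts.sum())
    n_within = config.n_populations * config.n_sequences_per_population
    if config.haplotype_length < total_fixed:
        raise ValueError(
            f"haplotype_length {config.haplotype_length} is shorter than the "
            f"{total_fixed} mutations the divergence steps require"
        )
    length = config.haplotype_length
    ancestral = rng.choice(list("ACGT"), size=length)
    free_sites = list(rng.permutation(length))
    alphabet = "ACGT"
    out = []
    for p, m in zip(pops, m_counts):
        consensus = ancestral.copy()
        for _ in range(m):
            if not free_sites:
                raise ValueError("haplotype_length too short for the requested mutations")
            site = free_sites.pop()
            consensus[site] = alphabet[(alphabet.index(consensus[site]) + rng.integers(1, 4)) % 4]
        seqs = []
        for _ in range(config.n_sequences_per_population):
            seq = consensus.copy()
            if config.within_variation > 0 and rng.random() < config.within_variation:
                if free_sites:
                    site = free_sites.pop()
                    seq[site] = alphabet[(alphabet.index(seq[site]) + rng.integers(1, 4)) % 4]
            seqs.append("".join(seq))
        out.append(HaplotypeSet(p, seqs))
    return out


def generate_conductance_raster(config: SyntheticStudyConfig,
                                coordinates: pd.DataFrame | None = None) -> ConductanceRaster:
    """Background conductance 1 with a river polyline of conductance 1 + k.

    Sites map to distinct cells (rows follow latitude, columns jittered
    around the grid centre); the river is an axis-aligned polyline visiting
    every site cell in latitudinal order.
    """
    rng = _rng(config.seed, "raster")
    if coordinates is None:
        coordinates = generate_coordinates(config)
    nrows, ncols = config.raster_shape
    lat = coordinates["latitude"].to_numpy()
    lat_span = max(lat.max() - lat.min(), 1e-9)
    rows = np.clip(((lat - lat.min()) / lat_span * (nrows - 1)).round().astype(int), 0, nrows - 1)
    cols = np.clip(
        ncols // 2 + rng.integers(-(ncols // 4), ncols // 4 + 1, size=len(lat)),
        0, ncols - 1,
    )
    cells: dict[str, tuple[int, int]] = {}
    taken: set[tuple[int, int]] = set()
    for label, r, c in zip(coordinates.index.astype(str), rows, cols):
        rc = (int(r), int(c))
        while rc in taken:  # nudge until free
            rc = (rc[0], (rc[1] + 1) % ncols)
        if not (0 <= rc[0] < nrows and 0 <= rc[1] < ncols):
            raise ValueError(f"site {label} falls outside the raster")
        taken.add(rc)
        cells[label] = rc
    grid = np.ones((nrows, ncols))
    k = config.river_conductance_k
    ordered = sorted(cells.values())
    for (r0, c0), (r1, c1) in zip(ordered, ordered[1:]):
        grid[r0:r1 + 1, c0] = 1.0 + k       # vertical leg
        lo, hi = sorted((c0, c1))
        grid[r1, lo:hi + 1] = 1.0 + k       # horizontal leg
    for r, c in cells.values():
        grid[r, c] = 1.0 + k
    return ConductanceRaster(grid, cells, cellsize=0.5, k=k)


# --------------------------------------------------------------------------
# principal-coordinate coupling
# --------------------------------------------------------------------------


def first_principal_coordinate(m: DistanceMatrix) -> np.ndarray:
    """First classical-MDS axis of a distance matrix, z-scored.

    Sign is fixed (largest-magnitude loading positive) for determinism.
    """
    d2 = m.values**2
    n = m.n
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigval, eigvec = np.linalg.eigh(b)
    axis = eigvec[:, -1] * np.sqrt(max(eigval[-1], 0.0))
    pivot = np.argmax(np.abs(axis))
    if axis[pivot] < 0:
        axis = -axis
    sd = axis.std()
    if sd == 0:
        raise ValueError("degenerate proxy matrix: first principal coordinate is constant")
    return (axis - axis.mean()) / sd


def build_proxy_matrices(config: SyntheticStudyConfig,
                         coordinates: pd.DataFrame,
                         environment: pd.DataFrame,
                         haplotypes: list[HaplotypeSet],
                         raster: ConductanceRaster) -> dict[str, DistanceMatrix]:
    return {
        "genetic": phi_st(haplotypes),
        "habitat": habitat_divergence(environment),
        "geographic": great_circle_distance(coordinates),
        "hydrologic": resistance_distance(raster),
    }


# --------------------------------------------------------------------------
# study assembly
# --------------------------------------------------------------------------


def generate_trait_table(config: SyntheticStudyConfig,
                         proxies: dict[str, DistanceMatrix]) -> pd.DataFrame:
    """Per-tank trait values with the configured proxy couplings.

    A coupled trait's population component is weight x (first principal
    coordinate of the proxy matrix); each tank adds Normal(0, noise_sd).
    Uncoupled traits are pure noise.  An affine per-trait display scale maps
    values onto realistic units without altering any distance structure.
    """
    rng = _rng(config.seed, "traits")
    pops = config.populations
    index = pd.MultiIndex.from_tuples(
        [(p, f"T{t + 1}") for p in pops for t in range(config.n_tanks_per_population)],
        names=["population", "tank"],
    )
    table = pd.DataFrame(index=index)
    axes = {}
    for trait in config.trait_names:
        if trait in config.coupling:
            proxy, weight = config.coupling[trait]
            if proxy not in axes:
                axes[proxy] = first_principal_coordinate(proxies[proxy])
            pop_component = weight * axes[proxy]
        else:
            pop_component = np.zeros(len(pops))
        base, scale = _TRAIT_SCALES.get(trait, (0.0, 1.0))
        values = []
        for i, _ in enumerate(pops):
            tank_noise = rng.normal(0.0, config.noise_sd, size=config.n_tanks_per_population)
            values.extend(base + scale * (pop_component[i] + tank_noise))
        table[trait] = values
    return table


def generate_cohort_counts(config: SyntheticStudyConfig,
                           trait_table: pd.DataFrame) -> pd.DataFrame:
    """Per-tank census integers consistent with the trait table.

    Where the trait table carries survival / swim-bladder / deformity rates
    the corresponding counts are derived from them; remaining counts are
    drawn within their invariant bounds.
    """
    rng = _rng(config.seed, "census")
    ni = config.n_individuals_per_tank
    ns = min(120, ni // 4)
    rows = []
    for (pop, tank), row in trait_table.iterrows():
        surv = float(np.clip(row.get("survival_rate", rng.uniform(30, 80)), 1.0, 99.0))
        nf = int(np.clip(round(surv * (ni - ns) / 100.0), 1, ni - ns))
        sb_rate = float(np.clip(row.get("swim_bladder_rate", rng.uniform(40, 90)), 0.0, 100.0))
        nm_rate = float(np.clip(row.get("deformity_rate", rng.uniform(2, 30)), 0.0, 100.0))
        sb = int(np.clip(round(sb_rate * nf / 100.0), 0, nf))
        nm = int(np.clip(round(nm_rate * nf / 100.0), 0, nf))
        dead = ni - ns - nf
        nd = int(round(0.8 * dead))
        aggr = rng.uniform(0.05, 0.4)
        ne = int(np.clip(rng.binomial(nd, aggr / 2) if nd else 0, 0, nd))
        nt = int(np.clip(rng.binomial(nd, aggr / 2) if nd else 0, 0, nd - ne))
        rows.append({
            "population": pop, "tank": tank, "Ni": ni, "Nf": nf, "Ns": ns,
            "SBplus": sb, "Nm": nm, "Ne": ne, "Nt": nt, "Nd": nd,
        })
    return pd.DataFrame(rows)


def generate_study(config: SyntheticStudyConfig) -> SyntheticStudy:
    """Generate a complete, reproducible study bundle."""
    coordinates = generate_coordinates(config)
    environment = generate_environment(config)
    haplotypes = generate_haplotypes(config)
    raster = generate_conductance_raster(config, coordinates)
    proxies = build_proxy_matrices(config, coordinates, environment, haplotypes, raster)
    trait_table = generate_trait_table(config, proxies)
    cohorts = generate_cohort_counts(config, trait_table)
    return SyntheticStudy(
        config=config,
        trait_table=trait_table,
        cohort_counts=cohorts,
        environment_table=environment,
        coordinates=coordinates,
        haplotypes=haplotypes,
        raster=raster,
        proxies=proxies,
        truth=dict(config.coupling),
    )


def write_study(study: SyntheticStudy, outdir: str | Path) -> None:
    """Write the study as the plain-text files the pipeline reads back."""
    from .io import write_ascii_grid, write_fasta  # local import to avoid a cycle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study.trait_table.to_csv(outdir / "trait_table.csv")
    study.cohort_counts.to_csv(outdir / "cohort_counts.csv", index=False)
    study.environment_table.to_csv(outdir / "environment.csv")
    study.coordinates.to_csv(outdir / "coords.csv")
    for hs in study.haplotypes:
        write_fasta(hs, outdir / f"haplotypes_{hs.population}.fasta")
    write_ascii_grid(study.raster, outdir / "raster.asc")
    truth = {t: {"proxy": p, "weight": w} for t, (p, w) in study.truth.items()}
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    sites = {label: list(map(int, rc)) for label, rc in study.raster.site_cells.items()}
    (outdir / "site_cells.json").write_text(json.dumps(sites, indent=2) + "\n")
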