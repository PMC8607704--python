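"""Key-trait-for-aquaculture (KTA) metrics from raw per-tank observations.

Each rearing tank (a replicate of its source population) yields a census of
larvae (:class:`CohortCounts`), length samples at the start and end of the
rearing period (:class:`LengthSample`), and behavioural arena recordings
(:class:`ArenaTrack`).  The functions here turn those raw observations into
the per-replicate trait values that downstream distance matrices are built
from:

* survival rate                 ``Nf * 100 / (Ni - Ns)``            [%]
* specific growth rate (SGR)    ``100 * (ln Lf - ln Li) / dT``      [%/day]
* growth heterogeneity          ``CV(final) / CV(initial)``         [ratio]
* swim-bladder inflation rate   ``100 * SB+ / Nf``                  [%]
* deformity rate                ``100 * Nm / Nf``                   [%]
* aggressiveness                ``(Ne + Nt) / Nd``                  [proportion]
* inter-individual distance     mean pairwise distance in the arena [mm]
* activity                      mean distance swum per second       [mm/s]
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# raw-observation containers
# --------------------------------------------------------------------------


@dataclass
class CohortCounts:
    """Per-tank larval census.

    ``Ni`` initial larvae, ``Nf`` final larvae, ``Ns`` larvae sampled out
    during the experiment, ``SBplus`` larvae with an inflated swim bladder,
    ``Nm`` deformed larvae, ``Ne`` enucleated dead larvae, ``Nt`` truncated
    dead larvae, ``Nd`` dead larvae counted over the aggression window.
    """

    Ni: int
    Nf: int
    Ns: int = 0
    SBplus: int = 0
    Nm: int = 0
    Ne: int = 0
    Nt: int = 0
    Nd: int = 0

    def __post_init__(self) -> None:
        for name in ("Ni", "Nf", "Ns", "SBplus", "Nm", "Ne", "Nt", "Nd"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a non-negative integer, got {v}")
            setattr(self, name, int(v))
        if self.Nf > self.Ni - self.Ns:
            raise ValueError("Nf exceeds Ni - Ns")
        if self.SBplus > self.Nf:
            raise ValueError("SBplus exceeds Nf")
        if self.Nm > self.Nf:
            raise ValueError("Nm exceeds Nf")
        if self.Ne + self.Nt > self.Nd:
            raise ValueError("Ne + Nt exceeds Nd")


@dataclass
class LengthSample:
    """Total lengths (mm) of sampled larvae at start and end of rearing."""

    initial_lengths: list[float]
    final_lengths: list[float]
    delta_T: float

    def __post_init__(self) -> None:
        self.initial_lengths = [float(x) for x in self.initial_lengths]
        self.final_lengths = [float(x) for x in self.final_lengths]
        if any(x <= 0 for x in self.initial_lengths + self.final_lengths):
            raise ValueError("lengths must be positive")
        if self.delta_T <= 0:
            raise ValueError("delta_T must be positive")


@dataclass
class ArenaTrack:
    """Ordered arena images, each giving (x, y) mm per group member.

    ``images`` is a list of (timestamp_s, coords) where coords is an array of
    shape (group_size, 2).  Images with a wrong number of individuals are
    dropped with a warning at computation time (fieldwork reality); timestamps
    must be strictly increasing.
    """

    images: list[tuple[float, np.ndarray]]
    group_size: int

    def __post_init__(self) -> None:
        if self.group_size < 1:
            raise ValueError("group_size must be >= 1")
        times = [t for t, _ in self.images]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("timestamps must be strictly increasing")
        self.images = [(float(t), np.asarray(c, dtype=float)) for t, c in self.images]

    def _valid_images(self) -> list[tuple[float, np.ndarray]]:
        keep = []
        for t, coords in self.images:
            if coords.shape == (self.group_size, 2):
                keep.append((t, coords))
            else:
                logger.warning(
                    "dropping arena image at t=%.1fs: %d individuals, expected %d",
                    t, coords.shape[0], self.group_size,
                )
        return keep


# --------------------------------------------------------------------------
# census-based rates
# --------------------------------------------------------------------------


def survival_rate(c: CohortCounts) -> float:
    """Percentage of larvae (net of sampling) alive at the end of rearing."""
    denom = c.Ni - c.Ns
    if denom <= 0:
        raise ZeroDivisionError("survival rate undefined: Ni <= Ns")
    return c.Nf * 100.0 / denom


def swim_bladder_rate(c: CohortCounts) -> float:
    """Percentage of final larvae with an inflated swim bladder."""
    if c.Nf == 0:
        raise ZeroDivisionError("swim bladder rate undefined: Nf = 0")
    return 100.0 * c.SBplus / c.Nf


def deformity_rate(c: CohortCounts) -> float:
    """Percentage of final larvae with visible skeletal deformities."""
    if c.Nf == 0:
        raise ZeroDivisionError("deformity rate undefined: Nf = 0")
    return 100.0 * c.Nm / c.Nf


def aggressiveness_rate(c: CohortCounts) -> float:
    """Proportion (not percent) of dead larvae showing aggression marks.

    Enucleated (one eye missing) and truncated (type-I cannibalism) dead
    larvae over all dead larvae counted in the aggression window.
    """
    if c.Nd == 0:
        raise ZeroDivisionError("aggressiveness undefined: Nd = 0")
    return (c.Ne + c.Nt) / c.Nd


# --------------------------------------------------------------------------
# growth metrics
# --------------------------------------------------------------------------


def specific_growth_rate(s: LengthSample) -> float:
    """SGR in %/day from tank-mean initial and final lengths."""
    li = float(np.mean(s.initial_lengths))
    lf = float(np.mean(s.final_lengths))
    return 100.0 * (math.log(lf) - math.log(li)) / s.delta_T


def _cv(x: np.ndarray) -> float:
    # sample (n-1) standard deviation convention
    return 100.0 * float(np.std(x, ddof=1)) / float(np.mean(x))


def growth_heterogeneity(s: LengthSample) -> float:
    """Ratio of final to initial length coefficient of variation."""
    cvi = _cv(np.asarray(s.initial_lengths))
    if cvi == 0:
        raise ZeroDivisionError("growth heterogeneity undefined: zero initial CV")
    return _cv(np.asarray(s.final_lengths)) / cvi


# --------------------------------------------------------------------------
# behavioural metrics
# --------------------------------------------------------------------------


def inter_individual_distance(t: ArenaTrack) -> float:
    """Mean distance (mm) from each individual to every other group member.

    Per image: each individual's mean Euclidean distance to the others is
    averaged over the group; those per-image values are averaged over images
    to give one value per replicate.  No identity tracking is needed.
    """
    if t.group_size < 2:
        raise ValueError("inter-individual distance needs group_size >= 2")
    images = t._valid_images()
    if not images:
        raise ValueError("no valid images")
    per_image = []
    for _, coords in images:
        diff = coords[:, None, :] - coords[None, :, :]
        d = np.sqrt((diff**2).sum(axis=-1))
        np.fill_diagonal(d, np.nan)
        per_image.append(float(np.nanmean(np.nanmean(d, axis=1))))
    return float(np.mean(per_image))


def activity(t: ArenaTrack, series_length: int = 6) -> float:
    """Mean distance swum per second (mm/s) over 1-s image series.

    The track is cut into consecutive runs of ``series_length`` images one
    second apart (individual order within a run identifies individuals).
    Each run yields 5 per-second displacements per individual; per-individual
    means are averaged over the group, then over runs.
    """
    images = t._valid_images()
    series: list[float] = []
    i = 0
    while i + series_length <= len(images):
        chunk = images[i : i + series_length]
        times = np.array([tt for tt, _ in chunk])
        if np.allclose(np.diff(times), 1.0, atol=1e-6):
            coords = np.stack([c for _, c in chunk])  # (T, group, 2)
            steps = np.sqrt(((coords[1:] - coords[:-1]) ** 2).sum(axis=-1))
            per_individual = steps.mean(axis=0)  # mean of the 5 displacements
            series.append(float(per_individual.mean()))
            i += series_length
        else:
            logger.warning("skipping non-consecutive image series starting at t=%.1fs", times[0])
            i += 1
    if not series:
        raise ValueError("no consecutive 1-s image series found")
    return float(np.mean(series))


# --------------------------------------------------------------------------
# tabular front-end used by the pipeline
# --------------------------------------------------------------------------

RATE_FUNCS = {
    "survival_rate": survival_rate,
    "swim_bladder_rate": swim_bladder_rate,
    "deformity_rate": deformity_rate,
    "aggressiveness": aggressiveness_rate,
}


def trait_table_from_cohorts(cohorts: pd.DataFrame) -> pd.DataFrame:
    """Compute census-based rate traits for every (population, tank) row.

    ``cohorts`` must have columns population, tank, Ni, Nf, Ns, SBplus, Nm,
    Ne, Nt, Nd.  Returns a table indexed by (population, tank).
    """
    rows = {}
    for _, row in cohorts.iterrows():
        c = CohortCounts(
            Ni=row["Ni"], Nf=row["Nf"], Ns=row["Ns"], SBplus=row["SBplus"],
            Nm=row["Nm"], Ne=row["Ne"], Nt=row["Nt"], Nd=row["Nd"],
        )
        rows[(row["population"], row["tank"])] = {
            name: f(c) for name, f in RATE_FUNCS.items()
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.names = ["population", "tank"]
    return out
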