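"""Immunoscore-style binary (I) and quaternary (Q) immune scores.

A score is defined by a set of marker x compartment populations (e.g. the
classic Immunoscore uses CD3 and CD8 at tumor center and invasive margin).
For each population, the per-tumor summed 4-ROI count is recoded relative
to the whole study population:

* binary: 0 (low) / 1 (high) with respect to the pooled median;
* quaternary: 0..3 by quartile range (0-25, 25-50, 50-75, 75-100%).

The score is the sum of the per-population codes, so a binary score over k
populations ranges over [0, k] and the matching quaternary score over
[0, 3k]. Values at a cut point take the higher code, which makes the
quaternary codes median-consistent with the binary ones (code >= 2 exactly
where the binary code is 1). Tumors lacking a compartment (biopsies have
no invasive margin) get a *missing* score for any definition that touches
it — missingness propagates, it is never imputed as zero.

Percentile convention: linear interpolation between order statistics
(midpoint median for even n), fixed here because quartile conventions
differ across software.
"""

from __future__ import annotations

import enum
import importlib.resources
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .records import Cohort, Compartment, Marker, MissingCompartmentError, sum_compartment


class PopulationKey(NamedTuple):
    """One of the 10 scoreable populations (5 markers x 2 compartments)."""

    marker: Marker
    compartment: Compartment

    @classmethod
    def parse(cls, token: str) -> "PopulationKey":
        marker, _, compartment = token.partition("_")
        return cls(Marker(marker), Compartment(compartment))

    @property
    def token(self) -> str:
        return f"{self.marker.value}_{self.compartment.value}"


ALL_POPULATIONS = tuple(PopulationKey(m, c) for m in Marker for c in Compartment)


class Resolution(str, enum.Enum):
    BINARY = "BINARY"
    QUATERNARY = "QUATERNARY"


@dataclass(frozen=True)
class ScoreDefinition:
    score_id: str
    resolution: Resolution
    populations: frozenset[PopulationKey]

    def __post_init__(self) -> None:
        if not self.populations:
            raise ValueError(f"score {self.score_id}: population set must be non-empty")

    @property
    def max_value(self) -> int:
        per_pop = 1 if self.resolution is Resolution.BINARY else 3
        return per_pop * len(self.populations)


def default_registry() -> list[ScoreDefinition]:
    """The packaged 20-score registry (I1:I10 and Q1:Q10, Qk matching Ik)."""
    with importlib.resources.files("mmrimmune.data").joinpath("score_registry.csv").open() as fh:
        frame = pd.read_csv(fh)
    return [
        ScoreDefinition(
            score_id=r.score_id,
            resolution=Resolution(r.resolution),
            populations=frozenset(PopulationKey.parse(t) for t in r.populations.split(";")),
        )
        for r in frame.itertuples()
    ]


def read_registry(path) -> list[ScoreDefinition]:
    frame = pd.read_csv(path)
    return [
        ScoreDefinition(
            score_id=r.score_id,
            resolution=Resolution(r.resolution),
            populations=frozenset(PopulationKey.parse(t) for t in r.populations.split(";")),
        )
        for r in frame.itertuples()
    ]


def _as_array(values: Sequence[Optional[float]]) -> np.ndarray:
    return np.array([np.nan if v is None else float(v) for v in values], dtype=float)


def threshold_binary(values: Sequence[Optional[float]]) -> np.ndarray:
    """Recode values 0 (below the median) / 1 (at or above); NaN passes through."""
    arr = _as_array(values)
    finite = arr[~np.isnan(arr)]
    if finite.size < 2:
        raise ValueError("binary thresholding needs at least 2 non-missing values")
    med = np.median(finite)
    out = np.where(arr >= med, 1.0, 0.0)
    out[np.isnan(arr)] = np.nan
    return out


def threshold_quaternary(values: Sequence[Optional[float]]) -> np.ndarray:
    """Recode values 0..3 by quartile; ties at a cut take the higher code."""
    arr = _as_array(values)
    finite = arr[~np.isnan(arr)]
    if finite.size < 4:
        raise ValueError("quaternary thresholding needs at least 4 non-missing values")
    cuts = np.percentile(finite, [25, 50, 75], method="linear")
    if np.all(finite == finite[0]):
        warnings.warn("degenerate (constant) input: all values coded 3", stacklevel=2)
    out = (arr[:, None] >= cuts[None, :]).sum(axis=1).astype(float)
    out[np.isnan(arr)] = np.nan
    return out


def compute_score(
    codes: Mapping[PopulationKey, Optional[float]], definition: ScoreDefinition
) -> Optional[int]:
    """Sum the per-population codes over the definition; missing propagates."""
    total = 0.0
    for pop in definition.populations:
        code = codes.get(pop)
        if code is None or (isinstance(code, float) and np.isnan(code)):
            return None
        total += code
    return int(total)


def population_sums(cohort: Cohort) -> pd.DataFrame:
    """Per-tumor summed counts, tumors x 10 population columns (NaN where the
    compartment is absent)."""
    rows = []
    for record in cohort:
        row: dict[str, float] = {}
        for pop in ALL_POPULATIONS:
            try:
                row[pop.token] = float(sum_compartment(record, pop.marker, pop.compartment))
            except MissingCompartmentError:
                row[pop.token] = np.nan
        rows.append(row)
    return pd.DataFrame(rows, index=[r.tumor_id for r in cohort])


def score_matrix(
    cohort: Cohort, registry: Optional[Sequence[ScoreDefinition]] = None
) -> pd.DataFrame:
    """Assemble the tumors x scores matrix.

    Thresholds are computed on the pooled study population (all tumors
    supplied, across molecular groups) so that scores are comparable across
    groups; biopsy tumors contribute to CT thresholds only.
    """
    registry = list(registry) if registry is not None else default_registry()
    ids = [d.score_id for d in registry]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate score ids in registry")
    sums = population_sums(cohort)
    codes: dict[Resolution, dict[PopulationKey, np.ndarray]] = {
        Resolution.BINARY: {},
        Resolution.QUATERNARY: {},
    }
    needed: dict[Resolution, set[PopulationKey]] = {
        Resolution.BINARY: set(),
        Resolution.QUATERNARY: set(),
    }
    for d in registry:
        needed[d.resolution] |= d.populations
    for res, pops in needed.items():
        threshold = threshold_binary if res is Resolution.BINARY else threshold_quaternary
        for pop in pops:
            codes[res][pop] = threshold(sums[pop.token].to_numpy())
    out = pd.DataFrame(index=sums.index, columns=ids, dtype=float)
    for d in registry:
        pop_codes = np.column_stack([codes[d.resolution][p] for p in sorted(d.populations)])
        out[d.score_id] = pop_codes.sum(axis=1)  # NaN propagates for missing IM
    return out


def export_heatmap_matrix(cohort: Cohort, registry=None) -> pd.DataFrame:
    """Tumors x scores matrix with cohort labels attached, for external
    heatmap/clustering tools (no rendering here)."""
    matrix = score_matrix(cohort, registry)
    matrix.insert(0, "cohort", [r.cohort.value for r in cohort])
    return matrix
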