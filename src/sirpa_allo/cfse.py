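"""CFSE division-deconvolution: precursors, proliferation and stimulation indices.

CFSE fluorescence halves at each cell division, so a 5-day culture resolves
into generation peaks g = 0..G.  A single precursor that divides n times
yields 2^n daughter cells, all in generation n; inverting that relationship
converts the observed generation histogram into absolute precursor numbers
(counts_g / 2^g) and division events.  The proliferation index (PI) is the
ratio of proliferation events to precursors, and a stimulation index (SI)
normalizes a condition's PI to a control PI — the IgG1 isotype control for
plate-bound costimulation assays, or the self-response for the mixed
lymphocyte reaction (MLR) used in antidonor immune monitoring.

Under the default lineage-tree events model a precursor reaching generation g
contributes 2^g − 1 binary-fission events (the internal nodes of a complete
binary tree with 2^g leaves).  The alternative "generations" model (events =
g per precursor) is provided for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

#: CFSE dye-dilution resolution limit: generations beyond this pool into it.
MAX_GENERATION = 8

EventsModel = Literal["lineage", "generations"]


class HistogramError(ValueError):
    """Invalid CFSE generation histogram."""


@dataclass(frozen=True)
class CFSEHistogram:
    """Cell counts per CFSE generation (0 = undivided) for one condition.

    Counts may be non-integer (flow counts are rate-scaled); they must be
    non-negative and not all zero.
    """

    counts: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 1 or counts.size == 0:
            raise HistogramError("histogram must be a non-empty 1-D count vector")
        if np.any(counts < 0) or not np.all(np.isfinite(counts)):
            raise HistogramError("histogram counts must be finite and non-negative")
        if not np.any(counts > 0):
            raise HistogramError("histogram has no cells")
        object.__setattr__(self, "counts", counts)

    @staticmethod
    def from_mapping(
        generation_counts: Mapping[int, float],
        label: str = "",
        max_generation: int = MAX_GENERATION,
    ) -> "CFSEHistogram":
        """Build from {generation: count}; generations > max_generation pool there."""
        counts = np.zeros(max_generation + 1)
        for g, c in generation_counts.items():
            if g < 0:
                raise HistogramError(f"negative generation {g}")
            counts[min(int(g), max_generation)] += c
        return CFSEHistogram(counts, label)

    @property
    def generations(self) -> np.ndarray:
        return np.arange(self.counts.size)

    @property
    def total_cells(self) -> float:
        return float(self.counts.sum())


@dataclass(frozen=True)
class ProliferationResult:
    precursors: float
    events: float
    pi: float
    per_generation: pd.DataFrame = field(repr=False)
    label: str = ""


@dataclass(frozen=True)
class StimulationIndex:
    """PI ratio of a condition over its control; undefined when control PI = 0."""

    si: float
    numerator_label: str
    denominator_label: str
    numerator_pi: float
    denominator_pi: float

    @property
    def defined(self) -> bool:
        return not np.isnan(self.si)


def precursors(h: CFSEHistogram) -> tuple[np.ndarray, float]:
    """Per-generation precursor numbers and their total.

    A generation-g peak of counts_g cells descends from counts_g / 2^g
    precursors.
    """
    per_gen = h.counts / np.exp2(h.generations)
    return per_gen, float(per_gen.sum())


def proliferation_index(h: CFSEHistogram, events_model: EventsModel = "lineage") -> ProliferationResult:
    """Proliferation events per precursor, deconvolved from the histogram.

    PI = Σ_g events_g / Σ_g precursors_g with events_g = precursors_g × (2^g − 1)
    under the lineage model (or precursors_g × g under the generations model).
    An all-undivided histogram gives PI = 0.
    """
    per_gen, total = precursors(h)
    g = h.generations
    if events_model == "lineage":
        events_per_precursor = np.exp2(g) - 1
    elif events_model == "generations":
        events_per_precursor = g.astype(float)
    else:
        raise ValueError(f"unknown events model {events_model!r}")
    events_g = per_gen * events_per_precursor
    events = float(events_g.sum())
    per_generation = pd.DataFrame(
        {"generation": g, "count": h.counts, "precursors": per_gen, "events": events_g}
    )
    return ProliferationResult(total, events, events / total, per_generation, h.label)


def stimulation_index(
    condition: CFSEHistogram,
    control: CFSEHistogram,
    events_model: EventsModel = "lineage",
) -> StimulationIndex:
    """PI of a condition normalized to a control's PI.

    A control with zero PI (all cells undivided) makes the ratio undefined;
    the result then carries NaN with both raw PIs attached rather than a
    silent 0 or infinity.
    """
    pi_num = proliferation_index(condition, events_model).pi
    pi_den = proliferation_index(control, events_model).pi
    si = pi_num / pi_den if pi_den > 0 else float("nan")
    return StimulationIndex(si, condition.label, control.label, pi_num, pi_den)


def mlr_stimulation_index(
    allo: CFSEHistogram, self_response: CFSEHistogram, events_model: EventsModel = "lineage"
) -> StimulationIndex:
    """MLR stimulation index: allogeneic PI over self-response PI."""
    return stimulation_index(allo, self_response, events_model)


def average_pi(
    replicates: Sequence[CFSEHistogram],
    how: Literal["post", "pre"] = "post",
    events_model: EventsModel = "lineage",
) -> float:
    """Average replicate wells: mean of per-well PIs ("post", default) or the
    PI of the pooled histogram ("pre")."""
    if not replicates:
        raise HistogramError("no replicate histograms")
    if how == "post":
        return float(np.mean([proliferation_index(h, events_model).pi for h in replicates]))
    if how == "pre":
        width = max(h.counts.size for h in replicates)
        pooled = np.zeros(width)
        for h in replicates:
            pooled[: h.counts.size] += h.counts
        return proliferation_index(CFSEHistogram(pooled, "pooled"), events_model).pi
    raise ValueError(f"unknown averaging mode {how!r}")


def read_histograms(path) -> dict[tuple[str, str], CFSEHistogram]:
    """Read a subject_id,condition,generation,count CSV into histograms."""
    df = pd.read_csv(path)
    required = {"subject_id", "condition", "generation", "count"}
    if missing := required - set(df.columns):
        raise HistogramError(f"{path}: missing columns {sorted(missing)}")
    out = {}
    for (subject, condition), grp in df.groupby(["subject_id", "condition"]):
        mapping = dict(zip(grp["generation"].astype(int), grp["count"].astype(float)))
        out[(str(subject), str(condition))] = CFSEHistogram.from_mapping(mapping, str(condition))
    return out
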