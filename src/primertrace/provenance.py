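"""Origin classification of primer-community ASVs and resolution of
"unique" ASVs to their most similar source sequence.

Every ASV detected in a trained (primer) community is classified by its
presence/absence in the source soil and source substrate: present in both →
Common, soil only → FromSoil, substrate only → FromSubstrate, neither →
Unique.  Unique ASVs are then resolved against the pooled soil + substrate
reference sequences by minimal p-distance under pairwise semi-global
alignment, and summarised per possible source (read totals and distance
mean / Q3 / max).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .align import DEFAULT_SCORING, PDistance, Scoring, global_align, p_distance
from .io import AsvRecord, CountTable

logger = logging.getLogger(__name__)

DEFAULT_MAJOR_THRESHOLD = 600
DEFAULT_PRESENCE_MIN = 1

#: Minimum fraction of the shorter sequence that an alignment must cover
#: (in comparable base–base columns) for a reference to be eligible as a
#: nearest neighbour.  Optimal free-end-gap alignments between unrelated
#: sequences are typically short, near-perfect overlaps whose p-distance is
#: meaninglessly small; requiring the alignment to span at least half the
#: amplicon restores a meaningful minimum-distance criterion.
DEFAULT_MIN_COVERAGE = 0.5

ORIGIN_CATEGORIES = ("Common", "FromSoil", "FromSubstrate", "Unique")
POSSIBLE_SOURCES = ("Common", "Soil", "Substrate")


@dataclass(frozen=True)
class OriginAssignment:
    """Origin category of one primer-community ASV.

    The category is a pure function of the two presence flags; ``is_major``
    marks ASVs whose summed primer reads exceed the major-taxon threshold
    (strictly greater).
    """

    asv_id: str
    present_in_soil: bool
    present_in_substrate: bool
    category: str
    primer_reads: int
    is_major: bool

    def __post_init__(self) -> None:
        expected = {
            (True, True): "Common",
            (True, False): "FromSoil",
            (False, True): "FromSubstrate",
            (False, False): "Unique",
        }[(self.present_in_soil, self.present_in_substrate)]
        if self.category != expected:
            raise ValueError(
                f"category {self.category!r} inconsistent with presence flags for {self.asv_id!r}"
            )
        if self.primer_reads < 0:
            raise ValueError("primer_reads must be non-negative")


@dataclass(frozen=True)
class SourceResolution:
    """Closest source ASV for one Unique ASV.

    ``possible_source`` is Common when the set of co-minimal references
    contains both a soil-present and a substrate-present sequence (including
    a single reference present in both pools).
    """

    asv_id: str
    nearest_asv_id: str
    distance: PDistance
    possible_source: str

    def __post_init__(self) -> None:
        if self.possible_source not in POSSIBLE_SOURCES:
            raise ValueError(f"unknown possible_source {self.possible_source!r}")


@dataclass(frozen=True)
class SourceSummary:
    """One row of the unique-ASV source summary (per possible source)."""

    possible_source: str
    n_reads: int
    mean_distance: float
    q3_distance: float
    max_distance: float


def _group_presence(table: CountTable, presence_min: int) -> pd.Series:
    """Pooled presence per ASV: total reads over the group ≥ presence_min."""
    return table.counts.sum(axis=0) >= presence_min


def classify_origin(
    primer: CountTable,
    soil: CountTable,
    substrate: CountTable,
    presence_min: int = DEFAULT_PRESENCE_MIN,
    major_threshold: int = DEFAULT_MAJOR_THRESHOLD,
) -> list[OriginAssignment]:
    """Classify every detected primer ASV by presence in soil and substrate.

    Presence in a source group is pooled over its replicates: the group's
    summed reads for the ASV must reach ``presence_min`` (default 1).  One
    assignment is produced per ASV with a nonzero primer count; the four
    categories partition those ASVs exhaustively and exclusively.
    """
    if presence_min < 1:
        raise ValueError("presence_min must be >= 1")
    primer_totals = primer.counts.sum(axis=0)
    primer_totals = primer_totals[primer_totals > 0]
    if primer_totals.empty:
        raise ValueError("primer table has no detected ASVs")
    soil_presence = _group_presence(soil, presence_min)
    substrate_presence = _group_presence(substrate, presence_min)
    out = []
    for asv_id, reads in primer_totals.items():
        in_soil = bool(soil_presence.get(asv_id, False))
        in_sub = bool(substrate_presence.get(asv_id, False))
        category = {
            (True, True): "Common",
            (True, False): "FromSoil",
            (False, True): "FromSubstrate",
            (False, False): "Unique",
        }[(in_soil, in_sub)]
        out.append(
            OriginAssignment(
                asv_id=str(asv_id),
                present_in_soil=in_soil,
                present_in_substrate=in_sub,
                category=category,
                primer_reads=int(reads),
                is_major=int(reads) > major_threshold,
            )
        )
    return out


def resolve_unique(
    unique_asvs: Sequence[AsvRecord],
    soil_refs: Sequence[AsvRecord],
    substrate_refs: Sequence[AsvRecord],
    soil_presence: Iterable[str] | None = None,
    substrate_presence: Iterable[str] | None = None,
    scoring: Scoring = DEFAULT_SCORING,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> list[SourceResolution]:
    """Resolve each Unique ASV to its closest source reference by p-distance.

    All-pairs semi-global alignment against the pooled soil + substrate
    references; the minimal p-distance wins.  References whose optimal
    alignment covers fewer than ``min_coverage`` × (shorter sequence length)
    comparable columns are ineligible (short-overlap alignments between
    unrelated amplicons are spuriously close); if no reference qualifies the
    full pool is used with a warning.  When several references are co-minimal
    (distance ties within 1e-12) they are considered jointly: the reported
    source is Common when both pools are represented.
    """
    pool: dict[str, AsvRecord] = {}
    for rec in list(soil_refs) + list(substrate_refs):
        if rec.asv_id in pool and pool[rec.asv_id].sequence != rec.sequence:
            raise ValueError(f"reference id {rec.asv_id!r} has conflicting sequences")
        pool[rec.asv_id] = rec
    if not pool:
        raise ValueError("empty pooled reference set")
    soil_ids = set(soil_presence) if soil_presence is not None else {r.asv_id for r in soil_refs}
    sub_ids = (
        set(substrate_presence)
        if substrate_presence is not None
        else {r.asv_id for r in substrate_refs}
    )

    results = []
    refs = list(pool.values())
    for query in unique_asvs:
        dists: list[tuple[str, PDistance]] = []
        eligible: list[tuple[str, PDistance]] = []
        for ref in refs:
            aln = global_align(query.sequence, ref.sequence, scoring)
            try:
                d = p_distance(aln)
            except ValueError:
                continue  # zero-overlap alignment: no defined distance
            dists.append((ref.asv_id, d))
            need = int(np.ceil(min_coverage * min(len(query), len(ref))))
            if d.n_compared_columns >= need:
                eligible.append((ref.asv_id, d))
        if not dists:
            raise ValueError(f"no reference aligns with {query.asv_id!r}")
        if not eligible:
            logger.warning(
                "no reference reaches %.0f%% coverage for %s; using the full pool",
                100 * min_coverage,
                query.asv_id,
            )
            eligible = dists
        best = min(d.value for _, d in eligible)
        co_minimal = [(rid, d) for rid, d in eligible if d.value <= best + 1e-12]
        any_soil = any(rid in soil_ids for rid, _ in co_minimal)
        any_sub = any(rid in sub_ids for rid, _ in co_minimal)
        source = "Common" if (any_soil and any_sub) else ("Soil" if any_soil else "Substrate")
        nearest_id, nearest_d = co_minimal[0]
        results.append(SourceResolution(query.asv_id, nearest_id, nearest_d, source))
    return results


def summarize_unique_sources(
    resolutions: Sequence[SourceResolution], assignments: Sequence[OriginAssignment]
) -> list[SourceSummary]:
    """Per-source summary of Unique ASVs: read totals and distance statistics.

    One row per possible source present, ordered Common, Soil, Substrate.
    ``n_reads`` sums the primer reads of the group's ASVs; the distance
    mean / Q3 (75th percentile, linear interpolation) / max are over the
    group's resolved distances.
    """
    by_id = {a.asv_id: a for a in assignments}
    for res in resolutions:
        a = by_id.get(res.asv_id)
        if a is None or a.category != "Unique":
            raise ValueError(f"resolution for non-Unique ASV {res.asv_id!r}")
    rows = []
    for source in POSSIBLE_SOURCES:
        group = [r for r in resolutions if r.possible_source == source]
        if not group:
            continue
        d = np.array([r.distance.value for r in group])
        rows.append(
            SourceSummary(
                possible_source=source,
                n_reads=int(sum(by_id[r.asv_id].primer_reads for r in group)),
                mean_distance=float(d.mean()),
                q3_distance=float(np.percentile(d, 75)),
                max_distance=float(d.max()),
            )
        )
    return rows


def source_summary_frame(rows: Sequence[SourceSummary]) -> pd.DataFrame:
    """Summary rows as a DataFrame laid out like the published table."""
    return pd.DataFrame(
        [
            {
                "possible_source": r.possible_source,
                "n_reads": r.n_reads,
                "mean": r.mean_distance,
                "q3": r.q3_distance,
                "max": r.max_distance,
            }
            for r in rows
        ],
        columns=["possible_source", "n_reads", "mean", "q3", "max"],
    )


def summarize_composition(
    assignments: Sequence[OriginAssignment], major_threshold: int = DEFAULT_MAJOR_THRESHOLD
) -> pd.DataFrame:
    """Composition of one primer community by origin category and size class.

    Rows are category × {major, minor} (major: primer reads strictly greater
    than ``major_threshold``); columns give the ASV count and summed reads.
    Grand totals are conserved against the assignments.
    """
    if major_threshold <= 0:
        raise ValueError("major_threshold must be positive")
    records = []
    for cat in ORIGIN_CATEGORIES:
        for size_class in ("major", "minor"):
            group = [
                a
                for a in assignments
                if a.category == cat
                and ((a.primer_reads > major_threshold) == (size_class == "major"))
            ]
            records.append(
                {
                    "category": cat,
                    "size_class": size_class,
                    "n_asvs": len(group),
                    "reads": int(sum(a.primer_reads for a in group)),
                }
            )
    return pd.DataFrame(records, columns=["category", "size_class", "n_asvs", "reads"])
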