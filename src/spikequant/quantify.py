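"""Spike-in correction: read counts to volumetric gene-copy abundances.

For each site and community ASV, one estimate is produced per
(technical replicate, internal standard) pair — nine with three of each —
and the site-level abundance is the mean of the retained estimates.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_ingest import CountTable, InputError, SampleRecord, StandardSpec, \
    validate_standards


class StandardDropout(Exception):
    """A (replicate, standard) pair with zero standard reads: the estimate
    is undefined and must be dropped by the caller."""


def standard_reads(counts: CountTable, standard: StandardSpec,
                   sample_id: str) -> int:
    """Total reads across all ASVs assigned to ``standard`` in one sample.

    ASV ids missing from the table contribute 0.
    """
    return sum(counts.reads(asv, sample_id) for asv in standard.asv_ids)


def volumetric_estimate(r_ij: float, c_s: float, r_sj: float,
                        v_j: float) -> float:
    """Gene copies per liter for one taxon/sample/standard combination:
    ``r_ij * c_s / (r_sj * v_j)``.

    Raises :class:`StandardDropout` when the standard received zero reads.
    """
    if c_s <= 0:
        raise InputError(f"standard copy load must be positive, got {c_s}")
    if v_j <= 0:
        raise InputError(f"filtered volume must be positive, got {v_j}")
    if r_sj < 0 or r_ij < 0:
        raise InputError("read counts must be non-negative")
    if r_sj == 0:
        raise StandardDropout("zero standard reads")
    return r_ij * c_s / (r_sj * v_j)


@dataclass
class EstimateSet:
    """All retained volumetric estimates for one (site, ASV)."""

    site_id: str
    asv_id: str
    estimates: list[tuple[int, str, float]]  # (replicate, standard, copies/L)
    mean: float
    min: float
    max: float
    n: int

    @classmethod
    def from_estimates(cls, site_id: str, asv_id: str,
                       estimates: Sequence[tuple[int, str, float]],
                       aggregator: str = "mean") -> "EstimateSet":
        values = [v for _, _, v in estimates]
        if not values:
            raise InputError(f"({site_id}, {asv_id}): no retained estimates")
        if any(not math.isfinite(v) or v < 0 for v in values):
            raise InputError(f"({site_id}, {asv_id}): invalid estimate value")
        if aggregator == "mean":
            center = float(np.mean(values))
        elif aggregator == "median":
            center = float(np.median(values))
        else:
            raise InputError(f"unknown aggregator {aggregator!r}")
        return cls(site_id=site_id, asv_id=asv_id,
                   estimates=list(estimates), mean=center,
                   min=float(min(values)), max=float(max(values)),
                   n=len(values))


@dataclass
class AbundanceMatrix:
    """EstimateSets for every (site, ASV), plus provenance records."""

    sets: dict[tuple[str, str], EstimateSet]
    slot_order: list[tuple[int, str]]
    site_info: dict[str, tuple[float, float, pd.Timestamp]] = \
        field(default_factory=dict)
    dropouts: list[dict] = field(default_factory=list)
    excluded_sites: list[dict] = field(default_factory=list)

    def sites(self) -> list[str]:
        seen: dict[str, None] = {}
        for site, _ in self.sets:
            seen.setdefault(site)
        return list(seen)

    def asvs(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, asv in self.sets:
            seen.setdefault(asv)
        return list(seen)


def _mean_timestamp(stamps: Sequence[pd.Timestamp]) -> pd.Timestamp:
    vals = pd.DatetimeIndex(stamps).asi8
    return pd.Timestamp(int(np.mean(vals)), unit="ns", tz="UTC")


def build_abundance_matrix(counts: CountTable,
                           metadata: Sequence[SampleRecord],
                           standards: Sequence[StandardSpec],
                           aggregator: str = "mean") -> AbundanceMatrix:
    """Produce per-(site, ASV) estimate sets from one count table.

    Standard ASVs are removed from the community universe; ASVs with zero
    reads everywhere are excluded; a (replicate, standard) slot with zero
    standard reads is dropped and logged; a site where every slot dropped
    out is excluded with a warning record.
    """
    validate_standards(standards)
    by_sample = {r.sample_id: r for r in metadata}
    for sid in counts.sample_ids:
        if sid not in by_sample:
            raise InputError(f"sample {sid!r} present in counts but missing "
                             f"from metadata")

    std_asvs = set().union(*(s.asv_ids for s in standards))
    nonzero = counts.counts.sum(axis=1) > 0
    community = [a for a, nz in zip(counts.asv_ids, nonzero)
                 if nz and a not in std_asvs]

    # group samples by site, order replicates numerically
    site_samples: dict[str, list[SampleRecord]] = {}
    for sid in counts.sample_ids:
        rec = by_sample[sid]
        site_samples.setdefault(rec.site_id, []).append(rec)
    for recs in site_samples.values():
        recs.sort(key=lambda r: r.replicate)

    max_rep = max((r.replicate for r in metadata), default=0)
    slot_order = [(rep, std.name)
                  for rep in range(1, max_rep + 1) for std in standards]

    matrix = AbundanceMatrix(sets={}, slot_order=slot_order)
    for site_id, recs in site_samples.items():
        matrix.site_info[site_id] = (
            float(np.mean([r.lat for r in recs])),
            float(np.mean([r.lon for r in recs])),
            _mean_timestamp([r.timestamp for r in recs]))
        # retained (replicate, standard) slots with their R_sj and volume
        slots: list[tuple[int, StandardSpec, SampleRecord, int]] = []
        for rec in recs:
            for std in standards:
                r_sj = standard_reads(counts, std, rec.sample_id)
                if r_sj == 0:
                    matrix.dropouts.append({
                        "site_id": site_id, "sample_id": rec.sample_id,
                        "replicate": rec.replicate, "standard": std.name,
                        "reason": "zero standard reads"})
                    continue
                slots.append((rec.replicate, std, rec, r_sj))
        if not slots:
            matrix.excluded_sites.append({
                "site_id": site_id,
                "reason": "all standards dropped out in all replicates"})
            continue
        for asv in community:
            ests = [(rep, std.name,
                     volumetric_estimate(counts.reads(asv, rec.sample_id),
                                         std.copies_added, r_sj,
                                         rec.volume_L))
                    for rep, std, rec, r_sj in slots]
            matrix.sets[(site_id, asv)] = EstimateSet.from_estimates(
                site_id, asv, ests, aggregator=aggregator)
    return matrix


@dataclass
class ErrorSummary:
    """Pooled technical percent errors for one group of estimate sets."""

    label: str
    percent_errors: np.ndarray
    percentile: float
    p_value: float  # percent error at `percentile`
    median: float

    @property
    def n(self) -> int:
        return int(self.percent_errors.size)


def pooled_percent_errors(
        groups: Iterable[tuple[Sequence[float], float]]) -> np.ndarray:
    """Pool |estimate - mean| / mean * 100 over (values, mean) groups.

    Groups with fewer than two values or non-positive mean are skipped.
    """
    pool: list[float] = []
    for values, mean in groups:
        if len(values) < 2 or not mean > 0:
            continue
        pool.extend(abs(v - mean) / mean * 100.0 for v in values)
    return np.asarray(pool, dtype=float)


def percent_error_summary(matrix: AbundanceMatrix,
                          asv_subset: set[str] | None = None,
                          percentile: float = 0.95,
                          label: str = "all") -> ErrorSummary:
    """Pipeline-wide percent-error pool over the given ASV subset.

    The reported quantile uses linear interpolation between order
    statistics (numpy's default), so it is reproducible across runs.
    """
    groups = (([v for _, _, v in es.estimates], es.mean)
              for (site, asv), es in matrix.sets.items()
              if asv_subset is None or asv in asv_subset)
    pool = pooled_percent_errors(groups)
    if pool.size == 0:
        raise InputError("no estimates to summarize")
    return ErrorSummary(
        label=label, percent_errors=pool, percentile=percentile,
        p_value=float(np.percentile(pool, percentile * 100.0,
                                    method="linear")),
        median=float(np.median(pool)))
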