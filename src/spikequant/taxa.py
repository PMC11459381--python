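"""ASV-to-taxon assignment, copy-number conversion, taxon aggregates.

Aggregation order per site and taxon: member-ASV gene-copy estimates are
summed within each (replicate, standard) slot, converted to cells via the
taxon's 16S copies-per-cell, and only then averaged across slots. Taxa
without a configured copy number stay in copies/L.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_ingest import InputError, _FLOAT_FMT
from .quantify import AbundanceMatrix, ErrorSummary, pooled_percent_errors

logger = logging.getLogger(__name__)

OTHER = "other"


class AmbiguousTaxonError(InputError):
    """An ASV's taxonomy string matched more than one configured taxon."""


class UndefinedRatioError(ValueError):
    """Ratio requested against a zero-mean denominator."""


@dataclass
class TaxonAssignment:
    """Deterministic ASV -> taxon mapping; unmatched ASVs map to 'other'."""

    mapping: dict[str, str]
    taxa: list[str]

    def taxon_of(self, asv_id: str) -> str:
        return self.mapping.get(asv_id, OTHER)


def assign_taxa(taxonomy: Mapping[str, str],
                patterns: Mapping[str, str]) -> TaxonAssignment:
    """Match semicolon-ranked taxonomy strings against substring patterns.

    A pattern matches when it occurs in any rank token. Two patterns
    matching the same ASV is a configuration error.
    """
    mapping: dict[str, str] = {}
    for asv, tax_string in taxonomy.items():
        ranks = [r.strip() for r in str(tax_string).split(";")]
        hits = [taxon for taxon, pat in patterns.items()
                if any(pat in rank for rank in ranks)]
        if len(hits) > 1:
            raise AmbiguousTaxonError(
                f"ASV {asv!r} matches multiple taxa: {sorted(hits)} "
                f"(taxonomy {tax_string!r})")
        mapping[asv] = hits[0] if hits else OTHER
    return TaxonAssignment(mapping=mapping, taxa=list(patterns))


def cells_from_copies(copy_abundance: float, copies_per_cell: float) -> float:
    """Convert copies/L to cells/L by dividing by 16S copies per cell."""
    if copies_per_cell < 1:
        raise InputError(f"copies_per_cell must be >= 1, got "
                         f"{copies_per_cell}")
    return copy_abundance / copies_per_cell


@dataclass
class TaxonAbundance:
    """Per-site taxon abundance with one value per retained slot."""

    site_id: str
    taxon: str
    estimates: list[tuple[int, str, float]]
    mean: float
    min: float
    max: float
    n: int
    unit: str  # "cells_per_L" or "copies_per_L"
    copies_per_cell: float | None
    lat: float | None = None
    lon: float | None = None
    timestamp: pd.Timestamp | None = None


def taxon_abundances(matrix: AbundanceMatrix,
                     assignment: TaxonAssignment,
                     copy_map: Mapping[str, float],
                     include_other: bool = True) -> list[TaxonAbundance]:
    """Aggregate the ASV-level matrix to taxon level, site by site.

    Slot alignment is by (replicate, standard) key, so the member-ASV sums
    combine like with like; a dropped slot is absent for every ASV of the
    sample, hence absent from the taxon as well.
    """
    for taxon, cpc in copy_map.items():
        if cpc < 1:
            raise InputError(f"copy number for {taxon!r} must be >= 1")
    targets = list(assignment.taxa)
    if include_other:
        targets.append(OTHER)

    by_site: dict[str, dict[str, list]] = {}
    for (site, asv), es in matrix.sets.items():
        taxon = assignment.taxon_of(asv)
        by_site.setdefault(site, {}).setdefault(taxon, []).append(es)

    out: list[TaxonAbundance] = []
    for site in sorted(by_site):
        members_by_taxon = by_site[site]
        info = matrix.site_info.get(site)
        lat, lon, ts = info if info is not None else (None, None, None)
        any_member = next(iter(members_by_taxon.values()))[0]
        site_slots = [(r, s) for r, s, _ in any_member.estimates]
        for taxon in targets:
            members = members_by_taxon.get(taxon, [])
            cpc = copy_map.get(taxon)
            if not members:
                logger.warning("taxon %r has no member ASVs at site %s",
                               taxon, site)
                slot_sums: dict[tuple[int, str], float] = {
                    key: 0.0 for key in site_slots}
            else:
                slot_sums = {}
                for es in members:
                    for rep, std, v in es.estimates:
                        slot_sums[(rep, std)] = \
                            slot_sums.get((rep, std), 0.0) + v
            factor = 1.0 if cpc is None else cpc
            ests = [(rep, std, total / factor)
                    for (rep, std), total in sorted(
                        slot_sums.items(),
                        key=lambda kv: matrix.slot_order.index(kv[0]))]
            values = [v for _, _, v in ests]
            out.append(TaxonAbundance(
                site_id=site, taxon=taxon, estimates=ests,
                mean=float(np.mean(values)), min=float(min(values)),
                max=float(max(values)), n=len(values),
                unit="copies_per_L" if cpc is None else "cells_per_L",
                copies_per_cell=cpc, lat=lat, lon=lon, timestamp=ts))
    return out


def abundance_ratio(numerator: TaxonAbundance,
                    denominator: TaxonAbundance) -> float:
    """Ratio of site-level means (ratio of means, not mean of ratios)."""
    if numerator.site_id != denominator.site_id:
        raise InputError(
            f"ratio across different sites: {numerator.site_id!r} vs "
            f"{denominator.site_id!r}")
    if not denominator.mean > 0:
        raise UndefinedRatioError(
            f"site {numerator.site_id}: zero-mean denominator "
            f"{denominator.taxon!r}")
    return numerator.mean / denominator.mean


def taxon_percent_error_summary(abundances: Sequence[TaxonAbundance],
                                taxon: str,
                                percentile: float = 0.95) -> ErrorSummary:
    """Percent-error pool of per-slot taxon estimates around site means."""
    groups = (([v for _, _, v in ta.estimates], ta.mean)
              for ta in abundances if ta.taxon == taxon)
    pool = pooled_percent_errors(groups)
    if pool.size == 0:
        raise InputError("no estimates to summarize")
    return ErrorSummary(
        label=taxon, percent_errors=pool, percentile=percentile,
        p_value=float(np.percentile(pool, percentile * 100.0,
                                    method="linear")),
        median=float(np.median(pool)))


# ---------------------------------------------------------------------------
# serialization

def write_taxon_table(abundances: Sequence[TaxonAbundance],
                      path: str | Path) -> None:
    slot_keys: list[tuple[int, str]] = []
    for ta in abundances:
        for rep, std, _ in ta.estimates:
            if (rep, std) not in slot_keys:
                slot_keys.append((rep, std))
    header = ["site_id", "taxon", "unit", "copies_per_cell",
              "site_lat", "site_lon", "site_time",
              "mean", "min", "max", "n_estimates"]
    header += [f"r{r}:{s}" for r, s in slot_keys]
    lines = ["\t".join(header)]
    for ta in abundances:
        by_slot = {(r, s): v for r, s, v in ta.estimates}
        row = [ta.site_id, ta.taxon, ta.unit,
               "NA" if ta.copies_per_cell is None
               else _FLOAT_FMT % ta.copies_per_cell,
               "NA" if ta.lat is None else _FLOAT_FMT % ta.lat,
               "NA" if ta.lon is None else _FLOAT_FMT % ta.lon,
               "NA" if ta.timestamp is None
               else pd.Timestamp(ta.timestamp).isoformat(),
               _FLOAT_FMT % ta.mean, _FLOAT_FMT % ta.min,
               _FLOAT_FMT % ta.max, str(ta.n)]
        for key in slot_keys:
            v = by_slot.get(key)
            row.append("NA" if v is None else _FLOAT_FMT % v)
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_taxon_table(path: str | Path) -> list[TaxonAbundance]:
    path = Path(path)
    out: list[TaxonAbundance] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        fixed = ["site_id", "taxon", "unit", "copies_per_cell",
                 "site_lat", "site_lon", "site_time",
                 "mean", "min", "max", "n_estimates"]
        if header[:len(fixed)] != fixed:
            raise InputError(f"{path}: not a taxon abundance table")
        slot_keys = []
        for col in header[len(fixed):]:
            rep_s, std = col.split(":", 1)
            slot_keys.append((int(rep_s[1:]), std))
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not parts or parts == [""]:
                continue
            ests = []
            for key, raw in zip(slot_keys, parts[len(fixed):]):
                if raw != "NA":
                    ests.append((key[0], key[1], float(raw)))
            values = [v for _, _, v in ests]
            out.append(TaxonAbundance(
                site_id=parts[0], taxon=parts[1], unit=parts[2],
                copies_per_cell=None if parts[3] == "NA" else float(parts[3]),
                lat=None if parts[4] == "NA" else float(parts[4]),
                lon=None if parts[5] == "NA" else float(parts[5]),
                timestamp=None if parts[6] == "NA"
                else pd.Timestamp(parts[6]),
                estimates=ests, mean=float(parts[7]), min=float(parts[8]),
                max=float(parts[9]), n=int(parts[10])))
    return out
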