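"""Pair amplicon sites with flow-cytometry events and validate agreement.

Pairing is greedy nearest-first one-to-one by default: candidate
(site, event) pairs within the distance and time bounds are sorted by
(distance, |time offset|, site_id, event_id) and accepted so that each
site and each event is used at most once. Relaxing the distance bound only
appends candidates to that order, so the pair count is non-decreasing.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_ingest import FcmObservation, InputError, SampleRecord, _FLOAT_FMT
from .taxa import TaxonAbundance

EARTH_RADIUS_KM = 6371.0


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance between two points, spherical Earth."""
    for lat in (lat1, lat2):
        if not -90.0 <= lat <= 90.0:
            raise InputError(f"latitude out of range: {lat}")
    for lon in (lon1, lon2):
        if not -180.0 <= lon < 180.0:
            raise InputError(f"longitude out of range: {lon}")
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = math.radians(lat2 - lat1)
    dl = math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * \
        math.sin(dl / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))


@dataclass(frozen=True)
class SitePoint:
    """A site's representative position/time: mean over its replicates."""

    site_id: str
    lat: float
    lon: float
    timestamp: pd.Timestamp


def site_points(metadata: Sequence[SampleRecord]) -> list[SitePoint]:
    by_site: dict[str, list[SampleRecord]] = {}
    for rec in metadata:
        by_site.setdefault(rec.site_id, []).append(rec)
    points = []
    for site_id in sorted(by_site):
        recs = by_site[site_id]
        ns = pd.DatetimeIndex([r.timestamp for r in recs]).asi8
        points.append(SitePoint(
            site_id=site_id,
            lat=float(np.mean([r.lat for r in recs])),
            lon=float(np.mean([r.lon for r in recs])),
            timestamp=pd.Timestamp(int(np.mean(ns)), unit="ns", tz="UTC")))
    return points


def site_points_from_abundances(
        abundances: Sequence[TaxonAbundance]) -> list[SitePoint]:
    """Site positions carried through the taxon abundance table."""
    seen: dict[str, SitePoint] = {}
    for ta in abundances:
        if ta.site_id in seen:
            continue
        if ta.lat is None or ta.lon is None or ta.timestamp is None:
            raise InputError(f"site {ta.site_id!r} lacks position/time "
                             f"metadata")
        seen[ta.site_id] = SitePoint(ta.site_id, ta.lat, ta.lon,
                                     pd.Timestamp(ta.timestamp))
    return [seen[s] for s in sorted(seen)]


@dataclass
class FcmEvent:
    """One FCM sampling event with its per-population observations."""

    event_id: str
    timestamp: pd.Timestamp
    lat: float
    lon: float
    populations: dict[str, FcmObservation]


def group_fcm_events(observations: Sequence[FcmObservation]) -> list[FcmEvent]:
    events: dict[str, FcmEvent] = {}
    for obs in observations:
        ev = events.get(obs.event_id)
        if ev is None:
            events[obs.event_id] = FcmEvent(
                event_id=obs.event_id, timestamp=obs.timestamp,
                lat=obs.lat, lon=obs.lon, populations={obs.population: obs})
        else:
            ev.populations[obs.population] = obs
    return [events[e] for e in sorted(events)]


@dataclass(frozen=True)
class MatchupCriteria:
    max_distance_km: float = 20.0
    max_hours: float = 6.0
    pairing_policy: str = "nearest_one_to_one"  # or "all_pairs"

    def __post_init__(self) -> None:
        if self.max_distance_km <= 0 or self.max_hours <= 0:
            raise InputError("matchup bounds must be positive")
        if self.pairing_policy not in ("nearest_one_to_one", "all_pairs"):
            raise InputError(f"unknown pairing policy "
                             f"{self.pairing_policy!r}")


@dataclass
class MatchupPair:
    site_id: str
    event_id: str
    distance_km: float
    delta_hours: float  # event time minus site time, signed


def find_matchups(sites: Sequence[SitePoint], events: Sequence[FcmEvent],
                  criteria: MatchupCriteria = MatchupCriteria()
                  ) -> list[MatchupPair]:
    """All (site, event) pairs within bounds, reduced per the policy.

    Deterministic under input reordering: candidates are sorted by
    (distance, |dt|, site_id, event_id) before greedy acceptance.
    """
    candidates: list[MatchupPair] = []
    for site in sites:
        for ev in events:
            d = haversine_km(site.lat, site.lon, ev.lat, ev.lon)
            dt = (ev.timestamp - site.timestamp).total_seconds() / 3600.0
            if d <= criteria.max_distance_km and \
                    abs(dt) <= criteria.max_hours:
                candidates.append(MatchupPair(site.site_id, ev.event_id,
                                              d, dt))
    candidates.sort(key=lambda p: (p.distance_km, abs(p.delta_hours),
                                   p.site_id, p.event_id))
    if criteria.pairing_policy == "all_pairs":
        return candidates
    used_sites: set[str] = set()
    used_events: set[str] = set()
    accepted = []
    for pair in candidates:
        if pair.site_id in used_sites or pair.event_id in used_events:
            continue
        used_sites.add(pair.site_id)
        used_events.add(pair.event_id)
        accepted.append(pair)
    return accepted


@dataclass
class RegressionResult:
    """OLS fit of y on x plus auxiliary slopes for auditability."""

    n_points: int
    slope: float
    intercept: float
    pearson_r: float
    slope_through_origin: float
    slope_x_on_y: float

    def as_dict(self) -> dict:
        return {"n_points": self.n_points, "slope": self.slope,
                "intercept": self.intercept, "pearson_r": self.pearson_r,
                "slope_through_origin": self.slope_through_origin,
                "slope_x_on_y": self.slope_x_on_y}


def paired_regression(points: Sequence[tuple[float, float]]
                      ) -> RegressionResult:
    """Ordinary least squares with free intercept, plus Pearson r.

    Orientation: x is the reference instrument (FCM), y the amplicon
    estimate; the reverse slope and the forced-through-origin slope are
    reported alongside.
    """
    if len(points) < 3:
        raise InputError(f"need >= 3 points for regression, got "
                         f"{len(points)}")
    x = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    if np.ptp(x) == 0:
        raise InputError("degenerate regression: zero variance in x")
    from scipy import stats
    fit = stats.linregress(x, y)
    origin = float(np.dot(x, y) / np.dot(x, x))
    if np.ptp(y) == 0:
        x_on_y = math.nan
    else:
        x_on_y = float(stats.linregress(y, x).slope)
    return RegressionResult(
        n_points=len(points), slope=float(fit.slope),
        intercept=float(fit.intercept), pearson_r=float(fit.rvalue),
        slope_through_origin=origin, slope_x_on_y=x_on_y)


def _abundance_lookup(abundances: Sequence[TaxonAbundance]
                      ) -> dict[tuple[str, str], TaxonAbundance]:
    return {(ta.site_id, ta.taxon): ta for ta in abundances}


@dataclass
class PairedValue:
    site_id: str
    event_id: str
    population: str
    fcm_mean: float
    fcm_range: tuple[float, float]
    amplicon_mean: float
    amplicon_range: tuple[float, float]


def paired_values(pairs: Sequence[MatchupPair],
                  abundances: Sequence[TaxonAbundance],
                  events: Sequence[FcmEvent],
                  populations: Sequence[str]) -> list[PairedValue]:
    """Join matchup pairs with both instruments' means and ranges."""
    lut = _abundance_lookup(abundances)
    ev_by_id = {e.event_id: e for e in events}
    out = []
    for pair in pairs:
        ev = ev_by_id[pair.event_id]
        for pop in populations:
            ta = lut.get((pair.site_id, pop))
            obs = ev.populations.get(pop)
            if ta is None or obs is None:
                continue
            out.append(PairedValue(
                site_id=pair.site_id, event_id=pair.event_id,
                population=pop, fcm_mean=obs.mean_count,
                fcm_range=obs.range, amplicon_mean=ta.mean,
                amplicon_range=(ta.min, ta.max)))
    return out


def cell_count_points(pairs: Sequence[MatchupPair],
                      abundances: Sequence[TaxonAbundance],
                      events: Sequence[FcmEvent],
                      populations: Sequence[str] = ("Prochlorococcus",
                                                    "Synechococcus")
                      ) -> list[tuple[float, float]]:
    """(FCM, amplicon) cell-count points, both populations pooled."""
    return [(pv.fcm_mean, pv.amplicon_mean)
            for pv in paired_values(pairs, abundances, events, populations)]


def ratio_points(pairs: Sequence[MatchupPair],
                 abundances: Sequence[TaxonAbundance],
                 events: Sequence[FcmEvent],
                 numerator: str = "Prochlorococcus",
                 denominator: str = "Synechococcus",
                 excluded: list | None = None
                 ) -> list[tuple[float, float]]:
    """(FCM ratio, amplicon ratio) points; pairs with a zero term in
    either instrument are excluded (and recorded if a list is given)."""
    lut = _abundance_lookup(abundances)
    ev_by_id = {e.event_id: e for e in events}
    pts = []
    for pair in pairs:
        ev = ev_by_id[pair.event_id]
        ta_n = lut.get((pair.site_id, numerator))
        ta_d = lut.get((pair.site_id, denominator))
        obs_n = ev.populations.get(numerator)
        obs_d = ev.populations.get(denominator)
        vals = (ta_n, ta_d, obs_n, obs_d)
        if any(v is None for v in vals) or not ta_d.mean > 0 or \
                not obs_d.mean_count > 0 or not ta_n.mean > 0 or \
                not obs_n.mean_count > 0:
            if excluded is not None:
                excluded.append({"site_id": pair.site_id,
                                 "event_id": pair.event_id,
                                 "reason": "zero or missing taxon value"})
            continue
        pts.append((obs_n.mean_count / obs_d.mean_count,
                    ta_n.mean / ta_d.mean))
    return pts


@dataclass
class SensitivityRow:
    distance_km: float
    n_pairs: int
    cell_regression: RegressionResult | None
    ratio_regression: RegressionResult | None
    flags: list[str] = field(default_factory=list)


def sensitivity_analysis(sites: Sequence[SitePoint],
                         events: Sequence[FcmEvent],
                         abundances: Sequence[TaxonAbundance],
                         distance_grid: Sequence[float],
                         max_hours: float = 6.0,
                         populations: Sequence[str] = ("Prochlorococcus",
                                                       "Synechococcus"),
                         pairing_policy: str = "nearest_one_to_one"
                         ) -> list[SensitivityRow]:
    """Re-run pairing and both regressions over a grid of distance bounds."""
    if not distance_grid:
        raise InputError("distance_grid must be non-empty")
    if list(distance_grid) != sorted(distance_grid):
        raise InputError("distance_grid must be ascending")
    rows: list[SensitivityRow] = []
    prev_n = 0
    for bound in distance_grid:
        criteria = MatchupCriteria(max_distance_km=bound,
                                   max_hours=max_hours,
                                   pairing_policy=pairing_policy)
        pairs = find_matchups(sites, events, criteria)
        row = SensitivityRow(distance_km=float(bound), n_pairs=len(pairs),
                             cell_regression=None, ratio_regression=None)
        try:
            row.cell_regression = paired_regression(
                cell_count_points(pairs, abundances, events, populations))
        except InputError as exc:
            row.flags.append(f"cell regression absent: {exc}")
        try:
            row.ratio_regression = paired_regression(
                ratio_points(pairs, abundances, events,
                             populations[0], populations[1]))
        except InputError as exc:
            row.flags.append(f"ratio regression absent: {exc}")
        if len(pairs) < prev_n:
            raise AssertionError("pair count decreased as the distance "
                                 "bound was relaxed")
        prev_n = len(pairs)
        rows.append(row)
    return rows


# ---------------------------------------------------------------------------
# result tables and plots

def write_pairs_table(pairs: Sequence[MatchupPair],
                      values: Sequence[PairedValue],
                      path: str | Path) -> None:
    header = ["site_id", "event_id", "distance_km", "delta_hours",
              "population", "fcm_mean", "fcm_min", "fcm_max",
              "amplicon_mean", "amplicon_min", "amplicon_max"]
    geo = {(p.site_id, p.event_id): p for p in pairs}
    lines = ["\t".join(header)]
    for pv in values:
        p = geo[(pv.site_id, pv.event_id)]
        lines.append("\t".join([
            pv.site_id, pv.event_id, _FLOAT_FMT % p.distance_km,
            _FLOAT_FMT % p.delta_hours, pv.population,
            _FLOAT_FMT % pv.fcm_mean, _FLOAT_FMT % pv.fcm_range[0],
            _FLOAT_FMT % pv.fcm_range[1], _FLOAT_FMT % pv.amplicon_mean,
            _FLOAT_FMT % pv.amplicon_range[0],
            _FLOAT_FMT % pv.amplicon_range[1]]))
    Path(path).write_text("\n".join(lines) + "\n")


def write_regressions_table(named: Mapping[str, RegressionResult],
                            path: str | Path) -> None:
    header = ["name", "n_points", "slope", "intercept", "pearson_r",
              "slope_through_origin", "slope_x_on_y"]
    lines = ["\t".join(header)]
    for name, rr in named.items():
        lines.append("\t".join([
            name, str(rr.n_points), _FLOAT_FMT % rr.slope,
            _FLOAT_FMT % rr.intercept, _FLOAT_FMT % rr.pearson_r,
            _FLOAT_FMT % rr.slope_through_origin,
            "NA" if math.isnan(rr.slope_x_on_y)
            else _FLOAT_FMT % rr.slope_x_on_y]))
    Path(path).write_text("\n".join(lines) + "\n")


def write_sensitivity_table(rows: Sequence[SensitivityRow],
                            path: str | Path) -> None:
    header = ["distance_km", "n_pairs",
              "cell_slope", "cell_r", "ratio_slope", "ratio_r", "flags"]
    lines = ["\t".join(header)]
    for row in rows:
        cs = cr = rs = rr_ = "NA"
        if row.cell_regression is not None:
            cs = _FLOAT_FMT % row.cell_regression.slope
            cr = _FLOAT_FMT % row.cell_regression.pearson_r
        if row.ratio_regression is not None:
            rs = _FLOAT_FMT % row.ratio_regression.slope
            rr_ = _FLOAT_FMT % row.ratio_regression.pearson_r
        lines.append("\t".join([
            _FLOAT_FMT % row.distance_km, str(row.n_pairs),
            cs, cr, rs, rr_, ";".join(row.flags)]))
    Path(path).write_text("\n".join(lines) + "\n")


def write_validation_plots(values: Sequence[PairedValue],
                           ratio_pts: Sequence[tuple[float, float]],
                           abundances: Sequence[TaxonAbundance],
                           outdir: str | Path) -> list[Path]:
    """Transect profile, amplicon-vs-FCM scatter, and ratio scatter."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    pops = sorted({pv.population for pv in values})

    fig, ax = plt.subplots(figsize=(7, 4))
    for pop in pops:
        tas = sorted((ta for ta in abundances
                      if ta.taxon == pop and ta.lat is not None),
                     key=lambda t: t.lat)
        if tas:
            lats = [ta.lat for ta in tas]
            ax.fill_between(lats, [ta.min for ta in tas],
                            [ta.max for ta in tas], alpha=0.3)
            ax.plot(lats, [ta.mean for ta in tas], label=f"{pop} (amplicon)")
        pvs = [pv for pv in values if pv.population == pop]
        site_lat = {ta.site_id: ta.lat for ta in abundances
                    if ta.lat is not None}
        ax.errorbar([site_lat[pv.site_id] for pv in pvs],
                    [pv.fcm_mean for pv in pvs],
                    yerr=[[pv.fcm_mean - pv.fcm_range[0] for pv in pvs],
                          [pv.fcm_range[1] - pv.fcm_mean for pv in pvs]],
                    fmt="s", ms=4, lw=1, label=f"{pop} (FCM)")
    ax.set_xlabel("latitude")
    ax.set_ylabel("cells / L")
    ax.set_yscale("log")
    ax.legend(fontsize=7)
    fig.tight_layout()
    p = outdir / "transect.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    site_lat = {ta.site_id: ta.lat for ta in abundances
                if ta.lat is not None}
    fig, ax = plt.subplots(figsize=(5, 5))
    xs = [pv.fcm_mean for pv in values]
    ys = [pv.amplicon_mean for pv in values]
    cs = [site_lat.get(pv.site_id, 0.0) for pv in values]
    sc = ax.scatter(xs, ys, c=cs, cmap="viridis")
    lim = [min(xs + ys), max(xs + ys)] if xs else [0, 1]
    ax.plot(lim, lim, "k--", lw=0.8)
    ax.set_xlabel("FCM cells / L")
    ax.set_ylabel("amplicon cells / L")
    ax.set_xscale("log")
    ax.set_yscale("log")
    fig.colorbar(sc, label="latitude")
    fig.tight_layout()
    p = outdir / "scatter_cells.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    fig, ax = plt.subplots(figsize=(5, 5))
    if ratio_pts:
        xs = [p_[0] for p_ in ratio_pts]
        ys = [p_[1] for p_ in ratio_pts]
        ax.scatter(xs, ys)
        lim = [min(xs + ys), max(xs + ys)]
        ax.plot(lim, lim, "k--", lw=0.8)
        ax.set_xscale("log")
        ax.set_yscale("log")
    ax.set_xlabel("FCM Pro:Syn ratio")
    ax.set_ylabel("amplicon Pro:Syn ratio")
    fig.tight_layout()
    p = outdir / "scatter_ratio.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)
    return written
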