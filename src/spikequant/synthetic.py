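"""Synthetic cruise-transect study generator.

Produces a fully specified ground truth — smooth latitudinal abundance
profiles for a small community, spike-in copy loads, sample geometry —
and simulates amplicon read counts (multinomial over community + standard
loads) and underway flow-cytometry observations from it. Because the truth
is closed-form, pipeline recovery can be asserted exactly.

Standards are exempt from per-replicate capture noise: they are added to
the lysis buffer after filtration, so filtration efficiency does not touch
them, while community taxa pass through the filter and do.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .io_ingest import (CountTable, FcmObservation, SampleRecord,
                        StandardSpec, standard_copy_load)

KM_PER_DEG_LAT = 2 * np.pi * 6371.0 / 360.0  # ~111.19 on the sphere used


def _slug(name: str) -> str:
    return name.lower().replace(" ", "_")


@dataclass(frozen=True)
class TaxonProfile:
    """A taxon's smooth latitudinal abundance profile (cells/L).

    ``cells(lat) = base + amplitude * sigmoid(sign * (lat - center) / width)``
    with ``sign = +1`` when ``rising`` (abundance increases northward).
    """

    name: str
    copies_per_cell: float
    base_cells_per_L: float
    amplitude_cells_per_L: float
    center_lat: float
    width_deg: float
    rising: bool = True
    fcm_visible: bool = False
    n_asvs: int = 1
    amplification_bias: float = 1.0

    def cells_at(self, lat: float | np.ndarray) -> np.ndarray:
        z = (np.asarray(lat, dtype=float) - self.center_lat) / self.width_deg
        if not self.rising:
            z = -z
        return self.base_cells_per_L + \
            self.amplitude_cells_per_L / (1.0 + np.exp(-z))

    def asv_weights(self) -> np.ndarray:
        # split one taxon across ASVs with fixed geometric weights
        w = 0.5 ** np.arange(self.n_asvs)
        return w / w.sum()


@dataclass(frozen=True)
class StandardConfig:
    name: str
    mass_ng: float
    genome_size_bp: float
    copies_per_genome: float
    taxonomy: str


def default_taxa() -> list[TaxonProfile]:
    return [
        TaxonProfile("Prochlorococcus", 1, 2.0e7, 1.8e8, 32.0, 2.0,
                     rising=False, fcm_visible=True, n_asvs=3),
        TaxonProfile("Synechococcus", 2, 4.0e6, 8.0e7, 32.0, 2.0,
                     rising=True, fcm_visible=True, n_asvs=2),
        TaxonProfile("Pelagibacter", 1, 2.0e8, 6.0e7, 30.0, 4.0,
                     rising=True),
        TaxonProfile("Roseobacter", 4, 1.5e7, 1.0e7, 33.0, 3.0,
                     rising=True),
    ]


def default_standards() -> list[StandardConfig]:
    return [
        StandardConfig("Blautia producta", 4.0, 6.6e6, 6,
                       "Bacteria;Bacillota;Clostridia;Lachnospirales;"
                       "Lachnospiraceae;Blautia;Blautia_producta"),
        StandardConfig("Deinococcus radiodurans", 4.0, 3.28e6, 3,
                       "Bacteria;Deinococcota;Deinococci;Deinococcales;"
                       "Deinococcaceae;Deinococcus;Deinococcus_radiodurans"),
        StandardConfig("Thermus thermophilus", 4.0, 2.13e6, 2,
                       "Bacteria;Deinococcota;Deinococci;Thermales;"
                       "Thermaceae;Thermus;Thermus_thermophilus"),
    ]


_TAXONOMY = {
    "Prochlorococcus": "Bacteria;Cyanobacteria;Cyanobacteriia;"
                       "Synechococcales;Cyanobiaceae;Prochlorococcus",
    "Synechococcus": "Bacteria;Cyanobacteria;Cyanobacteriia;"
                     "Synechococcales;Cyanobiaceae;Synechococcus_CC9902",
    "Pelagibacter": "Bacteria;Proteobacteria;Alphaproteobacteria;"
                    "Pelagibacterales;Pelagibacteraceae;Pelagibacter",
    "Roseobacter": "Bacteria;Proteobacteria;Alphaproteobacteria;"
                   "Rhodobacterales;Rhodobacteraceae;Roseobacter",
}


@dataclass(frozen=True)
class SimulationConfig:
    n_sites: int = 65
    site_spacing_km: float = 46.0
    replicates_per_site: int = 3
    standards: tuple[StandardConfig, ...] = \
        field(default_factory=lambda: tuple(default_standards()))
    target_spike_fraction: float = 0.01  # nominal; realized by the defaults
    reads_per_sample: int = 100_000
    depth_jitter: float = 0.2  # uniform +/- on reads_per_sample
    volume_L: float = 2.0
    volume_jitter: float = 0.1
    taxa: tuple[TaxonProfile, ...] = \
        field(default_factory=lambda: tuple(default_taxa()))
    replicate_noise_sigma: float = 0.1  # lognormal capture efficiency
    fcm_per_day: int = 3
    fcm_replicates: int = 3
    fcm_noise_sigma: float = 0.05
    fcm_start_offset_h: float = 1.0
    hours_between_sites: float = 3.4
    start_lat: float = 22.0
    lon: float = -152.0
    start_time: str = "2021-11-20T00:00:00Z"

    def __post_init__(self) -> None:
        if self.n_sites < 1 or self.replicates_per_site < 1:
            raise ValueError("site and replicate counts must be positive")
        if not 0 < self.target_spike_fraction < 0.5:
            raise ValueError("target_spike_fraction must be in (0, 0.5)")
        if self.reads_per_sample < 1 or self.volume_L <= 0:
            raise ValueError("reads and volume must be positive")
        names = [t.name for t in self.taxa]
        if len(names) != len(set(names)):
            raise ValueError("duplicate taxon names")


@dataclass
class GroundTruth:
    """Closed-form truth the pipeline is asked to recover."""

    config: SimulationConfig
    site_ids: list[str]
    lats: np.ndarray
    lons: np.ndarray
    times: pd.DatetimeIndex
    true_cells: pd.DataFrame   # site x taxon, cells/L
    true_copies: pd.DataFrame  # site x taxon, copies/L
    standard_copies: dict[str, float]

    @property
    def duration_hours(self) -> float:
        return (self.times[-1] - self.times[0]).total_seconds() / 3600.0

    def lat_at_hours(self, t_h: float | np.ndarray) -> np.ndarray:
        """Interpolate the ship's latitude at hours since transect start."""
        site_h = (self.times - self.times[0]).total_seconds() / 3600.0
        return np.interp(t_h, site_h, self.lats)

    def cells_at_hours(self, taxon: str, t_h: float) -> float:
        prof = next(t for t in self.config.taxa if t.name == taxon)
        return float(prof.cells_at(self.lat_at_hours(t_h)))


def make_transect(config: SimulationConfig) -> GroundTruth:
    """Lay sites along a northward meridional track at the configured
    spacing, with monotone timestamps and smooth abundance profiles."""
    n = config.n_sites
    site_ids = [f"S{i + 1:03d}" for i in range(n)]
    lats = config.start_lat + \
        np.arange(n) * config.site_spacing_km / KM_PER_DEG_LAT
    lons = np.full(n, config.lon)
    t0 = pd.Timestamp(config.start_time)
    times = pd.DatetimeIndex(
        [t0 + pd.Timedelta(hours=config.hours_between_sites * i)
         for i in range(n)])
    cells = pd.DataFrame(
        {t.name: t.cells_at(lats) for t in config.taxa}, index=site_ids)
    copies = pd.DataFrame(
        {t.name: cells[t.name] * t.copies_per_cell for t in config.taxa},
        index=site_ids)
    std_copies = {
        s.name: standard_copy_load(s.mass_ng, s.genome_size_bp,
                                   s.copies_per_genome)
        for s in config.standards}
    return GroundTruth(config=config, site_ids=site_ids, lats=lats,
                       lons=lons, times=times, true_cells=cells,
                       true_copies=copies, standard_copies=std_copies)


@dataclass
class SimulatedReads:
    """Read counts plus everything needed to ingest and to audit them."""

    counts: CountTable
    standards: list[StandardSpec]
    samples: list[SampleRecord]
    taxonomy: dict[str, str]
    asv_taxon: dict[str, str]
    capture: dict[str, float]          # per-sample filtration efficiency
    community_load: dict[str, float]   # copies on filter, per sample
    expected_standard_fraction: dict[str, float]


def simulate_reads(truth: GroundTruth, config: SimulationConfig,
                   rng: np.random.Generator) -> SimulatedReads:
    """Draw multinomial read vectors over community + standard loads.

    Per sample: community taxon load = cells * copies_per_cell * volume *
    capture * amplification_bias; standard load = its copy spike (no
    capture term). Read depth is jittered per sample.
    """
    sigma = config.replicate_noise_sigma
    # community ASVs, taxon loads split by fixed weights
    asv_ids: list[str] = []
    asv_taxon: dict[str, str] = {}
    asv_weight: list[float] = []
    asv_bias: list[float] = []
    taxonomy: dict[str, str] = {}
    for prof in config.taxa:
        weights = prof.asv_weights()
        for k in range(prof.n_asvs):
            aid = f"asv_{_slug(prof.name)}_{k + 1}"
            asv_ids.append(aid)
            asv_taxon[aid] = prof.name
            asv_weight.append(weights[k])
            asv_bias.append(prof.amplification_bias)
            taxonomy[aid] = _TAXONOMY.get(
                prof.name, f"Bacteria;Unclassified;{prof.name}")
    standards = []
    for s in config.standards:
        aid = f"std_{_slug(s.name)}"
        standards.append(StandardSpec(
            name=s.name, mass_ng=s.mass_ng, genome_size_bp=s.genome_size_bp,
            copies_per_genome=s.copies_per_genome,
            asv_ids=frozenset([aid])))
        taxonomy[aid] = s.taxonomy
    std_asv_ids = [next(iter(s.asv_ids)) for s in standards]
    std_loads = np.array([s.copies_added for s in standards])

    all_ids = asv_ids + std_asv_ids
    n_samples = len(truth.site_ids) * config.replicates_per_site
    counts = np.zeros((len(all_ids), n_samples), dtype=np.int64)

    samples: list[SampleRecord] = []
    capture: dict[str, float] = {}
    community_load: dict[str, float] = {}
    expected_frac: dict[str, float] = {}
    taxon_copies = truth.true_copies  # site x taxon
    col = 0
    sample_ids: list[str] = []
    for i, site in enumerate(truth.site_ids):
        for rep in range(1, config.replicates_per_site + 1):
            sid = f"{site}R{rep}"
            vol = config.volume_L * (
                1.0 + rng.uniform(-config.volume_jitter,
                                  config.volume_jitter))
            cap = float(np.exp(rng.normal(-sigma ** 2 / 2, sigma))) \
                if sigma > 0 else 1.0
            loads = np.array([
                taxon_copies.loc[site, asv_taxon[aid]] * w * vol * cap * b
                for aid, w, b in zip(asv_ids, asv_weight, asv_bias)])
            full = np.concatenate([loads, std_loads])
            depth = max(1, int(round(config.reads_per_sample * (
                1.0 + rng.uniform(-config.depth_jitter,
                                  config.depth_jitter)))))
            counts[:, col] = rng.multinomial(depth, full / full.sum())
            samples.append(SampleRecord(
                sample_id=sid, site_id=site, replicate=rep,
                volume_L=vol, lat=float(truth.lats[i]),
                lon=float(truth.lons[i]),
                timestamp=truth.times[i] +
                pd.Timedelta(minutes=2 * (rep - 1))))
            capture[sid] = cap
            community_load[sid] = float(loads.sum())
            expected_frac[sid] = float(std_loads.sum() / full.sum())
            sample_ids.append(sid)
            col += 1
    table = CountTable(asv_ids=all_ids, sample_ids=sample_ids, counts=counts)
    return SimulatedReads(counts=table, standards=standards, samples=samples,
                          taxonomy=taxonomy, asv_taxon=asv_taxon,
                          capture=capture, community_load=community_load,
                          expected_standard_fraction=expected_frac)


def simulate_fcm(truth: GroundTruth, config: SimulationConfig,
                 rng: np.random.Generator) -> list[FcmObservation]:
    """Place FCM events along the same track at the daily cadence, offset
    in time from the amplicon sites, with lognormal triplicate noise."""
    sigma = config.fcm_noise_sigma
    cadence = 24.0 / config.fcm_per_day
    t0 = truth.times[0]
    obs: list[FcmObservation] = []
    t_h = config.fcm_start_offset_h
    k = 0
    while t_h <= truth.duration_hours:
        lat = float(truth.lat_at_hours(t_h))
        event_id = f"F{k + 1:03d}"
        ts = t0 + pd.Timedelta(hours=t_h)
        for prof in config.taxa:
            if not prof.fcm_visible:
                continue
            true_cells = float(prof.cells_at(lat))
            if sigma > 0:
                reps = [true_cells *
                        float(np.exp(rng.normal(-sigma ** 2 / 2, sigma)))
                        for _ in range(config.fcm_replicates)]
            else:
                reps = [true_cells] * config.fcm_replicates
            obs.append(FcmObservation(
                event_id=event_id, timestamp=ts, lat=lat,
                lon=float(config.lon), population=prof.name,
                replicate_counts=reps))
        k += 1
        t_h += cadence
    return obs


@dataclass
class SyntheticStudy:
    truth: GroundTruth
    reads: SimulatedReads
    fcm: list[FcmObservation]
    config: SimulationConfig
    seed: int


def simulate_study(config: SimulationConfig | None = None,
                   seed: int = 0) -> SyntheticStudy:
    """Generate one complete, seed-deterministic synthetic study."""
    if config is None:
        config = SimulationConfig()
    rng = np.random.default_rng(seed)
    truth = make_transect(config)
    reads = simulate_reads(truth, config, rng)
    fcm = simulate_fcm(truth, config, rng)
    return SyntheticStudy(truth=truth, reads=reads, fcm=fcm,
                          config=config, seed=seed)


def default_patterns(config: SimulationConfig) -> dict[str, str]:
    return {t.name: t.name for t in config.taxa if t.fcm_visible}


def default_copy_map(config: SimulationConfig) -> dict[str, float]:
    return {t.name: float(t.copies_per_cell) for t in config.taxa
            if t.fcm_visible}


def write_simulation(study: SyntheticStudy, outdir: str | Path) -> dict:
    """Write the study in exactly the formats the ingest layer reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reads, truth = study.reads, study.truth

    counts_path = outdir / "counts.tsv"
    df = reads.counts.to_frame()
    df.index.name = "asv_id"
    df.to_csv(counts_path, sep="\t")

    meta_path = outdir / "meta.csv"
    rows = [{"sample_id": r.sample_id, "site_id": r.site_id,
             "replicate": r.replicate, "volume": f"{r.volume_L:.12g}",
             "volume_unit": "L", "lat": f"{r.lat:.12g}",
             "lon": f"{r.lon:.12g}", "datetime": r.timestamp.isoformat()}
            for r in reads.samples]
    pd.DataFrame(rows).to_csv(meta_path, index=False)

    standards_path = outdir / "standards.yaml"
    std_docs = [{"name": s.name, "mass_ng": s.mass_ng,
                 "genome_size_bp": s.genome_size_bp,
                 "copies_per_genome": s.copies_per_genome,
                 "asv_ids": sorted(s.asv_ids)} for s in reads.standards]
    standards_path.write_text(yaml.safe_dump(std_docs, sort_keys=False))

    tax_path = outdir / "taxonomy.tsv"
    tax_path.write_text(
        "asv_id\ttaxonomy\n" +
        "".join(f"{a}\t{t}\n" for a, t in reads.taxonomy.items()))

    copymap_path = outdir / "copymap.yaml"
    copymap_path.write_text(
        yaml.safe_dump(default_copy_map(study.config), sort_keys=True))

    fcm_path = outdir / "fcm.csv"
    fcm_rows = []
    for obs in study.fcm:
        for i, c in enumerate(obs.replicate_counts, start=1):
            fcm_rows.append({
                "event_id": obs.event_id,
                "datetime": obs.timestamp.isoformat(),
                "lat": f"{obs.lat:.12g}", "lon": f"{obs.lon:.12g}",
                "population": obs.population, "replicate": i,
                "abundance": f"{c / 1e3:.12g}",
                "abundance_unit": "cells_per_mL"})
    pd.DataFrame(fcm_rows).to_csv(fcm_path, index=False)

    truth_path = outdir / "truth.tsv"
    tr = truth.true_cells.copy()
    tr.index.name = "site_id"
    tr.insert(0, "lat", truth.lats)
    tr.to_csv(truth_path, sep="\t")

    return {"counts": counts_path, "metadata": meta_path,
            "standards": standards_path, "taxonomy": tax_path,
            "copymap": copymap_path, "fcm": fcm_path, "truth": truth_path}
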