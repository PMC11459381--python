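# spikequant

Absolute volumetric microbial abundances from amplicon sequencing with
internal genomic standards (spike-ins), plus flow-cytometry (FCM) matchup
validation and a synthetic cruise-transect simulator.

Given an ASV read-count table from samples spiked with known quantities of
genomic standard DNA, the pipeline converts reads to 16S gene copies per
liter of filtered seawater via

```
copies_per_L(i, j, s) = R_ij * C_s / (R_sj * V_j)
```

where `R_ij` are the taxon's reads, `C_s` the standard's known 16S copy
load, `R_sj` the standard's reads, and `V_j` the filtered volume. With
three technical replicates and three standards this yields nine estimates
per site and ASV; the reported abundance is their mean, with min/max and
the dropout-adjusted estimate count carried along. Gene-copy abundances
become cell abundances by dividing by per-taxon 16S copy numbers
(Prochlorococcus 1, Synechococcus 2), and the result is cross-validated
against FCM cell counts from events paired within configurable distance
and time windows (default 20 km / 6 h, greedy nearest one-to-one).

## Modules

| module | role |
| --- | --- |
| `spikequant.io_ingest` | readers/writers for all tables, unit normalization, standard copy-load arithmetic |
| `spikequant.quantify` | the spike-in correction, nine-estimate sets, percent-error statistics |
| `spikequant.taxa` | ASV→taxon assignment, copy-number conversion, taxon aggregates and ratios |
| `spikequant.matchup` | haversine pairing, OLS/Pearson regressions, distance-grid sensitivity analysis |
| `spikequant.synthetic` | closed-form transect ground truth, multinomial read simulation, FCM simulation |
| `spikequant.cli` | `spikequant` command line and the end-to-end `run` pipeline with a provenance manifest |

## CLI

```bash
# full synthetic study -> quantification -> taxa -> validation
cat > run.yaml <<EOF
seed: 1
simulate: {n_sites: 65, reads_per_sample: 100000}
validate: {distance_km: 20, hours: 6, grid: [10, 20, 30]}
EOF
spikequant run --config run.yaml --out outdir/

# or stage by stage
spikequant simulate --seed 1 --out sim/
spikequant quantify --counts sim/counts.tsv --metadata sim/meta.csv \
    --standards sim/standards.yaml --out abundances.tsv
spikequant taxa --abundances abundances.tsv --taxonomy sim/taxonomy.tsv \
    --copy-map sim/copymap.yaml --out taxon_abundances.tsv
spikequant validate --taxon-abundances taxon_abundances.tsv \
    --fcm sim/fcm.csv --out validation/
```

`run` writes a `manifest.json` with the config hash, file digests, seed,
per-stage row counts and all warnings (standard dropouts, excluded sites,
undefined ratios). Exit status 2 flags a config-schema error, 1 a stage
failure (with a partial manifest naming the stage).

## Input formats

- counts: TSV, first column `asv_id`, one integer column per sample
- metadata: CSV `sample_id,site_id,replicate,volume,volume_unit,lat,lon,datetime`
  (volumes in mL or L; timestamps ISO 8601 with zone)
- standards: YAML list of `{name, mass_ng, genome_size_bp,
  copies_per_genome, asv_ids}`; the copy load is derived as
  `mass * N_A / (genome_size * 650 g/mol per bp) * copies_per_genome`
- taxonomy: TSV `asv_id<TAB>semicolon;ranked;string`
- copy map: YAML `taxon: copies_per_cell`
- FCM: CSV `event_id,datetime,lat,lon,population,replicate,abundance,abundance_unit`
  (units `cells_per_uL`, `cells_per_mL` or `cells_per_L`)

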