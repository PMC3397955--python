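# msat

Perfect-microsatellite surveys of shotgun read sets, with per-species
coverage/composition profiles and phylogenetic autocorrelation analysis.

The package detects maximal perfect tandem-repeat tracks (unit lengths 1–6)
in FASTA/FASTQ reads, naming motif classes by their alphabetically minimal
representative under rotation and reverse complement (e.g. `AAC` stands for
ACA, CAA, TTG, TGT and GTT).  Qualification thresholds default to twelve
repetitions for homopolymers and five for di–hexanucleotide units;
homopolymers are tallied separately from total microsatellite coverage
(bases per Mb).  Species profiles feed comparative statistics: Wilcoxon
rank-sum tests between taxonomic groups, Spearman correlations of motif
shares against GC%, and Moran's I correlograms over clade partitions of an
ultrametric tree at divergence-time cutoffs (50 Mya, then multiples of
100 Mya).  A seeded simulation module generates 454-like reads with planted
repeat tracks, pure-birth trees, and Brownian-motion or white-noise traits.

## CLI

```bash
# scan reads and emit a track TSV plus a one-row species profile CSV
msat scan reads.fasta.gz --species "Aus bus" --taxonomy Chordata \
    --out-tracks tracks.tsv --out-profile profile.csv

# aggregate an existing track TSV into a profile
msat profile --tracks tracks.tsv --total-bases 8000000 --gc-count 3300000 \
    --species "Aus bus" --out profile.csv

# Moran's I correlogram of log coverage over clade-age cutoffs
msat correlogram --profiles profiles.csv --tree dated.nwk \
    --cutoffs 50,100,200,300 --out correlogram.csv

# Wilcoxon comparison of coverage between two species groups
msat compare --profiles profiles.csv --group1 plants.txt --group2 animals.txt \
    --out compare.csv

# synthetic data (reads with planted tracks / ultrametric tree / leaf trait)
msat simulate reads --n-reads 1000 --plant AC:8:20 --seed 1 \
    --out-fasta sim.fasta --out-truth truth.tsv
msat simulate tree --n-leaves 40 --root-age 900 --seed 1 --out tree.nwk
msat simulate trait --tree tree.nwk --model brownian --seed 1 --out trait.csv
```

Track files are BED-like TSV (0-based, half-open).  Scan thresholds can also
come from a TOML config (`--config run.toml`, flags override):

```toml
[scan]
count_partial_units = true
[scan.min_repetitions]
1 = 12
2 = 5
```

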