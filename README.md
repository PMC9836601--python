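# mitoanchor

Reference-anchored mitogenome reconstruction from low-coverage, degraded
shotgun reads — the kind of data museum specimens yield. Reads are placed
on a related species' circular mitogenome by k-mer seeded local alignment,
a per-site IUPAC consensus is called in the query's coordinate frame
(N where uncovered, the read base where reads agree, an ambiguity code
where they disagree), the cytosine-deamination damage signature is
quantified from the ambiguity calls, the query's annotation is lifted onto
the reconstruction, and the result is validated for query-independence.
A synthetic degraded-library simulator makes every stage testable against
known truth.

## Modules

| module      | role |
|-------------|------|
| `seqio`     | FASTA/FASTQ/annotation-TSV I/O, IUPAC alphabet utilities, GenBank 5-column feature table (.tbl) output |
| `simlib`    | degraded-library simulator: circular fragment sampling, terminal C→T / G→A deamination, endogenous dilution, sequencing error, truth tables |
| `kalign`    | k-mer seeded, windowed local alignment with `high`/`low` stringency presets |
| `consensus` | query-anchored pileup and per-site IUPAC consensus calling |
| `damage`    | ambiguity matrix by query base; deamination asymmetry ratio and exact binomial test |
| `liftover`  | annotation transfer and per-feature recovery (%N, fully-missing flags) |
| `validate`  | completeness report; query-independence (discordance) check |
| `pipeline`  | YAML-configured end-to-end runs with deterministic seeding |

## CLI

```sh
# full chain from a config (see the pipeline module docstring for the layout)
mitoanchor run --config config.yaml --out runs/demo

# stage by stage
mitoanchor simulate --truth-length 16000 --divergence 0.05 --depth 20 \
    --damage-dmax 0.3 --seed 7 --out sim/
mitoanchor align sim/sim_1.fastq sim/sim_2.fastq \
    --query sim/query.fasta --preset high --out alignments.tsv
mitoanchor reconstruct sim/sim_1.fastq sim/sim_2.fastq \
    --query sim/query.fasta --preset low --out recon/
mitoanchor damage --reconstruction recon/reconstruction.fasta \
    --calls recon/calls.tsv --query sim/query.fasta --out damage.json
mitoanchor liftover --reconstruction recon/reconstruction.fasta \
    --calls recon/calls.tsv --annotation features.tsv --out lift/
mitoanchor validate sim/sim_1.fastq sim/sim_2.fastq \
    --query q1.fasta --query q2.fasta --out val/
```

All outputs are plain text (FASTA, TSV, JSON); every run records its
parameters and seed in `run_log.json`.

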