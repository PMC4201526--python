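# evmir

Small-RNA sequencing analysis of miRNA enrichment in extracellular vesicles
(EVs): read QC, miRNA quantification, Venn enrichment classification against
the parental cell line, genomic cluster/family context, passenger-strand
dominance, and qRT-PCR concordance — plus a synthetic-study generator that
makes the whole pipeline testable end to end.

The package models a four-library design: two immunoaffinity-captured exosome
populations (**A33-Exos**, **EpCAM-Exos**), shed microvesicles (**sMVs**) and
the parental cell line (**CL**). A miRNA is *enriched* in an EV library when
its TPM is more than 5 in at least one library and its log2 TPM ratio over CL
is at least 1 (two-fold); the combination of the three EV calls yields seven
Venn categories.

See [docs/methods.md](docs/methods.md) for the full method definitions.

## Worked example

The package ships the printed study tables as fixtures. Reclassifying the
63-row enriched-miRNA TPM fixture from scratch
(`python examples/02_fixture_reclassification.py`) prints:

```
enriched miRNAs: 63
  A33_only: 32
  EpCAM_only: 2
  sMV_only: 4
  all_EVs: 6
  A33_EpCAM: 16
  A33_sMV: 2
  EpCAM_sMV: 1
per-EV totals: 56 25 13
enriched in both exosome captures: 22

top of each category:
  A33_only: hsa-miR-3677-3p (log2 A33/CL = 3.40)
  EpCAM_only: hsa-miR-106a-5p (log2 A33/CL = 0.54)
  sMV_only: hsa-miR-675-5p (log2 A33/CL = 0.95)
  all_EVs: hsa-miR-4454 (log2 A33/CL = 4.50)
  A33_EpCAM: hsa-miR-320d (log2 A33/CL = 6.13)
  A33_sMV: hsa-miR-193a-3p (log2 A33/CL = 1.75)
  EpCAM_sMV: hsa-miR-204-5p (log2 A33/CL = 0.72)

fixture check all_pass: True
```

## Library usage

```python
from evmir import (
    SimulationConfig, simulate_study, run_qc, ArmIndex, count_library,
    expression_matrix, enrichment_table,
)
from evmir.quantify import expression_cutoff

config = SimulationConfig(seed=1, n_precursors=100, n_reads_per_library=50_000)
bundle, truth, libraries = simulate_study(config)

profiles = []
index = ArmIndex(bundle)
for lib in config.library_names:
    clean, stats = run_qc(libraries[lib][0], library=lib)
    profiles.append(count_library(clean, bundle, lib, index))

matrix = expression_matrix(profiles)          # arms x libraries, columns sum to 1e6
records, summary = enrichment_table(matrix)   # per-arm table + Venn summary
print(summary["n_enriched"], summary["both_exosomes"])
```

Or run everything at once and get a hashed manifest:

```python
from evmir import PipelineConfig, SimulationConfig, run_pipeline

manifest = run_pipeline(PipelineConfig(
    outdir="out", simulate=SimulationConfig(seed=1, n_precursors=100)
))
```

## Command line

Each stage is also exposed as a subcommand:

```
evmir simulate --outdir data --seed 1 --n-precursors 100 --n-reads 50000
evmir qc data/raw/CL.fastq out/CL.clean.fastq
evmir quantify --reference data/reference --clean-fastq CL=out/CL.clean.fastq \
    --clean-fastq A33-Exos=out/A33.clean.fastq ... --out-prefix out/study
evmir enrich out/study.tpm.tsv --out-prefix out/study
evmir cluster --reference data/reference --out out/clusters.tsv
evmir strand --reference data/reference --tpm out/study.tpm.tsv --out out/strands.tsv
evmir qpcr ct.tsv --ev A33-Exos --ev EpCAM-Exos --ev sMVs --cl CL --out out/ddct.tsv
evmir run-all config.json
evmir fixture-check
```

## Examples

- `examples/01_full_pipeline.py` — simulate a study and run every stage.
- `examples/02_fixture_reclassification.py` — reproduce the printed Venn
  partition from the packaged TPM fixture.
- `examples/03_audic_claverie.py` — the Audic-Claverie test and its depth
  dependence.
- `examples/04_clusters_and_strands.py` — cluster detection/enrichment and
  strand-dominance switches.

## Testing

```
python -m pytest -q tests/                      # unit + acceptance suites
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`tests/test_acceptance.py` holds one test per acceptance criterion (fixture
reclassification, printed-arithmetic recomputation, oracle agreement for the
Audic-Claverie test and cluster detection, full-scale parameter recovery, and
the noiseless qPCR link). `scripts/acceptance.py` writes the headline numbers
as JSON; all randomness derives from `--seed`.
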