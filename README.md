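# dnbaudit

Quality-control auditing of artifacts specific to DNBSEQ/MGI sequencing
data, working directly on paired-end FASTQ:

* **misdemultiplexing audit** — when the insert is shorter than the read,
  the read runs through into the partial MGI adapter and the 10-base
  sample barcode; exact-matching that in-read barcode against the run's
  whitelist measures how many reads were assigned to the wrong sample
  (`rate = non-target whitelist matches / all whitelist matches`);
* **optical-duplicate scan** — MGI read names encode the camera field of
  view (`CxxRxx`) and an ordinal read ID tied to nanoball position;
  near-identical reads (end-to-end identity ≥ 95%, alignment length ≥
  read length) at characteristic within-FOV ID offsets (modes 1, 63, 85,
  195, 217) are optical duplicates. An exhaustive sliding-frame scan and
  a fast offset-restricted scan are provided, plus the ID-difference
  histogram;
* **improper-pair classification** — a four-case scheme combining adapter
  presence (short insert), mate overlap-merging, in-read barcode
  correctness and lightweight reference mapping;
* **association statistics** — chi-square (1 df, uncorrected) with both
  the proportion (rate) ratio and the cross-product odds ratio, testing
  whether artifact pairs are enriched for close-nanoball neighbourhood;
* **short-insert filter** — the recommended preprocessing step: discard
  every pair whose forward read contains the 22-base partial adapter;
* a **synthetic DNBSEQ run generator** that plants all of the above at
  configurable rates with per-pair truth labels, so every stage is
  testable without deposited data.

Intended for sequencing-facility and bioinformatics users who need to
quantify (and filter) these artifacts in their own MGI runs, and as a
reference implementation of the audit logic. See `docs/methods.md` for
the full model and the design decisions.

## Worked example

```python
from dnbaudit import (
    ADAPTER_F, RunConfig, misdemux_rate, resolve_inputs, scan_run,
    simulate_pairs, tabulate_barcodes, truth_rates,
)

config = RunConfig(n_pairs=50_000, seed=1)   # PE300-style study conditions
pairs, truth = simulate_pairs(config)
panel, refs = resolve_inputs(config)

print(truth_rates(truth))
# {'none': 0.9071, 'misdemux': 0.05074, 'improper_pair': 0.02102,
#  'duplicate': 0.02028, 'chimera': 0.00086}

obs = tabulate_barcodes([p.forward for p in pairs], ADAPTER_F)
report = misdemux_rate(obs, panel, config.target_barcode_id)
print(f"{report.rate_percent:.2f}% of {report.n_exact_panel_match}")
# 7.42% of 5741

scan, hits = scan_run([p.forward for p in pairs], method="all")
print(f"{100 * scan.rate:.3f}%", dict(sorted(scan.histogram.items()))[1])
# 4.056% 849
```

Reading the numbers: 7.42% of the 5,741 barcode-visible forward reads
carry a non-target whitelist barcode (the planted truth among visible
reads is 7.50% — misdemultiplexed pairs plus improper pairs, which also
carry wrong barcodes). The exhaustive scan finds that 4.056% of reads
have an optical duplicate (planted sources + copies: 4.056% exactly), and
849 of the duplicate pairs sit at the dominant ID-offset mode of 1.

The same stages are available from the shell:

```bash
dnb-audit simulate --n-pairs 10000 --seed 1 --out-dir scratch/demo
dnb-audit demux-audit --fastq scratch/demo/run_R1.fq
dnb-audit dup-scan --fastq scratch/demo/run_R1.fq --method fast --histogram hist.tsv
dnb-audit filter --r1 scratch/demo/run_R1.fq --r2 scratch/demo/run_R2.fq \
    --out-r1 clean_R1.fq --out-r2 clean_R2.fq
```

## Analysis walkthrough

`analysis/01…05` are numbered drivers that run the whole study on the
synthetic run and write tables under `results/`:

1. `01_simulate_run.py` — generate the run, summarise planted rates;
2. `02_misdemultiplexing.py` — forward/reverse misdemultiplexing rates,
   contaminant count tables, barcode inference;
3. `03_optical_duplicates.py` — both scans vs planted truth, ID-offset
   histogram;
4. `04_pair_classification.py` — four-case classification, the
   contain-adapter group comparison, filter summary;
5. `05_association.py` — neighbourhood-association chi-square and effect
   sizes.

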