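# extscan

Screen predicted proteomes (amino-acid FASTA) for extensin (EXT)
candidates and classify them.

The pipeline:

1. **Candidate screen** — proteins with two or more maximal Ser-Pro≥3
   runs (`SPPP` repeats) are candidates; everything else is `NON_EXT`.
2. **Motif annotation** — SP_n runs (binned SP3 / SP4 / SP5+ by maximal
   munch), overlapping Tyr-X-Tyr cross-linking motifs, AGP-style
   dipeptides, and arbitrary fixed-word patterns (e.g. `QAAA`).
3. **Region profiling** — sliding-window HRGP composition bias
   (P/A/V/S/G/T), a documented signal-peptide heuristic, Kyte–Doolittle
   transmembrane segments, and a GPI ω-site heuristic.  External
   predictor output (TSV) can override any heuristic call.
4. **Homology evidence** — exact Smith–Waterman (affine gaps, BLOSUM62,
   X = −1) against a small bundled, user-replaceable reference set of
   domain exemplars (LRR, kinase, FH2, EXT repeats), normalized by
   reference self-score.
5. **Classification** — a fixed, ordered rule list assigns one of:
   `CLASSICAL`, `SHORT` (<200 aa), `LRX`, `PERK`, `FH_EXT`,
   `LONG_CHIMERIC` (>2000 aa), `OTHER_CHIMERIC`, `POTENTIAL`, `NON_EXT`.
   Every decision carries an evidence dict and a rule trace.
6. **Summary statistics** — class census, pooled SP3/SP4/SP5+ repeat
   frequencies (classical EXTs by default), and mean YXY counts in
   classical vs non-classical EXTs.

A seeded synthetic-proteome generator plants labelled members of every
class (with exhaustive motif/region ground truth) so the full pipeline is
testable offline.

## CLI

```sh
extscan simulate --seed 1 --n-per-class 10 --background-n 20 --out-dir sim/
extscan scan      sim/proteome.fasta --out-dir scan_out/
extscan classify  sim/proteome.fasta --out-dir cls_out/ [--config cfg.txt] \
                  [--external-regions regions.tsv] [--references refs.fasta]
extscan summarize cls_out/classifications.tsv --out-dir summary_out/
```

* `scan` writes a per-protein motif TSV and a GFF3 motif track
  (1-based inclusive coordinates; everything internal is 0-based
  half-open).
* `classify` writes `classifications.tsv` with columns `id, label,
  length, sp3, sp4, sp5plus, yxy, signal_peptide, gpi, tm_count,
  hrgp_coverage, lrr_score, kinase_score, fh2_score, rule_trace`.
* `summarize` writes `summary.tsv` and a human-readable `report.txt`.
* Config files are flat `key=value` mirroring `ClassifierConfig`
  (thresholds: `short_max_len`, `long_min_len`, `classical_min_coverage`,
  `classical_min_sp`, `perk_nterm_bias`, `min_normalized`,
  `hrgp_window`, `hrgp_threshold`, `tm_window`, `tm_threshold`).
* Every run writes `run_manifest.json` (tool version, config hash,
  input checksums); primary outputs are byte-identical across re-runs.

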