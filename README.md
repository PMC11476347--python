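# prsmap

Site-specific integration of phage-related sequences (PRSs) — prophages and
genomic islands — into circular bacterial chromosomes, analyzed the way it is
done for *Sinorhizobium*-like alphaproteobacteria: anchor the chromosome at
the replication origin, call the terminus from strand-asymmetry signals,
number the tRNA genes along the oriC→terC axis, recover the attL/attR direct
repeats flanking every integrated element, test which tRNA genes are
integration **hot spots**, and compare the integrated elements to each other
through best-local-alignment synteny blocks.

The package is aimed at comparative genomicists studying temperate-phage and
genomic-island traffic in bacterial genomes. Element and tRNA annotations are
*inputs* (GFF3); the package does not predict prophages or tRNA genes. A
first-class synthetic-genome generator plants every structure the pipeline
must recover — with exact ground truth — so the whole analysis is testable
without downloads.

## The model

A tyrosine-integrase-mediated integration recombines the phage attachment
site *attP* with a bacterial site *attB* (usually the 3′ end of a tRNA gene),
producing an element flanked by two direct repeats, the recombinant sites
*attL* and *attR*:

```
      attB (gene 3' end + spacer)                 attL        attR
───[ tRNA gene ███████░░]─────────   →   ───[ tRNA gene ███████░░] ELEMENT ███████░░──
```

The copy coinciding with the tRNA gene is **attR** regardless of side; the
gene stays intact for 3′/5′ attachments and is disrupted when attR matches
only the gene interior ("central" anchor — in which case the element may
carry a replacement tRNA of the same isotype/anticodon). Key quantities:

* degree coordinates: `C° = C_bp · 360 / L_bp`, oriC at 0°;
* terC from the global extremum of the cumulative GC skew `(G−C)/(G+C)` and
  of the cumulative strand difference of the octamer GGGCAGGG, in windows of
  0.1% of the chromosome length;
* direct repeats 12–98 bp, one copy per element boundary, detected within a
  ±150 bp window of the annotated boundaries;
* per-gene integration frequencies partitioned into tiers by an exact 1-D
  minimum-variance (Fisher–Jenks) dynamic program; uniformity tested with a
  Pearson chi-square (`df = k − 1`);
* synteny blocks = single best local alignment per element pair
  (match +1 / mismatch −2 / gap −5 − 2·len), retained when > 8 kb and > 90%
  identity; Shannon index `H = −Σ p ln p` for integrase-origin diversity;
* nucleotide diversity `π` = mean pairwise difference per compared site.

## Worked example

```bash
python examples/hotspot_cohort.py
```

```
233 integrations in 25 tRNA genes across 27 strains
uniformity test: chi2 = 134.9, df = 24, P = 1.98e-17
tier 1: 14 genes, mean frequency 0.021 +- 0.001
tier 2: 8 genes, mean frequency 0.045 +- 0.003
tier 3: 3 genes, mean frequency 0.116 +- 0.000
hot spots (top tier): 010, 030, 039
```

Twenty-seven synthetic strains receive integrations with planted per-gene
shares of 0.02/0.05/0.11. The pipeline rejects uniform integration
(P ≈ 2 × 10⁻¹⁷), and the top frequency tier recovers exactly the three
planted hot-spot genes — 010 (Thr/GGT), 030 (Asn/GTT) and 039 (Lys/CTT).

Other examples: `replichore_geometry.py` (oriC anchoring and a terC call
within a fraction of a degree of the planted terminus),
`att_site_detection.py` (a 27 bp att split 17 bp in-gene + 10 bp spacer,
validated by in-silico excision), `synteny_blocks.py` (block detection,
the 8 kb/90% filter and the JSON export).

A thin CLI covers the two shell-friendly steps:

```bash
prsmap simulate --seed 1 --outdir sim/
prsmap analyze --fasta sim/genome.fasta --gff sim/features.gff3 \
               --probe-fasta sim/probe.fasta --outdir report/
```

## Layout

| path | contents |
| --- | --- |
| `src/prsmap/io.py` | FASTA/GFF3 I/O, circular `Chromosome`/`Feature` model, report writer |
| `src/prsmap/replichore.py` | oriC probe anchoring, degree coordinates, skew/octamer profiles, terC |
| `src/prsmap/trna.py` | tRNA catalog, ordinal numbering, strand asymmetry tests |
| `src/prsmap/attsites.py` | direct-repeat detection, attL/attR classification, nesting, excision |
| `src/prsmap/stats.py` | frequency tables, chi-square, Fisher–Jenks tiers, Shannon index |
| `src/prsmap/synteny.py` | best-block alignment, retention filter, pair classes, JSON export |
| `src/prsmap/trna_prs.py` | tRNA genes carried inside elements, replacement events |
| `src/prsmap/simulate.py` | synthetic chromosomes, planted integrations, cohorts, ground truth |
| `src/prsmap/pipeline.py` | per-strain analysis and cohort summaries |
| `src/prsmap/cli.py` | `prsmap simulate` / `prsmap analyze` |
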