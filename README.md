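# mutspect

Tools for analyzing **population differences in the rare-variant
mutational spectrum** — for population geneticists asking whether groups of
genomes differ in the *kinds* of mutations they carry, and whether such
differences reflect mutation-rate changes or demography.

Rare variants are recent, hence highly differentiated between populations,
which makes them sensitive probes of recent mutational processes. Each
polarized SNP is assigned to one of 96 trinucleotide classes (ancestral
base + flanks + derived base, reverse-complement pairs merged so the
ancestral base is a pyrimidine; `ACG>T` denotes ancestral ACG mutating its
middle base to T). From a panel of genomes, `mutspect` builds per-sample
count matrices `C` (96 × n) for a chosen derived-allele-count stratum —
e.g. f2 "doubletons", exactly two derived copies panel-wide — and
normalized intensities `X`, then:

- extracts **mutational signatures** by NMF (`X ≈ WH`, Lee–Seung
  multiplicative updates, fastICA or random initialization) with
  rank-selection diagnostics (consensus dispersion, RSS, silhouette),
  catalog matching by Pearson correlation, a PCA alternative, and a CpG
  floor correction;
- stratifies mutations by **transcriptional strand** (the
  untranscribed/transcribed log-ratio diagnostic of transcription-coupled
  repair), **methylation state** (rate ratios at high/low-methylation CpG
  sites) and **conservation / recombination deciles**;
- simulates **repeat (recurrent) mutations** on coalescent genealogies —
  two Poisson mutation events OR-ed per site — under constant size or
  exponential growth (time rescaling t′ = (1/g)(e^{gt}−1) for t ≤ s), and
  the resulting CpG-proportion-by-frequency curves: demography, not
  mutation rate, can reshape the CpG doubleton class;
- scores ancient genomes with a **damage-robust statistic**
  M = log₂[(X_TCC·X_ACC·X_TCT·X_CCC)/(X_TCA·X_ACA·X_TCA·X_CCA)] (all C>T
  classes; uniform deamination-like inflation cancels exactly), normalized
  to an African reference panel, with bootstrap quantiles;
- provides the **rate arithmetic** Δ = (q−p)/(1−q) linking a signature
  proportion shift p→q to the implied relative increase in total mutation
  rate, plus repeat-share and coalescent-time conversions.

A first-class synthetic-data generator produces every input the pipeline
consumes (FASTA reference, VCF panel with `AA` ancestral-allele tags, BED
tracks, TSV metadata) with planted, recorded ground truth, so the whole
pipeline is testable end-to-end. See `docs/methods.md` for models,
conventions and limitations.

## Worked example

Plant a 1.5× intensity boost on the four TCC>T-type signature classes in
one of two 15-sample populations, then recover it:

```python
import numpy as np
from mutspect.synthetic_data import (SyntheticGenomeSpec, PopulationSpec,
                                     generate_reference, generate_panel)
from mutspect.variant_spectrum import (SIGNATURE_1, count_spectrum, normalize,
                                       signature_proportion, group_z)
from mutspect.signature_inference import nmf_fit
from mutspect.rate_models import RateChange

ref, freqs = generate_reference(SyntheticGenomeSpec(length=400_000, seed=21))
mult = {c.label: 1.5 for c in SIGNATURE_1.classes}
pops = [PopulationSpec("boosted", "WestEurasia", 15, mult),
        PopulationSpec("control", "EastAsia", 15)]
panel, truth = generate_panel(ref, pops, 40_000, seed=22)

counts = count_spectrum(panel, ref, "f2")          # hom=2, het=1, joint f2
X = normalize(counts, "ata_c")                      # intensities vs ATA>C
props = signature_proportion(counts, SIGNATURE_1)   # per-individual
z = group_z(props.to_numpy(), np.arange(15), np.arange(15, 30))
fit = nmf_fit(X.values, rank=2, init="ica", seed=23)

share = fit.weights[SIGNATURE_1.indices].sum(0) / fit.weights.sum(0)
k = int(np.argmax(share))                           # signature-1-like factor
rc = RateChange(p=props[15:].mean(), q=props[:15].mean())
```

printing the quantities above gives:

```
mean signature-1 proportion: boosted 0.0630, control 0.0412
group Z = 11.9
NMF rank 2: rss = 118.8 after 595 iterations
mean loading: boosted 94.12, control 11.58
implied total-rate increase: 2.3%
```

The boosted population's per-individual signature-1 proportion separates
from the control at Z ≈ 12; the NMF factor carrying the signature-1
classes loads ~8× higher on boosted samples; and reading the two group
proportions back through Δ = (q−p)/(1−q) converts the planted enrichment
into the relative increase in genome-wide mutation rate it would imply if
only these classes changed.

The same analyses are scriptable from the shell:

```bash
mutspect run --config config.yaml --out results/      # staged, manifested run
mutspect spectrum --vcf panel.vcf --ref ref.fa --stratum f2 \
    --normalize ata_c --out intensities.tsv
mutspect signatures --matrix intensities.tsv --rank 4 --init ica \
    --catalog catalog.tsv --out-prefix sig
mutspect simulate --n 50 --trees 200000 --growth 100 --onset 0.01 \
    --seed 1 --out sfs.tsv
mutspect rate --p 0.078 --q 0.088
```

`mutspect run` validates its YAML config strictly (unknown keys rejected by
name), derives every stage seed from one run seed, and writes a
`manifest.json` with SHA-256 checksums — reruns are byte-identical.

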