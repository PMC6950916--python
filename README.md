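# cncc — DNA break end structures from strand-specific coverage

`cncc` determines the end structure of DNA double-strand breaks (DSBs) —
blunt, 3′ overhang, or 5′ overhang, and the overhang length — genome-wide
from break-mapping sequencing data (BLESS, END-seq, DSBCapture and similar
protocols), at single-nucleotide resolution.

## How it works

Break-mapping protocols ligate an adaptor to each blunted break end, so the
5′-most mapped position of read 1 marks the end precisely. Crucially, the
blunting step encodes the original end structure into the mapped
coordinates: 3′ overhangs are trimmed back, separating the two ends of one
break by the overhang length in reference coordinates, while 5′ overhangs
are filled in, making the two ends overlap.

Given per-base 5′-end coverage of the positive strand `x(i)` and the
negative strand `y(i)`, the package computes the **coverage-normalized cross
correlation** at every shift `t`:

```
CNCC(t) = Σ_i y(i) · x(i − t) / sqrt( Σ_i x(i)² · Σ_i y(i)² )
```

The sum runs within chromosomes (ends on different chromosomes never pair)
and the normalization is global. By Cauchy–Schwarz, |CNCC(t)| ≤ 1, and the
curve is invariant to rescaling the counts, so curves from libraries of
different depths are directly comparable.

Each end structure concentrates signal at a characteristic shift:

| End structure           | Shift    | Example enzyme |
|-------------------------|----------|----------------|
| blunt                   | −1       | HaeIII         |
| 3′ overhang of L nt     | −1 − L   | BanII (L = 4)  |
| 5′ overhang of L nt     | −1 + L   | BbvI (L = 4)   |
| resection (mixed 3′)    | spread over t < −1 | — |

Around this estimator the package provides:

- **Stringent shuffled control** (`cncc.shuffle`): permutes coverage values
  among the originally non-zero positions, then perturbs each position by a
  non-zero wiggle within ±W. Subtracting the control median gives the
  *relative CNCC* used for cross-treatment comparison.
- **Site-masking sensitivity scan** (`cncc.sensitivity`): masks increasing
  fractions of candidate sites and tracks the CNCC value at a target shift,
  quantifying how much of a spike a site set explains.
- **Resection signature** (`cncc.core.resection_range`): the contiguous run
  of shifts ≥ 90% of the curve maximum inside a window below −1, decoded to
  a 3′ overhang-length range.
- **Region break density** (`cncc.regions`): promoter/TSS/TTS/gene
  body/intergenic partition and BPMM (breaks per Mb per million mapped
  breaks), with Kruskal–Wallis + Dunn group comparison.
- **Spike-pair detection** (`cncc.pairs`): individual loci where a
  negative-strand spike sits a fixed gap upstream of a positive-strand
  spike, with FASTA export of flanking sequence for motif discovery.
- **Synthetic data** (`cncc.simulate`): digest, resection and mixture
  simulators with full ground truth, used throughout the test suite.

## Quickstart

Simulate a digest with 2-nt 3′ overhangs (AsiSI-like), compute the curve,
and decode the peak:

```
$ cat sim.yaml
genome:
  chr1: 2000000
n_sites: 200
end_structure: three_prime_overhang
overhang_len: 2
reads_per_end: 8
background_rate: 0.00005
seed: 5

$ cncc simulate --config sim.yaml --out-prefix demo
... simulated 200 sites, 3525 total reads

$ cncc compute --pos demo.pos.dz --neg demo.neg.dz \
      --min-shift -50 --max-shift 50 --out curve.tsv
... argmax shift -3 (CNCC 0.9738)

$ cncc call --curve curve.tsv --top 1
shift   cncc      kind                  overhang_nt
-3      0.973765  three_prime_overhang  2
```

The shuffled control (wiggle ±2 nt) suppresses the spike ~110×, confirming
it reflects paired ends rather than coverage autocorrelation:

```
$ cncc control --pos demo.pos.dz --neg demo.neg.dz \
      --wiggle 2 --seed 7 --min-shift -50 --max-shift 50 --out ctrl.tsv
# CNCC(-3): raw 0.9738, control 0.0088
```

Real data enters through `cncc coverage`, which builds the per-strand
`.dz` depth files (TSV: chrom, position, count) from single-nucleotide
break-end BED6 records or from a coordinate-sorted BAM (read-1 5′ ends of
proper pairs, duplicates and secondary/supplementary alignments removed).

Other commands: `cncc relative`, `cncc sensitivity`, `cncc density`,
`cncc pairs`, `cncc pairs-fasta`. See `cncc <command> --help`.

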