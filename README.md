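# amomarker

DNA-barcode authentication of **Amomi Fructus** — the crude drug prepared
from the ripe fruits of *Amomum villosum*, *A. villosum* var.
*xanthioides*, and *A. longiligulare* — against the morphologically
confusable *Amomum*, *Alpinia*, and *Elettaria* species that adulterate it
in herbal markets.

Sequencing five barcode loci (ITS, *matK*, *rbcL*, *rpoB*, *trnL-F*
intergenic spacer) separates the genuine species from every adulterant,
but is slow and costly for routine market surveillance.  This package
implements the faster alternative built on top of the barcode survey: an
**allele-specific multiplex PCR assay** whose gel band pattern identifies
the species in a single reaction, plus the survey analytics needed to
design and validate it.

The pipeline covers:

* **Alignment statistics** — per-locus site classification (conserved /
  variable / parsimony-informative / singleton), pairwise identity
  matrices, and multi-locus concatenation.
* **Diagnostic SNP discovery** — alignment columns at which each target
  species carries a fixed, distinguishing nucleotide (with a support rule
  that filters single-record noise but keeps genuine intraspecific
  variation).
* **Marker design** — species primers whose 3′-terminal base sits exactly
  on a diagnostic allele (one mismatch blocks extension in every other
  species), a universal internal-standard pair in a conserved 5.8S block,
  and multiplex assembly checks (product-size resolution, 3′-dimer
  screening, nearest-neighbor melting-temperature compatibility).
* **In-silico multiplex PCR** — binding-site search with a strict 3′
  anchor, product enumeration, gel-lane emulation, and band-pattern
  species calls.
* **Distance phylogenetics** — p/JC69/K2P/TN93 distances with pairwise
  deletion, UPGMA and neighbor-joining trees, bootstrap support, Newick
  output, monophyly tests.
* **Market monitoring** — the end-to-end workflow: multiplex assay per
  sample, confirmation by nearest-reference ITS identity (global
  affine-gap alignment), reconciliation with the declared name, and a
  report flagging mislabeled, mixed, and unknown-adulterant samples.

Real voucher sequences are not bundled.  A seeded synthetic-data module
generates a five-locus reference panel (25 in-group + 30 adulterant
records + 2 outgroups) with a *planted*, fully logged polymorphism
structure — 19 diagnostic positions in ITS, 1 in *matK*, 4 in *rbcL*, 1 in
*rpoB*, 7 in *trnL-F* (32 total) — and a 40-sample monitoring panel
containing mislabeled samples, one two-species mixture, and two samples of
an off-panel adulterant species.

## The assay logic

With primers AVF1 (anchored on an allele shared by *A. villosum* and its
variety), ALF1 (anchored on an *A. longiligulare*-specific allele) and the
universal pair ISF/ISR, one multiplex reaction yields:

| template                      | bands (b)        | verdict          |
|-------------------------------|------------------|------------------|
| *A. villosum* / var. *xanth.* | 270 + 100        | villosum group   |
| *A. longiligulare*            | 350 + 100        | longiligulare    |
| both (mixed sample)           | 270 + 350 + 100  | mixture          |
| any adulterant                | 100 only         | non-target       |
| no internal standard          | —                | assay failure    |

## Worked example

```python
from amomarker import (PanelConfig, design_marker_panel,
                       generate_reference_panel, simulate_pcr)

panel = generate_reference_panel(PanelConfig(seed=42))
markers = design_marker_panel(panel["ITS"])
for primer in markers.primers:
    print(primer.name, primer.orientation, primer.seq, round(primer.tm_c, 1))
villosum = panel["ITS"].records[0].degapped()
print(sorted(p.size for p in simulate_pcr(villosum, markers)))
```

prints

```
AVF1 forward CTTGGATGATTGTGAACGTGTCAACA 58.9
ALF1 reverse GGTCTCTTTGAGGACACATCCCG 59.7
ISF forward AGGGCGGAGTGCTCGGTTA 60.8
ISR reverse CCTCGTAGTACAGTTAGGTATTGTCA 56.2
[100, 270]
```

i.e. the designer recovered a forward villosum-group marker and a reverse
longiligulare marker anchored on planted diagnostic alleles, an internal
standard in the conserved block, and the *A. villosum* template produces
the 270-base species product next to the 100-base control band.

The numbered scripts under `analysis/` run the whole study workflow and
write tables under `results/`:

```sh
python analysis/01_generate_panel.py     # panels + truth log
python analysis/02_barcode_stats.py      # site classes, identity ranges
python analysis/03_design_markers.py     # SNP table + marker panel
python analysis/04_insilico_pcr.py       # 59/59 verdicts concordant
python analysis/05_phylogeny.py          # trees, monophyly, support
python analysis/06_monitor_market.py     # 40-sample monitoring report
```

The monitoring step reports 28 concordant samples, 9 mislabeled, 1
mixture (sample 9), and 2 unknown adulterants (samples 12 and 26, internal
standard only, below 0.95 ITS identity to every reference — candidate new
adulterants rather than any named species).

There is also a CLI (`amomarker generate|profile|snps|design|pcr|tree|
monitor`) exposing the same steps on FASTA/TSV files.

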