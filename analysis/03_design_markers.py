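#!/usr/bin/env python
"""Discover diagnostic SNPs and design the allele-specific multiplex panel.

Writes the SNP table (results/diagnostic_snps.tsv) and the four-primer
multiplex panel (results/marker_panel.tsv): one species marker for the
A. villosum group, one for A. longiligulare, and the universal
internal-standard pair in the conserved 5.8S-like block.
"""

import argparse
from pathlib import Path

from amomarker import (PanelConfig, PrimerConstraints,
                       assemble_multiplex_panel, design_internal_standard,
                       design_species_primer, find_diagnostic_snps,
                       generate_reference_panel)
from amomarker.marker_design import write_panel_tsv
from amomarker.synthetic_data import (A_LONGILIGULARE, A_VILLOSUM,
                                      A_XANTHIOIDES, INGROUP_SPECIES)


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=42)
    parser.add_argument("--out", default="results")
    args = parser.parse_args()
    outdir = Path(args.out)
    outdir.mkdir(parents=True, exist_ok=True)

    panel = generate_reference_panel(PanelConfig(seed=args.seed))

    total = 0
    with (outdir / "diagnostic_snps.tsv").open("w") as fh:
        fh.write("locus\tcolumn\tkind\tdiscriminated\t"
                 + "\t".join(INGROUP_SPECIES) + "\n")
        for locus, aln in panel.alignments.items():
            snps = find_diagnostic_snps(aln, INGROUP_SPECIES)
            total += len(snps)
            print(f"{locus}: {len(snps)} diagnostic positions")
            for snp in snps:
                fh.write(f"{locus}\t{snp.column}\t{snp.kind}\t"
                         f"{snp.discriminated_species or ''}\t"
                         + "\t".join(snp.alleles[sp]
                                     for sp in INGROUP_SPECIES) + "\n")
    print(f"total: {total} diagnostic positions across five loci")

    its = panel["ITS"]
    constraints = PrimerConstraints()
    is_pair = design_internal_standard(its, constraints)
    snps = find_diagnostic_snps(its, INGROUP_SPECIES)
    avf1 = design_species_primer(
        its, snps, A_VILLOSUM, constraints,
        target_species={A_VILLOSUM, A_XANTHIOIDES},
        is_pair=is_pair, name="AVF1")
    alf1 = design_species_primer(its, snps, A_LONGILIGULARE, constraints,
                                 is_pair=is_pair, name="ALF1")
    marker_panel = assemble_multiplex_panel([avf1, alf1], is_pair, its)
    write_panel_tsv(marker_panel, outdir / "marker_panel.tsv")

    print("\nmultiplex panel:")
    for p in marker_panel.primers:
        print(f"  {p.name:5s} {p.orientation:8s} {p.seq}  Tm {p.tm_c:.1f} C")
    for label, size in sorted(marker_panel.expected_products.items(),
                              key=lambda kv: kv[1]):
        print(f"  expected product {size:4d} b  <- {label}")


if __name__ == "__main__":
    main()
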