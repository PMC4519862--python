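#!/usr/bin/env python
"""Recompute haplotype-set statistics from locally downloaded sequences.

The deposited haplotype sequences (GenBank KC556828-KC556873 for the
mitochondrial control region, KC556874-KC556882 for the proPOx intron) are
optional validation inputs: download them yourself (e.g. with NCBI efetch),
align each set, and point this script at the aligned FASTA files.  It
reports the variable-site and gap-site counts and the mean pairwise
composite-likelihood (MCL) distance for each haplotype set, for comparison
with the published survey values.

Usage:
    python scripts/accession_check.py --control-fasta cr_haps.aln.fasta \
        --intron-fasta intron_haps.aln.fasta
"""

from __future__ import annotations

import argparse

from invabc.diversity import distance_matrix
from invabc.seq_io import PopulationMap, classify_sites, collapse_haplotypes, read_fasta


def report(path: str, locus: str, inheritance: str) -> None:
    aln = read_fasta(path, locus, inheritance)
    sc = classify_sites(aln)
    popmap = PopulationMap({sid: "all" for sid in aln.sample_ids})
    haps = collapse_haplotypes(aln, popmap)
    mcl = distance_matrix(haps, "MCL")
    print(f"== {locus} ({aln.n} sequences, {aln.length} sites) ==")
    print(f"variable sites:            {sc.n_variable}")
    print(f"  singleton (2 variants):  {sc.n_singleton_2var}")
    print(f"  informative (2 variants):{sc.n_pi_2var}")
    print(f"  informative (3 variants):{sc.n_pi_3var}")
    print(f"sites with gaps/N:         {sc.n_gap_sites}")
    print(f"distinct haplotypes:       {haps.n_haplotypes}")
    print(f"mean MCL distance:         {mcl.mean:.4f}")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--control-fasta", help="aligned control-region haplotypes")
    parser.add_argument("--intron-fasta", help="aligned intron haplotypes")
    args = parser.parse_args()
    if not (args.control_fasta or args.intron_fasta):
        parser.error("provide at least one aligned FASTA")
    if args.control_fasta:
        report(args.control_fasta, "control_region", "mitochondrial")
    if args.intron_fasta:
        report(args.intron_fasta, "propox_intron", "x_linked")


if __name__ == "__main__":
    main()
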