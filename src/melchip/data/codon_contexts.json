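{
  "_comment": "Synthetic coding-strand CDS windows (+/- 12 nt) around each panel codon. The target codons are fixed by the panel's own reference/alternate amino-acid labels; flanking codons are plausible filler (real context is used for the well-known BRAF 596-604 stretch) and are read only for frame alignment, never for validation. cds_start is the 1-based CDS coordinate of the first base of each window.",
  "contexts": [
    {"gene": "BRAF", "codon_number": 600, "cds_start": 1786, "sequence": "GGTCTAGCTACAGTGAAATCTCGATGG"},
    {"gene": "NRAS", "codon_number": 12, "cds_start": 22, "sequence": "GTAGTTGGAGCTGGTGGTGTTGGGAAA"},
    {"gene": "NRAS", "codon_number": 13, "cds_start": 25, "sequence": "GTTGGAGCTGGTGGTGTTGGGAAAAGC"},
    {"gene": "NRAS", "codon_number": 61, "cds_start": 169, "sequence": "GATACAGCTGGACAAGAAGAGTACAGT"},
    {"gene": "KIT", "codon_number": 557, "cds_start": 1657, "sequence": "TATGAAGTTCAGTGGAAGGTTGTTGAA"},
    {"gene": "KIT", "codon_number": 559, "cds_start": 1663, "sequence": "GTTCAGTGGAAGGTTGTTGAAGAAATT"},
    {"gene": "KIT", "codon_number": 576, "cds_start": 1714, "sequence": "AATCCTGAAAATCTTTATGTGGACCCA"},
    {"gene": "KIT", "codon_number": 642, "cds_start": 1912, "sequence": "GGTGAATTTGGAAAGGTTCTTGGAGAT"},
    {"gene": "KIT", "codon_number": 816, "cds_start": 2434, "sequence": "ATTAAAAATGATGACTCTAATTATGTG"},
    {"gene": "GNAQ", "codon_number": 209, "cds_start": 613, "sequence": "ACTGATGAAAATCAACGAATGGAAGAA"},
    {"gene": "GNA11", "codon_number": 209, "cds_start": 613, "sequence": "ACTGATGAAAATCAGCGCATGGAAGAA"},
    {"gene": "MAP2K1", "codon_number": 121, "cds_start": 349, "sequence": "GAACTTATGGAATGTAATTCTCCCTAT"},
    {"gene": "MAP2K1", "codon_number": 124, "cds_start": 358, "sequence": "GAATGTAATTCTCCCTATATTGTGGGA"},
    {"gene": "MAP2K2", "codon_number": 57, "cds_start": 157, "sequence": "GATGGTGAAATTTTCGATTTTCAGAAA"},
    {"gene": "MAP2K2", "codon_number": 60, "cds_start": 166, "sequence": "ATTTTCGATTTTCAGAAAGAAATGGTT"}
  ]
}
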