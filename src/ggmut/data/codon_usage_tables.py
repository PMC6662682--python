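"""Bundled relative synonymous codon-usage fractions.

Kazusa-style codon usage for the three selectable host organisms.
Values are fractions per amino acid (rounded to two decimals as commonly
tabulated); :class:`ggmut.seqcore.CodonUsageTable` renormalises each
amino-acid group at load so the fractions sum to exactly 1.

See ``README.md`` in this directory for provenance and versioning.
"""

USAGE_FRACTIONS: dict[str, dict[str, float]] = {
    "e_coli": {
        # Ala
        "GCG": 0.36, "GCC": 0.27, "GCA": 0.21, "GCT": 0.16,
        # Arg
        "CGC": 0.40, "CGT": 0.38, "CGG": 0.10, "CGA": 0.06,
        "AGA": 0.04, "AGG": 0.02,
        # Asn
        "AAC": 0.55, "AAT": 0.45,
        # Asp
        "GAT": 0.63, "GAC": 0.37,
        # Cys
        "TGC": 0.55, "TGT": 0.45,
        # Gln
        "CAG": 0.65, "CAA": 0.35,
        # Glu
        "GAA": 0.68, "GAG": 0.32,
        # Gly
        "GGC": 0.40, "GGT": 0.34, "GGG": 0.15, "GGA": 0.11,
        # His
        "CAT": 0.57, "CAC": 0.43,
        # Ile
        "ATT": 0.51, "ATC": 0.42, "ATA": 0.07,
        # Leu
        "CTG": 0.50, "TTA": 0.13, "TTG": 0.13, "CTT": 0.10,
        "CTC": 0.10, "CTA": 0.04,
        # Lys
        "AAA": 0.77, "AAG": 0.23,
        # Met
        "ATG": 1.00,
        # Phe
        "TTT": 0.57, "TTC": 0.43,
        # Pro
        "CCG": 0.52, "CCA": 0.19, "CCT": 0.16, "CCC": 0.13,
        # Ser
        "AGC": 0.28, "TCT": 0.15, "TCC": 0.15, "TCG": 0.15,
        "AGT": 0.15, "TCA": 0.12,
        # Thr
        "ACC": 0.44, "ACG": 0.27, "ACT": 0.17, "ACA": 0.13,
        # Trp
        "TGG": 1.00,
        # Tyr
        "TAT": 0.57, "TAC": 0.43,
        # Val
        "GTG": 0.37, "GTT": 0.26, "GTC": 0.22, "GTA": 0.15,
        # Stop
        "TAA": 0.64, "TGA": 0.29, "TAG": 0.07,
    },
    "s_cerevisiae": {
        "GCT": 0.38, "GCA": 0.29, "GCC": 0.22, "GCG": 0.11,
        "AGA": 0.48, "AGG": 0.21, "CGT": 0.14, "CGA": 0.07,
        "CGC": 0.06, "CGG": 0.04,
        "AAT": 0.59, "AAC": 0.41,
        "GAT": 0.65, "GAC": 0.35,
        "TGT": 0.63, "TGC": 0.37,
        "CAA": 0.69, "CAG": 0.31,
        "GAA": 0.70, "GAG": 0.30,
        "GGT": 0.47, "GGA": 0.22, "GGC": 0.19, "GGG": 0.12,
        "CAT": 0.64, "CAC": 0.36,
        "ATT": 0.46, "ATA": 0.27, "ATC": 0.26,
        "TTG": 0.29, "TTA": 0.28, "CTA": 0.14, "CTT": 0.13,
        "CTG": 0.11, "CTC": 0.06,
        "AAA": 0.58, "AAG": 0.42,
        "ATG": 1.00,
        "TTT": 0.59, "TTC": 0.41,
        "CCA": 0.42, "CCT": 0.31, "CCC": 0.15, "CCG": 0.12,
        "TCT": 0.26, "TCA": 0.21, "TCC": 0.16, "AGT": 0.16,
        "AGC": 0.11, "TCG": 0.10,
        "ACT": 0.35, "ACA": 0.30, "ACC": 0.22, "ACG": 0.14,
        "TGG": 1.00,
        "TAT": 0.56, "TAC": 0.44,
        "GTT": 0.39, "GTC": 0.21, "GTA": 0.21, "GTG": 0.19,
        "TAA": 0.47, "TGA": 0.30, "TAG": 0.23,
    },
    "a_thaliana": {
        "GCT": 0.43, "GCA": 0.27, "GCC": 0.16, "GCG": 0.14,
        "AGA": 0.35, "AGG": 0.20, "CGT": 0.17, "CGA": 0.12,
        "CGG": 0.09, "CGC": 0.07,
        "AAT": 0.52, "AAC": 0.48,
        "GAT": 0.68, "GAC": 0.32,
        "TGT": 0.60, "TGC": 0.40,
        "CAA": 0.56, "CAG": 0.44,
        "GAA": 0.52, "GAG": 0.48,
        "GGA": 0.37, "GGT": 0.34, "GGG": 0.16, "GGC": 0.14,
        "CAT": 0.61, "CAC": 0.39,
        "ATT": 0.41, "ATC": 0.35, "ATA": 0.24,
        "CTT": 0.26, "TTG": 0.22, "CTC": 0.17, "TTA": 0.14,
        "CTG": 0.11, "CTA": 0.11,
        "AAG": 0.52, "AAA": 0.48,
        "ATG": 1.00,
        "TTT": 0.51, "TTC": 0.49,
        "CCT": 0.38, "CCA": 0.33, "CCG": 0.17, "CCC": 0.11,
        "TCT": 0.28, "TCA": 0.20, "AGT": 0.16, "TCC": 0.13,
        "AGC": 0.13, "TCG": 0.10,
        "ACT": 0.34, "ACA": 0.31, "ACC": 0.20, "ACG": 0.15,
        "TGG": 1.00,
        "TAT": 0.52, "TAC": 0.48,
        "GTT": 0.41, "GTG": 0.26, "GTC": 0.19, "GTA": 0.15,
        "TGA": 0.44, "TAA": 0.36, "TAG": 0.20,
    },
}
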