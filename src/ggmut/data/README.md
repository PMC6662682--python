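# Bundled data

## Codon usage tables (`codon_usage_tables.py`)

Relative synonymous codon-usage fractions for the three selectable
expression hosts:

| key            | organism                   | source style                          |
|----------------|----------------------------|---------------------------------------|
| `e_coli`       | *Escherichia coli* K-12    | Kazusa codon-usage database (GenBank-derived fractions, 2-decimal tabulation) |
| `s_cerevisiae` | *Saccharomyces cerevisiae* | Kazusa codon-usage database            |
| `a_thaliana`   | *Arabidopsis thaliana*     | Kazusa codon-usage database            |

Values are the widely tabulated per-amino-acid fractions rounded to two
decimals; the loader renormalises each synonymous group so fractions sum
to exactly 1. These tables steer silent-mutation choice toward frequent
codons; design correctness does not depend on their exact decimals, only
on the relative ordering of synonymous codons.

Version: fractions as tabulated in the Kazusa release derived from
GenBank (the classic, stable tabulation reproduced in most cloning
tools). Bundled here as static data; swap in a different
`CodonUsageTable` at the API level for other hosts or newer counts.
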