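# ggmut — Golden Gate multi-site saturation mutagenesis toolkit

`ggmut` automates the design work behind Golden Gate–based mutagenesis
libraries for directed enzyme evolution: given an in-frame coding
sequence and a set of target residues, it designs the mutagenic primers
for one-pot type IIS restriction–ligation cloning, validates every
design by in-silico assembly, and evaluates finished libraries by Quick
Quality Control (QQC) of pooled Sanger chromatograms. It is aimed at
protein-engineering labs that want CASTing/ISM-style single- and
multi-site saturation mutagenesis (NDT, NNK, …) or defined point
mutations without hand-designing oligos.

## The method

Type IIS enzymes (BsaI `GGTCTC(N1)`, BbsI `GAAGAC(N2)`) cut outside
their non-palindromic recognition sequences, exposing arbitrary 4-nt
5′ overhangs. Of the 4⁴ = 256 possible overhangs, the 16 palindromic
ones self-anneal, leaving 240 usable junction overhangs — enough to
reassemble a gene from several PCR fragments seamlessly and
directionally, with the recognition site liberated from every correct
product (which is what drives the one-pot reaction to completion).

`ggmut` exploits this to mutagenize: mutation sites within ≤ 45 nt are
clustered onto one fragment junction, so a design with *k* clusters
needs *k* + 1 fragments and 2(*k* + 1) primers. Each primer is a
structured oligo

```
padding | recognition site | spacer | 4-bp overhang | mutagenic insert | binding
```

Saturation codons ride in the mutagenic insert (never in the overhang,
which must direct reassembly); point mutations are placed *inside* the
overhang when a valid window overlaps the codon, so the altered bases
themselves guide rejoining. Binding regions are extended until their
nearest-neighbor melting temperature (unified SantaLucia-1998
parameters, 50 mM Na⁺, 500 nM oligo) reaches the 60 °C target, and each
primer pair is balanced to within 5 °C. Internal BsaI/BbsI sites are
"domesticated" away with silent single-codon substitutions chosen by
relative synonymous codon usage (*E. coli*, *S. cerevisiae* or
*A. thaliana* tables); in the point-mutagenesis workflow those fixes
are folded into the same primer set. Designs of ≤ 3 fragments go
directly into the BsaI expression vector pAGM22082_CRed (overhangs
`AATG`/`GCTT`); larger designs are subcloned fragment-wise into the
BbsI cloning vector pAGM9121 (`CTCA`/`CGAG`) first.

Every design can be verified in silico (`verify_design`): simulated
PCR → digestion → overhang-directed ligation must reproduce the
template with substitutions exactly at the requested codons. For QQC,
the pooled library's `.ab1` chromatogram is anchored to the reference,
and at each randomized position the four channel intensities at the
called peak give the base proportions, scored by total-variation
distance against the expected degeneracy (e.g. NDT expects
¼/¼/¼/¼, ⅓ A/G/T, then pure T).

## Worked example

Design NDT saturation at five residues of a synthetic 300-codon CDS
(generated by the bundled fixture command):

```bash
ggmut fixture design --seed 1 --out-dir .
ggmut design fixture_cds.fasta -m 137:NDT -m 143:NDT -m 147:NDT \
      -m 232:NDT -m 234:NDT --out-dir out
```

prints

```
3 fragment(s), 6 primers; recommended workflow: one_step. Wrote primers.csv, design.json, protocol.txt
```

The five sites fall into two clusters (137/143/147 and 232/234), hence
three fragments and six primers, few enough for direct one-step
assembly into pAGM22082_CRed. The protocol file lists the primers,
e.g.

```
F2_fwd     Tm(binding)  60.0 C
  TTGGTCTCACCCTNDTGTGAACCTGAAGCATNDTTGCGCTGCCNDTCGCGGCAGGAGGGAAAT
```

— padding `TT`, BsaI site `GGTCTC`, 1-nt spacer, junction overhang
`CCCT`, the three NDT codons with the intervening wild-type codons
carried verbatim, then a binding region whose Tm (60.0 °C) is balanced
against its partner (61.4 °C) — followed by the PCR recipe, the 15 µl
Golden Gate cycling program (40 × [37 °C 2 min, 20 °C 5 min], 80 °C
inactivation) and vector-specific transformation notes. Validate and
analyze a pooled-library trace:

```bash
ggmut simulate out/design.json fixture_cds.fasta          # seamless or non-zero exit
ggmut qqc --ab1 pool.ab1 --design out/design.json --fasta fixture_cds.fasta
```

The QQC command writes per-position pie charts (`qqc_pies.png`) and a
CSV of A/C/G/T proportions with TV scores.

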