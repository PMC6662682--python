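# Methods

This note documents the models, conventions and numerical choices
behind `ggmut`, and what the synthetic test conditions do and do not
show about real data.

## Coordinates and sequence model

User-facing amino-acid positions are 1-based ("D137"); all nucleotide
coordinates are 0-based, half-open. A CDS must be in frame start-to-stop
(ATG … stop, no internal in-frame stop). Sequences are linear; sites
spanning a circular origin are out of scope. Double-stranded DNA is
represented throughout by its + strand plus overhang annotations; the
contracts checked here never need a full two-strand model. Degenerate
IUPAC bases are carried symbolically through design and simulation;
strict expansions are only sampled in the final verification step
(seeded RNG, default seed 17).

## Enzymes, vectors, overhangs

BsaI (`GGTCTC`, 1-nt spacer) and BbsI (`GAAGAC`, 2-nt spacer) both
leave 4-nt 5′ overhangs; the geometry constants follow the standard
REBASE definitions and are bundled as immutable constants. Vector
constants: pAGM9121 (BbsI, overhangs `CTCA`/`CGAG`, extrinsic to the
insert) and pAGM22082_CRed (BsaI, `AATG`/`GCTT`; the `AATG` overhang
overlaps the start codon — its last three bases *are* the ATG — and
`GCTT` sits after the stop). A junction overhang must be
non-palindromic, distinct from every other overhang in the design, and
not the reverse complement of any of them; 240 of the 256 4-mers are
eligible in principle.

## Domestication

Internal BsaI/BbsI sites are removed one at a time by the synonymous
single-codon substitution that (a) destroys the site, (b) creates no
new site of either enzyme on either strand (verified by a full re-scan
after each edit), and (c) has the highest relative synonymous usage in
the chosen organism, never below a configurable floor (default 0.05) so
rare codons are not introduced. Ties break by smaller codon index, then
alphabetically — a stated convention, since several synonymous codons
can be equally frequent. Only single-codon fixes are attempted; if none
works the site is reported as undomesticatable rather than guessing at
multi-codon edits. The bundled usage tables are classic Kazusa-style
per-amino-acid fractions (see `src/ggmut/data/README.md`); design
correctness depends only on the relative ordering of synonyms, not the
exact decimals.

The point-mutagenesis workflow folds domestication into the same design
pass: the silent fixes become extra codon edits carried on the primers,
so the template is mutagenized and domesticated in one cloning step.
The converse case is handled the same way — if every codon of a
requested target residue completes an enzyme site with its flanking
bases (e.g. a `GAAGA` context ahead of any proline codon's leading C),
the engine keeps the preferred codon and removes the created site with
a synonymous fix on an overlapped codon, allowing a synonymous
re-choice at the mutated codon itself since that preserves the target
residue.

## Fragmenting and overhang selection

Mutations are clustered greedily left-to-right: a mutation joins the
open cluster iff the nucleotide span from the cluster's first mutated
codon through this codon's end stays within `max_cluster_span_nt`
(default 45 nt — keeps the longest primer near the ~90-nt synthesis
limit). Each cluster contributes one junction, so fragments = clusters
+ 1; every fragment must be at least `min_fragment_len` (default 100
nt, a gel-resolvable PCR product), otherwise the design errs with
advice to merge clusters.

The junction sits immediately 5′ of the cluster's first mutated codon,
and the overhang is the 4-nt window of the (edit-applied) sequence
ending at the junction. If that window is palindromic, collides with an
already-chosen overhang (or a reverse complement of one), or would
create a stray enzyme site at the cassette boundary, the window is
shifted up to 6 nt further 5′, carrying the skipped template bases into
the mutagenic insert; exhaustion of the shift window is a hard error.
For clusters led by a *strict* edit (point mutation or silent fix),
windows ending 1–3 nt into the mutated codon are tried first, so the
altered bases themselves sit in the overhang and direct rejoining —
the fallback is the generic 5′ window. Randomized (degenerate) codons
can never occupy an overhang, since a mixed overhang cannot direct a
unique assembly.

## Primers and the Tm model

Each primer is `padding + recognition + spacer + overhang + insert +
binding`. Padding defaults to `TT` (supports enzyme binding at the
duplex end) and the spacer is `A`-filled to the enzyme's spacer length;
both are configurable, and any fixed non-site-forming choice is
equivalent. Mutagenic codons ride on the *forward* primer of the
downstream fragment (one convention keeps reverse primers short);
intervening wild-type codons inside a cluster are carried verbatim.

Binding regions anneal to the unmodified template (all edits live in
primer-carried segments), are 12–45 nt long, and are extended base by
base until the nearest-neighbor Tm reaches the 60 °C target — the
returned region is minimal. Tm uses the unified SantaLucia-1998
dinucleotide parameters with the matching entropy salt correction
(0.368·(N−1)·ln[Na⁺]) at 50 mM monovalent salt and 500 nM oligo.
If the 45-nt cap is hit below target (AT-rich templates) the primer is
flagged `low_tm` instead of failing. After both primers of a pair are
built, the cooler binding region is extended while that shrinks the
pair's Tm difference, targeting ≤ 5 °C. The tests hold this
implementation to within 0.1 °C of an independently written
nearest-neighbor implementation of the same published parameter set.

Stray-site policy: a primer with a *definite* (strict-base) extra
recognition site is rejected (the overhang search already avoids
cassette-boundary sites, and a domesticated template cannot contribute
any, so this is a hard error if it ever fires). A site that is merely
*possible* through some expansion of a degenerate insert is logged as a
warning, not an error: shifting an overhang cannot remove a possibility
that spans the randomized codon itself, and common saturation schemes
(NNK in a suitable context) inherently carry a small re-cutting risk
that practitioners accept. The simulator and verification operate on
the symbolic sequence, where only literal sites cut.

## Workflow rule and protocol

Designs of three or fewer fragments are recommended for one-step
assembly directly into the expression vector; larger designs use the
two-step route (per-fragment BbsI subcloning into pAGM9121, then BsaI
reassembly), which also supports iterative schemes (ISM/CASTing) by
re-mutagenizing one subcloned fragment at a time. The rendered protocol
is deterministic text: primer table, the standard 50 µl high-fidelity
PCR recipe, the 15 µl one-pot restriction–ligation program
(40 × [37 °C 2 min, 20 °C 5 min], 80 °C 20 min inactivation) and
vector-appropriate transformation/selection notes (LacZ blue/white for
pAGM9121, CRed orange/white for pAGM22082_CRed).

## Assembly simulation

The simulator is combinatorial and deterministic — no ligation
kinetics, no mismatch ligation, no colony-count or fidelity modeling
(an overhang-fidelity scoring hook is a possible extension, not
implemented). PCR requires exact binding matches in the correct
orientation; digestion requires exactly one inward-facing recognition
site per strand and exposes the 4-nt overhangs by cut-position
arithmetic; ligation chains fragments by exact overhang identity,
rejecting duplicated overhangs ("ambiguous assembly") and incomplete
chains ("unassemblable"). Verification asserts byte-level equality of
the assembled insert with the intended (possibly degenerate) library
sequence, confinement of substitutions to the designed codons, absence
of any residual assembly-enzyme site, and frame preservation of sampled
strict expansions.

## QQC

The ABIF reader takes the analyzed-trace channels (DATA9–12, ordered by
the filter-wheel tag FWO_), basecalls (PBAS) and peak locations (PLOC),
and quantifies each call as the channel intensities *at the called peak
scan* — simple and robust at the precision a pie chart needs; peak-area
integration is a conceivable alternative, not the default. Reads are
anchored to the reference by the longest exact match outside the
randomized codons (≥ 20 nt) with ungapped extension, requiring ≥ 80 %
identity over ≥ 60 nt; Sanger reads of plasmid pools have negligible
indels at this use, so no full aligner is needed. Reverse reads map
through reverse-complement coordinates and their base labels are
complemented. Divergence from the expected degeneracy is reported as
total-variation distance to the uniform distribution over allowed
bases (0 = perfect; 0.75 = a single base where N was expected); a TV
score is reported without a pass/fail verdict, since no quantitative
acceptance threshold for library quality is established.

## Synthetic data and what the tests show

All fixtures are generated programmatically and seeded. Random CDSs use
uniform sense codons (ATG…TAA); planted-site fixtures overwrite
codon-aligned pairs with recognition sequences on either strand and
verify the exact planted count. The two worked-design fixtures
reproduce the *positional geometry* of two classic benchmark
scenarios — a
711-nt CDS with a Leu codon at position 69 and one internal BbsI site
(point-mutagenesis case), and a 300-codon CDS with NDT saturation at
{137, 143, 147, 232, 234} (multi-site case) — but are synthetic
sequences, not the real mCherry/YfeX genes; fragment and primer counts
depend only on this geometry.

The chromatogram generator models a pooled library as the sum of
per-variant ideal traces: each strict expansion of a randomized codon
contributes its trace scaled by a multiplicative log-normal abundance
factor (σ = 0.1 in log space), emulating unequal variant representation
such as bias in the ordered primer mixture — the dominant distortion
observed in real pooled reads. A per-peak log-normal amplitude factor
adds height variability without touching proportions. What this does
*not* model: basecalling errors, dye blobs, mobility shifts, baseline
noise, indels, or channel cross-talk; passing QQC tests therefore
demonstrates correct bookkeeping and mixture arithmetic, not robustness
to degraded real-world traces. Problem sizes in the test and acceptance
sweeps (100 random designs of 600–1500 nt; 200 planted-site fixtures;
1000 random oligos for the Tm contract) were chosen as comfortably
large samples for the properties asserted.

## Known limitations

- Single-codon domestication only; pathological sites overlapping
  codons with no usable synonyms are reported, not worked around.
- No oligo secondary-structure screening (hairpins/dimers) and no
  synthesis-cost optimization.
- Overhang choice checks validity, not ligation-fidelity scores; all
  240 non-palindromic overhangs are treated as equally usable.
- The Tm pair-balancing is greedy (extend the cooler primer); it does
  not explore joint re-anchoring.
- Start and stop codons are not mutable by default (`allow_terminal`
  overrides at the caller's risk).
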