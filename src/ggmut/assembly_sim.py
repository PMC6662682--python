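"""In-silico Golden Gate one-pot restriction-ligation.

A combinatorial, deterministic oracle for the designs produced by
:mod:`ggmut.primerdesign`: simulate PCR product formation, type IIS
digestion (cutting outside the recognition site, exposing the 4-nt
overhangs), overhang-directed ligation, and verify that the intended
library is reconstructed seamlessly — substitutions exactly at the
requested codons and nowhere else, no frameshifts, and no residual
site of the assembly enzyme in the product (the recognition sequence is
liberated from a correct insert, which is what drives the one-pot
reaction to completion).

Degenerate (IUPAC) bases are carried through symbolically; strict
expansions are only sampled in :func:`verify_design`'s final check.
No ligation kinetics, mismatch ligation or colony modeling.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .errors import AssemblyError
from .primerdesign import DesignResult, Primer, VectorSpec
from .seqcore import (
    DnaSequence,
    TypeIISEnzyme,
    as_bases,
    expand_degenerate_codon,
    is_strict,
    reverse_complement,
)


@dataclass(frozen=True)
class DigestedFragment:
    """A double-stranded fragment after type IIS digestion, represented
    by its + strand core and the two exposed 4-nt 5' overhangs."""

    core: str
    left_overhang: str
    right_overhang: str


@dataclass(frozen=True)
class AssemblyOutcome:
    assembled_cds: str
    is_seamless: bool
    mutated_codon_indices: frozenset[int]


def _find_all(hay: str, needle: str) -> list[int]:
    out, i = [], hay.find(needle)
    while i != -1:
        out.append(i)
        i = hay.find(needle, i + 1)
    return out


# --------------------------------------------------------------------------

def simulate_pcr(template: "DnaSequence | str", fwd: Primer, rev: Primer) -> str:
    """PCR product: forward primer, template interior, reverse-complement
    of the reverse primer. Both binding regions must match the template
    exactly (forward on +, reverse on -), forward upstream of reverse."""
    t = as_bases(template)

    def locate(binding_plus: str, span: tuple[int, int] | None) -> tuple[int, int]:
        if span is not None:
            a, b = span
            if 0 <= a <= b <= len(t) and t[a:b] == binding_plus:
                return a, b
        i = t.find(binding_plus)
        if i == -1:
            raise AssemblyError("primer does not anneal to the template")
        return i, i + len(binding_plus)

    fa, fb = locate(fwd.binding, fwd.binding_span)
    ra, rb = locate(reverse_complement(rev.binding), rev.binding_span)
    if fwd.direction != "forward" or rev.direction != "reverse" or fb > ra:
        raise AssemblyError(
            "primer does not anneal: inverted or overlapping orientation"
        )
    return fwd.full_sequence + t[fb:ra] + reverse_complement(rev.full_sequence)


def digest(product: str, enzyme: TypeIISEnzyme) -> DigestedFragment:
    """Cut a PCR product with its terminal type IIS cassettes.

    Requires exactly one recognition site per strand, facing inward;
    returns the interior with its 4-nt overhangs exposed (recognition
    site and spacer removed)."""
    p = product.upper()
    plus = _find_all(p, enzyme.recognition)
    minus = _find_all(p, enzyme.recognition_rc)
    if len(plus) != 1 or len(minus) != 1:
        raise AssemblyError(
            f"internal site: expected one {enzyme.name} site per strand, "
            f"found {len(plus)} (+) and {len(minus)} (-)"
        )
    site_p, site_m = plus[0], minus[0]
    if site_p > site_m:
        raise AssemblyError(
            f"orientation: {enzyme.name} sites face outward"
        )
    cut_left = site_p + len(enzyme.recognition) + enzyme.spacer_len
    cut_right = site_m - enzyme.spacer_len - enzyme.overhang_len
    if cut_left + enzyme.overhang_len > cut_right:
        raise AssemblyError("orientation: cut positions overlap")
    left_oh = p[cut_left:cut_left + enzyme.overhang_len]
    right_oh = p[cut_right:cut_right + enzyme.overhang_len]
    core = p[cut_left + enzyme.overhang_len:cut_right]
    return DigestedFragment(core, left_oh, right_oh)


def ligate(
    fragments: "list[DigestedFragment] | tuple[DigestedFragment, ...]",
    vector: VectorSpec,
    template: "DnaSequence | str | None" = None,
) -> AssemblyOutcome:
    """Join fragments where one's right overhang equals the next's left
    overhang, from the vector 5' overhang to the vector 3' overhang.

    The chain must be unique: duplicated overhangs raise "ambiguous
    assembly"; a chain that cannot reach the 3' overhang through every
    fragment raises "unassemblable"."""
    frags = list(fragments)
    if not frags:
        raise AssemblyError("unassemblable: no fragments")

    by_left: dict[str, DigestedFragment] = {}
    for f in frags:
        if f.left_overhang in by_left:
            raise AssemblyError(
                f"ambiguous assembly: overhang {f.left_overhang} is shared"
            )
        by_left[f.left_overhang] = f
    rights = [f.right_overhang for f in frags]
    if len(set(rights)) != len(rights):
        raise AssemblyError("ambiguous assembly: duplicated right overhang")

    assembled = vector.five_prime_overhang
    cur = vector.five_prime_overhang
    used = 0
    while used < len(frags):
        frag = by_left.get(cur)
        if frag is None:
            raise AssemblyError(
                f"unassemblable: no fragment carries left overhang {cur}"
            )
        assembled += frag.core + frag.right_overhang
        cur = frag.right_overhang
        used += 1
    if cur != vector.three_prime_overhang:
        raise AssemblyError(
            f"unassemblable: chain ends at {cur}, expected "
            f"{vector.three_prime_overhang}"
        )

    if vector.overhang_includes_start:
        cds = assembled[1:len(assembled) - 4]
    else:
        cds = assembled[4:len(assembled) - 4]

    is_seamless = False
    mutated: frozenset[int] = frozenset()
    if template is not None:
        t = as_bases(template)
        if len(cds) == len(t):
            diff_codons = {
                i // 3 + 1 for i in range(len(t)) if cds[i] != t[i]
            }
            mutated = frozenset(diff_codons)
            is_seamless = True
    return AssemblyOutcome(cds, is_seamless, mutated)


def verify_design(
    seq: DnaSequence,
    result: DesignResult,
    seed: int = 17,
    n_samples: int = 4,
) -> AssemblyOutcome:
    """Run PCR -> digestion -> ligation for every fragment of a design
    and assert seamless reconstruction of the intended library.

    Checks: the assembled CDS equals the template with substitutions
    exactly at the designed codons; no literal site of the assembly
    enzyme survives in the insert; and sampled strict expansions of every
    degenerate codon stay in frame with the sampled codon at the site.
    """
    vector = result.vector
    enzyme = vector.enzyme
    digested = []
    for fwd, rev in result.primers:
        try:
            product = simulate_pcr(seq, fwd, rev)
            digested.append(digest(product, enzyme))
        except AssemblyError as err:
            raise AssemblyError(
                f"fragment {fwd.fragment_index + 1}: {err}"
            ) from err

    outcome = ligate(digested, vector, template=seq)
    expected = result.plan.mutated_cds
    if outcome.assembled_cds != expected:
        raise AssemblyError(
            "assembly is not seamless: reconstructed CDS differs from the "
            "designed library sequence"
        )
    designed_codons = {e.codon_index for e in result.plan.edits}
    if not outcome.mutated_codon_indices <= designed_codons:
        extra = outcome.mutated_codon_indices - designed_codons
        raise AssemblyError(
            f"substitutions outside the designed codons: {sorted(extra)}"
        )
    cds = outcome.assembled_cds
    for pat in (enzyme.recognition, enzyme.recognition_rc):
        if pat in cds:
            raise AssemblyError(
                f"assembled insert retains a {enzyme.name} site"
            )

    # sample strict expansions of the degenerate codons
    rng = random.Random(seed)
    sat = [e for e in result.plan.edits if not is_strict(e.new_codon)]
    for _ in range(n_samples if sat else 0):
        sampled = cds
        picks: dict[int, str] = {}
        for e in sat:
            choice = rng.choice(sorted(expand_degenerate_codon(e.new_codon)))
            picks[e.codon_index] = choice
            i = e.nt_start
            sampled = sampled[:i] + choice + sampled[i + 3:]
        if len(sampled) % 3 or not is_strict(sampled):
            raise AssemblyError("sampled library member is out of frame")
        for idx, choice in picks.items():
            if sampled[(idx - 1) * 3: idx * 3] != choice:
                raise AssemblyError(
                    f"sampled codon not found at position {idx}"
                )
    return outcome
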