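"""Mutagenic primer design for Golden Gate point / saturation mutagenesis.

The engine splits a CDS into PCR fragments at mutation clusters, picks
4-nt junction overhangs for directional reassembly, and emits structured
primers::

    padding | recognition site | spacer | overhang | mutagenic insert | binding

Binding regions are nearest-neighbor Tm-balanced to a 60 degC target.
Point mutations are, when possible, encoded inside the junction overhang
itself (so the altered information directs reassembly); randomisation
(degenerate) codons are always placed between the overhang and the
binding region, never inside the overhang.

Amino-acid positions are 1-based; nucleotide coordinates 0-based,
half-open.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, replace

import pandas as pd

from . import domestication as dom
from .errors import DesignError, ValidationError
from .seqcore import (
    DegenerateCodon,
    DnaSequence,
    GENETIC_CODE,
    SYNONYMS,
    BBSI,
    BSAI,
    TypeIISEnzyme,
    codon_usage,
    could_match,
    is_palindromic,
    is_strict,
    reverse_complement,
    validate_overhang,
)

logger = logging.getLogger(__name__)
logger.addHandler(logging.NullHandler())


# --------------------------------------------------------------------------
# Vectors

@dataclass(frozen=True)
class VectorSpec:
    """A Golden Gate acceptor vector: the enzyme that opens it and the
    two 4-nt overhangs it exposes."""

    name: str
    enzyme: TypeIISEnzyme
    five_prime_overhang: str
    three_prime_overhang: str
    #: the 5' overhang overlaps the ATG start codon (its last 3 nt are
    #: the start codon itself), as in start-codon AATG fusion vectors
    overhang_includes_start: bool = False

    def __post_init__(self) -> None:
        validate_overhang(self.five_prime_overhang)
        validate_overhang(self.three_prime_overhang)


#: level 0 universal cloning vector (BbsI, LacZ blue/white marker)
PAGM9121 = VectorSpec("pAGM9121", BBSI, "CTCA", "CGAG")
#: level 2 T7 expression vector (BsaI, CRed orange/white marker);
#: AATG overhang spans the start codon, GCTT sits after the stop
PAGM22082_CRED = VectorSpec(
    "pAGM22082_CRed", BSAI, "AATG", "GCTT", overhang_includes_start=True
)

VECTORS: dict[str, VectorSpec] = {
    "pAGM9121": PAGM9121,
    "pAGM22082_CRed": PAGM22082_CRED,
}


# --------------------------------------------------------------------------
# Configuration

@dataclass(frozen=True)
class DesignConfig:
    """Tunable design parameters (defaults are the tool's standard
    conditions)."""

    target_tm: float = 60.0          # degC, binding-region target
    max_cluster_span_nt: int = 45    # mutations closer than this share a fragment
    min_fragment_len: int = 100      # nt, gel-resolvable PCR product
    organism: str = "e_coli"
    padding: str = "TT"              # 5' bases ahead of the recognition site
    spacer_fill: str = "A"           # fill base between recognition and overhang
    min_usage: float = 0.05          # reject rarer synonymous codons
    pair_tm_tolerance: float = 5.0   # max |Tm_fwd - Tm_rev| per pair
    min_binding_len: int = 12
    max_binding_len: int = 45
    max_overhang_shift: int = 6      # 5' search window for junction overhangs
    allow_terminal: bool = False     # permit mutating start/stop codons
    force_undomesticated: bool = False
    seed: int = 17                   # rng seed for downstream sampling checks

    def __post_init__(self) -> None:
        for name in ("target_tm", "max_cluster_span_nt", "min_fragment_len",
                     "pair_tm_tolerance", "min_binding_len", "max_binding_len"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


# --------------------------------------------------------------------------
# Nearest-neighbor melting temperature

# Unified nearest-neighbor parameters (SantaLucia 1998):
# (delta-H kcal/mol, delta-S cal/mol/K) per stacked dinucleotide.
NN_PARAMS: dict[str, tuple[float, float]] = {
    "AA": (-7.9, -22.2), "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "GT": (-8.4, -22.4), "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}
NN_INIT_AT = (2.3, 4.1)
NN_INIT_GC = (0.1, -2.8)
NN_SYM = (0.0, -1.4)

_R_GAS = 1.987  # cal/mol/K

DEFAULT_NA_MM = 50.0      # monovalent salt, mM
DEFAULT_OLIGO_NM = 500.0  # primer concentration, nM


def melting_temperature(
    binding: str,
    na_mm: float = DEFAULT_NA_MM,
    oligo_nm: float = DEFAULT_OLIGO_NM,
) -> float:
    """Nearest-neighbor duplex Tm in degC.

    Unified SantaLucia-1998 parameters with the matching entropy salt
    correction (0.368 * (N-1) * ln[Na+]); default conditions 50 mM
    monovalent salt, 500 nM oligo.
    """
    s = binding.upper()
    if len(s) < 8:
        raise ValidationError(f"binding region too short for Tm ({len(s)} nt)")
    if not is_strict(s):
        raise ValidationError("degenerate bases not allowed in binding region")

    dh, ds = 0.0, 0.0
    for end in (s[0], s[-1]):
        inc = NN_INIT_AT if end in "AT" else NN_INIT_GC
        dh += inc[0]
        ds += inc[1]
    for i in range(len(s) - 1):
        dd = s[i:i + 2]
        if dd not in NN_PARAMS:
            dd = reverse_complement(dd)
        dh += NN_PARAMS[dd][0]
        ds += NN_PARAMS[dd][1]

    selfcomp = s == reverse_complement(s)
    if selfcomp:
        dh += NN_SYM[0]
        ds += NN_SYM[1]
        k = oligo_nm * 1e-9
    else:
        k = oligo_nm * 1e-9  # single excess-primer species

    ds += 0.368 * (len(s) - 1) * math.log(na_mm * 1e-3)
    return 1000.0 * dh / (ds + _R_GAS * math.log(k)) - 273.15


# --------------------------------------------------------------------------
# Binding-region extension

def extend_binding(
    template: "DnaSequence | str",
    anchor: int,
    direction: str,
    target_tm: float = 60.0,
    min_len: int = 12,
    max_len: int = 45,
) -> tuple[str, float, bool]:
    """Shortest binding region from *anchor* reaching *target_tm*.

    ``direction='forward'`` grows 3' (rightward, region ``[anchor,
    anchor+L)``); ``'reverse'`` grows 5' (leftward, region ``[anchor-L,
    anchor)``), returned as the + strand slice. Returns ``(region, tm,
    low_tm_flag)``; the flag is set when the *max_len* cap is reached
    below target.
    """
    t = str(template)
    if direction == "forward":
        room = len(t) - anchor
    elif direction == "reverse":
        room = anchor
    else:
        raise ValidationError(f"direction must be forward/reverse, got {direction!r}")
    if room < min_len:
        raise DesignError(
            f"template exhausted: {room} nt available at anchor {anchor}, "
            f"need >= {min_len}"
        )
    cap = min(max_len, room)
    for length in range(min_len, cap + 1):
        region = (t[anchor:anchor + length] if direction == "forward"
                  else t[anchor - length:anchor])
        tm = melting_temperature(region)
        if tm >= target_tm:
            return region, tm, False
    # cap reached below target
    region = (t[anchor:anchor + cap] if direction == "forward"
              else t[anchor - cap:anchor])
    return region, melting_temperature(region), True


# --------------------------------------------------------------------------
# Mutation specifications and codon edits

@dataclass(frozen=True)
class MutationSpec:
    """One requested mutation: a 1-based amino-acid position plus either
    a target residue (point) or a degenerate codon (saturation)."""

    aa_position: int
    mode: str  # 'point' | 'saturation'
    target: str

    def __post_init__(self) -> None:
        if self.mode not in ("point", "saturation"):
            raise ValidationError(f"unknown mutation mode {self.mode!r}")
        if self.aa_position < 1:
            raise ValidationError("aa_position must be >= 1")
        t = str(self.target).upper()
        if self.mode == "point":
            if t not in SYNONYMS or t == "*":
                raise ValidationError(f"invalid target residue {t!r}")
        else:
            t = str(DegenerateCodon(t))
        object.__setattr__(self, "target", t)


@dataclass(frozen=True)
class CodonEdit:
    """A resolved codon-level change at a 1-based codon index."""

    codon_index: int
    old_codon: str
    new_codon: str  # strict (point / silent fix) or degenerate (saturation)
    mode: str       # 'point' | 'saturation' | 'silent_fix'

    @property
    def nt_start(self) -> int:
        return (self.codon_index - 1) * 3

    @property
    def nt_end(self) -> int:
        return self.codon_index * 3

    @property
    def is_strict(self) -> bool:
        return is_strict(self.new_codon)


def _apply_codon(bases: str, codon_index: int, new_codon: str) -> str:
    i = (codon_index - 1) * 3
    return bases[:i] + new_codon + bases[i + 3:]


def _literal_site_count(bases: str, enzymes) -> int:
    n = 0
    for enz in enzymes:
        for pat in (enz.recognition, enz.recognition_rc):
            start = bases.find(pat)
            while start != -1:
                n += 1
                start = bases.find(pat, start + 1)
    return n


def resolve_edits(
    seq: DnaSequence,
    mutations: "list[MutationSpec]",
    vector: VectorSpec,
    config: DesignConfig,
) -> tuple[list[CodonEdit], str, list[dom.SilentFix]]:
    """Turn mutation specs (plus any required domestication fixes) into
    concrete codon edits and the resulting (possibly degenerate) CDS.

    Point-mutagenesis designs fold domestication into the same pass, as
    silent-fix codon edits carried on the primers. Saturation designs on
    an undomesticated gene are refused unless ``force_undomesticated``:
    the recommended path is to domesticate the template first.
    """
    lo = 1 if config.allow_terminal else 2
    hi = seq.n_codons if config.allow_terminal else seq.n_codons - 1
    positions = [m.aa_position for m in mutations]
    if len(set(positions)) != len(positions):
        raise ValidationError("duplicate mutation positions")
    for m in mutations:
        if not lo <= m.aa_position <= hi:
            raise ValidationError(
                f"position {m.aa_position} outside mutable range [{lo}, {hi}]"
            )

    usage = codon_usage(config.organism)
    enzymes = (BSAI, BBSI)
    sites = dom.scan_sites(seq, enzymes)
    fixes: list[dom.SilentFix] = []
    if sites:
        has_saturation = any(m.mode == "saturation" for m in mutations)
        if has_saturation and not config.force_undomesticated:
            raise DesignError(
                f"{len(sites)} internal BsaI/BbsI site(s) present: "
                "domesticate the template before building a saturation "
                "library (or set force_undomesticated)"
            )
        _, fixes = dom.domesticate(seq, usage, enzymes, config.min_usage)
        fix_positions = {f.codon_index for f in fixes}
        if fix_positions & set(positions):
            raise DesignError(
                "a domestication fix collides with a requested mutation "
                f"codon: {sorted(fix_positions & set(positions))}"
            )

    edits: list[CodonEdit] = [
        CodonEdit(f.codon_index, f.old_codon, f.new_codon, "silent_fix")
        for f in fixes
    ]
    work = seq.bases
    for e in edits:
        work = _apply_codon(work, e.codon_index, e.new_codon)

    # strict (point) edits first, saturation last: the working sequence
    # stays a valid strict CDS while sites are being checked and repaired
    ordered = sorted(mutations, key=lambda m: (m.mode == "saturation",
                                               m.aa_position))
    for m in ordered:
        old = seq.codon(m.aa_position)
        if m.mode == "saturation":
            edits.append(CodonEdit(m.aa_position, old, m.target, "saturation"))
            work = _apply_codon(work, m.aa_position, m.target)
            continue
        # point: pick the closest frequent codon for the target residue
        # that does not recreate an enzyme site in context
        if GENETIC_CODE[old] == m.target:
            logger.warning(
                "position %d already encodes %s; skipping no-op mutation",
                m.aa_position, m.target,
            )
            continue
        cands = sorted(
            SYNONYMS[m.target],
            key=lambda c: (
                sum(a != b for a, b in zip(c, old)),
                -usage.frequency(c),
                c,
            ),
        )
        preferred = [c for c in cands if usage.frequency(c) >= config.min_usage]
        baseline = _literal_site_count(work, enzymes)
        chosen = None
        for c in preferred or cands:
            trial = _apply_codon(work, m.aa_position, c)
            if _literal_site_count(trial, enzymes) <= baseline:
                chosen = c
                work = trial
                break
        if chosen is None:
            # every codon for the target residue forms a site with its
            # context; take the preferred codon and repair the created
            # site with a silent fix on a neighbouring codon
            chosen = (preferred or cands)[0]
            work = _apply_codon(work, m.aa_position, chosen)
            edits.append(CodonEdit(m.aa_position, old, chosen, "point"))
            work, edits = _repair_created_sites(
                seq, work, edits, usage, enzymes, config
            )
            continue
        edits.append(CodonEdit(m.aa_position, old, chosen, "point"))

    edits.sort(key=lambda e: e.codon_index)
    return edits, work, fixes


def _repair_created_sites(
    seq: DnaSequence,
    work: str,
    edits: list[CodonEdit],
    usage,
    enzymes,
    config: DesignConfig,
    max_rounds: int = 10,
) -> tuple[str, list[CodonEdit]]:
    """Remove enzyme sites introduced by a forced point edit.

    A synonymous substitution at the edit codon itself is allowed (the
    target residue is preserved); otherwise the fix lands on a
    neighbouring codon and is recorded as an additional silent edit.
    """
    by_index = {e.codon_index: i for i, e in enumerate(edits)}
    for _ in range(max_rounds):
        hits = dom.scan_sites(work, enzymes)
        if not hits:
            return work, edits
        fix = dom.propose_silent_fix(
            DnaSequence(work, is_cds=True), hits[0], usage, enzymes,
            config.min_usage,
        )
        work = _apply_codon(work, fix.codon_index, fix.new_codon)
        if fix.codon_index in by_index:
            i = by_index[fix.codon_index]
            edits[i] = replace(edits[i], new_codon=fix.new_codon)
        else:
            edits.append(CodonEdit(fix.codon_index, fix.old_codon,
                                   fix.new_codon, "silent_fix"))
            by_index[fix.codon_index] = len(edits) - 1
    raise DesignError("could not repair sites created by a point mutation")


# --------------------------------------------------------------------------
# Clustering

def cluster_mutations(
    positions: "list[int] | list[MutationSpec] | list[CodonEdit]",
    max_cluster_span_nt: int = 45,
) -> list[list]:
    """Greedy left-to-right clustering of mutation positions.

    A mutation joins the open cluster iff the nucleotide span from the
    cluster's first mutated codon to this codon's end stays within
    *max_cluster_span_nt*; each cluster becomes one fragment junction.
    """
    def pos_of(x):
        if isinstance(x, MutationSpec):
            return x.aa_position
        if isinstance(x, CodonEdit):
            return x.codon_index
        return int(x)

    items = sorted(positions, key=pos_of)
    if len({pos_of(x) for x in items}) != len(items):
        raise ValidationError("duplicate mutation positions")
    clusters: list[list] = []
    for x in items:
        p = pos_of(x)
        if clusters and (p - pos_of(clusters[-1][0]) + 1) * 3 <= max_cluster_span_nt:
            clusters[-1].append(x)
        else:
            clusters.append([x])
    return clusters


# --------------------------------------------------------------------------
# Fragment planning

@dataclass(frozen=True)
class Fragment:
    """One PCR fragment of the plan: CDS slice ``[start, end)`` plus the
    overhangs at its two junctions and the edits each primer carries."""

    index: int
    start: int
    end: int
    left_overhang: str
    right_overhang: str
    edits_on_forward: tuple[CodonEdit, ...] = ()
    edits_on_reverse: tuple[CodonEdit, ...] = ()


@dataclass(frozen=True)
class FragmentPlan:
    fragments: tuple[Fragment, ...]
    vector: VectorSpec
    template: DnaSequence
    mutated_cds: str  # template with all edits applied (may be degenerate)
    edits: tuple[CodonEdit, ...]

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)

    def all_overhangs(self) -> list[str]:
        ohs = [self.fragments[0].left_overhang]
        ohs += [f.right_overhang for f in self.fragments]
        return ohs


def _cassette_clean(prefix: str, enzyme: TypeIISEnzyme) -> bool:
    """Exactly one literal occurrence of the enzyme site (the intended
    one) in a primer prefix."""
    return _literal_site_count(prefix, (enzyme,)) == 1


def _select_junction(
    mutated: str,
    cluster: list[CodonEdit],
    used: set[str],
    vector: VectorSpec,
    config: DesignConfig,
    floor: int,
) -> int:
    """Choose the junction position (window end) for one cluster.

    Candidates: for clusters led by a strict (point / silent-fix) edit,
    windows overlapping the mutated codon first (so the altered bases
    themselves direct rejoining), then the generic window immediately 5'
    of the codon with up to ``max_overhang_shift`` nt of further 5'
    shift.
    """
    first = cluster[0]
    c0 = first.nt_start
    candidates: list[int] = []
    if first.is_strict:
        candidates += [c0 + 3, c0 + 2, c0 + 1]
    candidates += [c0 - s for s in range(0, config.max_overhang_shift + 1)]

    pad, enz = config.padding, vector.enzyme
    spacer = config.spacer_fill * enz.spacer_len
    for e in candidates:
        if e - 4 < max(floor, 0):
            continue
        w = mutated[e - 4:e]
        if len(w) != 4 or not is_strict(w) or is_palindromic(w):
            continue
        if w in used or reverse_complement(w) in used:
            continue
        fwd_prefix = pad + enz.recognition + spacer + w + mutated[e:e + 8]
        rev_prefix = (pad + enz.recognition + spacer + reverse_complement(w)
                      + reverse_complement(mutated[max(0, e - 12):e - 4]))
        if not (_cassette_clean(fwd_prefix, enz) and _cassette_clean(rev_prefix, enz)):
            continue
        used.add(w)
        return e
    raise DesignError(
        f"no valid overhang window for the junction at codon "
        f"{first.codon_index}"
    )


def plan_fragments(
    seq: DnaSequence,
    mutations: "list[MutationSpec]",
    vector: VectorSpec,
    config: DesignConfig = DesignConfig(),
) -> FragmentPlan:
    """Split the CDS into fragments at mutation clusters and assign
    junction overhangs. Fragment count = cluster count + 1."""
    edits, mutated, _ = resolve_edits(seq, mutations, vector, config)
    return plan_from_edits(seq, edits, mutated, vector, config)


def plan_from_edits(
    seq: DnaSequence,
    edits: list[CodonEdit],
    mutated: str,
    vector: VectorSpec,
    config: DesignConfig,
) -> FragmentPlan:
    clusters = cluster_mutations(edits, config.max_cluster_span_nt)
    used: set[str] = {vector.five_prime_overhang, vector.three_prime_overhang}

    junctions: list[int] = []
    floor = 0
    for cluster in clusters:
        e = _select_junction(mutated, cluster, used, vector, config, floor)
        junctions.append(e)
        floor = e
    if junctions != sorted(junctions):
        raise DesignError("junctions out of order; clusters too close")

    boundaries = [0] + junctions + [len(seq)]
    for a, b in zip(boundaries, boundaries[1:]):
        if b - a < config.min_fragment_len:
            raise DesignError(
                f"fragment [{a}, {b}) shorter than {config.min_fragment_len} nt;"
                " merge clusters (raise max_cluster_span_nt) or relax"
                " min_fragment_len"
            )

    fragments: list[Fragment] = []
    for i, (a, b) in enumerate(zip(boundaries, boundaries[1:])):
        left = (vector.five_prime_overhang if i == 0 else mutated[a - 4:a])
        right = (vector.three_prime_overhang if i == len(clusters)
                 else mutated[b - 4:b])
        fwd_edits = tuple(clusters[i - 1]) if i > 0 else ()
        rev_edits = ()
        if i < len(clusters):
            nxt = boundaries[i + 1]
            rev_edits = tuple(
                e for e in clusters[i]
                if e.nt_start < nxt and e.nt_end > nxt - 4
            )
        fragments.append(Fragment(i, a, b, left, right, fwd_edits, rev_edits))

    _check_overhang_set([f.left_overhang for f in fragments]
                        + [fragments[-1].right_overhang])
    return FragmentPlan(tuple(fragments), vector, seq, mutated, tuple(edits))


def _check_overhang_set(overhangs: list[str]) -> None:
    if len(set(overhangs)) != len(overhangs):
        raise DesignError(f"duplicate overhangs in plan: {overhangs}")
    for o in overhangs:
        validate_overhang(o)
        if reverse_complement(o) in set(overhangs) - {o}:
            raise DesignError(
                f"overhang {o} is the reverse complement of another overhang"
            )


# --------------------------------------------------------------------------
# Primers

@dataclass(frozen=True)
class Primer:
    """A structured mutagenic oligo.

    ``overhang`` is stored as its sense (+ strand) representation; all
    other segments are written in the primer's own 5'->3' orientation.
    ``binding_span`` is the + strand interval the binding region anneals
    to.
    """

    direction: str  # 'forward' | 'reverse'
    padding: str
    recognition: str
    spacer: str
    overhang: str
    mutagenic_insert: str
    binding: str
    binding_tm: float
    low_tm: bool
    fragment_index: int
    binding_span: tuple[int, int]

    @property
    def overhang_as_written(self) -> str:
        return (self.overhang if self.direction == "forward"
                else reverse_complement(self.overhang))

    @property
    def full_sequence(self) -> str:
        return (self.padding + self.recognition + self.spacer
                + self.overhang_as_written + self.mutagenic_insert
                + self.binding)

    @property
    def name(self) -> str:
        tag = "fwd" if self.direction == "forward" else "rev"
        return f"F{self.fragment_index + 1}_{tag}"


@dataclass(frozen=True)
class DesignResult:
    plan: FragmentPlan
    primers: tuple[tuple[Primer, Primer], ...]  # (forward, reverse) per fragment
    vector: VectorSpec
    workflow: str
    protocol_text: str
    fixes: tuple[dom.SilentFix, ...] = ()

    @property
    def all_primers(self) -> list[Primer]:
        return [p for pair in self.primers for p in pair]

    def primer_table(self) -> pd.DataFrame:
        rows = []
        for p in self.all_primers:
            rows.append({
                "name": p.name,
                "fragment": p.fragment_index + 1,
                "direction": p.direction,
                "padding": p.padding,
                "recognition": p.recognition,
                "spacer": p.spacer,
                "overhang": p.overhang_as_written,
                "mutagenic_insert": p.mutagenic_insert,
                "binding": p.binding,
                "binding_tm_c": round(p.binding_tm, 2),
                "low_tm": p.low_tm,
                "full_sequence_5to3": p.full_sequence,
            })
        return pd.DataFrame(rows)

    def to_report(self) -> dict:
        plan = self.plan
        return {
            "vector": self.vector.name,
            "enzyme": self.vector.enzyme.name,
            "workflow": self.workflow,
            "template": plan.template.bases,
            "mutated_cds": plan.mutated_cds,
            "edits": [
                {
                    "codon_index": e.codon_index,
                    "old_codon": e.old_codon,
                    "new_codon": e.new_codon,
                    "mode": e.mode,
                }
                for e in plan.edits
            ],
            "fragments": [
                {
                    "index": f.index,
                    "start": f.start,
                    "end": f.end,
                    "left_overhang": f.left_overhang,
                    "right_overhang": f.right_overhang,
                }
                for f in plan.fragments
            ],
            "primers": self.primer_table().to_dict(orient="records"),
        }


def _scan_possible_sites(full: str, enzyme: TypeIISEnzyme,
                         intended_at: int) -> list[int]:
    """Positions (excluding *intended_at*) where some expansion of the
    primer could contain the enzyme site, either strand."""
    hits = []
    m = len(enzyme.recognition)
    for i in range(len(full) - m + 1):
        win = full[i:i + m]
        if could_match(win, enzyme.recognition) and i != intended_at:
            hits.append(i)
        if could_match(win, enzyme.recognition_rc):
            hits.append(i)
    return hits


def build_primers(
    plan: FragmentPlan,
    config: DesignConfig = DesignConfig(),
) -> tuple[tuple[Primer, Primer], ...]:
    """Assemble the forward/reverse primer pair for every fragment."""
    seq = plan.template
    mutated = plan.mutated_cds
    vector = plan.vector
    enz = vector.enzyme
    pad = config.padding
    spacer = config.spacer_fill * enz.spacer_len
    n = len(plan.fragments)
    last = n - 1
    pairs: list[tuple[Primer, Primer]] = []

    for frag in plan.fragments:
        # ---- forward primer
        if frag.index == 0:
            oh = vector.five_prime_overhang
            insert = ""
            anchor = 3 if vector.overhang_includes_start else 0
        else:
            oh = frag.left_overhang
            m_end = max((e.nt_end for e in frag.edits_on_forward),
                        default=frag.start)
            insert = mutated[frag.start:m_end] if m_end > frag.start else ""
            anchor = max(frag.start, m_end)
        fbind, ftm, flow = extend_binding(
            seq, anchor, "forward", config.target_tm,
            config.min_binding_len, config.max_binding_len,
        )
        fwd = Primer("forward", pad, enz.recognition, spacer, oh, insert,
                     fbind, ftm, flow, frag.index,
                     (anchor, anchor + len(fbind)))

        # ---- reverse primer
        if frag.index == last:
            oh_r = vector.three_prime_overhang
            bind_end = len(seq)
        else:
            oh_r = frag.right_overhang
            bind_end = frag.end - 4
        rbind_plus, rtm, rlow = extend_binding(
            seq, bind_end, "reverse", config.target_tm,
            config.min_binding_len, config.max_binding_len,
        )
        rev = Primer("reverse", pad, enz.recognition, spacer, oh_r, "",
                     reverse_complement(rbind_plus), rtm, rlow, frag.index,
                     (bind_end - len(rbind_plus), bind_end))

        fwd, rev = _balance_pair(fwd, rev, seq, config)
        for p in (fwd, rev):
            _validate_primer(p, enz, pad)
        pairs.append((fwd, rev))
    return tuple(pairs)


def _balance_pair(fwd: Primer, rev: Primer, seq: DnaSequence,
                  config: DesignConfig) -> tuple[Primer, Primer]:
    """Extend the cooler binding region until the pair Tm difference is
    within tolerance (or extension stops helping)."""
    t = seq.bases
    while abs(fwd.binding_tm - rev.binding_tm) > config.pair_tm_tolerance:
        if fwd.binding_tm < rev.binding_tm:
            a, b = fwd.binding_span
            if b >= len(t) or b - a >= config.max_binding_len:
                break
            nb = t[a:b + 1]
            ntm = melting_temperature(nb)
            if abs(ntm - rev.binding_tm) >= abs(fwd.binding_tm - rev.binding_tm):
                break
            fwd = replace(fwd, binding=nb, binding_tm=ntm, binding_span=(a, b + 1))
        else:
            a, b = rev.binding_span
            if a <= 0 or b - a >= config.max_binding_len:
                break
            nb_plus = t[a - 1:b]
            ntm = melting_temperature(nb_plus)
            if abs(ntm - fwd.binding_tm) >= abs(fwd.binding_tm - rev.binding_tm):
                break
            rev = replace(rev, binding=reverse_complement(nb_plus),
                          binding_tm=ntm, binding_span=(a - 1, b))
    return fwd, rev


def _validate_primer(p: Primer, enzyme: TypeIISEnzyme, padding: str) -> None:
    full = p.full_sequence
    # binding region: no enzyme site on either strand
    if _literal_site_count(p.binding, (enzyme,)) > 0:
        raise DesignError(
            f"{p.name}: binding region contains a {enzyme.name} site; "
            "domesticate the template first"
        )
    # exactly one strict site: the deliberate cassette
    if _literal_site_count(full, (enzyme,)) != 1:
        raise DesignError(
            f"{p.name}: stray {enzyme.name} site in primer {full}"
        )
    possible = _scan_possible_sites(full, enzyme, intended_at=len(padding))
    if possible:
        logger.warning(
            "%s: degenerate expansion could form a %s site at offsets %s; "
            "a fraction of the library may be re-cut",
            p.name, enzyme.name, possible,
        )


# --------------------------------------------------------------------------
# Workflow choice and protocol rendering

def choose_workflow(n_fragments: int) -> str:
    """one_step (direct assembly into the expression vector) for designs
    of three or fewer PCR fragments, else two_step (per-fragment
    subcloning into the level 0 vector, then reassembly)."""
    if n_fragments < 1:
        raise ValidationError("n_fragments must be >= 1")
    return "one_step" if n_fragments <= 3 else "two_step"


def design(
    seq: DnaSequence,
    mutations: "list[MutationSpec]",
    vector: VectorSpec = PAGM22082_CRED,
    config: DesignConfig = DesignConfig(),
) -> DesignResult:
    """End-to-end design: resolve edits (including any domestication
    fixes), plan fragments, build primers, pick a workflow and render the
    bench protocol."""
    edits, mutated, fixes = resolve_edits(seq, mutations, vector, config)
    plan = plan_from_edits(seq, edits, mutated, vector, config)
    primers = build_primers(plan, config)
    workflow = choose_workflow(plan.n_fragments)
    result = DesignResult(plan, primers, vector, workflow, "", tuple(fixes))
    return replace(result, protocol_text=render_protocol(result))


def render_protocol(result: DesignResult) -> str:
    """Deterministic plain-text bench protocol for the design."""
    v = result.vector
    lines: list[str] = []
    w = lines.append
    w("=" * 72)
    w("Golden Gate mutagenesis protocol")
    w("=" * 72)
    w(f"Vector:    {v.name} ({v.enzyme.name}, overhangs "
      f"{v.five_prime_overhang}/{v.three_prime_overhang})")
    w(f"Workflow:  {result.workflow} "
      + ("(direct one-pot assembly; <= 3 fragments)"
         if result.workflow == "one_step"
         else "(subclone each fragment into pAGM9121 with BbsI, then "
              "reassemble into pAGM22082_CRed with BsaI)"))
    w(f"Fragments: {result.plan.n_fragments}   "
      f"Primers: {2 * result.plan.n_fragments}")
    if result.fixes:
        w("")
        w("Domestication fixes folded into the design (silent):")
        for f in result.fixes:
            w(f"  codon {f.codon_index}: {f.old_codon} -> {f.new_codon} "
              f"(usage {f.usage_freq:.2f})")
    w("")
    w("Primers (5'->3')")
    w("-" * 72)
    for p in result.all_primers:
        flag = "  [low-Tm]" if p.low_tm else ""
        w(f"{p.name:10s} Tm(binding) {p.binding_tm:5.1f} C{flag}")
        w(f"  {p.full_sequence}")
    w("")
    w("PCR (per fragment, 50 ul)")
    w("-" * 72)
    w("  100 ng template plasmid; 1x Phusion Green HF buffer; 3% (v/v) DMSO;")
    w("  200 uM dNTPs; 200 nM forward + 200 nM reverse primer;")
    w("  0.5 U Phusion High-Fidelity DNA polymerase.")
    w("  Cycling: 98 C 60 s; 35x [95 C 15 s, 60 C 30 s, 72 C 90 s/kb];")
    w("  72 C 10 min. Gel-check and column-purify the products.")
    w("")
    w("Golden Gate one-pot restriction-ligation (15 ul)")
    w("-" * 72)
    w("  1x T4 ligase buffer; 20 fmol acceptor plasmid; 20 fmol of each")
    enzyme_line = ("BbsI (5 U)" if v.enzyme.name == "BbsI"
                   else "BsaI-HFv2 (10 U)")
    w(f"  fragment; {enzyme_line}; 1-3 U T4 DNA ligase; ddH2O to 15 ul.")
    w("  Cycling: 40x [37 C 2 min, 20 C 5 min]; inactivate 80 C 20 min.")
    w("")
    w("Transformation")
    w("-" * 72)
    if v.name == "pAGM9121":
        w("  Transform the whole 15 ul into an E. coli cloning strain;")
        w("  plate on LB + spectinomycin + X-Gal + IPTG.")
        w("  Blue colonies = unmodified vector (LacZ); white = recombinant.")
        w("  For library fragments, inoculate the remaining transformation")
        w("  volume directly into liquid culture to preserve diversity.")
    else:
        w("  Transform into E. coli BL21(DE3) pLysS; plate on LB +")
        w("  kanamycin + chloramphenicol.")
        w("  Orange colonies = unmodified vector (CRed canthaxanthin")
        w("  operon); white = recombinant expression construct.")
    w("=" * 72)
    return "\n".join(lines) + "\n"


def write_design_report(result: DesignResult, path) -> None:
    with open(str(path), "w") as fh:
        json.dump(result.to_report(), fh, indent=2)


def load_design_report(path) -> dict:
    with open(str(path)) as fh:
        return json.load(fh)
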