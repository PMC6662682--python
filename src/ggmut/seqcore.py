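"""DNA sequence primitives for Golden Gate mutagenesis design.

IUPAC alphabet handling, degenerate codons, translation, relative
synonymous codon-usage tables, type IIS enzyme definitions and 4-nt
overhang arithmetic.

Coordinate conventions used throughout the package: user-facing amino
acid positions are 1-based (as in "D137"); nucleotide coordinates are
0-based, half-open.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from Bio.Seq import Seq
from Bio import SeqIO

from .errors import ValidationError

# --------------------------------------------------------------------------
# IUPAC alphabet

STRICT_BASES = "ACGT"

#: IUPAC nucleotide code -> set of strict bases it stands for
IUPAC_EXPANSION: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

IUPAC_CODES = frozenset(IUPAC_EXPANSION)

#: Watson-Crick complement, including degenerate codes (D<->H, B<->V, ...)
IUPAC_COMPLEMENT: dict[str, str] = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


def _check_iupac(bases: str, *, strict: bool = False) -> None:
    allowed = set(STRICT_BASES) if strict else IUPAC_CODES
    bad = set(bases.upper()) - allowed
    if bad:
        kind = "strict A/C/G/T" if strict else "IUPAC"
        raise ValidationError(
            f"non-{kind} character(s) {sorted(bad)} in sequence"
        )


def is_strict(bases: str) -> bool:
    """True if *bases* contains only A/C/G/T."""
    return set(bases.upper()) <= set(STRICT_BASES)


# --------------------------------------------------------------------------
# Sequence container

STANDARD_STOPS = frozenset({"TAA", "TAG", "TGA"})


@dataclass(frozen=True)
class DnaSequence:
    """A validated DNA string.

    ``is_cds=True`` additionally enforces: length divisible by 3, ATG
    start, a stop codon at the end and no internal in-frame stop.
    """

    bases: str
    description: str = ""
    is_cds: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "bases", self.bases.upper())
        _check_iupac(self.bases)
        if self.is_cds:
            _check_iupac(self.bases, strict=True)
            n = len(self.bases)
            if n == 0 or n % 3:
                raise ValidationError(
                    f"CDS length {n} is not a positive multiple of 3"
                )
            if self.bases[:3] != "ATG":
                raise ValidationError("CDS does not begin with ATG")
            if self.bases[-3:] not in STANDARD_STOPS:
                raise ValidationError("CDS does not end with a stop codon")
            for i in range(0, n - 3, 3):
                if self.bases[i:i + 3] in STANDARD_STOPS:
                    raise ValidationError(
                        f"internal stop codon at codon {i // 3 + 1}"
                    )

    def __len__(self) -> int:
        return len(self.bases)

    def __str__(self) -> str:
        return self.bases

    @property
    def n_codons(self) -> int:
        return len(self.bases) // 3

    def codon(self, index_1based: int) -> str:
        """The codon at 1-based codon index."""
        if not 1 <= index_1based <= self.n_codons:
            raise ValidationError(f"codon index {index_1based} out of range")
        i = (index_1based - 1) * 3
        return self.bases[i:i + 3]


def as_bases(seq: "DnaSequence | str") -> str:
    """Accept either a plain string or a DnaSequence, return the string."""
    s = seq.bases if isinstance(seq, DnaSequence) else str(seq).upper()
    _check_iupac(s)
    return s


def reverse_complement(seq: "DnaSequence | str") -> str:
    """Reverse complement; degenerate codes map to their complement codes
    (e.g. NDT -> AHN)."""
    return str(Seq(as_bases(seq)).reverse_complement())


def translate(seq: "DnaSequence | str") -> str:
    """Standard-genetic-code translation; stops rendered as '*'."""
    s = as_bases(seq)
    _check_iupac(s, strict=True)
    if len(s) % 3:
        raise ValidationError(f"length {len(s)} not divisible by 3")
    return str(Seq(s).translate())


# --------------------------------------------------------------------------
# Degenerate codons

@dataclass(frozen=True)
class DegenerateCodon:
    """A codon written in IUPAC ambiguity codes, e.g. NDT or NNK."""

    symbols: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "symbols", self.symbols.upper())
        if len(self.symbols) != 3:
            raise ValidationError(
                f"degenerate codon must have 3 symbols, got {self.symbols!r}"
            )
        _check_iupac(self.symbols)

    @property
    def cardinality(self) -> int:
        n = 1
        for c in self.symbols:
            n *= len(IUPAC_EXPANSION[c])
        return n

    def __str__(self) -> str:
        return self.symbols


def expand_degenerate_codon(codon: "DegenerateCodon | str") -> set[str]:
    """Full Cartesian expansion of a degenerate codon into strict codons."""
    c = codon if isinstance(codon, DegenerateCodon) else DegenerateCodon(codon)
    pools = [sorted(IUPAC_EXPANSION[s]) for s in c.symbols]
    return {"".join(p) for p in itertools.product(*pools)}


def could_match(iupac_window: str, strict_pattern: str) -> bool:
    """True if some strict expansion of *iupac_window* equals
    *strict_pattern* (both same length)."""
    if len(iupac_window) != len(strict_pattern):
        return False
    return all(
        p in IUPAC_EXPANSION[w] for w, p in zip(iupac_window, strict_pattern)
    )


# --------------------------------------------------------------------------
# Overhangs

def is_palindromic(overhang: str) -> bool:
    """A 4-mer that equals its own reverse complement self-anneals and
    cannot direct an assembly junction."""
    return overhang.upper() == reverse_complement(overhang)


def enumerate_valid_overhangs() -> set[str]:
    """All 4-nt overhangs usable for directional Golden Gate junctions:
    the 256 4-mers minus the 16 palindromic ones (240 total)."""
    return {
        "".join(p)
        for p in itertools.product(STRICT_BASES, repeat=4)
        if not is_palindromic("".join(p))
    }


def validate_overhang(overhang: str) -> str:
    o = overhang.upper()
    _check_iupac(o, strict=True)
    if len(o) != 4:
        raise ValidationError(f"overhang {o!r} is not 4 nt")
    if is_palindromic(o):
        raise ValidationError(f"overhang {o!r} is palindromic")
    return o


# --------------------------------------------------------------------------
# Type IIS enzymes

@dataclass(frozen=True)
class TypeIISEnzyme:
    """A type IIS restriction enzyme cutting outside its (non-palindromic)
    recognition sequence, leaving a 4-nt 5' overhang.

    ``spacer_len`` is the number of nucleotides between the end of the
    recognition sequence and the top-strand cut.
    """

    name: str
    recognition: str
    spacer_len: int
    overhang_len: int = 4

    def __post_init__(self) -> None:
        _check_iupac(self.recognition, strict=True)
        if self.overhang_len != 4:
            raise ValidationError("only 4-nt overhang enzymes are supported")
        if is_palindromic_site(self.recognition):
            raise ValidationError(
                f"{self.name}: recognition site must be non-palindromic"
            )

    @property
    def recognition_rc(self) -> str:
        return reverse_complement(self.recognition)


def is_palindromic_site(site: str) -> bool:
    return site.upper() == reverse_complement(site)


#: REBASE geometry: GGTCTC(N1) -> 4-nt 5' overhang
BSAI = TypeIISEnzyme("BsaI", "GGTCTC", 1)
#: REBASE geometry: GAAGAC(N2) -> 4-nt 5' overhang
BBSI = TypeIISEnzyme("BbsI", "GAAGAC", 2)

ENZYMES: dict[str, TypeIISEnzyme] = {"BsaI": BSAI, "BbsI": BBSI}


# --------------------------------------------------------------------------
# Codon usage

GENETIC_CODE: dict[str, str] = {
    c: translate(c)
    for c in ("".join(p) for p in itertools.product(STRICT_BASES, repeat=3))
}

SYNONYMS: dict[str, tuple[str, ...]] = {
    aa: tuple(sorted(c for c, a in GENETIC_CODE.items() if a == aa))
    for aa in set(GENETIC_CODE.values())
}


@dataclass(frozen=True)
class CodonUsageTable:
    """Relative synonymous codon usage for one organism.

    ``freq[codon]`` is the fraction of that codon among all synonymous
    codons of its amino acid; per amino acid the fractions sum to 1.
    """

    organism: str
    freq: dict[str, float] = field(repr=False)

    def __post_init__(self) -> None:
        # normalise per amino acid so the sum-to-1 invariant holds exactly
        norm: dict[str, float] = {}
        for aa, codons in SYNONYMS.items():
            total = sum(self.freq.get(c, 0.0) for c in codons)
            if total <= 0:
                raise ValidationError(
                    f"{self.organism}: no usage data for amino acid {aa}"
                )
            for c in codons:
                norm[c] = self.freq.get(c, 0.0) / total
        object.__setattr__(self, "freq", norm)

    def synonymous(self, codon: str) -> tuple[str, ...]:
        return SYNONYMS[GENETIC_CODE[codon.upper()]]

    def frequency(self, codon: str) -> float:
        return self.freq[codon.upper()]

    def best_codon(self, amino_acid: str) -> str:
        """Most frequent codon for an amino acid (ties alphabetical)."""
        codons = SYNONYMS[amino_acid.upper()]
        return max(codons, key=lambda c: (self.freq[c], c))


def codon_usage(organism: str) -> CodonUsageTable:
    """Bundled usage table for one of e_coli, s_cerevisiae, a_thaliana."""
    from .data.codon_usage_tables import USAGE_FRACTIONS

    key = organism.lower()
    if key not in USAGE_FRACTIONS:
        raise ValidationError(
            f"unknown organism {organism!r}; choose from "
            f"{sorted(USAGE_FRACTIONS)}"
        )
    return CodonUsageTable(key, dict(USAGE_FRACTIONS[key]))


# --------------------------------------------------------------------------
# FASTA input

def read_cds_fasta(path, record_id: str | None = None) -> DnaSequence:
    """Read a single-record FASTA file as a CDS.

    Multi-record input is an error unless *record_id* selects one record.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValidationError(f"{path}: no FASTA records")
    if record_id is not None:
        matches = [r for r in records if r.id == record_id]
        if not matches:
            raise ValidationError(f"{path}: no record with id {record_id!r}")
        rec = matches[0]
    elif len(records) > 1:
        raise ValidationError(
            f"{path}: {len(records)} records; specify a record id"
        )
    else:
        rec = records[0]
    return DnaSequence(str(rec.seq), description=rec.description, is_cds=True)
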