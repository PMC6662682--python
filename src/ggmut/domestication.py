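"""Removal of internal type IIS recognition sites from a CDS.

Golden Gate cloning requires the gene itself to be free of the assembly
enzyme's recognition sites; otherwise the one-pot reaction cuts inside
the insert. "Domestication" detects internal BsaI/BbsI sites on either
strand and removes each with a silent (synonymous) single-codon
substitution, preferring frequent codons in the chosen host organism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import pandas as pd

from .errors import UndomesticatableSiteError, ValidationError
from .seqcore import (
    BBSI,
    BSAI,
    CodonUsageTable,
    DnaSequence,
    TypeIISEnzyme,
    as_bases,
)

DEFAULT_ENZYMES: tuple[TypeIISEnzyme, ...] = (BSAI, BBSI)

#: synonymous codons rarer than this fraction are never proposed
DEFAULT_MIN_USAGE = 0.05


@dataclass(frozen=True)
class SiteHit:
    """One occurrence of a recognition sequence inside a sequence.

    ``start`` is the 0-based offset of the site on the + strand (for
    strand '-', of the reverse complement of the recognition sequence).
    ``overlapped_codons`` are the 1-based codon indices intersecting the
    site.
    """

    enzyme: TypeIISEnzyme
    strand: str  # '+' or '-'
    start: int
    overlapped_codons: tuple[int, ...]

    @property
    def end(self) -> int:
        return self.start + len(self.enzyme.recognition)


@dataclass(frozen=True)
class SilentFix:
    """A synonymous single-codon substitution that removes a site."""

    codon_index: int  # 1-based
    old_codon: str
    new_codon: str
    usage_freq: float


def _overlapped_codons(start: int, end: int, seq_len: int) -> tuple[int, ...]:
    first = start // 3
    last = (end - 1) // 3
    last = min(last, seq_len // 3 - 1)
    return tuple(range(first + 1, last + 2))


def scan_sites(
    seq: "DnaSequence | str",
    enzymes: "tuple[TypeIISEnzyme, ...] | list[TypeIISEnzyme]" = DEFAULT_ENZYMES,
) -> list[SiteHit]:
    """Every occurrence of each enzyme's recognition sequence, both
    strands, sorted by + strand start. Overlapping occurrences are all
    reported."""
    s = as_bases(seq)
    hits: list[SiteHit] = []
    for enz in enzymes:
        for strand, pattern in (("+", enz.recognition), ("-", enz.recognition_rc)):
            start = s.find(pattern)
            while start != -1:
                end = start + len(pattern)
                hits.append(
                    SiteHit(enz, strand, start, _overlapped_codons(start, end, len(s)))
                )
                start = s.find(pattern, start + 1)
    hits.sort(key=lambda h: (h.start, h.enzyme.name, h.strand))
    return hits


def _apply_codon(bases: str, codon_index: int, new_codon: str) -> str:
    i = (codon_index - 1) * 3
    return bases[:i] + new_codon + bases[i + 3:]


def propose_silent_fix(
    seq: DnaSequence,
    hit: SiteHit,
    usage: CodonUsageTable,
    enzymes: tuple[TypeIISEnzyme, ...] = DEFAULT_ENZYMES,
    min_usage: float = DEFAULT_MIN_USAGE,
) -> SilentFix:
    """The best synonymous single-codon substitution that destroys *hit*
    and creates no new recognition site of any enzyme on either strand.

    "Best" = maximal relative usage of the new codon (codons rarer than
    *min_usage* are rejected); ties broken by smallest codon index, then
    alphabetically.
    """
    if not seq.is_cds:
        raise ValidationError("silent fixes require a CDS")
    bases = seq.bases
    if hit.end > len(bases):
        raise ValidationError("site does not lie fully inside the CDS")

    before = len(scan_sites(bases, enzymes))
    candidates: list[tuple[float, int, str, str]] = []
    for ci in hit.overlapped_codons:
        if not 1 <= ci <= seq.n_codons:
            continue
        old = seq.codon(ci)
        for new in usage.synonymous(old):
            if new == old or usage.frequency(new) < min_usage:
                continue
            edited = _apply_codon(bases, ci, new)
            hits_after = scan_sites(edited, enzymes)
            if len(hits_after) >= before:
                continue  # site not destroyed, or a new one created
            if any(h.start == hit.start and h.strand == hit.strand
                   and h.enzyme.name == hit.enzyme.name for h in hits_after):
                continue
            candidates.append((usage.frequency(new), ci, new, old))

    if not candidates:
        raise UndomesticatableSiteError(
            f"undomesticatable site: {hit.enzyme.name} ({hit.strand}) at "
            f"nt {hit.start}, codons {hit.overlapped_codons}"
        )
    freq, ci, new, old = max(
        candidates, key=lambda t: (t[0], -t[1], [-ord(c) for c in t[2]])
    )
    return SilentFix(ci, old, new, freq)


def domesticate(
    seq: DnaSequence,
    usage: CodonUsageTable,
    enzymes: tuple[TypeIISEnzyme, ...] = DEFAULT_ENZYMES,
    min_usage: float = DEFAULT_MIN_USAGE,
    max_rounds: int = 100,
) -> tuple[DnaSequence, list[SilentFix]]:
    """Iteratively remove every internal recognition site.

    Returns the domesticated CDS and the applied fixes. The encoded
    protein is unchanged (fixes are synonymous by construction).
    """
    current = seq
    fixes: list[SilentFix] = []
    for _ in range(max_rounds):
        hits = scan_sites(current, enzymes)
        if not hits:
            return current, fixes
        fix = propose_silent_fix(current, hits[0], usage, enzymes, min_usage)
        current = DnaSequence(
            _apply_codon(current.bases, fix.codon_index, fix.new_codon),
            description=seq.description,
            is_cds=True,
        )
        fixes.append(fix)
    raise UndomesticatableSiteError(
        f"domestication did not converge within {max_rounds} rounds"
    )


# --------------------------------------------------------------------------
# Report writer

def fixes_table(fixes: list[SilentFix]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "codon_index": f.codon_index,
                "old_codon": f.old_codon,
                "new_codon": f.new_codon,
                "usage_freq": round(f.usage_freq, 4),
            }
            for f in fixes
        ],
        columns=["codon_index", "old_codon", "new_codon", "usage_freq"],
    )


def write_fixes_report(fixes: list[SilentFix], path) -> None:
    """Write the fixes table as CSV or JSON depending on the suffix."""
    df = fixes_table(fixes)
    path = str(path)
    if path.endswith(".json"):
        with open(path, "w") as fh:
            json.dump(df.to_dict(orient="records"), fh, indent=2)
    else:
        df.to_csv(path, index=False)
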