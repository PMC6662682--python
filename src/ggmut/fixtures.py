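"""Synthetic data generators.

Everything the test- and QQC pipelines need can be generated
deterministically: random CDSs (uniform sense codons), CDSs with planted
type IIS recognition sites, worked designs with the positional geometry
of representative case studies, and minimal-but-valid ABIF chromatogram
files for pooled-library traces with known channel mixtures.

All generators are seeded; the same seed gives byte-identical output.
"""

from __future__ import annotations

import random
import struct
from dataclasses import dataclass

import numpy as np

from .domestication import DEFAULT_ENZYMES, scan_sites
from .errors import ValidationError
from .seqcore import (
    DegenerateCodon,
    DnaSequence,
    GENETIC_CODE,
    STANDARD_STOPS,
    expand_degenerate_codon,
)

SENSE_CODONS = tuple(sorted(c for c, aa in GENETIC_CODE.items() if aa != "*"))


# --------------------------------------------------------------------------
# CDS generators

def random_cds(
    n_codons: int,
    seed: "int | random.Random" = 0,
    site_free: bool = True,
    description: str = "synthetic CDS",
) -> DnaSequence:
    """A random in-frame CDS: ATG, ``n_codons - 2`` uniform sense codons,
    TAA. With ``site_free`` the sequence is resampled until it contains
    no BsaI/BbsI site on either strand."""
    if n_codons < 4:
        raise ValidationError("need at least 4 codons")
    rng = seed if isinstance(seed, random.Random) else random.Random(seed)
    for _ in range(1000):
        body = "".join(rng.choice(SENSE_CODONS) for _ in range(n_codons - 2))
        bases = "ATG" + body + "TAA"
        if not site_free or not scan_sites(bases, DEFAULT_ENZYMES):
            return DnaSequence(bases, description=description, is_cds=True)
    raise RuntimeError("could not generate a site-free CDS")


def plant_sites(
    cds: DnaSequence,
    placements: "list[tuple[int, str, str]]",
) -> DnaSequence:
    """Overwrite codon-aligned positions with enzyme recognition sites.

    *placements* are ``(codon_index, enzyme_name, strand)`` tuples; the
    6-nt recognition sequence (or its reverse complement for '-')
    replaces codons ``codon_index`` and ``codon_index + 1``. Raises if
    the result does not contain exactly the requested sites, if a stop
    codon would be created in frame, or if the CDS constraints break.
    """
    from .seqcore import ENZYMES

    bases = cds.bases
    for codon_index, enzyme_name, strand in placements:
        enz = ENZYMES[enzyme_name]
        site = enz.recognition if strand == "+" else enz.recognition_rc
        i = (codon_index - 1) * 3
        if i < 3 or i + 6 > len(bases) - 3:
            raise ValidationError("placement overlaps start/stop codon")
        if site[:3] in STANDARD_STOPS or site[3:] in STANDARD_STOPS:
            raise ValidationError("site would introduce a stop codon")
        bases = bases[:i] + site + bases[i + 6:]
    planted = DnaSequence(bases, description=cds.description, is_cds=True)
    if len(scan_sites(planted, DEFAULT_ENZYMES)) != len(placements):
        raise ValidationError(
            "planting created extra or overlapping recognition sites; "
            "use a different base CDS or positions"
        )
    return planted


def planted_site_cds(
    n_codons: int = 200,
    n_sites: int = 2,
    seed: int = 0,
) -> tuple[DnaSequence, list[tuple[int, str, str]]]:
    """A random CDS carrying *n_sites* planted BsaI/BbsI sites at
    well-separated codon-aligned positions (both strands used)."""
    rng = random.Random(seed)
    for _ in range(200):
        base = random_cds(n_codons, rng)
        lo, hi = 3, n_codons - 3
        span = (hi - lo) // max(n_sites, 1)
        if span < 4:
            raise ValidationError("too many sites for this CDS length")
        placements = []
        for k in range(n_sites):
            pos = lo + k * span + rng.randrange(max(1, span - 3))
            enzyme = rng.choice(["BsaI", "BbsI"])
            strand = rng.choice(["+", "-"])
            placements.append((pos, enzyme, strand))
        try:
            return plant_sites(base, placements), placements
        except ValidationError:
            continue
    raise RuntimeError("could not construct a planted-site fixture")


def point_case_cds(seed: int = 11) -> DnaSequence:
    """Synthetic stand-in for a classic single point-mutagenesis
    scenario (mCherry-style L69V): a 237-codon CDS (711 nt) with a
    leucine codon at position 69 and one internal BbsI site around
    codon 150.

    This is synthetic data, not the real mCherry gene: the external
    sequence is not bundled, only its design-relevant geometry.
    """
    rng = random.Random(seed)
    for _ in range(200):
        cds = random_cds(237, rng, description="synthetic point-case CDS")
        bases = cds.bases[:204] + "CTG" + cds.bases[207:]  # Leu at codon 69
        try:
            cds = DnaSequence(bases, description=cds.description, is_cds=True)
            if scan_sites(cds, DEFAULT_ENZYMES):
                continue
            return plant_sites(cds, [(150, "BbsI", "+")])
        except ValidationError:
            continue
    raise RuntimeError("could not construct the point-case fixture")


def saturation_case_cds(seed: int = 5) -> DnaSequence:
    """Synthetic stand-in for a classic multi-site saturation scenario
    (YfeX-style): a 300-codon, site-free CDS suitable for NDT
    randomization at positions {137, 143, 147, 232, 234}."""
    return random_cds(300, seed, description="synthetic saturation-case CDS")


SATURATION_CASE_POSITIONS = (137, 143, 147, 232, 234)


# --------------------------------------------------------------------------
# ABIF chromatogram fixtures

#: filter-wheel order used in the generated files: DATA9..12 are G,A,T,C
FWO_ORDER = "GATC"
_BASE_COLUMNS = "ACGT"  # in-memory channel column order

_SCANS_PER_CALL = 12
_PEAK_OFFSET = 6
_PEAK_HEIGHT = 1000.0


def codon_base_weights(codon: "DegenerateCodon | str") -> np.ndarray:
    """Per-offset marginal base fractions (3 x ACGT) over the uniform
    expansion of a degenerate codon (e.g. NDT offset 2 -> A,G,T each
    1/3)."""
    expansion = sorted(expand_degenerate_codon(codon))
    w = np.zeros((3, 4))
    for strict in expansion:
        for k, b in enumerate(strict):
            w[k, _BASE_COLUMNS.index(b)] += 1.0
    return w / len(expansion)


@dataclass(frozen=True)
class SyntheticTrace:
    """Ideal per-call channel intensities (n x 4, ACGT columns) plus the
    primary basecalls; the ground truth behind a generated ABIF file."""

    channels: np.ndarray
    basecalls: str


def pooled_trace(
    reference: "DnaSequence | str",
    randomized: "dict[int, DegenerateCodon | str]",
    noise_sigma: float = 0.1,
    seed: int = 42,
    direction: str = "forward",
) -> SyntheticTrace:
    """Per-call channel intensities of a pooled-library Sanger trace.

    Non-randomized positions carry the reference base; randomized codon
    positions carry the degenerate codon's marginal base mixture.
    Multiplicative log-normal noise (sigma in log space) models peak
    height variability. ``direction='reverse'`` returns the reverse-
    complement read of the same molecules.
    """
    ref = str(reference)
    n = len(ref)
    rng = np.random.default_rng(seed)
    ideal = np.zeros((n, 4))
    for i, b in enumerate(ref):
        if b in _BASE_COLUMNS:
            ideal[i, _BASE_COLUMNS.index(b)] = 1.0
        else:  # degenerate reference base: uniform over its expansion
            from .seqcore import IUPAC_EXPANSION
            for s in IUPAC_EXPANSION[b]:
                ideal[i, _BASE_COLUMNS.index(s)] = 1.0
            ideal[i] /= ideal[i].sum()
    # pooled randomized codons: sum of per-variant ideal traces, each
    # variant weighted by a multiplicative log-normal factor (unequal
    # variant representation, e.g. bias in the ordered primer mixture)
    for codon_index, codon in sorted(randomized.items()):
        variants = sorted(expand_degenerate_codon(codon))
        weights = np.ones(len(variants))
        if noise_sigma > 0:
            weights = np.exp(rng.normal(0.0, noise_sigma, size=len(variants)))
        weights /= weights.sum()
        block = np.zeros((3, 4))
        for w, strict in zip(weights, variants):
            for k, b in enumerate(strict):
                block[k, _BASE_COLUMNS.index(b)] += w
        ideal[(codon_index - 1) * 3:(codon_index - 1) * 3 + 3] = block

    if direction == "reverse":
        # reverse the call order and swap complementary channels
        ideal = ideal[::-1][:, [3, 2, 1, 0]]  # A<->T, C<->G
    elif direction != "forward":
        raise ValidationError(f"direction must be forward/reverse: {direction!r}")

    channels = ideal * _PEAK_HEIGHT
    if noise_sigma > 0:
        # per-peak amplitude variability (scales all four channels of a
        # call together, so it perturbs heights but not proportions)
        channels = channels * np.exp(
            rng.normal(0.0, noise_sigma, size=(n, 1))
        )
    calls = "".join(_BASE_COLUMNS[int(np.argmax(row))] for row in channels)
    return SyntheticTrace(channels, calls)


# ---- minimal ABIF v1.01 writer -------------------------------------------

_DIR_STRUCT = struct.Struct(">4sihhiiii")  # name, number, etype, esize, n, size, offset, handle
_HEADER_SIZE = 128


def _entry(name: bytes, number: int, etype: int, esize: int,
           nelem: int, data: bytes) -> tuple[bytes, int, int, int, int, bytes]:
    return (name, number, etype, esize, nelem, data)


def write_abif(path, trace: SyntheticTrace) -> None:
    """Write a minimal, valid ABIF v1.01 chromatogram file.

    Contains the analyzed-trace arrays DATA9-12 (scan intensities, one
    Gaussian-free peak per call), primary basecalls PBAS1/2, peak scan
    locations PLOC1/2 and the filter-wheel order FWO_1.
    """
    n = len(trace.basecalls)
    n_scans = n * _SCANS_PER_CALL
    ploc = [_PEAK_OFFSET + _SCANS_PER_CALL * i for i in range(n)]

    # scan-level traces: intensity at the peak scan, zero elsewhere
    data_by_base: dict[str, np.ndarray] = {}
    for col, base in enumerate(_BASE_COLUMNS):
        arr = np.zeros(n_scans, dtype=">i2")
        vals = np.clip(np.round(trace.channels[:, col]), 0, 32000).astype(">i2")
        arr[np.asarray(ploc)] = vals
        data_by_base[base] = arr

    entries: list[tuple] = []
    for k, base in enumerate(FWO_ORDER):  # DATA9..DATA12 follow FWO_ order
        entries.append(_entry(b"DATA", 9 + k, 4, 2, n_scans,
                              data_by_base[base].tobytes()))
    pbas = trace.basecalls.encode("ascii")
    ploc_bytes = np.asarray(ploc, dtype=">i2").tobytes()
    pcon = bytes([40] * n)  # flat confidence; not used by the reader
    for number in (1, 2):
        entries.append(_entry(b"PBAS", number, 2, 1, n, pbas))
        entries.append(_entry(b"PLOC", number, 4, 2, n, ploc_bytes))
        entries.append(_entry(b"PCON", number, 2, 1, n, pcon))
    entries.append(_entry(b"FWO_", 1, 2, 1, 4, FWO_ORDER.encode("ascii")))

    blob = bytearray()
    directory = bytearray()
    base_offset = _HEADER_SIZE
    for name, number, etype, esize, nelem, data in entries:
        size = len(data)
        if size <= 4:
            offset_field = int.from_bytes(data.ljust(4, b"\0"), "big")
        else:
            offset_field = base_offset + len(blob)
            blob += data
        directory += _DIR_STRUCT.pack(name, number, etype, esize, nelem,
                                      size, offset_field, 0)

    dir_offset = base_offset + len(blob)
    header = bytearray(_HEADER_SIZE)
    header[0:4] = b"ABIF"
    struct.pack_into(">h", header, 4, 101)
    _DIR_STRUCT.pack_into(header, 6, b"tdir", 1, 1023, 28, len(entries),
                          len(entries) * 28, dir_offset, 0)
    with open(str(path), "wb") as fh:
        fh.write(bytes(header))
        fh.write(bytes(blob))
        fh.write(bytes(directory))
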