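"""Quick Quality Control of pooled-library Sanger chromatograms.

After building a saturation library, the pooled plasmid prep is Sanger
sequenced once; at each randomized codon the four fluorescence channels
mix in proportion to the base composition of the pool. This module reads
ABIF (".ab1") chromatograms, locates the randomized codons against the
reference design, extracts per-position A/C/G/T proportions, scores them
against the expected degeneracy (total-variation distance to the uniform
distribution over allowed bases) and renders the classic pie-chart
panel.

Peak quantification uses the analyzed-trace intensity at the called peak
scan (the PLOC tag), not peak-area integration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from Bio import SeqIO

from .errors import QqcError, ValidationError
from .primerdesign import DesignResult
from .seqcore import IUPAC_EXPANSION, DegenerateCodon, as_bases, is_strict, \
    reverse_complement

BASES = "ACGT"

#: pie-chart colors: adenine red, cytosine orange, guanine green,
#: thymine blue
BASE_COLORS = {"A": "#d62728", "C": "#ff7f0e", "G": "#2ca02c", "T": "#1f77b4"}


# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ChromatogramTrace:
    """Per-base-call channel intensities (n x 4, columns A/C/G/T, sampled
    at each call's peak scan), the primary basecalls and the peak scan
    locations."""

    channels: np.ndarray
    basecalls: str
    peak_locations: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.channels) == len(self.basecalls)
                == len(self.peak_locations)):
            raise ValidationError(
                "channels, basecalls and peak_locations must align"
            )
        if np.any(self.channels < 0):
            raise ValidationError("negative channel intensity")

    def __len__(self) -> int:
        return len(self.basecalls)


@dataclass(frozen=True)
class BaseDistribution:
    """Proportions of A/C/G/T at one randomized position (1-based codon
    index, offset 1-3 within the codon)."""

    codon_index: int
    offset: int
    proportions: tuple[float, float, float, float]  # A, C, G, T

    def __post_init__(self) -> None:
        p = self.proportions
        if abs(sum(p) - 1.0) > 1e-6 or min(p) < 0 or max(p) > 1:
            raise ValidationError("proportions must lie on the simplex")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(BASES, self.proportions))


# --------------------------------------------------------------------------

def read_abif(path) -> ChromatogramTrace:
    """Read an ABIF v1.01 chromatogram.

    Uses the analyzed-trace tags DATA9-12 (channel order from the
    filter-wheel tag FWO_), basecalls PBAS and peak locations PLOC;
    channel intensities are sampled at each call's peak scan.
    """
    try:
        record = SeqIO.read(str(path), "abi")
    except Exception as err:  # Biopython raises a mix of OSError/ValueError/struct.error
        raise QqcError(f"{path}: not an ABIF chromatogram ({err})") from err
    raw = record.annotations.get("abif_raw", {})
    try:
        fwo = raw["FWO_1"]
        fwo = fwo.decode("ascii") if isinstance(fwo, bytes) else str(fwo)
        data = {fwo[k]: np.asarray(raw[f"DATA{9 + k}"], dtype=float)
                for k in range(4)}
        pbas = raw.get("PBAS1", raw.get("PBAS2"))
        basecalls = (pbas.decode("ascii")
                     if isinstance(pbas, bytes) else str(pbas))
        ploc = np.asarray(raw.get("PLOC1", raw.get("PLOC2")), dtype=int)
    except (KeyError, TypeError) as err:
        raise QqcError(
            f"{path}: not an ABIF chromatogram (missing tag {err})"
        ) from err
    if basecalls is None or ploc is None:
        raise QqcError(f"{path}: not an ABIF chromatogram (no basecalls)")
    n_scans = min(len(v) for v in data.values())
    if len(ploc) != len(basecalls) or (len(ploc) and ploc.max() >= n_scans):
        raise QqcError(f"{path}: trace arrays inconsistent with basecalls")
    channels = np.column_stack([data[b][ploc] for b in BASES])
    return ChromatogramTrace(channels, basecalls, ploc)


# --------------------------------------------------------------------------

def _saturation_codons(design: "DesignResult | dict") -> dict[int, str]:
    """codon index -> degenerate codon symbols, from a design result or
    a loaded design-report dict."""
    if isinstance(design, DesignResult):
        edits = [
            (e.codon_index, e.new_codon)
            for e in design.plan.edits
            if not is_strict(e.new_codon)
        ]
    else:
        edits = [
            (e["codon_index"], e["new_codon"])
            for e in design["edits"]
            if not is_strict(e["new_codon"])
        ]
    return dict(edits)


def _mask_reference(ref: str, randomized: dict[int, str]) -> list[tuple[int, str]]:
    """Maximal reference segments that avoid the randomized codons, as
    (ref_start, segment) pairs."""
    blocked = np.zeros(len(ref), dtype=bool)
    for ci in randomized:
        blocked[(ci - 1) * 3: ci * 3] = True
    segments = []
    i = 0
    while i < len(ref):
        if blocked[i]:
            i += 1
            continue
        j = i
        while j < len(ref) and not blocked[j]:
            j += 1
        segments.append((i, ref[i:j]))
        i = j
    return segments


def locate_randomized_positions(
    trace: ChromatogramTrace,
    reference: "str | object",
    design: "DesignResult | dict",
    read_direction: str = "forward",
) -> dict[int, tuple[int, int, int]]:
    """Map each designed saturation codon to its three positions in the
    trace.

    The read is anchored to the reference by the longest exact match
    outside the randomized codons (>= 20 nt) and extended ungapped; the
    anchored alignment must reach >= 80% identity over >= 60 nt.
    Reverse reads are mapped through reverse-complement coordinates.
    """
    ref = as_bases(reference)
    randomized = _saturation_codons(design)
    if read_direction == "forward":
        read = trace.basecalls
    elif read_direction == "reverse":
        read = reverse_complement(trace.basecalls)
    else:
        raise ValidationError(f"read_direction must be forward/reverse")

    best: tuple[int, int, int] | None = None  # (len, ref_start, read_start)
    for ref_start, segment in _mask_reference(ref, randomized):
        # longest prefix-anchored exact occurrence of this segment
        lo, hi = 20, len(segment)
        found = None
        probe = segment[:hi]
        idx = read.find(probe)
        if idx != -1:
            found = (hi, ref_start, idx)
        else:
            # binary search the longest matching prefix of the segment
            while lo <= hi:
                mid = (lo + hi) // 2
                idx = read.find(segment[:mid])
                if idx != -1:
                    found = (mid, ref_start, idx)
                    lo = mid + 1
                else:
                    hi = mid - 1
        if found and (best is None or found[0] > best[0]):
            best = found
    if best is None or best[0] < 20:
        raise QqcError("read does not match reference (no anchor >= 20 nt)")

    _, ref_start, read_start = best
    offset = read_start - ref_start  # read index = ref index + offset
    ov_lo = max(0, -offset)
    ov_hi = min(len(ref), len(read) - offset)
    overlap = ov_hi - ov_lo
    matches = sum(
        1 for i in range(ov_lo, ov_hi)
        if read[i + offset] == ref[i] or (i // 3 + 1) in randomized
    )
    if overlap < 60 or matches / max(overlap, 1) < 0.80:
        raise QqcError(
            f"read does not match reference "
            f"({matches}/{overlap} identities over the anchored overlap)"
        )

    out: dict[int, tuple[int, int, int]] = {}
    for ci in sorted(randomized):
        idxs = []
        for k in range(3):
            ref_pos = (ci - 1) * 3 + k
            aligned = ref_pos + offset
            if not 0 <= aligned < len(read):
                raise QqcError(
                    f"randomized codon {ci} not covered by the read"
                )
            if read_direction == "reverse":
                idxs.append(len(read) - 1 - aligned)
            else:
                idxs.append(aligned)
        out[ci] = tuple(idxs)
    return out


# --------------------------------------------------------------------------

def extract_distributions(
    trace: ChromatogramTrace,
    positions: dict[int, tuple[int, int, int]],
    read_direction: str = "forward",
) -> list[BaseDistribution]:
    """Per-position base proportions: channel intensity at the called
    peak over the four-channel sum. For reverse reads the base labels
    are complemented so proportions refer to the sense strand."""
    out: list[BaseDistribution] = []
    for ci in sorted(positions):
        for k, tpos in enumerate(positions[ci], start=1):
            inten = trace.channels[tpos]
            total = float(inten.sum())
            if total <= 0:
                raise QqcError(
                    f"dead peak at trace position {tpos} "
                    f"(codon {ci}, offset {k})"
                )
            props = {b: float(v) / total for b, v in zip(BASES, inten)}
            if read_direction == "reverse":
                props = {b: props[reverse_complement(b)] for b in BASES}
            out.append(BaseDistribution(ci, k, tuple(props[b] for b in BASES)))
    return out


def compare_to_degeneracy(
    dist: BaseDistribution,
    codon: "DegenerateCodon | str",
) -> float:
    """Total-variation distance between the observed proportions and the
    uniform distribution over the bases the degenerate codon allows at
    this offset (disallowed bases expected at 0). Ranges over [0, 1]."""
    symbols = str(DegenerateCodon(str(codon)))
    allowed = IUPAC_EXPANSION[symbols[dist.offset - 1]]
    expected = {b: (1.0 / len(allowed) if b in allowed else 0.0)
                for b in BASES}
    obs = dist.as_dict()
    return 0.5 * sum(abs(obs[b] - expected[b]) for b in BASES)


# --------------------------------------------------------------------------

def qqc_table(
    distributions: list[BaseDistribution],
    randomized: dict[int, str],
) -> pd.DataFrame:
    """Tidy table of proportions and divergence scores per randomized
    position."""
    rows = []
    for d in distributions:
        rows.append({
            "codon_index": d.codon_index,
            "offset": d.offset,
            **{b: round(p, 4) for b, p in d.as_dict().items()},
            "tv_score": round(
                compare_to_degeneracy(d, randomized[d.codon_index]), 4
            ),
        })
    return pd.DataFrame(
        rows, columns=["codon_index", "offset", *BASES, "tv_score"]
    )


def render_qqc_report(
    distributions: list[BaseDistribution],
    randomized: dict[int, str],
    figure_path=None,
    table_path=None,
    group_by_codon: bool = True,
):
    """Pie-chart panel (one pie per randomized position) plus the CSV
    table. Returns (figure, table)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if not distributions:
        raise ValidationError("no distributions to render")
    table = qqc_table(distributions, randomized)

    codons = sorted({d.codon_index for d in distributions})
    nrows, ncols = (len(codons), 3) if group_by_codon else (1, len(distributions))
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(2.2 * ncols, 2.2 * nrows), squeeze=False
    )
    by_key = {(d.codon_index, d.offset): d for d in distributions}
    for r, ci in enumerate(codons):
        for k in range(1, 4):
            ax = axes[r][k - 1] if group_by_codon else axes[0][3 * r + k - 1]
            d = by_key.get((ci, k))
            if d is None:
                ax.axis("off")
                continue
            vals = [d.as_dict()[b] for b in BASES]
            ax.pie(
                vals,
                colors=[BASE_COLORS[b] for b in BASES],
                labels=[b if v > 0.02 else "" for b, v in zip(BASES, vals)],
                normalize=True,
                startangle=90,
                counterclock=False,
            )
            ax.set_title(f"codon {ci}.{k} ({randomized[ci]})", fontsize=8)
    fig.tight_layout()
    if figure_path is not None:
        fig.savefig(str(figure_path), dpi=150, metadata={"Software": None})
    if table_path is not None:
        table.to_csv(str(table_path), index=False)
    return fig, table


def analyze(
    ab1_path,
    reference: "str | object",
    design: "DesignResult | dict",
    read_direction: str = "forward",
) -> tuple[list[BaseDistribution], pd.DataFrame]:
    """Full QQC path: read the chromatogram, locate the randomized
    codons, extract distributions and score them."""
    trace = read_abif(ab1_path)
    positions = locate_randomized_positions(
        trace, reference, design, read_direction
    )
    dists = extract_distributions(trace, positions, read_direction)
    randomized = _saturation_codons(design)
    return dists, qqc_table(dists, randomized)
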