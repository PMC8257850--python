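"""IUPAC degenerate-motif scanning over peak sequences.

The m6A consensus motifs RRACH (R = A/G, H = A/C/U) and URUAY (Y = C/U) are
RNA motifs; they are normalized to DNA space (U -> T) at parse time and all
scanning happens on DNA.  Sequence ``N`` bases never match any pattern
symbol (including pattern ``N``).
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .genomic_io import GenomeSequence, MalformedRecordError

IUPAC_CODES: Dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class DegenerateMotif:
    """A named IUPAC pattern, stored DNA-normalized (U -> T, uppercase)."""

    name: str
    pattern: str

    def __post_init__(self):
        norm = self.pattern.upper().replace("U", "T")
        for i, sym in enumerate(norm):
            if sym not in IUPAC_CODES:
                raise MalformedRecordError(
                    f"motif {self.name!r}: invalid IUPAC symbol {sym!r} "
                    f"at position {i}"
                )
        object.__setattr__(self, "pattern", norm)

    def __len__(self) -> int:
        return len(self.pattern)


RRACH = DegenerateMotif("RRACH", "RRACH")
URUAY = DegenerateMotif("URUAY", "URUAY")


def expand_iupac(motif) -> frozenset:
    """Cartesian expansion of an IUPAC pattern into concrete DNA k-mers."""
    if not isinstance(motif, DegenerateMotif):
        motif = DegenerateMotif(str(motif), str(motif))
    choices = [IUPAC_CODES[sym] for sym in motif.pattern]
    return frozenset("".join(kmer) for kmer in itertools.product(*choices))


def _compiled(motif: DegenerateMotif) -> re.Pattern:
    # lookahead so overlapping hits are all reported
    body = "".join(
        c if len(IUPAC_CODES[c]) == 1 else f"[{IUPAC_CODES[c]}]"
        for c in motif.pattern
    )
    return re.compile(f"(?=({body}))")


def scan_sequence(
    seq: str, motif: DegenerateMotif, both_strands: bool = False
) -> List[Tuple[int, str]]:
    """All (possibly overlapping) motif hit start positions in ``seq``.

    Returns ``(position, strand)`` pairs; positions are always given on the
    forward coordinates of ``seq`` (the start of the matched window).
    """
    if not isinstance(motif, DegenerateMotif):
        motif = DegenerateMotif(str(motif), str(motif))
    seq = seq.upper()
    rx = _compiled(motif)
    hits = [(m.start(), "+") for m in rx.finditer(seq)]
    if both_strands:
        k = len(motif)
        rc = reverse_complement(seq)
        for m in rx.finditer(rc):
            hits.append((len(seq) - m.start() - k, "-"))
    return sorted(hits)


def _percent(count: int, total: int) -> float:
    if total == 0:
        return 0.0
    pct = Decimal(100 * count) / Decimal(total)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class MotifSummary:
    """Peak-level containment summary for one motif."""

    name: str
    n_total: int
    n_containing: int
    hits: Dict[str, List[Tuple[int, str]]] = field(default_factory=dict)

    @property
    def percentage(self) -> float:
        """Percent of peaks with >= 1 hit, rounded half-up to 2 decimals."""
        return _percent(self.n_containing, self.n_total)


def peak_motif_fraction(
    unipeaks: Sequence,
    genome: GenomeSequence,
    motif: DegenerateMotif,
    peak_strands: Optional[Mapping[str, str]] = None,
) -> MotifSummary:
    """Scan every peak's genomic slice for ``motif`` and summarize containment.

    ``peak_strands`` maps peak id to the annotated gene strand; peaks with a
    known strand are scanned on that strand only, unannotated (intergenic)
    peaks on both strands.  Hit positions are genomic starts of the matched
    window.
    """
    peak_strands = peak_strands or {}
    hits: Dict[str, List[Tuple[int, str]]] = {}
    n_containing = 0
    for peak in unipeaks:
        iv = peak.interval
        try:
            seq = genome.fetch(iv)
        except (KeyError, MalformedRecordError) as exc:
            raise MalformedRecordError(
                f"peak {peak.peak_id} outside genome: {exc}"
            ) from exc
        strand = peak_strands.get(peak.peak_id)
        if strand in ("+", "-"):
            raw = scan_sequence(
                seq if strand == "+" else reverse_complement(seq), motif
            )
            if strand == "-":
                k = len(motif)
                raw = [(iv.length - pos - k, "-") for pos, _ in raw]
        else:
            raw = scan_sequence(seq, motif, both_strands=True)
        peak_hits = sorted((iv.start + pos, st) for pos, st in raw)
        if peak_hits:
            n_containing += 1
            hits[peak.peak_id] = peak_hits
    return MotifSummary(
        name=motif.name,
        n_total=len(list(unipeaks)),
        n_containing=n_containing,
        hits=hits,
    )
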