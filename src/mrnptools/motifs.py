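"""Consensus motif scanning over transcript sequences.

Scans mRNA sense strands for fixed IUPAC consensus sites (e.g. CAUCAUCA) or
triplet repeats (e.g. (CNN)x6).  RNA and DNA alphabets are interchangeable on
input (U = T) and N matches any base.  Hit coordinates are 1-based inclusive,
the convention used for probe names such as "21-80"; the I/O layer offers the
0-based half-open (BED) convention.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from typing import Optional

__all__ = ["MotifKind", "MotifSpec", "MotifHit", "scan_motif"]

IUPAC = {
    "A": "A",
    "C": "C",
    "G": "G",
    "T": "T",
    "U": "T",
    "R": "AG",
    "Y": "CT",
    "S": "CG",
    "W": "AT",
    "K": "GT",
    "M": "AC",
    "B": "CGT",
    "D": "AGT",
    "H": "ACT",
    "V": "ACG",
    "N": "ACGT",
}

SEQUENCE_ALPHABET = set("ACGTUN")


class MotifKind(str, enum.Enum):
    FIXED_IUPAC = "FIXED_IUPAC"
    TRIPLET_REPEAT = "TRIPLET_REPEAT"


@dataclass(frozen=True)
class MotifSpec:
    motif_id: str
    kind: MotifKind
    pattern: str  # IUPAC consensus, or the repeat unit for TRIPLET_REPEAT
    repeat_count: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", MotifKind(self.kind))
        if not self.pattern:
            raise ValueError("motif pattern must be non-empty")
        pat = self.pattern.upper()
        object.__setattr__(self, "pattern", pat)
        bad = set(pat) - set(IUPAC)
        if bad:
            raise ValueError(f"invalid motif characters: {sorted(bad)}")
        if self.kind is MotifKind.TRIPLET_REPEAT:
            if self.repeat_count is None or self.repeat_count < 1:
                raise ValueError("triplet repeats need repeat_count >= 1")

    def expanded(self) -> str:
        """Full consensus in DNA letters (U folded into T)."""
        pat = "".join("T" if c == "U" else c for c in self.pattern)
        if self.kind is MotifKind.TRIPLET_REPEAT:
            return pat * self.repeat_count
        return pat


@dataclass(frozen=True)
class MotifHit:
    transcript: str
    start: int  # 1-based
    end: int  # inclusive
    matched: str
    motif_id: str

    @property
    def bed_interval(self) -> tuple[int, int]:
        """0-based half-open coordinates."""
        return self.start - 1, self.end


def _normalize_sequence(sequence: str) -> str:
    seq = sequence.upper()
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - SEQUENCE_ALPHABET
    if bad:
        raise ValueError(f"invalid sequence characters: {sorted(bad)}")
    return seq.replace("U", "T")


def _motif_regex(consensus: str) -> re.Pattern:
    parts = []
    for c in consensus:
        bases = IUPAC[c]
        # N in the sequence matches any motif position; motif N matches any base
        parts.append(f"[{bases}N]" if len(bases) < 4 else ".")
    return re.compile("".join(parts))


def scan_motif(
    sequence: str,
    motif: MotifSpec,
    transcript: str = "",
    overlap_allowed: bool = True,
) -> list[MotifHit]:
    """All matches of ``motif`` on the sense strand of ``sequence``.

    With ``overlap_allowed`` every matching start position is reported;
    otherwise matches are taken greedily left to right without overlap.
    """
    seq = _normalize_sequence(sequence)
    consensus = motif.expanded()
    pattern = _motif_regex(consensus)
    hits: list[MotifHit] = []
    width = len(consensus)
    if overlap_allowed:
        lookahead = re.compile(f"(?=({pattern.pattern}))")
        for m in lookahead.finditer(seq):
            start = m.start()
            hits.append(
                MotifHit(
                    transcript=transcript,
                    start=start + 1,
                    end=start + width,
                    matched=seq[start : start + width],
                    motif_id=motif.motif_id,
                )
            )
    else:
        for m in pattern.finditer(seq):
            hits.append(
                MotifHit(
                    transcript=transcript,
                    start=m.start() + 1,
                    end=m.start() + width,
                    matched=m.group(0),
                    motif_id=motif.motif_id,
                )
            )
    return hits
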