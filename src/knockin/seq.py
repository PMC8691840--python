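"""Small DNA sequence helpers shared across modules.

Coordinates are 0-based half-open internally; user-facing reports are
1-based (see individual modules).
"""

from __future__ import annotations

from Bio.Seq import Seq

IUPAC_DNA = set("ACGTRYSWKMBDHVN")
STOP_CODONS = {"TAA", "TAG", "TGA"}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


def revcomp(seq: str) -> str:
    """Reverse complement, IUPAC-aware."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


def is_dna(seq: str) -> bool:
    return all(c in IUPAC_DNA for c in seq.upper())


def translate(seq: str) -> str:
    """Translate an in-frame DNA string (trailing partial codon dropped)."""
    usable = len(seq) - len(seq) % 3
    return str(Seq(seq[:usable]).translate())


def codons(seq: str, frame: int = 0):
    """Yield successive codons of ``seq`` starting at offset ``frame``."""
    for i in range(frame, len(seq) - 2, 3):
        yield seq[i:i + 3]


def in_frame_stops(seq: str, frame: int = 0) -> list[int]:
    """Offsets of in-frame stop codons in ``seq`` relative to ``frame``."""
    return [i for i in range(frame, len(seq) - 2, 3)
            if seq[i:i + 3].upper() in STOP_CODONS]
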