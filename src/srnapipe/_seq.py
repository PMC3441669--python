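"""Nucleotide-string helpers shared across the pipeline.

Tags are stored internally in the DNA alphabet (T, uppercase); miRNA-facing
reports render them in the RNA alphabet (U).
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTUacgtu", "TGCAAtgcaa")

DNA_ALPHABET = frozenset("ACGT")
RNA_ALPHABET = frozenset("ACGU")


def to_dna(seq: str) -> str:
    """Uppercase and convert U to T."""
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    """Uppercase and convert T to U."""
    return seq.upper().replace("T", "U")


def revcomp(seq: str) -> str:
    """Reverse complement (alphabet-preserving: U maps back to A)."""
    out = seq.translate(_COMPLEMENT)[::-1]
    return out


def validate_nucleotides(seq: str, name: str = "sequence") -> str:
    """Return the DNA-normalized sequence or raise ValueError."""
    norm = to_dna(seq)
    if not norm or set(norm) - DNA_ALPHABET:
        bad = sorted(set(norm) - DNA_ALPHABET)
        raise ValueError(f"{name} contains invalid symbols {bad!r}: {seq!r}")
    return norm


def gc_fraction(seq: str) -> float:
    s = to_dna(seq)
    if not s:
        return 0.0
    return (s.count("G") + s.count("C")) / len(s)
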