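"""Small nucleotide-sequence helpers shared by the genome-facing modules."""

from __future__ import annotations

from typing import Mapping

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# anything outside ACGT (IUPAC ambiguity codes etc.) collapses to N
_NORMALIZE = {c: c for c in "ACGTN"}


def revcomp(seq: str) -> str:
    """Reverse complement; ambiguity codes map to N via normalize first."""
    return normalize(seq).translate(_COMPLEMENT)[::-1]


def normalize(seq: str) -> str:
    """Uppercase and collapse every non-ACGT symbol to N."""
    up = seq.upper()
    if all(c in "ACGTN" for c in up):
        return up
    return "".join(c if c in "ACGTN" else "N" for c in up)


def fetch(genome, contig: str, start: int, end: int) -> str:
    """Fetch genome[contig][start:end] (0-based half-open) as an upper-case string.

    Accepts a plain dict of strings or a pyfaidx.Fasta-like object.
    """
    rec = genome[contig]
    if isinstance(rec, str):
        return normalize(rec[start:end])
    return normalize(str(rec[start:end]))


def contig_length(genome, contig: str) -> int:
    rec = genome[contig]
    return len(rec)


def contig_names(genome) -> list[str]:
    if isinstance(genome, Mapping):
        return list(genome.keys())
    return list(genome.keys())  # pyfaidx.Fasta also has .keys()
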