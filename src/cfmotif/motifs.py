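"""Canonical 4-mer end-motif index and small sequence utilities.

A cfDNA fragment end motif is the first 4 bases at a fragment's 5'
terminus, read from the reference genome after alignment. There are
4^4 = 256 possible motifs; everything downstream (count vectors,
frequency profiles, feature matrices) is keyed by the single canonical
ordering defined here: lexicographic with A < C < G < T, i.e. base-4
positional encoding with A=0, C=1, G=2, T=3.
"""
from __future__ import annotations

import itertools

BASES = "ACGT"
MOTIF_LENGTH = 4
N_MOTIFS = len(BASES) ** MOTIF_LENGTH  # 256

_MOTIFS: tuple[str, ...] = tuple(
    "".join(p) for p in itertools.product(BASES, repeat=MOTIF_LENGTH)
)
_MOTIF_TO_INDEX: dict[str, int] = {m: i for i, m in enumerate(_MOTIFS)}
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def enumerate_motifs() -> tuple[str, ...]:
    """Return all 256 4-mers in canonical order ("AAAA" ... "TTTT").

    The returned tuple is a module-level constant, so repeated calls are
    cheap and the ordering is stable for the lifetime of the process.
    """
    return _MOTIFS


def motif_index(motif: str) -> int:
    """Position of ``motif`` in the canonical index (AAAA=0 ... TTTT=255)."""
    try:
        return _MOTIF_TO_INDEX[motif.upper()]
    except KeyError:
        raise KeyError(f"not a 4-mer over ACGT: {motif!r}") from None


def is_acgt(seq: str) -> bool:
    """True when every character of ``seq`` is one of A/C/G/T (upper-case)."""
    return all(c in BASES for c in seq)


def reverse_complement(seq: str) -> str:
    """Reverse complement; N is preserved as N."""
    return seq.translate(_COMPLEMENT)[::-1]
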