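"""Small nucleotide-sequence helpers shared across modules."""

from __future__ import annotations

_COMPLEMENT_DNA = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")
_COMPLEMENT_RNA = str.maketrans("ACGUTNacgutn", "UGCAANugcaan")

VALID_CHARS = frozenset("ACGTUN")


def revcomp(seq: str, alphabet: str = "DNA") -> str:
    """Reverse complement; U is treated as T in DNA mode and vice versa."""
    table = _COMPLEMENT_RNA if alphabet == "RNA" else _COMPLEMENT_DNA
    return seq.translate(table)[::-1]


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def check_alphabet(seq: str, where: str = "sequence") -> None:
    bad = set(seq.upper()) - VALID_CHARS
    if bad:
        raise ValueError(f"{where} contains non-nucleotide characters: {sorted(bad)}")
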