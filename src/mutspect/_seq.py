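"""Small shared sequence utilities."""

from __future__ import annotations

BASES = "ACGT"
PYRIMIDINES = frozenset("CT")
PURINES = frozenset("AG")

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def complement(base: str) -> str:
    try:
        return _COMP[base]
    except KeyError:
        raise ValueError(f"cannot complement base {base!r}") from None


def reverse_complement(seq: str) -> str:
    return "".join(_COMP.get(b, "N") for b in reversed(seq))
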