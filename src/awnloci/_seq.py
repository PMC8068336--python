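"""Small shared sequence primitives: translation, edit application,
seeded random nucleotide generation."""

from __future__ import annotations

import numpy as np
from Bio.Seq import Seq

_NUC = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_nucleotides(n: int, rng: np.random.Generator) -> str:
    """Uniform random nucleotide string of length ``n``."""
    return _NUC[rng.integers(0, 4, size=n)].tobytes().decode("ascii")


def translate(cds: str) -> str:
    """Translate a CDS with the standard genetic code.

    Translation starts at the first base (which must begin an ATG codon),
    stops at the first in-frame stop codon, and ignores a trailing partial
    codon.  Ambiguity codes are rejected.
    """
    if not cds.startswith("ATG"):
        raise ValueError("CDS does not start with ATG")
    if set(cds) - set("ACGT"):
        raise ValueError(f"CDS contains non-ACGT characters: {set(cds) - set('ACGT')}")
    n = len(cds) // 3 * 3
    return str(Seq(cds[:n]).translate(to_stop=True))


def apply_edit(seq: str, op: str, pos: int, arg) -> str:
    """Apply one edit at a 1-based position.

    ``op='del'`` removes ``arg`` bases starting at ``pos``; ``op='ins'``
    inserts the string ``arg`` before ``pos``.
    """
    if op == "del":
        length = int(arg)
        if pos < 1 or pos - 1 + length > len(seq):
            raise ValueError(f"deletion [{pos}, {pos + length - 1}] outside sequence")
        return seq[: pos - 1] + seq[pos - 1 + length :]
    if op == "ins":
        if pos < 1 or pos > len(seq) + 1:
            raise ValueError(f"insertion position {pos} outside sequence")
        return seq[: pos - 1] + str(arg) + seq[pos - 1 :]
    raise ValueError(f"unknown edit op {op!r}")


def apply_anchored_variants(seq: str, variants) -> str:
    """Apply anchored (pos, ref, alt) variants to ``seq``.

    Positions are 1-based; ``ref`` must match the sequence.  Variants are
    applied right-to-left so earlier coordinates stay valid; overlapping
    variants raise.
    """
    ordered = sorted(variants, key=lambda v: v[0])
    for (p1, r1, _), (p2, _, _) in zip(ordered, ordered[1:]):
        if p1 + len(r1) > p2:
            raise ValueError(f"overlapping variants at positions {p1} and {p2}")
    out = seq
    for pos, ref, alt in reversed(ordered):
        if out[pos - 1 : pos - 1 + len(ref)] != ref:
            raise ValueError(f"reference mismatch at position {pos}: expected {ref!r}")
        out = out[: pos - 1] + alt + out[pos - 1 + len(ref) :]
    return out
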