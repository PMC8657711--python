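"""Canonical 96-channel single-base-substitution category layout.

Every somatic SNV is represented, by convention starting from the
pyrimidine of the mutated base pair, as one of six substitution classes
(C>A, C>G, C>T, T>A, T>C, T>G) inside its trinucleotide context, giving
6 x 4 x 4 = 96 categories.  The order is substitution-major, then 5'
flank, then 3' flank, both lexicographic (A, C, G, T) -- the de facto
standard layout of published SBS catalogs, so user-supplied reference
tables align row-for-row.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

BASES = ("A", "C", "G", "T")
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_SUB_INDEX = {s: i for i, s in enumerate(SUBSTITUTIONS)}

PYRIMIDINES = frozenset("CT")
PURINES = frozenset("AG")


@dataclass(frozen=True)
class ContextCategory:
    """One pyrimidine-normalized trinucleotide mutation category."""

    substitution: str
    five_prime: str
    three_prime: str

    @property
    def label(self) -> str:
        return f"{self.five_prime}[{self.substitution}]{self.three_prime}"

    @property
    def index(self) -> int:
        return category_index(self.substitution, self.five_prime, self.three_prime)


def category_index(substitution: str, five_prime: str, three_prime: str) -> int:
    """Row index of a category in the canonical 96-channel order."""
    return (
        _SUB_INDEX[substitution] * 16
        + _BASE_INDEX[five_prime] * 4
        + _BASE_INDEX[three_prime]
    )


def category_from_index(idx: int) -> ContextCategory:
    if not 0 <= idx < 96:
        raise ValueError(f"category index out of range: {idx}")
    sub, rem = divmod(idx, 16)
    f5, f3 = divmod(rem, 4)
    return ContextCategory(SUBSTITUTIONS[sub], BASES[f5], BASES[f3])


def all_categories() -> list[ContextCategory]:
    """The 96 categories in canonical order."""
    return [category_from_index(i) for i in range(96)]


CATEGORY_LABELS: tuple[str, ...] = tuple(c.label for c in all_categories())

_LABEL_INDEX = {lab: i for i, lab in enumerate(CATEGORY_LABELS)}


def label_to_index(label: str) -> int:
    try:
        return _LABEL_INDEX[label]
    except KeyError:
        raise ValueError(f"not a canonical category label: {label!r}") from None


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def normalize_substitution(ref: str, alt: str, five_prime: str, three_prime: str
                           ) -> ContextCategory:
    """Pyrimidine-normalize a substitution with its flanks.

    If the reference base is a purine the substitution and both flanks
    are complemented and the flanks swap sides, so the category is always
    expressed on the strand carrying the pyrimidine.
    """
    if ref in PURINES:
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
        five_prime, three_prime = COMPLEMENT[three_prime], COMPLEMENT[five_prime]
    return ContextCategory(f"{ref}>{alt}", five_prime, three_prime)


# integer encodings used by the vectorized paths -----------------------------

_ENCODE = np.full(256, -1, dtype=np.int8)
for _b, _i in _BASE_INDEX.items():
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_COMP_CODE = np.array([3, 2, 1, 0], dtype=np.int8)  # A<->T, C<->G


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a sequence as int8 codes (A=0, C=1, G=2, T=3; other = -1)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
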