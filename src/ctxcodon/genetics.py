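"""Standard genetic code bookkeeping shared across the package.

Everything here is derived programmatically from Biopython's standard codon
table so the synonymous-family structure (two-, three-, four- and sixfold
degenerate groups, the fourfold subgroups of Leu/Ser/Arg, the NNY twofold
groups) is never hand-typed.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
#: complement permutation over the index order A,C,G,T (A<->T, C<->G)
COMPLEMENT_INDEX = np.array([3, 2, 1, 0])
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

#: the 61 sense codons, lexicographic order; index into codon-count vectors
SENSE_CODONS = tuple(sorted(_STANDARD.forward_table))
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
CODON_TO_AA = dict(_STANDARD.forward_table)
STOP_CODONS = frozenset(_STANDARD.stop_codons)

#: amino acid -> tuple of its sense codons
FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon in SENSE_CODONS:
    FAMILIES.setdefault(CODON_TO_AA[_codon], ())
for _codon in SENSE_CODONS:
    _aa = CODON_TO_AA[_codon]
    FAMILIES[_aa] = FAMILIES[_aa] + (_codon,)

#: the 18 amino acids with >= 2 synonymous codons
DEGENERATE_AAS = tuple(sorted(a for a, c in FAMILIES.items() if len(c) > 1))
SIXFOLD_AAS = tuple(sorted(a for a, c in FAMILIES.items() if len(c) == 6))

#: degeneracy class (2, 3, 4 or 6) per degenerate amino acid
FAMILY_FOLD = {a: len(FAMILIES[a]) for a in DEGENERATE_AAS}

#: codon prefixes (first two bases) at which the third position is fourfold
#: degenerate -- includes the fourfold subgroups of the sixfold amino acids
FOURFOLD_PREFIXES = frozenset(
    p
    for p in {c[:2] for c in SENSE_CODONS}
    if all(p + b in CODON_TO_AA for b in BASES)
    and len({CODON_TO_AA[p + b] for b in BASES}) == 1
)

#: the six twofold NNY groups entering the C2 statistic (Phe, Tyr, Cys,
#: His, Asn, Asp) -- AGY (Ser) is deliberately not one of them
C2_AAS = ("F", "Y", "C", "H", "N", "D")
C2_PREFIXES = frozenset(FAMILIES[a][0][:2] for a in C2_AAS)


@lru_cache(maxsize=None)
def synonymous_third_bases(codon: str) -> str:
    """Third bases that keep the amino acid, with the first two bases fixed.

    Because the first two bases are held fixed this automatically restricts
    sixfold amino acids to the subgroup (fourfold or twofold) the codon sits
    in, e.g. ``TTA -> "AG"`` but ``CTA -> "ACGT"``.
    """
    aa = CODON_TO_AA[codon]
    return "".join(b for b in BASES if CODON_TO_AA.get(codon[:2] + b) == aa)


def translate(seq: str) -> str:
    """Translate an in-frame CDS; raises on internal stops or frame errors."""
    if len(seq) % 3:
        raise ValueError(f"sequence length {len(seq)} is not a multiple of 3")
    aas = []
    n_codons = len(seq) // 3
    for i in range(n_codons):
        codon = seq[3 * i : 3 * i + 3]
        if codon in STOP_CODONS:
            if i != n_codons - 1:
                raise ValueError(f"internal stop codon {codon} at codon index {i}")
            break
        try:
            aas.append(CODON_TO_AA[codon])
        except KeyError:
            raise ValueError(f"invalid codon {codon!r} at codon index {i}") from None
    return "".join(aas)


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def encode(seq: str) -> np.ndarray:
    """Map a sequence over {A,C,G,T,-} to uint8 codes 0..3, gap = 4."""
    table = np.full(256, 255, dtype=np.uint8)
    for b, i in BASE_INDEX.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    table[ord("-")] = 4
    arr = table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        bad = seq[int(np.argmax(arr == 255))]
        raise ValueError(f"invalid character {bad!r} in sequence")
    return arr


def decode(arr: np.ndarray) -> str:
    return "".join("ACGT-"[i] for i in arr)
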