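"""Aligned sequence triplets: two ingroups plus an outgroup.

The first two records of a triplet are the closely related ingroup pair
whose differences are scored as substitutions; the third is the outgroup
used to orient ancestral vs derived states. Record order defines the roles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_ALPHABET = set("ACGT-")


@dataclass
class AlignedTriplet:
    ingroup1: str
    ingroup2: str
    outgroup: str
    identifiers: tuple[str, str, str] = field(
        default=("ingroup1", "ingroup2", "outgroup")
    )

    def __post_init__(self) -> None:
        seqs = (self.ingroup1, self.ingroup2, self.outgroup)
        if len({len(s) for s in seqs}) != 1:
            raise ValueError("all three aligned sequences must have equal length")
        for name, s in zip(self.identifiers, seqs):
            bad = set(s) - _ALPHABET
            if bad:
                raise ValueError(
                    f"sequence {name!r} contains invalid characters {sorted(bad)}"
                )

    def __len__(self) -> int:
        return len(self.ingroup1)

    @property
    def sequences(self) -> tuple[str, str, str]:
        return (self.ingroup1, self.ingroup2, self.outgroup)


def write_triplet_fasta(triplet: AlignedTriplet, path) -> None:
    """Write the three records in fixed role order: ingroup1, ingroup2, outgroup."""
    records = [
        SeqRecord(Seq(s), id=name, description="")
        for name, s in zip(triplet.identifiers, triplet.sequences)
    ]
    SeqIO.write(records, path, "fasta")


def read_triplet_fasta(path) -> AlignedTriplet:
    records = list(SeqIO.parse(path, "fasta"))
    if len(records) != 3:
        raise ValueError(f"{path}: expected exactly 3 records, found {len(records)}")
    seqs = [str(r.seq).upper() for r in records]
    return AlignedTriplet(*seqs, identifiers=tuple(r.id for r in records))
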