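"""Site filters and context-resolved substitution scoring of aligned triplets.

A site is scored only when its local alignment is trustworthy (enough
ungapped, sufficiently similar flanking columns between the two ingroups)
and its tetranucleotide context -- the two alignment columns on each side --
is gap-free and identical in all three sequences. Sites where the ingroups
agree are conserved observations; where they differ and the outgroup matches
one of them, the outgroup state is taken as ancestral; three-way differences
are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, NamedTuple

import numpy as np

from .alignments import AlignedTriplet
from .genetics import BASES, BASE_INDEX, FOURFOLD_PREFIXES, encode
from .matrices import ALL_CONTEXTS

ALL_SITES = "all_sites"
FOURFOLD_ONLY = "fourfold_degenerate_only"


@dataclass
class SiteFilterConfig:
    """Filter settings; defaults follow the intergenic-region protocol."""

    min_alignment_length: int = 70  # exclusive bound on alignment length
    window_radius: int = 5  # columns on each side of the scored site
    min_ungapped_pairs_in_window: int = 8
    min_ingroup_similarity_in_window: float = 0.70
    site_class: str = ALL_SITES

    def __post_init__(self) -> None:
        if not (0 < self.min_ingroup_similarity_in_window <= 1):
            raise ValueError("min_ingroup_similarity_in_window must be in (0, 1]")
        if self.min_ungapped_pairs_in_window > 2 * self.window_radius:
            raise ValueError(
                "min_ungapped_pairs_in_window cannot exceed the window size"
            )
        if self.site_class not in (ALL_SITES, FOURFOLD_ONLY):
            raise ValueError(f"unknown site_class {self.site_class!r}")


class SiteCall(NamedTuple):
    kind: str  # "conserved" | "substitution" | "ignored"
    ancestral: str | None
    derived: str | None


@dataclass(frozen=True)
class SiteObservation:
    alignment_position: int  # 0-based column index
    context: str  # NN_NN
    ancestral: str
    derived: str


class SiteObservations:
    """Column-oriented batch of site observations (numpy-backed)."""

    def __init__(self, positions, context_codes, ancestral_idx, derived_idx):
        self.positions = np.asarray(positions, dtype=np.int64)
        self.context_codes = np.asarray(context_codes, dtype=np.int64)
        self.ancestral_idx = np.asarray(ancestral_idx, dtype=np.int64)
        self.derived_idx = np.asarray(derived_idx, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.positions)

    def __iter__(self) -> Iterator[SiteObservation]:
        for p, c, a, d in zip(
            self.positions, self.context_codes, self.ancestral_idx, self.derived_idx
        ):
            yield SiteObservation(int(p), ALL_CONTEXTS[c], BASES[a], BASES[d])

    @property
    def n_substitutions(self) -> int:
        return int((self.ancestral_idx != self.derived_idx).sum())

    @classmethod
    def empty(cls) -> "SiteObservations":
        z = np.zeros(0, dtype=np.int64)
        return cls(z, z, z, z)

    @classmethod
    def concatenate(cls, batches) -> "SiteObservations":
        batches = list(batches) or [cls.empty()]
        return cls(
            np.concatenate([b.positions for b in batches]),
            np.concatenate([b.context_codes for b in batches]),
            np.concatenate([b.ancestral_idx for b in batches]),
            np.concatenate([b.derived_idx for b in batches]),
        )


def classify_site(in1: str, in2: str, out: str) -> SiteCall:
    """Classify one alignment column. Total over {A,C,G,T,-}^3."""
    if "-" in (in1, in2, out):
        return SiteCall("ignored", None, None)
    if in1 == in2:
        return SiteCall("conserved", in1, in1)
    if out == in1:
        return SiteCall("substitution", in1, in2)
    if out == in2:
        return SiteCall("substitution", in2, in1)
    return SiteCall("ignored", None, None)


def _window_counts(indicator: np.ndarray, radius: int) -> np.ndarray:
    """Per-position sum of ``indicator`` over the window of ``radius`` columns
    each side, excluding the position itself and truncated at the ends."""
    kernel = np.ones(2 * radius + 1)
    total = np.convolve(indicator.astype(float), kernel, mode="same")
    return np.rint(total - indicator).astype(np.int64)


def _filter_mask(triplet: AlignedTriplet, config: SiteFilterConfig) -> np.ndarray:
    a = encode(triplet.ingroup1)
    b = encode(triplet.ingroup2)
    ungapped = (a < 4) & (b < 4)
    ident = ungapped & (a == b)
    n_ung = _window_counts(ungapped, config.window_radius)
    n_id = _window_counts(ident, config.window_radius)
    sim = config.min_ingroup_similarity_in_window
    return (
        (n_ung >= config.min_ungapped_pairs_in_window)
        & (n_ung > 0)
        & (n_id + 1e-9 >= sim * n_ung)
    )


def site_passes_filters(
    triplet: AlignedTriplet, position: int, config: SiteFilterConfig
) -> bool:
    """Window filter at one column: enough ungapped ingroup pairs among the
    flanking columns and sufficient ingroup identity among those pairs."""
    if not 0 <= position < len(triplet):
        raise IndexError(f"position {position} outside alignment of length {len(triplet)}")
    return bool(_filter_mask(triplet, config)[position])


_FOURFOLD_PREFIX_GRID = np.zeros((4, 4), dtype=bool)
for _p in FOURFOLD_PREFIXES:
    _FOURFOLD_PREFIX_GRID[BASE_INDEX[_p[0]], BASE_INDEX[_p[1]]] = True


def extract_site_observations(
    triplet: AlignedTriplet,
    config: SiteFilterConfig | None = None,
    frame_annotation: np.ndarray | str | None = None,
) -> SiteObservations:
    """Score every eligible column of a triplet.

    ``frame_annotation`` is required when ``config.site_class`` is
    ``fourfold_degenerate_only``: either the string ``"cds"`` (the alignment
    is an in-frame CDS starting at column 0) or an integer array giving the
    within-codon position (0, 1, 2) of each column, -1 for non-coding.
    """
    config = config or SiteFilterConfig()
    L = len(triplet)
    if L <= config.min_alignment_length:
        return SiteObservations.empty()

    a = encode(triplet.ingroup1)
    b = encode(triplet.ingroup2)
    c = encode(triplet.outgroup)

    passes = _filter_mask(triplet, config)

    all3_eq = (a == b) & (b == c) & (a < 4)
    ctx_ok = np.zeros(L, dtype=bool)
    ctx_ok[2 : L - 2] = (
        all3_eq[: L - 4] & all3_eq[1 : L - 3] & all3_eq[3 : L - 1] & all3_eq[4:]
    )

    gapless = (a < 4) & (b < 4) & (c < 4)
    conserved = gapless & (a == b)
    substituted = gapless & (a != b) & ((c == a) | (c == b))
    keep = passes & ctx_ok & (conserved | substituted)

    if config.site_class == FOURFOLD_ONLY:
        if frame_annotation is None:
            raise ValueError(
                "fourfold_degenerate_only scoring requires a frame annotation"
            )
        if isinstance(frame_annotation, str):
            if frame_annotation != "cds":
                raise ValueError(f"unknown frame annotation {frame_annotation!r}")
            frame = np.arange(L) % 3
        else:
            frame = np.asarray(frame_annotation)
            if frame.shape != (L,):
                raise ValueError("frame annotation length must match the alignment")
        third = frame == 2
        fourfold = np.zeros(L, dtype=bool)
        idx = np.nonzero(third[2:])[0] + 2
        # codon prefix must be conserved in all three sequences (guaranteed by
        # ctx_ok at the two 5' neighbours) and fourfold degenerate
        fourfold[idx] = _FOURFOLD_PREFIX_GRID[a[idx - 2] % 4, a[idx - 1] % 4]
        keep &= third & fourfold

    pos = np.nonzero(keep)[0]
    anc = np.where(conserved[pos], a[pos], c[pos])
    der = np.where(
        conserved[pos], a[pos], np.where(c[pos] == a[pos], b[pos], a[pos])
    )
    codes = (
        a[pos - 2].astype(np.int64) * 64
        + a[pos - 1] * 16
        + a[pos + 1] * 4
        + a[pos + 2]
    )
    return SiteObservations(pos, codes, anc.astype(np.int64), der.astype(np.int64))
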