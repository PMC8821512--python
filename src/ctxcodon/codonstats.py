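"""Observed codon-usage statistics: ENC, CAI, PR2 and friends.

ENC is Wright's effective number of codons: per synonymous family the
homozygosity F-hat = (n * sum p^2 - 1) / (n - 1) is estimated from the n
codons observed for that amino acid, F-hat values are averaged within
degeneracy classes (2-, 3-, 4- and 6-fold) and combined as

    ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6

(20 = one codon per family, 61 = uniform usage; values above 61 from
sampling noise are truncated). CAI is the count-weighted geometric mean of
codon relative-adaptiveness values w derived from a reference gene set.
PR-AT and PR-GC are the A/(A+T) and G/(G+C) percentages at fourfold
degenerate third positions; C2 is the percent NNC among the six twofold
NNY groups (Phe, Tyr, Cys, His, Asn, Asp); GC3/GC3S are G+C fractions at
all/fourfold-degenerate third positions.

All statistics accept real-valued codon counts so the same code paths
serve observed genes, resampled sequences and deterministic expectations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genetics import (
    BASE_INDEX,
    C2_PREFIXES,
    CODON_INDEX,
    CODON_TO_AA,
    DEGENERATE_AAS,
    FAMILIES,
    FAMILY_FOLD,
    FOURFOLD_PREFIXES,
    SENSE_CODONS,
    STOP_CODONS,
    translate,
)

N_CODONS = len(SENSE_CODONS)

# --- precomputed masks over the 61 sense codons -----------------------------

#: (18, 61) family membership indicator, rows ordered as DEGENERATE_AAS
FAMILY_MATRIX = np.zeros((len(DEGENERATE_AAS), N_CODONS))
for _i, _aa in enumerate(DEGENERATE_AAS):
    for _c in FAMILIES[_aa]:
        FAMILY_MATRIX[_i, CODON_INDEX[_c]] = 1.0

FAMILY_FOLDS = np.array([FAMILY_FOLD[a] for a in DEGENERATE_AAS])

#: Wright's class weights: number of families and codons contributed per class
ENC_CLASSES = {2: 9.0, 3: 1.0, 4: 5.0, 6: 3.0}

_THIRD = np.array([BASE_INDEX[c[2]] for c in SENSE_CODONS])
FOURFOLD_SITE = np.array([c[:2] in FOURFOLD_PREFIXES for c in SENSE_CODONS])
_GC3 = np.array([c[2] in "GC" for c in SENSE_CODONS], dtype=float)
_A3 = (_THIRD == BASE_INDEX["A"]).astype(float)
_T3 = (_THIRD == BASE_INDEX["T"]).astype(float)
_G3 = (_THIRD == BASE_INDEX["G"]).astype(float)
_C3 = (_THIRD == BASE_INDEX["C"]).astype(float)
_C2C = np.array(
    [c[:2] in C2_PREFIXES and c[2] == "C" for c in SENSE_CODONS], dtype=float
)
_C2T = np.array(
    [c[:2] in C2_PREFIXES and c[2] == "T" for c in SENSE_CODONS], dtype=float
)
DEGENERATE_CODON = np.array(
    [len(FAMILIES[CODON_TO_AA[c]]) > 1 for c in SENSE_CODONS]
)


@dataclass
class CodonUsageTable:
    """Per-codon counts of one gene (real-valued counts are allowed)."""

    counts: np.ndarray
    gene_id: str = "gene"
    has_stop: bool = False

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if c.shape != (N_CODONS,) or (c < 0).any():
            raise ValueError(f"counts must be a non-negative length-{N_CODONS} vector")
        self.counts = c

    @classmethod
    def from_sequence(cls, seq: str, gene_id: str = "gene") -> "CodonUsageTable":
        seq = seq.upper()
        translate(seq)  # validates frame / internal stops with a useful message
        counts = np.zeros(N_CODONS)
        has_stop = False
        for i in range(len(seq) // 3):
            codon = seq[3 * i : 3 * i + 3]
            if codon in STOP_CODONS:
                has_stop = True
                break
            counts[CODON_INDEX[codon]] += 1
        return cls(counts, gene_id=gene_id, has_stop=has_stop)

    @property
    def length_codons(self) -> int:
        return int(round(self.counts.sum())) + int(self.has_stop)

    def __getitem__(self, codon: str) -> float:
        return float(self.counts[CODON_INDEX[codon]])


@dataclass
class CodonFitnessTable:
    """Relative adaptiveness w per sense codon; max w = 1 in every family."""

    w: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        if w.shape != (N_CODONS,) or (w <= 0).any() or (w > 1).any():
            raise ValueError("w must be a length-61 vector with values in (0, 1]")
        self.w = w

    def __getitem__(self, codon: str) -> float:
        return float(self.w[CODON_INDEX[codon]])


def _as_counts(usage) -> np.ndarray:
    if isinstance(usage, CodonUsageTable):
        return usage.counts
    return np.asarray(usage, dtype=float)


# --- ENC --------------------------------------------------------------------


def _family_homozygosity(counts: np.ndarray, finite_n: bool) -> np.ndarray:
    """(R, 18) F-hat per degenerate family; NaN where not computable.

    ``finite_n`` applies Wright's finite-sample estimator and his repairs
    (families with n < 2 or F-hat <= 0 are dropped from the class average);
    otherwise the infinite-sample homozygosity sum p^2 is used, as needed
    for real-valued expected usage.
    """
    counts = np.atleast_2d(counts)
    n = counts @ FAMILY_MATRIX.T
    s2 = (counts**2) @ FAMILY_MATRIX.T
    with np.errstate(divide="ignore", invalid="ignore"):
        sum_p2 = s2 / n**2
        if finite_n:
            f = (n * sum_p2 - 1.0) / (n - 1.0)
            f = np.where((n >= 2) & (f > 0), f, np.nan)
        else:
            f = np.where(n > 0, sum_p2, np.nan)
    return f


def _class_mean(f: np.ndarray, fold: int) -> np.ndarray:
    sub = f[:, FAMILY_FOLDS == fold]
    valid = ~np.isnan(sub)
    n_valid = valid.sum(axis=1)
    total = np.where(valid, sub, 0.0).sum(axis=1)
    return np.where(n_valid > 0, total / np.maximum(n_valid, 1), np.nan)


def enc_batch(counts: np.ndarray, finite_n: bool = True) -> np.ndarray:
    """Wright's ENC for each row of a (R, 61) count matrix."""
    f = _family_homozygosity(counts, finite_n)
    f2 = _class_mean(f, 2)
    f3 = _class_mean(f, 3)
    f4 = _class_mean(f, 4)
    f6 = _class_mean(f, 6)
    # Wright's missing-class repairs: an absent Ile (3-fold) class is
    # estimated as (F2+F4)/2; the same estimate is used for an absent
    # 6-fold class. Any class still missing (possible for short or
    # compositionally narrow genes) falls back to the mean of the
    # available class averages.
    repair = (f2 + f4) / 2.0
    f3 = np.where(np.isnan(f3), repair, f3)
    f6 = np.where(np.isnan(f6), repair, f6)
    stack = np.stack([f2, f3, f4, f6])
    present = ~np.isnan(stack)
    n_present = present.sum(axis=0)
    overall = np.where(
        n_present > 0,
        np.where(present, stack, 0.0).sum(axis=0) / np.maximum(n_present, 1),
        np.nan,
    )
    f2, f3, f4, f6 = (np.where(np.isnan(f), overall, f) for f in (f2, f3, f4, f6))
    enc = 2.0 + 9.0 / f2 + 1.0 / f3 + 5.0 / f4 + 3.0 / f6
    return np.minimum(enc, 61.0)


def enc(usage) -> float:
    """Wright's ENC of a gene (finite-sample estimator, truncated at 61)."""
    counts = _as_counts(usage)
    value = float(enc_batch(counts[None, :], finite_n=True)[0])
    if np.isnan(value):
        raise ValueError("ENC undefined: no degenerate family with usable counts")
    return value


def enc_expected_curve(gc3: float) -> float:
    """Wright's expected ENC at synonymous G+C fraction ``s``:
    ENC_E = 2 + s + 29 / (s^2 + (1-s)^2)."""
    s = float(gc3)
    if not 0.0 <= s <= 1.0:
        raise ValueError("gc3 must be a fraction in [0, 1]")
    return 2.0 + s + 29.0 / (s**2 + (1.0 - s) ** 2)


# --- CAI --------------------------------------------------------------------


def build_fitness_table(
    reference_usages, zero_count: float = 0.5
) -> CodonFitnessTable:
    """Relative adaptiveness from pooled reference codon counts.

    Counts are summed over the references; within every amino-acid family
    w = count / max count, with zero counts replaced by ``zero_count``
    occurrences before the division.
    """
    refs = list(reference_usages)
    if not refs:
        raise ValueError("at least one reference usage table is required")
    pooled = np.sum([_as_counts(u) for u in refs], axis=0)
    w = np.empty(N_CODONS)
    for aa, codons in FAMILIES.items():
        idx = [CODON_INDEX[c] for c in codons]
        fam = pooled[idx]
        top = fam.max()
        if top <= 0:
            raise ValueError(f"reference set has no counts for amino acid {aa}")
        fam = np.where(fam == 0, zero_count, fam)
        w[idx] = fam / top
    return CodonFitnessTable(w)


def cai_batch(counts: np.ndarray, fitness: CodonFitnessTable) -> np.ndarray:
    """Count-weighted geometric mean of w over degenerate codons, per row."""
    counts = np.atleast_2d(counts)
    deg = counts[:, DEGENERATE_CODON]
    logw = np.log(fitness.w[DEGENERATE_CODON])
    total = deg.sum(axis=1)
    with np.errstate(invalid="ignore"):
        return np.exp((deg @ logw) / total)


def cai(usage, fitness: CodonFitnessTable) -> float:
    counts = _as_counts(usage)
    if counts[DEGENERATE_CODON].sum() <= 0:
        raise ValueError("CAI undefined: no degenerate codons counted")
    return float(cai_batch(counts[None, :], fitness)[0])


# --- composition ------------------------------------------------------------


def _ratio_pct(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, 100.0 * num / den, np.nan)


def pr_at_batch(counts: np.ndarray) -> np.ndarray:
    counts = np.atleast_2d(counts)
    a = counts @ (_A3 * FOURFOLD_SITE)
    t = counts @ (_T3 * FOURFOLD_SITE)
    return _ratio_pct(a, a + t)


def pr_gc_batch(counts: np.ndarray) -> np.ndarray:
    counts = np.atleast_2d(counts)
    g = counts @ (_G3 * FOURFOLD_SITE)
    c = counts @ (_C3 * FOURFOLD_SITE)
    return _ratio_pct(g, g + c)


def c2_batch(counts: np.ndarray) -> np.ndarray:
    counts = np.atleast_2d(counts)
    c = counts @ _C2C
    t = counts @ _C2T
    return _ratio_pct(c, c + t)


def gc3(usage) -> float:
    counts = _as_counts(usage)
    total = counts.sum()
    return float(counts @ _GC3 / total) if total > 0 else float("nan")


def gc3s(usage) -> float:
    counts = _as_counts(usage) * FOURFOLD_SITE
    total = counts.sum()
    return float(counts @ _GC3 / total) if total > 0 else float("nan")


@dataclass
class CompositionStats:
    gene_id: str
    length_codons: int
    enc: float
    gc3: float
    gc3s: float
    pr_at: float
    pr_gc: float
    c2: float
    cai: float = field(default=float("nan"))


def composition_stats(
    gene: str,
    gene_id: str = "gene",
    fitness: CodonFitnessTable | None = None,
) -> CompositionStats:
    """All observed statistics of one in-frame CDS."""
    usage = CodonUsageTable.from_sequence(gene, gene_id=gene_id)
    counts = usage.counts
    return CompositionStats(
        gene_id=gene_id,
        length_codons=usage.length_codons,
        enc=enc(usage),
        gc3=gc3(usage),
        gc3s=gc3s(usage),
        pr_at=float(pr_at_batch(counts)[0]),
        pr_gc=float(pr_gc_batch(counts)[0]),
        c2=float(c2_batch(counts)[0]),
        cai=cai(usage, fitness) if fitness is not None else float("nan"),
    )
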