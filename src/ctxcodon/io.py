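"""Plain-text readers and writers for the pipeline's tabular formats.

Matrix TSV: header ``context<TAB>from<TAB>to<TAB>count``, one row per cell
including diagonals; contexts written as ``NN_NN`` and pooled keys as
``N_N|AT=k`` / ``N_N|RY=k``. Stationary TSV: context, fA, fC, fG, fT,
GC_pct, PR_AT, PR_GC. All writers accept a metadata mapping emitted as
leading ``# key: value`` comment lines.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
from Bio import SeqIO

from .codonstats import CodonUsageTable, CompositionStats
from .genetics import BASES, BASE_INDEX
from .matrices import (
    COMPLEMENT_COMBINED,
    POOLED48_AT,
    POOLED48_RY,
    RAW256,
    ContextMatrixSet,
    StationaryVector,
    canonical_context,
)
from .scoring import SiteObservations


def _write_header(handle, metadata: dict | None) -> None:
    for key, value in (metadata or {}).items():
        handle.write(f"# {key}: {value}\n")


def write_matrix_tsv(mset: ContextMatrixSet, path, metadata: dict | None = None) -> None:
    with open(path, "w") as fh:
        _write_header(fh, {**(metadata or {}), "level": mset.level})
        fh.write("context\tfrom\tto\tcount\n")
        for ctx in sorted(mset.keys()):
            m = mset[ctx]
            for i, a in enumerate(BASES):
                for j, b in enumerate(BASES):
                    fh.write(f"{ctx}\t{a}\t{b}\t{int(m[i, j])}\n")


def _infer_level(keys) -> str:
    keys = list(keys)
    if any("|AT=" in k for k in keys):
        return POOLED48_AT
    if any("|RY=" in k for k in keys):
        return POOLED48_RY
    if all(canonical_context(k) == k for k in keys) and len(keys) < 256:
        return COMPLEMENT_COMBINED
    return RAW256


def read_matrix_tsv(path, level: str | None = None) -> ContextMatrixSet:
    df = pd.read_csv(path, sep="\t", comment="#")
    matrices: dict[str, np.ndarray] = {}
    for ctx, grp in df.groupby("context"):
        m = np.zeros((4, 4), dtype=np.int64)
        for _, row in grp.iterrows():
            m[BASE_INDEX[row["from"]], BASE_INDEX[row["to"]]] = int(row["count"])
        matrices[str(ctx)] = m
    if level is None:
        with open(path) as fh:
            for line in fh:
                if line.startswith("# level:"):
                    level = line.split(":", 1)[1].strip()
                    break
                if not line.startswith("#"):
                    break
        level = level or _infer_level(matrices)
    return ContextMatrixSet(matrices, level=level)


def write_stationary_tsv(
    stationaries: dict[str, StationaryVector], path, metadata: dict | None = None
) -> None:
    with open(path, "w") as fh:
        _write_header(fh, metadata)
        fh.write("context\tfA\tfC\tfG\tfT\tGC_pct\tPR_AT\tPR_GC\n")
        for ctx in sorted(stationaries):
            sv = stationaries[ctx]
            f = sv.frequencies
            fh.write(
                f"{ctx}\t{f[0]:.6f}\t{f[1]:.6f}\t{f[2]:.6f}\t{f[3]:.6f}"
                f"\t{sv.gc_percent:.4f}\t{sv.pr_at:.4f}\t{sv.pr_gc:.4f}\n"
            )


def read_stationary_tsv(path) -> dict[str, StationaryVector]:
    df = pd.read_csv(path, sep="\t", comment="#")
    out = {}
    for _, row in df.iterrows():
        freqs = np.array([row["fA"], row["fC"], row["fG"], row["fT"]], dtype=float)
        out[str(row["context"])] = StationaryVector(freqs / freqs.sum(), str(row["context"]))
    return out


def write_observations_tsv(
    obs: SiteObservations, path, metadata: dict | None = None
) -> None:
    with open(path, "w") as fh:
        _write_header(fh, metadata)
        fh.write("position\tcontext\tancestral\tderived\n")
        for o in obs:
            fh.write(f"{o.alignment_position}\t{o.context}\t{o.ancestral}\t{o.derived}\n")


def write_stats_tsv(stats: list[CompositionStats], path, metadata: dict | None = None) -> None:
    with open(path, "w") as fh:
        _write_header(fh, metadata)
        df = pd.DataFrame(
            [
                {
                    "gene": s.gene_id,
                    "length_codons": s.length_codons,
                    "ENC": s.enc,
                    "GC3": s.gc3,
                    "GC3S": s.gc3s,
                    "PR_AT": s.pr_at,
                    "PR_GC": s.pr_gc,
                    "C2": s.c2,
                    "CAI": s.cai,
                }
                for s in stats
            ]
        )
        df.to_csv(fh, sep="\t", index=False, float_format="%.4f")


def read_cds_fasta(path) -> list[tuple[str, str]]:
    """(id, sequence) per record, uppercased."""
    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(path, "fasta")]


def usages_from_fasta(path) -> list[CodonUsageTable]:
    return [
        CodonUsageTable.from_sequence(seq, gene_id=name)
        for name, seq in read_cds_fasta(path)
    ]


def write_json(obj, path, metadata: dict | None = None) -> None:
    payload = {"metadata": metadata or {}, **obj} if metadata else obj
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(value):
    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, (np.integer, np.floating)):
        return value.item()
    raise TypeError(f"not JSON serializable: {type(value)}")
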