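"""Enrichment scoring and hit calling for T0 vs selected count tables.

The selection readout is qualitative — surviving (or sorted) cells carry the
protective peptides, and hits are ranked by selected-sample read abundance.
The computational stand-in implemented here scores each peptide by the
pseudocounted log2 ratio of its normalized post-selection frequency to its
baseline frequency, and calls a hit when the score clears a threshold and
the selected-sample raw count clears an abundance floor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .screen_readout import ScreenCountTable, normalize

DEFAULT_SCORE_MIN = 3.0
DEFAULT_READS_MIN = 100


@dataclass
class EnrichmentRecord:
    """Per-peptide enrichment: score = log2((f_sel + a_sel) / (f_T0 + a_T0)),
    with per-sample pseudocounts a; rank is 1-based by selected raw count
    descending (ties broken lexicographically by peptide)."""

    peptide: str
    f_t0: float
    f_sel: float
    score: float
    reads_sel: int
    rank: int = 0
    is_hit: bool = False


def _norm_freq(table: ScreenCountTable, sample: str) -> pd.Series:
    if table.norm_freq is None:
        table = normalize(table)
    return table.norm_freq[sample]


def score_enrichment(
    t0: ScreenCountTable,
    selected: ScreenCountTable,
    pseudocount: float | None = None,
) -> list[EnrichmentRecord]:
    """Score every peptide's enrichment between T0 and the selected sample.

    Both tables must carry exactly one sample over the same peptide
    universe. The default pseudocount is half a read in each sample's
    normalized-frequency units (0.5 * scalar / sample-total), which keeps
    scores finite for peptides absent from either sample. Records are
    returned in rank order.
    """
    if len(t0.samples) != 1 or len(selected.samples) != 1:
        raise ValueError("score_enrichment expects single-sample tables")
    if set(t0.peptides) != set(selected.peptides):
        raise ValueError("T0 and selected tables cover different peptide universes")
    s_t0, s_sel = t0.samples[0], selected.samples[0]
    f_t0 = _norm_freq(t0, s_t0)
    f_sel = _norm_freq(selected, s_sel).reindex(f_t0.index)
    raw_sel = selected.counts[s_sel].reindex(f_t0.index)
    if pseudocount is None:
        a_t0 = 0.5 * t0.scalar / t0.counts[s_t0].sum()
        a_sel = 0.5 * selected.scalar / selected.counts[s_sel].sum()
    else:
        a_t0 = a_sel = float(pseudocount)
    records = [
        EnrichmentRecord(
            peptide=pep,
            f_t0=float(f_t0[pep]),
            f_sel=float(f_sel[pep]),
            score=math.log2((f_sel[pep] + a_sel) / (f_t0[pep] + a_t0)),
            reads_sel=int(raw_sel[pep]),
        )
        for pep in f_t0.index
    ]
    records.sort(key=lambda r: (-r.reads_sel, r.peptide))
    for i, rec in enumerate(records, start=1):
        rec.rank = i
    return records


def call_hits(
    records: list[EnrichmentRecord],
    score_min: float = DEFAULT_SCORE_MIN,
    reads_min: int = DEFAULT_READS_MIN,
) -> list[EnrichmentRecord]:
    """Call hits: score >= score_min AND selected raw count >= reads_min.

    Sets ``is_hit`` on the input records and returns the hits ranked by
    selected-sample read count (most abundant first).
    """
    hits = []
    for rec in records:
        rec.is_hit = rec.score >= score_min and rec.reads_sel >= reads_min
        if rec.is_hit:
            hits.append(rec)
    hits.sort(key=lambda r: r.rank)
    return hits


def intersect_screens(
    per_screen_hits: list[list[EnrichmentRecord]],
) -> tuple[pd.DataFrame, str | None]:
    """Intersect ranked hit sets from parallel screens.

    Returns a consensus table (one row per peptide present in every
    screen's hit set, with per-screen ranks) and the peptide that is rank-1
    in every screen, or None when no such peptide exists.
    """
    if not per_screen_hits:
        raise ValueError("at least one screen required")
    sets = [{r.peptide for r in hits} for hits in per_screen_hits]
    consensus = set.intersection(*sets)
    rank_maps = [{r.peptide: r.rank for r in hits} for hits in per_screen_hits]
    rows = {
        pep: [rm[pep] for rm in rank_maps] for pep in sorted(consensus)
    }
    frame = pd.DataFrame.from_dict(
        rows, orient="index",
        columns=[f"rank_screen{i + 1}" for i in range(len(per_screen_hits))],
    )
    frame.index.name = "peptide"
    top = None
    for pep, ranks in rows.items():
        if all(r == 1 for r in ranks):
            top = pep
            break
    return frame, top


def enrichment_to_tsv(records: list[EnrichmentRecord], path: str | Path) -> None:
    """Write the enrichment table as TSV."""
    frame = pd.DataFrame(
        [
            (r.peptide, r.f_t0, r.f_sel, r.score, r.reads_sel, r.rank, r.is_hit)
            for r in records
        ],
        columns=["peptide", "f_T0", "f_sel", "score", "reads_sel", "rank", "is_hit"],
    )
    frame.to_csv(path, sep="\t", index=False)


def enrichment_from_tsv(path: str | Path) -> list[EnrichmentRecord]:
    """Read an enrichment table written by :func:`enrichment_to_tsv`."""
    frame = pd.read_csv(path, sep="\t")
    return [
        EnrichmentRecord(
            peptide=row.peptide, f_t0=row.f_T0, f_sel=row.f_sel, score=row.score,
            reads_sel=int(row.reads_sel), rank=int(row.rank), is_hit=bool(row.is_hit),
        )
        for row in frame.itertuples()
    ]
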