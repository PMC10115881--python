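"""C-terminal heptamer peptide library construction.

The pooled screen expresses, for every protein in a proteome, its C-terminal
k-mer (k = 7 by default) as a GFP-fused peptide; the amino-acid sequence of
the peptide later serves as its own sequencing barcode. This module builds
the deduplicated peptide set and maintains the peptide -> source-protein
mapping needed to trace a hit back to the proteins it came from.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Residues that cannot be encoded unambiguously by a single codon choice;
#: peptides containing them are excluded from the library.
AMBIGUOUS_RESIDUES = frozenset("XBZJUO*")

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class PeptideLibrary:
    """Deduplicated k-mer peptide set with peptide -> source-protein mapping.

    Attributes
    ----------
    peptides:
        The distinct library peptides, all of length ``k``.
    sources:
        Mapping of each peptide to the set of protein identifiers whose
        C-terminus it is. Every peptide maps to at least one source.
    k:
        Peptide length in residues.
    skipped:
        Protein identifiers excluded from the library, keyed by reason
        (``"too_short"`` or ``"ambiguous"``).
    """

    peptides: set[str]
    sources: dict[str, set[str]]
    k: int = 7
    skipped: dict[str, list[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.peptides)

    def __contains__(self, peptide: str) -> bool:
        return peptide in self.peptides


def as_protein_dict(proteome) -> dict[str, str]:
    """Normalize a proteome to ``{identifier: uppercase sequence}``.

    Accepts a mapping, an iterable of ``(id, sequence)`` pairs, or an
    iterable of Biopython ``SeqRecord`` objects.
    """
    if isinstance(proteome, Mapping):
        items: Iterable = proteome.items()
    else:
        proteome = list(proteome)
        if proteome and hasattr(proteome[0], "seq"):
            items = ((rec.id, str(rec.seq)) for rec in proteome)
        else:
            items = proteome
    out: dict[str, str] = {}
    for pid, seq in items:
        if pid in out:
            raise ValueError(f"duplicate protein identifier: {pid!r}")
        out[pid] = str(seq).upper()
    return out


def build_cterm_library(proteome, k: int = 7) -> PeptideLibrary:
    """Build the C-terminal k-mer library from a proteome.

    Every protein of length >= k contributes its C-terminal k-mer; proteins
    sharing a C-terminus collapse onto one peptide with merged source sets.
    Proteins shorter than k, or whose C-terminal k-mer contains ambiguous
    residues (X, B, Z, ...), are skipped and logged.

    Parameters
    ----------
    proteome:
        Mapping / pairs / SeqRecords, see :func:`as_protein_dict`.
    k:
        Peptide length, default 7.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    records = as_protein_dict(proteome)
    if not records:
        logger.warning("empty proteome: returning empty library")
        return PeptideLibrary(peptides=set(), sources={}, k=k)

    sources: dict[str, set[str]] = {}
    skipped: dict[str, list[str]] = {"too_short": [], "ambiguous": []}
    for pid, seq in records.items():
        if len(seq) < k:
            skipped["too_short"].append(pid)
            continue
        pep = seq[-k:]
        if AMBIGUOUS_RESIDUES & set(pep):
            skipped["ambiguous"].append(pid)
            continue
        sources.setdefault(pep, set()).add(pid)
    for reason, ids in skipped.items():
        if ids:
            logger.info("skipped %d proteins (%s)", len(ids), reason)
    return PeptideLibrary(peptides=set(sources), sources=sources, k=k,
                          skipped={r: v for r, v in skipped.items() if v})


def lookup_sources(library: PeptideLibrary, peptide: str) -> set[str]:
    """Source proteins for a peptide; empty set if it is not in the library."""
    return set(library.sources.get(peptide, set()))


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a protein FASTA file into ``{identifier: sequence}``."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_library_tsv(library: PeptideLibrary, path: str | Path) -> None:
    """Write ``peptide<TAB>source;source;...`` rows, peptides sorted."""
    with open(path, "w") as fh:
        fh.write("peptide\tsources\n")
        for pep in sorted(library.peptides):
            fh.write(f"{pep}\t{';'.join(sorted(library.sources[pep]))}\n")


def read_library_tsv(path: str | Path, k: int | None = None) -> PeptideLibrary:
    """Read a library written by :func:`write_library_tsv`."""
    sources: dict[str, set[str]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("peptide"):
            raise ValueError(f"unexpected header in {path}: {header!r}")
        for line in fh:
            pep, srcs = line.rstrip("\n").split("\t")
            sources[pep] = set(srcs.split(";")) if srcs else set()
    if k is None:
        k = len(next(iter(sources))) if sources else 7
    return PeptideLibrary(peptides=set(sources), sources=sources, k=k)
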