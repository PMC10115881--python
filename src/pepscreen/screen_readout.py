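"""Screen sequencing readout: FASTQ -> per-sample peptide count tables.

The screen uses the peptide-coding sequence itself as the barcode: each read
carries a fixed upstream adapter, a 3k-nucleotide coding window, and a fixed
downstream adapter. Reads are kept when their arithmetic mean per-base Phred
score is strictly greater than 30, the coding window is translated with the
standard genetic code, and the translated k-mer is matched exactly against
the peptide library. Counts are normalized to the per-sample total and
scaled (counts-per-million by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
import pysam
from Bio.Data import CodonTable

DEFAULT_SCALAR = 1e6
DEFAULT_MIN_MEAN_PHRED = 30.0

# Full standard genetic code, stops as '*'.
_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_STANDARD_TABLE.forward_table)
CODON_TO_AA.update({c: "*" for c in _STANDARD_TABLE.stop_codons})


@dataclass(frozen=True)
class FlankSpec:
    """Fixed sequence context flanking the peptide-coding window of a read."""

    upstream: str
    downstream: str


#: Default read architecture used by the synthetic FASTQ generator.
DEFAULT_FLANKS = FlankSpec(upstream="GGAGGTGGCGGA", downstream="GGATCCGGAGGC")


@dataclass
class QCTally:
    """Per-sample read accounting through filtering and matching."""

    total: int = 0
    passed: int = 0
    failed_quality: int = 0
    matched: int = 0
    unmatched: int = 0


@dataclass
class ScreenCountTable:
    """Per-sample peptide counts plus normalized frequencies.

    ``counts`` is a peptides x samples integer DataFrame. ``norm_freq``
    holds count / sample-total * scalar (populated by :func:`normalize`).
    """

    counts: pd.DataFrame
    scalar: float = DEFAULT_SCALAR
    norm_freq: pd.DataFrame | None = None
    qc: dict[str, QCTally] = field(default_factory=dict)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def peptides(self) -> list[str]:
        return list(self.counts.index)

    def sample(self, name: str) -> "ScreenCountTable":
        """A single-sample view of this table (counts, norm_freq, qc)."""
        if name not in self.counts.columns:
            raise KeyError(f"unknown sample {name!r}")
        return ScreenCountTable(
            counts=self.counts[[name]],
            scalar=self.scalar,
            norm_freq=None if self.norm_freq is None else self.norm_freq[[name]],
            qc={name: self.qc[name]} if name in self.qc else {},
        )

    def to_tsv(self, path: str | Path) -> None:
        """Write raw counts (and normalized frequencies if present)."""
        path = Path(path)
        self.counts.to_csv(path, sep="\t", index_label="peptide")
        if self.norm_freq is not None:
            norm_path = path.with_name(path.stem + ".norm" + path.suffix)
            self.norm_freq.to_csv(norm_path, sep="\t", index_label="peptide")

    @classmethod
    def from_tsv(cls, path: str | Path, scalar: float = DEFAULT_SCALAR) -> "ScreenCountTable":
        counts = pd.read_csv(path, sep="\t", index_col="peptide")
        return cls(counts=counts, scalar=scalar)


FastqRead = tuple[str, str, str]  # (name, sequence, quality string)


def read_fastq(path: str | Path) -> Iterator[FastqRead]:
    """Stream (name, sequence, quality) tuples from a FASTQ file.

    Plain or gzip-compressed Sanger Phred+33 FASTQ, via pysam/htslib.
    """
    with pysam.FastxFile(str(path)) as fx:
        for entry in fx:
            if entry.quality is None:
                raise ValueError(f"record {entry.name!r} lacks a quality string")
            yield entry.name, entry.sequence, entry.quality


def mean_phred(quality: str) -> float:
    """Arithmetic mean of the integer per-base Phred scores of a read."""
    if not quality:
        raise ValueError("empty quality string")
    raw = quality.encode("ascii")
    return (sum(raw) - 33 * len(raw)) / len(raw)


def filter_reads(
    reads: Iterable[FastqRead],
    min_mean_phred: float = DEFAULT_MIN_MEAN_PHRED,
) -> tuple[list[FastqRead], QCTally]:
    """Keep reads whose mean per-base Phred is strictly above the threshold.

    Returns the passing reads and a tally of total / passed / failed reads.
    Malformed records (sequence and quality lengths differing) raise a
    ValueError naming the record.
    """
    passing: list[FastqRead] = []
    tally = QCTally()
    for name, seq, qual in reads:
        if len(seq) != len(qual):
            raise ValueError(
                f"malformed FASTQ record {name!r}: sequence length "
                f"{len(seq)} != quality length {len(qual)}"
            )
        tally.total += 1
        if mean_phred(qual) > min_mean_phred:
            tally.passed += 1
            passing.append((name, seq, qual))
        else:
            tally.failed_quality += 1
    return passing, tally


def _translate_window(window: str) -> str | None:
    """Translate a coding window; None on stop codon or unknown codon."""
    aa = []
    for i in range(0, len(window), 3):
        res = CODON_TO_AA.get(window[i : i + 3])
        if res is None or res == "*":
            return None
        aa.append(res)
    return "".join(aa)


def _count_reads(
    reads: Iterable[FastqRead],
    peptides: set[str] | frozenset[str],
    k: int,
    flanks: FlankSpec,
    tally: QCTally,
) -> dict[str, int]:
    counts: dict[str, int] = {}
    up, down = flanks.upstream, flanks.downstream
    up_len, win_len = len(up), 3 * k
    for _name, seq, _qual in reads:
        i = seq.find(up)
        if i < 0:
            tally.unmatched += 1
            continue
        start = i + up_len
        end = start + win_len
        if len(seq) < end or (down and not seq.startswith(down, end)):
            tally.unmatched += 1
            continue
        pep = _translate_window(seq[start:end])
        if pep is None or pep not in peptides:
            tally.unmatched += 1
            continue
        counts[pep] = counts.get(pep, 0) + 1
        tally.matched += 1
    return counts


def extract_and_count(
    reads_by_sample: Mapping[str, Iterable[FastqRead]],
    library,
    flanks: FlankSpec = DEFAULT_FLANKS,
    scalar: float = DEFAULT_SCALAR,
) -> ScreenCountTable:
    """Count library peptides in quality-passing reads, per sample.

    The peptide-coding window is located by the upstream flank, translated
    with the standard genetic code, and matched exactly against the library.
    Reads with a missing flank, a stop codon, a truncated window, or no
    library match are tallied as unmatched. Rows cover the full library so
    unobserved peptides appear with count 0.
    """
    peptides = frozenset(library.peptides)
    index = sorted(peptides)
    columns: dict[str, list[int]] = {}
    qc: dict[str, QCTally] = {}
    for sample, reads in reads_by_sample.items():
        tally = QCTally()
        counts = _count_reads(reads, peptides, library.k, flanks, tally)
        tally.total = tally.passed = tally.matched + tally.unmatched
        columns[sample] = [counts.get(p, 0) for p in index]
        qc[sample] = tally
    frame = pd.DataFrame(columns, index=pd.Index(index, name="peptide"), dtype="int64")
    return ScreenCountTable(counts=frame, scalar=scalar, qc=qc)


def count_fastq_samples(
    fastq_by_sample: Mapping[str, str | Path],
    library,
    flanks: FlankSpec = DEFAULT_FLANKS,
    min_mean_phred: float = DEFAULT_MIN_MEAN_PHRED,
    scalar: float = DEFAULT_SCALAR,
) -> ScreenCountTable:
    """Single-pass pipeline: stream each sample's FASTQ, filter on mean
    Phred, extract/translate/match, and return the count table with full QC.

    Equivalent to ``filter_reads`` followed by ``extract_and_count`` but
    without materializing the passing reads in memory.
    """
    peptides = frozenset(library.peptides)
    index = sorted(peptides)
    columns: dict[str, list[int]] = {}
    qc: dict[str, QCTally] = {}
    for sample, path in fastq_by_sample.items():
        tally = QCTally()

        def passing(tally=tally, path=path):
            for name, seq, qual in read_fastq(path):
                if len(seq) != len(qual):
                    raise ValueError(f"malformed FASTQ record {name!r}")
                tally.total += 1
                if mean_phred(qual) > min_mean_phred:
                    tally.passed += 1
                    yield name, seq, qual
                else:
                    tally.failed_quality += 1

        counts = _count_reads(passing(), peptides, library.k, flanks, tally)
        columns[sample] = [counts.get(p, 0) for p in index]
        qc[sample] = tally
    frame = pd.DataFrame(columns, index=pd.Index(index, name="peptide"), dtype="int64")
    return ScreenCountTable(counts=frame, scalar=scalar, qc=qc)


def normalize(table: ScreenCountTable, scalar: float | None = None) -> ScreenCountTable:
    """Populate normalized frequencies: count / sample-total * scalar.

    Raises on any sample with zero total reads (the normalization is
    undefined there), naming the sample.
    """
    if scalar is None:
        scalar = table.scalar
    totals = table.counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total counts: {list(zero.index)}")
    norm = table.counts.astype("float64") / totals * scalar
    return replace(table, scalar=scalar, norm_freq=norm)
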