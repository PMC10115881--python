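"""Seeded generators for every input the screen pipeline consumes.

The generative model for the pooled screen: baseline peptide frequencies f
are drawn from a symmetric Dirichlet(alpha); the pre-selection (T0) sample
is multinomial(D, f); selection multiplies each peptide's frequency by a
survival weight e_i (1 for neutral peptides, enrichment_factor for planted
protective peptides) and renormalizes, so the selected sample is
multinomial(D, f*e / sum(f*e)). FASTQ reads encode each counted molecule as
adapter + single-codon-per-residue coding sequence + adapter with per-base
Phred qualities. FP curves are drawn from the saturation (or competitive
displacement) binding model plus Gaussian noise. All generators are
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .binding_models import BindingCurve, competition_signal, saturation_model
from .library_design import PeptideLibrary
from .screen_readout import DEFAULT_FLANKS, FastqRead, FlankSpec, ScreenCountTable

import pandas as pd

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Fixed single codon per residue (most common human codon); the screen
#: treats the peptide as its own barcode, so codon degeneracy is irrelevant.
CODON_OF: dict[str, str] = {
    "A": "GCC", "C": "TGC", "D": "GAC", "E": "GAG", "F": "TTC",
    "G": "GGC", "H": "CAC", "I": "ATC", "K": "AAG", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCC", "Q": "CAG", "R": "CGG",
    "S": "AGC", "T": "ACC", "V": "GTG", "W": "TGG", "Y": "TAC",
}


def encode_peptide(peptide: str) -> str:
    """Reverse-translate a peptide with the fixed one-codon-per-residue table."""
    try:
        return "".join(CODON_OF[aa] for aa in peptide)
    except KeyError as exc:
        raise ValueError(f"peptide {peptide!r} contains unencodable residue {exc}") from exc


# ---------------------------------------------------------------------------
# Proteome
# ---------------------------------------------------------------------------

def gen_proteome(
    n_proteins: int,
    length_range: tuple[int, int] = (50, 500),
    seed: int = 0,
) -> dict[str, str]:
    """Generate a random proteome: uniform residue composition, uniform
    lengths on ``length_range`` (inclusive). Returns ``{id: sequence}``."""
    lo, hi = length_range
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid length range {length_range}")
    rng = np.random.default_rng(seed)
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    out: dict[str, str] = {}
    lengths = rng.integers(lo, hi + 1, size=n_proteins)
    for i, length in enumerate(lengths):
        seq = aa[rng.integers(0, 20, size=int(length))].tobytes().decode()
        out[f"prot{i + 1:05d}"] = seq
    return out


def write_fasta(proteome: dict[str, str], path: str | Path, width: int = 60) -> None:
    """Write ``{id: sequence}`` as FASTA."""
    with open(path, "w") as fh:
        for pid, seq in proteome.items():
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Pooled screen counts
# ---------------------------------------------------------------------------

@dataclass
class ScreenSimConfig:
    """Generative parameters for the synthetic pooled screen.

    ``enrichment_factor`` is the multiplicative survival weight e applied to
    each planted peptide during selection (1 = neutral); ``depth`` D is the
    total reads per sample; ``dirichlet_alpha`` the concentration of the
    symmetric Dirichlet over baseline frequencies.
    """

    library_size: int = 5000
    planted_hits: int = 10
    enrichment_factor: float = 50.0
    depth: int = 1_000_000
    dirichlet_alpha: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.planted_hits > self.library_size:
            raise ValueError("planted_hits must be <= library_size")
        if self.planted_hits < 0 or self.library_size < 1:
            raise ValueError("library_size >= 1 and planted_hits >= 0 required")
        if self.enrichment_factor < 0:
            raise ValueError("enrichment_factor must be >= 0")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if self.dirichlet_alpha <= 0:
            raise ValueError("dirichlet_alpha must be > 0")


@dataclass
class ScreenSim:
    """A simulated screen: T0/selected count tables plus generative truth."""

    t0: ScreenCountTable
    selected: ScreenCountTable
    planted: list[str]
    baseline_freq: np.ndarray
    enrichment: np.ndarray
    peptides: list[str] = field(default_factory=list)


def gen_screen_counts(
    cfg: ScreenSimConfig,
    library: PeptideLibrary,
    baseline_freq: np.ndarray | None = None,
    planted_peptides: list[str] | None = None,
) -> ScreenSim:
    """Simulate T0 and post-selection count tables for a peptide library.

    T0 counts ~ multinomial(D, f), f ~ Dirichlet(alpha); selected counts
    ~ multinomial(D, f*e / sum(f*e)). The planted peptides (drawn without
    replacement from the library) carry e = enrichment_factor; all others
    e = 1. Column sums equal D exactly. ``baseline_freq`` fixes f instead
    of drawing it and ``planted_peptides`` fixes the planted identities
    (useful for studying the resampling layer alone).
    """
    if len(library) == 0:
        raise ValueError("empty peptide library")
    if len(library) != cfg.library_size:
        raise ValueError(
            f"library size {len(library)} != cfg.library_size {cfg.library_size}"
        )
    rng = np.random.default_rng(cfg.seed)
    peptides = sorted(library.peptides)
    n = len(peptides)
    if planted_peptides is not None:
        if len(planted_peptides) != cfg.planted_hits:
            raise ValueError("planted_peptides length must equal cfg.planted_hits")
        pos = {p: i for i, p in enumerate(peptides)}
        planted_idx = np.array([pos[p] for p in planted_peptides], dtype=int)
    else:
        planted_idx = rng.choice(n, size=cfg.planted_hits, replace=False)
    enrichment = np.ones(n)
    enrichment[planted_idx] = cfg.enrichment_factor
    if baseline_freq is not None:
        f = np.asarray(baseline_freq, dtype=float)
        if f.shape != (n,) or not np.isclose(f.sum(), 1.0):
            raise ValueError("baseline_freq must be a length-n probability vector")
    else:
        f = rng.dirichlet(np.full(n, cfg.dirichlet_alpha))
    w = f * enrichment
    w = w / w.sum()
    t0_counts = rng.multinomial(cfg.depth, f)
    sel_counts = rng.multinomial(cfg.depth, w)
    index = pd.Index(peptides, name="peptide")
    t0 = ScreenCountTable(pd.DataFrame({"T0": t0_counts}, index=index))
    sel = ScreenCountTable(pd.DataFrame({"selected": sel_counts}, index=index))
    return ScreenSim(
        t0=t0,
        selected=sel,
        planted=sorted(peptides[i] for i in planted_idx),
        baseline_freq=f,
        enrichment=enrichment,
        peptides=peptides,
    )


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

_PASS_MU_DEFAULT = 37.0
_FAIL_MU = 22.0
_CHUNK = 200_000


def gen_fastq(
    counts: dict[str, int] | ScreenCountTable,
    out: str | Path | None = None,
    codon_map: dict[str, str] | None = None,
    quality_model: tuple[float, float] = (_PASS_MU_DEFAULT, 2.0),
    fail_fraction: float = 0.0,
    flanks: FlankSpec = DEFAULT_FLANKS,
    seed: int = 0,
    sample: str = "sample",
) -> list[FastqRead] | Path:
    """Emit one FASTQ read per counted molecule.

    Each read is upstream flank + coding sequence + downstream flank. A
    ``fail_fraction`` of reads receives per-base qualities clipped to <= 30
    (mean <= 30, so they fail the strict mean-Phred>30 filter); the rest
    draw per-base qualities around ``quality_model`` = (mean, spread),
    clipped to >= 31. Read order is a seeded permutation.

    If ``out`` is a path, reads are written there and the path returned;
    otherwise a list of (name, sequence, quality) tuples is returned.
    """
    if not 0 <= fail_fraction <= 1:
        raise ValueError("fail_fraction must be in [0, 1]")
    if isinstance(counts, ScreenCountTable):
        if len(counts.samples) != 1:
            raise ValueError("gen_fastq takes a single-sample table")
        col = counts.samples[0]
        count_map = {p: int(c) for p, c in counts.counts[col].items() if c > 0}
    else:
        count_map = {p: int(c) for p, c in counts.items() if c > 0}

    peptides = sorted(count_map)
    if codon_map is None:
        codon_map = {p: encode_peptide(p) for p in peptides}
    else:
        missing = [p for p in peptides if p not in codon_map]
        if missing:
            raise ValueError(f"peptides lacking codon mapping: {missing[:5]}...")

    seqs = [flanks.upstream + codon_map[p] + flanks.downstream for p in peptides]
    read_len = len(seqs[0]) if seqs else 0
    if any(len(s) != read_len for s in seqs):
        raise ValueError("all peptides must yield equal-length reads")

    rng = np.random.default_rng(seed)
    pep_idx = np.repeat(
        np.arange(len(peptides)), [count_map[p] for p in peptides]
    )
    pep_idx = rng.permutation(pep_idx)
    n_reads = len(pep_idx)
    fail = rng.random(n_reads) < fail_fraction
    mu_pass, spread = quality_model

    def quality_block(lo: int, hi: int) -> list[str]:
        m = hi - lo
        mu = np.where(fail[lo:hi], _FAIL_MU, mu_pass)[:, None]
        q = np.rint(rng.normal(mu, spread, size=(m, read_len)))
        q = np.where(fail[lo:hi, None], np.clip(q, 2, 30), np.clip(q, 31, 41))
        raw = (q + 33).astype(np.uint8).tobytes()
        return [
            raw[i * read_len : (i + 1) * read_len].decode("ascii") for i in range(m)
        ]

    def records():
        for lo in range(0, n_reads, _CHUNK):
            hi = min(lo + _CHUNK, n_reads)
            quals = quality_block(lo, hi)
            for j, q in zip(range(lo, hi), quals):
                yield f"{sample}.read{j + 1}", seqs[pep_idx[j]], q

    if out is None:
        return list(records())
    out = Path(out)
    with open(out, "w") as fh:
        for name, seq, qual in records():
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")
    return out


# ---------------------------------------------------------------------------
# Fluorescence polarization curves
# ---------------------------------------------------------------------------

def dilution_series(top_uM: float = 30.0, n_points: int = 12) -> np.ndarray:
    """1:1 (two-fold) serial dilution from ``top_uM``, strictly decreasing."""
    return top_uM / 2.0 ** np.arange(n_points)


@dataclass
class FPSimConfig:
    """Generative parameters for a synthetic FP saturation curve.

    Defaults mirror the assay design: probe constant at 50 nM, receptor
    serially diluted 1:1 from 30 uM (12 points), 5 replicates, 2 mp noise.
    """

    kd: float = 1.8                # uM
    bmax: float = 150.0            # mp
    background: float = 50.0       # mp
    hill: float = 1.0
    noise_sd: float = 2.0          # mp
    replicates: int = 5
    series: np.ndarray | None = None   # receptor concentrations, uM
    probe_conc_nM: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.series is None:
            self.series = dilution_series()
        self.series = np.asarray(self.series, dtype=float)
        if np.any(self.series <= 0) or self.kd <= 0 or self.probe_conc_nM <= 0:
            raise ValueError("all concentrations must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def gen_fp_curve(cfg: FPSimConfig) -> BindingCurve:
    """Synthetic saturation FP curve: model + Normal(0, noise_sd) noise."""
    rng = np.random.default_rng(cfg.seed)
    x = np.tile(cfg.series, cfg.replicates)
    rep = np.repeat(np.arange(1, cfg.replicates + 1), len(cfg.series))
    y = saturation_model(x, cfg.kd, cfg.bmax, cfg.background, cfg.hill)
    if cfg.noise_sd > 0:
        y = y + rng.normal(0.0, cfg.noise_sd, size=y.shape)
    return BindingCurve(
        X=x, Y=y, replicate=rep, role="saturation", probe_conc_nM=cfg.probe_conc_nM
    )


@dataclass
class CompetitionSimConfig:
    """Generative parameters for a synthetic competitive-displacement curve.

    Defaults mirror the competition assay: probe 50 nM, receptor held at
    1 uM, competitor serially diluted 1:1 from 30 uM.
    """

    ki: float = 0.64               # uM
    kd_probe: float = 1.8          # uM
    receptor_conc_uM: float = 1.0
    probe_conc_nM: float = 50.0
    bmax: float = 150.0
    background: float = 50.0
    noise_sd: float = 2.0
    replicates: int = 5
    series: np.ndarray | None = None   # competitor concentrations, uM
    include_zero: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.series is None:
            self.series = dilution_series()
        self.series = np.asarray(self.series, dtype=float)
        if self.ki <= 0 or self.kd_probe <= 0 or self.receptor_conc_uM <= 0:
            raise ValueError("all constants must be > 0")
        if self.noise_sd < 0 or self.replicates < 1:
            raise ValueError("noise_sd >= 0 and replicates >= 1 required")


def gen_competition_curve(cfg: CompetitionSimConfig) -> BindingCurve:
    """Synthetic displacement curve from the exact competitive equilibrium."""
    rng = np.random.default_rng(cfg.seed)
    series = cfg.series
    if cfg.include_zero:
        series = np.concatenate([series, [0.0]])
    x = np.tile(series, cfg.replicates)
    rep = np.repeat(np.arange(1, cfg.replicates + 1), len(series))
    y = competition_signal(
        x, cfg.ki, cfg.kd_probe, cfg.probe_conc_nM, cfg.receptor_conc_uM,
        cfg.bmax, cfg.background,
    )
    if cfg.noise_sd > 0:
        y = y + rng.normal(0.0, cfg.noise_sd, size=y.shape)
    return BindingCurve(
        X=x, Y=y, replicate=rep, role="competition",
        probe_conc_nM=cfg.probe_conc_nM, receptor_conc_uM=cfg.receptor_conc_uM,
    )


# ---------------------------------------------------------------------------
# Interface fixture
# ---------------------------------------------------------------------------

def gen_interface_fixture(
    n_complexes: int,
    planted: tuple[str, str] | None = None,
    go_universe: list[str] | None = None,
    pd_terms: list[str] | None = None,
    seed: int = 0,
    planted_complex_id: str | None = None,
):
    """Generate a small structure-interface fixture.

    Each complex has two protein partners, full chain sequences, and one or
    two interface segments per partner (substrings of the chain at stated
    1-based coordinates), plus per-protein GO annotations drawn from
    ``go_universe``. When ``planted = (peptide, segment)`` is given, exactly
    one complex carries the planted segment verbatim as an interface segment
    on one partner, and both partners of that complex share two disease
    (pd_terms) annotations so the planted match also ranks well.
    """
    from .target_deconvolution import InterfaceComplex, InterfaceFixture, Segment

    if planted is not None and len(planted[1]) < len(planted[0]):
        raise ValueError("planted segment must be at least as long as the peptide")
    rng = np.random.default_rng(seed)
    if go_universe is None:
        go_universe = [f"GO:{i:07d}" for i in range(1, 41)]
    if pd_terms is None:
        k = min(8, len(go_universe))
        pd_terms = [go_universe[i] for i in rng.choice(len(go_universe), k, replace=False)]
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)

    def random_seq(length: int) -> str:
        return aa[rng.integers(0, 20, size=length)].tobytes().decode()

    planted_at = int(rng.integers(n_complexes)) if (planted and n_complexes) else -1
    complexes: list[InterfaceComplex] = []
    annotations: dict[str, set[str]] = {}
    for c in range(n_complexes):
        cid = f"C{c + 1:03d}"
        partners = (f"{cid}_A", f"{cid}_B")
        chains: dict[str, str] = {}
        segments: list[Segment] = []
        for p, partner in enumerate(partners):
            chain = random_seq(int(rng.integers(80, 200)))
            if c == planted_at and p == 1:
                _pep, seg = planted
                pos = int(rng.integers(10, len(chain) - len(seg) - 10))
                chain = chain[:pos] + seg + chain[pos + len(seg):]
                segments.append(Segment(partner=partner, sequence=seg, start=pos + 1))
            for _ in range(int(rng.integers(1, 3))):
                seg_len = int(rng.integers(10, 19))
                pos = int(rng.integers(0, len(chain) - seg_len + 1))
                segments.append(
                    Segment(partner=partner, sequence=chain[pos : pos + seg_len],
                            start=pos + 1)
                )
            chains[partner] = chain
            n_terms = int(rng.integers(3, 9))
            terms = {go_universe[i] for i in rng.choice(len(go_universe), n_terms, replace=False)}
            annotations[partner] = terms
        if c == planted_at:
            shared = set(pd_terms[:2])
            for partner in partners:
                annotations[partner] |= shared
            if planted_complex_id is not None:
                cid = planted_complex_id
                partners = (f"{cid}_A", f"{cid}_B")
                # re-key chains/annotations under the requested id
                old_a, old_b = chains.keys()
                chains = dict(zip(partners, chains.values()))
                segments = [
                    Segment(partner=partners[0] if s.partner == old_a else partners[1],
                            sequence=s.sequence, start=s.start)
                    for s in segments
                ]
                annotations[partners[0]] = annotations.pop(old_a)
                annotations[partners[1]] = annotations.pop(old_b)
        complexes.append(
            InterfaceComplex(complex_id=cid, partners=partners,
                             segments=segments, chain_sequences=chains)
        )
    return InterfaceFixture(
        complexes=complexes, annotations=annotations, pd_terms=set(pd_terms)
    )
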