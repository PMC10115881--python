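"""Structural target deconvolution of hit peptides.

A hit peptide is a candidate short linear motif (SLiM). To find the
protein-protein interaction it mimics, the peptide is slid across the
interface segments of a collection of structure complexes, keeping every
window within a bounded Hamming distance (three mismatches by default).
Candidate complexes are then ranked by sequence identity and by how many
disease-enriched GO terms the two interaction partners share, and extended
peptide variants are proposed from the source chain around the best-match
window. Interface segments can be supplied directly (fixture) or derived
from two-chain coordinates by a heavy-atom distance cutoff.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

DEFAULT_MAX_MISMATCH = 3
DEFAULT_CONTACT_CUTOFF = 5.0   # Angstrom, heavy-atom distance
DEFAULT_MIN_RUN = 5            # residues


# ---------------------------------------------------------------------------
# Fixture types
# ---------------------------------------------------------------------------

@dataclass
class Segment:
    """An interface segment: contiguous chain residues in contact with the
    partner chain. ``start`` is the 1-based, inclusive position of the
    segment's first residue on the full chain."""

    partner: str
    sequence: str
    start: int


@dataclass
class InterfaceComplex:
    complex_id: str
    partners: tuple[str, str]
    segments: list[Segment]
    chain_sequences: dict[str, str]


@dataclass
class InterfaceFixture:
    """Structure complexes with interface segments and GO annotations.

    ``pd_terms`` is the disease-enriched GO term set (an input list; GO
    enrichment itself is upstream of this package).
    """

    complexes: list[InterfaceComplex]
    annotations: dict[str, set[str]] = field(default_factory=dict)
    pd_terms: set[str] = field(default_factory=set)

    def validate(self) -> None:
        for cplx in self.complexes:
            for seg in cplx.segments:
                chain = cplx.chain_sequences.get(seg.partner)
                if chain is None:
                    raise ValueError(
                        f"{cplx.complex_id}: segment partner {seg.partner!r} "
                        f"has no chain sequence"
                    )
                s = seg.start - 1
                if chain[s : s + len(seg.sequence)] != seg.sequence:
                    raise ValueError(
                        f"{cplx.complex_id}: segment {seg.sequence!r} does not "
                        f"match chain {seg.partner!r} at position {seg.start}"
                    )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "complexes": [
                {
                    "complex_id": c.complex_id,
                    "partners": list(c.partners),
                    "segments": [asdict(s) for s in c.segments],
                    "chain_sequences": c.chain_sequences,
                }
                for c in self.complexes
            ],
            "annotations": {k: sorted(v) for k, v in self.annotations.items()},
            "pd_terms": sorted(self.pd_terms),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "InterfaceFixture":
        payload = json.loads(Path(path).read_text())
        complexes = [
            InterfaceComplex(
                complex_id=c["complex_id"],
                partners=tuple(c["partners"]),
                segments=[Segment(**s) for s in c["segments"]],
                chain_sequences=c["chain_sequences"],
            )
            for c in payload["complexes"]
        ]
        annotations = {k: set(v) for k, v in payload["annotations"].items()}
        return cls(complexes=complexes, annotations=annotations,
                   pd_terms=set(payload["pd_terms"]))


@dataclass
class InterfaceMatch:
    """A peptide placed on an interface-segment window.

    ``offset`` is the 1-based position of the window's first residue on the
    full chain; ``identity`` = (k - mismatches) / k; ``is_best`` marks the
    minimum-mismatch window of its (peptide, segment) pair (leftmost on
    ties)."""

    peptide: str
    complex_id: str
    partner: str
    offset: int
    window: str
    mismatches: int
    identity: float
    pd_go_count: int | None = None
    rank: int | None = None
    is_best: bool = False


# ---------------------------------------------------------------------------
# Scanning and ranking
# ---------------------------------------------------------------------------

def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def scan_peptide(
    peptide: str,
    fixture: InterfaceFixture,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
) -> list[InterfaceMatch]:
    """Slide the peptide across every interface segment, keeping windows
    within ``max_mismatch`` Hamming distance.

    Segments shorter than the peptide yield no windows. Within each
    (peptide, segment) pair the minimum-distance window is flagged
    ``is_best`` (leftmost on ties).
    """
    if not peptide:
        raise ValueError("empty peptide")
    k = len(peptide)
    matches: list[InterfaceMatch] = []
    for cplx in fixture.complexes:
        for seg in cplx.segments:
            seg_matches: list[InterfaceMatch] = []
            for i in range(len(seg.sequence) - k + 1):
                window = seg.sequence[i : i + k]
                mm = hamming(peptide, window)
                if mm <= max_mismatch:
                    seg_matches.append(
                        InterfaceMatch(
                            peptide=peptide,
                            complex_id=cplx.complex_id,
                            partner=seg.partner,
                            offset=seg.start + i,
                            window=window,
                            mismatches=mm,
                            identity=(k - mm) / k,
                        )
                    )
            if seg_matches:
                best = min(seg_matches, key=lambda m: (m.mismatches, m.offset))
                best.is_best = True
            matches.extend(seg_matches)
    return matches


def count_pd_go(
    cplx: InterfaceComplex,
    annotations: dict[str, set[str]],
    pd_terms: set[str],
) -> int:
    """Disease GO terms shared by BOTH partners of a complex:
    ``|pd_terms & annotation(partner1) & annotation(partner2)|``.
    Partners without annotations contribute an empty set (logged)."""
    terms = set(pd_terms)
    for partner in cplx.partners:
        ann = annotations.get(partner)
        if ann is None:
            logger.info("no GO annotations for %s; treating as empty", partner)
            ann = set()
        terms &= ann
    return len(terms)


def annotate_pd_go(
    matches: list[InterfaceMatch], fixture: InterfaceFixture
) -> list[InterfaceMatch]:
    """Fill ``pd_go_count`` on each match from its complex's partners."""
    by_id = {c.complex_id: c for c in fixture.complexes}
    for m in matches:
        m.pd_go_count = count_pd_go(by_id[m.complex_id], fixture.annotations,
                                    fixture.pd_terms)
    return matches


def rank_matches(matches: list[InterfaceMatch]) -> list[InterfaceMatch]:
    """Sort matches by (mismatches asc, pd_go_count desc, complex_id asc),
    with partner and offset as final deterministic tie-breaks; assign
    1-based ranks. ``pd_go_count`` must be populated first."""
    for m in matches:
        if m.pd_go_count is None:
            raise ValueError(f"pd_go_count not populated for match on {m.complex_id}")
    ranked = sorted(
        matches,
        key=lambda m: (m.mismatches, -m.pd_go_count, m.complex_id, m.partner, m.offset),
    )
    for i, m in enumerate(ranked, start=1):
        m.rank = i
    return ranked


def deconvolve(
    peptide: str,
    fixture: InterfaceFixture,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
) -> list[InterfaceMatch]:
    """Full deconvolution: scan, keep the best window per segment, annotate
    disease-GO sharing, and rank."""
    matches = [m for m in scan_peptide(peptide, fixture, max_mismatch) if m.is_best]
    return rank_matches(annotate_pd_go(matches, fixture))


def matches_to_tsv(matches: list[InterfaceMatch], path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            (m.peptide, m.complex_id, m.partner, m.offset, m.window,
             m.mismatches, m.identity, m.pd_go_count, m.rank)
            for m in matches
        ],
        columns=["peptide", "complex_id", "partner", "offset", "window",
                 "mismatches", "identity", "pd_go_count", "rank"],
    )
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Peptide extension
# ---------------------------------------------------------------------------

def propose_extensions(
    match: InterfaceMatch,
    lengths: list[int],
    fixture: InterfaceFixture,
) -> list[str]:
    """Propose extended peptide variants from the source chain.

    For each requested length L >= k, returns every length-L substring of
    the matched chain that fully contains the match window, in N-to-C
    order. Lengths exceeding the chain are skipped with a warning.
    """
    by_id = {c.complex_id: c for c in fixture.complexes}
    chain = by_id[match.complex_id].chain_sequences[match.partner]
    k = len(match.peptide)
    s = match.offset - 1          # 0-based window start on the chain
    e = s + k                     # 0-based exclusive end
    out: list[str] = []
    for L in lengths:
        if L < k:
            raise ValueError(f"extension length {L} shorter than peptide ({k})")
        if L > len(chain):
            warnings.warn(f"length {L} exceeds chain length {len(chain)}; skipped")
            continue
        lo = max(0, e - L)
        hi = min(s, len(chain) - L)
        out.extend(chain[a : a + L] for a in range(lo, hi + 1))
    return out


# ---------------------------------------------------------------------------
# Interface extraction from coordinates
# ---------------------------------------------------------------------------

@dataclass
class ChainStructure:
    """Heavy-atom coordinates of one chain.

    ``atom_residue`` maps each atom to its residue ordinal (0-based,
    consecutive along the chain); ``sequence`` is the one-letter chain
    sequence when known."""

    chain_id: str
    coords: np.ndarray              # (n_atoms, 3)
    atom_residue: np.ndarray        # (n_atoms,)
    sequence: str | None = None

    @property
    def n_residues(self) -> int:
        return int(self.atom_residue.max()) + 1 if len(self.atom_residue) else 0


def _interfacial_residues(a: ChainStructure, b: ChainStructure, cutoff: float) -> set[int]:
    tree_b = cKDTree(b.coords)
    pairs = cKDTree(a.coords).query_ball_tree(tree_b, r=cutoff)
    return {int(a.atom_residue[i]) for i, hits in enumerate(pairs) if hits}


def _runs(residues: set[int], n_residues: int, min_run: int, bridge_gap: int = 1) -> list[tuple[int, int]]:
    """Maximal runs of flagged residues, bridging gaps <= bridge_gap, kept
    when their length is >= min_run. Returns 0-based [start, end) pairs."""
    if not residues:
        return []
    ordered = sorted(residues)
    runs: list[tuple[int, int]] = []
    start = prev = ordered[0]
    for r in ordered[1:]:
        if r - prev <= bridge_gap + 1:
            prev = r
        else:
            runs.append((start, prev + 1))
            start = prev = r
    runs.append((start, prev + 1))
    return [(s, e) for s, e in runs if e - s >= min_run]


def extract_interface_segments(
    chains: tuple[ChainStructure, ChainStructure] | list[ChainStructure],
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    min_run: int = DEFAULT_MIN_RUN,
) -> dict[str, list[Segment]]:
    """Derive interface segments from two-chain heavy-atom coordinates.

    A residue is interfacial iff any of its heavy atoms lies within
    ``cutoff`` of any heavy atom of the other chain. Maximal runs of
    interfacial residues (single-residue gaps bridged) of length >=
    ``min_run`` become segments with 1-based chain coordinates.
    """
    if len(chains) != 2:
        raise ValueError(f"exactly two chains required, got {len(chains)}")
    a, b = chains
    out: dict[str, list[Segment]] = {}
    for this, other in ((a, b), (b, a)):
        residues = _interfacial_residues(this, other, cutoff)
        segs = []
        for s, e in _runs(residues, this.n_residues, min_run):
            seq = this.sequence[s:e] if this.sequence else ""
            segs.append(Segment(partner=this.chain_id, sequence=seq, start=s + 1))
        out[this.chain_id] = segs
    return out


_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


def read_pdb_chains(path: str | Path) -> list[ChainStructure]:
    """Read heavy-atom chain coordinates from a PDB file (first model)."""
    import gemmi

    structure = gemmi.read_structure(str(path))
    structure.setup_entities()
    chains: list[ChainStructure] = []
    model = structure[0]
    for chain in model:
        coords, residue_idx, seq = [], [], []
        for ri, res in enumerate(chain):
            seq.append(_THREE_TO_ONE.get(res.name.upper(), "X"))
            for atom in res:
                if atom.element.name == "H":
                    continue
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                residue_idx.append(ri)
        if coords:
            chains.append(
                ChainStructure(
                    chain_id=chain.name,
                    coords=np.asarray(coords, dtype=float),
                    atom_residue=np.asarray(residue_idx, dtype=int),
                    sequence="".join(seq),
                )
            )
    return chains
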