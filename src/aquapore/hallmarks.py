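"""Aquaporin sequence hallmarks: ORF, pI/MW, motifs, hydropathy, ar/R mapping, in-silico PCR.

Water-selective aquaporins share a compact set of sequence signatures: two
Asn-Pro-Ala (NPA) boxes on the pore-lining hemi-helices, six transmembrane
stretches detectable as hydrophobic runs, an aromatic/arginine (ar/R)
selectivity filter of four residues, and, in insect Drip channels, a
C-terminus ending in "SYDF".  This module locates those features on cDNA
or protein records and additionally performs degenerate in-silico PCR.

All coordinates are 1-based inclusive.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

__all__ = [
    "SequenceRecord",
    "OrfResult",
    "ProteinAnnotation",
    "PcrProduct",
    "HydropathyProfile",
    "AlignmentResult",
    "FilterSite",
    "IUPAC_DNA",
    "find_longest_orf",
    "protein_mw",
    "protein_pi",
    "scan_motif",
    "cterm_motif",
    "hydropathy_profile",
    "global_align",
    "map_selectivity_filter",
    "in_silico_pcr",
    "variant_length_diff",
    "annotate_transcript",
    "reverse_complement",
]

#: IUPAC nucleotide degeneracy codes -> the set of concrete bases matched.
IUPAC_DNA: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_IUPAC_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D",
    "S": "S", "W": "W", "N": "N",
}

_PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")
_STOPS = {"TAA", "TAG", "TGA"}


def _load_table(name: str) -> dict:
    with resources.files("aquapore.data").joinpath(name).open() as fh:
        return json.load(fh)


_MASSES = _load_table("residue_masses.json")
_PKA = _load_table("pka_bjellqvist.json")
_KD = _load_table("kyte_doolittle.json")["values"]


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide or protein sequence (upper-case, IUPAC-checked)."""

    id: str
    alphabet: str  # "dna" | "protein"
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("empty sequence")
        if self.alphabet == "dna":
            allowed = set(IUPAC_DNA)
        elif self.alphabet == "protein":
            allowed = _PROTEIN_ALPHABET | {"X"}
        else:
            raise ValueError(f"alphabet must be 'dna' or 'protein', got {self.alphabet!r}")
        bad = set(self.residues) - allowed
        if bad:
            raise ValueError(f"invalid {self.alphabet} characters: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)


def reverse_complement(seq: str) -> str:
    """Reverse complement honoring IUPAC degeneracy codes."""
    try:
        return "".join(_IUPAC_COMPLEMENT[b] for b in reversed(seq.upper()))
    except KeyError as exc:
        raise ValueError(f"not a nucleotide code: {exc.args[0]!r}") from None


@dataclass(frozen=True)
class OrfResult:
    """Longest forward-strand ORF: 1-based nucleotide span (stop included)."""

    start: int
    end: int
    protein: str  # stop excluded

    @property
    def length_aa(self) -> int:
        return len(self.protein)


def find_longest_orf(seq: SequenceRecord | str) -> OrfResult | None:
    """Longest ATG-to-stop span over the three forward reading frames.

    Ties are broken by the smaller start coordinate.  Returns None when no
    complete ORF exists.  The search is forward-strand only, as for
    oriented mRNA/RACE products.
    """
    nt = seq.residues if isinstance(seq, SequenceRecord) else str(seq).upper()
    if len(nt) < 6:
        raise ValueError("sequence shorter than two codons")
    best: OrfResult | None = None
    for frame in range(3):
        start_idx: int | None = None
        for i in range(frame, len(nt) - 2, 3):
            codon = nt[i : i + 3]
            if start_idx is None:
                if codon == "ATG":
                    start_idx = i
            elif codon in _STOPS:
                span = i + 3 - start_idx
                if best is None or span > (best.end - best.start + 1) or (
                    span == (best.end - best.start + 1) and start_idx + 1 < best.start
                ):
                    protein = str(Seq(nt[start_idx : i + 3]).translate())[:-1]
                    best = OrfResult(start=start_idx + 1, end=i + 3, protein=protein)
                start_idx = None
    return best


def protein_mw(protein: str) -> float:
    """Average molecular mass in daltons (ExPASy residue masses + one water)."""
    if not protein:
        raise ValueError("empty protein")
    masses = _MASSES["residues"]
    try:
        return sum(masses[aa] for aa in protein) + _MASSES["water"]
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r}") from None


def _net_charge(ph: float, counts: dict[str, int], nterm: str, cterm: str) -> float:
    pos, neg = _PKA["positive"], _PKA["negative"]
    nterm_pka = _PKA["nterm_by_residue"].get(nterm, pos["Nterm"])
    cterm_pka = _PKA["cterm_by_residue"].get(cterm, neg["Cterm"])
    charge = 1.0 / (1.0 + 10 ** (ph - nterm_pka))
    charge -= 1.0 / (1.0 + 10 ** (cterm_pka - ph))
    for aa, pka in pos.items():
        if aa != "Nterm" and counts.get(aa):
            charge += counts[aa] / (1.0 + 10 ** (ph - pka))
    for aa, pka in neg.items():
        if aa != "Cterm" and counts.get(aa):
            charge -= counts[aa] / (1.0 + 10 ** (pka - ph))
    return charge


def protein_pi(protein: str, charge_tol: float = 1e-4) -> float:
    """Isoelectric point by bisection on the Henderson-Hasselbalch net charge.

    Uses the Bjellqvist pKa set (residue-specific terminal pKas included),
    iterating until the absolute net charge falls below ``charge_tol``.
    """
    if not protein:
        raise ValueError("empty protein")
    bad = set(protein) - _PROTEIN_ALPHABET
    if bad:
        raise ValueError(f"unknown residues: {sorted(bad)}")
    counts = {aa: protein.count(aa) for aa in "DECYHKR"}
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        q = _net_charge(mid, counts, protein[0], protein[-1])
        if abs(q) < charge_tol:
            break
        if q > 0:
            lo = mid
        else:
            hi = mid
    return mid


def scan_motif(protein: str, motif: str) -> list[int]:
    """All 1-based start positions of an exact (possibly overlapping) motif."""
    if not motif:
        raise ValueError("empty motif")
    return [m.start() + 1 for m in re.finditer(f"(?={re.escape(motif)})", protein)]


def cterm_motif(protein: str, k: int = 4) -> str:
    """The terminal k residues of a protein."""
    if len(protein) < k:
        raise ValueError(f"protein of length {len(protein)} has no {k}-mer terminus")
    return protein[-k:]


@dataclass(frozen=True)
class HydropathyProfile:
    """Sliding-window Kyte-Doolittle means and called hydrophobic segments."""

    window: int
    centers: np.ndarray  # 1-based residue position of each full-window center
    values: np.ndarray
    segments: list[tuple[int, int]]  # 1-based inclusive center-position intervals


def hydropathy_profile(
    protein: str,
    window: int = 19,
    threshold: float = 1.6,
    min_len: int = 1,
    merge_gap: int = 3,
) -> HydropathyProfile:
    """Centered sliding-window Kyte-Doolittle hydropathy with segment calls.

    The mean is defined only where the window fits entirely inside the
    sequence.  Segments are maximal runs of centers whose mean exceeds
    ``threshold``; runs separated by at most ``merge_gap`` sub-threshold
    centers are merged, and runs shorter than ``min_len`` centers dropped.
    This is a plain hydropathy heuristic, not a topology predictor.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > len(protein):
        raise ValueError("window longer than protein")
    vals = np.array([_KD[aa] for aa in protein], dtype=float)
    kernel = np.ones(window) / window
    means = np.convolve(vals, kernel, mode="valid")
    half = window // 2
    centers = np.arange(half + 1, half + 1 + means.size)

    above = means > threshold
    runs: list[list[int]] = []
    for idx in np.flatnonzero(above):
        if runs and idx - runs[-1][-1] - 1 <= merge_gap:
            runs[-1].append(idx)
        else:
            runs.append([idx])
    segments = [
        (int(centers[r[0]]), int(centers[r[-1]]))
        for r in runs
        if r[-1] - r[0] + 1 >= min_len
    ]
    return HydropathyProfile(window=window, centers=centers, values=means, segments=segments)


@dataclass(frozen=True)
class AlignmentResult:
    """Global pairwise alignment with percent identity over all columns."""

    aligned_a: str
    aligned_b: str
    score: float
    percent_identity: float


def global_align(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> AlignmentResult:
    """Needleman-Wunsch global alignment with affine gaps.

    Percent identity is matches divided by alignment columns (gaps count
    as columns).  The first optimal traceback is reported, which makes the
    result deterministic.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    aln = aligner.align(a, b)[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    matches = sum(x == y and x != "-" for x, y in zip(row_a, row_b))
    return AlignmentResult(
        aligned_a=row_a,
        aligned_b=row_b,
        score=float(aln.score),
        percent_identity=100.0 * matches / len(row_a),
    )


@dataclass(frozen=True)
class FilterSite:
    """One selectivity-filter position mapped from template to query."""

    template_position: int
    template_residue: str
    query_residue: str | None  # None when the template position aligns to a gap
    query_position: int | None


def map_selectivity_filter(
    query: str,
    template: str,
    template_positions: Sequence[int],
    **align_kwargs,
) -> list[FilterSite]:
    """Map template residue positions (e.g. the ar/R constriction of bovine
    AQP1: 58, 182, 191, 197) onto a query protein via global alignment."""
    for p in template_positions:
        if not 1 <= p <= len(template):
            raise ValueError(f"template position {p} outside 1..{len(template)}")
    aln = global_align(query, template, **align_kwargs)
    wanted = set(template_positions)
    found: dict[int, FilterSite] = {}
    qpos = tpos = 0
    for qc, tc in zip(aln.aligned_a, aln.aligned_b):
        if qc != "-":
            qpos += 1
        if tc != "-":
            tpos += 1
            if tpos in wanted:
                found[tpos] = FilterSite(
                    template_position=tpos,
                    template_residue=tc,
                    query_residue=None if qc == "-" else qc,
                    query_position=None if qc == "-" else qpos,
                )
    return [found[p] for p in template_positions]


@dataclass(frozen=True)
class PcrProduct:
    """A predicted amplicon; coordinates are 1-based inclusive on the template."""

    forward_start: int
    reverse_end: int
    length_bp: int
    forward_primer: str
    reverse_primer: str


def _primer_regex(primer: str) -> re.Pattern:
    try:
        parts = [
            base if len(IUPAC_DNA[base]) == 1 else f"[{IUPAC_DNA[base]}]"
            for base in primer.upper()
        ]
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC code in primer: {exc.args[0]!r}") from None
    return re.compile("(?=(" + "".join(parts) + "))")


def in_silico_pcr(
    template: SequenceRecord | str,
    fwd: str,
    rev: str,
    max_products: int = 10,
    min_primer_len: int = 10,
) -> list[PcrProduct]:
    """Degenerate-primer PCR prediction on the forward strand.

    The forward primer is matched directly; the reverse primer is
    reverse-complemented and matched on the forward strand.  IUPAC
    degeneracy is honored on the primer side only — an N in the template
    matches nothing.  Every forward site is paired with every
    non-overlapping downstream reverse site; products are sorted by length
    and include both primer footprints.
    """
    if len(fwd) < min_primer_len or len(rev) < min_primer_len:
        raise ValueError(f"primers must be at least {min_primer_len} nt")
    nt = template.residues if isinstance(template, SequenceRecord) else str(template).upper()
    fwd_starts = [m.start() for m in _primer_regex(fwd).finditer(nt)]
    rev_rc = reverse_complement(rev)
    rev_ends = [m.start() + len(rev_rc) for m in _primer_regex(rev_rc).finditer(nt)]
    products = [
        PcrProduct(
            forward_start=fs + 1,
            reverse_end=re_,
            length_bp=re_ - fs,
            forward_primer=fwd,
            reverse_primer=rev,
        )
        for fs in fwd_starts
        for re_ in rev_ends
        if re_ - len(rev_rc) >= fs + len(fwd)  # reverse footprint fully downstream
    ]
    products.sort(key=lambda p: (p.length_bp, p.forward_start))
    return products[:max_products]


def variant_length_diff(a: SequenceRecord | str, b: SequenceRecord | str) -> int:
    """Absolute length difference (bp) between two transcript variants."""
    la = len(a.residues) if isinstance(a, SequenceRecord) else len(a)
    lb = len(b.residues) if isinstance(b, SequenceRecord) else len(b)
    return abs(lb - la)


@dataclass
class ProteinAnnotation:
    """Aggregate hallmark annotation of one transcript (1-based coordinates)."""

    record_id: str
    orf_start: int
    orf_end: int
    protein: str
    length_aa: int
    mw_kda: float
    pi: float
    npa_starts: list[int]
    cterm_motif: str
    tm_segments: list[tuple[int, int]]
    arR: list[FilterSite] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "record_id": self.record_id,
            "coordinates": "1-based inclusive",
            "orf_start": self.orf_start,
            "orf_end": self.orf_end,
            "protein": self.protein,
            "length_aa": self.length_aa,
            "mw_kda": round(self.mw_kda, 3),
            "pi": round(self.pi, 2),
            "npa_starts": self.npa_starts,
            "cterm_motif": self.cterm_motif,
            "tm_segments": [list(s) for s in self.tm_segments],
        }
        if self.arR:
            d["arR"] = [
                {
                    "template_position": s.template_position,
                    "template_residue": s.template_residue,
                    "query_residue": s.query_residue,
                    "query_position": s.query_position,
                }
                for s in self.arR
            ]
        return d


def annotate_transcript(
    record: SequenceRecord,
    motif: str = "NPA",
    cterm_k: int = 4,
    hydropathy_window: int = 19,
    hydropathy_threshold: float = 1.6,
    template: str | None = None,
    template_positions: Sequence[int] = (58, 182, 191, 197),
) -> ProteinAnnotation:
    """Run the full hallmark annotation on a cDNA record.

    When a template protein is supplied (e.g. bovine AQP1), the ar/R
    selectivity-filter positions are mapped onto the query by global
    alignment; the default template positions are the vertebrate AQP1
    constriction residues.
    """
    orf = find_longest_orf(record)
    if orf is None:
        raise ValueError(f"no ORF found in {record.id}")
    profile = hydropathy_profile(
        orf.protein, window=hydropathy_window, threshold=hydropathy_threshold
    )
    sites: list[FilterSite] = []
    if template is not None:
        sites = map_selectivity_filter(orf.protein, template, template_positions)
    return ProteinAnnotation(
        record_id=record.id,
        orf_start=orf.start,
        orf_end=orf.end,
        protein=orf.protein,
        length_aa=orf.length_aa,
        mw_kda=protein_mw(orf.protein) / 1000.0,
        pi=protein_pi(orf.protein),
        npa_starts=scan_motif(orf.protein, motif),
        cterm_motif=cterm_motif(orf.protein, cterm_k),
        tm_segments=profile.segments,
        arR=sites,
    )
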