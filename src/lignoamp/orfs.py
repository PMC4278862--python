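"""Translation, stop-codon screening and class II peroxidase classification.

Basidiomycota class II peroxidases (CAZy family AA2) fall into four
subfamilies distinguished by two diagnostic residues:

* a manganese-binding aspartate, homologous to Asp-175 of the
  *Phanerochaete chrysosporium* MnP1 protein (GenBank AAA33744), crucial
  for Mn(II) oxidation;
* a surface catalytic tryptophan, homologous to Trp-171 of
  *P. chrysosporium* LiPH8 (GenBank AAA53109), responsible for oxidation of
  phenolic/aromatic substrates.

A peptide with the aspartate but not the tryptophan is a manganese
peroxidase (MnP); the tryptophan without the aspartate marks a lignin
peroxidase (LiP); both together a versatile peroxidase (VP); neither a
generic peroxidase (GP). A query that does not cover an anchor column is
unclassifiable.

The bundled anchor fixtures are deterministic *synthetic* stand-ins for the
two GenBank records (which cannot be redistributed here); the diagnostic
residues are pinned at the published positions, and the synthetic AA2
amplicons this package generates share the same backbone, so anchor-column
alignment is exact by construction.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Optional, Sequence

from Bio import Align, SeqIO
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

__all__ = [
    "TranslationResult",
    "AnchorResidue",
    "PeroxidaseCall",
    "translate",
    "stop_codon_screen",
    "classify_aa2",
    "nearest_reference_identity",
    "default_anchors",
    "load_reference_panel",
]


@dataclass(frozen=True)
class TranslationResult:
    frame: int
    peptide: str
    internal_stops: int
    frame_selection: str  # "configured" | "inferred"


@dataclass(frozen=True)
class AnchorResidue:
    anchor_protein: str
    anchor_sequence: str
    anchor_position: int  # 1-based residue index in anchor_sequence
    expected_residue: str  # "D" | "W"
    meaning: str

    def __post_init__(self) -> None:
        if self.expected_residue not in ("D", "W"):
            raise ValueError("expected_residue must be D or W")
        residue = self.anchor_sequence[self.anchor_position - 1]
        if residue != self.expected_residue:
            raise ValueError(
                f"{self.anchor_protein}: residue at {self.anchor_position} is "
                f"{residue!r}, expected {self.expected_residue!r}"
            )


@dataclass(frozen=True)
class PeroxidaseCall:
    query: str
    has_mn_asp: Optional[bool]  # None = anchor column not covered
    has_cat_trp: Optional[bool]
    subfamily: str  # MnP | LiP | VP | GP | unclassifiable
    aligned_columns: tuple[Optional[int], ...] = ()


_STOP = "*"


def _count_internal_stops(peptide: str) -> int:
    """Stops followed by at least one more codon; a stop as the final
    complete codon is terminal, not internal."""
    return peptide[:-1].count(_STOP)


def translate(insert: str, frame: int | str = 0) -> TranslationResult:
    """Translate a nucleotide insert in a fixed or inferred reading frame.

    ``frame="infer"`` picks the frame with the fewest internal stops
    (ties: longest stop-free stretch, then lowest frame index).
    """
    insert = insert.upper().replace("U", "T")
    if len(insert) < 3:
        raise ValueError("insert must be at least one codon long")

    def _one(f: int) -> tuple[str, int]:
        usable = insert[f: f + 3 * ((len(insert) - f) // 3)]
        peptide = str(Seq(usable).translate())
        return peptide, _count_internal_stops(peptide)

    if frame == "infer":
        candidates = []
        for f in range(3):
            peptide, stops = _one(f)
            longest_clean = max((len(s) for s in peptide.split(_STOP)), default=0)
            candidates.append((stops, -longest_clean, f, peptide))
        stops, _, f, peptide = min(candidates)
        return TranslationResult(f, peptide, stops, "inferred")
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1, 2 or 'infer'")
    peptide, stops = _one(frame)
    return TranslationResult(frame, peptide, stops, "configured")


def stop_codon_screen(result: TranslationResult) -> bool:
    """Pass iff the predicted ORF contains no internal stop codon."""
    return result.internal_stops == 0


def _make_protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10
    aligner.extend_gap_score = -1
    aligner.end_insertion_score = 0
    aligner.end_deletion_score = 0
    return aligner


_PROT_ALIGNER = _make_protein_aligner()


def _query_residue_at(anchor: str, query: str, position_0: int) -> Optional[str]:
    """Query residue aligned to anchor position ``position_0`` (0-based).

    Returns None when the column lies in a terminal gap (query does not
    cover it) and "-" when the anchor residue aligns to an internal gap.
    """
    aln = _PROT_ALIGNER.align(anchor, query)[0]
    t_blocks, q_blocks = aln.aligned
    if len(t_blocks) == 0:
        return None
    if position_0 < t_blocks[0][0] or position_0 >= t_blocks[-1][1]:
        return None  # terminal gap: anchor column not covered by the query
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        if ts <= position_0 < te:
            return query[qs + (position_0 - ts)]
    return "-"  # internal deletion in the query


def default_anchors() -> list[AnchorResidue]:
    """The two bundled (synthetic stand-in) anchor definitions."""
    anchors = []
    for fname, pos, residue, meaning, label in (
        ("synthetic_anchor_mnp.faa", 175, "D", "Mn-binding aspartate", "MnP1-like"),
        ("synthetic_anchor_lip.faa", 171, "W", "catalytic tryptophan", "LiPH8-like"),
    ):
        ref = importlib.resources.files("lignoamp.data") / fname
        with importlib.resources.as_file(ref) as path:
            record = next(SeqIO.parse(str(path), "fasta"))
        anchors.append(AnchorResidue(label, str(record.seq), pos, residue, meaning))
    return anchors


def classify_aa2(
    peptide: str,
    anchors: Optional[Sequence[AnchorResidue]] = None,
) -> PeroxidaseCall:
    """Four-way MnP/LiP/VP/GP call from the two diagnostic anchor columns.

    The query peptide is globally aligned (BLOSUM62, gap open -10, extend
    -1, terminal gaps free) to each anchor protein and the residue in the
    anchor column inspected. Any anchor column falling in a terminal gap
    makes the call ``unclassifiable``.
    """
    if not peptide:
        raise ValueError("classify_aa2 requires a non-empty peptide")
    peptide = peptide.upper()
    if anchors is None:
        anchors = default_anchors()
    evidence: dict[str, Optional[bool]] = {}
    columns: list[Optional[int]] = []
    for anchor in anchors:
        residue = _query_residue_at(anchor.anchor_sequence, peptide, anchor.anchor_position - 1)
        columns.append(anchor.anchor_position if residue is not None else None)
        evidence[anchor.expected_residue] = (
            None if residue is None else residue == anchor.expected_residue
        )
    has_d, has_w = evidence.get("D"), evidence.get("W")
    if has_d is None or has_w is None:
        subfamily = "unclassifiable"
    elif has_d and not has_w:
        subfamily = "MnP"
    elif has_w and not has_d:
        subfamily = "LiP"
    elif has_d and has_w:
        subfamily = "VP"
    else:
        subfamily = "GP"
    return PeroxidaseCall(peptide, has_d, has_w, subfamily, tuple(columns))


def load_reference_panel(path: Optional[str] = None) -> list[tuple[str, str]]:
    """Load a (label, peptide) reference panel; defaults to the bundled
    synthetic GH5-5 panel."""
    if path is None:
        ref = importlib.resources.files("lignoamp.data") / "synthetic_gh5_5_panel.faa"
        with importlib.resources.as_file(ref) as p:
            records = list(SeqIO.parse(str(p), "fasta"))
    else:
        records = list(SeqIO.parse(path, "fasta"))
    return [(r.id, str(r.seq)) for r in records]


def nearest_reference_identity(
    peptide: str,
    panel: Sequence[tuple[str, str]],
) -> tuple[str, float]:
    """Best-matching panel member and percent of similar amino-acid positions.

    Similarity counts positions whose BLOSUM62 substitution score is
    positive, divided by aligned columns (terminal gaps excluded). Ties are
    broken by panel order. A hit below ~70% similarity is conventionally
    taken as failing family-membership confirmation.
    """
    if not panel:
        raise ValueError("nearest_reference_identity requires a non-empty panel")
    if not peptide:
        raise ValueError("nearest_reference_identity requires a non-empty peptide")
    matrix = _PROT_ALIGNER.substitution_matrix
    best: Optional[tuple[float, int, str]] = None
    for order, (label, ref) in enumerate(panel):
        aln = _PROT_ALIGNER.align(ref, peptide.upper())[0]
        t_blocks, q_blocks = aln.aligned
        similar = 0
        columns = 0
        prev_t = prev_q = None
        for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
            if prev_t is not None:
                columns += (ts - prev_t) + (qs - prev_q)
            for i in range(te - ts):
                columns += 1
                if matrix[ref[ts + i], peptide[qs + i].upper()] > 0:
                    similar += 1
            prev_t, prev_q = te, qe
        pct = 100.0 * similar / columns if columns else 0.0
        if best is None or pct > best[0]:
            best = (pct, order, label)
    pct, _, label = best
    return label, pct
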