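"""Degenerate-primer model: IUPAC/inosine matching, in-silico PCR and
amplifiability auditing of gene models.

A :class:`DegeneratePrimer` is an oligo over the IUPAC nucleotide alphabet
extended with inosine (``I``), stored 5'->3'. Matching is ungapped
(Hamming-style) within the primer footprint: primers are short, and the
read-quality filters downstream count *mismatches*, not gaps. Inosine is a
physical universal-pairing analog and matches any template base, exactly
like ``N`` in the primer; a template ``N`` on the other hand is an unknown
base and is only accepted by a primer ``I``/``N`` position.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from itertools import product as _iterproduct
from pathlib import Path
from typing import Iterator, Optional, Sequence

__all__ = [
    "IUPAC_SETS",
    "DegeneratePrimer",
    "PrimerPair",
    "BindingSite",
    "Amplicon",
    "GeneModel",
    "AmplifiabilityVerdict",
    "revcomp",
    "degeneracy",
    "match_window",
    "find_binding_sites",
    "in_silico_pcr",
    "evaluate_amplifiability",
    "amplifiable_fraction",
    "load_primer_bundle",
]

#: Base sets encoded by each allowed primer symbol. ``I`` (inosine) pairs
#: with all four bases and is deliberately identical to ``N`` here.
IUPAC_SETS = {
    "A": frozenset("A"), "C": frozenset("C"),
    "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"),
    "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"),
    "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"), "I": frozenset("ACGT"),
}

_WILDCARDS = frozenset("NI")

_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N", "I": "I",
}


def revcomp(seq: str) -> str:
    """Reverse complement of a (possibly degenerate) nucleotide string."""
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"cannot complement symbol {exc.args[0]!r}") from exc


def _validate_alphabet(sequence: str) -> None:
    for ch in sequence:
        if ch not in IUPAC_SETS:
            raise ValueError(
                f"invalid primer symbol {ch!r}; allowed: {''.join(sorted(IUPAC_SETS))}"
            )


@dataclass(frozen=True)
class DegeneratePrimer:
    """A degenerate oligo, stored 5'->3' with whitespace stripped."""

    name: str
    sequence: str
    orientation: str  # "forward" | "reverse"
    family: str = ""

    def __post_init__(self) -> None:
        seq = "".join(self.sequence.split()).upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise ValueError("primer sequence must be non-empty")
        _validate_alphabet(seq)
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"orientation must be forward/reverse, got {self.orientation!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    def expansions(self, limit: int = 100_000) -> Iterator[str]:
        """Yield every concrete oligo the degenerate sequence encodes."""
        if degeneracy(self) > limit:
            raise ValueError("degeneracy exceeds expansion limit")
        for combo in _iterproduct(*(sorted(IUPAC_SETS[c]) for c in self.sequence)):
            yield "".join(combo)


@dataclass(frozen=True)
class PrimerPair:
    fwd: DegeneratePrimer
    rev: DegeneratePrimer
    expected_product_length: int
    targeted_groups: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.expected_product_length <= len(self.fwd) + len(self.rev):
            raise ValueError("expected product length must exceed the two primer lengths")

    @property
    def family(self) -> str:
        return self.fwd.family

    def length_bounds(self, tolerance: float = 0.30) -> tuple[int, int]:
        lo = int(round(self.expected_product_length * (1 - tolerance)))
        hi = int(round(self.expected_product_length * (1 + tolerance)))
        return lo, hi


@dataclass(frozen=True)
class BindingSite:
    template_id: str
    start: int  # 0-based, on the + strand
    strand: str  # "+" | "-"
    mismatches: int
    aligned_window: str


@dataclass(frozen=True)
class Amplicon:
    sequence: str
    start: int  # 0-based half-open span on the + strand
    end: int
    strand: str
    fwd_mismatches: int
    rev_mismatches: int

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneModel:
    """A genomic gene copy with an ordered exon structure.

    Exons are 0-based half-open intervals on ``genomic_sequence``; the
    spliced coding sequence is their concatenation.
    """

    gene_id: str
    genomic_sequence: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        exons = tuple((int(a), int(b)) for a, b in self.exons)
        object.__setattr__(self, "exons", exons)
        prev_end = 0
        for start, end in exons:
            if start < prev_end or end <= start or end > len(self.genomic_sequence):
                raise ValueError(f"{self.gene_id}: malformed exon interval ({start}, {end})")
            prev_end = end

    @property
    def spliced(self) -> str:
        return "".join(self.genomic_sequence[a:b] for a, b in self.exons)

    def spliced_interval_is_contiguous(self, start: int, end: int) -> bool:
        """True if spliced positions [start, end) fall inside a single exon."""
        offset = 0
        for a, b in self.exons:
            length = b - a
            if start >= offset and end <= offset + length:
                return True
            offset += length
        return False


@dataclass(frozen=True)
class AmplifiabilityVerdict:
    gene_id: str
    status: str  # amplifiable | divergent_site | intron_disrupted | no_product
    fwd_mismatches: Optional[int] = None
    rev_mismatches: Optional[int] = None
    product_length: Optional[int] = None


def degeneracy(primer: DegeneratePrimer | str) -> int:
    """Number of concrete oligos a degenerate primer encodes.

    Multiplicative over positions; ``I`` and ``N`` each contribute 4.
    """
    seq = primer.sequence if isinstance(primer, DegeneratePrimer) else primer.upper()
    _validate_alphabet(seq)
    n = 1
    for ch in seq:
        n *= len(IUPAC_SETS[ch])
    return n


def match_window(primer: DegeneratePrimer | str, window: str) -> int:
    """Ungapped mismatch count of a primer against an equal-length window.

    A position matches iff the window base is in the primer code's base set;
    a window ``N`` matches only a primer ``I``/``N``.
    """
    pattern = primer.sequence if isinstance(primer, DegeneratePrimer) else primer.upper()
    window = window.upper()
    if len(window) != len(pattern):
        raise ValueError(
            f"window length {len(window)} != primer length {len(pattern)}"
        )
    mismatches = 0
    for p, w in zip(pattern, window):
        if w == "N":
            if p not in _WILDCARDS:
                mismatches += 1
        elif w not in IUPAC_SETS[p]:
            mismatches += 1
    return mismatches


def _scan(pattern: str, template: str, max_mm: int) -> Iterator[tuple[int, int]]:
    k = len(pattern)
    for i in range(len(template) - k + 1):
        mm = match_window(pattern, template[i : i + k])
        if mm <= max_mm:
            yield i, mm


def find_binding_sites(
    template: str,
    primer: DegeneratePrimer,
    max_mm: int = 2,
    template_id: str = "",
) -> list[BindingSite]:
    """All ungapped binding sites of ``primer`` on both strands of ``template``.

    Minus-strand sites are reported in + strand coordinates; the site window
    there matches the reverse complement of the primer.
    """
    template = template.upper()
    if len(template) < len(primer):
        return []
    sites: list[BindingSite] = []
    for i, mm in _scan(primer.sequence, template, max_mm):
        sites.append(BindingSite(template_id, i, "+", mm, template[i : i + len(primer)]))
    rc_pattern = revcomp(primer.sequence)
    for i, mm in _scan(rc_pattern, template, max_mm):
        sites.append(BindingSite(template_id, i, "-", mm, template[i : i + len(primer)]))
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def in_silico_pcr(
    template: str,
    pair: PrimerPair,
    max_mm: int = 2,
    min_len: Optional[int] = None,
    max_len: Optional[int] = None,
    length_tolerance: float = 0.30,
) -> list[Amplicon]:
    """Enumerate all PCR products of ``pair`` on ``template``.

    A product spans the forward-primer footprint through the (reverse
    complemented) reverse-primer footprint inclusive of both; every
    orientation and (fwd, rev) site combination within the length bounds is
    reported, sorted by start coordinate then length.
    """
    if min_len is None or max_len is None:
        lo, hi = pair.length_bounds(length_tolerance)
        min_len = lo if min_len is None else min_len
        max_len = hi if max_len is None else max_len
    if min_len > max_len:
        raise ValueError("min_len must not exceed max_len")
    template = template.upper()
    fwd_sites = find_binding_sites(template, pair.fwd, max_mm)
    rev_sites = find_binding_sites(template, pair.rev, max_mm)
    amplicons: list[Amplicon] = []
    # Plus-strand products: forward primer on +, reverse primer on -.
    for f in (s for s in fwd_sites if s.strand == "+"):
        for r in (s for s in rev_sites if s.strand == "-"):
            start, end = f.start, r.start + len(pair.rev)
            if end - start < max(len(pair.fwd) + len(pair.rev), min_len):
                continue
            if end - start > max_len:
                continue
            amplicons.append(
                Amplicon(template[start:end], start, end, "+", f.mismatches, r.mismatches)
            )
    # Minus-strand products: forward primer on -, reverse primer on +.
    for f in (s for s in fwd_sites if s.strand == "-"):
        for r in (s for s in rev_sites if s.strand == "+"):
            start, end = r.start, f.start + len(pair.fwd)
            if end - start < max(len(pair.fwd) + len(pair.rev), min_len):
                continue
            if end - start > max_len:
                continue
            amplicons.append(
                Amplicon(revcomp(template[start:end]), start, end, "-", f.mismatches, r.mismatches)
            )
    amplicons.sort(key=lambda a: (a.start, len(a), a.strand))
    return amplicons


def _site_ceiling(primer: DegeneratePrimer, max_mm: int) -> int:
    """Mismatch level above which a window no longer counts as a
    recognisable (if divergent) binding site: a quarter of the primer
    length, never below the configured PCR tolerance."""
    return max(max_mm, -(-len(primer) // 4))


def _best_site_combination(
    spliced: str, pair: PrimerPair, min_len: int, max_len: int, max_mm: int
) -> Optional[tuple[int, int, int, int]]:
    """Least-mismatch (fwd_start, fwd_mm, rev_start, rev_mm) combination whose
    product length is within bounds, allowing divergent (but still
    recognisable) sites."""
    fwd_sites = [
        s for s in find_binding_sites(spliced, pair.fwd, _site_ceiling(pair.fwd, max_mm))
        if s.strand == "+"
    ]
    rev_sites = [
        s for s in find_binding_sites(spliced, pair.rev, _site_ceiling(pair.rev, max_mm))
        if s.strand == "-"
    ]
    best = None
    for f in fwd_sites:
        for r in rev_sites:
            length = r.start + len(pair.rev) - f.start
            if length < max(min_len, len(pair.fwd) + len(pair.rev)) or length > max_len:
                continue
            key = (f.mismatches + r.mismatches, f.start, r.start)
            if best is None or key < best[0]:
                best = (key, f, r)
    if best is None:
        return None
    _, f, r = best
    return f.start, f.mismatches, r.start, r.mismatches


def evaluate_amplifiability(
    gene: GeneModel,
    pair: PrimerPair,
    max_mm: int = 2,
    length_tolerance: float = 0.30,
) -> AmplifiabilityVerdict:
    """Judge whether a genomic gene copy can yield a PCR product.

    The primer search runs on the spliced coding sequence (mimicking
    amplification from mRNA-derived templates); a binding site whose genomic
    projection crosses an exon junction is disrupted by an intron on the
    genomic copy and the verdict is ``intron_disrupted``. Sites present only
    above the mismatch ceiling give ``divergent_site``; absent or
    length-incompatible sites give ``no_product``.
    """
    spliced = gene.spliced
    min_len, max_len = pair.length_bounds(length_tolerance)
    combo = _best_site_combination(spliced, pair, min_len, max_len, max_mm)
    if combo is None:
        return AmplifiabilityVerdict(gene.gene_id, "no_product")
    f_start, f_mm, r_start, r_mm = combo
    product_length = r_start + len(pair.rev) - f_start
    if f_mm > max_mm or r_mm > max_mm:
        return AmplifiabilityVerdict(gene.gene_id, "divergent_site", f_mm, r_mm, None)
    fwd_ok = gene.spliced_interval_is_contiguous(f_start, f_start + len(pair.fwd))
    rev_ok = gene.spliced_interval_is_contiguous(r_start, r_start + len(pair.rev))
    if not (fwd_ok and rev_ok):
        return AmplifiabilityVerdict(gene.gene_id, "intron_disrupted", f_mm, r_mm, None)
    return AmplifiabilityVerdict(gene.gene_id, "amplifiable", f_mm, r_mm, product_length)


def amplifiable_fraction(
    genes: Sequence[GeneModel],
    pair: PrimerPair,
    max_mm: int = 2,
    length_tolerance: float = 0.30,
) -> tuple[float, list[AmplifiabilityVerdict]]:
    """Fraction of gene copies judged amplifiable, with per-gene verdicts."""
    if not genes:
        raise ValueError("amplifiable_fraction requires at least one gene model")
    verdicts = [
        evaluate_amplifiability(g, pair, max_mm=max_mm, length_tolerance=length_tolerance)
        for g in genes
    ]
    n_ok = sum(v.status == "amplifiable" for v in verdicts)
    return n_ok / len(verdicts), verdicts


def load_primer_bundle(path: Optional[str | Path] = None) -> dict[str, PrimerPair]:
    """Load a primer-pair bundle (family -> PrimerPair) from a TSV file.

    Columns: family, name, sequence, orientation, expected_product_length,
    targeted_groups (semicolon separated). The default bundle ships the four
    published pairs for GH7, GH5-5, GH11 and AA2.
    """
    if path is None:
        ref = importlib.resources.files("lignoamp.data") / "primers.tsv"
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append(line.split("\t"))
    header = rows[0]
    records = [dict(zip(header, r)) for r in rows[1:]]
    by_family: dict[str, dict[str, dict]] = {}
    for rec in records:
        by_family.setdefault(rec["family"], {})[rec["orientation"]] = rec
    pairs: dict[str, PrimerPair] = {}
    for family, recs in by_family.items():
        if set(recs) != {"forward", "reverse"}:
            raise ValueError(f"primer bundle for {family} must contain one forward and one reverse primer")
        fwd = DegeneratePrimer(recs["forward"]["name"], recs["forward"]["sequence"], "forward", family)
        rev = DegeneratePrimer(recs["reverse"]["name"], recs["reverse"]["sequence"], "reverse", family)
        groups = tuple(recs["forward"].get("targeted_groups", "").split(";"))
        pairs[family] = PrimerPair(fwd, rev, int(recs["forward"]["expected_product_length"]), groups)
    return pairs
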