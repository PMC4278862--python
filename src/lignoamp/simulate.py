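"""Synthetic gene families, communities and error-bearing paired reads.

The generator reproduces the statistical structure the pipeline assumes so
that every stage is testable without downloads:

* several divergent coding-sequence variants per gene family, each carrying
  exactly one conserved forward and one reverse primer-binding site at the
  published product spacing, stop-free in the design frame;
* skewed community abundances (few dominant taxa plus a long tail of rare
  ones), with configurable overlap between the supports of two samples
  emulating a beech/spruce-like paired design with unequal depth;
* per-base substitution errors, ``N`` calls, optional homopolymer
  artifacts and chimeric (bimeric) read pairs spliced from two parent
  amplicons;
* a truth table tracing every read to (variant, sample, chimera flag).

All randomness flows from a single seed through spawned child generators,
so outputs (including FASTQ bytes) are identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .orfs import default_anchors
from .primers import (
    DegeneratePrimer,
    GeneModel,
    IUPAC_SETS,
    PrimerPair,
    find_binding_sites,
    in_silico_pcr,
    load_primer_bundle,
    revcomp,
)
from .reads import ReadPair

__all__ = [
    "SimulatedVariant",
    "SimulatedFamily",
    "SimulatedCommunity",
    "ReadSimConfig",
    "simulate_family",
    "simulate_community",
    "simulate_reads",
    "simulate_gene_models",
    "simulate_study",
    "write_paired_fastq",
]

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}

_CODONS = {}
for _b1 in _BASES:
    for _b2 in _BASES:
        for _b3 in _BASES:
            _codon = _b1 + _b2 + _b3
            if _codon in _STOPS:
                continue
            from Bio.Seq import Seq as _Seq

            _CODONS.setdefault(str(_Seq(_codon).translate()), []).append(_codon)

# Anchor geometry of the synthetic AA2 scaffold: the amplicon insert covers
# backbone residues _AA2_REGION_START..+n_codons of the bundled synthetic
# MnP-like anchor, so the Trp-171 and Asp-175 columns fall inside every
# simulated AA2 amplicon.
_AA2_REGION_START = 130  # 0-based backbone residue index
_TRP_COL = 170  # 0-based: Trp-171 column
_ASP_COL = 174  # 0-based: Asp-175 column

_SUBFAMILY_RESIDUES = {
    # (residue at Trp-171 column, residue at Asp-175 column)
    "MnP": ("F", "D"),
    "LiP": ("W", "A"),
    "VP": ("W", "D"),
    "GP": ("F", "A"),
}


@dataclass(frozen=True)
class SimulatedVariant:
    variant_id: str
    amplicon: str  # full product including both primer footprints
    insert: str  # primer-trimmed region
    subfamily: Optional[str] = None  # AA2 truth label
    genomic: Optional[str] = None
    exons: Optional[tuple[tuple[int, int], ...]] = None


@dataclass(frozen=True)
class SimulatedFamily:
    family: str
    pair: PrimerPair
    variants: tuple[SimulatedVariant, ...]
    min_pairwise_divergence: float
    seed: int


@dataclass(frozen=True)
class SimulatedCommunity:
    samples: tuple[str, ...]
    abundances: np.ndarray  # n_samples x n_variants
    model: str
    depths: tuple[int, ...]
    seed: int


@dataclass(frozen=True)
class ReadSimConfig:
    """Error-process parameters for read simulation.

    Defaults emulate a 2x250 MiSeq run: ~0.2% per-base substitution error,
    rare N calls, 1% chimeric pairs and no homopolymer artifacts.
    """

    read_length: int = 250
    substitution_rate: float = 0.002
    n_rate: float = 0.001
    chimera_rate: float = 0.01
    homopolymer_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("substitution_rate", "n_rate", "chimera_rate", "homopolymer_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


def _concrete(primer: DegeneratePrimer, rng: np.random.Generator) -> str:
    return "".join(
        sorted(IUPAC_SETS[c])[rng.integers(len(IUPAC_SETS[c]))] for c in primer.sequence
    )


def _random_stopfree_codons(n: int, rng: np.random.Generator) -> str:
    codons = [c for v in _CODONS.values() for c in v]
    codons.sort()
    return "".join(codons[rng.integers(len(codons))] for _ in range(n))


def _has_long_homopolymer(seq: str, max_run: int = 7) -> bool:
    run, prev = 1, ""
    for ch in seq:
        run = run + 1 if ch == prev else 1
        if run > max_run:
            return True
        prev = ch
    return False


def _reverse_translate(peptide: str, rng: np.random.Generator) -> str:
    return "".join(
        _CODONS[aa][rng.integers(len(_CODONS[aa]))] for aa in peptide
    )


def _amplicon_is_clean(amplicon: str, pair: PrimerPair, max_mm: int) -> bool:
    """Exactly one forward and one reverse site, one in-bounds product."""
    fwd_sites = [s for s in find_binding_sites(amplicon, pair.fwd, max_mm) if s.strand == "+"]
    rev_sites = [s for s in find_binding_sites(amplicon, pair.rev, max_mm) if s.strand == "-"]
    if len(fwd_sites) != 1 or len(rev_sites) != 1:
        return False
    products = in_silico_pcr(amplicon, pair, max_mm=max_mm)
    return len(products) == 1 and products[0].sequence == amplicon


def _mutation_budget(target: float, insert_len: int, amplicon_len: int) -> int:
    """Per-variant mutation count giving ~target expected pairwise divergence.

    Two variants each carrying k substitutions at uniform insert positions
    differ at about 2k - 1.25 k^2/L positions; solve for the smallest k
    reaching target * amplicon_len.
    """
    goal = target * amplicon_len
    for k in range(1, insert_len):
        if 2 * k - 1.25 * k * k / insert_len >= goal:
            return k
    raise ValueError("divergence target infeasible for this amplicon length")


def _mutate_insert(
    insert: str,
    k: int,
    rng: np.random.Generator,
    frozen: frozenset[int] = frozenset(),
) -> str:
    """Apply exactly k substitutions, avoiding frozen positions and never
    creating a stop codon in the design frame."""
    seq = list(insert)
    available = [i for i in range(len(seq)) if i not in frozen]
    positions = rng.choice(len(available), size=k, replace=False)
    for idx in positions:
        pos = available[idx]
        for _ in range(12):
            new = _BASES[rng.integers(4)]
            if new == seq[pos]:
                continue
            old = seq[pos]
            seq[pos] = new
            codon_start = 3 * (pos // 3)
            codon = "".join(seq[codon_start: codon_start + 3])
            if len(codon) == 3 and codon in _STOPS:
                seq[pos] = old
                continue
            break
    return "".join(seq)


def _pairwise_min_divergence(amplicons: Sequence[str]) -> float:
    arrs = [np.frombuffer(a.encode(), dtype=np.uint8) for a in amplicons]
    best = 1.0
    for i in range(len(arrs)):
        for j in range(i + 1, len(arrs)):
            d = float((arrs[i] != arrs[j]).mean())
            best = min(best, d)
    return best


def _build_ancestor_insert(
    family: str,
    insert_len: int,
    rng: np.random.Generator,
    subfamily: Optional[str],
) -> tuple[str, frozenset[int]]:
    """Ancestor insert sequence and the set of frozen nucleotide positions
    (AA2 anchor codons)."""
    n_codons, remainder = divmod(insert_len, 3)
    if family == "AA2":
        backbone = default_anchors()[0].anchor_sequence
        peptide = list(backbone[_AA2_REGION_START: _AA2_REGION_START + n_codons])
        trp_idx = _TRP_COL - _AA2_REGION_START
        asp_idx = _ASP_COL - _AA2_REGION_START
        if not (0 <= trp_idx < n_codons and 0 <= asp_idx < n_codons):
            raise ValueError("AA2 insert does not span the anchor columns")
        trp_res, asp_res = _SUBFAMILY_RESIDUES[subfamily or "MnP"]
        peptide[trp_idx] = trp_res
        peptide[asp_idx] = asp_res
        insert = _reverse_translate("".join(peptide), rng)
        frozen = frozenset(
            list(range(3 * trp_idx, 3 * trp_idx + 3))
            + list(range(3 * asp_idx, 3 * asp_idx + 3))
        )
    else:
        insert = _random_stopfree_codons(n_codons, rng)
        frozen = frozenset()
    if remainder:
        # pad with bases that cannot complete a stop codon
        insert += "C" * remainder
    return insert, frozen


def simulate_family(
    family: str,
    n_variants: int,
    target_divergence: float = 0.10,
    pair: Optional[PrimerPair] = None,
    seed: int = 0,
    max_mm: int = 2,
    planted_subfamilies: Optional[Sequence[str]] = None,
    intron_mode: str = "none",
    max_attempts: int = 20,
) -> SimulatedFamily:
    """Evolve ``n_variants`` amplifiable coding variants of one gene family.

    The ancestor is built around exact (concrete) primer sites at the
    published product spacing; variants accumulate random substitutions
    outside the primer footprints, never creating stop codons in the design
    frame, until the realised minimum pairwise divergence sits within 20%
    of ``target_divergence``. AA2 families carry planted subfamily labels
    realised through the two diagnostic anchor codons, which are frozen
    during evolution. ``intron_mode`` optionally attaches genomic copies:
    ``"internal"`` plants an intron between the primer sites,
    ``"disrupt_fwd"`` inside the forward footprint.
    """
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    if not 0.0 < target_divergence < 0.5:
        raise ValueError("target_divergence must be in (0, 0.5)")
    if intron_mode not in ("none", "internal", "disrupt_fwd"):
        raise ValueError(f"unknown intron_mode {intron_mode!r}")
    if pair is None:
        pair = load_primer_bundle()[family]
    if planted_subfamilies is not None:
        if family != "AA2":
            raise ValueError("planted subfamilies only apply to AA2")
        if len(planted_subfamilies) != n_variants:
            raise ValueError("one planted subfamily per variant required")
        unknown = set(planted_subfamilies) - set(_SUBFAMILY_RESIDUES)
        if unknown:
            raise ValueError(f"unknown subfamilies {unknown}")

    insert_len = pair.expected_product_length - len(pair.fwd) - len(pair.rev)
    amp_len = pair.expected_product_length
    seed_seq = np.random.SeedSequence(seed)
    for attempt, child in enumerate(seed_seq.spawn(max_attempts)):
        rng = np.random.default_rng(child)
        fwd_concrete = _concrete(pair.fwd, rng)
        rev_concrete = _concrete(pair.rev, rng)

        def assemble(insert: str) -> str:
            return fwd_concrete + insert + revcomp(rev_concrete)

        base_subfamily = planted_subfamilies[0] if planted_subfamilies else None
        ancestor_insert, frozen = _build_ancestor_insert(
            family, insert_len, rng, base_subfamily
        )
        if not _amplicon_is_clean(assemble(ancestor_insert), pair, max_mm):
            continue
        if _has_long_homopolymer(assemble(ancestor_insert)):
            continue

        variants: list[SimulatedVariant] = []
        k = 0 if n_variants == 1 else _mutation_budget(target_divergence, insert_len, amp_len)
        ok = True
        for v in range(n_variants):
            subfamily = planted_subfamilies[v] if planted_subfamilies else None
            produced = None
            for _ in range(60):
                insert = ancestor_insert
                if subfamily is not None:
                    # re-pin the anchor codons for this variant's label
                    trp_res, asp_res = _SUBFAMILY_RESIDUES[subfamily]
                    trp_idx = _TRP_COL - _AA2_REGION_START
                    asp_idx = _ASP_COL - _AA2_REGION_START
                    insert = (
                        insert[: 3 * trp_idx]
                        + _CODONS[trp_res][rng.integers(len(_CODONS[trp_res]))]
                        + insert[3 * trp_idx + 3: 3 * asp_idx]
                        + _CODONS[asp_res][rng.integers(len(_CODONS[asp_res]))]
                        + insert[3 * asp_idx + 3:]
                    )
                if v > 0 or n_variants > 1:
                    insert = _mutate_insert(insert, k, rng, frozen)
                amplicon = assemble(insert)
                if _has_long_homopolymer(amplicon):
                    continue
                if not _amplicon_is_clean(amplicon, pair, max_mm):
                    continue
                produced = (insert, amplicon)
                break
            if produced is None:
                ok = False
                break
            insert, amplicon = produced
            genomic = exons = None
            if intron_mode != "none":
                genomic, exons = _attach_genomic(amplicon, intron_mode, rng)
            variants.append(
                SimulatedVariant(
                    f"{family}_v{v + 1:03d}", amplicon, insert, subfamily, genomic, exons
                )
            )
        if not ok:
            continue
        if n_variants > 1:
            realized = _pairwise_min_divergence([v.amplicon for v in variants])
            if not (0.8 * target_divergence <= realized <= 1.2 * target_divergence):
                continue
        else:
            realized = 0.0
        return SimulatedFamily(family, pair, tuple(variants), realized, seed)
    raise RuntimeError(
        f"could not realise {n_variants} {family} variants at divergence "
        f"{target_divergence} within {max_attempts} attempts"
    )


def _attach_genomic(
    amplicon: str, intron_mode: str, rng: np.random.Generator
) -> tuple[str, tuple[tuple[int, int], ...]]:
    flank_l = _random_stopfree_codons(17, rng)[:50]
    flank_r = _random_stopfree_codons(17, rng)[:50]
    intron = "GT" + "".join(_BASES[rng.integers(4)] for _ in range(56)) + "AG"
    if intron_mode == "disrupt_fwd":
        cut = 10  # inside the forward primer footprint
    else:
        cut = len(amplicon) // 2
    genomic = flank_l + amplicon[:cut] + intron + amplicon[cut:] + flank_r
    a = len(flank_l)
    exons = (
        (a, a + cut),
        (a + cut + len(intron), a + cut + len(intron) + len(amplicon) - cut),
    )
    return genomic, exons


def simulate_gene_models(
    pair: PrimerPair,
    statuses: Sequence[str],
    seed: int = 0,
    max_mm: int = 2,
) -> tuple[list[GeneModel], list[str]]:
    """Genomic gene copies with planted amplifiability verdicts.

    ``statuses`` lists the expected verdict for each gene:
    ``amplifiable``, ``intron_disrupted``, ``divergent_site`` or
    ``no_product``. Returns the gene models and the planted truth labels.
    """
    allowed = {"amplifiable", "intron_disrupted", "divergent_site", "no_product"}
    unknown = set(statuses) - allowed
    if unknown:
        raise ValueError(f"unknown statuses {unknown}")
    family = simulate_family(
        pair.family or "GH11", 1, pair=pair, seed=seed, max_mm=max_mm
    )
    amplicon = family.variants[0].amplicon
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    genes: list[GeneModel] = []
    for idx, status in enumerate(statuses):
        gene_id = f"gene_{idx + 1:03d}_{status}"
        flank_l = "".join(_BASES[rng.integers(4)] for _ in range(50))
        flank_r = "".join(_BASES[rng.integers(4)] for _ in range(50))
        if status == "amplifiable":
            genomic = flank_l + amplicon + flank_r
            exons = ((50, 50 + len(amplicon)),)
        elif status == "intron_disrupted":
            genomic, exons = _attach_genomic(amplicon, "disrupt_fwd", rng)
        elif status == "divergent_site":
            seq = list(amplicon)
            planted = 0
            pos = 0
            while planted < max_mm + 1 and pos < len(pair.fwd):
                code = IUPAC_SETS[pair.fwd.sequence[pos]]
                options = [b for b in _BASES if b not in code]
                if options:
                    seq[pos] = options[rng.integers(len(options))]
                    planted += 1
                pos += 1
            if planted < max_mm + 1:
                raise RuntimeError("forward primer too degenerate to plant divergence")
            genomic = flank_l + "".join(seq) + flank_r
            exons = ((50, 50 + len(amplicon)),)
        else:  # no_product: scramble the reverse footprint beyond recognition
            lr = len(pair.rev)
            core = amplicon[:-lr] + "".join(
                sorted(set(_BASES) - {b})[rng.integers(3)] for b in amplicon[-lr:]
            )
            genomic = flank_l + core + flank_r
            exons = ((50, 50 + len(core)),)
        genes.append(GeneModel(gene_id, genomic, exons))
    return genes, list(statuses)


def _ranked_probabilities(
    model: str, n: int, rng: np.random.Generator, r: float = 0.8, alpha: float = 0.3
) -> np.ndarray:
    if n == 0:
        return np.array([])
    if model == "geometric":
        if not 0.0 < r < 1.0:
            raise ValueError("geometric ratio r must be in (0, 1)")
        p = r ** np.arange(1, n + 1)
    elif model == "log-series":
        if not 0.0 < alpha < 1.0:
            raise ValueError("log-series parameter must be in (0, 1)")
        draws = rng.logseries(1 - alpha, size=n).astype(float)
        p = np.sort(draws)[::-1]
    else:
        raise ValueError(f"unknown abundance model {model!r}")
    return p / p.sum()


def simulate_community(
    n_variants: int,
    n_samples: int = 2,
    model: str = "geometric",
    depth: int | Sequence[int] = 1000,
    shared_fraction: float = 1.0,
    seed: int = 0,
    r: float = 0.8,
    alpha: float = 0.3,
    ensure_support: bool = True,
) -> SimulatedCommunity:
    """Ranked-abundance community draws for ``n_samples`` samples.

    ``shared_fraction`` controls the overlap of the per-sample variant
    supports (1.0: all samples may contain every variant; 0.0: disjoint
    supports). Within its support each sample gets its own random rank
    order, so the dominant variants differ between samples. With
    ``ensure_support`` every supported variant receives at least one read
    before the multinomial remainder is drawn.
    """
    if not 0.0 <= shared_fraction <= 1.0:
        raise ValueError("shared_fraction must be in [0, 1]")
    depths = tuple([depth] * n_samples) if np.isscalar(depth) else tuple(int(d) for d in depth)
    if len(depths) != n_samples:
        raise ValueError("one depth per sample required")
    master = np.random.default_rng(seed)
    n_shared = int(round(shared_fraction * n_variants))
    order = master.permutation(n_variants)
    shared = set(order[:n_shared].tolist())
    leftover = order[n_shared:].tolist()
    supports = []
    for s in range(n_samples):
        own = leftover[s::n_samples]
        supports.append(sorted(shared | set(own)))
    abundances = np.zeros((n_samples, n_variants), dtype=np.int64)
    children = np.random.SeedSequence(seed).spawn(n_samples)
    for s, (support, child) in enumerate(zip(supports, children)):
        rng = np.random.default_rng(child)
        if not support:
            continue
        p = _ranked_probabilities(model, len(support), rng, r=r, alpha=alpha)
        ranks = rng.permutation(len(support))
        probs = p[ranks]
        d = depths[s]
        floor = np.zeros(len(support), dtype=np.int64)
        if ensure_support and d >= len(support):
            floor += 1
            d -= len(support)
        counts = floor + rng.multinomial(d, probs)
        abundances[s, support] = counts
    samples = tuple(f"sample_{s + 1}" for s in range(n_samples))
    return SimulatedCommunity(samples, abundances, model, depths, seed)


def _apply_errors(
    seq: str, quals: np.ndarray, cfg: ReadSimConfig, rng: np.random.Generator
) -> str:
    arr = list(seq)
    n = len(arr)
    if cfg.substitution_rate > 0:
        hits = np.where(rng.random(n) < cfg.substitution_rate)[0]
        for i in hits:
            arr[i] = sorted(set(_BASES) - {arr[i]})[rng.integers(3)]
    if cfg.n_rate > 0:
        hits = np.where(rng.random(n) < cfg.n_rate)[0]
        for i in hits:
            arr[i] = "N"
    if cfg.homopolymer_rate > 0 and rng.random() < cfg.homopolymer_rate and n >= 8:
        start = int(rng.integers(0, n - 8 + 1))
        base = _BASES[rng.integers(4)]
        arr[start: start + 8] = [base] * 8
    return "".join(arr)


def simulate_reads(
    family: SimulatedFamily,
    community: SimulatedCommunity,
    cfg: ReadSimConfig = ReadSimConfig(),
    seed: int = 0,
) -> tuple[list[ReadPair], pd.DataFrame]:
    """Draw error-bearing paired reads from a community over a family.

    Chimeric pairs splice two distinct parent amplicons (drawn with
    probability proportional to abundance) at a breakpoint uniform over the
    central 70% of the product; junctions in the terminal 15% are
    unidentifiable in principle and are not generated. Returns the read
    pairs and a truth table (read_id, sample, variant, is_chimera, ...).
    """
    if community.abundances.shape[1] != len(family.variants):
        raise ValueError("community and family disagree on the number of variants")
    rng = np.random.default_rng(np.random.SeedSequence([seed, family.seed]).generate_state(1)[0])
    pairs: list[ReadPair] = []
    truth_rows = []
    amplicons = [v.amplicon for v in family.variants]
    for s, sample in enumerate(community.samples):
        counts = community.abundances[s]
        total = counts.sum()
        if total == 0:
            continue
        probs = counts / total
        variant_stream = np.repeat(np.arange(len(counts)), counts)
        rng.shuffle(variant_stream)
        for idx, v_idx in enumerate(variant_stream):
            read_id = f"{sample}|{family.family}|r{idx + 1:06d}"
            is_chimera = bool(rng.random() < cfg.chimera_rate) and (probs > 0).sum() >= 2
            if is_chimera:
                pa = int(rng.choice(len(counts), p=probs))
                pb = pa
                while pb == pa:
                    pb = int(rng.choice(len(counts), p=probs))
                L = len(amplicons[pa])
                breakpoint_ = int(rng.integers(int(0.15 * L), int(0.85 * L)))
                amplicon = amplicons[pa][:breakpoint_] + amplicons[pb][breakpoint_:]
                variant_label = f"chimera:{family.variants[pa].variant_id}+{family.variants[pb].variant_id}"
            else:
                amplicon = amplicons[v_idx]
                variant_label = family.variants[v_idx].variant_id
                breakpoint_ = -1
            read_len = min(cfg.read_length, len(amplicon))
            fwd = amplicon[:read_len]
            rev = revcomp(amplicon)[:read_len]
            fq = 37 - rng.integers(0, 3, size=read_len)
            rq = 37 - rng.integers(0, 3, size=read_len)
            fwd = _apply_errors(fwd, fq, cfg, rng)
            rev = _apply_errors(rev, rq, cfg, rng)
            pairs.append(
                ReadPair(read_id, fwd, rev, tuple(int(q) for q in fq), tuple(int(q) for q in rq), sample)
            )
            truth_rows.append(
                {
                    "read_id": read_id,
                    "sample": sample,
                    "family": family.family,
                    "variant": variant_label,
                    "is_chimera": is_chimera,
                    "breakpoint": breakpoint_,
                    "has_n": "N" in fwd or "N" in rev,
                }
            )
    return pairs, pd.DataFrame(truth_rows)


def write_paired_fastq(pairs: Sequence[ReadPair], fwd_path, rev_path) -> None:
    """Write read pairs as phred+33 paired FASTQ files."""
    with open(fwd_path, "w") as f1, open(rev_path, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.read_id}/1\n{p.fwd_seq}\n+\n{''.join(chr(q + 33) for q in p.fwd_qual)}\n")
            f2.write(f"@{p.read_id}/2\n{p.rev_seq}\n+\n{''.join(chr(q + 33) for q in p.rev_qual)}\n")


def simulate_study(
    outdir: str | Path,
    seed: int = 0,
    families: Sequence[str] = ("GH7", "GH11", "AA2"),
    n_variants: int = 20,
    target_divergence: float = 0.10,
    depths: Sequence[int] = (1000, 1000),
    shared_fraction: float = 0.3,
    cfg: ReadSimConfig = ReadSimConfig(),
) -> dict:
    """Simulate a pooled multi-family two-sample study and write its files.

    Per sample one pair of FASTQ files is written with all families pooled
    (as in a mixed MiSeq library), plus a combined truth table and a
    manifest. Returns a dict with paths, the families and the communities.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed_seq = np.random.SeedSequence(seed)
    children = seed_seq.spawn(len(families))
    sim_families = {}
    communities = {}
    all_pairs: dict[str, list[ReadPair]] = {}
    truths = []
    for fam_name, child in zip(families, children):
        fam_seed = int(child.generate_state(1)[0] % (2**31))
        planted = None
        if fam_name == "AA2":
            cycle = ["MnP", "LiP", "VP", "GP"]
            planted = [cycle[i % 4] for i in range(n_variants)]
        fam = simulate_family(
            fam_name, n_variants, target_divergence, seed=fam_seed,
            planted_subfamilies=planted,
        )
        com = simulate_community(
            n_variants, n_samples=len(depths), depth=list(depths),
            shared_fraction=shared_fraction, seed=fam_seed,
        )
        reads, truth = simulate_reads(fam, com, cfg, seed=fam_seed)
        sim_families[fam_name] = fam
        communities[fam_name] = com
        truths.append(truth)
        for p in reads:
            all_pairs.setdefault(p.sample, []).append(p)
    manifest_rows = []
    for sample, pairs in sorted(all_pairs.items()):
        f1 = outdir / f"{sample}_R1.fastq"
        f2 = outdir / f"{sample}_R2.fastq"
        write_paired_fastq(pairs, f1, f2)
        manifest_rows.append({"sample": sample, "fwd": str(f1), "rev": str(f2), "family": "mixed"})
    manifest = outdir / "manifest.tsv"
    pd.DataFrame(manifest_rows).to_csv(manifest, sep="\t", index=False)
    truth = pd.concat(truths, ignore_index=True)
    truth_path = outdir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    return {
        "manifest": manifest,
        "truth": truth_path,
        "families": sim_families,
        "communities": communities,
        "seed": seed,
    }
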