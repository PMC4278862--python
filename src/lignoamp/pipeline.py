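"""End-to-end orchestration: merge -> QC -> dereplicate -> chimera screen ->
cluster/cutoff -> singleton policy -> translate/classify -> diversity.

Intermediate artifacts are plain text (FASTA/FASTQ/TSV) so any stage can be
swapped against external tools for concordance checks; every run writes a
metadata sidecar recording the configuration and seed, and re-running with
identical inputs is byte-identical.
"""

from __future__ import annotations

import dataclasses
import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml
from Bio import SeqIO

from . import chimera as chimera_mod
from . import cluster as cluster_mod
from . import diversity as diversity_mod
from . import orfs, reads
from .chimera import UniqueSequence
from .primers import PrimerPair, load_primer_bundle
from .reads import MergedRead, ReadPair

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "read_manifest"]


@dataclass
class PipelineConfig:
    primer_bundle: Optional[str] = None
    max_mm: int = 2
    max_homopolymer: int = 7
    gh7_truncation: int = 210
    unmerged_families: tuple[str, ...] = ("GH7",)
    min_overlap: int = 20
    max_overlap_mismatch_frac: float = 0.25
    cutoff: dict = field(default_factory=dict)  # family -> identity % override; else auto
    plateau_frac: float = 0.06
    chimera_min_parent_skew: float = 2.0
    chimera_min_segment_identity: float = 0.99
    chimera_min_score_margin: int = 2
    keep_singletons: bool = False
    diversity_repetitions: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("max_mm", "max_homopolymer", "gh7_truncation", "min_overlap",
                     "diversity_repetitions"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for family, pct in self.cutoff.items():
            if not 80 <= float(pct) <= 100:
                raise ValueError(f"cutoff override for {family} must be in [80, 100]%")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "unmerged_families" in data:
            data["unmerged_families"] = tuple(data["unmerged_families"])
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    qc_log: pd.DataFrame
    curves: dict[str, cluster_mod.ClusterCountCurve]
    cutoffs: dict[str, cluster_mod.SelectedCutoff]
    clusters: dict[str, list[cluster_mod.SequenceCluster]]
    tables: dict[str, cluster_mod.AbundanceTable]
    filtered_tables: dict[str, cluster_mod.AbundanceTable]
    classifications: dict[str, pd.DataFrame]
    diversity: dict[str, pd.DataFrame]
    attrition: pd.DataFrame


def read_manifest(path: str | Path) -> pd.DataFrame:
    manifest = pd.read_csv(path, sep="\t")
    required = {"sample", "fwd", "rev"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest lacks columns {sorted(missing)}")
    if "family" not in manifest.columns:
        manifest["family"] = "mixed"
    for _, row in manifest.iterrows():
        for key in ("fwd", "rev"):
            if not Path(row[key]).exists():
                raise FileNotFoundError(f"manifest file missing: {row[key]}")
    return manifest


def _open_maybe_gz(path: str | Path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _read_pairs(row) -> list[ReadPair]:
    with _open_maybe_gz(row.fwd) as f1, _open_maybe_gz(row.rev) as f2:
        fwd_records = list(SeqIO.parse(f1, "fastq"))
        rev_records = list(SeqIO.parse(f2, "fastq"))
    if len(fwd_records) != len(rev_records):
        raise ValueError(f"{row.sample}: mate files differ in read count")
    out = []
    for r1, r2 in zip(fwd_records, rev_records):
        out.append(
            ReadPair(
                r1.id.removesuffix("/1"),
                str(r1.seq).upper(),
                str(r2.seq).upper(),
                tuple(r1.letter_annotations["phred_quality"]),
                tuple(r2.letter_annotations["phred_quality"]),
                row.sample,
            )
        )
    return out


def _process_pair(
    pair: ReadPair,
    family: Optional[str],
    primer_pairs: dict[str, PrimerPair],
    config: PipelineConfig,
) -> MergedRead:
    """QC one read pair through the family-appropriate route."""
    if family is None:
        family = reads.assign_family(pair.fwd_seq, list(primer_pairs.values()), config.max_mm)
    if family is None or family not in primer_pairs:
        return MergedRead(pair.read_id, "", pair.sample, qc_flags=frozenset({"ambiguous_family"}))
    ppair = primer_pairs[family]
    if family in config.unmerged_families:
        # long product: forward read only, anchored at and trimmed of the
        # forward primer, truncated to a fixed window
        raw = MergedRead(pair.read_id, pair.fwd_seq, pair.sample, family=family)
        try:
            read = reads.truncate_forward(raw, ppair.fwd, config.gh7_truncation, config.max_mm)
        except ValueError:
            return raw.with_flag("primer_mismatch")
    else:
        read = reads.merge_pair(pair, config.min_overlap, config.max_overlap_mismatch_frac)
        if "unmerged" in read.qc_flags:
            return dataclasses.replace(read, family=family)
        read = reads.locate_trim_primers(read, ppair, config.max_mm)
    if not read.qc_flags:
        if not reads.filter_ns(read):
            read = read.with_flag("contains_N")
        if not reads.filter_homopolymer(read, config.max_homopolymer):
            read = read.with_flag("homopolymer")
    return dataclasses.replace(read, family=family)


def _classify_family(
    family: str,
    clusters: Sequence[cluster_mod.SequenceCluster],
) -> pd.DataFrame:
    rows = []
    for cl in clusters:
        result = orfs.translate(cl.representative, frame="infer")
        row = {
            "cluster_id": cl.cluster_id,
            "frame": result.frame,
            "internal_stops": result.internal_stops,
            "stop_free": orfs.stop_codon_screen(result),
            "peptide": result.peptide,
        }
        if family == "AA2":
            call = orfs.classify_aa2(result.peptide)
            row.update(
                subfamily=call.subfamily,
                has_mn_asp=call.has_mn_asp,
                has_cat_trp=call.has_cat_trp,
            )
        elif family == "GH5-5":
            label, pct = orfs.nearest_reference_identity(
                result.peptide, orfs.load_reference_panel()
            )
            row.update(nearest_reference=label, similarity_pct=round(pct, 2))
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(
    manifest: str | Path | pd.DataFrame,
    config: PipelineConfig = PipelineConfig(),
    outdir: Optional[str | Path] = None,
) -> PipelineResult:
    """Run every stage on the samples listed in the manifest.

    The manifest is tab-separated with columns sample, fwd, rev and
    optionally family ("mixed" pools several families per library; reads
    are then assigned by their 5' primer footprint). Artifacts are written
    under ``outdir`` when given; the result object carries everything in
    memory either way.
    """
    if not isinstance(manifest, pd.DataFrame):
        manifest = read_manifest(manifest)
    primer_pairs = load_primer_bundle(config.primer_bundle)

    qc_rows = []
    accepted: dict[str, dict[str, list[MergedRead]]] = {}  # family -> sample -> reads
    for row in manifest.itertuples():
        family_hint = None if row.family == "mixed" else row.family
        for pair in _read_pairs(row):
            read = _process_pair(pair, family_hint, primer_pairs, config)
            qc_rows.append(
                {
                    "read_id": read.read_id,
                    "sample": row.sample,
                    "family": read.family or "unassigned",
                    "flags": ";".join(sorted(read.qc_flags)) or "pass",
                }
            )
            if read.passed and read.trimmed:
                accepted.setdefault(read.family, {}).setdefault(row.sample, []).append(read)
    qc_log = pd.DataFrame(qc_rows)

    curves: dict[str, cluster_mod.ClusterCountCurve] = {}
    cutoffs: dict[str, cluster_mod.SelectedCutoff] = {}
    clusters: dict[str, list[cluster_mod.SequenceCluster]] = {}
    tables: dict[str, cluster_mod.AbundanceTable] = {}
    filtered: dict[str, cluster_mod.AbundanceTable] = {}
    classifications: dict[str, pd.DataFrame] = {}
    diversity: dict[str, pd.DataFrame] = {}
    attrition_rows = []

    for family, by_sample in sorted(accepted.items()):
        pooled_uniques: list[UniqueSequence] = []
        n_in = n_chimeric = 0
        for sample, sample_reads in sorted(by_sample.items()):
            uniques = chimera_mod.dereplicate(
                ((r.read_id, r.sequence) for r in sample_reads), sample=sample
            )
            verdicts = chimera_mod.detect_bimeras(
                uniques,
                min_parent_skew=config.chimera_min_parent_skew,
                min_segment_identity=config.chimera_min_segment_identity,
                min_score_margin=config.chimera_min_score_margin,
            )
            chimeric = {v.query.sequence for v in verdicts if v.is_chimeric}
            n_in += len(sample_reads)
            n_chimeric += sum(u.abundance for u in uniques if u.sequence in chimeric)
            pooled_uniques.extend(u for u in uniques if u.sequence not in chimeric)

        curve = cluster_mod.cluster_count_curve(pooled_uniques)
        curves[family] = curve
        if family in config.cutoff:
            identity = float(config.cutoff[family]) / 100.0
            cutoffs[family] = cluster_mod.SelectedCutoff(
                int(round(100 - float(config.cutoff[family]))), identity, True
            )
        else:
            cutoffs[family] = cluster_mod.select_cutoff(curve, config.plateau_frac)
        family_clusters = cluster_mod.cluster_greedy(pooled_uniques, cutoffs[family].identity)
        clusters[family] = family_clusters
        table = cluster_mod.build_abundance_table(family_clusters)
        tables[family] = table
        filtered[family] = (
            table if config.keep_singletons else cluster_mod.remove_singletons(table)
        )
        classifications[family] = _classify_family(family, family_clusters)
        active = [s for s in table.samples if table.total(s) > 0]
        if len(active) >= 2:
            diversity[family] = diversity_mod.diversity_report(
                table,
                repetitions=config.diversity_repetitions,
                seed=config.seed,
            )
        attrition_rows.append(
            {
                "family": family,
                "reads_in": n_in,
                "chimeric_reads": n_chimeric,
                "reads_clustered": sum(c.total_abundance for c in family_clusters),
                "clusters": len(family_clusters),
                "clusters_non_singleton": int(filtered[family].counts.shape[0]),
            }
        )

    result = PipelineResult(
        qc_log, curves, cutoffs, clusters, tables, filtered, classifications,
        diversity, pd.DataFrame(attrition_rows),
    )
    if outdir is not None:
        _write_result(result, Path(outdir), config)
    return result


def _write_result(result: PipelineResult, outdir: Path, config: PipelineConfig) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.qc_log.to_csv(outdir / "qc_log.tsv", sep="\t", index=False)
    result.attrition.to_csv(outdir / "attrition.tsv", sep="\t", index=False)
    for family in result.curves:
        fam_dir = outdir / family.replace("/", "_")
        fam_dir.mkdir(exist_ok=True)
        result.curves[family].to_frame().to_csv(fam_dir / "curve.tsv", sep="\t", index=False)
        result.tables[family].to_tsv(fam_dir / "abundance.tsv")
        result.filtered_tables[family].to_tsv(fam_dir / "abundance_no_singletons.tsv")
        result.classifications[family].to_csv(fam_dir / "classification.tsv", sep="\t", index=False)
        if family in result.diversity:
            result.diversity[family].to_csv(fam_dir / "diversity.tsv", sep="\t", index=False)
        with open(fam_dir / "representatives.fasta", "w") as fh:
            for cl in result.clusters[family]:
                fh.write(f">{cl.cluster_id};size={cl.total_abundance}\n{cl.representative}\n")
        with open(fam_dir / "representatives_aa.fasta", "w") as fh:
            for _, row in result.classifications[family].iterrows():
                fh.write(f">{row.cluster_id}\n{row.peptide}\n")
    meta = {
        "config": config.to_dict(),
        "seed": config.seed,
        "cutoffs": {
            fam: {"dissimilarity_pct": c.dissimilarity_pct, "identity": c.identity,
                  "plateau_found": c.plateau_found}
            for fam, c in result.cutoffs.items()
        },
    }
    (outdir / "run_metadata.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
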