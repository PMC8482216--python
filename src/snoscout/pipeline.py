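"""End-to-end orchestration: feature filter -> cluster calling ->
classification -> homology -> host correlation -> TU assembly.

`run_all` is the library entry point behind the ``snoscout run-all`` CLI;
every stage writes a deterministic, tab-delimited artifact plus one summary
JSON, so two runs with identical config and seed are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import cluster_call, feature_assign, homology, host_link, sno_annotate, tu_assembly
from .io import (
    read_alignments,
    read_annotation,
    read_fasta,
    read_fasta_with_descriptions,
    write_candidates,
)
from .sno_annotate import ClassifierParams

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    genome: str = ""
    annotation: str = ""                   # GFF3
    bed_paths: dict = field(default_factory=dict)  # feature_class -> BED path
    alignments: str = ""                   # size-selected library (SAM or TSV)
    total_alignments: str = ""             # spliced total-RNA library (TU stage)
    candidate_counts: str = ""             # per-sample counts with locus coords
    host_counts: str = ""                  # gene-level counts
    reference: str = ""                    # known sncRNA FASTA with family tags
    min_mapq: int = 0
    min_reads: int = 20
    merge_gap: int = 0
    min_length: int = 50
    promoter_window: int = 1000
    stranded: bool = False
    same_class_is_unique: bool = True
    classifier: ClassifierParams = field(default_factory=ClassifierParams)
    min_identity: float = 0.8
    min_coverage: float = 0.5
    kmer: int = 11
    junction_min_support: int = 2
    tu_window: int = 10_000
    log_correlation: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cls_params = raw.pop("classifier", None)
        cfg = cls(**raw)
        if cls_params:
            cfg.classifier = ClassifierParams(**cls_params)
        return cfg


def run_all(config: PipelineConfig, outdir: str | Path, force: bool = False) -> dict:
    """Execute every stage and write results under ``outdir``.

    Returns the summary dict (also written as summary.json).  Refuses to
    overwrite an existing result directory unless ``force`` is set; a stage
    failure leaves a FAILED marker naming the stage.
    """
    outdir = Path(outdir)
    if (outdir / "summary.json").exists() and not force:
        raise FileExistsError(f"{outdir} already holds results; pass force=True to redo")
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "FAILED").unlink(missing_ok=True)

    stage = "setup"
    try:
        summary: dict = {"seed": config.seed}

        stage = "assign"
        reads = read_alignments(config.alignments, config.min_mapq)
        features = read_annotation(
            config.annotation or None, config.bed_paths or None, config.promoter_window
        )
        index = feature_assign.build_index(features)
        assignments = feature_assign.assign_reads(
            reads, index, config.stranded, config.same_class_is_unique
        )
        composition = feature_assign.composition_summary(assignments)
        composition.to_csv(outdir / "composition.tsv", sep="\t", index=False)
        label_of = {a.read_id: a.label for a in assignments}

        stage = "call-clusters"
        novel_reads = [r for r in reads if label_of[r.read_id] in ("iR", "IR")]
        candidates = cluster_call.call_clusters(
            novel_reads, label_of, introns=features,
            min_reads=config.min_reads, merge_gap=config.merge_gap,
            min_length=config.min_length,
        )
        genome = read_fasta(config.genome)
        cluster_call.extract_sequences(candidates, genome)
        summary["n_candidates"] = len(candidates)
        summary["candidates_by_context"] = {
            ctx: sum(c.context == ctx for c in candidates)
            for ctx in ("intronic", "intergenic")
        }
        summary["size_statistics"] = (
            cluster_call.size_statistics(candidates) if candidates else None
        )

        stage = "classify"
        class_rows = []
        for c in candidates:
            call = sno_annotate.classify_candidate(c.sequence, config.classifier)
            c.sno_class = call
            class_rows.append({
                "candidate_id": c.candidate_id, "label": call.label,
                "confidence": round(call.confidence, 6),
                "structure_score": round(call.structure_score, 6),
                "boxes": ";".join(
                    f"{h.box}:{h.position}:{h.matched}:{h.mismatches}"
                    for h in call.box_hits
                ),
            })
        pd.DataFrame(
            class_rows, columns=["candidate_id", "label", "confidence", "structure_score", "boxes"]
        ).to_csv(outdir / "class_calls.tsv", sep="\t", index=False)
        labels = [c.sno_class.label for c in candidates]
        summary["class_counts"] = {
            lab: labels.count(lab)
            for lab in ("CD", "HACA", "SCA_CD", "SCA_HACA", "SCA_TANDEM", "unknown")
        }
        summary["n_predicted_sno"] = sum(1 for l in labels if l != "unknown")

        stage = "homology"
        hom_rows = []
        if config.reference:
            refs = read_fasta_with_descriptions(config.reference)
            kindex = homology.build_kmer_index(refs, k=config.kmer)
            for c in candidates:
                hit = homology.assign_family(
                    c.candidate_id, c.sequence, kindex,
                    config.min_identity, config.min_coverage,
                )
                c.homology = hit
                if hit is not None:
                    hom_rows.append({
                        "candidate_id": c.candidate_id, "subject_id": hit.subject_id,
                        "family": hit.subject_family,
                        "identity": round(hit.identity, 6),
                        "coverage": round(hit.query_coverage, 6),
                        "score": hit.alignment_score, "strand": hit.strand,
                    })
        pd.DataFrame(
            hom_rows, columns=["candidate_id", "subject_id", "family", "identity",
                               "coverage", "score", "strand"]
        ).to_csv(outdir / "homology.tsv", sep="\t", index=False)
        summary["n_with_homology"] = len(hom_rows)
        summary["n_unrelated_to_known"] = len(candidates) - len(hom_rows)

        stage = "correlate"
        mean_r = None
        if config.candidate_counts and config.host_counts:
            mean_r = _correlate_stage(config, candidates, features, outdir)
        summary["mean_host_correlation"] = mean_r

        stage = "assemble-tu"
        tu_summary = _tu_stage(config, candidates, outdir)
        summary.update(tu_summary)

        stage = "candidates"
        write_candidates(candidates, outdir / "candidates.bed")

        with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        (outdir / "run_log.txt").write_text(
            "snoscout run-all\nconfig:\n"
            + json.dumps(_config_echo(config), indent=2, sort_keys=True)
            + "\n",
            encoding="utf-8",
        )
        return summary
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n", encoding="utf-8")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def _correlate_stage(config, candidates, features, outdir) -> float | None:
    cand_counts = pd.read_csv(config.candidate_counts, sep="\t", index_col=0)
    host_counts = pd.read_csv(config.host_counts, sep="\t", index_col=0)
    coord_cols = ["contig", "start", "end", "strand"]
    has_coords = all(c in cand_counts.columns for c in coord_cols)
    samples = [c for c in cand_counts.columns if c not in coord_cols]
    pairs = []
    matrix = {}
    for c in candidates:
        if c.context != "intronic":
            continue
        host = host_link.link_host(c, features)
        c.host_gene_id = host
        if host is None or host not in host_counts.index:
            continue
        if has_coords:
            rows = cand_counts[
                (cand_counts["contig"] == c.interval.contig)
                & (cand_counts["start"] < c.interval.end)
                & (cand_counts["end"] > c.interval.start)
            ]
            if rows.empty:
                continue
            overlap = (
                rows[["end"]].to_numpy().clip(max=c.interval.end)
                - rows[["start"]].to_numpy().clip(min=c.interval.start)
            ).ravel()
            row = rows.iloc[int(overlap.argmax())]
        elif c.candidate_id in cand_counts.index:
            row = cand_counts.loc[c.candidate_id]
        else:
            continue
        matrix[c.candidate_id] = row[samples].to_numpy(dtype=float)
        pairs.append((c.candidate_id, host))
    if not pairs:
        pd.DataFrame(columns=["candidate_id", "host_gene_id", "r", "n_samples", "defined"]).to_csv(
            outdir / "correlations.tsv", sep="\t", index=False
        )
        return None
    cand_matrix = pd.DataFrame.from_dict(matrix, orient="index", columns=samples)
    table, mean_r = host_link.correlation_report(
        pairs, cand_matrix, host_counts[ [s for s in samples] ],
        log_transform=config.log_correlation,
    )
    table = table.copy()
    table["r"] = table["r"].round(6)
    table.to_csv(outdir / "correlations.tsv", sep="\t", index=False)
    return mean_r


def _tu_stage(config, candidates, outdir) -> dict:
    intergenic = [c for c in candidates if c.context == "intergenic"]
    tus: dict[str, tu_assembly.TranscriptionalUnit | None] = {}
    assembled = []
    if config.total_alignments and intergenic:
        total_reads = read_alignments(config.total_alignments)
        junctions = tu_assembly.extract_junctions(total_reads, config.junction_min_support)
        coverage = tu_assembly.CoverageTrack(total_reads)
        for c in intergenic:
            tu = tu_assembly.assemble_tu(c, junctions, coverage, window=config.tu_window)
            tus[c.candidate_id] = tu
            if tu is not None:
                assembled.append(tu)
    else:
        tus = {c.candidate_id: None for c in intergenic}
    table = tu_assembly.classify_intergenic(intergenic, tus)
    table.to_csv(outdir / "tu_classification.tsv", sep="\t", index=False)
    tu_assembly.write_tu_gff3(assembled, outdir / "tus.gff3")
    return {
        "n_intergenic": len(intergenic),
        "n_intron_hosted_novel_TU": len(assembled),
        "n_autonomous_or_unknown": len(intergenic) - len(assembled),
    }


def _config_echo(config: PipelineConfig) -> dict:
    d = asdict(config)
    d["classifier"] = asdict(config.classifier)
    return d
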