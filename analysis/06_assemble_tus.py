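"""Reconstruct transcriptional units around intergenic candidates from
spliced total-RNA evidence and reclassify the hosted ones.

An intergenic snoRNA inside a junction-evidenced intron is not autonomous:
it marks an unannotated host transcript.
"""

from _common import RESULTS_DIR, load_candidates


def main() -> None:
    from snoscout.io import read_alignments
    from snoscout.tu_assembly import (
        CoverageTrack,
        assemble_tu,
        classify_intergenic,
        extract_junctions,
        write_tu_gff3,
    )

    paths, _, candidates = load_candidates()
    total_reads = read_alignments(paths["total_alignments"])
    junctions = extract_junctions(total_reads)
    coverage = CoverageTrack(total_reads)
    intergenic = [c for c in candidates if c.context == "intergenic"]
    tus = {c.candidate_id: assemble_tu(c, junctions, coverage) for c in intergenic}
    table = classify_intergenic(intergenic, tus)
    RESULTS_DIR.mkdir(exist_ok=True)
    table.to_csv(RESULTS_DIR / "06_tu_classification.tsv", sep="\t", index=False)
    assembled = [t for t in tus.values() if t is not None]
    write_tu_gff3(assembled, RESULTS_DIR / "06_tus.gff3")
    print(table.to_string(index=False))
    print(f"\n{len(junctions)} junctions; {len(assembled)}/{len(intergenic)} "
          "intergenic candidates reclassified as hosted by a novel transcript")


if __name__ == "__main__":
    main()
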