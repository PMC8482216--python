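"""Call candidate sncRNA loci: clusters of >= 20 distinct reads in intronic
or intergenic space, with read-end-consensus boundaries and genomic
sequences attached.
"""

import pandas as pd

from _common import RESULTS_DIR, load_candidates


def main() -> None:
    from snoscout.cluster_call import size_statistics

    _, _, candidates = load_candidates()
    table = pd.DataFrame([{
        "candidate_id": c.candidate_id, "contig": c.interval.contig,
        "start": c.interval.start, "end": c.interval.end,
        "strand": c.interval.strand, "length": len(c.interval),
        "read_count": c.read_count, "max_depth": c.max_depth,
        "context": c.context,
    } for c in candidates])
    RESULTS_DIR.mkdir(exist_ok=True)
    table.to_csv(RESULTS_DIR / "03_candidates.tsv", sep="\t", index=False)
    stats = size_statistics(candidates)
    by_ctx = table.context.value_counts().to_dict()
    print(table.head(10).to_string(index=False))
    print(f"\n{len(candidates)} candidates ({by_ctx}); length mean "
          f"{stats['mean']:.1f} nt, median {stats['median']:.0f}, "
          f"range {stats['min']:.0f}-{stats['max']:.0f}")


if __name__ == "__main__":
    main()
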