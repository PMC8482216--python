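"""Generate the synthetic study conditions and summarize what was planted.

A ~200 kb genome carries 8 four-exon genes, 30 snoRNA loci (10 C/D,
10 H/ACA, 10 scaRNA; 24 intronic, 6 intergenic of which 4 sit inside
unannotated two-exon transcripts), 10 decoy loci held below 20 reads, and a
size-selected read library (50-200 nt inserts) plus spliced total-RNA
evidence and correlated candidate/host expression counts.
"""

import pandas as pd

from _common import RESULTS_DIR, dataset_paths


def main() -> None:
    paths = dataset_paths()
    truth = pd.read_csv(paths["truth_loci"], sep="\t")
    overview = (
        truth.groupby(["sno_class", "context"])
        .agg(n=("locus_id", "size"),
             mean_length=("end", lambda e: float((e - truth.loc[e.index, "start"]).mean())),
             mean_depth=("simulated_reads", "mean"))
        .reset_index()
    )
    RESULTS_DIR.mkdir(exist_ok=True)
    overview.to_csv(RESULTS_DIR / "01_dataset_overview.tsv", sep="\t", index=False)
    print(overview.to_string(index=False))
    decoys = truth[truth.sno_class == "decoy"]
    print(f"\n{len(truth) - len(decoys)} planted snoRNA loci, "
          f"{len(decoys)} decoys (max decoy depth {decoys.simulated_reads.max()} reads); "
          f"files under {paths['genome'].parent}")


if __name__ == "__main__":
    main()
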