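"""Assign every read of the size-selected library to one genomic feature
class and tabulate the composition.

Reads over exons, promoters, UTRs, known sncRNAs or repeats are removed
from novelty calling; reads spanning two different feature classes are
dropped as MF (multiple feature); what survives is the intronic (iR) and
intergenic (IR) read population the cluster caller consumes.
"""

from _common import RESULTS_DIR, load_assigned


def main() -> None:
    from snoscout.feature_assign import composition_summary

    _, reads, _, assignments = load_assigned()
    table = composition_summary(assignments)
    RESULTS_DIR.mkdir(exist_ok=True)
    table.to_csv(RESULTS_DIR / "02_composition.tsv", sep="\t", index=False)
    print(table.to_string(index=False))
    novel = table.set_index("label").loc[["iR", "IR"], "count"].sum()
    print(f"\n{len(reads)} reads total; {novel} in intronic/intergenic space "
          "feed cluster calling")


if __name__ == "__main__":
    main()
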