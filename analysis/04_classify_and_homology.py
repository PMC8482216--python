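"""Classify candidates into snoRNA classes from box motifs and structure,
and assign homology to the known-sncRNA reference families."""

import pandas as pd

from _common import RESULTS_DIR, load_candidates


def main() -> None:
    from snoscout.homology import assign_family, build_kmer_index
    from snoscout.io import read_fasta_with_descriptions
    from snoscout.sno_annotate import ClassifierParams, classify_candidate

    paths, _, candidates = load_candidates()
    params = ClassifierParams()
    index = build_kmer_index(read_fasta_with_descriptions(paths["known_sncrnas"]))
    rows = []
    for c in candidates:
        call = classify_candidate(c.sequence, params)
        hit = assign_family(c.candidate_id, c.sequence, index)
        rows.append({
            "candidate_id": c.candidate_id, "context": c.context,
            "class": call.label, "confidence": round(call.confidence, 3),
            "homolog": hit.subject_id if hit else "",
            "homolog_family": hit.subject_family if hit else "",
            "identity": round(hit.identity, 3) if hit else "",
        })
    table = pd.DataFrame(rows)
    RESULTS_DIR.mkdir(exist_ok=True)
    table.to_csv(RESULTS_DIR / "04_class_and_homology.tsv", sep="\t", index=False)
    print(table["class"].value_counts().to_string())
    n_hom = (table.homolog != "").sum()
    print(f"\n{(table['class'] != 'unknown').sum()}/{len(table)} candidates "
          f"predicted as snoRNAs; {n_hom} have a known homolog, "
          f"{len(table) - n_hom} are unrelated to the reference set")


if __name__ == "__main__":
    main()
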