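"""Shared plumbing for the numbered analysis drivers: dataset location,
lazy generation, and the stages every driver builds on."""

from __future__ import annotations

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

DATA_DIR = ROOT / "scratch" / "data"
RESULTS_DIR = ROOT / "results"
SEED = 1


def dataset_paths() -> dict:
    """Generate the synthetic dataset once under scratch/data (seeded)."""
    from snoscout.synthetic_data import SimulationConfig, simulate_dataset

    marker = DATA_DIR / "truth_loci.tsv"
    if not marker.exists():
        simulate_dataset(SimulationConfig(seed=SEED), DATA_DIR)
    return {p.stem: p for p in DATA_DIR.iterdir()}


def load_assigned():
    """Reads + annotation + per-read feature labels (the Fig-style filter)."""
    from snoscout import feature_assign
    from snoscout.io import read_alignments, read_annotation

    paths = dataset_paths()
    reads = read_alignments(paths["medium_alignments"])
    features = read_annotation(paths["annotation"])
    index = feature_assign.build_index(features)
    assignments = feature_assign.assign_reads(reads, index)
    return paths, reads, features, assignments


def load_candidates():
    from snoscout import cluster_call
    from snoscout.io import read_fasta

    paths, reads, features, assignments = load_assigned()
    label_of = {a.read_id: a.label for a in assignments}
    novel = [r for r in reads if label_of[r.read_id] in ("iR", "IR")]
    candidates = cluster_call.call_clusters(novel, label_of, introns=features)
    cluster_call.extract_sequences(candidates, read_fasta(paths["genome"]))
    return paths, features, candidates
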