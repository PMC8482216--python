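"""Host-gene assignment for intronic candidates and candidate–host
expression correlation.

Counts are log(x+1)-transformed before the Pearson correlation (raw mode
available); an undefined correlation (zero variance) is reported as None
and excluded from the summary mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cluster_call import Candidate
from .io import FeatureRecord

log = logging.getLogger(__name__)


@dataclass
class CorrelationResult:
    candidate_id: str
    host_gene_id: str
    r: float | None
    n_samples: int


def link_host(candidate: Candidate, annotation: Sequence[FeatureRecord]) -> str | None:
    """The gene whose intron fully contains an intronic candidate.

    When introns of several genes contain it, the gene whose intron
    boundaries are nearest (smallest total distance from the candidate to
    the intron ends) wins; ties break lexicographically and are logged.
    Intergenic candidates map to None.
    """
    if candidate.context == "intergenic":
        return None
    iv = candidate.interval
    hits = []
    for feat in annotation:
        if feat.feature_class != "iR" or feat.gene_id is None:
            continue
        if feat.interval.contains(iv):
            slack = (iv.start - feat.interval.start) + (feat.interval.end - iv.end)
            hits.append((slack, feat.gene_id))
    if not hits:
        raise ValueError(
            f"candidate {candidate.candidate_id} labeled intronic but no intron "
            "record contains it (inconsistent upstream assignment)"
        )
    hits.sort()
    genes = {g for _, g in hits}
    if len(genes) > 1:
        log.info("candidate %s inside introns of %d genes; choosing %s "
                 "(nearest boundaries)", candidate.candidate_id, len(genes), hits[0][1])
    return hits[0][1]


def pearson(x: Sequence[float], y: Sequence[float], log_transform: bool = True) -> float | None:
    """Product-moment correlation of (optionally log(x+1)-transformed)
    count vectors; None when either vector has zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("pearson requires equal-length vectors of >= 3 samples")
    if log_transform:
        x = np.log1p(x)
        y = np.log1p(y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        log.warning("zero-variance vector; correlation undefined")
        return None
    return float(stats.pearsonr(x, y).statistic)


def correlation_report(
    pairs: Sequence[tuple[str, str]],
    candidate_counts: pd.DataFrame,
    host_counts: pd.DataFrame,
    log_transform: bool = True,
) -> tuple[pd.DataFrame, float | None]:
    """Per-pair correlations plus the mean over defined values.

    Both matrices are rows=ids, columns=samples; sample columns must agree.
    Pairs with undefined r are flagged (``defined`` = False) and excluded
    from the mean.
    """
    samples = [c for c in candidate_counts.columns if c in host_counts.columns]
    missing = [c for c in candidate_counts.columns if c not in host_counts.columns]
    if missing or not samples:
        raise ValueError(f"sample columns missing from host counts: {missing}")
    rows = []
    for cand_id, host_id in pairs:
        if cand_id not in candidate_counts.index:
            raise ValueError(f"candidate {cand_id} absent from candidate counts")
        if host_id not in host_counts.index:
            raise ValueError(f"gene {host_id} absent from host counts")
        r = pearson(
            candidate_counts.loc[cand_id, samples].to_numpy(),
            host_counts.loc[host_id, samples].to_numpy(),
            log_transform=log_transform,
        )
        rows.append({
            "candidate_id": cand_id, "host_gene_id": host_id,
            "r": np.nan if r is None else r, "n_samples": len(samples),
            "defined": r is not None,
        })
    table = pd.DataFrame(rows, columns=["candidate_id", "host_gene_id", "r", "n_samples", "defined"])
    defined = table.loc[table["defined"], "r"]
    mean_r = float(defined.mean()) if len(defined) else None
    return table, mean_r
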