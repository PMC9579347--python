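"""Binding-affinity scoring and the pipeline's filtering rules.

The binding affinity of a DBS is the product of its length and the
arithmetic mean identity of the triplexes at the site, with identity as a
fraction — a 100-bp DBS whose triplexes average 60% identity scores 60.
Only DBSs with affinity strictly above the threshold (default 60) are
carried into comparative analyses.

A genome-scale prefilter selects lncRNAs that plausibly act in the
nucleus: a lncRNA qualifies when it has strictly more than
``tts_threshold`` raw TTSs (pre-merge triplexes, the unit a genome-wide
triplex screen reports) across the promoter set.
"""

from __future__ import annotations

import pandas as pd

from .triplex import DBS, TriplexParams, find_triplexes


def binding_affinity(dbs: DBS) -> float:
    """DBS length x mean member identity (identity as a fraction)."""
    if dbs.length < 1:
        raise ValueError("zero-length DBS")
    return dbs.length * dbs.mean_identity


def filter_dbs_by_affinity(dbs_list: list[DBS], threshold: float = 60.0,
                           strict: bool = True) -> list[DBS]:
    """Retain DBSs with affinity > threshold (strict by default)."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if strict:
        return [d for d in dbs_list if binding_affinity(d) > threshold]
    return [d for d in dbs_list if binding_affinity(d) >= threshold]


def passes_tts_threshold(tts_count: int, tts_threshold: int = 2000) -> bool:
    """Strict comparison: exactly ``tts_threshold`` TTSs fails."""
    return tts_count > tts_threshold


def nuclear_lncrna_prefilter(lncrna, promoter_set,
                             params: TriplexParams = TriplexParams(),
                             tts_threshold: int = 2000) -> tuple[bool, int]:
    """Count a lncRNA's raw TTSs across a promoter set and test the cutoff.

    Returns ``(passes, tts_count)``; counting happens before any DBS
    merging.
    """
    if not promoter_set:
        raise ValueError("promoter_set must be non-empty")
    count = 0
    for prom in promoter_set:
        count += len(find_triplexes(lncrna, prom, params))
    return passes_tts_threshold(count, tts_threshold), count


def summarize_dbs(dbs_by_sample: dict[str, list[DBS]]) -> pd.DataFrame:
    """Per-sample summary: lncRNA count, DBS count, mean length, mean affinity.

    Means are arithmetic over the retained DBSs of the sample; affinity is
    on the length x identity-fraction scale, reported to 1 decimal.  Empty
    samples get zero rows with an explicit flag.
    """
    rows = []
    for sample, dbss in dbs_by_sample.items():
        if dbss:
            rows.append({
                "sample": sample,
                "lncrna_count": len({d.lncrna_id for d in dbss}),
                "dbs_count": len(dbss),
                "mean_dbs_length": round(sum(d.length for d in dbss) / len(dbss), 1),
                "mean_affinity": round(
                    sum(binding_affinity(d) for d in dbss) / len(dbss), 1),
                "empty": False,
            })
        else:
            rows.append({"sample": sample, "lncrna_count": 0, "dbs_count": 0,
                         "mean_dbs_length": 0.0, "mean_affinity": 0.0,
                         "empty": True})
    return pd.DataFrame(rows)
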