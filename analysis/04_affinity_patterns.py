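#!/usr/bin/env python
"""Per-lncRNA affinity orderings across species on the ordering-design
cohort.

Reads the ``patterns`` cohort (60% of lncRNAs built to bind strongest in
the focal species, 40% in the second), scans each lncRNA against its
target promoters in all three genomes, applies the best-DBD rule and the
affinity filter, classifies each lncRNA's per-species mean affinity
ordering, and compares recovered proportions with the designed ones.
"""

import json
import pathlib
import sys

import pandas as pd

from lncdbs import comparative, seqio
from lncdbs.cohort import CohortConfig
from lncdbs.scoring import filter_dbs_by_affinity
from lncdbs.triplex import best_dbd_dbs, find_triplexes

ROOT = pathlib.Path(__file__).resolve().parents[1]
COHORT = ROOT / "scratch" / "cohorts" / "patterns"
OUT = ROOT / "results" / "patterns"
SPECIES = ("horse", "donkey", "przewalski")


def main() -> int:
    if not COHORT.exists():
        sys.exit("run analysis/01_simulate_cohorts.py first")
    cfg = CohortConfig(**{k: (tuple(v) if isinstance(v, list) else v)
                          for k, v in json.load(
                              open(COHORT / "cohort_config.json")).items()})
    manifest = pd.read_csv(COHORT / "truth_manifest.tsv", sep="\t")
    assemblies = {sp: seqio.load_genome(COHORT / f"{sp}.fa", name=sp)
                  for sp in SPECIES}
    annotation = seqio.read_gff(COHORT / "horse.gff3")
    gmap = {g.gene_id: g for g in annotation}
    lncrnas = {g.gene_id: seqio.assemble_lncrna(g, assemblies["horse"])
               for g in annotation if g.biotype == "lncRNA"}
    targets = manifest.groupby("lncrna_id")["gene_id"].unique()

    dbs_by_sp = {}
    for sp in SPECIES:
        kept = []
        for lnc_id, lnc in lncrnas.items():
            ts = []
            for gid in sorted(targets[lnc_id]):
                window = seqio.extract_promoter(
                    gmap[gid], assemblies[sp], cfg.upstream, cfg.downstream)
                ts.extend(find_triplexes(lnc.seq, window.seq,
                                         lncrna_id=lnc_id, promoter_id=gid))
            if ts:
                _, dbss = best_dbd_dbs(ts)
                kept.extend(filter_dbs_by_affinity(dbss, 60.0))
        dbs_by_sp[sp] = kept

    patterns, excluded = comparative.classify_patterns(dbs_by_sp)
    props = comparative.pattern_proportions(patterns)
    OUT.mkdir(parents=True, exist_ok=True)
    table = pd.DataFrame(
        [{"label": k, "proportion": round(v, 4),
          "count": sum(p.label == k for p in patterns),
          "designed": (cfg.pattern_fractions or {}).get(k, 0.0)}
         for k, v in props.items()])
    table.to_csv(OUT / "pattern_proportions.tsv", sep="\t", index=False)
    print(f"classified {len(patterns)} lncRNAs "
          f"({len(excluded)} excluded as inactive in some species)")
    print(table.to_string(index=False))
    print(f"\ntable under {OUT}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
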