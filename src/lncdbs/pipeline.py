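"""End-to-end orchestration of the two study designs.

Two group designs are supported, mirroring a chronological series of
samples of one species and an interspecific trio of related genomes:

* ``chronological`` — a modern reference plus ancient consensus samples
  (FASTA, or VCF applied to the reference).  Stages: consensus →
  extraction → N-filters → triplex scan → summaries → lncRNA distance
  matrix between samples.
* ``interspecific`` — several species with shared gene ids.  Stages:
  extraction → N-filters → lncRNA homolog search → triplex scan →
  TTS-count prefilter → best-DBD rule → affinity filter → summaries →
  DBS orthology, affinity-ordering patterns, per-gene counts.
* ``simulate+both`` — generate a synthetic cohort first, then run both
  designs on it and cross-check stage counts against the truth manifest.

Every tabular output is TSV with ``#`` metadata headers carrying the
exact seed and parameter set; a run manifest (JSON) records per-stage
record counts.  With ``resume=True``, stages whose outputs already exist
are not rewritten; the expensive scan stage is reloaded from its table.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field, fields

import pandas as pd

from . import comparative, scoring, seqio
from .cohort import Cohort, CohortConfig, generate_cohort, write_cohort
from .triplex import ALL_MOTIFS, DBS, Triplex, TriplexParams, best_dbd_dbs, find_triplexes

MODES = ("chronological", "interspecific", "simulate+both")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    mode: str = "simulate+both"
    outdir: str = "pipeline_out"
    seed: int = 0
    # data sources (non-simulate modes)
    species: list[str] = field(default_factory=list)
    focal: str = ""
    ancient_samples: list[str] = field(default_factory=list)
    genome_paths: dict[str, str] = field(default_factory=dict)
    gff_paths: dict[str, str] = field(default_factory=dict)
    vcf_paths: dict[str, str] = field(default_factory=dict)
    genes_file: str | None = None
    ncds_file: str | None = None
    # simulate mode
    cohort: CohortConfig | None = None
    # thresholds (defaults reproduce the reference analysis settings)
    upstream: int = 3500
    downstream: int = 1500
    lncrna_n_max: float = 0.10
    promoter_n_max: float = 0.30
    min_identity: float = 0.60
    min_length: int = 50
    merge_overlap: int = 1
    affinity_min: float = 60.0
    tts_min: int = 2000
    flank: int = 100_000
    tie_tol: float = 0.0
    affinity_filter_ancient: bool = False
    motifs: tuple[str, ...] = ALL_MOTIFS

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")

    @property
    def params(self) -> TriplexParams:
        return TriplexParams(min_identity=self.min_identity,
                             min_length=self.min_length, motifs=self.motifs,
                             merge_overlap=self.merge_overlap)

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        return cls.from_dict(parse_config_file(path))

    @classmethod
    def from_dict(cls, raw: dict[str, str]) -> "PipelineConfig":
        kwargs: dict = {}
        cohort_kwargs: dict = {}
        cohort_types = {f.name: f for f in fields(CohortConfig)}
        simple = {f.name: f for f in fields(cls)}
        for key, val in raw.items():
            if key.startswith("cohort."):
                name = key[len("cohort."):]
                if name not in cohort_types:
                    raise KeyError(f"unknown cohort key {name!r}")
                cohort_kwargs[name] = _coerce(val, cohort_types[name].type)
            elif key.startswith("genome."):
                kwargs.setdefault("genome_paths", {})[key[7:]] = val
            elif key.startswith("gff."):
                kwargs.setdefault("gff_paths", {})[key[4:]] = val
            elif key.startswith("vcf."):
                kwargs.setdefault("vcf_paths", {})[key[4:]] = val
            elif key in ("species", "ancient_samples"):
                kwargs[key] = [s.strip() for s in val.split(",") if s.strip()]
            elif key == "motifs":
                kwargs[key] = tuple(s.strip() for s in val.split(","))
            elif key in simple:
                kwargs[key] = _coerce(val, simple[key].type)
            else:
                raise KeyError(f"unknown config key {key!r}")
        if cohort_kwargs or kwargs.get("mode") == "simulate+both":
            if "seed" in kwargs and "seed" not in cohort_kwargs:
                cohort_kwargs["seed"] = int(kwargs["seed"])
            kwargs["cohort"] = CohortConfig(**cohort_kwargs)
        return cls(**kwargs)


def _coerce(val: str, ftype) -> object:
    t = str(ftype)
    if "bool" in t:
        return str(val).strip().lower() in ("1", "true", "yes", "on")
    if "int" in t:
        return int(val)
    if "float" in t:
        return float(val)
    return val


def parse_config_file(path: str) -> dict[str, str]:
    """Flat ``key = value`` format; '#' starts a comment."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"bad config line: {line!r}")
            key, val = line.split("=", 1)
            out[key.strip()] = val.strip()
    return out


# ---------------------------------------------------------------------------
# small I/O helpers


def _tsv_header(config: PipelineConfig, stage: str) -> list[str]:
    return [f"stage={stage}", f"seed={config.seed}",
            "params=" + json.dumps({
                "min_identity": config.min_identity,
                "min_length": config.min_length,
                "affinity_min": config.affinity_min,
                "tts_min": config.tts_min,
                "flank": config.flank,
                "upstream": config.upstream,
                "downstream": config.downstream,
            }, sort_keys=True)]


def write_tsv(df: pd.DataFrame, path: str, config: PipelineConfig,
              stage: str) -> None:
    with open(path, "w") as fh:
        for line in _tsv_header(config, stage):
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def dbs_table(dbs_by_sample: dict[str, list[DBS]],
              promoters: dict[str, dict[str, seqio.PromoterWindow]]
              ) -> pd.DataFrame:
    rows = []
    for sample, dbss in dbs_by_sample.items():
        for d in dbss:
            window = promoters[sample][d.promoter_id]
            rows.append({
                "sample": sample, "lncrna_id": d.lncrna_id,
                "gene_id": d.promoter_id, "start": d.start, "end": d.end,
                "length": d.length,
                "mean_identity": round(d.mean_identity, 4),
                "affinity": round(scoring.binding_affinity(d), 1),
                "n_members": len(d.members),
                "motifs": ",".join(sorted({t.motif for t in d.members})),
                "strands": ",".join(sorted({t.purine_strand for t in d.members})),
                "seq": window.seq[d.start:d.end],
            })
    return pd.DataFrame(rows, columns=[
        "sample", "lncrna_id", "gene_id", "start", "end", "length",
        "mean_identity", "affinity", "n_members", "motifs", "strands", "seq"])


def _dbs_from_table(df: pd.DataFrame) -> dict[str, list[DBS]]:
    """Rebuild minimal DBS objects (one synthetic member triplex each, with
    the recorded mean identity) from a scan table."""
    out: dict[str, list[DBS]] = {}
    for row in df.itertuples(index=False):
        matches = int(round(row.mean_identity * row.length))
        member = Triplex(lncrna_id=row.lncrna_id, promoter_id=row.gene_id,
                         tfo_start=0, tfo_end=row.length,
                         tts_start=row.start, tts_end=row.end,
                         purine_strand="+", motif="pyrimidine",
                         orientation="parallel", matches=matches)
        out.setdefault(row.sample, []).append(
            DBS(promoter_id=row.gene_id, lncrna_id=row.lncrna_id,
                start=int(row.start), end=int(row.end), members=[member]))
    return out


# ---------------------------------------------------------------------------
# shared stages


def extract_promoters(assembly: seqio.GenomeAssembly,
                      genes: list[seqio.GeneModel], candidate_ids: list[str],
                      config: PipelineConfig
                      ) -> dict[str, seqio.PromoterWindow]:
    by_id = {g.gene_id: g for g in genes}
    missing = [gid for gid in candidate_ids if gid not in by_id]
    if missing:
        raise PipelineError("extract", f"genes absent from annotation: {missing}")
    windows = {}
    for gid in candidate_ids:
        w = seqio.extract_promoter(by_id[gid], assembly,
                                   upstream=config.upstream,
                                   downstream=config.downstream)
        windows[gid] = w
    return windows


def scan_sample(lncrnas: dict[str, str],
                promoters: dict[str, seqio.PromoterWindow],
                config: PipelineConfig, apply_tts_min: bool = True,
                apply_affinity: bool = True
                ) -> tuple[list[DBS], dict[str, int], dict[str, str]]:
    """Scan one sample: triplexes → TTS prefilter → best DBD → affinity.

    Returns (retained DBSs, per-lncRNA TTS counts, drop reasons).
    """
    params = config.params
    kept: list[DBS] = []
    tts_counts: dict[str, int] = {}
    drops: dict[str, str] = {}
    for lnc_id, lnc_seq in lncrnas.items():
        triplexes: list[Triplex] = []
        for gid, window in promoters.items():
            triplexes.extend(find_triplexes(
                lnc_seq, window.seq, params, lncrna_id=lnc_id, promoter_id=gid))
        tts_counts[lnc_id] = len(triplexes)
        if not triplexes:
            drops[lnc_id] = "no_triplexes"
            continue
        if apply_tts_min and not scoring.passes_tts_threshold(
                len(triplexes), config.tts_min):
            drops[lnc_id] = "tts_count_below_threshold"
            continue
        _, dbss = best_dbd_dbs(triplexes, config.merge_overlap)
        if apply_affinity:
            dbss = scoring.filter_dbs_by_affinity(dbss, config.affinity_min)
        if dbss:
            kept.extend(dbss)
        else:
            drops[lnc_id] = "no_dbs_after_filters"
    return kept, tts_counts, drops


# ---------------------------------------------------------------------------
# the two designs


def run_interspecific(assemblies: dict[str, seqio.GenomeAssembly],
                      genes_by_sp: dict[str, list[seqio.GeneModel]],
                      focal: str,
                      focal_lncrnas: dict[str, seqio.LncRNASequence],
                      candidate_genes: list[str], ncds_genes: list[str],
                      config: PipelineConfig, outdir: str,
                      resume: bool = False) -> dict:
    os.makedirs(outdir, exist_ok=True)
    counts: dict[str, dict] = {}
    species = list(assemblies)

    # extraction + N filters
    promoters: dict[str, dict[str, seqio.PromoterWindow]] = {}
    for sp in species:
        ws = extract_promoters(assemblies[sp], genes_by_sp[sp],
                               candidate_genes, config)
        kept = seqio.filter_by_n(list(ws.values()), config.promoter_n_max)
        promoters[sp] = {w.gene_id: w for w in kept}
    lnc_kept = seqio.filter_by_n(list(focal_lncrnas.values()),
                                 config.lncrna_n_max)
    counts["extract"] = {sp: len(promoters[sp]) for sp in species}
    counts["lncrna_filter"] = {"in": len(focal_lncrnas), "out": len(lnc_kept)}

    # homolog search for non-focal species
    lncrnas_by_sp: dict[str, dict[str, str]] = {
        focal: {l.lncrna_id: l.seq for l in lnc_kept}}
    homolog_counts: dict[str, int] = {}
    for sp in species:
        if sp == focal:
            continue
        idxs = {c: comparative.KmerIndex(s, 16)
                for c, s in assemblies[sp].contigs.items()}
        found: dict[str, str] = {}
        for l in lnc_kept:
            hit = comparative.find_lncrna_homolog(l.seq, assemblies[sp],
                                                  indexes=idxs)
            if hit is not None:
                found[l.lncrna_id] = hit.seq
        lncrnas_by_sp[sp] = found
        homolog_counts[sp] = len(found)
    counts["homologs"] = homolog_counts
    shared = set(lncrnas_by_sp[focal])
    for sp in species[1:]:
        shared &= set(lncrnas_by_sp.get(sp, {}))
    counts["shared_lncrnas"] = len(shared)

    # triplex scan per species (shared lncRNAs only)
    scan_path = os.path.join(outdir, "dbs.tsv")
    if resume and os.path.exists(scan_path):
        dbs_by_sp = _dbs_from_table(read_tsv(scan_path))
        counts["scan"] = {sp: len(dbs_by_sp.get(sp, [])) for sp in species}
    else:
        dbs_by_sp = {}
        for sp in species:
            lset = {k: v for k, v in lncrnas_by_sp[sp].items() if k in shared}
            dbss, tts_counts, drops = scan_sample(lset, promoters[sp], config)
            dbs_by_sp[sp] = dbss
            counts.setdefault("scan", {})[sp] = len(dbss)
            counts.setdefault("scan_drops", {})[sp] = drops
        write_tsv(dbs_table(dbs_by_sp, promoters), scan_path, config, "scan")

    # summaries
    summary = scoring.summarize_dbs(dbs_by_sp)
    write_tsv(summary, os.path.join(outdir, "summary.tsv"), config, "summary")

    # orthology: all ordered species pairs
    calls_by_dir: dict[tuple[str, str], list[comparative.OrthologyCall]] = {}
    window_cache: dict[tuple[str, str], comparative.KmerIndex] = {}
    for src in species:
        src_proms = promoters[src]
        for tgt in species:
            if tgt == src:
                continue
            tgt_genes = {g.gene_id: g for g in genes_by_sp[tgt]}
            calls = []
            for d in dbs_by_sp.get(src, []):
                seq = src_proms[d.promoter_id].seq[d.start:d.end]
                gene = tgt_genes.get(d.promoter_id)
                idx = None
                if gene is not None:
                    key = (tgt, gene.gene_id)
                    idx = window_cache.get(key)
                    if idx is None:
                        idx = comparative.orthology_window_index(
                            gene, assemblies[tgt], config.flank)
                        window_cache[key] = idx
                calls.append(comparative.dbs_orthology(
                    seq, f"{d.lncrna_id}:{d.promoter_id}:{d.start}", gene,
                    assemblies[tgt], target_species=tgt, flank=config.flank,
                    window_index=idx))
            calls_by_dir[(src, tgt)] = calls
    ortho = comparative.orthology_table(calls_by_dir)
    write_tsv(ortho, os.path.join(outdir, "orthology.tsv"), config, "orthology")

    # affinity-ordering patterns
    patterns, excluded = comparative.classify_patterns(dbs_by_sp, config.tie_tol)
    if patterns:
        props = comparative.pattern_proportions(patterns)
        pat_df = pd.DataFrame(
            [{"label": k, "proportion": round(v, 4),
              "count": sum(p.label == k for p in patterns)}
             for k, v in props.items()])
    else:
        pat_df = pd.DataFrame(columns=["label", "proportion", "count"])
    write_tsv(pat_df, os.path.join(outdir, "patterns.tsv"), config, "patterns")
    counts["patterns"] = {"classified": len(patterns), "excluded": len(excluded)}

    # per-gene counts over the NCDS list
    gene_counts = comparative.per_gene_dbs_counts(
        dbs_by_sp, ncds_genes or candidate_genes,
        known_genes=set(candidate_genes))
    write_tsv(gene_counts, os.path.join(outdir, "per_gene_counts.tsv"),
              config, "per_gene_counts")

    manifest = {"design": "interspecific", "seed": config.seed,
                "counts": counts}
    with open(os.path.join(outdir, "run_manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    return {"counts": counts, "dbs_by_species": dbs_by_sp,
            "summary": summary, "orthology": ortho, "patterns": pat_df,
            "per_gene_counts": gene_counts}


def run_chronological(samples: dict[str, seqio.GenomeAssembly],
                      annotation: list[seqio.GeneModel],
                      candidate_genes: list[str], config: PipelineConfig,
                      outdir: str, resume: bool = False) -> dict:
    os.makedirs(outdir, exist_ok=True)
    counts: dict[str, dict] = {}
    lnc_models = [g for g in annotation if g.biotype == "lncRNA"]

    lnc_by_sample: dict[str, dict[str, str]] = {}
    promoters: dict[str, dict[str, seqio.PromoterWindow]] = {}
    for name, asm in samples.items():
        lncs = [seqio.assemble_lncrna(g, asm) for g in lnc_models]
        kept = seqio.filter_by_n(lncs, config.lncrna_n_max)
        lnc_by_sample[name] = {l.lncrna_id: l.seq for l in kept}
        ws = extract_promoters(asm, annotation, candidate_genes, config)
        pkept = seqio.filter_by_n(list(ws.values()), config.promoter_n_max)
        promoters[name] = {w.gene_id: w for w in pkept}
    # the shared lncRNA set across all samples (the analyzable intersection)
    shared = set.intersection(*[set(d) for d in lnc_by_sample.values()])
    counts["lncrna_filter"] = {name: len(d) for name, d in lnc_by_sample.items()}
    counts["shared_lncrnas"] = len(shared)
    counts["promoter_filter"] = {name: len(p) for name, p in promoters.items()}

    scan_path = os.path.join(outdir, "dbs.tsv")
    if resume and os.path.exists(scan_path):
        dbs_by_sample = _dbs_from_table(read_tsv(scan_path))
        counts["scan"] = {s: len(d) for s, d in dbs_by_sample.items()}
    else:
        dbs_by_sample = {}
        for name in samples:
            lset = {k: v for k, v in lnc_by_sample[name].items() if k in shared}
            dbss, _, drops = scan_sample(
                lset, promoters[name], config, apply_tts_min=False,
                apply_affinity=config.affinity_filter_ancient)
            dbs_by_sample[name] = dbss
            counts.setdefault("scan", {})[name] = len(dbss)
        write_tsv(dbs_table(dbs_by_sample, promoters), scan_path, config, "scan")

    summary = scoring.summarize_dbs(dbs_by_sample)
    write_tsv(summary, os.path.join(outdir, "summary.tsv"), config, "summary")

    # mean per-lncRNA p-distance between samples
    names = list(samples)
    dist = pd.DataFrame(0.0, index=names, columns=names)
    for i, x in enumerate(names):
        for y in names[i + 1:]:
            ds = [comparative.pairwise_distance(lnc_by_sample[x][l],
                                                lnc_by_sample[y][l])
                  for l in sorted(shared)]
            d = sum(ds) / len(ds) if ds else 0.0
            dist.loc[x, y] = d
            dist.loc[y, x] = d
    dist_out = dist.round(6).reset_index().rename(columns={"index": "sample"})
    write_tsv(dist_out, os.path.join(outdir, "lncrna_distances.tsv"),
              config, "distances")

    manifest = {"design": "chronological", "seed": config.seed, "counts": counts}
    with open(os.path.join(outdir, "run_manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    return {"counts": counts, "dbs_by_sample": dbs_by_sample,
            "summary": summary, "distances": dist}


# ---------------------------------------------------------------------------
# top-level entry


def _load_gene_list(path: str) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def run_pipeline(config: PipelineConfig, resume: bool = False) -> dict:
    """Execute the configured design(s); returns the report bundle."""
    os.makedirs(config.outdir, exist_ok=True)
    report: dict = {"mode": config.mode, "seed": config.seed}

    if config.mode == "simulate+both":
        cohort_cfg = config.cohort or CohortConfig(seed=config.seed)
        cohort = generate_cohort(cohort_cfg)
        cohort_dir = os.path.join(config.outdir, "cohort")
        write_cohort(cohort, cohort_dir)
        report["cohort_dir"] = cohort_dir
        report["truth_records"] = len(cohort.manifest)
        report["interspecific"] = _interspecific_from_cohort(
            cohort, config, os.path.join(config.outdir, "interspecific"),
            resume)
        report["chronological"] = _chronological_from_cohort(
            cohort, config, os.path.join(config.outdir, "chronological"),
            resume)
        return report

    if config.mode == "interspecific":
        assemblies = {sp: seqio.load_genome(config.genome_paths[sp], name=sp)
                      for sp in config.species}
        genes_by_sp = {sp: seqio.read_gff(config.gff_paths[sp])
                       for sp in config.species}
        focal = config.focal or config.species[0]
        lnc_models = [g for g in genes_by_sp[focal] if g.biotype == "lncRNA"]
        focal_lncrnas = {g.gene_id: seqio.assemble_lncrna(g, assemblies[focal])
                         for g in lnc_models}
        candidates = (_load_gene_list(config.genes_file) if config.genes_file
                      else [g.gene_id for g in genes_by_sp[focal]
                            if g.biotype == "coding"])
        ncds = (_load_gene_list(config.ncds_file) if config.ncds_file
                else candidates)
        report["interspecific"] = run_interspecific(
            assemblies, genes_by_sp, focal, focal_lncrnas, candidates, ncds,
            config, config.outdir, resume)
        return report

    # chronological
    samples: dict[str, seqio.GenomeAssembly] = {}
    focal = config.focal or config.species[0]
    reference = seqio.load_genome(config.genome_paths[focal], name=focal)
    samples[focal] = reference
    for name in config.ancient_samples:
        if name in config.genome_paths:
            samples[name] = seqio.load_genome(config.genome_paths[name],
                                              name=name)
        elif name in config.vcf_paths:
            samples[name] = seqio.apply_variants(reference,
                                                 config.vcf_paths[name])
        else:
            raise PipelineError("consensus", f"no genome or VCF for {name!r}")
    annotation = seqio.read_gff(config.gff_paths[focal])
    candidates = (_load_gene_list(config.genes_file) if config.genes_file
                  else [g.gene_id for g in annotation if g.biotype == "coding"])
    report["chronological"] = run_chronological(
        samples, annotation, candidates, config, config.outdir, resume)
    return report


def _interspecific_from_cohort(cohort: Cohort, config: PipelineConfig,
                               outdir: str, resume: bool) -> dict:
    cfg = dataclasses.replace(
        config, upstream=cohort.config.upstream,
        downstream=cohort.config.downstream, flank=cohort.config.flank)
    genes_by_sp = {sp: cohort.genes for sp in cohort.species}
    return run_interspecific(
        dict(cohort.assemblies), genes_by_sp, cohort.focal,
        dict(cohort.lncrnas), [g.gene_id for g in cohort.genes],
        cohort.ncds_genes, cfg, outdir, resume)


def _chronological_from_cohort(cohort: Cohort, config: PipelineConfig,
                               outdir: str, resume: bool) -> dict:
    cfg = dataclasses.replace(
        config, upstream=cohort.config.upstream,
        downstream=cohort.config.downstream, flank=cohort.config.flank)
    samples = {cohort.focal: cohort.assemblies[cohort.focal]}
    for anc in cohort.ancient:
        samples[anc.name] = anc.assembly
    annotation = cohort.genes + cohort.lncrna_genes
    return run_chronological(samples, annotation,
                             [g.gene_id for g in cohort.genes], cfg, outdir,
                             resume)
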