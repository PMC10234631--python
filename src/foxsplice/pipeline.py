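"""End-to-end orchestration: simulate -> deg -> classify -> enrich -> splice-sites -> retention.

One master seed expands deterministically into per-stage seeds, every stage
writes its artifacts as plain-text tables (TSV / FASTA / BED / JSON), and the
run report echoes the configuration together with per-stage record counts so
every reported number is re-derivable from the persisted intermediates. Runs
with identical configuration are byte-identical.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from foxsplice import __version__, synthetic
from foxsplice.config import SimulationConfig, stage_seed
from foxsplice.deg import deg_pipeline, split_by_direction, filter_expressed, MIN_RPKM
from foxsplice.enrichment import directional_enrichment, DEFAULT_R
from foxsplice.ms_catalog import build_pairs, collapse_to_genes, label_counts
from foxsplice.retention import compare_retained_vs_control, select_events, MV_DPSI_CUTOFF
from foxsplice.splice import (extract_splice_sites, gene_average_pfm, information_content,
                              classify_py_tract, train_wmm, score_site)

ALL_STAGES = ("simulate", "deg", "classify", "enrich", "splice_sites", "retention")


@dataclass
class PipelineConfig:
    """Single configuration covering every stage."""

    seed: int = 0
    outdir: str = "results/pipeline"
    stages: tuple = ALL_STAGES
    sim: SimulationConfig = None  # seeded from the master seed when omitted
    min_rpkm: float = MIN_RPKM
    shrna: str = "Sh3"
    expression_mode: str = "all"
    resamples: int = 10_000
    n_control: int = 500
    mv_cutoff: float = MV_DPSI_CUTOFF
    intron_profile: str = "crich"

    def __post_init__(self) -> None:
        if self.sim is None:
            self.sim = SimulationConfig(seed=stage_seed(self.seed, "simulate"))
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sim"] = self.sim.to_dict()
        d["stages"] = list(self.stages)
        return d

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "sim" in d and d["sim"] is not None:
            d["sim"] = SimulationConfig.from_dict(d["sim"])
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the toggled stages, write artifacts, and return the run report."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "config": config.to_dict(), "stages": {}}
    sim = config.sim

    expression = truth = pairs = intron_set = events = None
    if "simulate" in config.stages:
        expression, truth = synthetic.gen_expression_table(sim)
        pairs = synthetic.gen_ms_pair_table(sim)
        intron_set = synthetic.gen_intron_set(sim, config.intron_profile)
        events, ev_truth = synthetic.gen_retention_events(intron_set, sim)
        synthetic.write_tsv(expression, out / "expression.tsv")
        synthetic.write_tsv(truth, out / "expression_truth.tsv")
        synthetic.write_tsv(pairs, out / "ms_pairs.tsv")
        synthetic.write_fasta(intron_set.genome, out / "genome.fa")
        synthetic.write_bed(intron_set.bed_rows(), out / "introns.bed")
        synthetic.write_tsv(events, out / "events.tsv")
        synthetic.write_tsv(ev_truth, out / "events_truth.tsv")
        report["stages"]["simulate"] = {
            "n_genes": len(expression),
            "n_pairs": len(pairs),
            "n_introns": len(intron_set.records),
            "n_events": len(events),
        }

    donors = synthetic.donor_labels(sim)
    up = down = None
    if "deg" in config.stages:
        if expression is None:
            expression = synthetic.read_tsv(out / "expression.tsv")
        calls = deg_pipeline(expression, donors, config.shrna,
                             config.min_rpkm, config.expression_mode)
        up, down = split_by_direction(calls)
        deg_df = pd.DataFrame(
            {"gene_id": [c.gene_id for c in calls],
             "direction": [c.direction for c in calls]}).sort_values("gene_id")
        synthetic.write_tsv(deg_df, out / "degs.tsv")
        report["stages"]["deg"] = {
            "n_input_genes": len(expression),
            "n_degs": len(calls),
            "n_up": len(up),
            "n_down": len(down),
            "n_discordant": len(calls) - len(up) - len(down),
        }

    gene_sets = None
    if "classify" in config.stages:
        if pairs is None:
            pairs = synthetic.read_tsv(out / "ms_pairs.tsv")
        classified = build_pairs(pairs)
        gene_sets = collapse_to_genes(classified)
        counts = label_counts(classified)
        pair_df = pd.DataFrame([{"snp_id": p.snp_id, "gene_id": p.gene_id,
                                 "odds_ratio": p.odds_ratio, "nes": p.nes,
                                 "label": p.label} for p in classified])
        synthetic.write_tsv(pair_df, out / "ms_pairs_classified.tsv")
        report["stages"]["classify"] = {
            "n_pairs": len(classified),
            "pair_labels": counts,
            "n_susceptibility_genes": len(gene_sets.susceptibility),
            "n_pathogenic_genes": len(gene_sets.pathogenic),
            "n_protective_genes": len(gene_sets.protective),
            "n_conflicted_genes": len(gene_sets.conflicted),
        }

    if "enrich" in config.stages:
        if up is None or gene_sets is None:
            raise ValueError("enrich stage requires the deg and classify stages")
        universe = filter_expressed(
            expression, [c for c in expression.columns if c.startswith("rpkm_")],
            config.min_rpkm)
        results = directional_enrichment(
            up, down, gene_sets.pathogenic, gene_sets.protective, universe,
            R=config.resamples, seed=stage_seed(config.seed, "enrich"))
        enrich_report = {name: r.to_dict() for name, r in results.items()}
        with open(out / "enrichment.json", "w") as fh:
            json.dump(enrich_report, fh, indent=2, sort_keys=True)
        report["stages"]["enrich"] = {
            name: {"k": r.k, "empirical_p": r.empirical_p, "exact_p": r.exact_p,
                   "null_mode": r.null_mode}
            for name, r in results.items()
        }

    records = None
    if "splice_sites" in config.stages:
        genome = intron_set.genome if intron_set is not None else None
        if genome is None:
            import pyfaidx
            genome = pyfaidx.Fasta(str(out / "genome.fa"))
        bed = (intron_set.bed_rows() if intron_set is not None
               else synthetic.read_bed(out / "introns.bed"))
        records = extract_splice_sites(genome, bed)
        by_gene: dict[str, list] = {}
        for r in records:
            by_gene.setdefault(r.gene_id, []).append(r)
        pfm_frames = []
        n_crich = 0
        for gene_id in sorted(by_gene):
            pfm = gene_average_pfm(by_gene[gene_id])
            label, _ = classify_py_tract(pfm)
            n_crich += label == "C-rich"
            frame = pfm.to_frame()
            frame.insert(0, "gene_id", gene_id)
            frame.insert(1, "position", frame.index)
            ic, _ = information_content(pfm)
            frame["information_bits"] = ic
            pfm_frames.append(frame)
        synthetic.write_tsv(pd.concat(pfm_frames, ignore_index=True), out / "gene_pfms.tsv")
        report["stages"]["splice_sites"] = {
            "n_introns_extracted": len(records),
            "n_genes": len(by_gene),
            "n_genes_crich": n_crich,
            "n_noncanonical": sum(not r.canonical for r in records),
        }

    if "retention" in config.stages:
        if events is None:
            events = synthetic.read_tsv(out / "events.tsv")
        if records is None:
            raise ValueError("retention stage requires the splice_sites stage")
        classified_events = select_events(events, config.mv_cutoff)
        intron_by_pos = {(r.chrom, r.start, r.end, r.strand): r for r in records}
        intron_map = {}
        for row in events.itertuples(index=False):
            rec = intron_by_pos.get((row.chrom, row.start, row.end, row.strand))
            if rec is not None:
                intron_map[row.event_id] = rec
        model_3ss = train_wmm([r.three_ss for r in records], "3ss")
        model_5ss = train_wmm([r.five_ss for r in records], "5ss")
        scores = {
            "5ss": {e: score_site(model_5ss, r.five_ss) for e, r in intron_map.items()},
            "3ss": {e: score_site(model_3ss, r.three_ss) for e, r in intron_map.items()},
        }
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # short control sets are expected at small n
            comparison = compare_retained_vs_control(
                events, intron_map, scores, config.mv_cutoff, config.n_control,
                seed=stage_seed(config.seed, "retention"))
        synthetic.write_tsv(classified_events, out / "events_classified.tsv")
        class_counts = classified_events["class"].value_counts().to_dict()
        report["stages"]["retention"] = {
            "n_events": len(events),
            "class_counts": {k: int(v) for k, v in sorted(class_counts.items())},
            "n_retained_compared": comparison.n_retained,
            "n_control_compared": comparison.n_control,
            "composition_means": comparison.composition_means,
            "composition_pvalues": comparison.composition_pvalues,
            "score_medians": comparison.score_medians,
            "score_pvalues": comparison.score_pvalues,
            "outliers_removed": comparison.outliers_removed,
            "n_missing_sequence": comparison.n_missing_sequence,
        }

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# input validation


def validate_inputs(paths: dict, max_rows: int = 5) -> list[dict]:
    """Schema-check each input kind; returns diagnostics instead of raising.

    ``paths`` maps an input kind (``expression``, ``pairs``, ``bed``,
    ``events``) to a file path. Each diagnostic names the violated rule and
    lists up to ``max_rows`` offending rows.
    """
    diagnostics: list[dict] = []

    def add(kind, rule, rows):
        if len(rows):
            diagnostics.append({"input": kind, "rule": rule,
                                "offending_rows": rows[:max_rows]})

    if "expression" in paths:
        df = synthetic.read_tsv(paths["expression"])
        if "gene_id" not in df.columns:
            add("expression", "gene_id column required", [list(df.columns)])
        rpkm_cols = [c for c in df.columns if c.startswith("rpkm_")]
        if not rpkm_cols:
            add("expression", "at least one rpkm_* column required", [list(df.columns)])
        else:
            bad = df.index[(df[rpkm_cols] < 0).any(axis=1)].tolist()
            add("expression", "RPKM values must be >= 0", bad)

    if "pairs" in paths:
        df = synthetic.read_tsv(paths["pairs"])
        missing = [c for c in ("snp_id", "gene_id", "odds_ratio") if c not in df.columns]
        if missing:
            add("pairs", f"required columns missing: {missing}", [list(df.columns)])
        else:
            bad = df.index[~(df["odds_ratio"] > 0)].tolist()
            add("pairs", "odds ratio must satisfy OR > 0", bad)

    if "bed" in paths:
        rows = synthetic.read_bed(paths["bed"])
        bad = [i for i, r in enumerate(rows) if r[1] >= r[2]]
        add("bed", "interval must satisfy start < end", bad)
        bad = [i for i, r in enumerate(rows) if len(r) > 5 and r[5] not in ("+", "-")]
        add("bed", "strand must be + or -", bad)

    if "events" in paths:
        df = synthetic.read_tsv(paths["events"])
        missing = [c for c in ("event_id", "dpsi", "mv_dpsi") if c not in df.columns]
        if missing:
            add("events", f"required columns missing: {missing}", [list(df.columns)])
        else:
            add("events", "mv_dpsi must be >= 0", df.index[df["mv_dpsi"] < 0].tolist())
            bad = df.index[(df["dpsi"] < -100) | (df["dpsi"] > 100)].tolist()
            add("events", "dpsi must lie in [-100, 100]", bad)

    return diagnostics
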