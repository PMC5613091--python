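"""End-to-end orchestration: run every analysis stage on a genome (+ optional
hit table) and write a report bundle of TSV/JSON/Newick artefacts."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genome_io import GenomeSet, load_genome
from .replication import (DEFAULT_MOTIFS, find_repabc_modules,
                          find_solitary_replicases, type_module)
from .composition import (cumulative_gc_skew, predict_ori_ter,
                          windowed_gc_content, windowed_gc_skew)
from .codon_usage import (classify_chromids, cluster_units, dendrogram_newick,
                          ordinate, replicon_rscu, rscu_matrix, RSCU_CODONS)
from .painting import (GroupConfig, paint_genes, read_hit_table,
                       segment_origin_blocks, summarize_origins)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All tunables of the pipeline (defaults: 1,000/10,000-bp windows, 500-bp palindrome pad, 11-42-bp spacers,
    E < 1e-5, self TaxID 293088, close group TaxID 356)."""

    sequence_path: str = ""
    feature_table: Optional[str] = None
    hit_table: Optional[str] = None
    designated_chromosome: Optional[str] = None
    output_dir: str = "plasmidfusion_out"
    motifs: dict = field(default_factory=lambda: dict(DEFAULT_MOTIFS))
    pad: int = 500
    min_spacer: int = 11
    max_spacer: int = 42
    max_mismatch: int = 0
    max_operon_gap: int = 2000
    gc_window: int = 1000
    skew_window: int = 10000
    evalue_cutoff: float = 1e-5
    self_taxids: tuple = (293088,)
    close_group_taxid: int = 356
    max_hits: int = 500
    chromid_threshold_factor: float = 0.5
    chromid_absolute_threshold: float = 1.5
    min_block: int = 3
    masked_products: str = r"transposase"
    seed: int = 0

    def validate(self) -> None:
        if self.max_spacer < self.min_spacer:
            raise ValueError(
                f"max_spacer {self.max_spacer} < min_spacer {self.min_spacer}")
        if self.pad < 0 or self.gc_window < 1 or self.skew_window < 1:
            raise ValueError("windows and pad must be positive")
        if self.evalue_cutoff <= 0:
            raise ValueError("evalue cutoff must be > 0")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return RunConfig(**data)


def run_pipeline(cfg: RunConfig, genome: Optional[GenomeSet] = None,
                 hits: Optional[pd.DataFrame] = None) -> dict:
    """Run all stages in dependency order, writing a report bundle under
    ``cfg.output_dir``; optional stages degrade to 'skipped'.  Returns the
    JSON-serializable summary."""
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if genome is None:
        genome = load_genome(cfg.sequence_path, cfg.feature_table,
                             cfg.designated_chromosome)
    if hits is None and cfg.hit_table:
        hits = read_hit_table(cfg.hit_table)

    summary: dict = {
        "tool": "plasmidfusion", "version": __version__,
        "config_hash": cfg.config_hash(), "seed": cfg.seed,
        "replicons": {r.id: r.length for r in genome.replicons},
        "designated_chromosome": genome.designated_chromosome,
        "stages": {},
    }

    # --- replication modules + palindrome typing -------------------------
    module_rows = []
    n_modules = n_solitary = 0
    for rep in genome.replicons:
        modules = find_repabc_modules(rep, max_operon_gap=cfg.max_operon_gap)
        for m in modules:
            type_module(m, rep, cfg.motifs, cfg.pad, cfg.max_mismatch,
                        cfg.min_spacer, cfg.max_spacer)
            d = m.doublet
            w0 = m.window[0] if m.window else 0
            module_rows.append({
                "replicon": rep.id, "span_start": m.span[0], "span_end": m.span[1],
                "strand": m.strand, "locus_tags": ";".join(m.locus_tags),
                "compat_label": m.compat_label,
                "doublet_first": w0 + d.first.position - 1 if d else "",
                "doublet_second": w0 + d.second.position - 1 if d else "",
                "spacer": d.spacer if d else "",
            })
        n_modules += len(modules)
        sol = find_solitary_replicases(rep, max_operon_gap=cfg.max_operon_gap)
        n_solitary += len(sol)
        for f in sol:
            module_rows.append({
                "replicon": rep.id, "span_start": f.start, "span_end": f.end,
                "strand": f.strand, "locus_tags": f.locus_tag,
                "compat_label": "solitary_repC", "doublet_first": "",
                "doublet_second": "", "spacer": "",
            })
    pd.DataFrame(module_rows).to_csv(out / "repabc_modules.tsv", sep="\t", index=False)
    summary["stages"]["replication_modules"] = {
        "status": "ok", "n_modules": n_modules, "n_solitary_replicases": n_solitary,
        "labels": sorted(r["compat_label"] for r in module_rows),
    }

    # --- composition ------------------------------------------------------
    comp = {}
    for rep in genome.replicons:
        gc = windowed_gc_content(rep, cfg.gc_window)
        skew = windowed_gc_skew(rep, cfg.skew_window)
        pd.DataFrame({"position": gc.centers, "gc_content": gc.values,
                      "deviation": gc.deviation_from_mean}).to_csv(
            out / f"{rep.id}.gc_content.tsv", sep="\t", index=False)
        pd.DataFrame({"position": skew.centers, "gc_skew": skew.values}).to_csv(
            out / f"{rep.id}.gc_skew.tsv", sep="\t", index=False)
        entry = {"mean_gc": gc.mean}
        try:
            pred = predict_ori_ter(cumulative_gc_skew(rep), rep.topology)
            entry.update(ori=pred.ori_position, ter=pred.ter_position,
                         method=pred.method)
        except ValueError as exc:
            entry["ori_error"] = str(exc)
        comp[rep.id] = entry
    (out / "composition.json").write_text(json.dumps(comp, indent=1, sort_keys=True))
    summary["stages"]["composition"] = {"status": "ok", **{k: v for k, v in comp.items()}}

    # --- codon usage / chromid calls -------------------------------------
    profiles = [replicon_rscu(r) for r in genome.replicons]
    mat = rscu_matrix(profiles)
    pd.DataFrame(mat, index=[p.unit_id for p in profiles],
                 columns=list(RSCU_CODONS)).to_csv(out / "rscu_matrix.tsv", sep="\t")
    rscu_stage = {"status": "ok"}
    if len(profiles) >= 3:
        ordn = ordinate(profiles)
        pd.DataFrame({
            "unit": ordn.unit_ids,
            "PC1": ordn.coords[:, 0], "PC2": ordn.coords[:, 1],
        }).to_csv(out / "rscu_ordination.tsv", sep="\t", index=False)
        rscu_stage["explained_variance_pct_2d"] = float(
            ordn.explained_variance_pct[:2].sum())
    else:
        rscu_stage["ordination"] = "skipped (needs >= 3 replicons)"
    if len(profiles) >= 2:
        Z, labels = cluster_units(profiles)
        (out / "rscu_dendrogram.nwk").write_text(dendrogram_newick(Z, labels))
    calls = classify_chromids(profiles, genome.designated_chromosome,
                              cfg.chromid_threshold_factor,
                              cfg.chromid_absolute_threshold)
    pd.DataFrame([asdict(c) for c in calls]).to_csv(
        out / "chromid_calls.tsv", sep="\t", index=False)
    rscu_stage["chromid_calls"] = {c.replicon_id: c.call for c in calls}
    summary["stages"]["codon_usage"] = rscu_stage

    # --- origin painting --------------------------------------------------
    if hits is None:
        summary["stages"]["origin_painting"] = {"status": "skipped",
                                                "reason": "no hit table"}
    else:
        gcfg = GroupConfig(self_taxids=frozenset(cfg.self_taxids),
                           close_group_taxid=cfg.close_group_taxid,
                           evalue_cutoff=cfg.evalue_cutoff, max_hits=cfg.max_hits)
        paint_stage = {"status": "ok", "per_replicon": {}}
        call_rows, block_rows = [], []
        for rep in genome.replicons:
            feats = rep.cds_features()
            if not feats:
                continue
            calls = paint_genes(hits, [f.locus_tag for f in feats], gcfg)
            for c, f in zip(calls, feats):
                c.start, c.end, c.product = f.start, f.end, f.product
                call_rows.append({"replicon": rep.id, "locus_tag": c.locus_tag,
                                  "start": c.start, "end": c.end,
                                  "origin": c.origin,
                                  "close_fraction": round(c.close_fraction, 4)})
            summ = summarize_origins(calls, gcfg)
            paint_stage["per_replicon"][rep.id] = summ
            try:
                seg = segment_origin_blocks(calls, cfg.min_block,
                                            cfg.masked_products, gcfg,
                                            circular=rep.topology == "circular",
                                            replicon_length=rep.length)
                for b in seg.blocks:
                    block_rows.append({"replicon": rep.id, "start": b.start,
                                       "end": b.end, "origin": b.dominant_origin,
                                       "n_genes": b.n_genes})
                paint_stage["per_replicon"][rep.id]["n_blocks"] = len(seg.blocks)
                paint_stage["per_replicon"][rep.id]["breakpoints"] = seg.breakpoints
            except ValueError as exc:
                paint_stage["per_replicon"][rep.id]["segmentation_error"] = str(exc)
        pd.DataFrame(call_rows).to_csv(out / "origin_calls.tsv", sep="\t", index=False)
        pd.DataFrame(block_rows).to_csv(out / "origin_blocks.tsv", sep="\t", index=False)
        summary["stages"]["origin_painting"] = paint_stage

    (out / "report.json").write_text(json.dumps(summary, indent=1, sort_keys=True,
                                                default=str))
    return summary
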