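"""Orchestration: qc → (delineation) → ancestral reconstruction → scan → summaries.

Runs the whole per-orthogroup cascade over a directory of inputs and writes
a reproducible run directory:

``sites.tsv``
    every detected convergent/parallel site (original 1-based coordinates)
``summary.tsv``
    site/gene counts per foreground subset, both counting conventions
``removals.tsv``
    per-stage removal log (orthogroup, sequence, stage, reason)
``manifest.json``
    parameters, seed, model name and per-stage orthogroup counts

Inputs are post-delineation orthogroups: ``<og>.faa`` (protein alignment)
with ``<og>.nwk`` (rooted gene tree); an optional ``<og>.fna`` supplies
coding sequences for the premature-stop filter.  When a leaf→species map is
configured, ortholog-clade delineation and the single-copy rule run first
and non-qualifying orthogroups are skipped.  Reruns with the same
configuration produce byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import qc_filters
from .convergence import scan_identical, summarize_scan
from .orthologs import extract_ortholog_clades, select_single_copy
from .phylo_model import load_model, marginal_asr
from .seqio import (Msa, PhyloTree, ValidationError, parse_newick,
                    read_fasta_cds, read_fasta_msa, read_species_map,
                    restrict_tree, site_records_frame, write_site_report)

PAPER_DEFAULTS = {
    "min_len": 20,
    "min_cov": 0.30,
    "min_taxa": 2,
    "b3": 2,
    "b4": 5,
    "gap_mode": "half",
    "min_support": 0.95,
    "min_species": 4,
    "min_outgroups": 2,
    "max_family_members": 100,
    "fdr": 0.05,
    "require_exclusive": True,
    "min_outgroup_residues": 2,
    "min_anc_posterior": 0.0,
    "model": "LG",
    "plus_f": True,
    "mask": True,
}


@dataclass
class PipelineConfig:
    input_dir: str
    out_dir: str
    foreground: list[str]
    species_map: Optional[str] = None
    seed: int = 0
    options: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {k: raw.pop(k) for k in
                 ("input_dir", "out_dir", "foreground", "species_map", "seed")
                 if k in raw}
        return cls(options=raw.get("options", {}), **known)

    def opt(self, key: str):
        return self.options.get(key, PAPER_DEFAULTS[key])


def _qc_one(og: str, msa: Msa, cds, cfg: PipelineConfig,
            removals: list[dict]) -> Optional[Msa]:
    def log(recs):
        removals.extend({"orthogroup": og, "sequence": r.seq_id,
                         "stage": r.stage, "reason": r.reason} for r in recs)

    if cds is not None:
        kept_cds, removed = qc_filters.remove_premature_stops(cds)
        log(removed)
        bad = {r.seq_id for r in removed}
        remaining = [i for i in msa.ids if i not in bad]
        if len(remaining) < 2:
            return None
        msa = msa.select_rows(remaining).drop_allgap_columns()

    msa, removed = qc_filters.clean_alignment(
        msa, cfg.opt("min_len"), cfg.opt("min_cov"), cfg.opt("min_taxa"))
    log(removed)
    if msa is None:
        return None

    if cfg.opt("mask"):
        msa = qc_filters.mask_blocks(msa, b3=cfg.opt("b3"), b4=cfg.opt("b4"),
                                     gap_mode=cfg.opt("gap_mode"))
        if msa.n_columns == 0:
            removals.append({"orthogroup": og, "sequence": "*",
                             "stage": "mask_blocks", "reason": "no_columns"})
            return None

    msa, removed = qc_filters.drop_high_missing(msa)
    log(removed)
    if msa is None or msa.n_sequences < 2:
        return None
    return msa


def run_pipeline(config: PipelineConfig | str | Path) -> Path:
    """Execute the full scan; returns the run directory.

    Per-orthogroup failures are logged and skipped; an empty or missing
    input directory fails fast naming the qc stage.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    cfg = config
    in_dir = Path(cfg.input_dir)
    alignments = sorted(in_dir.glob("*.faa"))
    if not alignments:
        raise ValidationError(f"qc stage: no .faa alignments in {in_dir}")
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    species_of = read_species_map(cfg.species_map) if cfg.species_map else None
    model = load_model(cfg.opt("model")) if not cfg.opt("plus_f") else None

    removals: list[dict] = []
    records = []
    stage_counts = {"input": len(alignments), "qc_dropped": 0,
                    "delineation_dropped": 0, "scan_failed": 0, "scanned": 0}
    skip_log: list[dict] = []

    for fasta in alignments:
        og = fasta.stem
        try:
            msa = read_fasta_msa(fasta)
            tree_path = fasta.with_suffix(".nwk")
            if not tree_path.exists():
                raise ValidationError("missing gene tree")
            tree = parse_newick(tree_path.read_text(), species_of=species_of)
            cds_path = fasta.with_suffix(".fna")
            cds = read_fasta_cds(cds_path) if cds_path.exists() else None

            if species_of is not None:
                targets = {species_of.get(t, t) for t in cfg.foreground}
                sets = extract_ortholog_clades(
                    tree, cfg.opt("min_support"), cfg.opt("min_species"))
                singles = select_single_copy(sets, targets,
                                             cfg.opt("min_outgroups"))
                members = set().union(*(s.member_ids for s in singles)) \
                    if singles else set()
                if not set(cfg.foreground) <= members:
                    stage_counts["delineation_dropped"] += 1
                    skip_log.append({"orthogroup": og, "stage": "delineation",
                                     "reason": "not_single_copy"})
                    continue

            msa = _qc_one(og, msa, cds, cfg, removals)
            if msa is None:
                stage_counts["qc_dropped"] += 1
                skip_log.append({"orthogroup": og, "stage": "qc",
                                 "reason": "dropped"})
                continue

            shared = [i for i in msa.ids if i in set(tree.leaf_labels)]
            if len(shared) < 2:
                raise ValidationError("alignment and tree share < 2 taxa")
            msa = msa.select_rows(shared)
            tree = restrict_tree(tree, shared)
            fg = [t for t in cfg.foreground if t in shared]
            if len(fg) < 2:
                stage_counts["scan_failed"] += 1
                skip_log.append({"orthogroup": og, "stage": "scan",
                                 "reason": "foreground_lost_in_qc"})
                continue

            og_model = (load_model(cfg.opt("model"), msa_for_frequencies=msa)
                        if cfg.opt("plus_f") else model)
            asr = marginal_asr(tree, msa, og_model)
            records.extend(scan_identical(
                tree, asr, msa, fg,
                require_exclusive=cfg.opt("require_exclusive"),
                min_outgroup_residues=cfg.opt("min_outgroup_residues"),
                min_anc_posterior=cfg.opt("min_anc_posterior"),
                orthogroup_id=og))
            stage_counts["scanned"] += 1
        except ValidationError as exc:
            stage_counts["scan_failed"] += 1
            skip_log.append({"orthogroup": og, "stage": "error",
                             "reason": str(exc)})

    write_site_report(records, out_dir / "sites.tsv")
    summarize_scan(records, cfg.foreground).to_csv(
        out_dir / "summary.tsv", sep="\t", index=False)
    pd.DataFrame(removals, columns=["orthogroup", "sequence", "stage",
                                    "reason"]).to_csv(
        out_dir / "removals.tsv", sep="\t", index=False)
    manifest = {
        "seed": cfg.seed,
        "foreground": sorted(cfg.foreground),
        "parameters": {k: cfg.opt(k) for k in sorted(PAPER_DEFAULTS)},
        "stage_counts": stage_counts,
        "skipped": skip_log,
        "n_records": len(records),
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out_dir
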