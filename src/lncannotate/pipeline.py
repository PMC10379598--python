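"""End-to-end orchestration: predict -> align -> filter -> classify ->
conserve -> annotate, with a cascade report and resumable outputs.

The single YAML/dict config carries per-stage blocks and a global seed.
Any stage's product may be supplied precomputed (a predictions TSV instead
of training, blast-tab hits instead of the native search).  Outputs are
plain TSV/BED/CSV files; a manifest keyed by the hash of the config and
all inputs lets an unchanged rerun be skipped entirely.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import classifier as clf
from . import conservation as cons
from . import io as lio
from . import location as loc
from . import reports, stats
from .core import SequenceRecord

logger = logging.getLogger(__name__)

__all__ = ["default_config", "run_all"]


def default_config() -> dict:
    """All tunable thresholds with their standard defaults."""
    return {
        "seed": 1,
        "min_length": 200,             # nt; lncRNA length convention
        "mrna_to_lncrna_ratio": 2,
        "train_fraction": 0.8,
        "n_replicates": 5,
        "min_identity": 50.0,          # percent, inclusive
        "max_evalue": 1e-50,           # blast-tab ingestion path
        "tpm_threshold": 1.0,          # strict >
        "min_intron": 60,              # bp, strict <
        "run_on_distance": 2000,       # bp, class 'p'
        "min_locus_coverage": 0.8,
        "reference_species": "maize",
    }


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _run_key(config: dict, input_paths: list[Path]) -> str:
    h = hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode())
    for p in sorted(input_paths):
        h.update(p.name.encode())
        h.update(_hash_file(p).encode())
    return h.hexdigest()


def run_all(config: dict, out_dir: str | Path) -> Path:
    """Run the full pipeline per ``config``; returns the output directory.

    Required config keys: ``transcripts_fasta``, ``alignments_gff3``,
    ``annotation_gff3``.  Optional: ``predictions_tsv`` (or ``model`` /
    ``train_lncrna_fasta`` + ``train_mrna_fasta``), ``te_gff3``,
    ``library_fasta`` + ``species_map_tsv`` (or ``hits_tsv``),
    ``expression_tsv`` + ``library_meta_tsv``, ``chrom_lengths_tsv``, and
    any threshold from :func:`default_config`.
    """
    cfg = default_config()
    cfg.update(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    path_keys = [
        "transcripts_fasta", "alignments_gff3", "annotation_gff3",
        "predictions_tsv", "te_gff3", "library_fasta", "species_map_tsv",
        "hits_tsv", "expression_tsv", "library_meta_tsv", "chrom_lengths_tsv",
        "train_lncrna_fasta", "train_mrna_fasta", "model",
    ]
    inputs = []
    for key in path_keys:
        if cfg.get(key):
            p = Path(cfg[key])
            if not p.exists():
                raise FileNotFoundError(f"config key {key}: {p} does not exist")
            inputs.append(p)
    for key in ("transcripts_fasta", "alignments_gff3", "annotation_gff3"):
        if not cfg.get(key):
            raise ValueError(f"config key {key} is required")

    run_key = _run_key(cfg, inputs)
    manifest_path = out / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        if manifest.get("run_key") == run_key and all(
            (out / f).exists() for f in manifest.get("outputs", [])
        ):
            logger.info("inputs and config unchanged; skipping completed run")
            return out

    t0 = time.monotonic()
    logger.info("seed=%s", cfg["seed"])

    # --- stage 1: input transcripts and length filter ---------------------
    records = lio.read_fasta(cfg["transcripts_fasta"])
    n_input = len(records)
    records = [r for r in records if len(r.seq) >= cfg["min_length"]]
    n_length = len(records)

    # --- stage 2: coding/noncoding prediction -----------------------------
    trained_csv = None
    if cfg.get("predictions_tsv"):
        pred = pd.read_csv(cfg["predictions_tsv"], sep="\t")
    else:
        if cfg.get("model"):
            model = clf.TrainedModel.load(cfg["model"])
        else:
            lncrnas = lio.read_fasta(cfg["train_lncrna_fasta"])
            mrnas = lio.read_fasta(cfg["train_mrna_fasta"])
            tc = clf.TrainingConfig(
                mrna_to_lncrna_ratio=cfg["mrna_to_lncrna_ratio"],
                train_fraction=cfg["train_fraction"],
                n_replicates=cfg["n_replicates"],
                seed=cfg["seed"],
            )
            models = clf.train_replicates(lncrnas, mrnas, tc)
            trained_csv = clf.metrics_csv(models, out / "training_metrics.csv")
            model = clf.select_best_model(models)
            model.save(out / "model.joblib")
        pred = clf.predict(records, model)
        pred.to_csv(out / "predictions.tsv", sep="\t", index=False)
    noncoding_ids = set(pred.loc[pred["label"] == "noncoding", "transcript_id"])
    coding_ids = set(pred.loc[pred["label"] == "coding", "transcript_id"])
    n_noncoding = sum(1 for r in records if r.id in noncoding_ids)

    # --- stage 3: alignments ----------------------------------------------
    aligned_all = lio.read_gff3_transcripts(cfg["alignments_gff3"], prefer_name=True)
    kept_ids = {r.id for r in records}
    aligned = [
        t for t in aligned_all
        if t.transcript_id in noncoding_ids and t.transcript_id in kept_ids
    ]
    aligned.sort(key=lambda t: t.transcript_id)
    n_aligned = len(aligned)

    # --- stage 4+5: loci and noise filter ---------------------------------
    loci = loc.build_loci(aligned)
    aligned = loc.noise_filter(aligned, loci, cfg["min_locus_coverage"])
    n_noise = len(aligned)

    # --- stage 6: TE filter ------------------------------------------------
    if cfg.get("te_gff3"):
        te = lio.read_gff3_intervals(cfg["te_gff3"])
        aligned = loc.te_filter(aligned, te)
    n_te = len(aligned)

    # --- stage 7: class codes and verdicts --------------------------------
    annotation = lio.read_gff3_transcripts(cfg["annotation_gff3"])
    ann_by_id = {t.transcript_id: t for t in annotation}
    rows = []
    for t in aligned:
        code = loc.assign_class_code(t, annotation, cfg["run_on_distance"])
        biotype = ann_by_id[code.reference_id].biotype if code.reference_id else None
        verdict = loc.apply_decision_table(code.code, biotype)
        rows.append(
            {
                "transcript_id": t.transcript_id,
                "chrom": t.chrom,
                "strand": t.strand,
                "class_code": code.code,
                "matched_reference": code.reference_id or "NA",
                "verdict": verdict,
            }
        )
    codes = pd.DataFrame(rows)
    codes.to_csv(out / "class_codes.tsv", sep="\t", index=False)

    novel_verdicts = {"intronic", "antisense", "intergenic"}
    novel_ids = set(codes.loc[codes["verdict"].isin(novel_verdicts), "transcript_id"])
    novel = [t for t in aligned if t.transcript_id in novel_ids]
    n_candidates = len(novel)
    novel_loci = loc.build_loci(novel)
    lio.write_loci_bed(novel_loci, out / "loci.bed")
    lio.write_loci_gff3(novel_loci, out / "loci.gff3")

    cascade = reports.cascade_report(
        {
            "input": n_input,
            "length_filtering": n_length,
            "predicted_noncoding": n_noncoding,
            "genome_alignment": n_aligned,
            "noise_filtered": n_noise,
            "te_filtered": n_te,
            "lncRNA_candidate_transcripts": n_candidates,
            "lncRNA_candidate_loci": len(novel_loci),
        }
    )
    cascade.to_csv(out / "cascade.tsv", sep="\t", index=False)

    class_counts = {
        "antisense": int((codes["verdict"] == "antisense").sum()),
        "intron": int((codes["verdict"] == "intronic").sum()),
        "intergenic": int((codes["verdict"] == "intergenic").sum()),
    }
    known = int((codes["verdict"] == "known_lncrna").sum())
    reports.class_count_report(class_counts, known).to_csv(
        out / "class_counts.tsv", sep="\t", index=False
    )

    # --- stage 8: conservation --------------------------------------------
    seq_by_id = {r.id: r for r in records}
    novel_records = [seq_by_id[t.transcript_id] for t in novel if t.transcript_id in seq_by_id]
    labels = None
    if cfg.get("hits_tsv"):
        hits = [
            h for h in lio.read_tabular_hits(cfg["hits_tsv"])
            if h.evalue is not None and h.evalue <= cfg["max_evalue"]
        ]
        species_map = _read_species_map(cfg.get("species_map_tsv"))
        hits = [
            dataclasses.replace(h, subject_species=species_map.get(h.subject_id))
            for h in hits
        ]
        labels = cons.label_conservation(
            novel_records, hits, cfg["reference_species"], cfg["min_identity"]
        )
    elif cfg.get("library_fasta"):
        library = lio.read_fasta(cfg["library_fasta"])
        species_map = _read_species_map(cfg.get("species_map_tsv"))
        hits = cons.identity_search(
            novel_records, library, min_identity=cfg["min_identity"],
            species_of=species_map,
        )
        labels = cons.label_conservation(
            novel_records, hits, cfg["reference_species"], cfg["min_identity"]
        )
    if labels is not None:
        pd.DataFrame(
            [
                {
                    "query_id": l.query_id,
                    "label": l.label,
                    "subject": l.best_hit.subject_id if l.best_hit else "NA",
                    "species": (l.best_hit.subject_species or "NA") if l.best_hit else "NA",
                    "identity": round(l.best_hit.percent_identity, 2) if l.best_hit else "NA",
                }
                for l in labels
            ]
        ).to_csv(out / "conservation.tsv", sep="\t", index=False)
        summary = cons.conservation_summary(labels)
        reports.conservation_report(
            n_candidates, summary["homologous"],
            summary["non_conserved_same_species"], summary["conserved_other_species"],
        ).to_csv(out / "conservation_summary.tsv", sep="\t", index=False)

    # --- stage 9: annotation statistics -----------------------------------
    summary = stats.structural_stats(novel, cfg["min_intron"])
    summary.table().to_csv(out / "structural_summary.tsv", sep="\t", header=False)
    pd.DataFrame(
        {"transcript_id": list(summary.excluded), "reason": list(summary.excluded.values())}
    ).to_csv(out / "structural_excluded.tsv", sep="\t", index=False)

    if cfg.get("chrom_lengths_tsv"):
        cl = pd.read_csv(cfg["chrom_lengths_tsv"], sep="\t")
        chrom_lengths = dict(zip(cl.iloc[:, 0].astype(str), cl.iloc[:, 1].astype(int)))
    else:
        chrom_lengths = {}
        for t in annotation + aligned:
            chrom_lengths[t.chrom] = max(chrom_lengths.get(t.chrom, 0), t.span.end)
    gene_spans = [t.span for t in annotation if t.biotype == "mRNA"]
    density, windows = stats.chromosome_density(
        novel_loci, chrom_lengths, gene_spans=gene_spans
    )
    density.to_csv(out / "chromosome_density.tsv", sep="\t", index=False)
    windows.to_csv(out / "window_counts.tsv", sep="\t", index=False)

    anti = [t for t in novel if t.transcript_id in
            set(codes.loc[codes["verdict"] == "antisense", "transcript_id"])]
    matched = dict(zip(codes["transcript_id"], codes["matched_reference"]))
    if anti:
        stats.antisense_exon_profile(anti, matched, annotation).to_csv(
            out / "antisense_exon_profile.tsv", sep="\t", index=False
        )

    if cfg.get("expression_tsv") and cfg.get("library_meta_tsv"):
        matrix = lio.read_expression(cfg["expression_tsv"], cfg["library_meta_tsv"])
        groups: dict[str, str] = {}
        if labels is not None:
            for l in labels:
                groups[l.query_id] = (
                    "conserved_lncRNA" if l.label == "conserved" else "non_conserved_lncRNA"
                )
        else:
            groups.update({t.transcript_id: "non_conserved_lncRNA" for t in novel})
        for tid in coding_ids:
            if tid in set(matrix.transcripts):
                groups[tid] = "mRNA"
        groups = {t: g for t, g in groups.items() if t in set(matrix.transcripts)}
        if groups:
            stats.expression_specificity(matrix, groups, cfg["tpm_threshold"]).to_csv(
                out / "expression_specificity.tsv", sep="\t", index_label="rna_type"
            )

    outputs = sorted(
        p.name for p in out.iterdir() if p.is_file() and p.name != "manifest.json"
    )
    manifest_path.write_text(
        json.dumps({"run_key": run_key, "seed": cfg["seed"], "outputs": outputs}, indent=2)
        + "\n"
    )
    logger.info("pipeline finished in %.1f s", time.monotonic() - t0)
    return out


def _read_species_map(path: Optional[str]) -> dict[str, str]:
    if not path:
        return {}
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
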