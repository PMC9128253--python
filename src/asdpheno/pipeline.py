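"""End-to-end orchestration: simulate -> qc -> extract -> stats -> validate
-> cluster -> map-dsm5 -> build-ontology, with one config, per-stage seeds
derived from a single global seed, and a JSON run manifest recording
versions, seeds, input digests and per-stage counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import (
    assign_clusters,
    build_matrix,
    embed_2d,
    factorize,
    select_top_patients,
    tfidf,
)
from .dsm5 import (
    PROFILE_CRITERIA,
    cluster_radar,
    dsm5_rule,
    load_criterion_lexicons,
    map_terms,
    patient_profile,
)
from .embedding import PrecomputedEmbedding, TrigramHashEmbedding
from .extraction import (
    drop_unmapped,
    load_default_lexicon,
    load_lexicon,
    match_terms,
    semantic_filter,
)
from .io import (
    read_mentions_tsv,
    read_notes_jsonl,
    read_patients_tsv,
    write_mentions_tsv,
    write_notes_jsonl,
    write_patients_tsv,
)
from .ontology import build_ontology, serialize, validate_ontology
from .qc import qc_filter
from .stats import compute_term_stats, or_filter
from .synthetic import CohortConfig, default_scenario, generate_cohorts
from .validation import load_gold_terms, validate_terms, validated_to_frame

logger = logging.getLogger(__name__)

STAGES = ("simulate", "qc", "extract", "stats", "validate", "cluster",
          "map_dsm5", "build_ontology")


@dataclass
class PipelineConfig:
    """Structured configuration for a full run (YAML-serializable)."""

    output_dir: str = "asdpheno_out"
    notes_path: str | None = None  # None -> simulate
    patients_path: str | None = None
    lexicon_path: str | None = None  # None -> packaged lexicon
    gold_path: str | None = None  # None -> packaged gold list
    criterion_lexicon_path: str | None = None
    embedding_vectors_path: str | None = None  # None -> built-in provider
    embedding_dimension: int = 700
    # simulation
    n_asd: int = 2000
    n_psych: int = 2000
    n_nonpsych: int = 2000
    # QC thresholds
    min_words: int = 100
    min_visits: int = 10
    date_window_days: int = 365
    # statistics
    or_cutoff: float = 1.5
    or_mode: str = "both"
    # validation
    similarity_threshold: float = 0.5
    # clustering
    nmf_a: int = 8
    matrix_mode: str = "binary"
    factorize_tfidf: bool = True
    top_n_per_cohort: int = 2000
    tsne_perplexity: float = 30.0
    ontology_formats: tuple[str, ...] = ("rdfxml", "owl", "json")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.or_cutoff <= 0 or not 0 <= self.similarity_threshold <= 1:
            raise ValueError("thresholds outside documented ranges")
        if self.min_words < 0 or self.min_visits < 0 or self.date_window_days < 0:
            raise ValueError("QC thresholds must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "ontology_formats" in data:
            data["ontology_formats"] = tuple(data["ontology_formats"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["ontology_formats"] = list(d["ontology_formats"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed: global seed fanned out through a SeedSequence keyed by
    the stage's position, so stages are individually reproducible."""
    idx = STAGES.index(stage)
    ss = np.random.SeedSequence(entropy=global_seed, spawn_key=(100 + idx,))
    return int(ss.generate_state(1)[0] % (2**31))


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


@dataclass
class Manifest:
    version: str = __version__
    seed: int = 0
    stage_seeds: dict = field(default_factory=dict)
    input_digests: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    elapsed: dict = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                         sort_keys=True) + "\n")


def run_all(config: PipelineConfig) -> Manifest:
    """Execute every stage; returns the manifest (also written to disk).

    A stage failure aborts with the stage name and cause; outputs of the
    completed stages are retained in ``output_dir``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(seed=config.seed,
                        stage_seeds={s: stage_seed(config.seed, s) for s in STAGES})
    stage = "setup"
    try:
        # -- simulate / load ------------------------------------------------
        stage = "simulate"
        t0 = time.perf_counter()
        if config.notes_path is None:
            scen_cfg, profiles = default_scenario()
            scen_cfg = dataclasses.replace(
                scen_cfg, n_asd=config.n_asd, n_psych=config.n_psych,
                n_nonpsych=config.n_nonpsych, seed=stage_seed(config.seed, "simulate"),
            )
            patients, notes, truth = generate_cohorts(scen_cfg, profiles)
            write_patients_tsv(patients, out / "patients.tsv")
            write_notes_jsonl(notes, out / "notes.jsonl")
            truth.write(out / "ledger")
        else:
            notes = read_notes_jsonl(config.notes_path)
            patients = read_patients_tsv(config.patients_path)
            manifest.input_digests["notes"] = _digest(Path(config.notes_path))
        manifest.counts["simulate"] = {"patients": len(patients), "notes": len(notes)}
        manifest.elapsed["simulate"] = round(time.perf_counter() - t0, 3)

        # -- qc --------------------------------------------------------------
        stage = "qc"
        t0 = time.perf_counter()
        hq_notes, report = qc_filter(
            notes, patients, min_words=config.min_words,
            min_visits=config.min_visits, date_window_days=config.date_window_days,
        )
        if not hq_notes:
            raise RuntimeError(
                "QC removed every note; check min_words/min_visits thresholds"
            )
        report.to_frame().to_csv(out / "qc_report.tsv", sep="\t", index=False)
        write_notes_jsonl(hq_notes, out / "notes_hq.jsonl")
        manifest.counts["qc"] = {"notes_in": report.n_notes_in,
                                 "notes_out": report.n_notes_out}
        manifest.elapsed["qc"] = round(time.perf_counter() - t0, 3)

        # -- extract ---------------------------------------------------------
        stage = "extract"
        t0 = time.perf_counter()
        lexicon = (load_lexicon(config.lexicon_path) if config.lexicon_path
                   else load_default_lexicon())
        mentions = match_terms(hq_notes, lexicon)
        n_raw = len(mentions)
        mentions = semantic_filter(drop_unmapped(mentions))
        write_mentions_tsv(mentions, out / "mentions.tsv")
        manifest.counts["extract"] = {"mentions_raw": n_raw,
                                      "mentions_filtered": len(mentions)}
        manifest.elapsed["extract"] = round(time.perf_counter() - t0, 3)

        # -- stats -----------------------------------------------------------
        stage = "stats"
        t0 = time.perf_counter()
        hq_ids = {n.patient_id for n in hq_notes}
        hq_patients = [p for p in patients if p.patient_id in hq_ids]
        stats = compute_term_stats(mentions, hq_patients)
        stats.to_csv(out / "term_stats.tsv", sep="\t", index=False)
        candidates = or_filter(stats, cutoff=config.or_cutoff, mode=config.or_mode)
        candidates.to_csv(out / "candidates.tsv", sep="\t", index=False)
        manifest.counts["stats"] = {"terms": len(stats), "candidates": len(candidates)}
        manifest.elapsed["stats"] = round(time.perf_counter() - t0, 3)

        # -- validate --------------------------------------------------------
        stage = "validate"
        t0 = time.perf_counter()
        provider = (PrecomputedEmbedding(config.embedding_vectors_path)
                    if config.embedding_vectors_path
                    else TrigramHashEmbedding(config.embedding_dimension))
        gold = load_gold_terms(config.gold_path)
        validated = validate_terms(candidates, gold, provider,
                                   threshold=config.similarity_threshold)
        validated_to_frame(validated).to_csv(out / "validated_terms.tsv",
                                             sep="\t", index=False)
        if not validated:
            raise RuntimeError("no candidate term passed embedding validation")
        manifest.counts["validate"] = {"gold": len(gold), "validated": len(validated)}
        manifest.elapsed["validate"] = round(time.perf_counter() - t0, 3)

        # -- cluster ---------------------------------------------------------
        stage = "cluster"
        t0 = time.perf_counter()
        term_keys = sorted({t.cui for t in validated if t.cui})
        clinical = [p for p in hq_patients if p.cohort in ("ASD", "PSYCH")]
        matrix = build_matrix(clinical, term_keys, mentions, mode=config.matrix_mode)
        matrix = select_top_patients(matrix, clinical, config.top_n_per_cohort)
        weighted = tfidf(matrix) if config.factorize_tfidf else matrix
        weighted.write(out / "matrix_tfidf")
        fact = factorize(weighted, a=config.nmf_a,
                         seed=stage_seed(config.seed, "cluster"))
        assignment = assign_clusters(fact, weighted.patient_ids)
        if len(weighted.patient_ids) > max(5, config.tsne_perplexity):
            assignment.coordinates = embed_2d(
                fact, weighted.patient_ids,
                seed=stage_seed(config.seed, "cluster"),
                perplexity=config.tsne_perplexity,
            )
        assignment.to_frame().to_csv(out / "clusters.tsv", sep="\t", index=False)
        manifest.counts["cluster"] = {
            "patients": len(weighted.patient_ids),
            "terms": len(weighted.term_keys),
            "clusters": len(set(assignment.labels.values())),
        }
        manifest.elapsed["cluster"] = round(time.perf_counter() - t0, 3)

        # -- map-dsm5 ----------------------------------------------------
        stage = "map_dsm5"
        t0 = time.perf_counter()
        lexicons = load_criterion_lexicons(config.criterion_lexicon_path)
        surface_by_cui = {t.cui: t.surface_form for t in validated if t.cui}
        mappings = map_terms(surface_by_cui, lexicons, provider)
        mappings.to_csv(out / "dsm5_mappings.tsv", sep="\t", index=False)
        manifest.counts["map_dsm5"] = {
            "terms_mapped": int((mappings["criterion"] != "").sum())
        }
        manifest.elapsed["map_dsm5"] = round(time.perf_counter() - t0, 3)

        # -- build-ontology ----------------------------------------------
        stage = "build_ontology"
        t0 = time.perf_counter()
        onto = build_ontology(validated, mappings, stats, lexicons, provider,
                              metadata={"seed": config.seed})
        violations = validate_ontology(onto)
        if violations:
            raise RuntimeError(f"ontology invariant violations: {violations[:5]}")
        for fmt in config.ontology_formats:
            ext = {"rdfxml": ".rdf.xml", "owl": ".owl", "json": ".json"}[fmt]
            serialize(onto, out / f"ontology{ext}", format=fmt)
        # per-patient DSM-5 profiles and per-cluster radar table
        mention_by_pid: dict[str, list] = {}
        for m in mentions:
            mention_by_pid.setdefault(m.patient_id, []).append(m)
        asd_ids = [pid for pid in assignment.labels
                   if pid in {p.patient_id for p in clinical if p.cohort == "ASD"}]
        profiles = [patient_profile(pid, mention_by_pid.get(pid, []), onto)
                    for pid in asd_ids]
        prof_rows = [
            {"patient_id": p.patient_id,
             **{c: int(c in p.presence) for c in PROFILE_CRITERIA},
             "dsm5_rule": int(dsm5_rule(p))}
            for p in profiles
        ]
        pd.DataFrame(prof_rows).to_csv(out / "patient_profiles.tsv",
                                       sep="\t", index=False)
        radar = cluster_radar(profiles, assignment.labels)
        radar.to_csv(out / "cluster_radar.tsv", sep="\t")
        manifest.counts["build_ontology"] = onto.level_counts()
        manifest.elapsed["build_ontology"] = round(time.perf_counter() - t0, 3)
    except Exception as exc:
        logger.error("pipeline failed at stage %r: %s", stage, exc)
        manifest.counts.setdefault("failed_stage", stage)
        manifest.write(out / "manifest.json")
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    manifest.write(out / "manifest.json")
    return manifest
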