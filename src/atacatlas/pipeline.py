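"""End-to-end pipeline: simulate/load -> QC -> reproducible peaks ->
consensus merge -> count matrix -> specificity -> correlations -> motif
summary, with every intermediate written to disk and a machine-readable
run manifest.

One global seed governs all stochastic stages; per-stage sub-seeds are
derived deterministically from it, so identical config + seed reproduces
identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Literal

import numpy as np
import yaml

from . import __version__
from .fragments import FragmentSet
from .io import (
    SampleRecord,
    ValidationError,
    read_bed,
    read_sample_sheet,
    write_bed,
    write_matrix,
    write_sample_sheet,
)
from .motifs import (
    MotifModel,
    build_enrichment_matrix,
    cluster_tissues_by_motifs,
    read_motifs,
    sample_background,
    select_display_motifs,
)
from .peaks import build_counts_matrix, merge_standard_peaks, reproducible_peaks
from .qc import apply_qc_filter, qc_report, tss_enrichment_score
from .reproducibility import correlation_matrix, replicate_correlation_summary
from .simulate import (
    DEFAULT_MOTIFS,
    SimulationConfig,
    simulate_atlas,
    simulate_peak_sequences,
)
from .specificity import aggregate_by_tissue, specificity_table, write_specificity_table

logger = logging.getLogger("atacatlas")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage (and sample if any)."""


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one of ``simulation`` (a :class:`SimulationConfig`) or the four
    input paths must be provided. Defaults are the atlas constants: QC
    thresholds TSS >= 10.0 and >= 10,000 reproducible peaks, entropy cutoff
    3.5 bits (auto-rescaled for panels other than 20 tissues when left
    ``None``), motif display rule mean > 20 / top 50 by CV.
    """

    output_dir: str | Path = "atacatlas_run"
    seed: int = 0
    simulation: SimulationConfig | None = None
    sample_sheet: str | Path | None = None
    fragments_dir: str | Path | None = None
    peaks_dir: str | Path | None = None
    tss_file: str | Path | None = None
    min_tss: float = 10.0
    min_peaks: int = 10000
    min_overlap_fraction: float = 0.5
    entropy_threshold: float | None = None
    aggregation: Literal["tissue", "tissue_sex"] = "tissue"
    motif_mean_floor: float = 20.0
    motif_top_k: int = 50
    motif_file: str | Path | None = None
    run_motifs: bool = True

    def __post_init__(self) -> None:
        paths = (self.sample_sheet, self.fragments_dir, self.peaks_dir, self.tss_file)
        have_paths = any(p is not None for p in paths)
        if (self.simulation is None) == (not have_paths):
            raise ValidationError(
                "provide exactly one of a simulation block or input paths"
            )
        if have_paths and not all(p is not None for p in paths):
            raise ValidationError(
                "input mode needs sample_sheet, fragments_dir, peaks_dir and tss_file"
            )
        if self.min_tss <= 0 or self.min_peaks <= 0:
            raise ValidationError("QC thresholds must be positive")

    @classmethod
    def synthetic_demo(cls, seed: int = 0,
                       output_dir: str | Path = "atacatlas_run",
                       simulation: SimulationConfig | None = None,
                       **overrides) -> "PipelineConfig":
        """A pipeline config for a synthetic run.

        The absolute reproducible-peak QC threshold targets genome-scale
        data; here it is rescaled to three quarters of the simulated peak
        universe so the filter still separates good from broken libraries
        at toy-genome scale.
        """
        sim = simulation or SimulationConfig()
        n_peaks = sim.n_shared_peaks + sim.n_restricted_peaks
        overrides.setdefault("min_peaks", max(1, int(0.75 * n_peaks)))
        return cls(simulation=sim, seed=seed, output_dir=output_dir, **overrides)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open() as fh:
            data = dict(yaml.safe_load(fh))
        if "simulation" in data and data["simulation"] is not None:
            data["simulation"] = SimulationConfig.from_dict(data["simulation"])
        return cls(**data)

    def to_jsonable(self) -> dict:
        data = asdict(self)
        for key in ("output_dir", "sample_sheet", "fragments_dir", "peaks_dir",
                    "tss_file", "motif_file"):
            if data[key] is not None:
                data[key] = str(data[key])
        return data


def _sub_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s % (2**31)) for s in state]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage, writing intermediates under ``output_dir``.

    Returns the run manifest (also written as ``manifest.json``): package
    version, seed, config hash, and per-stage row counts. QC-failed samples
    are dropped — with a logged list — before matrix construction; if no
    sample passes, the run aborts with an explicit error.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _sub_seeds(config.seed, 3)
    stages: list[dict] = []

    # ---- stage: inputs (simulate or load) ----
    if config.simulation is not None:
        sim = simulate_atlas(replace(config.simulation, seed=seeds[0]))
        records = sim.records
        fragments = sim.fragments
        peak_calls = sim.peak_calls
        tss = sim.tss
        sim.write(outdir / "simulated_input")
        stages.append({"stage": "simulate", "n_samples": len(records),
                       "n_true_peaks": len(sim.truth.peaks)})
        logger.info("simulated %d samples", len(records))
    else:
        records = read_sample_sheet(config.sample_sheet)
        fragments = {}
        peak_calls = {}
        for rec in records:
            frag_path = Path(config.fragments_dir) / f"{rec.sample_id}.bed"
            call_path = Path(config.peaks_dir) / f"{rec.sample_id}.bed"
            try:
                fragments[rec.sample_id] = FragmentSet.read_bed(frag_path)
                peak_calls[rec.sample_id] = read_bed(call_path)
            except Exception as exc:
                raise PipelineError(
                    f"stage load: sample {rec.sample_id}: {exc}"
                ) from exc
        tss = read_bed(config.tss_file)
        stages.append({"stage": "load", "n_samples": len(records)})

    # ---- stage: QC metrics ----
    try:
        for rec in records:
            score, _ = tss_enrichment_score(fragments[rec.sample_id], tss)
            rec.tss_enrichment = round(float(score), 2)
    except Exception as exc:
        raise PipelineError(f"stage qc: {exc}") from exc

    # ---- stage: replicate-reproducible peaks ----
    pairs: dict[tuple[str, str], dict[int, SampleRecord]] = {}
    for rec in records:
        pairs.setdefault((rec.tissue, rec.gender), {})[rec.replicate] = rec
    reproducible: dict[tuple[str, str], list] = {}
    for key, reps in pairs.items():
        if len(reps) == 2:
            kept = reproducible_peaks(
                peak_calls[reps[1].sample_id], peak_calls[reps[2].sample_id],
                config.min_overlap_fraction,
            )
        else:  # unpaired sample: its own calls stand in
            (only,) = reps.values()
            kept = sorted(peak_calls[only.sample_id],
                          key=lambda p: (p.chrom, p.start))
        reproducible[key] = kept
        for rec in reps.values():
            rec.reproducible_peaks = len(kept)
    stages.append({"stage": "reproducible_peaks",
                   "n_pairs": len(reproducible),
                   "mean_reproducible": float(np.mean(
                       [len(v) for v in reproducible.values()]))})

    # ---- stage: QC filter ----
    report = qc_report(records, config.min_tss, config.min_peaks,
                       outdir / "qc_report.tsv")
    passing, failing = apply_qc_filter(records, config.min_tss, config.min_peaks)
    for rec, reasons in failing:
        logger.warning("QC fail %s: %s", rec.sample_id, "; ".join(reasons))
    if not passing:
        raise PipelineError("stage qc_filter: no samples pass QC")
    write_sample_sheet(records, outdir / "sample_sheet.tsv")
    stages.append({"stage": "qc_filter", "n_pass": len(passing),
                   "n_fail": len(failing)})

    # ---- stage: consensus merge ----
    passing_ids = {r.sample_id for r in passing}
    by_tissue: dict[str, list] = {}
    for (tissue, gender), kept in reproducible.items():
        reps = pairs[(tissue, gender)]
        if any(r.sample_id in passing_ids for r in reps.values()):
            by_tissue.setdefault(tissue, []).extend(kept)
    consensus, contributors = merge_standard_peaks(by_tissue)
    write_bed(consensus, outdir / "consensus_peaks.bed")
    stages.append({"stage": "merge", "n_consensus_peaks": len(consensus)})

    # ---- stage: counts + normalization ----
    try:
        matrix = build_counts_matrix(
            {r.sample_id: fragments[r.sample_id] for r in passing},
            consensus,
            library_sizes={r.sample_id: r.usable_reads for r in passing},
        )
    except Exception as exc:
        raise PipelineError(f"stage counts: {exc}") from exc
    matrix.write(outdir)
    stages.append({"stage": "counts", "n_peaks": len(consensus),
                   "n_samples": len(passing)})

    # ---- stage: specificity ----
    tissue_matrix = aggregate_by_tissue(matrix.rpm, passing, config.aggregation)
    spec = specificity_table(tissue_matrix, config.entropy_threshold, consensus)
    write_specificity_table(spec, outdir / "specificity.tsv")
    n_restricted = int((spec["restricted"] == True).sum())  # noqa: E712
    stages.append({"stage": "specificity", "n_peaks": len(spec),
                   "n_restricted": n_restricted,
                   "n_tissues": tissue_matrix.shape[1]})

    # ---- stage: correlations ----
    corr = correlation_matrix(matrix.log_rpm)
    write_matrix(corr.values, outdir / "correlations.tsv")
    (outdir / "correlation_leaf_order.txt").write_text(
        "\n".join(corr.leaf_order) + "\n"
    )
    summary = replicate_correlation_summary(corr, passing)
    stages.append({"stage": "correlations", **summary})

    # ---- stage: motif summary ----
    if config.run_motifs:
        restricted_home = {
            pid: spec.loc[pid, "assigned_tissue"]
            for pid in spec.index
            if spec.loc[pid, "restricted"] is True
        }
        if config.motif_file is not None:
            models = read_motifs(config.motif_file)
            library = [(m.motif_id, m.consensus, m.max_mismatch) for m in models]
        else:
            library = list(DEFAULT_MOTIFS)
            models = [MotifModel(*m) for m in library]
        if restricted_home:
            seqs = simulate_peak_sequences(
                consensus, restricted_home, motifs=library, seed=seeds[1]
            )
            targets: dict[str, dict[str, str]] = {}
            for pid, tissue in restricted_home.items():
                targets.setdefault(tissue, {})[pid] = seqs[pid]
            pool = {pid: s for pid, s in seqs.items() if pid not in restricted_home}
            background = sample_background(
                pool, n=len(restricted_home), seed=seeds[2]
            )
            enrich = build_enrichment_matrix(targets, background, models)
            write_matrix(enrich.neglog10_p, outdir / "motif_matrix.tsv")
            selected = select_display_motifs(
                enrich, config.motif_mean_floor, config.motif_top_k
            )
            (outdir / "selected_motifs.txt").write_text(
                "\n".join(selected) + ("\n" if selected else "")
            )
            cluster_on = selected if len(selected) >= 1 else None
            if enrich.neglog10_p.shape[1] >= 2:
                # fall back to the full matrix when the display rule keeps
                # nothing (small synthetic runs rarely reach mean > 20)
                _, tissue_order = cluster_tissues_by_motifs(enrich, cluster_on)
                (outdir / "motif_tissue_order.txt").write_text(
                    "\n".join(tissue_order) + "\n"
                )
            stages.append({"stage": "motifs", "n_motifs": len(models),
                           "n_target_tissues": len(targets),
                           "n_selected": len(selected)})
        else:
            stages.append({"stage": "motifs", "skipped": "no restricted peaks"})

    # ---- manifest ----
    # the hash identifies the analysis, not the destination directory
    hashed = {k: v for k, v in config.to_jsonable().items() if k != "output_dir"}
    config_json = json.dumps(hashed, sort_keys=True)
    manifest = {
        "package": "atacatlas",
        "version": __version__,
        "seed": config.seed,
        "config_hash": hashlib.sha256(config_json.encode()).hexdigest(),
        "config": config.to_jsonable(),
        "stages": stages,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
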