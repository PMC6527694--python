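"""Synthetic multi-tissue ATAC-seq atlas generator.

Emulates the statistical structure of a fragment-level chromatin
accessibility atlas so the whole downstream pipeline is testable without
sequencing data:

* a toy genome of equal-length chromosomes carrying non-overlapping
  accessible regions ("true peaks"), some shared by all tissues and some
  restricted to a single home tissue where they are up-weighted by a fold
  factor;
* per-sample fragments drawn from a mixture of uniform genomic background,
  a TSS-proximal excess (producing TSS enrichment), and in-peak placement
  proportional to each sample's expected peak rates;
* fragment lengths from a mixture of sub-nucleosomal and mono/di/tri-
  nucleosome modes, reproducing the characteristic insert-size periodicity;
* negative-binomial-like replicate noise via multiplicative gamma jitter on
  peak rates;
* per-replicate "peak calls" (true peaks with independent dropout) so the
  replicate-reproducibility filter has something to do.

Ground truth (peak labels, home tissues, closed-form expected counts) is
returned alongside the data for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .fragments import FragmentSet
from .io import (
    GenomicInterval,
    SampleRecord,
    ValidationError,
    write_bed,
    write_sample_sheet,
)

DEFAULT_LENGTH_MODES: tuple[tuple[float, float, float], ...] = (
    (60.0, 15.0, 0.45),   # sub-nucleosomal
    (200.0, 25.0, 0.35),  # mono-nucleosome
    (400.0, 35.0, 0.15),  # di-nucleosome
    (600.0, 45.0, 0.05),  # tri-nucleosome
)


class PlacementError(RuntimeError):
    """Requested peaks cannot be placed without overlap."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic atlas.

    Defaults describe a 20-tissue panel with two technical replicates per
    tissue (mirroring the atlas design this package targets), a 50 Mb toy
    genome, and strongly tissue-restricted elements (``restricted_fold``)
    whose entropy falls clearly below the 3.5-bit specificity cutoff.
    """

    n_tissues: int = 20
    replicates_per_tissue: int = 2
    n_chromosomes: int = 5
    chromosome_length: int = 10_000_000
    n_shared_peaks: int = 400
    n_restricted_peaks: int = 200
    peak_width_range: tuple[int, int] = (300, 800)
    n_tss: int = 300
    fragments_per_sample: int = 250_000
    background_fraction: float = 0.25
    tss_fraction: float = 0.05
    fragment_length_modes: tuple[tuple[float, float, float], ...] = DEFAULT_LENGTH_MODES
    restricted_fold: float = 16.0
    dispersion: float = 0.05
    peak_dropout: float = 0.1
    seed: int = 0
    # geometry details
    edge_margin: int = 2_000
    min_peak_gap: int = 1_000
    tss_clearance: int = 2_500
    tss_offset_sd: float = 150.0
    min_fragment_length: int = 20
    max_fragment_length: int = 1_000

    def __post_init__(self) -> None:
        if self.n_tissues < 2:
            raise ValidationError("need at least 2 tissues")
        if self.replicates_per_tissue < 1:
            raise ValidationError("need at least 1 replicate per tissue")
        weights = sum(w for _, _, w in self.fragment_length_modes)
        if abs(weights - 1.0) > 1e-9:
            raise ValidationError("fragment length mode weights must sum to 1")
        if not self.restricted_fold > 1:
            raise ValidationError("restricted_fold must exceed 1")
        if not 0 <= self.background_fraction < 1:
            raise ValidationError("background_fraction must be in [0, 1)")
        if not 0 <= self.tss_fraction < 1:
            raise ValidationError("tss_fraction must be in [0, 1)")
        if self.background_fraction + self.tss_fraction >= 1:
            raise ValidationError("background + TSS fractions must leave in-peak mass")
        if self.dispersion < 0:
            raise ValidationError("dispersion must be >= 0")
        if not 0 <= self.peak_dropout < 1:
            raise ValidationError("peak_dropout must be in [0, 1)")
        lo, hi = self.peak_width_range
        if not 0 < lo <= hi:
            raise ValidationError("invalid peak_width_range")

    @property
    def tissues(self) -> list[str]:
        return [f"tissue_{i + 1:02d}" for i in range(self.n_tissues)]

    @property
    def chromosomes(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    @property
    def genome_size(self) -> int:
        return self.n_chromosomes * self.chromosome_length

    @property
    def mean_fragment_length(self) -> float:
        return sum(m * w for m, _, w in self.fragment_length_modes)

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimulationConfig":
        data = dict(data)
        if "peak_width_range" in data:
            data["peak_width_range"] = tuple(data["peak_width_range"])
        if "fragment_length_modes" in data:
            data["fragment_length_modes"] = tuple(
                tuple(m) for m in data["fragment_length_modes"]
            )
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with Path(path).open() as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class GroundTruth:
    """Generative-model ground truth used as the oracle in recovery tests."""

    peaks: list[GenomicInterval]
    labels: dict[str, str]                 # peak name -> {shared, restricted}
    home_tissue: dict[str, str]            # restricted peak name -> tissue
    expected_assignment: pd.DataFrame      # peak x sample in-peak expectation
    fragments_per_sample: int
    background_fraction: float
    tss_fraction: float
    genome_size: int
    mean_fragment_length: float

    @property
    def restricted_peaks(self) -> list[str]:
        return [n for n, lab in self.labels.items() if lab == "restricted"]

    @property
    def shared_peaks(self) -> list[str]:
        return [n for n, lab in self.labels.items() if lab == "shared"]


@dataclass
class SimulatedAtlas:
    """Everything one simulation run produces."""

    config: SimulationConfig
    chrom_sizes: dict[str, int]
    tss: list[GenomicInterval]
    fragments: dict[str, FragmentSet]
    peak_calls: dict[str, list[GenomicInterval]]
    records: list[SampleRecord]
    truth: GroundTruth

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        (outdir / "fragments").mkdir(parents=True, exist_ok=True)
        (outdir / "peak_calls").mkdir(exist_ok=True)
        write_sample_sheet(self.records, outdir / "sample_sheet.tsv")
        write_bed(self.tss, outdir / "tss.bed")
        truth_peaks = [
            replace(p, score=1.0 if self.truth.labels[p.name] == "restricted" else 0.0)
            for p in self.truth.peaks
        ]
        write_bed(truth_peaks, outdir / "truth_peaks.bed")
        for sid, frags in self.fragments.items():
            frags.write_bed(outdir / "fragments" / f"{sid}.bed")
        for sid, calls in self.peak_calls.items():
            write_bed(calls, outdir / "peak_calls" / f"{sid}.bed")


# --------------------------------------------------------------------------
# Generator internals
# --------------------------------------------------------------------------

def _place_peaks(config: SimulationConfig, rng: np.random.Generator
                 ) -> list[GenomicInterval]:
    """Place peaks without overlap, keeping ``min_peak_gap`` between peaks
    and ``edge_margin`` off chromosome ends. Deterministic gap allocation:
    no rejection sampling, so feasibility is checked exactly."""
    n_total = config.n_shared_peaks + config.n_restricted_peaks
    counts = np.full(config.n_chromosomes, n_total // config.n_chromosomes)
    counts[: n_total % config.n_chromosomes] += 1
    lo, hi = config.peak_width_range
    peaks: list[GenomicInterval] = []
    for chrom, k in zip(config.chromosomes, counts):
        if k == 0:
            continue
        widths = rng.integers(lo, hi + 1, size=int(k))
        span = config.chromosome_length - 2 * config.edge_margin
        needed = int(widths.sum()) + (int(k) - 1) * config.min_peak_gap
        slack = span - needed
        if slack < 0:
            raise PlacementError(
                f"cannot place {k} peaks on {chrom}: need {needed} bp of "
                f"{span} bp available; use longer chromosomes or fewer peaks"
            )
        cuts = np.sort(rng.uniform(0.0, slack, size=int(k))).astype(np.int64)
        offsets = np.concatenate(
            ([0], np.cumsum(widths[:-1] + config.min_peak_gap))
        )
        starts = config.edge_margin + cuts + offsets
        for s, w in zip(starts, widths):
            peaks.append(GenomicInterval(chrom, int(s), int(s + w)))
    peaks.sort(key=lambda p: (p.chrom, p.start))
    return [
        replace(p, name=f"peak_{i + 1:05d}") for i, p in enumerate(peaks)
    ]


def _place_tss(config: SimulationConfig, peaks: Sequence[GenomicInterval],
               rng: np.random.Generator) -> list[GenomicInterval]:
    """TSS points placed uniformly, at least ``tss_clearance`` from any peak
    so TSS-proximal fragments never contaminate peak counts."""
    bounds: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in config.chromosomes:
        ps = np.array([p.start for p in peaks if p.chrom == chrom])
        pe = np.array([p.end for p in peaks if p.chrom == chrom])
        bounds[chrom] = (ps - config.tss_clearance, pe + config.tss_clearance)
    tss: list[GenomicInterval] = []
    attempts = 0
    while len(tss) < config.n_tss:
        attempts += 1
        if attempts > 200 * config.n_tss:
            raise PlacementError("cannot place TSSs clear of peaks")
        chrom = config.chromosomes[int(rng.integers(config.n_chromosomes))]
        pos = int(rng.integers(config.edge_margin,
                               config.chromosome_length - config.edge_margin))
        lo, hi = bounds[chrom]
        idx = np.searchsorted(lo, pos, side="right") - 1
        if idx >= 0 and pos < hi[idx]:
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        tss.append(GenomicInterval(chrom, pos, pos + 1,
                                   name=f"tss_{len(tss) + 1:04d}", strand=strand))
    tss.sort(key=lambda t: (t.chrom, t.start))
    return tss


def _peak_weights(config: SimulationConfig, home: np.ndarray,
                  tissue_index: int) -> np.ndarray:
    """Noise-free peak rate weights for one tissue. ``home[j]`` is the home
    tissue index of peak j, or -1 for shared peaks (unit weight)."""
    w = np.ones(len(home))
    w[home == tissue_index] = config.restricted_fold
    return w


def _draw_lengths(config: SimulationConfig, n: int,
                  rng: np.random.Generator) -> np.ndarray:
    modes = config.fragment_length_modes
    weights = np.array([w for _, _, w in modes])
    comp = rng.choice(len(modes), size=n, p=weights / weights.sum())
    means = np.array([m for m, _, _ in modes])[comp]
    sds = np.array([s for _, s, _ in modes])[comp]
    lengths = np.rint(rng.normal(means, sds)).astype(np.int64)
    return np.clip(lengths, config.min_fragment_length, config.max_fragment_length)


def _accounting(config: SimulationConfig, rng: np.random.Generator
                ) -> tuple[int, int, int]:
    """Draw (total, mapped, chrM) read counts consistent with usable =
    fragments_per_sample. Mitochondrial reads are bookkeeping only."""
    usable = config.fragments_per_sample
    chrm_frac = rng.uniform(0.01, 0.25)
    other_frac = rng.uniform(0.1, 0.3)
    mapped = int(round(usable / (1.0 - chrm_frac - other_frac)))
    chrm = int(round(chrm_frac * mapped))
    total = int(round(mapped / rng.uniform(0.95, 0.995)))
    return max(total, mapped), mapped, chrm


def simulate_atlas(config: SimulationConfig | None = None, **overrides
                   ) -> SimulatedAtlas:
    """Run the generator. Identical config + seed gives identical output."""
    if config is None:
        config = SimulationConfig(**overrides)
    elif overrides:
        config = replace(config, **overrides)
    rng = np.random.default_rng(config.seed)

    peaks = _place_peaks(config, rng)
    n_peaks = len(peaks)
    home = np.full(n_peaks, -1, dtype=np.int64)
    if config.n_restricted_peaks:
        restricted_idx = rng.choice(n_peaks, size=config.n_restricted_peaks,
                                    replace=False)
        # home tissues cycle so every tissue owns ~equal numbers
        homes = np.arange(config.n_restricted_peaks) % config.n_tissues
        home[restricted_idx] = rng.permutation(homes)
    tss = _place_tss(config, peaks, rng)

    tissues = config.tissues
    sample_ids: list[str] = []
    sample_tissue: list[int] = []
    for ti in range(config.n_tissues):
        for r in range(config.replicates_per_tissue):
            sample_ids.append(f"{tissues[ti]}_r{r + 1}")
            sample_tissue.append(ti)

    peak_starts = np.array([p.start for p in peaks], dtype=np.int64)
    peak_widths = np.array([len(p) for p in peaks], dtype=np.int64)
    chrom_index = {c: i for i, c in enumerate(config.chromosomes)}
    peak_chrom = np.array([chrom_index[p.chrom] for p in peaks], dtype=np.int32)
    tss_pos = np.array([t.start for t in tss], dtype=np.int64)
    tss_chrom = np.array([chrom_index[t.chrom] for t in tss], dtype=np.int32)

    in_peak_frac = 1.0 - config.background_fraction - config.tss_fraction
    expected = {}
    fragments: dict[str, FragmentSet] = {}
    peak_calls: dict[str, list[GenomicInterval]] = {}
    records: list[SampleRecord] = []

    for sid, ti in zip(sample_ids, sample_tissue):
        w = _peak_weights(config, home, ti)
        expected[sid] = config.fragments_per_sample * in_peak_frac * w / w.sum()

        noisy = w.copy()
        if config.dispersion > 0:
            shape = 1.0 / config.dispersion
            noisy = w * rng.gamma(shape, config.dispersion, size=n_peaks)
        probs = np.concatenate((
            [config.background_fraction, config.tss_fraction],
            in_peak_frac * noisy / noisy.sum(),
        ))
        counts = rng.multinomial(config.fragments_per_sample, probs)
        n_bg, n_tssfrag = int(counts[0]), int(counts[1])
        peak_counts = counts[2:]

        # midpoints per category
        bg_chrom = rng.integers(0, config.n_chromosomes, n_bg).astype(np.int32)
        bg_mid = rng.integers(0, config.chromosome_length, n_bg)
        t_idx = rng.integers(0, len(tss_pos), n_tssfrag)
        t_off = np.rint(rng.normal(0.0, config.tss_offset_sd, n_tssfrag))
        t_mid = tss_pos[t_idx] + np.clip(t_off, -1000, 1000).astype(np.int64)
        t_chrom = tss_chrom[t_idx]
        rep = np.repeat(np.arange(n_peaks), peak_counts)
        p_mid = peak_starts[rep] + np.floor(
            rng.random(len(rep)) * peak_widths[rep]
        ).astype(np.int64)
        p_chrom = peak_chrom[rep]

        mids = np.concatenate((bg_mid, t_mid, p_mid))
        chroms = np.concatenate((bg_chrom, t_chrom, p_chrom))
        lengths = _draw_lengths(config, len(mids), rng)
        starts = np.maximum(mids - lengths // 2, 0)
        ends = np.minimum(starts + lengths, config.chromosome_length)
        frag = FragmentSet(tuple(config.chromosomes), chroms, starts, ends)
        fragments[sid] = frag.sorted()

        keep = rng.random(n_peaks) >= config.peak_dropout
        peak_calls[sid] = [p for p, k in zip(peaks, keep) if k]

        total, mapped, chrm = _accounting(config, rng)
        gender = "Female" if ti % 2 == 0 else "Male"
        records.append(SampleRecord(
            sample_id=sid, strain="synthetic", serial=1 if gender == "Female" else 2,
            gender=gender, tissue=tissues[ti],
            replicate=int(sid.rsplit("_r", 1)[1]),
            total_reads=total, mapped_reads=mapped, chrm_reads=chrm,
            usable_reads=config.fragments_per_sample,
        ))

    truth = GroundTruth(
        peaks=peaks,
        labels={p.name: ("restricted" if home[j] >= 0 else "shared")
                for j, p in enumerate(peaks)},
        home_tissue={p.name: tissues[home[j]]
                     for j, p in enumerate(peaks) if home[j] >= 0},
        expected_assignment=pd.DataFrame(
            expected, index=[p.name for p in peaks]
        ),
        fragments_per_sample=config.fragments_per_sample,
        background_fraction=config.background_fraction,
        tss_fraction=config.tss_fraction,
        genome_size=config.genome_size,
        mean_fragment_length=config.mean_fragment_length,
    )
    return SimulatedAtlas(
        config=config,
        chrom_sizes={c: config.chromosome_length for c in config.chromosomes},
        tss=tss, fragments=fragments, peak_calls=peak_calls,
        records=records, truth=truth,
    )


def expected_counts(truth: GroundTruth, sample: str,
                    include_background: bool = True) -> pd.Series:
    """Closed-form expectation of each peak's fragment count for a sample.

    The in-peak term comes directly from the generative rates; the optional
    background term adds the chance that a uniform background fragment
    overlaps the peak, ``bg_frac * (width + mean_len - 1) / genome_size``
    per fragment (edge clipping and length rounding neglected — both are
    far below sampling noise at any realistic size).
    """
    if sample not in truth.expected_assignment.columns:
        raise KeyError(f"unknown sample {sample!r}")
    exp = truth.expected_assignment[sample].copy()
    if include_background:
        widths = np.array([len(p) for p in truth.peaks], dtype=float)
        per_frag = (widths + truth.mean_fragment_length - 1.0) / truth.genome_size
        exp = exp + (truth.fragments_per_sample * truth.background_fraction) * per_frag
    return exp


# --------------------------------------------------------------------------
# Synthetic peak sequences (inputs to the motif-summary stage)
# --------------------------------------------------------------------------

#: A small library of TF-like consensus motifs (IUPAC) used for planting.
DEFAULT_MOTIFS: tuple[tuple[str, str, int], ...] = (
    ("Ebox_NeuroG", "GCAGATGG", 1),
    ("CEBP", "TTGCGCAAT", 1),
    ("MEF2", "CTAAAAATAG", 1),
    ("HNF1", "GTTAATNATTAAC", 2),
    ("GATA", "AGATAAGA", 1),
    ("FOXA", "TGTTTACTT", 1),
    ("ETS", "ACAGGAAGTG", 1),
    ("NFKB", "GGGACTTTCC", 1),
)

_IUPAC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def default_motif_plan(tissues: Sequence[str],
                       motifs: Sequence[tuple[str, str, int]] = DEFAULT_MOTIFS,
                       ) -> dict[str, list[str]]:
    """Assign each motif to a pair of consecutive tissues (cyclically), so
    tissues sharing a planted motif should end up as clustering neighbors."""
    plan: dict[str, list[str]] = {}
    for i, (motif_id, _, _) in enumerate(motifs):
        a = (2 * i) % len(tissues)
        plan[motif_id] = [tissues[a], tissues[(a + 1) % len(tissues)]]
    return plan


def simulate_peak_sequences(
    peaks: Sequence[GenomicInterval],
    home_tissue: Mapping[str, str],
    motif_plan: Mapping[str, Sequence[str]] | None = None,
    motifs: Sequence[tuple[str, str, int]] = DEFAULT_MOTIFS,
    plant_rate: float = 0.9,
    seed: int = 0,
) -> dict[str, str]:
    """Random peak sequences with motifs planted in tissue-restricted peaks.

    ``home_tissue`` maps a peak name to the tissue it is restricted to
    (e.g. ``GroundTruth.home_tissue``); peaks absent from it receive plain
    random sequence and serve as background. ``motif_plan`` maps motif id
    to the tissues in whose restricted peaks a concrete motif instance is
    embedded (with probability ``plant_rate``).
    """
    rng = np.random.default_rng(seed)
    consensus = {mid: cons for mid, cons, _ in motifs}
    if motif_plan is None:
        tissues = sorted(set(home_tissue.values()))
        motif_plan = default_motif_plan(tissues, motifs) if tissues else {}
    by_tissue: dict[str, list[str]] = {}
    for mid, tlist in motif_plan.items():
        if mid not in consensus:
            raise KeyError(f"motif {mid!r} not in the supplied library")
        for t in tlist:
            by_tissue.setdefault(t, []).append(mid)

    alphabet = np.array(list("ACGT"))
    seqs: dict[str, str] = {}
    for peak in peaks:
        seq = list(alphabet[rng.integers(0, 4, len(peak))])
        home = home_tissue.get(peak.name)
        if home is not None:
            for mid in by_tissue.get(home, []):
                if rng.random() >= plant_rate:
                    continue
                inst = [str(rng.choice(list(_IUPAC[c]))) for c in consensus[mid]]
                if rng.random() < 0.5:
                    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
                    inst = [comp[b] for b in reversed(inst)]
                pos = int(rng.integers(0, len(seq) - len(inst) + 1))
                seq[pos : pos + len(inst)] = inst
        seqs[peak.name] = "".join(seq)
    return seqs
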