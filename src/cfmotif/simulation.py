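"""Synthetic cfDNA cohort generator.

Real plasma WGS cohorts for end-motif studies are rarely deposited, so
every downstream stage here is exercised on simulated data with the
statistical structure the analysis assumes:

* a random reference contig (i.i.d. bases at a chosen GC content);
* per-class 256-motif spectra: a base spectrum, with a named set of
  motifs multiplied (up) or divided (down) by a fold change in the
  cancer class, then renormalised;
* per-sample spectra drawn from a Dirichlet centred on the class
  spectrum (between-sample biological variability), end-motif counts
  from a multinomial over the sample spectrum (sampling noise);
* optionally, individual aligned fragments whose 5'-end motifs follow a
  given spectrum, written as coordinate-sorted paired-end SAM, plus a
  fragment-length mixture (short tumor-like mode ~145 bp, background
  mode ~167 bp) for realism of the I/O path;
* cohort metadata mirroring the study composition: 106 cancer / 100
  healthy, cancer types lung/gastrointestinal/other 33/54/19, stages
  II/III/IV at 2.8/13.2/84.0%, 44 immunotherapy-treated patients of
  whom 13 (29.5%) respond. Composition is allocated by exact counts and
  shuffled, so the printed cohort structure is reproduced at the
  default n.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .cohort import SampleMeta
from .errors import ConfigurationError, SimulationError
from .motifs import (
    MOTIF_LENGTH,
    N_MOTIFS,
    enumerate_motifs,
    is_acgt,
    motif_index,
    reverse_complement,
)
from .profiling import FragmentRecord

# The thirteen differential motifs: four enriched and nine depleted in cancer.
UP_MOTIFS = ("AAAA", "ATGA", "ACAC", "ACGA")
DOWN_MOTIFS = ("AAGG", "AGGC", "AGGA", "ACTG", "AGGG", "ACCC", "ACCT", "ACCG", "AACG")


@dataclass(frozen=True)
class ReferenceSequence:
    """A simulated reference contig over {A,C,G,T}."""

    name: str
    seq: str

    def __post_init__(self) -> None:
        if len(self.seq) < 1000:
            raise ConfigurationError("reference length must be >= 1000")
        if not is_acgt(self.seq):
            raise ConfigurationError("reference alphabet restricted to A/C/G/T")

    @property
    def length(self) -> int:
        return len(self.seq)


def make_reference(
    length: int, gc_content: float = 0.5, seed: int = 0, name: str = "chrS"
) -> ReferenceSequence:
    """I.i.d. random reference: P(G)=P(C)=gc/2, P(A)=P(T)=(1-gc)/2."""
    if length < 1000:
        raise ConfigurationError(f"length must be >= 1000, got {length}")
    if not 0 < gc_content < 1:
        raise ConfigurationError(f"gc_content must be in (0, 1), got {gc_content}")
    rng = np.random.default_rng(seed)
    p = [(1 - gc_content) / 2, gc_content / 2, gc_content / 2, (1 - gc_content) / 2]
    bases = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=p)
    return ReferenceSequence(name=name, seq=bases.tobytes().decode("ascii"))


def reference_motif_freqs(reference: ReferenceSequence) -> np.ndarray:
    """Empirical 4-mer frequencies of a reference (forward strand)."""
    counts = np.zeros(N_MOTIFS, dtype=np.int64)
    seq = reference.seq
    for p in range(len(seq) - MOTIF_LENGTH + 1):
        counts[motif_index(seq[p : p + MOTIF_LENGTH])] += 1
    return counts / counts.sum()


@dataclass(frozen=True)
class LengthMixture:
    """Two-component Gaussian fragment-length mixture.

    ``tumor_weight`` is the probability of the short tumor-like
    component; lengths are rounded and clamped to at least 4 bp.
    """

    tumor_mode: float = 145.0
    tumor_sd: float = 15.0
    background_mode: float = 167.0
    background_sd: float = 20.0
    tumor_weight: float = 0.15

    def __post_init__(self) -> None:
        if not 0 <= self.tumor_weight <= 1:
            raise ConfigurationError("tumor_weight must be in [0, 1]")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        short = rng.random(n) < self.tumor_weight
        lengths = np.where(
            short,
            rng.normal(self.tumor_mode, self.tumor_sd, n),
            rng.normal(self.background_mode, self.background_sd, n),
        )
        return np.maximum(np.rint(lengths).astype(int), MOTIF_LENGTH)


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level generator settings (defaults = the study conditions)."""

    n_cancer: int = 106
    n_healthy: int = 100
    base_freqs: np.ndarray | None = None  # None -> uniform 1/256
    effect_motifs_up: tuple[str, ...] = UP_MOTIFS
    effect_motifs_down: tuple[str, ...] = DOWN_MOTIFS
    fold_change: float = 1.3
    dirichlet_concentration: float = 2000.0
    fragments_per_sample: int = 50_000
    length_dist: LengthMixture = field(default_factory=LengthMixture)
    tumor_length_weight_cancer: float = 0.40
    tumor_length_weight_healthy: float = 0.15
    cancer_type_props: dict[str, float] = field(
        default_factory=lambda: {"lung": 33 / 106, "gastrointestinal": 54 / 106, "other": 19 / 106}
    )
    stage_props: dict[str, float] = field(
        default_factory=lambda: {"II": 0.028, "III": 0.132, "IV": 0.840}
    )
    n_immunotherapy: int | None = None  # None -> 44/106 of n_cancer, rounded
    response_rate: float = 13 / 44
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cancer < 0 or self.n_healthy < 0:
            raise ConfigurationError("cohort sizes must be nonnegative")
        if self.n_cancer + self.n_healthy == 0:
            raise ConfigurationError("empty cohort: n_cancer + n_healthy must be > 0")
        if self.fold_change <= 0:
            raise ConfigurationError("fold_change must be > 0")
        if self.dirichlet_concentration <= 0:
            raise ConfigurationError("dirichlet_concentration must be > 0")
        overlap = set(self.effect_motifs_up) & set(self.effect_motifs_down)
        if overlap:
            raise ConfigurationError(f"up/down motif sets overlap: {sorted(overlap)}")
        for m in (*self.effect_motifs_up, *self.effect_motifs_down):
            motif_index(m)  # raises on malformed motifs
        if self.base_freqs is not None:
            freqs = np.asarray(self.base_freqs, dtype=float)
            if freqs.shape != (N_MOTIFS,):
                raise ConfigurationError("base_freqs must be a 256-vector")
            if (freqs < 0).any():
                raise ConfigurationError("base_freqs entries must be >= 0")
            if abs(float(freqs.sum()) - 1.0) > 1e-9:
                raise ConfigurationError("base_freqs must sum to 1 (tolerance 1e-9)")
            object.__setattr__(self, "base_freqs", freqs)
        if self.n_immunotherapy is None:
            object.__setattr__(
                self, "n_immunotherapy", round(self.n_cancer * 44 / 106)
            )
        if self.n_immunotherapy > self.n_cancer:
            raise ConfigurationError("n_immunotherapy cannot exceed n_cancer")
        if not 0 <= self.response_rate <= 1:
            raise ConfigurationError("response_rate must be in [0, 1]")

    def resolved_base_freqs(self) -> np.ndarray:
        if self.base_freqs is None:
            return np.full(N_MOTIFS, 1.0 / N_MOTIFS)
        return self.base_freqs

    def with_reference_base_freqs(self, reference: ReferenceSequence) -> "SimulationConfig":
        """Default base spectrum: empirical 4-mer frequencies of the reference."""
        return replace(self, base_freqs=reference_motif_freqs(reference))

    def length_mixture_for(self, label: str) -> LengthMixture:
        weight = (
            self.tumor_length_weight_cancer
            if label == "cancer"
            else self.tumor_length_weight_healthy
        )
        return replace(self.length_dist, tumor_weight=weight)


def class_motif_spectrum(config: SimulationConfig, label: str) -> np.ndarray:
    """Expected motif spectrum of a class.

    Healthy = base spectrum. Cancer = base spectrum with the up-motifs
    multiplied and the down-motifs divided by ``fold_change``, then
    renormalised to sum 1.
    """
    base = config.resolved_base_freqs().copy()
    if label == "healthy":
        return base
    if label != "cancer":
        raise ConfigurationError(f"label must be 'cancer' or 'healthy', got {label!r}")
    for m in config.effect_motifs_up:
        base[motif_index(m)] *= config.fold_change
    for m in config.effect_motifs_down:
        base[motif_index(m)] /= config.fold_change
    return base / base.sum()


def _exact_allocation(n: int, props: dict[str, float]) -> list[str]:
    """Allocate n items to categories by rounded proportions (largest-remainder)."""
    keys = list(props)
    raw = np.array([props[k] * n for k in keys])
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - counts))
    for i in range(remainder):
        counts[order[i % len(keys)]] += 1
    out: list[str] = []
    for k, c in zip(keys, counts):
        out.extend([k] * int(c))
    return out


def _cohort_metas(config: SimulationConfig, rng: np.random.Generator) -> list[SampleMeta]:
    metas: list[SampleMeta] = []
    nc = config.n_cancer
    types = _exact_allocation(nc, config.cancer_type_props)
    stages = _exact_allocation(nc, config.stage_props)
    rng.shuffle(types)
    rng.shuffle(stages)
    immuno = np.zeros(nc, dtype=bool)
    immuno[: config.n_immunotherapy] = True
    rng.shuffle(immuno)
    n_resp = round(config.response_rate * config.n_immunotherapy)
    responses_pool = ["response"] * n_resp + ["non_response"] * (
        config.n_immunotherapy - n_resp
    )
    rng.shuffle(responses_pool)
    resp_iter = iter(responses_pool)
    # covariates loosely matching the study arms: older, more-male,
    # lower-BMI cancer patients vs younger, mostly-female controls
    sexes_c = _exact_allocation(nc, {"M": 0.604, "F": 0.396})
    bmis_c = _exact_allocation(nc, {"<=24": 0.60, ">24": 0.40})
    rng.shuffle(sexes_c)
    rng.shuffle(bmis_c)
    ages_c = np.clip(np.rint(rng.normal(67, 12, nc)), 33, 93)
    for i in range(nc):
        metas.append(
            SampleMeta(
                sample_id=f"cancer_{i + 1:03d}",
                label="cancer",
                cancer_type=types[i],
                stage=stages[i],
                age=float(ages_c[i]),
                sex=sexes_c[i],
                bmi_class=bmis_c[i],
                immunotherapy=bool(immuno[i]),
                response=next(resp_iter) if immuno[i] else None,
            )
        )
    nh = config.n_healthy
    sexes_h = _exact_allocation(nh, {"M": 0.27, "F": 0.73})
    bmis_h = _exact_allocation(nh, {"<=24": 0.35, ">24": 0.65})
    rng.shuffle(sexes_h)
    rng.shuffle(bmis_h)
    ages_h = np.clip(np.rint(rng.normal(57, 14, nh)), 24, 88)
    for i in range(nh):
        metas.append(
            SampleMeta(
                sample_id=f"healthy_{i + 1:03d}",
                label="healthy",
                age=float(ages_h[i]),
                sex=sexes_h[i],
                bmi_class=bmis_h[i],
            )
        )
    return metas


def sample_profile(
    spectrum: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """One sample's motif frequencies: Dirichlet draw then multinomial counts."""
    alpha = np.maximum(config.dirichlet_concentration * spectrum, 1e-9)
    p = rng.dirichlet(alpha)
    counts = rng.multinomial(config.fragments_per_sample, p)
    return counts / counts.sum()


def simulate_cohort_profiles(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, list[SampleMeta]]:
    """Per-sample motif frequency matrix plus cohort metadata.

    Deterministic for a fixed ``config.seed``: metadata, Dirichlet draws
    and multinomial counts all come from one seeded generator.
    """
    rng = np.random.default_rng(config.seed)
    metas = _cohort_metas(config, rng)
    spectra = {label: class_motif_spectrum(config, label) for label in ("cancer", "healthy")}
    rows = np.empty((len(metas), N_MOTIFS))
    for i, meta in enumerate(metas):
        rows[i] = sample_profile(spectra[meta.label], config, rng)
    matrix = pd.DataFrame(
        rows,
        index=pd.Index([m.sample_id for m in metas], name="sample_id"),
        columns=list(enumerate_motifs()),
    )
    return matrix, metas


class _MotifPositionLookup:
    """All reference placements of each 4-mer, on both strands.

    A forward occurrence at position p places a fragment 5' end at p
    (upstream end); a reverse occurrence at end-coordinate e means the
    reverse complement of reference[e-4:e] equals the motif, placing a
    reverse-strand 5' end at e.
    """

    def __init__(self, reference: ReferenceSequence):
        fwd: list[list[int]] = [[] for _ in range(N_MOTIFS)]
        rev: list[list[int]] = [[] for _ in range(N_MOTIFS)]
        seq = reference.seq
        for p in range(len(seq) - MOTIF_LENGTH + 1):
            kmer = seq[p : p + MOTIF_LENGTH]
            idx = motif_index(kmer)
            fwd[idx].append(p)
            rev[motif_index(reverse_complement(kmer))].append(p + MOTIF_LENGTH)
        self.forward = [np.asarray(v, dtype=np.int64) for v in fwd]
        self.reverse = [np.asarray(v, dtype=np.int64) for v in rev]

    def n_sites(self, idx: int) -> int:
        return len(self.forward[idx]) + len(self.reverse[idx])


def simulate_fragments(
    spectrum: np.ndarray,
    reference: ReferenceSequence,
    n_fragments: int,
    length_dist: LengthMixture | None = None,
    seed: int = 0,
    lookup: _MotifPositionLookup | None = None,
) -> tuple[list[FragmentRecord], np.ndarray]:
    """Fragments whose sampled 5'-end motifs follow ``spectrum``.

    For each fragment a motif is drawn from the spectrum, a matching
    reference placement and strand uniformly among all occurrences, and
    a length from the mixture (clamped to the contig). Only the sampled
    end is motif-controlled; the opposite end reads whatever the
    reference dictates. Returns the fragments plus the ground-truth
    256-vector counting *both* end motifs of every fragment, for oracle
    tests against the alignment-file extraction path.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    if spectrum.shape != (N_MOTIFS,):
        raise ConfigurationError("spectrum must be a 256-vector")
    spectrum = spectrum / spectrum.sum()
    length_dist = length_dist or LengthMixture()
    lookup = lookup or _MotifPositionLookup(reference)
    missing = [
        enumerate_motifs()[i]
        for i in range(N_MOTIFS)
        if spectrum[i] > 0 and lookup.n_sites(i) == 0
    ]
    if missing:
        raise SimulationError(
            f"motifs absent from reference {reference.name!r}: {missing[:5]}"
        )
    rng = np.random.default_rng(seed)
    motif_draws = rng.choice(N_MOTIFS, size=n_fragments, p=spectrum)
    lengths = length_dist.sample(n_fragments, rng)
    seq = reference.seq
    ref_len = reference.length
    fragments: list[FragmentRecord] = []
    truth = np.zeros(N_MOTIFS, dtype=np.int64)
    for idx, length in zip(motif_draws, lengths):
        fwd = lookup.forward[idx]
        rev = lookup.reverse[idx]
        k = int(rng.integers(0, len(fwd) + len(rev)))
        if k < len(fwd):
            start = int(fwd[k])
            end = min(start + int(length), ref_len)
            end = max(end, start + MOTIF_LENGTH)
            strand = "+"
        else:
            end = int(rev[k - len(fwd)])
            start = max(end - int(length), 0)
            start = min(start, end - MOTIF_LENGTH)
            strand = "-"
        fragments.append(
            FragmentRecord(contig=reference.name, start=start, end=end, strand_of_read1=strand)
        )
        truth[motif_index(seq[start : start + MOTIF_LENGTH])] += 1
        truth[motif_index(reverse_complement(seq[end - MOTIF_LENGTH : end]))] += 1
    return fragments, truth


def write_reference_fasta(reference: ReferenceSequence, path: str | Path) -> None:
    """Write the reference as FASTA (60-column) and create its .fai index."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f">{reference.name}\n")
        for i in range(0, reference.length, 60):
            fh.write(reference.seq[i : i + 60] + "\n")
    pysam.faidx(str(path))


_READ_LENGTH = 50


def write_alignments(
    fragments: Sequence[FragmentRecord],
    reference: ReferenceSequence,
    path: str | Path,
    read_prefix: str = "frag",
) -> None:
    """Emit fragments as a coordinate-sorted paired-end SAM file.

    Each fragment becomes one properly paired template: two perfectly
    aligned reads (MAPQ 60) covering the fragment's two ends, with the
    template interval equal to the fragment interval. Input order is
    irrelevant; output records are sorted by coordinate.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": reference.name, "LN": reference.length}],
    }
    segments: list[pysam.AlignedSegment] = []
    ah = pysam.AlignmentHeader.from_dict(header)
    for i, frag in enumerate(fragments):
        if frag.contig != reference.name or frag.start < 0 or frag.end > reference.length:
            raise SimulationError(
                f"fragment [{frag.start}, {frag.end}) outside contig "
                f"{reference.name!r} (length {reference.length})"
            )
        rlen = min(frag.length, _READ_LENGTH)
        tlen = frag.length
        left_seq = reference.seq[frag.start : frag.start + rlen]
        right_start = frag.end - rlen
        right_seq = reference.seq[right_start : frag.end]
        # read1 forward at the left end when strand '+', else read1 is the
        # reverse-strand read at the right end
        for is_left in (True, False):
            seg = pysam.AlignedSegment(ah)
            is_read1 = is_left == (frag.strand_of_read1 == "+")
            seg.query_name = f"{read_prefix}{i:07d}"
            seg.reference_id = 0
            seg.mapping_quality = frag.mapq
            seg.cigartuples = [(0, rlen)]
            seg.query_sequence = left_seq if is_left else right_seq
            seg.query_qualities = pysam.qualitystring_to_array("I" * rlen)
            seg.reference_start = frag.start if is_left else right_start
            seg.next_reference_id = 0
            seg.next_reference_start = right_start if is_left else frag.start
            seg.template_length = tlen if is_left else -tlen
            flag = 0x1 | 0x2  # paired, proper pair
            flag |= 0x40 if is_read1 else 0x80
            if not is_left:
                flag |= 0x10  # this read reverse
            else:
                flag |= 0x20  # mate reverse
            if frag.duplicate:
                flag |= 0x400
            seg.flag = flag
            segments.append(seg)
    segments.sort(key=lambda s: s.reference_start)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for seg in segments:
            out.write(seg)


def simulate_sample_alignment(
    config: SimulationConfig,
    label: str,
    reference: ReferenceSequence,
    path: str | Path,
    seed: int,
    lookup: _MotifPositionLookup | None = None,
) -> np.ndarray:
    """Simulate one sample's fragments and write them as SAM.

    Returns the ground-truth both-end motif count vector.
    """
    spectrum = class_motif_spectrum(config, label)
    fragments, truth = simulate_fragments(
        spectrum,
        reference,
        config.fragments_per_sample,
        config.length_mixture_for(label),
        seed=seed,
        lookup=lookup,
    )
    write_alignments(fragments, reference, path)
    return truth
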