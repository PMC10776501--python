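"""Extraction of 4-bp 5' end motifs from aligned cfDNA fragments.

A sequenced cfDNA template (a "fragment") has two 5' termini: the
upstream end on the forward reference strand and the downstream end on
the reverse strand. The end motif at each terminus is read from the
*reference* sequence at the aligned coordinate — not from the read
bases — which makes the profile robust to sequencing error:

* upstream motif  = reference[start : start + 4), forward strand
* downstream motif = reverse complement of reference[end - 4 : end)

with fragments held as 0-based half-open intervals. By default both
termini contribute one motif each, so a sample's 256-long count vector
tallies two ends per passing fragment.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .errors import EmptyProfileError, ExtractionError, InputError
from .motifs import MOTIF_LENGTH, enumerate_motifs, is_acgt, motif_index, reverse_complement

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FragmentRecord:
    """One aligned cfDNA fragment (sequencing template).

    Coordinates are 0-based half-open on ``contig``; ``strand_of_read1``
    records which template end carries read 1's 5' terminus ('+' means
    read 1 is the forward-strand read at ``start``).
    """

    contig: str
    start: int
    end: int
    strand_of_read1: str = "+"
    mapq: int = 60
    proper_pair: bool = True
    duplicate: bool = False
    secondary: bool = False
    supplementary: bool = False

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid fragment interval [{self.start}, {self.end}) on {self.contig}"
            )
        if self.strand_of_read1 not in "+-":
            raise ValueError(f"strand_of_read1 must be '+' or '-', got {self.strand_of_read1!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class QCParams:
    """Fragment-level quality filters applied before motif extraction.

    Defaults are conventional WGS-fragmentomics settings: MAPQ >= 30,
    properly paired, non-duplicate primary alignments, both 5' ends
    counted, ambiguous (non-ACGT) motifs dropped. All are configurable
    and the filter tallies are reported alongside the counts.
    """

    min_mapq: int = 30
    require_proper_pair: bool = True
    drop_duplicates: bool = True
    count_both_ends: bool = True
    skip_non_acgt: bool = True

    def __post_init__(self) -> None:
        if self.min_mapq < 0:
            raise ValueError("min_mapq must be >= 0")

    def passes(self, fragment: FragmentRecord) -> bool:
        if fragment.secondary or fragment.supplementary:
            return False
        if fragment.mapq < self.min_mapq:
            return False
        if self.require_proper_pair and not fragment.proper_pair:
            return False
        if self.drop_duplicates and fragment.duplicate:
            return False
        return True


@dataclass
class MotifCountVector:
    """Per-sample tally of end motifs over the canonical 256-motif index."""

    counts: np.ndarray
    total_ends_counted: int
    fragments_seen: int
    fragments_filtered: int
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(enumerate_motifs()),):
            raise ValueError("counts must be a 256-vector on the canonical motif index")
        if int(self.counts.sum()) != self.total_ends_counted:
            raise ValueError("sum(counts) must equal total_ends_counted")


@dataclass
class MotifProfile:
    """Per-sample end-motif frequency vector (sums to 1)."""

    freqs: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.shape != (len(enumerate_motifs()),):
            raise ValueError("freqs must be a 256-vector on the canonical motif index")


def _contig_sequence(reference, contig: str) -> str:
    """Fetch a full contig as an upper-case string from several reference shapes."""
    if isinstance(reference, str):
        return reference.upper()
    if isinstance(reference, Mapping):
        try:
            return str(reference[contig]).upper()
        except KeyError:
            raise ExtractionError(f"contig {contig!r} absent from reference") from None
    if hasattr(reference, "seq") and hasattr(reference, "name"):  # ReferenceSequence
        if reference.name != contig:
            raise ExtractionError(
                f"fragment contig {contig!r} does not match reference {reference.name!r}"
            )
        return reference.seq.upper()
    if hasattr(reference, "fetch"):  # pysam.FastaFile
        return reference.fetch(contig).upper()
    raise TypeError(f"unsupported reference type: {type(reference)!r}")


def fragment_end_motifs(
    fragment: FragmentRecord,
    reference,
    qc: QCParams | None = None,
) -> list[str]:
    """End motifs of one fragment, after QC.

    Returns 0–2 motifs: both termini when ``qc.count_both_ends``, else
    only the motif at read 1's 5' terminus. Fragments failing QC or
    shorter than 4 bp yield an empty list; motifs containing non-ACGT
    characters are dropped when ``qc.skip_non_acgt``.
    """
    qc = qc or QCParams()
    if not qc.passes(fragment):
        return []
    if fragment.length < MOTIF_LENGTH:
        return []
    seq = _contig_sequence(reference, fragment.contig)
    if fragment.end > len(seq):
        raise ExtractionError(
            f"fragment [{fragment.start}, {fragment.end}) exceeds contig "
            f"{fragment.contig!r} length {len(seq)}"
        )
    upstream = seq[fragment.start : fragment.start + MOTIF_LENGTH]
    downstream = reverse_complement(seq[fragment.end - MOTIF_LENGTH : fragment.end])
    if qc.count_both_ends:
        motifs = [upstream, downstream]
    else:
        motifs = [upstream if fragment.strand_of_read1 == "+" else downstream]
    if qc.skip_non_acgt:
        motifs = [m for m in motifs if is_acgt(m)]
    return motifs


def tally_fragments(
    fragments: Iterable[FragmentRecord],
    reference,
    qc: QCParams | None = None,
    sample_id: str = "",
) -> MotifCountVector:
    """Tally end motifs over an in-memory fragment collection."""
    qc = qc or QCParams()
    counts = np.zeros(len(enumerate_motifs()), dtype=np.int64)
    seen = filtered = 0
    for frag in fragments:
        seen += 1
        motifs = fragment_end_motifs(frag, reference, qc)
        if not motifs:
            filtered += 1
            continue
        for m in motifs:
            counts[motif_index(m)] += 1
    return MotifCountVector(
        counts=counts,
        total_ends_counted=int(counts.sum()),
        fragments_seen=seen,
        fragments_filtered=filtered,
        sample_id=sample_id,
    )


def _fragment_from_pair(r1: pysam.AlignedSegment, r2: pysam.AlignedSegment) -> FragmentRecord:
    first, second = (r1, r2) if r1.is_read1 else (r2, r1)
    start = min(r1.reference_start, r2.reference_start)
    end = max(r1.reference_end, r2.reference_end)
    return FragmentRecord(
        contig=r1.reference_name,
        start=start,
        end=end,
        strand_of_read1="-" if first.is_reverse else "+",
        mapq=min(r1.mapping_quality, r2.mapping_quality),
        proper_pair=r1.is_proper_pair and r2.is_proper_pair,
        duplicate=r1.is_duplicate or r2.is_duplicate,
    )


def profile_sample(
    alignment_path: str | Path,
    reference_path: str | Path,
    qc: QCParams | None = None,
    sample_id: str | None = None,
) -> MotifCountVector:
    """Profile one sample: reconstruct fragments from read pairs and tally motifs.

    Reads a coordinate-sorted SAM/BAM and the reference FASTA it was
    aligned to. Each properly paired template contributes one
    :class:`FragmentRecord` (mate order in the file is irrelevant, so
    counts are invariant to record shuffling); unpaired leftovers are
    counted as filtered. Secondary/supplementary and unmapped records
    never enter pairing.
    """
    qc = qc or QCParams()
    alignment_path = Path(alignment_path)
    reference_path = Path(reference_path)
    sample_id = sample_id if sample_id is not None else alignment_path.stem

    if not reference_path.with_suffix(reference_path.suffix + ".fai").exists():
        pysam.faidx(str(reference_path))
    fasta = pysam.FastaFile(str(reference_path))
    try:
        contigs = {name: fasta.get_reference_length(name) for name in fasta.references}
        with pysam.AlignmentFile(str(alignment_path), "r", check_sq=False) as af:
            for name, length in zip(af.references, af.lengths):
                if name not in contigs:
                    raise InputError(
                        f"alignment contig {name!r} absent from reference {reference_path}"
                    )
                if contigs[name] != length:
                    raise InputError(
                        f"contig {name!r} length mismatch: alignment header says {length}, "
                        f"reference says {contigs[name]}"
                    )
            seqs = {name: fasta.fetch(name).upper() for name in af.references}
            pending: dict[str, pysam.AlignedSegment] = {}
            fragments: list[FragmentRecord] = []
            unpaired = 0
            for read in af:
                if read.is_unmapped or read.is_secondary or read.is_supplementary:
                    unpaired += 1
                    continue
                if not read.is_paired:
                    unpaired += 1
                    continue
                mate = pending.pop(read.query_name, None)
                if mate is None:
                    pending[read.query_name] = read
                else:
                    fragments.append(_fragment_from_pair(mate, read))
            if pending:
                unpaired += len(pending)
                logger.warning(
                    "%s: %d unpaired reads counted as filtered", alignment_path, len(pending)
                )
    finally:
        fasta.close()

    counts = tally_fragments(fragments, seqs, qc, sample_id=sample_id)
    # leftover reads are seen-and-filtered pseudo-fragments so that
    # total_ends_counted <= 2 * (fragments_seen - fragments_filtered) holds
    counts.fragments_seen += unpaired
    counts.fragments_filtered += unpaired
    return counts


def counts_to_frequencies(counts: MotifCountVector) -> MotifProfile:
    """Convert a count vector to frequencies: freq[m] = count[m] / total ends."""
    if counts.total_ends_counted == 0:
        raise EmptyProfileError(
            f"sample {counts.sample_id!r} has no counted ends; cannot form a profile"
        )
    return MotifProfile(
        freqs=counts.counts / counts.total_ends_counted, sample_id=counts.sample_id
    )


def build_matrix(profiles: Sequence[MotifProfile]) -> pd.DataFrame:
    """Stack profiles into a samples x 256 matrix (rows in input order)."""
    ids = [p.sample_id for p in profiles]
    dup = {s for s in ids if ids.count(s) > 1}
    if dup:
        raise InputError(f"duplicate sample ids: {sorted(dup)}")
    return pd.DataFrame(
        np.vstack([p.freqs for p in profiles]) if profiles else np.empty((0, 256)),
        index=pd.Index(ids, name="sample_id"),
        columns=list(enumerate_motifs()),
    )


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a profile matrix as TSV with motif-named columns (10 sig. digits)."""
    matrix.to_csv(path, sep="\t", float_format="%.10g")


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a profile matrix TSV written by :func:`write_matrix`."""
    matrix = pd.read_csv(path, sep="\t", index_col="sample_id")
    expected = list(enumerate_motifs())
    if list(matrix.columns) != expected:
        raise InputError(f"{path}: columns are not the canonical 256-motif index")
    return matrix


def write_counts(counts: MotifCountVector, path: str | Path) -> None:
    """Per-sample motif table: motif, count, frequency."""
    total = counts.total_ends_counted
    freqs = counts.counts / total if total else np.zeros_like(counts.counts, dtype=float)
    pd.DataFrame(
        {"motif": list(enumerate_motifs()), "count": counts.counts, "frequency": freqs}
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")
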