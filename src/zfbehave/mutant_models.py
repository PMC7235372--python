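"""Transcript variant application and truncated-protein prediction.

Applies substitutions and small deletions to a cDNA sequence in 1-based
transcript coordinates (5'UTR included), translates from the annotated
start codon to the first stop, and compares mutant against wild-type
proteins (identical prefix, frameshifted tail, domain coverage).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

__all__ = [
    "TranscriptModel",
    "Variant",
    "VariantEffect",
    "ProteinComparison",
    "apply_variant",
    "predict_protein",
    "compare_proteins",
    "find_longest_orf",
    "load_transcript_fasta",
    "load_bundled_transcript",
    "DMRT3A_ACCESSION",
    "TOY_TRANSCRIPT",
]

STOP_CODONS = {"TAA", "TAG", "TGA"}

#: RefSeq accession of the zebrafish dmrt3a mRNA used for the published models
DMRT3A_ACCESSION = "NM_001005779.2"

#: 60-nt download-free fixture: 5'UTR (9 nt) + ATG + 12 codons + TAA + 3'UTR (9 nt)
_TOY_CDS = "ATG" + "GCTTACGGATCGCCCTACCTCTACGGGTGCTGTCCA" + "TAA"
TOY_TRANSCRIPT = "GGCACGAGG" + _TOY_CDS + "GGAGCACGG"
assert len(TOY_TRANSCRIPT) == 60


@dataclass
class TranscriptModel:
    """cDNA sequence with 1-based inclusive CDS coordinates."""

    transcript_id: str
    sequence: str
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper().replace("U", "T")
        n = len(self.sequence)
        if not (1 <= self.cds_start < self.cds_end <= n):
            raise ValueError("CDS coordinates out of range")
        cds = self.cds
        if len(cds) % 3 != 0:
            raise ValueError("CDS length must be divisible by 3")
        if not cds.startswith("ATG"):
            raise ValueError("CDS must start with ATG")
        if cds[-3:] not in STOP_CODONS:
            raise ValueError("CDS must end at a stop codon")

    @property
    def cds(self) -> str:
        return self.sequence[self.cds_start - 1:self.cds_end]

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Variant:
    """A substitution or deletion in 1-based transcript coordinates.

    Deletions are closed intervals [start, end]; substitutions have
    start == end plus ref/alt bases.
    """

    kind: str  # "substitution" | "deletion"
    start: int
    end: int
    ref: Optional[str] = None
    alt: Optional[str] = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("substitution", "deletion"):
            raise ValueError(f"unknown variant kind {self.kind!r}")
        if self.start < 1 or self.end < self.start:
            raise ValueError("invalid variant interval")
        if self.kind == "substitution":
            if self.start != self.end:
                raise ValueError("substitution must cover a single position")
            if not self.ref or not self.alt:
                raise ValueError("substitution requires ref and alt bases")


@dataclass
class VariantEffect:
    protein_length_aa: int
    stop_codon_span: Optional[tuple[int, int]]  # 1-based, mutated coordinates
    protein: str
    non_stop: bool = False


@dataclass
class ProteinComparison:
    identical_prefix_aa: int
    frameshifted_tail_aa: int
    domain_coverage: dict  # name -> (covered_aa, domain_aa)


# ---------------------------------------------------------------------------

def apply_variant(model: TranscriptModel, v: Variant) -> str:
    """Return the mutated sequence; the reference base(s) must match."""
    seq = model.sequence
    if v.end > len(seq):
        raise ValueError(
            f"variant interval {v.start}-{v.end} outside transcript "
            f"of length {len(seq)}")
    if v.kind == "substitution":
        observed = seq[v.start - 1]
        expected = v.ref.upper().replace("U", "T")
        if observed != expected:
            raise ValueError(
                f"reference mismatch at position {v.start}: transcript has "
                f"{observed!r}, variant expects {expected!r}")
        return seq[:v.start - 1] + v.alt.upper().replace("U", "T") + seq[v.start:]
    # deletion, closed interval
    if v.ref is not None:
        observed = seq[v.start - 1:v.end]
        expected = v.ref.upper().replace("U", "T")
        if observed != expected:
            raise ValueError(
                f"reference mismatch at {v.start}-{v.end}: transcript has "
                f"{observed!r}, variant expects {expected!r}")
    return seq[:v.start - 1] + seq[v.end:]


def predict_protein(sequence: str, cds_start: int) -> VariantEffect:
    """Translate from ``cds_start`` (1-based) to the first in-frame stop.

    ``protein_length_aa`` counts residues before the stop; the stop-codon
    span is reported in the coordinates of the sequence as given (i.e.
    mutated coordinates when applied to a mutated transcript).
    """
    sequence = sequence.upper().replace("U", "T")
    if not 1 <= cds_start <= len(sequence) - 2:
        raise ValueError("cds_start outside sequence")
    if sequence[cds_start - 1:cds_start + 2] != "ATG":
        logger.warning("sequence at cds_start %d is not ATG", cds_start)
    frame = sequence[cds_start - 1:]
    frame = frame[:len(frame) - len(frame) % 3]
    aa = str(Seq(frame).translate())
    stop_idx = aa.find("*")
    if stop_idx == -1:
        logger.warning("no in-frame stop codon before sequence end (non-stop)")
        return VariantEffect(protein_length_aa=len(aa), stop_codon_span=None,
                             protein=aa, non_stop=True)
    stop_start = cds_start + 3 * stop_idx
    return VariantEffect(protein_length_aa=stop_idx,
                         stop_codon_span=(stop_start, stop_start + 2),
                         protein=aa[:stop_idx])


def compare_proteins(wt: str, mut: str,
                     domains: Sequence[tuple[str, int, int]] = ()) -> ProteinComparison:
    """Identical N-terminal prefix, frameshifted tail, domain coverage.

    ``domains`` are (name, start_aa, end_aa) intervals, 1-based inclusive,
    in wild-type protein coordinates; coverage is the overlap with the
    residues the mutant protein retains (its identical prefix).
    """
    if not wt or not mut:
        raise ValueError("both proteins must be non-empty")
    prefix = 0
    for x, y in zip(wt, mut):
        if x != y:
            break
        prefix += 1
    tail = len(mut) - prefix
    coverage = {}
    for name, start, end in domains:
        if end < start or start < 1:
            raise ValueError(f"invalid domain interval for {name!r}")
        covered = max(0, min(end, prefix) - start + 1)
        coverage[name] = (covered, end - start + 1)
    return ProteinComparison(identical_prefix_aa=prefix,
                             frameshifted_tail_aa=tail,
                             domain_coverage=coverage)


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def find_longest_orf(sequence: str) -> tuple[int, int]:
    """1-based inclusive span of the longest ATG..stop ORF on the + strand."""
    seq = sequence.upper().replace("U", "T")
    best: Optional[tuple[int, int]] = None
    for frame in range(3):
        i = frame
        while i + 2 < len(seq):
            if seq[i:i + 3] == "ATG":
                j = i
                while j + 2 < len(seq):
                    if seq[j:j + 3] in STOP_CODONS:
                        if best is None or (j + 3 - i) > (best[1] - best[0] + 1):
                            best = (i + 1, j + 3)
                        break
                    j += 3
                # skip past this start; nested ATGs give shorter ORFs
                i = j + 3 if j + 2 < len(seq) else len(seq)
            else:
                i += 3
    if best is None:
        raise ValueError("no complete ORF found")
    return best


def load_transcript_fasta(path, transcript_id: Optional[str] = None,
                          cds_start: Optional[int] = None,
                          cds_end: Optional[int] = None) -> TranscriptModel:
    """Read a single-record FASTA into a TranscriptModel.

    When CDS coordinates are not supplied the longest ORF is used, with a
    warning (plain FASTA carries no annotation).
    """
    record = next(SeqIO.parse(str(path), "fasta"))
    seq = str(record.seq).upper().replace("U", "T")
    if cds_start is None or cds_end is None:
        cds_start, cds_end = find_longest_orf(seq)
        logger.warning("no CDS annotation given for %s; using longest ORF "
                       "%d-%d", record.id, cds_start, cds_end)
    return TranscriptModel(transcript_id=transcript_id or record.id,
                           sequence=seq, cds_start=cds_start, cds_end=cds_end)


def load_bundled_transcript(accession: str = DMRT3A_ACCESSION) -> TranscriptModel:
    """Load a transcript record bundled under ``zfbehave/data``.

    The dmrt3a record itself is not redistributed with the package; place
    ``<accession>.fa`` (e.g. fetched with NCBI efetch) in the data
    directory to enable the accession-dependent checks.
    """
    data_dir = resources.files("zfbehave").joinpath("data")
    for suffix in (".fa", ".fasta"):
        candidate = data_dir.joinpath(accession + suffix)
        if candidate.is_file():
            with resources.as_file(candidate) as p:
                return load_transcript_fasta(p, transcript_id=accession)
    raise FileNotFoundError(
        f"transcript record {accession} is not bundled; fetch it as FASTA "
        f"(e.g. efetch -db nuccore -id {accession} -format fasta) and save "
        f"it as src/zfbehave/data/{accession}.fa")
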