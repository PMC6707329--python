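"""Hypothetical lncRNA peptidome construction.

Three-frame translation of lncRNA transcripts into stop-free polypeptide
segments, in-silico tryptic digestion, assembly of a merged search database
(lncRNA segments + canonical proteome), and the novelty filter that removes
candidate peptides whose sequence occurs in the canonical proteome.

Only the sense strand is translated (three frames, not six): the transcripts
are mature RNAs with a defined orientation.  Coordinates are 0-based,
half-open throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BIOTYPES = frozenset(
    {
        "lincRNA",
        "antisense",
        "processed_transcript",
        "sense_intronic",
        "sense_overlapping",
        "unknown",
    }
)

_NT_RE = re.compile(r"^[ACGTN]+$")

LNC_PREFIX = "lncpep"


class InputError(ValueError):
    """Malformed user input (bad sequence, bad table, missing column)."""


@dataclass(frozen=True)
class NucleotideTranscript:
    """A lncRNA transcript: id, GENCODE-style biotype and nucleotide sequence."""

    transcript_id: str
    sequence: str
    biotype: str = "unknown"

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if not self.sequence:
            raise InputError(f"transcript {self.transcript_id!r}: empty sequence")
        if not _NT_RE.match(self.sequence):
            bad = sorted(set(self.sequence) - set("ACGTN"))
            raise InputError(
                f"transcript {self.transcript_id!r}: non-nucleotide characters {bad}"
            )
        if self.biotype not in BIOTYPES:
            raise InputError(
                f"transcript {self.transcript_id!r}: unknown biotype {self.biotype!r}"
            )


@dataclass(frozen=True)
class OrfPolypeptide:
    """A stop-free amino-acid segment from one reading frame of a transcript.

    ``aa_start`` is the 0-based offset of the segment within the frame's full
    translation; ``segment_index`` orders the stop-delimited segments of that
    frame.
    """

    transcript_id: str
    frame: int
    segment_index: int
    aa_start: int
    sequence: str

    @property
    def entry_id(self) -> str:
        return f"{LNC_PREFIX}|{self.transcript_id}|F{self.frame}|S{self.segment_index}"


@dataclass(frozen=True)
class TrypticPeptide:
    """One tryptic peptide on a parent polypeptide, 0-based half-open start."""

    sequence: str
    parent_id: str
    start: int
    missed_cleavages: int

    @property
    def end(self) -> int:
        return self.start + len(self.sequence)


@dataclass
class ReferenceProteome:
    """Canonical proteome entries plus a concatenated substring index.

    The index is a single string with a separator that cannot occur in a
    peptide, so novelty lookups are one ``in`` test.
    """

    entries: dict[str, str]
    _index: str = field(default="", repr=False)
    _index_il: str = field(default="", repr=False)

    def __post_init__(self) -> None:
        for pid, seq in self.entries.items():
            if not seq:
                raise InputError(f"proteome entry {pid!r}: empty sequence")
        joined = "$" + "$".join(self.entries.values()) + "$" if self.entries else ""
        self._index = joined
        self._index_il = joined.replace("I", "L")

    def contains(self, peptide: str, collapse_il: bool = True) -> bool:
        """True iff ``peptide`` occurs as a contiguous substring of any entry."""
        if not self.entries:
            return False
        if collapse_il:
            return peptide.replace("I", "L") in self._index_il
        return peptide in self._index


# ---------------------------------------------------------------------------
# translation


def three_frame_translate(
    transcript: NucleotideTranscript, min_orf_len: int = 8
) -> list[OrfPolypeptide]:
    """Translate a transcript in frames 0/1/2 and split at stop codons.

    Every stop-free segment of length >= ``min_orf_len`` is emitted.  Codons
    containing N translate to X unless the ambiguity does not affect the
    amino acid (e.g. GGN -> G); trailing partial codons are dropped.
    """
    if min_orf_len < 1:
        raise ValueError("min_orf_len must be >= 1")
    out: list[OrfPolypeptide] = []
    nt = transcript.sequence
    for frame in range(3):
        sub = nt[frame:]
        sub = sub[: len(sub) - len(sub) % 3]
        if not sub:
            continue
        aa = str(Seq(sub).translate())
        seg_idx = 0
        pos = 0
        for segment in aa.split("*"):
            if len(segment) >= min_orf_len:
                out.append(
                    OrfPolypeptide(
                        transcript_id=transcript.transcript_id,
                        frame=frame,
                        segment_index=seg_idx,
                        aa_start=pos,
                        sequence=segment,
                    )
                )
                seg_idx += 1
            pos += len(segment) + 1  # +1 skips the stop
    return out


# ---------------------------------------------------------------------------
# digestion


def _cleavage_sites(sequence: str) -> list[int]:
    """Positions i such that trypsin cuts between i-1 and i (K/R not before P)."""
    return [
        i + 1
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def tryptic_digest(
    parent_sequence: str,
    parent_id: str = "",
    max_missed: int = 2,
    min_len: int = 6,
    drop_x: bool = True,
) -> list[TrypticPeptide]:
    """Enumerate tryptic peptides with up to ``max_missed`` missed cleavages.

    Cleavage occurs after K or R except when the next residue is P.  Peptides
    containing X (untranslatable codons) are dropped by default: they cannot
    be matched to spectra.
    """
    if max_missed < 0 or min_len < 1:
        raise ValueError("max_missed must be >= 0 and min_len >= 1")
    if "*" in parent_sequence:
        raise InputError(f"stop symbol in polypeptide {parent_id!r}")
    bounds = [0] + _cleavage_sites(parent_sequence) + [len(parent_sequence)]
    peptides: list[TrypticPeptide] = []
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + max_missed + 2, len(bounds))):
            seq = parent_sequence[bounds[i] : bounds[j]]
            if len(seq) < min_len:
                continue
            if drop_x and "X" in seq:
                continue
            peptides.append(
                TrypticPeptide(
                    sequence=seq,
                    parent_id=parent_id,
                    start=bounds[i],
                    missed_cleavages=j - i - 1,
                )
            )
    return peptides


# ---------------------------------------------------------------------------
# database assembly and novelty filter


def build_search_db(
    transcripts: Iterable[NucleotideTranscript],
    proteome: ReferenceProteome,
    min_orf_len: int = 8,
) -> list[SeqRecord]:
    """Merge translated lncRNA segments with the canonical proteome.

    lncRNA entries get namespaced headers ``lncpep|<transcript>|F<frame>|S<i>``;
    canonical entries pass through unchanged.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for tx in transcripts:
        for orf in three_frame_translate(tx, min_orf_len=min_orf_len):
            if orf.entry_id in seen:
                raise InputError(f"duplicate database id {orf.entry_id!r}")
            seen.add(orf.entry_id)
            records.append(SeqRecord(Seq(orf.sequence), id=orf.entry_id, description=""))
    for pid, seq in proteome.entries.items():
        if pid.startswith(LNC_PREFIX + "|") or pid in seen:
            raise InputError(f"id collision between namespaces: {pid!r}")
        records.append(SeqRecord(Seq(seq), id=pid, description=""))
    return records


def novelty_filter(
    peptides: Iterable[TrypticPeptide],
    proteome: ReferenceProteome,
    collapse_il: bool = True,
) -> tuple[list[TrypticPeptide], list[TrypticPeptide]]:
    """Partition peptides into (retained, discarded) by proteome substring match.

    With ``collapse_il`` (default, since isobaric I/L are indistinguishable by
    MS) the match is performed after replacing I with L on both sides.
    """
    retained, discarded = [], []
    for pep in peptides:
        if proteome.contains(pep.sequence, collapse_il=collapse_il):
            discarded.append(pep)
        else:
            retained.append(pep)
    return retained, discarded


# ---------------------------------------------------------------------------
# I/O


def read_transcripts(
    fasta_path, biotype_path=None
) -> list[NucleotideTranscript]:
    """Read a nucleotide FASTA plus an optional transcript->biotype TSV."""
    biotypes: dict[str, str] = {}
    if biotype_path is not None:
        with open(biotype_path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:2] != ["transcript_id", "biotype"]:
                raise InputError(
                    "biotype table must have header 'transcript_id<TAB>biotype'"
                )
            for line in fh:
                if line.strip():
                    tid, bt = line.rstrip("\n").split("\t")[:2]
                    biotypes[tid] = bt
    out = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        out.append(
            NucleotideTranscript(
                transcript_id=rec.id,
                sequence=str(rec.seq),
                biotype=biotypes.get(rec.id, "unknown"),
            )
        )
    return out


def read_proteome(fasta_path) -> ReferenceProteome:
    entries: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in entries:
            raise InputError(f"duplicate proteome id {rec.id!r}")
        entries[rec.id] = str(rec.seq)
    return ReferenceProteome(entries=entries)


def write_fasta(records: Iterable[SeqRecord], path) -> None:
    SeqIO.write(list(records), str(path), "fasta")


def write_digest_tsv(peptides: Iterable[TrypticPeptide], path) -> None:
    with open(path, "w") as fh:
        fh.write("peptide\tparent_id\tstart\tmissed\n")
        for p in peptides:
            fh.write(f"{p.sequence}\t{p.parent_id}\t{p.start}\t{p.missed_cleavages}\n")


def read_digest_tsv(path) -> list[TrypticPeptide]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["peptide", "parent_id", "start", "missed"]:
            raise InputError("digest table header mismatch")
        for line in fh:
            if line.strip():
                seq, pid, start, missed = line.rstrip("\n").split("\t")
                out.append(TrypticPeptide(seq, pid, int(start), int(missed)))
    return out
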