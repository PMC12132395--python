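"""Longest-ORF coding classification of transcripts.

Transcripts are called protein-coding when their longest open reading frame
reaches a minimum protein length (default 100 aa, sense strand only, universal
nuclear genetic code) — the same settings the field's standard long-ORF
scanners use as a first coding filter. Only complete ORFs compete by default:
ATG-initiated and stop-terminated. 5'-partial ORFs (a frame-initial stop-free
prefix without a start codon) can be enabled; ORFs running off the 3' end are
never reported.

Ties between equal-length ORFs are broken deterministically: sense strand
before antisense, then smaller start coordinate, then lower frame index.
Codons containing N translate to 'X' and neither start nor terminate an ORF.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Collection, Iterable, Mapping

from Bio.Data import CodonTable

from .errors import ConsistencyError, ParameterError, SequenceError
from .formats import FastaRecord, OrthogroupTable

__all__ = [
    "OrfParams",
    "OrfCall",
    "MethodSummary",
    "translate",
    "reverse_complement",
    "find_longest_orf",
    "classify_coding",
    "summarize_method",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
#: Universal nuclear code: codon -> residue, stops -> '*'.
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
CODON_TO_AA.update({c: "*" for c in _STANDARD.stop_codons})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class OrfParams:
    """Settings of the long-ORF scan.

    min_protein_length
        Minimum accepted protein length in amino acids (default 100).
    stranded
        If true (default), only the sense strand is scanned; otherwise both
        strands in all six frames.
    allow_5prime_partial
        If true, a frame-initial stop-free prefix (no ATG required) competes
        as a 5'-partial ORF. Off by default.
    genetic_code
        NCBI translation-table ID; only the universal code (1) is supported.
    """

    min_protein_length: int = 100
    stranded: bool = True
    allow_5prime_partial: bool = False
    genetic_code: int = 1

    def __post_init__(self) -> None:
        if self.min_protein_length < 1:
            raise ParameterError("min_protein_length must be >= 1")
        if self.genetic_code != 1:
            raise ParameterError("only the universal genetic code is supported")


@dataclass(frozen=True)
class OrfCall:
    """The accepted ORF of one transcript.

    Coordinates are 1-based inclusive on the scanned (reading) strand:
    for ``strand == '-'`` they refer to the reverse complement of the
    transcript. ``nt_end`` includes the stop codon when ``complete``.
    """

    transcript_id: str
    frame: int
    nt_start: int
    nt_end: int
    protein: str
    complete: bool
    strand: str = "+"
    has_start: bool = True

    def __post_init__(self) -> None:
        span = self.nt_end - self.nt_start + 1
        expected = span // 3 - (1 if self.complete else 0)
        if span % 3 or len(self.protein) != expected:
            raise SequenceError(
                f"ORF span {span} nt inconsistent with protein length "
                f"{len(self.protein)}"
            )
        if "*" in self.protein:
            raise SequenceError("ORF protein contains an internal stop")

    @property
    def protein_length(self) -> int:
        return len(self.protein)


def _check_alphabet(sequence: str) -> str:
    seq = sequence.upper()
    bad = set(seq) - {"A", "C", "G", "T", "N"}
    if bad:
        raise SequenceError(f"invalid nucleotide characters {sorted(bad)}")
    return seq


def reverse_complement(sequence: str) -> str:
    return _check_alphabet(sequence).translate(_COMPLEMENT)[::-1]


def translate(codons: str) -> str:
    """Translate an in-frame nucleotide string under the universal code.

    Stop codons yield ``'*'``; any codon containing N yields ``'X'`` (never
    resolved, even when the residue would be unambiguous).
    """
    seq = _check_alphabet(codons)
    if len(seq) % 3:
        raise SequenceError(
            f"sequence length {len(seq)} is not divisible by 3"
        )
    out = []
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        out.append("X" if "N" in codon else CODON_TO_AA[codon])
    return "".join(out)


def find_longest_orf(
    sequence: str, params: OrfParams = OrfParams(), transcript_id: str = ""
) -> OrfCall | None:
    """Return the single longest accepted ORF of a transcript, or ``None``.

    Within one stop-delimited segment only the earliest ATG can yield the
    maximal ORF, so the scan is linear per frame.
    """
    seq = _check_alphabet(sequence)
    strands = [("+", seq)]
    if not params.stranded:
        strands.append(("-", seq.translate(_COMPLEMENT)[::-1]))

    candidates: list[tuple[tuple[int, int, int, int], OrfCall]] = []
    for strand_idx, (strand, s) in enumerate(strands):
        for frame in range(3):
            open_start: int | None = None  # earliest ATG codon idx since stop
            saw_stop = False
            n_codons = (len(s) - frame) // 3
            for ci in range(n_codons):
                codon = s[frame + 3 * ci : frame + 3 * ci + 3]
                if codon in STOP_CODONS:
                    starts: list[tuple[int, bool]] = []
                    if open_start is not None:
                        starts.append((open_start, True))
                    if (
                        params.allow_5prime_partial
                        and not saw_stop
                        and open_start != 0
                    ):
                        starts.append((0, False))
                    for start_ci, has_start in starts:
                        plen = ci - start_ci
                        if plen < params.min_protein_length:
                            continue
                        nt_start = frame + 3 * start_ci + 1
                        nt_end = frame + 3 * ci + 3
                        call = OrfCall(
                            transcript_id=transcript_id,
                            frame=frame,
                            nt_start=nt_start,
                            nt_end=nt_end,
                            protein=translate(
                                s[nt_start - 1 : nt_end - 3]
                            ),
                            complete=True,
                            strand=strand,
                            has_start=has_start,
                        )
                        candidates.append(
                            ((-plen, strand_idx, nt_start, frame), call)
                        )
                    open_start = None
                    saw_stop = True
                elif codon == START_CODON and open_start is None:
                    open_start = ci
    if not candidates:
        return None
    return min(candidates, key=lambda kv: kv[0])[1]


def classify_coding(
    transcripts: Iterable[FastaRecord], params: OrfParams = OrfParams()
) -> dict[str, OrfCall]:
    """Map each transcript with an accepted ORF to its :class:`OrfCall`."""
    calls: dict[str, OrfCall] = {}
    seen: set[str] = set()
    for rec in transcripts:
        if rec.id in seen:
            raise ConsistencyError(f"duplicate transcript ID {rec.id!r}")
        seen.add(rec.id)
        call = find_longest_orf(rec.sequence, params, transcript_id=rec.id)
        if call is not None:
            calls[rec.id] = call
    return calls


@dataclass(frozen=True)
class MethodSummary:
    """Per-annotation-method transcript accounting.

    ``n_coding_in_orthogroups`` counts coding transcripts whose protein ID
    appears in at least one orthogroup under the method's proteome column;
    the remainder are unassigned, so assigned + unassigned = coding.
    """

    method_id: str
    n_transcripts: int
    n_coding: int
    n_coding_in_orthogroups: int
    n_unassigned_proteins: int

    def __post_init__(self) -> None:
        ok = (
            0 <= self.n_coding <= self.n_transcripts
            and 0 <= self.n_coding_in_orthogroups <= self.n_coding
            and self.n_coding_in_orthogroups + self.n_unassigned_proteins
            == self.n_coding
        )
        if not ok:
            raise ConsistencyError(
                f"inconsistent method summary counts: {self}"
            )


def summarize_method(
    transcripts: Iterable[FastaRecord],
    orf_calls: Mapping[str, OrfCall] | Collection[str],
    table: OrthogroupTable,
    proteome_id: str,
    method_id: str = "",
) -> MethodSummary:
    """Count transcripts, coding calls, and orthogroup assignment for a method.

    Every protein ID the table lists under ``proteome_id`` must correspond to
    a coding call; orphans raise :class:`ConsistencyError`.
    """
    transcript_ids = [rec.id for rec in transcripts]
    coding_ids = set(orf_calls)
    assigned_ids = set(table.proteins_for(proteome_id))
    orphans = assigned_ids - coding_ids
    if orphans:
        raise ConsistencyError(
            f"orthogroup members of {proteome_id!r} without a coding call: "
            f"{sorted(orphans)[:10]}"
        )
    n_in_og = sum(1 for t in coding_ids if t in assigned_ids)
    return MethodSummary(
        method_id=method_id or proteome_id,
        n_transcripts=len(transcript_ids),
        n_coding=len(coding_ids),
        n_coding_in_orthogroups=n_in_og,
        n_unassigned_proteins=len(coding_ids) - n_in_og,
    )
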