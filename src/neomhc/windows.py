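"""Missense SNVs -> 2n-1 mutant contexts -> candidate n-mer epitopes.

A missense substitution at protein position p is expanded, for each epitope
length n, into the 2n-1 residues centred on p (shorter when a protein
terminus truncates the context). Every length-n substring of that context
containing the mutated residue is a candidate epitope; each is paired with
its self counterpart, the reference substring at the same coordinates,
which differs from the mutant at exactly one position.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable

from neomhc.sequences import STANDARD_AA

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class ProteinContext:
    transcript_id: str
    protein_seq: str
    mut_pos: int  # 1-based
    ref_aa: str
    alt_aa: str
    n: int

    def __post_init__(self) -> None:
        if not (1 <= self.mut_pos <= len(self.protein_seq)):
            raise ValueError(
                f"mut_pos {self.mut_pos} outside protein of length "
                f"{len(self.protein_seq)}"
            )
        if self.protein_seq[self.mut_pos - 1] != self.ref_aa:
            raise ValueError(
                f"protein has {self.protein_seq[self.mut_pos - 1]!r} at "
                f"position {self.mut_pos}, expected ref {self.ref_aa!r}"
            )


@dataclasses.dataclass
class PeptideWindow:
    seq: str  # mutant n-mer
    n: int
    start: int  # 1-based protein coordinate of the window's first residue
    mut_offset: int  # 1-based position of the mutation within the window
    self_seq: str | None = None  # reference n-mer at the same coordinates
    transcripts: frozenset[str] = frozenset()
    mutation_id: str = ""
    starts_by_transcript: dict[str, int] = dataclasses.field(
        default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.seq) != self.n:
            raise ValueError("window sequence must have length n")
        if not (1 <= self.mut_offset <= self.n):
            raise ValueError("mut_offset outside the window")
        if not (self.start <= self.start + self.mut_offset - 1):
            raise ValueError("inconsistent window coordinates")
        if self.self_seq is not None:
            diffs = [i for i, (a, b)
                     in enumerate(zip(self.seq, self.self_seq), 1) if a != b]
            if diffs != [self.mut_offset]:
                raise ValueError(
                    f"mutant and self must differ exactly at offset "
                    f"{self.mut_offset}, differ at {diffs}"
                )


def mutant_context(protein_seq: str, mut_pos: int, alt_aa: str,
                   n: int) -> tuple[str, int]:
    """Return the (up to) 2n-1 residue mutant context and its 1-based start.

    The context is protein_seq[max(1, p-n+1) .. min(L, p+n-1)] with the
    residue at p replaced by ``alt_aa``; truncation at either terminus
    shortens it but never removes the mutated residue.
    """
    L = len(protein_seq)
    if not (1 <= mut_pos <= L):
        raise ValueError(f"mut_pos {mut_pos} outside protein of length {L}")
    ref_aa = protein_seq[mut_pos - 1]
    if alt_aa == ref_aa:
        raise ValueError(f"synonymous change {ref_aa}->{alt_aa} at {mut_pos}")
    if alt_aa not in STANDARD_AA:
        raise ValueError(f"alt residue {alt_aa!r} not a standard amino acid")
    start = max(1, mut_pos - n + 1)
    end = min(L, mut_pos + n - 1)
    context = (protein_seq[start - 1:mut_pos - 1] + alt_aa
               + protein_seq[mut_pos:end])
    return context, start


def enumerate_windows(
    context: str,
    mut_offset_in_context: int,
    n: int,
    *,
    context_start: int = 1,
    transcript_id: str = "",
    mutation_id: str = "",
) -> list[PeptideWindow]:
    """All length-n substrings of the context containing the mutation,
    in N->C order. An untruncated 2n-1 context yields exactly n windows;
    a context shorter than n yields none (with a warning)."""
    if len(context) < n:
        logger.warning("context of length %d shorter than n=%d; no windows",
                       len(context), n)
        return []
    if not (1 <= mut_offset_in_context <= len(context)):
        raise ValueError("mutation offset outside context")
    if set(context) - STANDARD_AA:
        logger.warning("context contains non-standard residues; skipped")
        return []
    windows = []
    for offset in range(len(context) - n + 1):
        if not (offset + 1 <= mut_offset_in_context <= offset + n):
            continue
        start = context_start + offset
        windows.append(PeptideWindow(
            seq=context[offset:offset + n],
            n=n, start=start,
            mut_offset=mut_offset_in_context - offset,
            transcripts=frozenset({transcript_id} if transcript_id else set()),
            mutation_id=mutation_id,
            starts_by_transcript=(
                {transcript_id: start} if transcript_id else {}),
        ))
    return windows


def self_counterpart_coords(protein_seq: str, start: int, n: int) -> str:
    """Reference substring at 1-based [start, start+n-1]."""
    if start < 1 or start + n - 1 > len(protein_seq):
        raise ValueError(
            f"window [{start}, {start + n - 1}] outside protein of "
            f"length {len(protein_seq)}"
        )
    return protein_seq[start - 1:start + n - 1]


def self_counterpart(window: PeptideWindow, protein_seq: str) -> str:
    """Self peptide for a window: the reference residues at the window's
    own coordinates. Must differ from the mutant at exactly ``mut_offset``."""
    self_seq = self_counterpart_coords(protein_seq, window.start, window.n)
    diffs = [i for i, (a, b) in enumerate(zip(window.seq, self_seq), 1)
             if a != b]
    if diffs != [window.mut_offset]:
        raise ValueError(
            f"window at start {window.start} does not match the reference "
            f"protein (differences at {diffs}, expected [{window.mut_offset}])"
        )
    return self_seq


def windows_for_mutation(
    protein_seq: str,
    mut_pos: int,
    alt_aa: str,
    n: int,
    *,
    transcript_id: str = "",
    mutation_id: str = "",
) -> list[PeptideWindow]:
    """Context construction + enumeration + self-counterpart pairing."""
    context, start = mutant_context(protein_seq, mut_pos, alt_aa, n)
    windows = enumerate_windows(
        context, mut_pos - start + 1, n,
        context_start=start, transcript_id=transcript_id,
        mutation_id=mutation_id,
    )
    for w in windows:
        w.self_seq = self_counterpart(w, protein_seq)
    return windows


def merge_transcripts(windows: Iterable[PeptideWindow]) -> list[PeptideWindow]:
    """Collapse identical (seq, n) windows, unioning transcript origins and
    keeping per-transcript start coordinates."""
    merged: dict[tuple[str, int], PeptideWindow] = {}
    order: list[tuple[str, int]] = []
    for w in windows:
        key = (w.seq, w.n)
        if key not in merged:
            merged[key] = dataclasses.replace(
                w, transcripts=frozenset(w.transcripts),
                starts_by_transcript=dict(w.starts_by_transcript))
            order.append(key)
        else:
            m = merged[key]
            m.starts_by_transcript.update(w.starts_by_transcript)
            merged[key] = dataclasses.replace(
                m, transcripts=m.transcripts | w.transcripts)
    return [merged[k] for k in order]
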