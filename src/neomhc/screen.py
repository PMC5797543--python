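"""Screen analytics: identity landscape and KL sequence logos.

Turns per-allele binding-energy screen results into the downstream
analyses: BLOSUM62 similarity of groove residues to a reference allele
(normalised by the reference self-score), selection of alleles binding
better than a threshold allele, and Kullback-Leibler sequence logos of
groove columns among good binders.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from neomhc.threader import ScreenResult, TemplateComplex, _align

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"


def blosum62(a: str, b: str) -> float:
    return float(_BLOSUM62[a, b])


def identity_to_reference(groove_seq: str, ref_groove_seq: str) -> float:
    """BLOSUM62 similarity over groove columns, normalised by the
    reference's self-score: identity(x, x) == 1."""
    if len(groove_seq) != len(ref_groove_seq):
        raise ValueError("groove strings must have equal length")
    if not groove_seq:
        raise ValueError("empty groove strings")
    score = sum(blosum62(a, b) for a, b in zip(groove_seq, ref_groove_seq))
    self_score = sum(blosum62(b, b) for b in ref_groove_seq)
    return score / self_score


def groove_sequence(tc: TemplateComplex, allele_seq: str) -> str:
    """The allele's residues at the template's groove positions, read off
    the same global alignment the threading step uses. Gapped groove
    positions raise (such alleles are rejected by threading too)."""
    heavy = tc.structure.chain(tc.heavy_chain)
    template_seq = heavy.sequence()
    alignment = _align(template_seq, allele_seq)
    mapping: dict[int, str] = {}
    for (ts, te), (as_, ae) in zip(*alignment.aligned):
        for k in range(te - ts):
            mapping[ts + k] = allele_seq[as_ + k]
    groove_set = set(tc.groove_resseqs)
    letters = []
    for i, res in enumerate(heavy.residues):
        if res.resseq in groove_set:
            if i not in mapping:
                raise ValueError(f"alignment gap at groove residue "
                                 f"{res.resseq}")
            letters.append(mapping[i])
    return "".join(letters)


def template_groove_sequence(tc: TemplateComplex) -> str:
    heavy = tc.structure.chain(tc.heavy_chain)
    groove_set = set(tc.groove_resseqs)
    return "".join(r.one_letter for r in heavy.residues
                   if r.resseq in groove_set)


def select_good_binders(screen_results: Sequence[ScreenResult],
                        threshold_allele: str) -> list[ScreenResult]:
    """Alleles with mean dE strictly lower (better) than the threshold
    allele's."""
    by_name = {r.allele: r for r in screen_results}
    if threshold_allele not in by_name:
        raise ValueError(f"threshold allele {threshold_allele!r} not in "
                         "screen results")
    cutoff = by_name[threshold_allele].mean_delta_e
    return [r for r in screen_results
            if r.status == "scored" and r.mean_delta_e < cutoff]


@dataclasses.dataclass
class LogoMatrix:
    """Per-column letter frequencies, KL divergence (bits) and letter
    heights (frequency x KL)."""

    frequencies: np.ndarray  # (n_cols, 20) in AA_ORDER
    kl: np.ndarray  # (n_cols,)
    heights: np.ndarray  # (n_cols, 20)

    @property
    def n_cols(self) -> int:
        return len(self.kl)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for col in range(self.n_cols):
            for i, letter in enumerate(AA_ORDER):
                rows.append({"column": col + 1, "letter": letter,
                             "frequency": self.frequencies[col, i],
                             "kl": self.kl[col],
                             "height": self.heights[col, i]})
        return pd.DataFrame(rows)


UNIFORM_BACKGROUND = {a: 1.0 / 20.0 for a in AA_ORDER}


def kl_logo(sequences: Sequence[str],
            background: dict[str, float] | None = None,
            pseudocount: float = 0.5) -> LogoMatrix:
    """Kullback-Leibler logo of aligned equal-length sequences.

    Column KL = sum_a p(a) log2(p(a)/q(a)) with a per-letter pseudocount
    of ``pseudocount`` before normalisation; heights are p(a) x KL. The
    background must support every observed letter.
    """
    if not sequences:
        raise ValueError("no sequences for the logo")
    length = len(sequences[0])
    if any(len(s) != length for s in sequences):
        raise ValueError("sequences must be aligned to equal length")
    q = background or UNIFORM_BACKGROUND
    missing = {a for s in sequences for a in s} - {a for a, p in q.items()
                                                   if p > 0}
    if missing:
        raise ValueError(f"background assigns zero mass to observed "
                         f"letters {sorted(missing)}")
    qv = np.array([q.get(a, 0.0) for a in AA_ORDER])
    freqs = np.zeros((length, 20))
    kl = np.zeros(length)
    for col in range(length):
        counts = np.full(20, pseudocount)
        for s in sequences:
            counts[AA_ORDER.index(s[col])] += 1.0
        p = counts / counts.sum()
        freqs[col] = p
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, p * np.log2(
                np.where(p > 0, p, 1.0) / np.where(qv > 0, qv, np.nan)), 0.0)
        kl[col] = float(np.nansum(terms))
    heights = freqs * kl[:, None]
    return LogoMatrix(frequencies=freqs, kl=kl, heights=heights)


def max_kl_bits() -> float:
    """KL (bits) of a fully conserved column against the uniform
    background with no pseudocount: log2(20)."""
    return math.log2(20.0)


def landscape_table(screen_results: Sequence[ScreenResult],
                    reference: str) -> pd.DataFrame:
    """One row per scored allele: allele, mean/sd dE, identity to the
    reference, flags for the reference and the polyAla control; sorted by
    mean dE ascending (best binder first)."""
    rows = []
    for r in screen_results:
        if r.status != "scored":
            rows.append({"allele": r.allele, "mean_delta_e": np.nan,
                         "sd_delta_e": np.nan, "identity": np.nan,
                         "is_reference": r.allele == reference,
                         "is_control": "polyAla" in r.allele,
                         "status": r.status})
            continue
        rows.append({"allele": r.allele, "mean_delta_e": r.mean_delta_e,
                     "sd_delta_e": r.sd_delta_e, "identity": r.identity,
                     "is_reference": r.allele == reference,
                     "is_control": "polyAla" in r.allele,
                     "status": r.status})
    frame = pd.DataFrame(rows)
    return frame.sort_values("mean_delta_e", na_position="last",
                             kind="mergesort").reset_index(drop=True)
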