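"""Peptide/MHC binding calls, percentile-rank filtering and IAR ranking.

Scoring goes through a pluggable predictor interface. The bundled
``PSSMScorer`` is a deliberately simple, fully seeded position-specific
scoring model with a random-peptide background for percentile calibration.
It exists so the pipeline is runnable and testable end to end without any
external predictor; it is NOT a reimplementation of the IEDB consensus
method, and its percentile values should never be compared with published
consensus scores. Precomputed tables from any real predictor can be
substituted via ``TablePredictor``.

A call's percentile rank is 100 x the fraction of a background score set
that is strictly better than the call; lower is stronger. Calls with rank
greater than the cutoff (default 5.0, boundary kept) are discarded as
non-binders. Kept calls are grouped by mutation and transcript set into
ImmunoActive Regions (IARs) and ranked by a weighted composite of the best
contained binder, transcript expression, allele promiscuity, and 9/10-mer
overlap support.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from pathlib import Path
from typing import Iterable, Protocol, Sequence

import numpy as np
import pandas as pd

from neomhc.windows import PeptideWindow

logger = logging.getLogger(__name__)

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}


@dataclasses.dataclass
class BindingCall:
    peptide: str
    allele: str
    percentile_rank: float  # [0, 100], lower = better
    self_rank: float | None = None
    window: PeptideWindow | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.percentile_rank <= 100.0):
            raise ValueError("percentile rank outside [0, 100]")

    @property
    def better_than_self(self) -> bool | None:
        if self.self_rank is None:
            return None
        return self.percentile_rank < self.self_rank


class Predictor(Protocol):
    def percentile(self, peptide: str, allele: str) -> float: ...


def percentile_rank(score: float, background_scores: np.ndarray) -> float:
    """100 x fraction of background scores strictly better (higher) than
    ``score``. Monotone non-increasing in score quality."""
    background = np.asarray(background_scores, dtype=float)
    if background.size == 0:
        raise ValueError("empty background score set")
    n_better = int(np.sum(background > score))
    return 100.0 * n_better / background.size


def _stable_seed(*parts: object) -> int:
    digest = hashlib.sha256("|".join(map(str, parts)).encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


class PSSMScorer:
    """Seeded per-allele, per-length log-odds matrices with a random
    background sample for percentile calibration.

    Matrices are drawn deterministically from (master seed, allele, length),
    with anchor positions (2 and the C-terminus) given a larger score
    spread, mimicking the anchor-dominated specificity of class I grooves.
    """

    def __init__(self, master_seed: int = 2018,
                 background_size: int = 100_000,
                 anchor_scale: float = 3.0):
        self.master_seed = master_seed
        self.background_size = background_size
        self.anchor_scale = anchor_scale
        self._matrices: dict[tuple[str, int], np.ndarray] = {}
        self._backgrounds: dict[tuple[str, int], np.ndarray] = {}

    def matrix(self, allele: str, n: int) -> np.ndarray:
        key = (allele, n)
        if key not in self._matrices:
            rng = np.random.default_rng(
                _stable_seed(self.master_seed, allele, n))
            m = rng.normal(0.0, 1.0, size=(n, 20))
            m[1] *= self.anchor_scale  # position 2 anchor
            m[-1] *= self.anchor_scale  # C-terminal anchor
            self._matrices[key] = m
        return self._matrices[key]

    def background(self, allele: str, n: int) -> np.ndarray:
        """Sorted scores of ``background_size`` random peptides drawn from
        uniform residue frequencies (seeded per allele/length)."""
        key = (allele, n)
        if key not in self._backgrounds:
            m = self.matrix(allele, n)
            rng = np.random.default_rng(
                _stable_seed(self.master_seed, allele, n, "background"))
            idx = rng.integers(0, 20, size=(self.background_size, n))
            scores = m[np.arange(n)[None, :], idx].sum(axis=1)
            self._backgrounds[key] = np.sort(scores)
        return self._backgrounds[key]

    def score(self, peptide: str, allele: str) -> float:
        m = self.matrix(allele, len(peptide))
        try:
            idx = [_AA_INDEX[a] for a in peptide]
        except KeyError as exc:
            raise ValueError(f"non-standard residue in {peptide!r}") from exc
        return float(m[np.arange(len(peptide)), idx].sum())

    def percentile(self, peptide: str, allele: str) -> float:
        background = self.background(allele, len(peptide))
        score = self.score(peptide, allele)
        # background is sorted ascending; strictly better = strictly higher
        n_better = background.size - int(
            np.searchsorted(background, score, side="right"))
        return 100.0 * n_better / background.size


class TablePredictor:
    """Percentiles from a precomputed (peptide, allele, percentile) table,
    e.g. exported from an external consensus predictor."""

    def __init__(self, table: pd.DataFrame):
        required = {"peptide", "allele", "percentile"}
        if not required.issubset(table.columns):
            raise ValueError(f"table must have columns {sorted(required)}")
        self._lookup = {
            (row.peptide, row.allele): float(row.percentile)
            for row in table.itertuples()
        }

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TablePredictor":
        return cls(pd.read_csv(path, sep="\t"))

    def percentile(self, peptide: str, allele: str) -> float:
        try:
            return self._lookup[(peptide, allele)]
        except KeyError:
            raise KeyError(
                f"no precomputed percentile for {peptide}/{allele}") from None


def score_windows(windows: Sequence[PeptideWindow], alleles: Sequence[str],
                  predictor: Predictor) -> list[BindingCall]:
    """One call per (window, allele) pair."""
    calls = []
    for w in windows:
        for allele in alleles:
            calls.append(BindingCall(
                peptide=w.seq, allele=allele,
                percentile_rank=predictor.percentile(w.seq, allele),
                window=w,
            ))
    return calls


def filter_binders(calls: Iterable[BindingCall],
                   cutoff: float = 5.0) -> list[BindingCall]:
    """Keep calls with percentile rank <= cutoff (strictly greater
    dropped)."""
    return [c for c in calls if c.percentile_rank <= cutoff]


def attach_self_rank(call: BindingCall, self_seq: str,
                     predictor: Predictor) -> BindingCall:
    """Score the self counterpart with the identical predictor/background.

    A mutant whose self peptide ranks better is retained but flagged (and
    logged); a self sequence identical to the mutant violates the
    Hamming-1 pairing and is an error.
    """
    if self_seq == call.peptide:
        raise ValueError("self peptide identical to mutant peptide")
    call.self_rank = predictor.percentile(self_seq, call.allele)
    if call.better_than_self is False:
        logger.warning(
            "%s on %s: self peptide ranks better (%.2f) than mutant (%.2f)",
            call.peptide, call.allele, call.self_rank, call.percentile_rank)
    return call


@dataclasses.dataclass
class IAR:
    """ImmunoActive Region: kept calls grouped by mutation and transcript
    set, with the metrics the composite ranking consumes."""

    mutation_id: str
    transcripts: frozenset[str]
    calls: list[BindingCall]
    best_rank: float
    expression: float
    promiscuity: int
    overlap_count: int
    composite: float = float("nan")


def group_iars(
    kept_calls: Sequence[BindingCall],
    expression: dict[str, float] | None = None,
    overlap_rank_delta: float = 2.0,
) -> list[IAR]:
    """Group kept calls into IARs keyed by (mutation, transcript set).

    ``expression`` maps mutation_id -> transcript-level expression (0 when
    absent). ``overlap_count`` counts distinct 10-mer peptides in the IAR
    that overlap (by protein coordinates) a 9-mer bound to the same allele
    with |rank difference| <= ``overlap_rank_delta``.
    """
    groups: dict[tuple[str, frozenset[str]], list[BindingCall]] = {}
    for call in kept_calls:
        if call.window is None:
            raise ValueError("grouping requires calls with window provenance")
        key = (call.window.mutation_id, call.window.transcripts)
        groups.setdefault(key, []).append(call)
    iars = []
    for (mutation_id, transcripts), calls in groups.items():
        nines = [c for c in calls if c.window.n == 9]
        tens = [c for c in calls if c.window.n == 10]
        overlapping = set()
        for c10 in tens:
            s10, e10 = c10.window.start, c10.window.start + 9
            for c9 in nines:
                if c9.allele != c10.allele:
                    continue
                s9, e9 = c9.window.start, c9.window.start + 8
                if (s10 <= e9 and s9 <= e10 and
                        abs(c10.percentile_rank - c9.percentile_rank)
                        <= overlap_rank_delta):
                    overlapping.add(c10.peptide)
                    break
        iars.append(IAR(
            mutation_id=mutation_id,
            transcripts=transcripts,
            calls=list(calls),
            best_rank=min(c.percentile_rank for c in calls),
            expression=(expression or {}).get(mutation_id, 0.0),
            promiscuity=len({c.allele for c in calls}),
            overlap_count=len(overlapping),
        ))
    return iars


def _minmax(values: np.ndarray) -> np.ndarray:
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def rank_iars(iars: Sequence[IAR],
              weights: Sequence[float] = (0.4, 0.3, 0.2, 0.1)) -> list[IAR]:
    """Order IARs by descending composite score.

    composite = w1 (1 - best_rank/100) + w2 norm(expression)
              + w3 norm(promiscuity) + w4 norm(overlap_count)

    with min-max normalisation within the sample; ties break by
    mutation_id. Weights must be non-negative.
    """
    if any(w < 0 for w in weights):
        raise ValueError("IAR ranking weights must be non-negative")
    if len(weights) != 4:
        raise ValueError("exactly four weights expected")
    if not iars:
        return []
    w1, w2, w3, w4 = weights
    expr = _minmax(np.array([i.expression for i in iars], dtype=float))
    prom = _minmax(np.array([i.promiscuity for i in iars], dtype=float))
    over = _minmax(np.array([i.overlap_count for i in iars], dtype=float))
    ranked = []
    for i, iar in enumerate(iars):
        composite = (w1 * (1.0 - iar.best_rank / 100.0)
                     + w2 * expr[i] + w3 * prom[i] + w4 * over[i])
        ranked.append(dataclasses.replace(iar, composite=float(composite)))
    ranked.sort(key=lambda r: (-r.composite, r.mutation_id))
    return ranked


def iar_table(iars: Sequence[IAR]) -> pd.DataFrame:
    rows = [{
        "rank": i + 1,
        "mutation": iar.mutation_id,
        "transcripts": ",".join(sorted(iar.transcripts)),
        "best_rank": iar.best_rank,
        "expression": iar.expression,
        "promiscuity": iar.promiscuity,
        "overlap_count": iar.overlap_count,
        "composite": iar.composite,
        "n_calls": len(iar.calls),
    } for i, iar in enumerate(iars)]
    return pd.DataFrame(rows)
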