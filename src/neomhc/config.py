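"""Toolkit configuration.

All numeric defaults are the constants used throughout the pipeline: the
0.1 allele-fraction cutoff and 5% percentile-rank binder cutoff of the
variant/epitope pipeline, the 3.5 A groove definition, and the
100-model / top-10 protocol of the binding-energy screen.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml


@dataclasses.dataclass
class ToolConfig:
    """Shared knobs for every subcommand and library entry point.

    Attributes
    ----------
    allele_fraction_cutoff:
        Tumor-DNA allele fraction below which a variant needs RNA support
        (strict ``<`` comparison).
    expression_cutoff:
        Gene-expression value at or below which a gene counts as
        unexpressed. The expression metric itself (counts vs normalised)
        is caller-defined.
    percentile_cutoff:
        Percentile rank above which a peptide/MHC call is discarded as a
        non-binder (calls with rank <= cutoff are kept).
    groove_cutoff:
        Heavy-atom distance (A) from the peptide defining groove residues.
    n_models, top_k:
        Size of the refined-model pool per allele and the number of lowest
        binding-energy models averaged into the reported score.
    sasa_probe, sasa_points:
        Solvent probe radius (A) and sphere-point count for Shrake-Rupley
        surface areas.
    peptide_lengths:
        Epitope lengths n; each missense variant is expanded to a 2n-1
        context per length.
    overlap_rank_delta:
        Maximum |rank(10-mer) - rank(9-mer)| (percentile points) for the
        two calls to count as "similar affinity" in the IAR overlap metric.
    iar_weights:
        Composite IAR ranking weights (best binder, expression,
        promiscuity, 9/10-mer overlap).
    master_seed:
        Root of every random stream in the toolkit.
    """

    allele_fraction_cutoff: float = 0.1
    expression_cutoff: float = 0.0
    max_caller_rejects: int = 2
    percentile_cutoff: float = 5.0
    groove_cutoff: float = 3.5
    n_models: int = 100
    top_k: int = 10
    sasa_probe: float = 1.4
    sasa_points: int = 960
    peptide_lengths: tuple[int, ...] = (9, 10, 15)
    overlap_rank_delta: float = 2.0
    iar_weights: tuple[float, float, float, float] = (0.4, 0.3, 0.2, 0.1)
    master_seed: int = 2018

    def __post_init__(self) -> None:
        for name in (
            "allele_fraction_cutoff",
            "percentile_cutoff",
            "groove_cutoff",
            "sasa_probe",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.top_k > self.n_models:
            raise ValueError("top_k must be <= n_models")
        if self.top_k < 1 or self.n_models < 1:
            raise ValueError("n_models and top_k must be >= 1")
        self.peptide_lengths = tuple(int(n) for n in self.peptide_lengths)
        self.iar_weights = tuple(float(w) for w in self.iar_weights)
        if any(w < 0 for w in self.iar_weights):
            raise ValueError("IAR ranking weights must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ToolConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        )
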