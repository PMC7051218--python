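"""Synthetic protein x replicate tables with the statistical structure the
pipeline assumes.

Generative model
----------------
Each protein's base abundance is log-normal (natural-log mean/SD set by the
config).  Observed abundance in replicate r of passage b is::

    observed[p, r] = base[p] * bio_factor[p, b] * tech_factor[p, r]

with multiplicative, mean-1 log-normal passage effects (total CV =
``bio_cv``, shared by all technical replicates of one passage) and injection
effects (total CV = ``tech_cv``, independent per run).  Each effect is
hierarchical: part of its log-variance is a sample-level component common to
every protein in that passage/injection (prep yield, loading amount,
ion-source efficiency) and the rest is protein-specific (a protein's vesicle
loading shifting between passages, peptide-level interference between runs).
The split is set by ``bio_shared_fraction`` / ``tech_shared_fraction``;
without a shared component, per-replicate identification counts would
average the protein-specific effects away and biological replicates would
look no more variable than technical ones, contrary to what label-free
replicate series show.  Detection is Bernoulli with a
logistic probability in log abundance::

    P(detected) = 1 / (1 + exp(-slope * (ln observed - midpoint)))

so low-abundance proteins drop out often (producing a large singleton
occupancy class) while the top of the dynamic range is detected in every
replicate.  The LFQ-flavor table holds the observed abundances as-is; the
APEX-flavor table is the same matrix rescaled so each replicate column sums
to the normalization constant C.  Both share one detection mask, as both
derive from the same runs.

Everything is reproducible from the config's seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit

from .io_design import (
    DEFAULT_NORMALIZATION_CONSTANT,
    AbundanceTable,
    Flavor,
    Numbering,
    ReplicateDesign,
    build_design,
)

__all__ = ["SyntheticConfig", "SyntheticTruth", "generate", "write_fixture"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the generative model.

    Defaults emulate a deep LC-MS/MS profile of vesicle cargo: ~1000
    proteins spanning several decades of abundance, passage effects clearly
    larger than injection effects, and dropout centred at the median log
    abundance so roughly half the detections at the median are missed.
    """

    n_proteins: int = 1000
    n_bio: int = 3
    n_tech: int = 3
    log_abundance_mean: float = 10.0
    log_abundance_sd: float = 2.0
    bio_cv: float = 0.5
    tech_cv: float = 0.1
    bio_shared_fraction: float = 0.5
    tech_shared_fraction: float = 0.5
    detection_midpoint: float = 10.0
    detection_slope: float = 0.8
    normalization_constant: float = DEFAULT_NORMALIZATION_CONSTANT
    numbering: Numbering = Numbering.TR_TRIADS_SAME_LYSATE
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "numbering", Numbering(self.numbering))
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if self.n_bio < 2 or self.n_tech < 2:
            raise ValueError("need n_bio >= 2 and n_tech >= 2")
        if self.bio_cv < 0 or self.tech_cv < 0:
            raise ValueError("coefficients of variation must be non-negative")
        for frac in (self.bio_shared_fraction, self.tech_shared_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("shared fractions must lie in [0, 1]")
        if not self.detection_slope > 0:
            raise ValueError("detection_slope must be positive")
        if not self.log_abundance_sd > 0:
            raise ValueError("log_abundance_sd must be positive")
        if not self.normalization_constant > 0:
            raise ValueError("normalization_constant must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["numbering"] = self.numbering.value
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        return cls(**d)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth factors behind a generated dataset.

    ``observed = base * bio_factor * tech_factor`` wherever ``detected`` is
    true, else the recorded value is 0.
    """

    protein_ids: tuple[str, ...]
    replicate_ids: tuple[str, ...]
    bio_labels: tuple[str, ...]
    base_abundance: np.ndarray  # (proteins,)
    bio_factor: np.ndarray  # (proteins, passages)
    tech_factor: np.ndarray  # (proteins, replicates)
    detected: np.ndarray  # (proteins, replicates) bool

    def to_dict(self) -> dict:
        return {
            "protein_ids": list(self.protein_ids),
            "replicate_ids": list(self.replicate_ids),
            "bio_labels": list(self.bio_labels),
            "base_abundance": self.base_abundance.tolist(),
            "bio_factor": self.bio_factor.tolist(),
            "tech_factor": self.tech_factor.tolist(),
            "detected": self.detected.astype(int).tolist(),
        }


def _hierarchical_factors(
    rng: np.random.Generator,
    cv: float,
    shared_fraction: float,
    n_proteins: int,
    n_units: int,
) -> np.ndarray:
    """Mean-1 multiplicative effects for ``n_units`` samples x ``n_proteins``.

    Total log-variance ``ln(1 + cv^2)`` is split into a per-unit component
    shared by all proteins (``shared_fraction``) and an independent
    per-(protein, unit) component.  Returns a (n_proteins, n_units) array.
    """
    if cv == 0:
        return np.ones((n_proteins, n_units))
    sigma2 = np.log1p(cv**2)
    s2_shared = shared_fraction * sigma2
    s2_spec = sigma2 - s2_shared
    shared = rng.normal(0.0, np.sqrt(s2_shared), n_units) if s2_shared > 0 else np.zeros(n_units)
    specific = (
        rng.normal(0.0, np.sqrt(s2_spec), (n_proteins, n_units))
        if s2_spec > 0
        else np.zeros((n_proteins, n_units))
    )
    return np.exp(shared[None, :] + specific - sigma2 / 2)


def generate(
    config: SyntheticConfig,
) -> tuple[AbundanceTable, AbundanceTable, ReplicateDesign, SyntheticTruth]:
    """Draw one dataset: (LFQ-flavor table, APEX-flavor table, design, truth)."""
    rng = np.random.default_rng(config.seed)
    design = build_design(config.n_bio, config.n_tech, config.numbering)
    replicate_ids = design.replicate_ids
    bio_labels = design.bio_labels
    n_reps = len(replicate_ids)
    width = len(str(config.n_proteins))
    protein_ids = tuple(f"P{i + 1:0{width}d}" for i in range(config.n_proteins))

    base = rng.lognormal(config.log_abundance_mean, config.log_abundance_sd, config.n_proteins)
    bio = _hierarchical_factors(
        rng, config.bio_cv, config.bio_shared_fraction, config.n_proteins, config.n_bio
    )
    tech = _hierarchical_factors(
        rng, config.tech_cv, config.tech_shared_fraction, config.n_proteins, n_reps
    )

    bio_idx = np.array(
        [bio_labels.index(design.assignments[r][0]) for r in replicate_ids]
    )
    observed = base[:, None] * bio[:, bio_idx] * tech

    with np.errstate(divide="ignore"):
        logit = config.detection_slope * (np.log(observed) - config.detection_midpoint)
    p_detect = expit(logit)
    detected = rng.random((config.n_proteins, n_reps)) < p_detect

    lfq_values = np.where(detected, observed, 0.0)
    col_sums = lfq_values.sum(axis=0)
    scale = np.divide(
        config.normalization_constant,
        col_sums,
        out=np.zeros_like(col_sums),
        where=col_sums > 0,
    )
    apex_values = lfq_values * scale

    lfq = AbundanceTable(
        protein_ids=protein_ids,
        replicate_ids=replicate_ids,
        values=lfq_values,
        flavor=Flavor.LFQ,
        normalization_constant=config.normalization_constant,
    )
    apex = AbundanceTable(
        protein_ids=protein_ids,
        replicate_ids=replicate_ids,
        values=apex_values,
        flavor=Flavor.APEX,
        normalization_constant=config.normalization_constant,
    )
    truth = SyntheticTruth(
        protein_ids=protein_ids,
        replicate_ids=replicate_ids,
        bio_labels=bio_labels,
        base_abundance=base,
        bio_factor=bio,
        tech_factor=tech,
        detected=detected,
    )
    return lfq, apex, design, truth


def write_fixture(config: SyntheticConfig, directory: str | Path) -> dict[str, Path]:
    """Materialize one generated dataset as re-readable files.

    Emits ``lfq.tsv``, ``apex.tsv``, ``design.json``, ``truth.json`` and
    ``config.json`` under ``directory``; returns the paths written.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    lfq, apex, design, truth = generate(config)
    paths = {
        "lfq": directory / "lfq.tsv",
        "apex": directory / "apex.tsv",
        "design": directory / "design.json",
        "truth": directory / "truth.json",
        "config": directory / "config.json",
    }
    lfq.write(paths["lfq"])
    apex.write(paths["apex"])
    paths["design"].write_text(json.dumps(design.to_dict(), indent=2) + "\n")
    paths["truth"].write_text(json.dumps(truth.to_dict()) + "\n")
    paths["config"].write_text(json.dumps(config.to_dict(), indent=2) + "\n")
    return paths
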