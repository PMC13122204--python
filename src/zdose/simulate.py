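"""Synthetic qPCR plates from ZZ/Z0 genotypes.

The amplification model is the standard exponential one: a template present
at ``copies`` relative copy number crosses the detection threshold at

    ``Cq = cq_ref - ln(copies) / ln(1 + E)``

where ``E`` is the per-cycle amplification efficiency (E = 1 is perfect
doubling) and ``cq_ref`` the quantification cycle of a single relative copy
at the reference input.  Autosomal targets are diploid in both sexes
(2 copies); the Z-linked target has 2 copies in ZZ males and 1 in Z0
females, which at E = 1 is exactly one cycle of separation.

Replicate noise is Gaussian on the cycle scale; differences in input DNA
amount between animals (swab yield varies widely) are modelled as a single
additive Cq offset shared by both targets of a sample, which the dCq
subtraction cancels.  Occasional aberrant wells can be injected as fixed
shifts at a configurable probability.  All draws come from one
``numpy.random.Generator`` in a fixed documented order, so a seed fully
determines a plate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from zdose.genotyping import CqMeasurement, TargetRole

__all__ = [
    "AssayModel",
    "SimConfig",
    "expected_cq",
    "simulate_sample",
    "simulate_cohort",
    "simulate_dilution_series",
]

AUTOSOME_COPIES = 2
SEX_COPIES = {"ZZ": 2, "Z0": 1}


@dataclass(frozen=True)
class AssayModel:
    """Amplification model of one primer pair.

    efficiency: per-cycle fractional gain; assays are accepted in the
        0.90-1.10 window, so that is the realistic range.
    cq_ref: Cq of a single relative template copy at reference input.
    """

    target_role: TargetRole
    efficiency: float = 1.0
    cq_ref: float = 22.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "target_role", TargetRole(self.target_role))
        if self.efficiency <= 0:
            raise ValueError("efficiency must be > 0")
        if not 0 < self.cq_ref < 45:
            raise ValueError("cq_ref must be within (0, 45)")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for a simulated cohort.

    Defaults mirror the assay as run in practice: quadruplicate technical
    replicates, an 81-animal cohort (40 ZZ / 41 Z0), 100 %-efficient assays
    on both targets, replicate noise of 0.12 cycles, and per-sample input
    offsets of 0.5 cycles SD.  Aberrant wells are off by default and can be
    switched on via ``outlier_prob``/``outlier_shift``.
    """

    n_male: int = 40
    n_female: int = 41
    replicates: int = 4
    noise_sd: float = 0.12
    sample_offset_sd: float = 0.5
    outlier_prob: float = 0.0
    outlier_shift: float = 2.0
    seed: int = 0
    autosome: AssayModel = field(
        default_factory=lambda: AssayModel(TargetRole.AUTOSOME, 1.0, 21.0)
    )
    sex: AssayModel = field(
        default_factory=lambda: AssayModel(TargetRole.SEX, 1.0, 22.0)
    )

    def __post_init__(self) -> None:
        if self.n_male < 0 or self.n_female < 0:
            raise ValueError("genotype counts must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not 0 <= self.outlier_prob <= 1:
            raise ValueError("outlier_prob must be in [0, 1]")
        for sd in (self.noise_sd, self.sample_offset_sd):
            if sd < 0:
                raise ValueError("noise SDs must be >= 0")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


def expected_cq(copies: float, model: AssayModel) -> float | None:
    """Deterministic Cq of ``copies`` relative template copies.

    ``copies`` may be any positive real (fractional values arise in
    dilution series); 0 copies never amplifies and yields a missing Cq.
    """
    if copies < 0:
        raise ValueError("copies must be >= 0")
    if copies == 0:
        return None
    return model.cq_ref - math.log(copies) / math.log(1.0 + model.efficiency)


def simulate_sample(
    genotype: str,
    config: SimConfig,
    rng: np.random.Generator,
    sample_id: str = "sample",
) -> list[CqMeasurement]:
    """Simulate all wells of one animal.

    Draw order (fixed for reproducibility): the shared input-amount offset,
    then for the autosome followed by the sex target, per replicate: the
    Gaussian noise term, the aberrant-well uniform, and — only when the
    well is aberrant — the shift-direction uniform.
    """
    if genotype not in SEX_COPIES:
        raise ValueError(f"genotype must be ZZ or Z0, got {genotype!r}")
    offset = rng.normal(0.0, config.sample_offset_sd)
    wells: list[CqMeasurement] = []
    plan = [
        (config.autosome, AUTOSOME_COPIES),
        (config.sex, SEX_COPIES[genotype]),
    ]
    for model, copies in plan:
        base = expected_cq(copies, model)
        for rep in range(config.replicates):
            noise = rng.normal(0.0, config.noise_sd)
            u = rng.random()
            cq = None
            if base is not None:
                cq = base + offset + noise
                if u < config.outlier_prob:
                    sign = 1.0 if rng.random() < 0.5 else -1.0
                    cq += sign * config.outlier_shift
            wells.append(
                CqMeasurement(
                    sample_id=sample_id,
                    target_role=model.target_role,
                    well_id=f"{sample_id}:{model.target_role.value}:{rep + 1}",
                    cq=cq,
                )
            )
    return wells


def simulate_cohort(
    config: SimConfig,
) -> tuple[list[CqMeasurement], pd.DataFrame]:
    """Simulate a plate of ``n_male`` ZZ and ``n_female`` Z0 animals.

    Returns the flat well list plus a truth table (sample_id, genotype,
    true_sex) for scoring pipeline output against known ground truth.
    """
    rng = np.random.default_rng(config.seed)
    wells: list[CqMeasurement] = []
    truth_rows = []
    n_total = config.n_male + config.n_female
    width = max(3, len(str(n_total)))
    genotypes = ["ZZ"] * config.n_male + ["Z0"] * config.n_female
    for i, genotype in enumerate(genotypes, start=1):
        sid = f"animal_{i:0{width}d}"
        wells.extend(simulate_sample(genotype, config, rng, sample_id=sid))
        truth_rows.append(
            {
                "sample_id": sid,
                "genotype": genotype,
                "true_sex": "male" if genotype == "ZZ" else "female",
            }
        )
    return wells, pd.DataFrame(truth_rows)


def plate_to_frame(wells: list[CqMeasurement]) -> pd.DataFrame:
    """Render wells in the Cq-table dialect read by ``zdose.io``."""
    return pd.DataFrame(
        {
            "Sample": [w.sample_id for w in wells],
            "Target": [w.target_role.value for w in wells],
            "Well": [w.well_id for w in wells],
            "Cq": [
                "Undetermined" if w.cq is None else f"{w.cq:.6f}" for w in wells
            ],
        }
    )


def simulate_dilution_series(
    model: AssayModel,
    dilution_factors: list[float],
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    start_copies: float = 1e4,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate a standard curve: Cq at each serial dilution of the input.

    ``dilution_factors`` are cumulative (e.g. ``[1, 10, 100, 1000]`` for a
    10-fold series).  Returns (log10 relative input, Cq) pairs; at E = 1
    the slope of Cq on log10 input is -log2(10) = -3.3219.
    """
    if len(dilution_factors) < 3:
        raise ValueError("need at least 3 dilution points")
    if any(f <= 0 for f in dilution_factors):
        raise ValueError("dilution factors must be > 0")
    if rng is None:
        rng = np.random.default_rng(0)
    log10_input = np.array([math.log10(start_copies / f) for f in dilution_factors])
    cqs = np.array(
        [
            expected_cq(start_copies / f, model) + rng.normal(0.0, noise_sd)
            for f in dilution_factors
        ]
    )
    return log10_input, cqs
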