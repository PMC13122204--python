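"""Cq replicate tables to male/female/repeat calls.

The pipeline is: per-sample/per-target replicate QC (outlier screen, mean,
SEM) -> within-sample dosage difference dCq = Cq(autosome) - Cq(sex) ->
two-cluster split of the plate's dCq values -> normalisation to the male
(greater-dCq) cluster median, giving ddCq ~ 0 for ZZ males and ~ -1 for Z0
females -> threshold classification at the cluster midpoint (-0.5) with a
precision guard that flags samples for repeat.

Everything in this module is deterministic; all randomness lives in
:mod:`zdose.simulate`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

MAX_CYCLES_DEFAULT = 45.0

#: Default classification threshold: the midpoint between the male (0) and
#: female (-1) ddCq cluster centres.
DDCQ_THRESHOLD_DEFAULT = -0.5

#: Default replicate outlier screen: discard Cq values differing by more
#: than one cycle from the replicate-group mean.
OUTLIER_THRESHOLD_DEFAULT = 1.0

#: Inter-cluster gaps below this (cycles) raise the unimodality flag.
MIN_CLUSTER_GAP_DEFAULT = 0.3


class TargetRole(str, Enum):
    AUTOSOME = "autosome"
    SEX = "sex"


class SexCall(str, Enum):
    MALE = "male"
    FEMALE = "female"
    REPEAT = "repeat"


class NoUsableReplicatesError(ValueError):
    """A replicate group contains no usable (non-missing) Cq values."""


class NoMaleReferenceError(ValueError):
    """No male cluster could be resolved and no male standard was given."""


@dataclass(frozen=True)
class CqMeasurement:
    """One well: a raw quantification cycle for a sample/target pair.

    ``cq`` is ``None`` for wells the instrument reported as Undetermined
    (no amplification within ``max_cycles``); such wells are dropped from
    analysis, never imputed to the cycle ceiling.
    """

    sample_id: str
    target_role: TargetRole
    well_id: str = ""
    cq: float | None = None
    max_cycles: float = MAX_CYCLES_DEFAULT

    def __post_init__(self) -> None:
        role = TargetRole(self.target_role)
        object.__setattr__(self, "target_role", role)
        if self.cq is not None:
            if isinstance(self.cq, float) and math.isnan(self.cq):
                object.__setattr__(self, "cq", None)
            elif not math.isfinite(self.cq) or not 0 < self.cq <= self.max_cycles:
                raise ValueError(
                    f"Cq {self.cq!r} for {self.sample_id}/{role.value} outside "
                    f"(0, {self.max_cycles}]"
                )


@dataclass(frozen=True)
class ReplicateGroup:
    """QC'd summary of the technical replicates of one sample/target.

    The outlier screen is a single pass: every raw value is compared with
    the mean of *all* raw values and discarded when it deviates by strictly
    more than the threshold.  Mean and SEM are recomputed on survivors.
    """

    sample_id: str
    target_role: TargetRole
    raw_cqs: tuple[float, ...]
    kept_cqs: tuple[float, ...]
    mean_cq: float
    sem_cq: float
    n_discarded: int

    @property
    def n_kept(self) -> int:
        return len(self.kept_cqs)

    @property
    def low_confidence(self) -> bool:
        """Fewer than two surviving replicates: SEM is not estimable."""
        return self.n_kept < 2

    @property
    def sem_for_repeat_rule(self) -> float:
        """SEM used by the repeat rule; +inf when not estimable."""
        return math.inf if self.low_confidence else self.sem_cq


@dataclass(frozen=True)
class SampleDosage:
    """Per-animal dosage result and final call."""

    sample_id: str
    delta_cq: float
    ddcq: float
    sem_total: float
    call: SexCall
    reference_used: str  # "cluster_median" | "male_standard"
    flags: tuple[str, ...] = ()


@dataclass
class ClusterSplit:
    """Optimal 1-D two-cluster partition of dCq values."""

    high_ids: list[str]
    low_ids: list[str]
    gap: float            # distance between nearest members of opposite clusters
    median_distance: float
    within_ss: float
    unimodal: bool


@dataclass
class CohortResult:
    samples: list[SampleDosage]
    male_cluster_ids: list[str]
    female_cluster_ids: list[str]
    normalization_offset: float
    threshold: float
    reference_used: str
    cluster_gap: float | None = None
    cluster_median_distance: float | None = None
    unimodal_flag: bool = False
    excluded: dict[str, str] = field(default_factory=dict)
    log: list[str] = field(default_factory=list)

    @property
    def calls(self) -> dict[str, SexCall]:
        return {s.sample_id: s.call for s in self.samples}


@dataclass
class GenotypeConfig:
    """Tunable parameters of the genotyping pipeline.

    ``male_standard``: dCq value of a known-male reference sample; when set
    it replaces cluster-median normalisation (needed for batches without a
    male cluster, e.g. all-female groups).
    """

    outlier_threshold: float = OUTLIER_THRESHOLD_DEFAULT
    threshold: float = DDCQ_THRESHOLD_DEFAULT
    male_standard: float | None = None
    min_cluster_gap: float = MIN_CLUSTER_GAP_DEFAULT


def _clean(raw_cqs: Iterable[float | None]) -> list[float]:
    out = []
    for v in raw_cqs:
        if v is None:
            continue
        v = float(v)
        if math.isnan(v):
            continue
        out.append(v)
    return out


def summarize_replicates(
    raw_cqs: Sequence[float | None],
    outlier_threshold: float = OUTLIER_THRESHOLD_DEFAULT,
    sample_id: str = "",
    target_role: TargetRole = TargetRole.AUTOSOME,
) -> ReplicateGroup:
    """Screen a replicate group for outliers and summarise the survivors.

    Missing values (``None``/NaN, i.e. Undetermined wells) are dropped
    before screening.  The screen compares each value with the mean of all
    raw values; deviations strictly greater than ``outlier_threshold``
    cycles are discarded.  SEM is the sample standard deviation of the
    survivors over sqrt(n), 0 when only one value survives (the group is
    then flagged low-confidence and its SEM is treated as +inf by the
    repeat rule).
    """
    values = _clean(raw_cqs)
    if not values:
        raise NoUsableReplicatesError(
            f"no usable replicates for sample {sample_id!r} / "
            f"{TargetRole(target_role).value}"
        )
    screen_mean = float(np.mean(values))
    kept = [v for v in values if abs(v - screen_mean) <= outlier_threshold]
    n_discarded = len(values) - len(kept)
    if kept:
        mean_cq = float(np.mean(kept))
        sem_cq = (
            float(np.std(kept, ddof=1) / math.sqrt(len(kept)))
            if len(kept) >= 2
            else 0.0
        )
    else:  # pathological spread: everything deviates from the mean by >1
        mean_cq = math.nan
        sem_cq = math.nan
    return ReplicateGroup(
        sample_id=sample_id,
        target_role=TargetRole(target_role),
        raw_cqs=tuple(values),
        kept_cqs=tuple(kept),
        mean_cq=mean_cq,
        sem_cq=sem_cq,
        n_discarded=n_discarded,
    )


def compute_delta_cq(
    auto_group: ReplicateGroup, sex_group: ReplicateGroup
) -> tuple[float, float]:
    """dCq = mean Cq(autosome) - mean Cq(sex); SEM is the arithmetic sum.

    The summed SEM (not quadrature) is the per-animal precision figure used
    by the repeat rule.
    """
    if auto_group.sample_id != sex_group.sample_id:
        raise ValueError(
            f"sample id mismatch: {auto_group.sample_id!r} vs "
            f"{sex_group.sample_id!r}"
        )
    if math.isnan(auto_group.mean_cq) or math.isnan(sex_group.mean_cq):
        raise NoUsableReplicatesError(
            f"undefined replicate mean for sample {auto_group.sample_id!r}"
        )
    delta_cq = auto_group.mean_cq - sex_group.mean_cq
    sem_total = auto_group.sem_for_repeat_rule + sex_group.sem_for_repeat_rule
    return delta_cq, sem_total


def split_two_clusters(
    delta_cqs: Sequence[float],
    ids: Sequence[str] | None = None,
    min_gap: float = MIN_CLUSTER_GAP_DEFAULT,
) -> ClusterSplit:
    """Optimal 1-D two-cluster partition by exhaustive sorted-split search.

    The optimal two-means partition in one dimension is contiguous in
    sorted order, so scanning every split point of the sorted values finds
    the global minimum of the within-cluster sum of squares.  Ties between
    equal-SS splits are broken toward the larger inter-cluster gap.  The
    cluster with the greater median is labelled high (= male, carrying two
    Z copies and hence the greater dCq).  A gap below ``min_gap`` raises
    the unimodality flag: the split is then unreliable and a male standard
    should be used instead.
    """
    values = [float(v) for v in delta_cqs]
    n = len(values)
    if n < 2:
        raise ValueError("need at least 2 samples to split; use a male standard")
    if ids is None:
        ids = [str(i) for i in range(n)]
    if len(ids) != n:
        raise ValueError("ids and delta_cqs length mismatch")

    order = sorted(range(n), key=lambda i: values[i])
    xs = np.array([values[i] for i in order])
    # prefix sums for O(1) within-SS of any contiguous block
    c1 = np.concatenate([[0.0], np.cumsum(xs)])
    c2 = np.concatenate([[0.0], np.cumsum(xs * xs)])

    def block_ss(i: int, j: int) -> float:  # xs[i:j]
        m = j - i
        s = c1[j] - c1[i]
        return float(c2[j] - c2[i] - s * s / m)

    best = None  # (ss, -gap, k)
    for k in range(1, n):
        ss = block_ss(0, k) + block_ss(k, n)
        gap = float(xs[k] - xs[k - 1])
        key = (ss, -gap, k)
        if best is None or key < best:
            best = key
    _, neg_gap, k = best
    gap = -neg_gap
    low_idx = order[:k]
    high_idx = order[k:]
    low_vals = xs[:k]
    high_vals = xs[k:]
    median_distance = float(abs(np.median(high_vals) - np.median(low_vals)))
    return ClusterSplit(
        high_ids=[ids[i] for i in high_idx],
        low_ids=[ids[i] for i in low_idx],
        gap=gap,
        median_distance=median_distance,
        within_ss=best[0],
        unimodal=gap < min_gap,
    )


def normalize_ddcq(
    delta_cqs: Sequence[float], reference: float
) -> list[float]:
    """ddCq_i = dCq_i - reference (male cluster median or male standard)."""
    if not math.isfinite(reference):
        raise ValueError("normalisation reference must be finite")
    return [float(v) - float(reference) for v in delta_cqs]


def call_sex(
    ddcq: float,
    sem_total: float,
    threshold: float = DDCQ_THRESHOLD_DEFAULT,
) -> SexCall:
    """Classify one ddCq value against the male/female midpoint.

    Samples whose ddCq lies within one summed SEM of the threshold (or
    exactly on it) are insufficiently precise and flagged for repeat;
    otherwise greater than threshold is male (ZZ), less is female (Z0).
    """
    if not math.isfinite(ddcq):
        raise ValueError("ddcq must be finite")
    if sem_total < 0:
        raise ValueError("sem_total must be >= 0")
    if ddcq == threshold or abs(ddcq - threshold) < sem_total:
        return SexCall.REPEAT
    return SexCall.MALE if ddcq > threshold else SexCall.FEMALE


def genotype_cohort(
    measurements: Iterable[CqMeasurement],
    config: GenotypeConfig | None = None,
) -> CohortResult:
    """Run the full plate workflow: QC, dCq, clustering, ddCq, calls.

    Samples missing one of the two target roles, or whose replicates are
    entirely discarded by the outlier screen, are reported in
    ``result.excluded`` rather than silently dropped.  Samples with fewer
    than two surviving replicates on either target are auto-flagged repeat.
    When the clusters are too close to resolve (unimodality flag) and no
    male standard is configured, the run aborts with an instructive error.
    """
    config = config or GenotypeConfig()
    by_sample: dict[str, dict[TargetRole, list[float | None]]] = {}
    sample_order: list[str] = []
    for m in measurements:
        if m.sample_id not in by_sample:
            by_sample[m.sample_id] = {}
            sample_order.append(m.sample_id)
        by_sample[m.sample_id].setdefault(m.target_role, []).append(m.cq)

    log: list[str] = []
    excluded: dict[str, str] = {}
    deltas: dict[str, float] = {}
    sems: dict[str, float] = {}
    sample_flags: dict[str, list[str]] = {}

    for sid in sample_order:
        roles = by_sample[sid]
        missing = [r for r in (TargetRole.AUTOSOME, TargetRole.SEX) if r not in roles]
        if missing:
            excluded[sid] = "missing target role(s): " + ", ".join(
                r.value for r in missing
            )
            continue
        try:
            groups = {
                role: summarize_replicates(
                    roles[role],
                    outlier_threshold=config.outlier_threshold,
                    sample_id=sid,
                    target_role=role,
                )
                for role in (TargetRole.AUTOSOME, TargetRole.SEX)
            }
            delta, sem_total = compute_delta_cq(
                groups[TargetRole.AUTOSOME], groups[TargetRole.SEX]
            )
        except NoUsableReplicatesError as exc:
            excluded[sid] = str(exc)
            continue
        flags = []
        for role, g in groups.items():
            if g.low_confidence:
                flags.append(f"low-confidence:{role.value}")
            elif g.n_discarded >= 2:
                flags.append(f"low-replicate:{role.value}")
            if g.n_discarded:
                log.append(
                    f"{sid}/{role.value}: discarded {g.n_discarded} outlier(s)"
                )
        deltas[sid] = delta
        sems[sid] = sem_total
        sample_flags[sid] = flags

    if not deltas:
        raise NoUsableReplicatesError("no sample produced a usable dCq")

    ordered_ids = [s for s in sample_order if s in deltas]
    delta_list = [deltas[s] for s in ordered_ids]

    split: ClusterSplit | None = None
    if len(ordered_ids) >= 2:
        split = split_two_clusters(
            delta_list, ids=ordered_ids, min_gap=config.min_cluster_gap
        )

    if config.male_standard is not None:
        reference = float(config.male_standard)
        reference_used = "male_standard"
    else:
        if split is None:
            raise NoMaleReferenceError(
                "fewer than 2 samples: supply a male standard "
                "(GenotypeConfig.male_standard)"
            )
        if split.unimodal:
            raise NoMaleReferenceError(
                f"dCq values do not separate into two clusters "
                f"(gap {split.gap:.3g} < {config.min_cluster_gap}); the batch "
                "may be single-sex — re-run with a male standard "
                "(GenotypeConfig.male_standard)"
            )
        reference = float(np.median([deltas[s] for s in split.high_ids]))
        reference_used = "cluster_median"

    ddcqs = normalize_ddcq(delta_list, reference)

    samples: list[SampleDosage] = []
    for sid, ddcq in zip(ordered_ids, ddcqs):
        flags = list(sample_flags[sid])
        call = call_sex(ddcq, sems[sid], threshold=config.threshold)
        if any(f.startswith("low-confidence") for f in flags):
            call = SexCall.REPEAT
        if split is not None and not split.unimodal:
            in_male_cluster = sid in split.high_ids
            threshold_male = ddcq > config.threshold
            if call is not SexCall.REPEAT and in_male_cluster != threshold_male:
                flags.append("cluster-threshold-disagreement")
                log.append(
                    f"{sid}: cluster membership and threshold call disagree "
                    f"(ddcq {ddcq:.3f})"
                )
        samples.append(
            SampleDosage(
                sample_id=sid,
                delta_cq=deltas[sid],
                ddcq=ddcq,
                sem_total=sems[sid],
                call=call,
                reference_used=reference_used,
                flags=tuple(flags),
            )
        )

    for sid, reason in excluded.items():
        log.append(f"{sid}: excluded ({reason})")

    return CohortResult(
        samples=samples,
        male_cluster_ids=list(split.high_ids) if split else [],
        female_cluster_ids=list(split.low_ids) if split else [],
        normalization_offset=reference,
        threshold=config.threshold,
        reference_used=reference_used,
        cluster_gap=split.gap if split else None,
        cluster_median_distance=split.median_distance if split else None,
        unimodal_flag=split.unimodal if split else False,
        excluded=excluded,
        log=log,
    )
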