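"""Synthetic resting-state cohort generator.

Emulates 90-region resting-state cohorts (two groups, ~28-38 subjects each,
~238 retained volumes) with block-correlated, temporally autocorrelated
signals and an injected group difference in a chosen ROI subset.

Signal model per subject::

    roi_j(t) = sqrt(rho) * B_{block(j)}(t) + sqrt(1 - rho) * eps_j(t)

where every latent component (block signals ``B``, noise ``eps``, and the
patient coupling signal) is stationary AR(1)-filtered white noise with unit
marginal variance, so the expected within-block correlation is exactly
``rho``.  For patients, a shared signal scaled by ``effect_size`` is added
to the affected ROIs and to a designated target block, raising the coupling
between them; columns are z-scored afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import CohortDataset, ROITimeSeries

__all__ = ["SimulationConfig", "GroundTruth", "simulate_subject", "simulate_cohort"]


def _default_partition(n_rois: int, n_blocks: int = 6) -> list[list[int]]:
    idx = np.array_split(np.arange(n_rois), n_blocks)
    return [list(map(int, b)) for b in idx if len(b)]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror a two-group resting-state study: 28 controls vs 38
    patients, 90 regions, 238 retained volumes, moderate within-block
    correlation and temporal autocorrelation.
    """

    n_control: int = 28
    n_patient: int = 38
    n_rois: int = 90
    n_timepoints: int = 238
    block_partition: list[list[int]] | None = None
    within_block_corr: float = 0.4
    ar_coefficient: float = 0.3
    affected_rois: list[int] = field(default_factory=lambda: [0, 1, 2, 3])
    effect_size: float = 0.8
    seed: int = 0
    tr_seconds: float = 2.0

    def __post_init__(self) -> None:
        if self.block_partition is None:
            self.block_partition = _default_partition(self.n_rois)
        flat = sorted(j for b in self.block_partition for j in b)
        if flat != list(range(self.n_rois)):
            raise ValueError("block_partition must be disjoint and cover all ROIs exactly once")
        if not set(self.affected_rois) <= set(range(self.n_rois)):
            raise ValueError("affected_rois must be a subset of ROI indices")
        if self.n_timepoints < 20:
            raise ValueError("n_timepoints must be >= 20")
        if not (0 <= self.within_block_corr < 1):
            raise ValueError("within_block_corr must lie in [0, 1)")
        if not (-1 < self.ar_coefficient < 1):
            raise ValueError("ar_coefficient must lie in (-1, 1)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be nonnegative")

    @property
    def block_of(self) -> np.ndarray:
        out = np.empty(self.n_rois, dtype=int)
        for b, members in enumerate(self.block_partition):
            out[members] = b
        return out

    def target_block(self) -> int:
        """Block receiving the patient coupling signal: the last block with
        no affected ROI (falls back to the last block)."""
        affected = set(self.affected_rois)
        for b in range(len(self.block_partition) - 1, -1, -1):
            if not affected & set(self.block_partition[b]):
                return b
        return len(self.block_partition) - 1


@dataclass
class GroundTruth:
    """Injected structure of a simulated cohort."""

    block_partition: list[list[int]]
    affected_rois: list[int]
    target_block: int
    corr_control: np.ndarray
    corr_patient: np.ndarray


def _target_correlations(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    rho = config.within_block_corr
    block = config.block_of
    same_block = block[:, None] == block[None, :]
    base = np.where(same_block, rho, 0.0)
    np.fill_diagonal(base, 1.0)

    e2 = config.effect_size**2
    coupled = np.zeros(config.n_rois, dtype=bool)
    coupled[config.affected_rois] = True
    coupled[config.block_partition[config.target_block()]] = True
    var = np.where(coupled, 1.0 + e2, 1.0)
    cov = base.copy()
    both = coupled[:, None] & coupled[None, :]
    cov = cov + np.where(both, e2, 0.0)
    np.fill_diagonal(cov, var)
    d = np.sqrt(var)
    corr_pat = cov / np.outer(d, d)
    return base, corr_pat


def _ar1(rng: np.random.Generator, t: int, n: int, phi: float) -> np.ndarray:
    """n independent stationary AR(1) series of length t, unit marginal variance."""
    x = np.empty((t, n))
    innov_sd = np.sqrt(1.0 - phi**2)
    x[0] = rng.standard_normal(n)
    eps = rng.standard_normal((t - 1, n)) * innov_sd
    for i in range(1, t):
        x[i] = phi * x[i - 1] + eps[i - 1]
    return x


def simulate_subject(
    config: SimulationConfig, group: str, subject_seed: int
) -> ROITimeSeries:
    """One subject's T x R time-series matrix; deterministic given the seed."""
    if group not in ("control", "patient"):
        raise ValueError(f"group must be 'control' or 'patient', got {group!r}")
    rng = np.random.default_rng(np.random.SeedSequence(subject_seed))
    t, r = config.n_timepoints, config.n_rois
    phi = config.ar_coefficient
    n_blocks = len(config.block_partition)

    blocks = _ar1(rng, t, n_blocks, phi)
    noise = _ar1(rng, t, r, phi)
    shared = _ar1(rng, t, 1, phi)[:, 0]  # drawn for both groups: same stream layout

    rho = config.within_block_corr
    data = np.sqrt(rho) * blocks[:, config.block_of] + np.sqrt(1.0 - rho) * noise
    if group == "patient" and config.effect_size > 0:
        coupled = sorted(
            set(config.affected_rois)
            | set(config.block_partition[config.target_block()])
        )
        data[:, coupled] += config.effect_size * shared[:, None]
    # z-score columns: downstream sparse regression assumes standardized input
    data = (data - data.mean(axis=0)) / data.std(axis=0, ddof=1)
    sid = f"{'sub' if group == 'control' else 'pat'}-{subject_seed}"
    return ROITimeSeries(sid, data, [f"ROI{j + 1}" for j in range(r)], config.tr_seconds)


def simulate_cohort(config: SimulationConfig) -> tuple[CohortDataset, GroundTruth]:
    """Simulate the full two-group cohort with per-subject derived seeds."""
    if config.n_control == 0 or config.n_patient == 0:
        raise ValueError("both groups must have at least one subject")
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_control + config.n_patient)
    subjects, labels = [], []
    for i, child in enumerate(children):
        group = "control" if i < config.n_control else "patient"
        sub_seed = int(child.generate_state(1, dtype=np.uint32)[0] >> 1)
        ts = simulate_subject(config, group, sub_seed)
        ts.subject_id = f"{'con' if group == 'control' else 'pat'}{i:03d}"
        subjects.append(ts)
        labels.append(group)
    corr_con, corr_pat = _target_correlations(config)
    truth = GroundTruth(
        block_partition=[list(b) for b in config.block_partition],
        affected_rois=list(config.affected_rois),
        target_block=config.target_block(),
        corr_control=corr_con,
        corr_patient=corr_pat,
    )
    return CohortDataset(subjects=subjects, labels=labels), truth
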