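"""Synthetic rating panels and screening operating characteristics.

The generator emulates the data regime the validation procedure assumes: a
small panel (default 10 experts, 30 items, 1-5 scale) in high agreement,
with optional injected discordant experts. Each rating is a latent item
relevance ``mu_j`` perturbed by symmetric continuous noise, rounded to the
nearest integer and clamped to the scale:

    r_ij = clamp(round(mu_j + eps_ij)),   eps_ij ~ Normal(0, sigma)

A deviant expert answers deviantly on each item independently with
probability ``p_dev``; a deviant answer replaces the rating by
``clamp(round(mu_j - delta))`` — a low-ball offset, mirroring how real
discordant judges under-score a high-consensus item.

Draws are ordered so that, for a fixed seed, raising ``p_dev`` only adds
deviant cells and raising ``delta`` only moves deviant ratings further
down. This common-random-numbers coupling makes the screening rule's
sensitivity pathwise monotone in both parameters, which the test suite
exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .data import LikertScale, RatingMatrix
from .screening import DeviancePolicy, screen_experts
from .aiken import aiken_v

__all__ = [
    "SimulationConfig",
    "SimulatedPanel",
    "OperatingCharacteristics",
    "simulate_panel",
    "screening_operating_characteristics",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for one synthetic panel.

    Parameters
    ----------
    n_experts, n_items : int
        Panel shape; defaults (10, 30) match the reference study design.
    scale : LikertScale
    mu : sequence of float, or (lo, hi) range
        Latent per-item relevance. A length-``n_items`` sequence is used
        as-is; a 2-tuple draws each ``mu_j`` uniformly from [lo, hi].
        Default (4.0, 5.0): a high-agreement questionnaire.
    sigma : float
        SD of the latent rater perturbation, in rating points. Default 0.5,
        which keeps most ratings within one point of consensus.
    n_deviant_experts : int
        Experts whose answers are contaminated (the first rows after a
        seeded shuffle of expert identities).
    delta : float
        Points subtracted from ``mu_j`` on a deviant answer. Default 3, the
        screening rule's own deviance distance.
    p_dev : float
        Per-item probability that a deviant expert answers deviantly.
    seed : int
        Seed for the generator; identical configs give identical panels.
    """

    n_experts: int = 10
    n_items: int = 30
    scale: LikertScale = field(default_factory=LikertScale)
    mu: Sequence[float] | tuple[float, float] = (4.0, 5.0)
    sigma: float = 0.5
    n_deviant_experts: int = 0
    delta: float = 3.0
    p_dev: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_experts < 1 or self.n_items < 1:
            raise ValueError("panel must have at least 1 expert and 1 item")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if not 0 <= self.p_dev <= 1:
            raise ValueError("p_dev must lie in [0, 1]")
        if not 0 <= self.n_deviant_experts <= self.n_experts:
            raise ValueError("n_deviant_experts must lie in [0, n_experts]")
        if self.delta <= 0:
            raise ValueError("delta must be positive")


@dataclass(frozen=True)
class SimulatedPanel:
    """A generated panel plus the ground truth needed to score recovery."""

    matrix: RatingMatrix
    true_deviants: tuple[str, ...]
    realized_deviant_cells: tuple[tuple[str, str], ...]
    clean_matrix: RatingMatrix


def _resolve_mu(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    mu = config.mu
    if isinstance(mu, tuple) and len(mu) == 2 and all(np.isscalar(v) for v in mu):
        lo, hi = float(mu[0]), float(mu[1])
        if hi < lo:
            raise ValueError("mu range must have lo <= hi")
        return rng.uniform(lo, hi, size=config.n_items)
    arr = np.asarray(mu, dtype=float)
    if arr.shape != (config.n_items,):
        raise ValueError(f"mu must have length n_items={config.n_items}")
    return arr


def simulate_panel(config: SimulationConfig) -> SimulatedPanel:
    """Generate one panel; deterministic given ``config.seed``.

    Draw order (mu, noise, deviant identities, deviance mask) is part of
    the contract: it keeps panels comparable across ``delta``/``p_dev``
    under a common seed.
    """
    rng = np.random.default_rng(config.seed)
    scale = config.scale
    mu = _resolve_mu(config, rng)
    eps = (
        rng.normal(0.0, config.sigma, size=(config.n_experts, config.n_items))
        if config.sigma > 0
        else np.zeros((config.n_experts, config.n_items))
    )
    base = np.clip(np.rint(mu[None, :] + eps), scale.lowest, scale.highest).astype(np.int64)

    expert_ids = [f"E{i+1}" for i in range(config.n_experts)]
    item_ids = [str(j + 1) for j in range(config.n_items)]
    deviant_rows = rng.choice(config.n_experts, size=config.n_deviant_experts, replace=False)
    mask_u = rng.uniform(size=(config.n_deviant_experts, config.n_items))

    ratings = base.copy()
    realized: list[tuple[str, str]] = []
    deviant_value = np.clip(np.rint(mu - config.delta), scale.lowest, scale.highest).astype(np.int64)
    for d, row in enumerate(deviant_rows):
        hit = mask_u[d] < config.p_dev
        ratings[row, hit] = deviant_value[hit]
        realized.extend((expert_ids[row], item_ids[j]) for j in np.flatnonzero(hit))

    matrix = RatingMatrix("simulated", scale, expert_ids, item_ids, ratings)
    clean = RatingMatrix("simulated-clean", scale, expert_ids, item_ids, base)
    return SimulatedPanel(
        matrix=matrix,
        true_deviants=tuple(expert_ids[i] for i in sorted(deviant_rows)),
        realized_deviant_cells=tuple(realized),
        clean_matrix=clean,
    )


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Monte-Carlo estimates of the screening rule's behaviour."""

    replicates: int
    sensitivity: float
    specificity: float
    mean_V_bias: float


def screening_operating_characteristics(
    config: SimulationConfig,
    policy: DeviancePolicy | None = None,
    replicates: int = 500,
) -> OperatingCharacteristics:
    """Estimate sensitivity/specificity of the exclusion rule by simulation.

    Replicate ``r`` uses seed ``config.seed + r`` (a fixed-increment master
    seed scheme, so growing ``replicates`` never perturbs earlier draws).
    Sensitivity is the fraction of injected deviant experts excluded;
    specificity the fraction of clean experts retained; ``mean_V_bias`` the
    mean over items and replicates of V(screened final panel) minus V(clean
    panel without injected deviance).
    """
    if replicates < 1:
        raise ValueError("need at least one replicate")
    policy = policy or DeviancePolicy()
    dev_total = dev_caught = 0
    clean_total = clean_kept = 0
    bias_sum = 0.0
    bias_n = 0
    for r in range(replicates):
        panel = simulate_panel(replace(config, seed=config.seed + r))
        result = screen_experts(panel.matrix, panel.matrix.expert_ids, policy)
        excluded = set(result.excluded_experts)
        deviants = set(panel.true_deviants)
        dev_total += len(deviants)
        dev_caught += len(deviants & excluded)
        clean = set(panel.matrix.expert_ids) - deviants
        clean_total += len(clean)
        clean_kept += len(clean - excluded)
        retained = [e for e in panel.matrix.expert_ids if e not in excluded]
        for item in panel.matrix.item_ids:
            _, v_screened, _ = aiken_v(
                panel.matrix.item_ratings(item, retained), config.scale
            )
            _, v_clean, _ = aiken_v(panel.clean_matrix.item_ratings(item), config.scale)
            bias_sum += v_screened - v_clean
            bias_n += 1
    return OperatingCharacteristics(
        replicates=replicates,
        sensitivity=dev_caught / dev_total if dev_total else float("nan"),
        specificity=clean_kept / clean_total if clean_total else float("nan"),
        mean_V_bias=bias_sum / bias_n,
    )
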