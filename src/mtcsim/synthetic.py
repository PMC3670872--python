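"""Synthetic trial-network skeletons emulating a published antidepressant network.

The defaults reproduce the summary structure of the 12-treatment
antidepressant evidence base that motivates this package: 117 randomized
trials contributing 236 treatment arms and 25,928 participants in total.
The trial-level table behind those summaries was never published, so the
generator emulates it: exact conservation of the trial/arm/participant
totals, guaranteed connectivity of the comparison graph (via a random
spanning tree over treatments), and uniform assignment of the remaining
trials to treatment pairs unless a degree-weighted attachment exponent is
requested.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml

from .network import Arm, Trial, TrialNetwork

__all__ = [
    "GeneratorConfig",
    "ConfigError",
    "generate_skeleton",
    "allocate_sample_sizes",
    "config_from_file",
]


class ConfigError(ValueError):
    """A generator configuration violates its invariants."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the skeleton generator.

    Defaults are the published summary counts of the emulated network.
    ``dispersion`` controls the coefficient-of-variation-like spread of
    arm sample sizes around the mean (0 gives a maximally even split);
    ``attachment_exponent`` = 0 assigns non-tree trials uniformly over
    treatment pairs, > 0 weights treatments by degree**exponent
    (preferential attachment) for denser hubs.
    """

    n_treatments: int = 12
    n_trials: int = 117
    n_arms_total: int = 236
    n_participants_total: int = 25_928
    seed: int = 0
    dispersion: float = 0.25
    attachment_exponent: float = 0.0
    treatment_labels: Optional[tuple[str, ...]] = None

    def validate(self) -> None:
        if self.n_treatments < 2:
            raise ConfigError("need at least 2 treatments")
        if self.n_trials < 1:
            raise ConfigError("need at least 1 trial")
        if self.n_arms_total < 2 * self.n_trials:
            raise ConfigError("n_arms_total must be >= 2 per trial")
        if self.n_arms_total - 2 * self.n_trials > self.n_trials:
            raise ConfigError(
                "surplus arms exceed the trial count: only third arms are laid,"
                " so n_arms_total <= 3 * n_trials is required"
            )
        if self.n_participants_total < self.n_arms_total:
            raise ConfigError("need at least 1 participant per arm")
        if self.n_trials < self.n_treatments - 1:
            raise ConfigError(
                "cannot connect the comparison graph:"
                " n_trials must be >= n_treatments - 1"
            )
        if self.dispersion < 0:
            raise ConfigError("dispersion must be non-negative")
        if self.treatment_labels is not None and len(self.treatment_labels) != self.n_treatments:
            raise ConfigError("treatment_labels length must equal n_treatments")

    @property
    def labels(self) -> list[str]:
        if self.treatment_labels is not None:
            return list(self.treatment_labels)
        width = max(2, len(str(self.n_treatments)))
        return [f"T{i + 1:0{width}d}" for i in range(self.n_treatments)]


def allocate_sample_sizes(
    n_arms: int,
    total: int,
    seed=None,
    dispersion: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Split ``total`` participants over ``n_arms`` arms, conserving the sum.

    ``dispersion=0`` gives the most even split (sizes differ by at most 1;
    which arms get the extra unit is randomized).  ``dispersion>0`` draws a
    symmetric gamma weight vector with coefficient of variation equal to
    ``dispersion``, apportions ``total - n_arms`` proportionally (one
    participant per arm is reserved so every size is positive) and repairs
    the rounding by a largest-remainder pass so the sum is exact.
    """
    if total < n_arms:
        raise ValueError(f"total {total} < n_arms {n_arms}")
    if rng is None:
        rng = np.random.default_rng(seed)
    if dispersion == 0:
        base, rem = divmod(total, n_arms)
        sizes = np.full(n_arms, base, dtype=np.int64)
        if rem:
            sizes[rng.choice(n_arms, size=rem, replace=False)] += 1
        return sizes
    shape = 1.0 / dispersion**2
    w = rng.gamma(shape, 1.0, size=n_arms)
    raw = w / w.sum() * (total - n_arms)
    sizes = 1 + np.floor(raw).astype(np.int64)
    deficit = total - int(sizes.sum())
    if deficit:
        order = np.argsort(-(raw - np.floor(raw)), kind="stable")
        sizes[order[:deficit]] += 1
    return sizes


def _random_spanning_tree(k: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    # random recursive tree over a random node permutation: connected by design
    order = rng.permutation(k)
    return [
        (int(order[int(rng.integers(0, i))]), int(order[i]))
        for i in range(1, k)
    ]


def generate_skeleton(cfg: GeneratorConfig) -> TrialNetwork:
    """Generate a connected skeleton network matching ``cfg`` exactly.

    Deterministic given ``cfg.seed``.  The first ``n_treatments - 1``
    comparisons realize a random spanning tree (guaranteeing connectivity);
    remaining trials draw treatment pairs uniformly (or degree-weighted).
    Surplus arms beyond two per trial are placed as third arms on randomly
    chosen trials.  Responders are left unset.
    """
    cfg.validate()
    labels = cfg.labels
    k = cfg.n_treatments
    rng_topo = np.random.default_rng([cfg.seed, 0])
    rng_sizes = np.random.default_rng([cfg.seed, 1])

    pairs: list[tuple[int, int]] = list(_random_spanning_tree(k, rng_topo))
    degree = np.zeros(k, dtype=float)
    for a, b in pairs:
        degree[a] += 1
        degree[b] += 1
    for _ in range(cfg.n_trials - len(pairs)):
        if cfg.attachment_exponent > 0:
            w = (degree + 1.0) ** cfg.attachment_exponent
            a = int(rng_topo.choice(k, p=w / w.sum()))
            w2 = w.copy()
            w2[a] = 0.0
            b = int(rng_topo.choice(k, p=w2 / w2.sum()))
        else:
            a, b = (int(x) for x in rng_topo.choice(k, size=2, replace=False))
        pairs.append((a, b))
        degree[a] += 1
        degree[b] += 1

    # arm multiplicity: surplus arms realized as third arms
    n_extra = cfg.n_arms_total - 2 * cfg.n_trials
    trial_arms: list[list[int]] = [list(p) for p in pairs]
    if n_extra:
        chosen = rng_topo.choice(cfg.n_trials, size=n_extra, replace=False)
        for idx in chosen:
            present = set(trial_arms[idx])
            others = [t for t in range(k) if t not in present]
            trial_arms[idx].append(int(rng_topo.choice(others)))

    # shuffle trial order so tree trials are not clustered at the front
    perm = rng_topo.permutation(cfg.n_trials)
    trial_arms = [trial_arms[i] for i in perm]

    sizes = allocate_sample_sizes(
        cfg.n_arms_total, cfg.n_participants_total, dispersion=cfg.dispersion, rng=rng_sizes
    )
    width = max(3, len(str(cfg.n_trials)))
    trials: list[Trial] = []
    pos = 0
    for i, arm_trts in enumerate(trial_arms):
        arms = [
            Arm(treatment=labels[t], n=int(sizes[pos + j]))
            for j, t in enumerate(arm_trts)
        ]
        pos += len(arm_trts)
        trials.append(Trial(id=f"S{i + 1:0{width}d}", arms=arms))
    return TrialNetwork(trials=trials, treatments=labels)


def config_from_file(path: Union[str, Path]) -> GeneratorConfig:
    """Load a GeneratorConfig from YAML or JSON with matching keys."""
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping of config keys")
    if "treatment_labels" in data and data["treatment_labels"] is not None:
        data["treatment_labels"] = tuple(data["treatment_labels"])
    try:
        cfg = GeneratorConfig(**data)
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    cfg.validate()
    return cfg
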