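"""Fill trial-network skeletons with randomized binary responses.

Under the null model every participant responds with the same probability
regardless of arm (default 0.57, the overall response rate of the emulated
antidepressant network).  Alternatives are expressed as per-treatment
log-odds shifts, used by the parameter-recovery and calibration tests.

Responses are drawn as one binomial count per arm rather than as
individual Bernoulli draws — distributionally identical and far cheaper.
Replications use counter-based substreams, so replication ``i`` is
reproducible in isolation and results do not depend on evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
from scipy.special import expit, logit

from .network import Arm, Trial, TrialNetwork

__all__ = ["ResponseModel", "simulate_responses", "replicate_null", "replication_rng"]


@dataclass(frozen=True)
class ResponseModel:
    """Per-participant response model on the logit scale.

    ``P(response) = expit(logit(baseline_p) + effects[treatment])``;
    with all effects zero (the null) this is ``baseline_p`` in every arm.
    """

    baseline_p: float = 0.57
    effects: Mapping[str, float] = field(default_factory=dict)

    def response_probability(self, treatment: str) -> float:
        if not 0.0 <= self.baseline_p <= 1.0:
            raise ValueError(f"baseline_p {self.baseline_p} outside [0, 1]")
        eff = self.effects.get(treatment, 0.0)
        if eff == 0.0:
            return float(self.baseline_p)
        if self.baseline_p in (0.0, 1.0):
            return float(self.baseline_p)  # degenerate baseline dominates any shift
        return float(expit(logit(self.baseline_p) + eff))


def simulate_responses(
    skeleton: TrialNetwork,
    model: ResponseModel = ResponseModel(),
    seed=None,
    rng: np.random.Generator | None = None,
) -> TrialNetwork:
    """Return a copy of ``skeleton`` with responder counts drawn per arm.

    Refuses to overwrite: raises ``ValueError`` if any arm already has a
    responder count.  Raises ``KeyError`` if the model shifts a treatment
    the network does not contain.  Deterministic given ``seed``.
    """
    if skeleton.any_responses:
        raise ValueError(
            "skeleton already carries responder counts; refusing to overwrite"
        )
    unknown = set(model.effects) - set(skeleton.treatments)
    if unknown:
        raise KeyError(f"effects reference treatments not in the network: {sorted(unknown)}")
    if rng is None:
        rng = np.random.default_rng(seed)
    trials = []
    for trial in skeleton.trials:
        arms = [
            Arm(
                treatment=a.treatment,
                n=a.n,
                r=int(rng.binomial(a.n, model.response_probability(a.treatment))),
            )
            for a in trial.arms
        ]
        trials.append(Trial(id=trial.id, arms=arms))
    return TrialNetwork(trials=trials, treatments=list(skeleton.treatments))


def replication_rng(master_seed: int, index: int) -> np.random.Generator:
    """Independent substream for replication ``index`` of ``master_seed``."""
    return np.random.default_rng([int(master_seed), int(index)])


def replicate_null(
    skeleton: TrialNetwork,
    model: ResponseModel,
    n_reps: int,
    master_seed: int,
    write_dir=None,
) -> Iterator[TrialNetwork]:
    """Yield ``n_reps`` independently filled copies of ``skeleton``.

    Replication ``i`` uses the substream ``(master_seed, i)``, so it can be
    regenerated in isolation and the stream is order-independent.  When
    ``write_dir`` is given each replication is also written there as
    arm-level CSV (``rep_00000.csv``, ...).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if write_dir is not None:
        from pathlib import Path

        from .network import write_network

        write_dir = Path(write_dir)
        write_dir.mkdir(parents=True, exist_ok=True)
    for i in range(n_reps):
        filled = simulate_responses(skeleton, model, rng=replication_rng(master_seed, i))
        if write_dir is not None:
            write_network(filled, write_dir / f"rep_{i:05d}.csv")
        yield filled
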