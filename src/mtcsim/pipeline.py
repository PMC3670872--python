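"""Monte Carlo family-wise error experiment over null trial networks.

One skeleton network is generated once and reused across replications
(fixed design, random responses).  Each replication fills the skeleton
under the null response model, fits the Bayesian MTC model, flags the
pairwise contrasts whose 95% interval excludes OR = 1, and records the
count ``x`` of significant contrasts.  The summary holds the empirical
distribution P(X = x) = f(x) / n_reps, the family-wise rate
P(X >= 1), the expectation E[X], and the independent-binomial reference
``m * alpha`` for comparison.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy.stats import norm

from .engine import (
    MCMCConfig,
    MTCModelSpec,
    contrast_estimates,
    contrast_table,
    convergence_diagnostics,
    fit_mtc,
)
from .network import TrialNetwork
from .simulate import ResponseModel, replication_rng, simulate_responses
from .synthetic import GeneratorConfig, generate_skeleton

__all__ = [
    "SimulationConfig",
    "SimulationSummary",
    "BinomialReference",
    "count_significant",
    "binomial_reference",
    "bonferroni_threshold",
    "run_experiment",
    "recount_significant",
    "distribution_table",
    "plot_distribution",
    "save_summary",
    "load_simulation_config",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to reproduce one Monte Carlo experiment."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    response: ResponseModel = field(default_factory=ResponseModel)
    model: MTCModelSpec = field(default_factory=MTCModelSpec)
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    n_reps: int = 1000
    alpha: float = 0.05
    rule: str = "normal"
    master_seed: int = 0
    n_workers: int = 1
    regenerate_skeleton: bool = False

    def validate(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.rule not in ("normal", "credible"):
            raise ValueError(f"unknown rule {self.rule!r}")
        self.generator.validate()


@dataclass(frozen=True)
class BinomialReference:
    """What m independent tests at level p would give."""

    expected: float  # m * p
    p_any: float  # 1 - (1 - p)^m


def binomial_reference(m: int, p: float) -> BinomialReference:
    """Independent-tests reference: E[X] = m*p, P(X>=1) = 1 - (1-p)^m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie in (0, 1)")
    return BinomialReference(expected=m * p, p_any=1.0 - (1.0 - p) ** m)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-comparison level alpha/m bounding the family-wise rate by alpha."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def count_significant(contrasts) -> int:
    """Number of contrasts flagged significant in a contrast list/table."""
    if isinstance(contrasts, pd.DataFrame):
        return int(contrasts["significant"].sum())
    return sum(1 for c in contrasts if c.significant)


@dataclass
class SimulationSummary:
    """Results of :func:`run_experiment`.

    ``counts[j]`` is the number of significant contrasts in completed
    replication ``rep_ids[j]``; ``log_or_mean``/``log_or_sd`` cache the
    posterior summaries of every contrast so significance can be recounted
    at other alpha levels without refitting.
    """

    pairs: list[tuple[str, str]]
    counts: np.ndarray
    rep_ids: list[int]
    failed_reps: list[int]
    log_or_mean: np.ndarray  # (n_completed, m)
    log_or_sd: np.ndarray
    alpha: float
    rule: str
    n_reps_requested: int
    max_psrf: np.ndarray = field(default_factory=lambda: np.array([]))

    # -- derived statistics ------------------------------------------------
    @property
    def m(self) -> int:
        return len(self.pairs)

    @property
    def n_completed(self) -> int:
        return len(self.counts)

    @property
    def frequencies(self) -> np.ndarray:
        """f(x) for x = 0..max observed."""
        return np.bincount(self.counts)

    @property
    def probabilities(self) -> np.ndarray:
        """P(X = x) = f(x) / n_completed."""
        return self.frequencies / self.n_completed

    @property
    def p_any(self) -> float:
        """Family-wise rate P(X >= 1)."""
        return float(np.mean(self.counts >= 1))

    @property
    def expectation(self) -> float:
        """E[X], the mean significant-contrast count per replication."""
        return float(np.mean(self.counts))

    @property
    def binomial(self) -> BinomialReference:
        return binomial_reference(self.m, self.alpha)

    @property
    def per_contrast_frequency(self) -> pd.Series:
        """Fraction of replications in which each contrast was significant."""
        sig = self._significance(self.alpha)
        labels = [f"{a}:{b}" for a, b in self.pairs]
        return pd.Series(sig.mean(axis=0), index=labels)

    def _significance(self, alpha: float) -> np.ndarray:
        z = norm.ppf(1.0 - alpha / 2.0)
        return np.abs(self.log_or_mean) > z * self.log_or_sd


def recount_significant(summary: SimulationSummary, alpha: float) -> np.ndarray:
    """Per-replication significant counts at another alpha, from the cached
    posterior means/SDs (normal-approximation rule)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    return summary._significance(alpha).sum(axis=1).astype(int)


def distribution_table(
    summary: SimulationSummary, truncate: Optional[int] = None
) -> pd.DataFrame:
    """Rows (x, f(x), P(X=x)) for x = 0..max observed (or ``truncate``)."""
    f = summary.frequencies
    if truncate is not None:
        f = f[: truncate + 1]
    return pd.DataFrame(
        {"x": np.arange(len(f)), "f": f, "p": f / summary.n_completed}
    )


def plot_distribution(summary: SimulationSummary, ax=None, truncate: Optional[int] = None):
    """Histogram of P(X = x) — the probability of x significant contrasts."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    tab = distribution_table(summary, truncate=truncate)
    ax.bar(tab["x"], tab["p"], color="0.4")
    ax.set_xlabel("number of significant contrasts")
    ax.set_ylabel("probability")
    return ax


def _child_seed(*parts: int) -> int:
    return int(
        np.random.SeedSequence(list(parts)).generate_state(1, dtype=np.uint32)[0]
        % (2**31)
    )


def _one_replication(
    i: int,
    skeleton: TrialNetwork,
    cfg: SimulationConfig,
    out_dir: Optional[Path],
):
    """Fit one replication; returns (i, mean, sd, significant, max_psrf, failed, secs)."""
    t0 = time.perf_counter()
    rep_path = None
    if out_dir is not None:
        rep_path = out_dir / "contrasts" / f"rep_{i:05d}.csv"
        if rep_path.exists():  # checkpoint: reuse the cached contrast table
            tab = pd.read_csv(rep_path)
            return (
                i,
                tab["logOR_mean"].to_numpy(),
                tab["logOR_sd"].to_numpy(),
                tab["significant"].to_numpy(bool),
                np.nan,
                False,
                0.0,
            )
    if cfg.regenerate_skeleton:
        skeleton = generate_skeleton(
            replace(cfg.generator, seed=_child_seed(cfg.master_seed, i, 3))
        )
    filled = simulate_responses(
        skeleton, cfg.response, rng=replication_rng(cfg.master_seed, i)
    )
    mcmc = replace(cfg.mcmc, seed=[cfg.master_seed, i, 2])
    post = fit_mtc(filled, cfg.model, mcmc)
    max_psrf = np.nan
    failed = False
    if cfg.mcmc.chains >= 2:
        diag = convergence_diagnostics(post)
        max_psrf = diag.max_psrf
        if diag.flagged:  # one retry with doubled iterations
            longer = replace(
                mcmc, burn_in=2 * mcmc.burn_in, draws=2 * mcmc.draws,
                seed=[cfg.master_seed, i, 4],
            )
            post = fit_mtc(filled, cfg.model, longer)
            diag = convergence_diagnostics(post)
            max_psrf = diag.max_psrf
            failed = diag.flagged
    contrasts = contrast_estimates(post, alpha=cfg.alpha, rule=cfg.rule)
    tab = contrast_table(contrasts)
    if rep_path is not None and not failed:
        rep_path.parent.mkdir(parents=True, exist_ok=True)
        tab.to_csv(rep_path, index=False)
    return (
        i,
        tab["logOR_mean"].to_numpy(),
        tab["logOR_sd"].to_numpy(),
        tab["significant"].to_numpy(bool),
        max_psrf,
        failed,
        time.perf_counter() - t0,
    )


def run_experiment(
    cfg: SimulationConfig,
    out_dir: Union[str, Path, None] = None,
    progress: bool = False,
) -> SimulationSummary:
    """Run the full null-hypothesis Monte Carlo experiment.

    The skeleton is generated once from ``cfg.generator`` and reused; each
    replication draws responses and an MCMC seed from independent
    substreams of ``cfg.master_seed``, so the summary is reproducible and
    independent of both replication order and worker count.  Replications
    whose PSRF stays above 1.05 after one doubled-length retry are excluded
    from all denominators and listed in ``failed_reps``.  When ``out_dir``
    is given, per-replication contrast tables are checkpointed there and
    reloaded on resume.
    """
    cfg.validate()
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    skeleton = generate_skeleton(cfg.generator)
    k = len(skeleton.treatments)
    pairs = [
        (skeleton.treatments[i], skeleton.treatments[j])
        for i in range(k)
        for j in range(i + 1, k)
    ]

    indices = list(range(cfg.n_reps))
    if cfg.n_workers > 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=cfg.n_workers)(
            delayed(_one_replication)(i, skeleton, cfg, out_path) for i in indices
        )
    else:
        results = []
        for i in indices:
            results.append(_one_replication(i, skeleton, cfg, out_path))
            if progress:
                r = results[-1]
                print(
                    f"rep {i + 1}/{cfg.n_reps}: x={int(r[3].sum())}"
                    f" psrf={r[4]:.3f} ({r[6]:.1f}s)",
                    flush=True,
                )

    results.sort(key=lambda r: r[0])
    completed = [r for r in results if not r[5]]
    failed = [r[0] for r in results if r[5]]
    if failed:
        warnings.warn(
            f"{len(failed)} replication(s) failed convergence after retry and were"
            f" excluded: {failed}"
        )
    summary = SimulationSummary(
        pairs=pairs,
        counts=np.array([int(r[3].sum()) for r in completed], dtype=int),
        rep_ids=[r[0] for r in completed],
        failed_reps=failed,
        log_or_mean=np.vstack([r[1] for r in completed]),
        log_or_sd=np.vstack([r[2] for r in completed]),
        alpha=cfg.alpha,
        rule=cfg.rule,
        n_reps_requested=cfg.n_reps,
        max_psrf=np.array([r[4] for r in completed]),
    )
    if out_path is not None:
        runlog = pd.DataFrame(
            {
                "rep": [r[0] for r in results],
                "n_significant": [int(r[3].sum()) for r in results],
                "max_psrf": [r[4] for r in results],
                "failed": [r[5] for r in results],
                "seconds": [r[6] for r in results],
            }
        )
        runlog.to_csv(out_path / "runlog.csv", index=False)
        distribution_table(summary).to_csv(out_path / "distribution.csv", index=False)
        save_summary(summary, out_path / "summary.json")
    return summary


def save_summary(summary: SimulationSummary, path: Union[str, Path]) -> None:
    ref = summary.binomial
    payload = {
        "n_reps_requested": summary.n_reps_requested,
        "n_completed": summary.n_completed,
        "failed_reps": summary.failed_reps,
        "m_comparisons": summary.m,
        "alpha": summary.alpha,
        "rule": summary.rule,
        "p_any": summary.p_any,
        "expectation": summary.expectation,
        "binomial_expected": ref.expected,
        "binomial_p_any": ref.p_any,
        "frequencies": summary.frequencies.tolist(),
        "counts": summary.counts.tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_simulation_config(path: Union[str, Path]) -> SimulationConfig:
    """Build a SimulationConfig from a YAML/JSON file with nested sections
    ``generator``, ``response``, ``model``, ``mcmc`` plus top-level keys."""
    import yaml

    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping")
    kwargs = dict(data)
    if "generator" in kwargs:
        g = dict(kwargs["generator"])
        if g.get("treatment_labels") is not None:
            g["treatment_labels"] = tuple(g["treatment_labels"])
        kwargs["generator"] = GeneratorConfig(**g)
    if "response" in kwargs:
        kwargs["response"] = ResponseModel(**kwargs["response"])
    if "model" in kwargs:
        kwargs["model"] = MTCModelSpec(**kwargs["model"])
    if "mcmc" in kwargs:
        kwargs["mcmc"] = MCMCConfig(**kwargs["mcmc"])
    cfg = SimulationConfig(**kwargs)
    cfg.validate()
    return cfg
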