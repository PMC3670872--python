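"""Arm-level randomized-trial networks: domain types, CSV I/O and validation.

The on-disk format is the arm-level CSV layout common in network
meta-analysis: one row per treatment arm with columns
``study,treatment,responders,sampleSize``.  ``responders`` may be left
empty, in which case the file describes a *skeleton* — a trial network
whose design (treatments and sample sizes) is fixed but whose binary
outcomes have not yet been observed or simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import networkx as nx
import pandas as pd

__all__ = [
    "Arm",
    "Trial",
    "TrialNetwork",
    "ValidationReport",
    "NetworkFormatError",
    "NetworkValidationError",
    "read_network",
    "write_network",
    "validate_network",
]

#: required CSV header, in canonical order
CSV_COLUMNS = ("study", "treatment", "responders", "sampleSize")


class NetworkFormatError(ValueError):
    """The file does not conform to the arm-level CSV dialect."""


class NetworkValidationError(ValueError):
    """The parsed network violates a structural invariant."""


@dataclass(frozen=True)
class Arm:
    """One randomized arm: a treatment, ``n`` randomized, ``r`` responders.

    ``r`` is ``None`` for skeleton networks where outcomes are not yet set.
    Invariants (``0 <= r <= n``, ``n >= 1``) are checked by
    :func:`validate_network` rather than at construction time so that
    invalid inputs can be *reported* instead of silently rejected.
    """

    treatment: str
    n: int
    r: Optional[int] = None

    @property
    def has_response(self) -> bool:
        return self.r is not None


@dataclass
class Trial:
    """A single randomized trial: an identifier plus its ordered arms.

    The first listed arm is the trial's baseline for model
    parameterization downstream.
    """

    id: str
    arms: list[Arm] = field(default_factory=list)

    @property
    def treatments(self) -> list[str]:
        return [a.treatment for a in self.arms]

    @property
    def n_participants(self) -> int:
        return sum(a.n for a in self.arms)


@dataclass
class TrialNetwork:
    """A collection of trials over an ordered treatment set."""

    trials: list[Trial]
    treatments: list[str]

    # -- summary statistics -------------------------------------------------
    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_arms(self) -> int:
        return sum(len(t.arms) for t in self.trials)

    @property
    def n_participants(self) -> int:
        return sum(t.n_participants for t in self.trials)

    @property
    def has_responses(self) -> bool:
        """True when every arm carries an observed/simulated responder count."""
        return all(a.has_response for t in self.trials for a in t.arms)

    @property
    def any_responses(self) -> bool:
        return any(a.has_response for t in self.trials for a in t.arms)

    # -- graph structure ----------------------------------------------------
    def comparison_graph(self) -> nx.Graph:
        """Undirected graph: nodes are treatments, an edge joins two
        treatments co-randomized in at least one trial; edge attribute
        ``n_trials`` counts the supporting trials."""
        g = nx.Graph()
        g.add_nodes_from(self.treatments)
        for trial in self.trials:
            trts = trial.treatments
            for i in range(len(trts)):
                for j in range(i + 1, len(trts)):
                    u, v = trts[i], trts[j]
                    if g.has_edge(u, v):
                        g[u][v]["n_trials"] += 1
                    else:
                        g.add_edge(u, v, n_trials=1)
        return g

    @property
    def is_connected(self) -> bool:
        g = self.comparison_graph()
        return g.number_of_nodes() > 0 and nx.is_connected(g)


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_network`: empty ``violations`` iff valid."""

    violations: list[str] = field(default_factory=list)

    @property
    def is_valid(self) -> bool:
        return not self.violations

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if self.is_valid:
            return "network valid"
        return "network invalid:\n" + "\n".join(f"  - {v}" for v in self.violations)


def validate_network(net: TrialNetwork) -> ValidationReport:
    """Collect every structural violation in ``net``.

    Checks: >=2 arms per trial, no duplicate treatment within a trial,
    positive sample sizes, ``0 <= r <= n`` where set, every arm's treatment
    declared, every declared treatment used in at least one trial, and a
    connected comparison graph.
    """
    v: list[str] = []
    used: set[str] = set()
    declared = set(net.treatments)
    for trial in net.trials:
        if len(trial.arms) < 2:
            v.append(f"trial {trial.id!r}: fewer than 2 arms ({len(trial.arms)})")
        seen: set[str] = set()
        for idx, arm in enumerate(trial.arms):
            used.add(arm.treatment)
            if arm.treatment in seen:
                v.append(f"trial {trial.id!r}: duplicate treatment {arm.treatment!r}")
            seen.add(arm.treatment)
            if arm.treatment not in declared:
                v.append(
                    f"trial {trial.id!r} arm {idx}: treatment {arm.treatment!r}"
                    " not in the network's treatment list"
                )
            if arm.n < 1:
                v.append(f"trial {trial.id!r} arm {idx}: sample size {arm.n} < 1")
            if arm.r is not None and not (0 <= arm.r <= arm.n):
                v.append(
                    f"trial {trial.id!r} arm {idx} ({arm.treatment}):"
                    f" responders {arm.r} outside [0, {arm.n}]"
                )
    for t in net.treatments:
        if t not in used:
            v.append(f"treatment {t!r} is used in zero trials")
    if net.trials and not net.is_connected:
        comps = sorted(
            sorted(c) for c in nx.connected_components(net.comparison_graph())
        )
        v.append(f"comparison graph is disconnected: components {comps}")
    return ValidationReport(v)


def _parse_responders(value) -> Optional[int]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    if not s:
        return None
    try:
        return int(float(s)) if float(s) == int(float(s)) else int(s)
    except ValueError as exc:
        raise NetworkFormatError(f"non-integer responders value {value!r}") from exc


def read_network(path: Union[str, Path]) -> TrialNetwork:
    """Read and validate an arm-level CSV; see module docstring for dialect.

    Row order within a study is preserved as arm order (the first row of a
    study is its baseline arm); treatments are ordered by first appearance.

    Raises :class:`NetworkFormatError` for a malformed file and
    :class:`NetworkValidationError` when the parsed network violates an
    invariant (e.g. ``r > n`` or a disconnected comparison graph).
    """
    try:
        df = pd.read_csv(path, dtype={"study": str, "treatment": str})
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise NetworkFormatError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise NetworkFormatError(f"{path}: missing required column(s) {missing}")
    trials: dict[str, Trial] = {}
    treatments: list[str] = []
    for row in df.itertuples(index=False):
        study = str(getattr(row, "study"))
        trt = str(getattr(row, "treatment"))
        n_raw = getattr(row, "sampleSize")
        if pd.isna(n_raw):
            raise NetworkFormatError(f"{path}: empty sampleSize in study {study!r}")
        arm = Arm(treatment=trt, n=int(n_raw), r=_parse_responders(getattr(row, "responders")))
        trials.setdefault(study, Trial(id=study)).arms.append(arm)
        if trt not in treatments:
            treatments.append(trt)
    net = TrialNetwork(trials=list(trials.values()), treatments=treatments)
    report = validate_network(net)
    if not report.is_valid:
        raise NetworkValidationError(str(report))
    return net


def write_network(net: TrialNetwork, path: Union[str, Path]) -> None:
    """Write ``net`` as arm-level CSV, deterministically ordered by study id
    (string sort) then arm order; unset responders become empty cells."""
    rows = []
    for trial in sorted(net.trials, key=lambda t: t.id):
        for arm in trial.arms:
            rows.append(
                {
                    "study": trial.id,
                    "treatment": arm.treatment,
                    "responders": "" if arm.r is None else arm.r,
                    "sampleSize": arm.n,
                }
            )
    df = pd.DataFrame(rows, columns=list(CSV_COLUMNS))
    df.to_csv(path, index=False)


def network_from_tables(
    tables: Iterable[tuple[str, Sequence[tuple[str, int, Optional[int]]]]],
    treatments: Optional[Sequence[str]] = None,
) -> TrialNetwork:
    """Convenience constructor from ``(study_id, [(treatment, n, r), ...])``."""
    trials = [
        Trial(id=sid, arms=[Arm(treatment=t, n=n, r=r) for t, n, r in arms])
        for sid, arms in tables
    ]
    if treatments is None:
        treatments = []
        for tr in trials:
            for a in tr.arms:
                if a.treatment not in treatments:
                    treatments.append(a.treatment)
    return TrialNetwork(trials=trials, treatments=list(treatments))
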