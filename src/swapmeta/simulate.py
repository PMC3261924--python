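"""Mechanistic simulator of cis-element / trans-factor coevolution.

The model is the simplest generative process that realizes every outcome
category of the swap rubric.  A regulatory system is a multiset of binding
sites on one cis element (each site carries a specificity label from a
finite alphabet) plus a set of activating transcription factors (each with a
specificity label and a set of expression domains).  The output pattern is
the union of the domains of every factor whose label matches at least one
site — activator-only, union semantics, no repression or cooperativity.

An ancestor is cloned into a donor and a host lineage which evolve
independently for a number of steps.  Per step at most one event occurs:

- ``site_gain`` / ``site_loss`` — cis-only changes (a new site matching an
  existing factor, or loss of a random site);
- ``trans_domain_change`` — a factor's expression domains are resampled
  (trans-only change);
- ``coevolution_conserving`` — a factor and its matching site(s) are jointly
  relabeled to a fresh, lineage-private symbol; the output pattern is
  provably unchanged, but the dependence is now private to the lineage
  (Developmental Systems Drift when it surfaces in a swap);
- ``coevolution_diverging`` — a factor gets a fresh label *and* new domains
  and its site(s) are rewritten, changing the output and making the cis
  element depend on a lineage-private label.

The swap pattern is the donor cis element read by the host trans factors.
Because coevolution events introduce lineage-private labels, they break the
swap even when both endogenous patterns are conserved — the mechanistic
route to misregulation, and the analogue of Dobzhansky-Muller
incompatibility for regulatory interactions.

Optional detection noise: with probability ``epsilon`` each truly-different
pairwise relation is recorded as alike (missed subtle differences).  A
triple made inconsistent by such a miss is repaired to all-alike — an
observer who misses one difference is taken to miss the entailed one.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import yaml

from swapmeta.dataset import ALIKE, DIFFERENT, SwapExperiment
from swapmeta.classify import classify_controlled, Category


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class TransFactor:
    """An activating factor: binding specificity plus expression domains."""

    label: str
    domains: frozenset


@dataclass
class RegulatoryState:
    """Genotype of one lineage: cis binding sites + trans factors."""

    cis_sites: Counter = field(default_factory=Counter)  # label -> copies
    trans_factors: list[TransFactor] = field(default_factory=list)

    def copy(self) -> "RegulatoryState":
        return RegulatoryState(Counter(self.cis_sites),
                               list(self.trans_factors))


@dataclass(frozen=True)
class EvolutionRates:
    """Per-step event probabilities; at most one event per lineage-step."""

    site_gain: float = 0.05
    site_loss: float = 0.05
    trans_domain_change: float = 0.05
    coevolution_conserving: float = 0.03
    coevolution_diverging: float = 0.03

    def __post_init__(self):
        vals = (self.site_gain, self.site_loss, self.trans_domain_change,
                self.coevolution_conserving, self.coevolution_diverging)
        if any(not (0.0 <= v <= 1.0) for v in vals):
            raise SimulationError("rates must be probabilities in [0, 1]")
        if sum(vals) > 1.0 + 1e-12:
            raise SimulationError(
                "rates must sum to <= 1 (at most one event per step)")

    def items(self):
        return [("site_gain", self.site_gain),
                ("site_loss", self.site_loss),
                ("trans_domain_change", self.trans_domain_change),
                ("coevolution_conserving", self.coevolution_conserving),
                ("coevolution_diverging", self.coevolution_diverging)]


@dataclass(frozen=True)
class SimulatorConfig:
    """Ancestral system and universe sizes.

    Defaults: alphabet of 12 specificity labels, 10 expression domains,
    3 ancestral factors with distinct labels and disjoint domains, 2 of
    which have an ancestral binding site — small enough for exhaustive
    checking yet rich enough that all five categories arise.
    """

    alphabet_size: int = 12
    domain_universe: int = 10
    n_factors: int = 3
    n_sites: int = 2
    rates: EvolutionRates = field(default_factory=EvolutionRates)

    def __post_init__(self):
        if self.n_factors < 1 or self.n_factors > self.alphabet_size:
            raise SimulationError("need 1 <= n_factors <= alphabet_size")
        if self.n_sites > self.n_factors:
            raise SimulationError("ancestral sites each match a distinct "
                                  "factor; need n_sites <= n_factors")

    def ancestor(self) -> RegulatoryState:
        """Deterministic ancestral state: factor i has label s{i} and an
        equal share of the domain universe; the first n_sites factors have
        one binding site each."""
        domains = [f"d{i}" for i in range(self.domain_universe)]
        factors = []
        per = max(1, self.domain_universe // self.n_factors)
        for i in range(self.n_factors):
            chunk = domains[i * per:(i + 1) * per] or [domains[i % len(domains)]]
            factors.append(TransFactor(f"s{i}", frozenset(chunk)))
        sites = Counter(f"s{i}" for i in range(self.n_sites))
        return RegulatoryState(sites, factors)

    @classmethod
    def from_yaml(cls, path) -> "SimulatorConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        rates = EvolutionRates(**raw.pop("rates", {}))
        return cls(rates=rates, **raw)


@dataclass
class SimulatedExperiment:
    """A simulated swap with its ground truth."""

    donor_pattern: frozenset
    host_pattern: frozenset
    swap_pattern: frozenset
    true_mode: str  # none | cis_only | trans_only | coevolution_*
    event_log: list[tuple[str, int, str]]  # (lineage, step, event type)
    divergence_time: int
    detection_noise_applied: bool = False


def expression_pattern(cis_sites: Counter | Iterable[str],
                       trans_factors: Sequence[TransFactor]) -> frozenset:
    """Union of domains of every factor whose label matches >= 1 cis site."""
    labels = set(cis_sites)
    out: set = set()
    for f in trans_factors:
        if f.label in labels:
            out |= f.domains
    return frozenset(out)


# ---------------------------------------------------------------------------
# Lineage evolution
# ---------------------------------------------------------------------------

def _fresh_label(lineage: str, counter: list[int]) -> str:
    counter[0] += 1
    return f"{lineage}:novel{counter[0]}"


def _resample_domains(rng: np.random.Generator, universe: int,
                      current: frozenset) -> frozenset:
    """A random domain subset guaranteed different from ``current``."""
    domains = [f"d{i}" for i in range(universe)]
    for _ in range(64):
        pick = frozenset(d for d in domains if rng.random() < 0.5)
        if pick != current:
            return pick
    # degenerate universes only; flip one element deterministically
    d0 = domains[0]
    return current ^ {d0}


def evolve_lineage(state: RegulatoryState, steps: int, rates: EvolutionRates,
                   rng: np.random.Generator, lineage: str = "L",
                   domain_universe: int = 10
                   ) -> tuple[RegulatoryState, list[tuple[str, int, str]]]:
    """Evolve one lineage for ``steps`` steps; at most one event per step.

    Returns the evolved state and the event log as (lineage, step, event)
    tuples.  Events that cannot apply (e.g. site loss on an empty cis
    element) are logged with a ``:noop`` suffix and leave the state
    unchanged.  Deterministic for a given generator state.
    """
    if steps < 0:
        raise SimulationError("steps must be >= 0")
    state = state.copy()
    log: list[tuple[str, int, str]] = []
    fresh = [0]
    for step in range(steps):
        u = rng.random()
        acc = 0.0
        event = None
        for name, p in rates.items():
            acc += p
            if u < acc:
                event = name
                break
        if event is None:
            continue

        if event == "site_gain":
            if not state.trans_factors:
                log.append((lineage, step, "site_gain:noop"))
                continue
            f = state.trans_factors[rng.integers(len(state.trans_factors))]
            state.cis_sites[f.label] += 1
            log.append((lineage, step, "site_gain"))

        elif event == "site_loss":
            sites = sorted(state.cis_sites.elements())
            if not sites:
                log.append((lineage, step, "site_loss:noop"))
                continue
            lost = sites[rng.integers(len(sites))]
            state.cis_sites[lost] -= 1
            if state.cis_sites[lost] == 0:
                del state.cis_sites[lost]
            log.append((lineage, step, "site_loss"))

        elif event == "trans_domain_change":
            if not state.trans_factors:
                log.append((lineage, step, "trans_domain_change:noop"))
                continue
            i = int(rng.integers(len(state.trans_factors)))
            f = state.trans_factors[i]
            state.trans_factors[i] = TransFactor(
                f.label, _resample_domains(rng, domain_universe, f.domains))
            log.append((lineage, step, "trans_domain_change"))

        else:  # coevolution events act on a factor with >= 1 matching site
            matched = [i for i, f in enumerate(state.trans_factors)
                       if state.cis_sites.get(f.label, 0) > 0]
            if not matched:
                log.append((lineage, step, f"{event}:noop"))
                continue
            i = matched[int(rng.integers(len(matched)))]
            f = state.trans_factors[i]
            new_label = _fresh_label(lineage, fresh)
            copies = state.cis_sites.pop(f.label)
            state.cis_sites[new_label] = copies
            if event == "coevolution_conserving":
                state.trans_factors[i] = TransFactor(new_label, f.domains)
            else:
                state.trans_factors[i] = TransFactor(
                    new_label,
                    _resample_domains(rng, domain_universe, f.domains))
            log.append((lineage, step, event))
    return state, log


# ---------------------------------------------------------------------------
# Swap experiments
# ---------------------------------------------------------------------------

_CIS_EVENTS = {"site_gain", "site_loss"}
_TRANS_EVENTS = {"trans_domain_change"}
_COEV_EVENTS = {"coevolution_conserving", "coevolution_diverging"}


def _true_mode(log: Sequence[tuple[str, int, str]],
               donor_pattern: frozenset, host_pattern: frozenset) -> str:
    """Derive the true evolutionary mode from the joint event log.

    Precedence: any coevolution event on either lineage makes the mode
    coevolution (conserved vs divergent by whether the endogenous patterns
    still match); otherwise independent cis and trans events jointly count
    as divergent coevolution; otherwise cis-only / trans-only / none.
    """
    events = {e.split(":")[0] for (_, _, e) in log if not e.endswith(":noop")}
    if events & _COEV_EVENTS:
        return ("coevolution_conserved" if donor_pattern == host_pattern
                else "coevolution_divergent")
    has_cis = bool(events & _CIS_EVENTS)
    has_trans = bool(events & _TRANS_EVENTS)
    if has_cis and has_trans:
        return "coevolution_divergent"
    if has_cis:
        return "cis_only"
    if has_trans:
        return "trans_only"
    return "none"


def _noisy_relations(donor: frozenset, host: frozenset, swap: frozenset,
                     epsilon: float, rng: np.random.Generator
                     ) -> tuple[str, str, str, bool]:
    """Pairwise relations with detection noise and consistency repair."""
    true_rels = [ALIKE if donor == host else DIFFERENT,
                 ALIKE if swap == donor else DIFFERENT,
                 ALIKE if swap == host else DIFFERENT]
    rels = list(true_rels)
    flipped = False
    if epsilon > 0:
        for i, r in enumerate(rels):
            if r == DIFFERENT and rng.random() < epsilon:
                rels[i] = ALIKE
                flipped = True
    rdh, rsd, rsh = rels
    consistent = ((rdh == ALIKE and rsd == rsh)
                  or (rdh == DIFFERENT and not (rsd == rsh == ALIKE)))
    if not consistent:  # a missed difference entails missing the rest
        rels = [ALIKE, ALIKE, ALIKE]
    return rels[0], rels[1], rels[2], flipped


def simulate_swap_experiment(config: SimulatorConfig, divergence_time: int,
                             rates: EvolutionRates | None = None,
                             epsilon: float = 0.0,
                             rng: np.random.Generator | None = None
                             ) -> SimulatedExperiment:
    """Clone the ancestor, evolve donor and host lineages independently,
    and perform the swap (donor cis read by host trans)."""
    if not (0.0 <= epsilon <= 1.0):
        raise SimulationError("epsilon must be in [0, 1]")
    rates = rates or config.rates
    rng = rng if rng is not None else np.random.default_rng()
    ancestor = config.ancestor()
    donor, log_d = evolve_lineage(ancestor, divergence_time, rates, rng,
                                  "donor", config.domain_universe)
    host, log_h = evolve_lineage(ancestor, divergence_time, rates, rng,
                                 "host", config.domain_universe)
    donor_pattern = expression_pattern(donor.cis_sites, donor.trans_factors)
    host_pattern = expression_pattern(host.cis_sites, host.trans_factors)
    swap_pattern = expression_pattern(donor.cis_sites, host.trans_factors)
    log = log_d + log_h
    return SimulatedExperiment(
        donor_pattern=donor_pattern, host_pattern=host_pattern,
        swap_pattern=swap_pattern,
        true_mode=_true_mode(log, donor_pattern, host_pattern),
        event_log=log, divergence_time=divergence_time,
        detection_noise_applied=epsilon > 0)


def coded_view(sim: SimulatedExperiment, index: int, epsilon: float,
               rng: np.random.Generator) -> SwapExperiment:
    """The SwapExperiment coding of a simulated swap (always controlled:
    the simulator observes all three patterns)."""
    rdh, rsd, rsh, flipped = _noisy_relations(
        sim.donor_pattern, sim.host_pattern, sim.swap_pattern, epsilon, rng)
    sim.detection_noise_applied = flipped
    return SwapExperiment(
        id=f"S{index:05d}", gene="sim", donor_taxon="donor lineage",
        host_taxon="D. melanogaster", strata=frozenset(), controlled=True,
        rel_donor_host=rdh, rel_swap_donor=rsd, rel_swap_host=rsh,
        expectation="unstated", provenance="simulated",
        citation=f"simulated, divergence_time={sim.divergence_time}")


def classify_simulated(sim: SimulatedExperiment, epsilon: float,
                       rng: np.random.Generator) -> Category:
    """Category the rubric assigns to a simulated swap's (possibly noisy)
    relation triple."""
    rdh, rsd, rsh, _ = _noisy_relations(
        sim.donor_pattern, sim.host_pattern, sim.swap_pattern, epsilon, rng)
    return classify_controlled(rdh, rsd, rsh)


def simulate_cohort(n: int, time_grid: Sequence[int],
                    rates: EvolutionRates | None = None,
                    epsilon: float = 0.0, seed: int = 0,
                    config: SimulatorConfig | None = None
                    ) -> tuple[list[SimulatedExperiment], list[SwapExperiment]]:
    """Simulate ``n`` swap experiments per time-grid point.

    A single seed determines the whole cohort: each experiment consumes an
    independent, reproducible substream spawned from (seed, experiment
    index), and the two lineages consume that substream in a fixed order.
    Returns the truth records and the coded SwapExperiment view, which flows
    through the classifier and the tally statistics unchanged.
    """
    if n < 1:
        raise SimulationError("n must be >= 1")
    config = config or SimulatorConfig()
    rates = rates or config.rates
    truths: list[SimulatedExperiment] = []
    coded: list[SwapExperiment] = []
    root = np.random.SeedSequence(seed)
    streams = root.spawn(len(time_grid) * n)
    idx = 0
    for t in time_grid:
        for _ in range(n):
            rng = np.random.default_rng(streams[idx])
            sim = simulate_swap_experiment(config, t, rates, epsilon, rng)
            truths.append(sim)
            coded.append(coded_view(sim, idx, epsilon, rng))
            idx += 1
    return truths, coded
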