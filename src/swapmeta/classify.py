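"""The inference rubric: pattern relations -> evolutionary-mode categories.

A controlled swap observes three patterns (donor endogenous, host endogenous,
swap) and hence three pairwise relations.  Of the 8 possible relation
triples, 6 are logically consistent and map one-to-one onto five categories:

==========  ===========  ==========  ========  =============================
donor-host  swap-donor   swap-host   category  interpretation
==========  ===========  ==========  ========  =============================
alike       alike        alike       C1        conservation
different   different    alike       C2        divergence in trans alone
different   alike        different   C3        divergence in cis alone
different   different    different   C4        cis-trans coevolution,
                                               divergent output
alike       different    different   C5        cis-trans coevolution with
                                               conserved output (DSD)
==========  ===========  ==========  ========  =============================

The host-like swap (C2) shows the host trans factors determine the pattern;
the donor-like swap (C3) shows the donor cis element is sufficient; a swap
matching neither pattern (C4/C5) reveals coevolved cis-trans interactions
that malfunction when split between species ("misregulation"); C5 output
conservation despite diverged interactions is Developmental Systems Drift.
The three remaining triples are inconsistent (if donor and host patterns are
alike the swap cannot match exactly one of them; if they differ it cannot
match both) and are rejected.

Non-controlled swaps know only one endogenous pattern and fall into two
categories: swap alike to the known pattern (NC_I, suspected conservation)
or different from it (NC_II, divergence of an unresolvable mode).
"""

from __future__ import annotations

from dataclasses import dataclass

from swapmeta.dataset import (ALIKE, DIFFERENT, UNKNOWN, SwapExperiment)

CATEGORY_VALUES = ("C1", "C2", "C3", "C4", "C5", "NC_I", "NC_II")


class ClassificationError(ValueError):
    """Relation triple outside the rubric, or invalid dispatch."""


@dataclass(frozen=True)
class Category:
    """One of the seven outcome categories (C1-C5 controlled, NC_I/NC_II
    non-controlled)."""

    value: str

    def __post_init__(self):
        if self.value not in CATEGORY_VALUES:
            raise ClassificationError(f"unknown category {self.value!r}")

    @property
    def controlled(self) -> bool:
        return not self.value.startswith("NC")

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class GroupLabels:
    """Derived groupings of a category.

    ``conservation_axis``: conserved (C1, NC_I) vs diverged (C2-C5, NC_II).
    ``mode_axis``: conservation (C1, NC_I), divergence (C2, C3),
    misregulation (C4, C5), or unresolved (NC_II — without controls the mode
    of divergence cannot be separated).
    """

    conservation_axis: str
    mode_axis: str


_CONTROLLED_MAP = {
    (ALIKE, ALIKE, ALIKE): "C1",
    (DIFFERENT, DIFFERENT, ALIKE): "C2",
    (DIFFERENT, ALIKE, DIFFERENT): "C3",
    (DIFFERENT, DIFFERENT, DIFFERENT): "C4",
    (ALIKE, DIFFERENT, DIFFERENT): "C5",
}

_GROUPS = {
    "C1": GroupLabels("conserved", "conservation"),
    "C2": GroupLabels("diverged", "divergence"),
    "C3": GroupLabels("diverged", "divergence"),
    "C4": GroupLabels("diverged", "misregulation"),
    "C5": GroupLabels("diverged", "misregulation"),
    "NC_I": GroupLabels("conserved", "conservation"),
    "NC_II": GroupLabels("diverged", "unresolved"),
}


def classify_controlled(rel_donor_host: str, rel_swap_donor: str,
                        rel_swap_host: str) -> Category:
    """Map a consistent relation triple to its category (parsimony rubric).

    Raises :class:`ClassificationError` on the three inconsistent triples or
    on any ``unknown`` relation.
    """
    triple = (rel_donor_host, rel_swap_donor, rel_swap_host)
    for r in triple:
        if r not in (ALIKE, DIFFERENT):
            raise ClassificationError(
                f"controlled classification needs alike/different relations, "
                f"got {triple}")
    try:
        return Category(_CONTROLLED_MAP[triple])
    except KeyError:
        if rel_donor_host == ALIKE:
            reason = ("donor and host patterns are alike, so the swap "
                      "cannot match exactly one of them")
        else:
            reason = ("donor and host patterns differ, so the swap cannot "
                      "match both")
        raise ClassificationError(
            f"inconsistent relation triple {triple}: {reason}") from None


def classify_noncontrolled(known_side: str, rel_swap_known: str) -> Category:
    """Classify a swap for which only one endogenous pattern is known.

    ``known_side`` ('donor' or 'host') is recorded for reporting only; the
    category depends solely on whether the swap resembles the known pattern.
    """
    if known_side not in ("donor", "host"):
        raise ClassificationError(f"unknown side {known_side!r}")
    if rel_swap_known == ALIKE:
        return Category("NC_I")
    if rel_swap_known == DIFFERENT:
        return Category("NC_II")
    raise ClassificationError(
        "nothing to classify: the swap-vs-known relation is unknown")


def classify_experiment(exp: SwapExperiment) -> Category:
    """Dispatch to the controlled or non-controlled rubric per the record."""
    violations = exp.violations()
    if violations:
        raise ClassificationError(
            f"experiment {exp.id}: invalid record: " + "; ".join(violations))
    try:
        if exp.controlled:
            return classify_controlled(exp.rel_donor_host,
                                       exp.rel_swap_donor, exp.rel_swap_host)
        if exp.rel_swap_donor != UNKNOWN:
            return classify_noncontrolled("donor", exp.rel_swap_donor)
        return classify_noncontrolled("host", exp.rel_swap_host)
    except ClassificationError as e:
        raise ClassificationError(f"experiment {exp.id}: {e}") from None


def group(category: Category) -> GroupLabels:
    """Derived conservation-axis and mode-axis labels of a category."""
    return _GROUPS[category.value]


def sex_tissue_fidelity(exp: SwapExperiment) -> tuple[bool, bool]:
    """Recorded (proper sex, proper tissue) fidelity of a sex-specific swap.

    Fidelity is a curated observation about the swap pattern, orthogonal to
    the category (a swap can diverge in mode yet retain proper sex
    specificity), so it is read from the coded flags rather than re-derived.
    """
    if not exp.sex_specific:
        raise ClassificationError(
            f"experiment {exp.id}: sex/tissue fidelity is undefined for "
            f"non-sex-specific experiments")
    return bool(exp.swap_sex_proper), bool(exp.swap_tissue_proper)
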