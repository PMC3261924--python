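"""Data model, I/O, and constraint-driven reconstruction of the swap dataset.

The curated literature dataset behind the meta-analysis (230 enhancer-swap
experiments anchored on *D. melanogaster* or *C. elegans*) is not distributed
row-by-row; only its marginal tallies are published.  This module therefore
provides, besides the usual typed I/O:

- :class:`TallyConstraint` — one published marginal (a subset predicate plus
  an expected count), loaded from JSON;
- :func:`build_fixture` — an integer-feasibility reconstruction that emits a
  table of ``provenance=reconstructed`` rows jointly satisfying every
  constraint, deterministic for a given seed;
- :func:`validate_dataset` — a non-raising recount of every constraint plus
  all row invariants.

Only subset tallies of the reconstructed table are meaningful; row identities
(species names, gene names, citations) are synthetic placeholders.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import LinearConstraint, milp

# ---------------------------------------------------------------------------
# Controlled vocabularies
# ---------------------------------------------------------------------------

ALIKE = "alike"
DIFFERENT = "different"
UNKNOWN = "unknown"
RELATIONS = (ALIKE, DIFFERENT, UNKNOWN)

HOSTS = ("D. melanogaster", "C. elegans")

STRATA = frozenset({
    "caenorhabditis",
    "non_caenorhabditis_worm",
    "worm_close_pair",
    "drosophila",
    "sophophora",
    "obscura_group",
    "non_drosophila_insect",
    "sex_specific_sophophora",
    "sex_specific_distant_insect",
})

EXPECTATIONS = ("conservation", "divergence", "unstated")
PROVENANCES = ("curated", "reconstructed", "simulated")


class DatasetError(ValueError):
    """Malformed experiment table or constraint file."""


class InfeasibleConstraintsError(DatasetError):
    """No experiment table can satisfy the constraint set jointly.

    ``conflict`` holds a minimal conflicting subset of constraint labels
    found by a deletion filter.
    """

    def __init__(self, conflict: Sequence[str]):
        self.conflict = list(conflict)
        super().__init__(
            "constraint set is infeasible; minimal conflicting subset: "
            + ", ".join(self.conflict)
        )


@dataclass(frozen=True)
class PatternRelation:
    """Recorded relation between two expression patterns.

    ``unknown`` is only legal for relations involving a pattern that was
    never observed, i.e. in non-controlled experiments.
    """

    value: str

    def __post_init__(self):
        if self.value not in RELATIONS:
            raise DatasetError(f"invalid pattern relation {self.value!r}")

    def __str__(self) -> str:  # serializes as the bare token
        return self.value


def _rel(value: str) -> str:
    if value not in RELATIONS:
        raise DatasetError(f"invalid pattern relation {value!r}")
    return value


@dataclass
class SwapExperiment:
    """One coded enhancer-swap test.

    ``rel_donor_host``, ``rel_swap_donor`` and ``rel_swap_host`` record the
    pairwise pattern comparisons between the donor endogenous pattern, the
    host endogenous pattern and the swap (donor cis-DNA read out in the host
    trans background).  ``controlled`` means both endogenous patterns were
    known, enabling the five-way classification.
    """

    id: str
    gene: str
    donor_taxon: str
    host_taxon: str
    strata: frozenset = field(default_factory=frozenset)
    controlled: bool = True
    rel_donor_host: str = UNKNOWN
    rel_swap_donor: str = UNKNOWN
    rel_swap_host: str = UNKNOWN
    expectation: str = "unstated"
    sex_specific: bool = False
    swap_sex_proper: bool | None = None
    swap_tissue_proper: bool | None = None
    enhancer: str = ""
    fragment_longest: bool = True
    provenance: str = "curated"
    citation: str = ""

    def __post_init__(self):
        self.strata = frozenset(self.strata)
        if not self.enhancer:
            self.enhancer = self.gene
        for r in (self.rel_donor_host, self.rel_swap_donor, self.rel_swap_host):
            _rel(r)

    # -- invariants ---------------------------------------------------------

    def violations(self) -> list[str]:
        """All invariant violations for this record (empty list = valid)."""
        v: list[str] = []
        if self.host_taxon not in HOSTS:
            v.append(f"{self.id}: host_taxon {self.host_taxon!r} is not an "
                     f"anchor species {HOSTS}")
        extra = self.strata - STRATA
        if extra:
            v.append(f"{self.id}: unknown strata {sorted(extra)}")
        if self.expectation not in EXPECTATIONS:
            v.append(f"{self.id}: invalid expectation {self.expectation!r}")
        if self.provenance not in PROVENANCES:
            v.append(f"{self.id}: invalid provenance {self.provenance!r}")
        rels = (self.rel_donor_host, self.rel_swap_donor, self.rel_swap_host)
        if self.controlled:
            if any(r == UNKNOWN for r in rels):
                v.append(f"{self.id}: controlled experiment with an unknown "
                         f"relation (all three patterns were observed)")
            elif self.rel_donor_host == ALIKE and \
                    self.rel_swap_donor != self.rel_swap_host:
                v.append(f"{self.id}: donor and host patterns are alike but "
                         f"the swap matches only one of them")
            elif self.rel_donor_host == DIFFERENT and \
                    self.rel_swap_donor == self.rel_swap_host == ALIKE:
                v.append(f"{self.id}: donor and host patterns differ but the "
                         f"swap is recorded alike to both")
        else:
            known = [r != UNKNOWN for r in (self.rel_swap_donor,
                                            self.rel_swap_host)]
            if sum(known) != 1 or self.rel_donor_host != UNKNOWN:
                v.append(f"{self.id}: non-controlled experiment must know "
                         f"exactly one of swap-vs-donor / swap-vs-host and "
                         f"nothing else")
        if not self.sex_specific and (self.swap_sex_proper is not None or
                                      self.swap_tissue_proper is not None):
            v.append(f"{self.id}: sex/tissue fidelity flags are only "
                     f"applicable to sex-specific experiments")
        return v

    def validate(self) -> "SwapExperiment":
        v = self.violations()
        if v:
            raise DatasetError("; ".join(v))
        return self


# ---------------------------------------------------------------------------
# Tally constraints
# ---------------------------------------------------------------------------

#: Subset keys understood by constraint predicates.  ``stratum`` tests
#: membership of one label in the row's strata set; ``category`` tests the
#: classifier-assigned category (string or list of strings); ``group`` tests
#: a derived grouping: conserved/diverged (conservation axis) or
#: conservation/divergence/misregulation/unresolved (mode axis).
SUBSET_KEYS = ("stratum", "controlled", "category", "group", "expectation",
               "gene", "sex_specific", "swap_sex_proper", "swap_tissue_proper")

_GROUP_CATEGORIES = {
    "conserved": {"C1", "NC_I"},
    "diverged": {"C2", "C3", "C4", "C5", "NC_II"},
    "conservation": {"C1", "NC_I"},
    "divergence": {"C2", "C3"},
    "misregulation": {"C4", "C5"},
    "unresolved": {"NC_II"},
}


@dataclass(frozen=True)
class TallyConstraint:
    """One published marginal: a subset predicate and its expected count."""

    label: str
    subset: Mapping[str, object]
    expected_count: int
    note: str = ""

    def __post_init__(self):
        if self.expected_count < 0:
            raise DatasetError(f"{self.label}: negative expected count")
        bad = set(self.subset) - set(SUBSET_KEYS)
        if bad:
            raise DatasetError(f"{self.label}: unknown subset keys {sorted(bad)}")
        g = self.subset.get("group")
        if g is not None and g not in _GROUP_CATEGORIES:
            raise DatasetError(f"{self.label}: unknown group {g!r}")

    def _category_set(self) -> set[str] | None:
        cats: set[str] | None = None
        if "category" in self.subset:
            c = self.subset["category"]
            cats = {c} if isinstance(c, str) else set(c)
        if "group" in self.subset:
            g = _GROUP_CATEGORIES[self.subset["group"]]
            cats = g if cats is None else cats & g
        return cats

    def matches(self, exp: SwapExperiment, category: str | None = None) -> bool:
        """Does ``exp`` (with classifier ``category``) satisfy the subset?"""
        s = self.subset
        if "stratum" in s and s["stratum"] not in exp.strata:
            return False
        for key in ("controlled", "expectation", "gene", "sex_specific",
                    "swap_sex_proper", "swap_tissue_proper"):
            if key in s and getattr(exp, key) != s[key]:
                return False
        cats = self._category_set()
        if cats is not None:
            if category is None:
                from swapmeta.classify import classify_experiment
                category = classify_experiment(exp).value
            if category not in cats:
                return False
        return True


def load_constraints(path: str | Path) -> list[TallyConstraint]:
    """Read a JSON array of ``{label, subset, expected_count[, note]}``."""
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    if not isinstance(raw, list):
        raise DatasetError("constraint file must be a JSON array")
    out = []
    for item in raw:
        try:
            out.append(TallyConstraint(
                label=item["label"],
                subset=dict(item.get("subset", {})),
                expected_count=int(item["expected_count"]),
                note=item.get("note", ""),
            ))
        except KeyError as e:
            raise DatasetError(f"constraint missing field {e}") from e
    return out


def packaged_constraints() -> list[TallyConstraint]:
    """The packaged constraint set encoding the published marginal tallies."""
    with resources.as_file(
            resources.files("swapmeta.data") / "constraints.json") as p:
        return load_constraints(p)


def packaged_fixture() -> list[SwapExperiment]:
    """The packaged 230-row reconstructed dataset (built with seed 1)."""
    with resources.as_file(
            resources.files("swapmeta.data") / "fixture.tsv") as p:
        return read_experiments(p)


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

COLUMNS = ["id", "gene", "enhancer", "donor_taxon", "host_taxon", "strata",
           "controlled", "rel_donor_host", "rel_swap_donor", "rel_swap_host",
           "expectation", "sex_specific", "swap_sex_proper",
           "swap_tissue_proper", "fragment_longest", "provenance", "citation"]

_BOOL = {"true": True, "false": False}


def _parse_bool(token: str, col: str, row: int) -> bool:
    try:
        return _BOOL[token]
    except KeyError:
        raise DatasetError(f"row {row}: column {col!r} must be true/false, "
                           f"got {token!r}") from None


def _parse_opt_bool(token: str, col: str, row: int) -> bool | None:
    if token == "na":
        return None
    return _parse_bool(token, col, row)


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_experiments(path: str | Path) -> list[SwapExperiment]:
    """Read a TSV/CSV experiment table into validated records.

    The header must name every :data:`COLUMNS` field.  Unknown relations use
    the literal sentinel ``unknown``; empty relation cells are an error.
    Row order is preserved.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str,
                     keep_default_na=False)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise DatasetError(f"missing column(s): {', '.join(missing)}")
    errors: list[str] = []
    out: list[SwapExperiment] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        r = row._asdict()
        try:
            for rel_col in ("rel_donor_host", "rel_swap_donor",
                            "rel_swap_host"):
                if r[rel_col] == "":
                    raise DatasetError(
                        f"row {i}: empty relation cell {rel_col!r} (use the "
                        f"sentinel 'unknown')")
                if r[rel_col] not in RELATIONS:
                    raise DatasetError(
                        f"row {i}: invalid relation {r[rel_col]!r} in "
                        f"{rel_col!r}")
            exp = SwapExperiment(
                id=r["id"],
                gene=r["gene"],
                enhancer=r["enhancer"],
                donor_taxon=r["donor_taxon"],
                host_taxon=r["host_taxon"],
                strata=frozenset(s for s in r["strata"].split(";") if s),
                controlled=_parse_bool(r["controlled"], "controlled", i),
                rel_donor_host=r["rel_donor_host"],
                rel_swap_donor=r["rel_swap_donor"],
                rel_swap_host=r["rel_swap_host"],
                expectation=r["expectation"],
                sex_specific=_parse_bool(r["sex_specific"], "sex_specific", i),
                swap_sex_proper=_parse_opt_bool(
                    r["swap_sex_proper"], "swap_sex_proper", i),
                swap_tissue_proper=_parse_opt_bool(
                    r["swap_tissue_proper"], "swap_tissue_proper", i),
                fragment_longest=_parse_bool(
                    r["fragment_longest"], "fragment_longest", i),
                provenance=r["provenance"],
                citation=r["citation"],
            )
            v = exp.violations()
            if v:
                raise DatasetError(f"row {i}: " + "; ".join(v))
            out.append(exp)
        except DatasetError as e:
            errors.append(str(e))
    if errors:
        raise DatasetError("invalid experiment table:\n" + "\n".join(errors))
    return out


def to_frame(experiments: Iterable[SwapExperiment]) -> pd.DataFrame:
    """Serialize records to a DataFrame in canonical column order."""
    def b(x):
        return "na" if x is None else ("true" if x else "false")

    rows = []
    for e in experiments:
        rows.append({
            "id": e.id, "gene": e.gene, "enhancer": e.enhancer,
            "donor_taxon": e.donor_taxon, "host_taxon": e.host_taxon,
            "strata": ";".join(sorted(e.strata)),
            "controlled": b(e.controlled),
            "rel_donor_host": e.rel_donor_host,
            "rel_swap_donor": e.rel_swap_donor,
            "rel_swap_host": e.rel_swap_host,
            "expectation": e.expectation,
            "sex_specific": b(e.sex_specific),
            "swap_sex_proper": b(e.swap_sex_proper),
            "swap_tissue_proper": b(e.swap_tissue_proper),
            "fragment_longest": b(e.fragment_longest),
            "provenance": e.provenance, "citation": e.citation,
        })
    return pd.DataFrame(rows, columns=COLUMNS)


def write_experiments(path: str | Path,
                      experiments: Iterable[SwapExperiment]) -> None:
    """Write records as TSV (or CSV if the path ends in .csv)."""
    path = Path(path)
    to_frame(experiments).to_csv(path, sep=_sep_for(path), index=False)


# ---------------------------------------------------------------------------
# Deduplication
# ---------------------------------------------------------------------------

def deduplicate(experiments: Sequence[SwapExperiment],
                return_removed: bool = False):
    """Keep at most one record per (enhancer, donor, host) triple.

    Repeat tests of the same element between the same species pair are
    redundant; when several fragment lengths of one element were coded, only
    the record flagged as the longest fragment is kept.  Idempotent; input
    order of survivors is preserved.
    """
    best: dict[tuple, SwapExperiment] = {}
    order: list[tuple] = []
    for e in experiments:
        key = (e.enhancer, e.donor_taxon, e.host_taxon)
        if key not in best:
            best[key] = e
            order.append(key)
        elif e.fragment_longest and not best[key].fragment_longest:
            best[key] = e
    kept = [best[k] for k in order]
    if return_removed:
        kept_ids = {e.id for e in kept}
        removed = [e for e in experiments if e.id not in kept_ids]
        return kept, removed
    return kept


# ---------------------------------------------------------------------------
# Constraint-driven fixture reconstruction
# ---------------------------------------------------------------------------

# Row templates are the cross product of a fixed catalog of cohort profiles
# (reflecting the study design: which clades were swapped into which anchor
# host) with the classifier category, the stated expectation, and — in the
# sex-specific cohorts — the fidelity flags.  build_fixture solves an integer
# feasibility program for template multiplicities.

_PROFILES = [
    # (name, strata, host, donors, genes, yellow allowed)
    ("worm_close",
     frozenset({"caenorhabditis", "worm_close_pair"}),
     "C. elegans",
     ["C. briggsae", "C. remanei", "C. brenneri", "C. japonica"],
     ["egl-17", "pes-1", "lin-48", "unc-119", "ceh-13", "mec-3"], False),
    ("worm_distant",
     frozenset({"non_caenorhabditis_worm"}),
     "C. elegans",
     ["P. pacificus", "B. malayi", "H. contortus", "S. stercoralis",
      "O. volvulus"],
     ["myo-2", "hlh-1", "gpd-2", "cpr-1"], False),
    ("fly_sophophora",
     frozenset({"drosophila", "sophophora"}),
     "D. melanogaster",
     ["D. simulans", "D. sechellia", "D. yakuba", "D. erecta",
      "D. ananassae"],
     ["eve", "hb", "dpp", "sal", "ftz"], True),
    ("fly_drosophila_subgenus",
     frozenset({"drosophila"}),
     "D. melanogaster",
     ["D. virilis", "D. mojavensis", "D. grimshawi", "D. hydei"],
     ["eve", "hb", "Ubx", "wg"], True),
    ("fly_obscura",
     frozenset({"drosophila", "sophophora", "obscura_group"}),
     "D. melanogaster",
     ["D. pseudoobscura", "D. persimilis", "D. miranda", "D. subobscura"],
     ["eve", "Adh", "per", "esg"], False),
    ("fly_sex",
     frozenset({"drosophila", "sophophora", "sex_specific_sophophora"}),
     "D. melanogaster",
     ["D. simulans", "D. yakuba", "D. erecta", "D. ananassae"],
     ["dsx", "yp1", "fru", "Sgs-4"], False),
    ("insect_distant",
     frozenset({"non_drosophila_insect"}),
     "D. melanogaster",
     ["T. castaneum", "A. gambiae", "A. mellifera", "Themira minor",
      "M. domestica"],
     ["eve", "hb", "pdm", "grim"], False),
    ("insect_sex",
     frozenset({"non_drosophila_insect", "sex_specific_distant_insect"}),
     "D. melanogaster",
     ["B. mori", "M. domestica", "Themira minor", "Calliphora vicina"],
     ["chorion-s15", "yp1", "dsx", "Lcp"], False),
]

_CONTROLLED_CATS = ("C1", "C2", "C3", "C4", "C5")
_NC_CATS = ("NC_I", "NC_II")

# canonical relation triples realizing each controlled category
_CANONICAL_TRIPLE = {
    "C1": (ALIKE, ALIKE, ALIKE),
    "C2": (DIFFERENT, DIFFERENT, ALIKE),
    "C3": (DIFFERENT, ALIKE, DIFFERENT),
    "C4": (DIFFERENT, DIFFERENT, DIFFERENT),
    "C5": (ALIKE, DIFFERENT, DIFFERENT),
}


@dataclass(frozen=True)
class _Template:
    profile: str
    strata: frozenset
    host: str
    category: str
    expectation: str
    sex_specific: bool
    swap_sex_proper: bool | None
    swap_tissue_proper: bool | None
    gene: str | None  # None = generic gene assigned at materialization

    @property
    def controlled(self) -> bool:
        return self.category in _CONTROLLED_CATS


def _template_catalog() -> list[_Template]:
    templates = []
    for name, strata, host, _donors, _genes, yellow_ok in _PROFILES:
        sex = "sex_specific" in " ".join(strata) or any(
            s.startswith("sex_specific") for s in strata)
        flag_sets = ([(True, True), (True, False), (False, True),
                      (False, False)] if sex else [(None, None)])
        genes: list[str | None] = [None] + (["yellow"] if yellow_ok else [])
        for cat in _CONTROLLED_CATS + _NC_CATS:
            for expectation in ("conservation", "divergence"):
                for sp, tp in flag_sets:
                    for gene in genes:
                        templates.append(_Template(
                            profile=name, strata=strata, host=host,
                            category=cat, expectation=expectation,
                            sex_specific=sex, swap_sex_proper=sp,
                            swap_tissue_proper=tp, gene=gene))
    return templates


def _template_matches(t: _Template, c: TallyConstraint) -> bool:
    s = c.subset
    if "stratum" in s and s["stratum"] not in t.strata:
        return False
    if "controlled" in s and t.controlled != s["controlled"]:
        return False
    if "expectation" in s and t.expectation != s["expectation"]:
        return False
    if "gene" in s and t.gene != s["gene"]:
        return False
    if "sex_specific" in s and t.sex_specific != s["sex_specific"]:
        return False
    for key in ("swap_sex_proper", "swap_tissue_proper"):
        if key in s and getattr(t, key) != s[key]:
            return False
    cats = c._category_set()
    if cats is not None and t.category not in cats:
        return False
    return True


def _solve(constraints: Sequence[TallyConstraint],
           templates: Sequence[_Template]) -> np.ndarray | None:
    """Minimal-total integer solution of the tally system, or None."""
    n = len(templates)
    if not constraints:
        return np.zeros(n, dtype=int)
    A = np.zeros((len(constraints), n))
    b = np.array([c.expected_count for c in constraints], dtype=float)
    for i, c in enumerate(constraints):
        for j, t in enumerate(templates):
            if _template_matches(t, c):
                A[i, j] = 1.0
    ub = max(1.0, b.max())
    res = milp(c=np.ones(n),
               constraints=LinearConstraint(A, b, b),
               integrality=np.ones(n),
               bounds=(0, ub))
    if not res.success:
        return None
    return np.round(res.x).astype(int)


def _minimal_conflict(constraints: Sequence[TallyConstraint],
                      templates: Sequence[_Template]) -> list[str]:
    """Deletion-filter a minimal infeasible subset of constraints."""
    core = list(constraints)
    i = 0
    while i < len(core):
        trial = core[:i] + core[i + 1:]
        if _solve(trial, templates) is None:
            core = trial  # constraint i is not needed for infeasibility
        else:
            i += 1
    return [c.label for c in core]


def build_fixture(constraints: Sequence[TallyConstraint],
                  seed: int) -> list[SwapExperiment]:
    """Reconstruct a ``provenance=reconstructed`` table satisfying every
    constraint exactly.

    Template multiplicities are solved as an integer feasibility program
    (minimal total size when the total is unconstrained); the seed controls
    only presentational randomness (row order, donor species and gene name
    cycling, which side of a non-controlled swap is known).  Identical seeds
    give identical tables; different seeds give identical constraint tallies.

    Raises :class:`InfeasibleConstraintsError` (listing a minimal conflicting
    subset) if the constraints cannot be satisfied jointly.
    """
    templates = _template_catalog()
    counts = _solve(constraints, templates)
    if counts is None:
        raise InfeasibleConstraintsError(
            _minimal_conflict(constraints, templates))

    rng = np.random.default_rng(seed)
    profile_info = {p[0]: p for p in _PROFILES}
    gene_cursor: dict[str, int] = {}
    donor_cursor: dict[str, int] = {}

    proto: list[SwapExperiment] = []
    for t, m in zip(templates, counts):
        for _ in range(int(m)):
            _, _, host, donors, genes, _ = profile_info[t.profile]
            gi = gene_cursor.get(t.profile, 0)
            di = donor_cursor.get(t.profile, 0)
            gene = t.gene or genes[gi % len(genes)]
            donor = donors[di % len(donors)]
            gene_cursor[t.profile] = gi + 1
            donor_cursor[t.profile] = di + 1
            if t.controlled:
                rdh, rsd, rsh = _CANONICAL_TRIPLE[t.category]
            else:
                known = ALIKE if t.category == "NC_I" else DIFFERENT
                if rng.random() < 0.5:
                    rdh, rsd, rsh = UNKNOWN, known, UNKNOWN
                else:
                    rdh, rsd, rsh = UNKNOWN, UNKNOWN, known
            proto.append(SwapExperiment(
                id="pending", gene=gene, donor_taxon=donor, host_taxon=host,
                strata=t.strata, controlled=t.controlled,
                rel_donor_host=rdh, rel_swap_donor=rsd, rel_swap_host=rsh,
                expectation=t.expectation, sex_specific=t.sex_specific,
                swap_sex_proper=t.swap_sex_proper,
                swap_tissue_proper=t.swap_tissue_proper,
                provenance="reconstructed",
                citation="reconstructed from published marginal tallies",
            ))

    order = rng.permutation(len(proto))
    out = []
    for new_idx, old_idx in enumerate(order, start=1):
        e = proto[old_idx]
        eid = f"R{new_idx:03d}"
        out.append(replace(e, id=eid, enhancer=f"{e.gene}.{eid}").validate())
    return out


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Outcome of recounting every constraint over a classified dataset."""

    constraint_lines: list[tuple[str, int, int, bool]]  # label, exp, obs, ok
    invariant_violations: list[str]
    dedup_notes: list[str]

    @property
    def passed(self) -> bool:
        return (all(ok for *_, ok in self.constraint_lines)
                and not self.invariant_violations)

    def to_dict(self) -> dict:
        return {
            "passed": self.passed,
            "constraints": [
                {"label": lbl, "expected": exp, "observed": obs, "pass": ok}
                for lbl, exp, obs, ok in self.constraint_lines],
            "invariant_violations": list(self.invariant_violations),
            "dedup_notes": list(self.dedup_notes),
        }

    def __str__(self) -> str:
        lines = [f"{'PASS' if ok else 'FAIL'}  {lbl}: expected {exp}, "
                 f"observed {obs}"
                 for lbl, exp, obs, ok in self.constraint_lines]
        lines += [f"INVARIANT  {v}" for v in self.invariant_violations]
        lines += [f"DEDUP  {n}" for n in self.dedup_notes]
        lines.append(f"overall: {'PASS' if self.passed else 'FAIL'}")
        return "\n".join(lines)


def validate_dataset(experiments: Sequence[SwapExperiment],
                     constraints: Sequence[TallyConstraint]
                     ) -> ValidationReport:
    """Evaluate every constraint and every row invariant; never raises."""
    from swapmeta.classify import classify_experiment

    categories: dict[str, str | None] = {}
    violations: list[str] = []
    for e in experiments:
        v = e.violations()
        violations.extend(v)
        if v:
            categories[e.id] = None
            continue
        try:
            categories[e.id] = classify_experiment(e).value
        except Exception as err:  # inconsistent triple
            categories[e.id] = None
            violations.append(str(err))

    lines = []
    for c in constraints:
        observed = sum(
            1 for e in experiments
            if categories[e.id] is not None
            and c.matches(e, categories[e.id]))
        lines.append((c.label, c.expected_count, observed,
                      observed == c.expected_count))

    _, removed = deduplicate(experiments, return_removed=True)
    notes = [f"duplicate of ({e.enhancer}, {e.donor_taxon}, {e.host_taxon}) "
             f"removed: {e.id}" for e in removed]
    return ValidationReport(lines, violations, notes)
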