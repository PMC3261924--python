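"""Pipeline orchestration: the full meta-analysis and the simulation studies.

:func:`run_meta_analysis` recomputes every published aggregate from a
classified experiment table and marks each entry pass/fail against its
published reference value.  The two simulation studies probe the inference
rubric itself: :func:`run_identifiability_study` asks whether
single-mechanism evolutionary regimes land in the categories the rubric
assigns to them, and :func:`run_tempo_study` asks whether misregulation
(cis-trans coevolution) overtakes simple divergence as divergence time
grows — the qualitative trend seen across clades of increasing phylogenetic
distance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from swapmeta.dataset import SwapExperiment
from swapmeta.classify import classify_experiment, group
from swapmeta.simulate import (EvolutionRates, SimulatorConfig,
                               simulate_cohort)
from swapmeta.stats import (ContingencyTable2x2, fisher_exact_two_sided,
                            proportion_summary, z_test_proportions_one_tailed)


@dataclass
class ReportEntry:
    """One published aggregate: computed value vs reference."""

    label: str
    subset: str
    value: float | int | None
    cmp: str  # eq | ge | le | gt | lt | approx2dp
    reference: float | int | None
    detail: Mapping = field(default_factory=dict)
    note: str = ""

    @property
    def computable(self) -> bool:
        return self.value is not None

    @property
    def passed(self) -> bool | None:
        if self.value is None or self.reference is None:
            return None
        v, r = self.value, self.reference
        return {
            "eq": v == r,
            "approx2dp": round(v, 2) == r,
            "ge": v >= r,
            "le": v <= r,
            "gt": v > r,
            "lt": v < r,
        }[self.cmp]

    def to_dict(self) -> dict:
        return {"label": self.label, "subset": self.subset,
                "value": self.value, "cmp": self.cmp,
                "reference": self.reference, "pass": self.passed,
                "detail": dict(self.detail), "note": self.note}


@dataclass
class MetaAnalysisReport:
    """Sectioned collection of reference-keyed entries."""

    sections: dict[str, list[ReportEntry]] = field(default_factory=dict)

    def entries(self) -> list[ReportEntry]:
        return [e for sec in self.sections.values() for e in sec]

    def entry(self, label: str) -> ReportEntry:
        for e in self.entries():
            if e.label == label:
                return e
        raise KeyError(label)

    @property
    def all_passed(self) -> bool:
        return all(e.passed for e in self.entries() if e.passed is not None)

    def to_dict(self) -> dict:
        return {"all_passed": self.all_passed,
                "sections": {name: [e.to_dict() for e in sec]
                             for name, sec in self.sections.items()}}

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, **kw)


def _pct(count: int, total: int) -> float | None:
    if total == 0:
        return None
    return 100.0 * count / total


def run_meta_analysis(experiments: Sequence[SwapExperiment]
                      ) -> MetaAnalysisReport:
    """Recompute every published aggregate over a classified dataset.

    Entries whose defining stratum is absent from the data are marked
    not-computable (value None) and the run continues.
    """
    cats = {e.id: classify_experiment(e) for e in experiments}
    axes = {e.id: group(cats[e.id]) for e in experiments}

    def diverged(e):
        return axes[e.id].conservation_axis == "diverged"

    def in_stratum(label):
        return [e for e in experiments if label in e.strata]

    def count_cat(pool, values):
        return sum(1 for e in pool if cats[e.id].value in values)

    report = MetaAnalysisReport()

    # -- tempo: divergence is rampant --------------------------------------
    n_div, n_all, _ = proportion_summary(list(experiments), diverged)
    ctrl = [e for e in experiments if e.controlled]
    nctrl = [e for e in experiments if not e.controlled]
    c_div, c_all, _ = proportion_summary(ctrl, diverged)
    u_div, u_all, _ = proportion_summary(nctrl, diverged)
    report.sections["tempo_rampant"] = [
        ReportEntry("diverged_overall_pct", "all experiments",
                    _pct(n_div, n_all), "ge", 60.0,
                    {"count": n_div, "total": n_all},
                    "published as 'over 60% (145/230)'"),
        ReportEntry("diverged_controlled_pct", "controlled",
                    None if not c_all else round(_pct(c_div, c_all)),
                    "eq", 72, {"count": c_div, "total": c_all},
                    "published as '105/146; 72%'"),
        ReportEntry("diverged_noncontrolled_pct", "non-controlled",
                    None if not u_all else round(_pct(u_div, u_all)),
                    "eq", 48, {"count": u_div, "total": u_all},
                    "published as '40/84; 48%'"),
    ]

    # -- tempo: accumulation with genetic divergence -----------------------
    close_worm = in_stratum("worm_close_pair")
    obscura = in_stratum("obscura_group")
    if close_worm and obscura:
        cw_cons = sum(1 for e in close_worm if not diverged(e))
        cw_div = len(close_worm) - cw_cons
        ob_cons = sum(1 for e in obscura if not diverged(e))
        ob_div = len(obscura) - ob_cons
        table = ContingencyTable2x2(
            cw_cons, cw_div, ob_cons, ob_div,
            ("close worm pair", "obscura group"), ("conserved", "diverged"))
        p = fisher_exact_two_sided(table).p_value
        report.sections["tempo_accumulation"] = [
            ReportEntry("close_worm_conserved", "worm_close_pair",
                        cw_cons, "eq", 34),
            ReportEntry("close_worm_diverged", "worm_close_pair",
                        cw_div, "eq", 30),
            ReportEntry("obscura_conserved", "obscura_group",
                        ob_cons, "eq", 9),
            ReportEntry("obscura_diverged", "obscura_group",
                        ob_div, "eq", 12),
            ReportEntry("fisher_close_worm_vs_obscura", "2x2 above",
                        p, "approx2dp", 0.46, {"table": table.as_list()}),
        ]
    else:
        report.sections["tempo_accumulation"] = [
            ReportEntry("fisher_close_worm_vs_obscura",
                        "worm_close_pair x obscura_group", None, "approx2dp",
                        0.46, note="stratum missing; not computable")]

    # -- mode: cis alone beats trans alone ---------------------------------
    yellow = [e for e in experiments if e.gene == "yellow"]
    if yellow:
        report.sections["mode_cis_trans"] = [
            ReportEntry("yellow_total", "gene=yellow", len(yellow), "eq", 26),
            ReportEntry("yellow_cis_only", "gene=yellow, C3",
                        count_cat(yellow, {"C3"}), "eq", 15),
            ReportEntry("yellow_trans_only", "gene=yellow, C2",
                        count_cat(yellow, {"C2"}), "eq", 3),
            ReportEntry("yellow_cis_trans", "gene=yellow, C4",
                        count_cat(yellow, {"C4"}), "eq", 4),
        ]
    else:
        report.sections["mode_cis_trans"] = [
            ReportEntry("yellow_cis_only", "gene=yellow", None, "eq", 15,
                        note="no yellow rows; not computable")]
    insects = [e for e in experiments
               if e.host_taxon == "D. melanogaster" and e.controlled]
    if insects:
        n3 = count_cat(insects, {"C3"})
        n2 = count_cat(insects, {"C2"})
        z = z_test_proportions_one_tailed(n3, len(insects), n2, len(insects),
                                          "greater")
        # the published z (5.01) is computed from per-category counts shown
        # only in a figure; the statistic is reported without a reference
        report.sections["mode_cis_trans"].append(
            ReportEntry("insect_c3_vs_c2_ztest", "insect controlled",
                        z.statistic, "gt", 0.0,
                        {"C3": n3, "C2": n2, "n": len(insects),
                         "p_value": z.p_value}))

    # -- tempo and mode: misregulation increases with distance -------------
    entries = []
    strata_rows = [("caenorhabditis", "caenorhabditis", (7, 11, 6), False),
                   ("drosophila", "drosophila", (23, 39, 22), False),
                   ("non_drosophila_insect", "non_drosophila_insect",
                    (11, 6, 21), False),
                   ("non_caenorhabditis_worm", "non_caenorhabditis_worm",
                    (3, None, 20), True)]
    counts: dict[str, tuple[int, int, int]] = {}
    for name, stratum, refs, pool_ncii in strata_rows:
        pool = in_stratum(stratum)
        if not pool:
            entries.append(ReportEntry(f"{name}_row", stratum, None, "eq",
                                       None, note="stratum missing"))
            continue
        if pool_ncii:
            cons = count_cat(pool, {"NC_I"})
            div_mis = count_cat(pool, {"C4", "C5", "NC_II"})
            entries.append(ReportEntry(
                f"{name}_conservation", stratum, cons, "eq", refs[0]))
            entries.append(ReportEntry(
                f"{name}_divergence_misregulation_pooled", stratum, div_mis,
                "eq", refs[2],
                note="published as 10 + 10 across two columns (Categories "
                     "4, 5, II pooled); encoded as one pooled tally of 20"))
        else:
            cons = count_cat(pool, {"C1"})
            div = count_cat(pool, {"C2", "C3"})
            mis = count_cat(pool, {"C4", "C5"})
            counts[name] = (cons, div, mis)
            entries.append(ReportEntry(
                f"{name}_conservation", stratum, cons, "eq", refs[0]))
            entries.append(ReportEntry(
                f"{name}_divergence", stratum, div, "eq", refs[1]))
            entries.append(ReportEntry(
                f"{name}_misregulation", stratum, mis, "eq", refs[2]))
    if "caenorhabditis" in counts and "drosophila" in counts:
        _, wd, wm = counts["caenorhabditis"]
        _, fd, fm = counts["drosophila"]
        t = ContingencyTable2x2(wd, wm, fd, fm,
                                ("Caenorhabditis", "Drosophila"),
                                ("divergence", "misregulation"))
        entries.append(ReportEntry(
            "fisher_worm_vs_fly_mode", "divergence vs misregulation",
            fisher_exact_two_sided(t).p_value, "gt", 0.9,
            {"table": t.as_list()}, "published as p>0.9"))
    if "drosophila" in counts and "non_drosophila_insect" in counts:
        _, fd, fm = counts["drosophila"]
        _, id_, im = counts["non_drosophila_insect"]
        t = ContingencyTable2x2(fd, fm, id_, im,
                                ("Drosophila", "non-Drosophila insect"),
                                ("divergence", "misregulation"))
        entries.append(ReportEntry(
            "fisher_fly_vs_distant_insect_mode",
            "divergence vs misregulation",
            fisher_exact_two_sided(t).p_value, "lt", 0.001,
            {"table": t.as_list()}, "published as p<0.001"))
        if id_:
            entries.append(ReportEntry(
                "distant_insect_misregulation_ratio",
                "non_drosophila_insect", im / id_, "ge", 3.0,
                {"misregulation": im, "divergence": id_},
                "published as 'over three times more often'"))
    report.sections["misregulation_distance"] = entries

    # -- sex- vs tissue-specific fidelity ----------------------------------
    entries = []
    for stratum, label, ref_proper in [
            ("sex_specific_sophophora", "sophophora", 14),
            ("sex_specific_distant_insect", "distant_insect", 3)]:
        pool = in_stratum(stratum)
        if not pool:
            entries.append(ReportEntry(f"{label}_sex_proper", stratum, None,
                                       "eq", ref_proper,
                                       note="stratum missing"))
            continue
        proper = sum(1 for e in pool if e.swap_sex_proper)
        entries.append(ReportEntry(f"{label}_sex_specific_total", stratum,
                                   len(pool), "eq", 15))
        entries.append(ReportEntry(f"{label}_sex_proper", stratum, proper,
                                   "eq", ref_proper))
    distant = in_stratum("sex_specific_distant_insect")
    if distant:
        mis = [e for e in distant if not e.swap_sex_proper]
        tissue_ok = sum(1 for e in mis if e.swap_tissue_proper)
        entries.append(ReportEntry(
            "distant_insect_sex_improper_tissue_proper",
            "sex_specific_distant_insect, sex-misregulated", tissue_ok,
            "eq", 11, {"misregulated": len(mis)},
            "published as '11/12 misregulated enhancers maintained "
            "tissue-specific expression'"))
    report.sections["sex_tissue"] = entries

    # -- expectations vs outcomes ------------------------------------------
    exp_cons = [e for e in experiments if e.expectation == "conservation"]
    exp_div = [e for e in experiments if e.expectation == "divergence"]
    ec_div, ec_all, _ = proportion_summary(exp_cons, diverged)
    ed_div, ed_all, _ = proportion_summary(exp_div, diverged)
    report.sections["expectations"] = [
        ReportEntry("expected_conservation_observed_divergence_pct",
                    "expectation=conservation",
                    None if not ec_all else round(_pct(ec_div, ec_all)),
                    "ge", 50, {"count": ec_div, "total": ec_all},
                    "published as '50% (72/141)'; 100*72/141 rounds to 51"),
        ReportEntry("expected_divergence_observed_divergence_pct",
                    "expectation=divergence",
                    None if not ed_all else _pct(ed_div, ed_all),
                    "ge", 80.0, {"count": ed_div, "total": ed_all},
                    "published as 'over 80% (73/89)'"),
    ]
    return report


# ---------------------------------------------------------------------------
# Simulation studies
# ---------------------------------------------------------------------------

def run_identifiability_study(regimes: Mapping[str, EvolutionRates],
                              n: int = 1000, divergence_time: int = 10,
                              epsilon: float = 0.0, seed: int = 0,
                              config: SimulatorConfig | None = None
                              ) -> pd.DataFrame:
    """Confusion matrix of true mode (rows) x inferred category (columns).

    One cohort per named rate regime; all cohorts share the ancestor and
    divergence time.  Cell counts sum to the number of classified swaps.
    """
    config = config or SimulatorConfig()
    rows = []
    for regime_idx, (name, rates) in enumerate(sorted(regimes.items())):
        truths, coded = simulate_cohort(
            n, [divergence_time], rates, epsilon,
            seed=(seed * 7919 + regime_idx) % (2**31), config=config)
        for sim, exp in zip(truths, coded):
            rows.append({"regime": name, "true_mode": sim.true_mode,
                         "category": classify_experiment(exp).value})
    df = pd.DataFrame(rows)
    matrix = pd.crosstab([df["regime"], df["true_mode"]], df["category"])
    return matrix


#: Default divergence-time grid for the tempo study: a doubling ladder that
#: spans the pre-saturation regime of the default model (beyond ~20 steps the
#: finite pattern space saturates; see the methods note).
DEFAULT_TIME_GRID = (1, 2, 4, 8, 16)

#: Single-mechanism rate regimes used by the identifiability study.
IDENTIFIABILITY_REGIMES = {
    "cis_only": EvolutionRates(site_gain=0.1, site_loss=0.1,
                               trans_domain_change=0.0,
                               coevolution_conserving=0.0,
                               coevolution_diverging=0.0),
    "trans_only": EvolutionRates(site_gain=0.0, site_loss=0.0,
                                 trans_domain_change=0.2,
                                 coevolution_conserving=0.0,
                                 coevolution_diverging=0.0),
    "conserving_coevolution": EvolutionRates(site_gain=0.0, site_loss=0.0,
                                             trans_domain_change=0.0,
                                             coevolution_conserving=0.2,
                                             coevolution_diverging=0.0),
    "diverging_coevolution": EvolutionRates(site_gain=0.0, site_loss=0.0,
                                            trans_domain_change=0.0,
                                            coevolution_conserving=0.0,
                                            coevolution_diverging=0.2),
}


def run_tempo_study(rates: EvolutionRates, time_grid: Sequence[int],
                    n: int = 5000, seed: int = 0, epsilon: float = 0.0,
                    config: SimulatorConfig | None = None) -> pd.DataFrame:
    """Outcome-fraction table over an increasing divergence-time grid.

    Returns one row per grid point with the fractions of swaps classified
    as conserved (C1), divergence (C2/C3) and misregulation (C4/C5), plus
    the misregulation share among diverged outcomes; rows sum to 1 within
    rounding.  Seed-pinned and deterministic.
    """
    if not time_grid or list(time_grid) != sorted(time_grid):
        raise ValueError("time_grid must be non-empty and sorted")
    config = config or SimulatorConfig()
    records = []
    for t in time_grid:
        _, coded = simulate_cohort(n, [t], rates, epsilon,
                                   seed=(seed * 104729 + t) % (2**31),
                                   config=config)
        cats = [classify_experiment(e).value for e in coded]
        cons = sum(c == "C1" for c in cats) / n
        div = sum(c in ("C2", "C3") for c in cats) / n
        mis = sum(c in ("C4", "C5") for c in cats) / n
        diverged = div + mis
        records.append({
            "time": t, "conserved_fraction": cons,
            "divergence_fraction": div, "misregulation_fraction": mis,
            "misregulation_share_of_diverged":
                (mis / diverged) if diverged else 0.0})
    return pd.DataFrame.from_records(records)
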