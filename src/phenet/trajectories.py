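"""Directed disease-trajectory inference from dated first diagnoses.

For each candidate pair (A, B) from the co-occurrence-validated
sub-network — excluding ancestor/descendant pairs of the same phenocode
family, whose ordering is an artefact of the hierarchy rule — a two-step
procedure decides whether A precedes B in a way that is not explained by
age or sex:

1.  A per-event logistic model over every patient's diagnosis sequence,

        logit P(Y_ij = B) = b0 + b1 * I(A before event j) + b2 * Age_ij
                            + b3 * Sex_i,

    fitted over all events up to (and including) each patient's first B.
    Directed pairs with b1 > 0 and Wald p below the Bonferroni threshold
    over the number of fitted models survive.

2.  A one-sided binomial majority-ordering test: among the n dual-
    diagnosed patients (same-date ties excluded), x have A strictly
    first; P(X >= x | Bin(n, 0.5)) is Bonferroni-corrected over the
    step-1 survivors and only the majority direction (x/n > 0.5) is
    kept, so the retained arc set can contain no 2-cycles.

Retained arcs are annotated with the median inter-event time among
patients with that ordering and a follow-up span above the configured
minimum; nodes carry prevalence, the cause-of-death mortality rate
(deaths attributed to the code or a descendant divided by prevalence —
may exceed 1 when death precedes any clinical record), sink flags and
giant-component membership.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import binomtest

from .io_phenome import is_ancestor, phenocode_ancestors, phenocode_level, time_bin

logger = logging.getLogger(__name__)

_DAYS_PER_YEAR = 365.25


@dataclass
class DirectionFit:
    """Result of one Eq-style logistic fit for a directed pair."""

    beta1: float = np.nan
    pvalue: float = np.nan
    ok: bool = False
    reason: str = ""


@dataclass
class DirectedResult:
    """Directed network plus full per-pair statistics."""

    graph: nx.DiGraph
    pair_stats: pd.DataFrame
    nodes: pd.DataFrame
    arcs: pd.DataFrame
    n_models: int = 0
    n_step1: int = 0
    dropped_patients: int = 0
    extra: dict = field(default_factory=dict)


def eligible_pairs(subnet: nx.Graph) -> list[tuple[str, str]]:
    """Sub-network links that are not ancestor/descendant of the same
    phenocode (siblings and unrelated codes are retained)."""
    pairs = []
    for a, b in sorted(tuple(sorted(e)) for e in subnet.edges):
        if is_ancestor(a, b) or is_ancestor(b, a):
            continue
        pairs.append((a, b))
    return pairs


def patient_followup(events: pd.DataFrame) -> pd.Series:
    """Follow-up span per patient in years (last minus first event date)."""
    grouped = events.groupby("patient_id")["date"]
    return (grouped.max() - grouped.min()).dt.days / _DAYS_PER_YEAR


def filter_followup(
    events: pd.DataFrame, min_years: float = 2.0
) -> tuple[pd.DataFrame, int]:
    """Restrict events to patients whose follow-up span exceeds
    ``min_years``; returns the filtered events and the number of
    patients dropped."""
    span = patient_followup(events)
    keep = span.index[span > min_years]
    dropped = int(span.size - keep.size)
    return events[events["patient_id"].isin(keep)], dropped


def build_event_table(
    events: pd.DataFrame, patients: pd.DataFrame, a: str, b: str
) -> pd.DataFrame:
    """Per-event regression rows for the directed pair A -> B.

    One row per (patient, event) over the patient's (date, code)-sorted
    first-diagnosis sequence, truncated at the first B event inclusive;
    patients never diagnosed with B contribute all their events.  The
    outcome indicates whether the event is B; ``prior_a`` indicates an A
    diagnosis at a *strictly* earlier date (a same-date A carries no
    ordering information); ``age`` is the patient's age in years at the
    event and ``sex`` the 0/1 sex code.
    """
    pat = patients.set_index("patient_id")
    ordered = events.sort_values(["patient_id", "date", "phenocode"],
                                 kind="mergesort")
    rows = []
    for pid, group in ordered.groupby("patient_id", sort=False):
        codes = group["phenocode"].to_numpy()
        dates = group["date"].to_numpy()
        birth = pat.at[pid, "birth_date"]
        sex = int(pat.at[pid, "sex"])
        a_date = dates[codes == a][0] if (codes == a).any() else None
        for j in range(len(codes)):
            prior_a = bool(a_date is not None and a_date < dates[j])
            rows.append({
                "patient_id": pid,
                "outcome": int(codes[j] == b),
                "prior_a": int(prior_a),
                "age": (pd.Timestamp(dates[j]) - birth).days / _DAYS_PER_YEAR,
                "sex": sex,
            })
            if codes[j] == b:
                break
    return pd.DataFrame(rows, columns=["patient_id", "outcome", "prior_a",
                                       "age", "sex"])


def fit_direction(
    table: pd.DataFrame,
    include_age: bool = True,
    include_sex: bool = True,
    test: str = "wald",
) -> DirectionFit:
    """Maximum-likelihood logistic fit of the directed-pair model.

    Returns the coefficient of the prior-A indicator and its p-value
    (Wald by default; ``test="lr"`` uses a likelihood-ratio test against
    the model without the indicator).  Degenerate inputs (single-class
    outcome, constant indicator) and non-convergence are flagged
    inestimable rather than raised.
    """
    if table["outcome"].nunique() < 2:
        return DirectionFit(reason="single-class outcome")
    if table["prior_a"].nunique() < 2:
        return DirectionFit(reason="constant prior-A indicator")
    cols = ["prior_a"] + (["age"] if include_age else []) \
        + (["sex"] if include_sex else [])
    exog = sm.add_constant(table[cols].astype(float), has_constant="add")
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(table["outcome"].astype(float), exog).fit(
                disp=0, maxiter=200)
    except Exception as exc:  # separation, singular design, ...
        return DirectionFit(reason=f"fit failed: {exc}")
    if not fit.mle_retvals.get("converged", False):
        return DirectionFit(reason="did not converge")
    beta1 = float(fit.params["prior_a"])
    if test == "lr":
        reduced_cols = [c for c in cols if c != "prior_a"]
        reduced = sm.add_constant(table[reduced_cols].astype(float),
                                  has_constant="add")
        with np.errstate(all="ignore"):
            fit0 = sm.Logit(table["outcome"].astype(float), reduced).fit(
                disp=0, maxiter=200)
        from scipy.stats import chi2
        stat = 2 * (fit.llf - fit0.llf)
        pvalue = float(chi2.sf(max(stat, 0.0), df=1))
    else:
        pvalue = float(fit.pvalues["prior_a"])
    if not np.isfinite(pvalue):
        return DirectionFit(beta1=beta1, reason="non-finite p-value")
    return DirectionFit(beta1=beta1, pvalue=pvalue, ok=True)


def ordering_counts(events: pd.DataFrame, a: str, b: str) -> tuple[int, int]:
    """(x, n): among patients with both diseases and distinct dates, the
    number with A strictly first and the number of such patients."""
    sub = events[events["phenocode"].isin((a, b))]
    wide = sub.pivot_table(index="patient_id", columns="phenocode",
                           values="date", aggfunc="first")
    if a not in wide.columns or b not in wide.columns:
        return 0, 0
    dual = wide.dropna(subset=[a, b])
    untied = dual[dual[a] != dual[b]]
    return int((untied[a] < untied[b]).sum()), int(len(untied))


def binomial_ordering_test(x: int, n: int, p0: float = 0.5) -> float:
    """One-sided upper-tail P(X >= x) under Binomial(n, p0)."""
    if n < 1 or not 0 <= x <= n:
        raise ValueError(f"invalid ordering counts x={x}, n={n}")
    return float(binomtest(x, n, p0, alternative="greater").pvalue)


def median_interval(
    events: pd.DataFrame, a: str, b: str, min_followup_years: float = 2.0
) -> float:
    """Median years from A to B among patients with that ordering and a
    follow-up span exceeding the minimum; NaN when no patient qualifies."""
    span = patient_followup(events)
    sub = events[events["phenocode"].isin((a, b))]
    wide = sub.pivot_table(index="patient_id", columns="phenocode",
                           values="date", aggfunc="first")
    if a not in wide.columns or b not in wide.columns:
        return float("nan")
    dual = wide.dropna(subset=[a, b])
    dual = dual[dual[a] < dual[b]]
    dual = dual[span.loc[dual.index] > min_followup_years]
    if dual.empty:
        return float("nan")
    return float((dual[b] - dual[a]).dt.days.median() / _DAYS_PER_YEAR)


def mortality_rates(
    patients: pd.DataFrame, codes, prevalence: pd.Series
) -> pd.Series:
    """Cause-of-death count divided by prevalence, per disease.

    A death is attributed to a disease when the disease's code or any
    descendant of it appears among the patient's cause-of-death codes;
    deaths without a prior clinical record of the disease still count in
    the numerator, so rates above 1 are possible (they are logged, not
    clipped).
    """
    deaths = {code: 0 for code in codes}
    cause_lists = patients["cod_phenocodes"].fillna("")
    for causes in cause_lists:
        if not causes:
            continue
        attributed = set()
        for cause in causes.split(";"):
            attributed.add(cause)
            attributed.update(phenocode_ancestors(cause))
        for code in deaths:
            if code in attributed:
                deaths[code] += 1
    rates = {}
    for code in codes:
        prev = int(prevalence.get(code, 0))
        rates[code] = deaths[code] / prev if prev else float("nan")
        if prev and rates[code] > 1:
            logger.info("mortality rate > 1 for %s (%d deaths, prevalence %d)",
                        code, deaths[code], prev)
    return pd.Series(rates)


def build_directed_network(
    subnet: nx.Graph,
    events: pd.DataFrame,
    patients: pd.DataFrame,
    alpha1: float = 0.05,
    alpha2: float = 0.05,
    min_followup_years: float = 2.0,
    include_age: bool = True,
    followup_filter_all: bool = True,
    test: str = "wald",
) -> DirectedResult:
    """Run the two-step directed-pair procedure and assemble the network.

    ``events`` must already be hierarchy-expanded and restricted to the
    network's disease universe.  With ``followup_filter_all`` (default)
    the minimum-follow-up filter applies to the whole stage, not only to
    the interval estimates.  Step-1 and step-2 Bonferroni denominators
    are the realized numbers of fitted models and of step-1 survivors.
    """
    if followup_filter_all:
        events, dropped = filter_followup(events, min_followup_years)
    else:
        dropped = 0

    candidates = eligible_pairs(subnet)
    records = []
    fits: dict[tuple[str, str], DirectionFit] = {}
    for a, b in candidates:
        for first, second in ((a, b), (b, a)):
            table = build_event_table(events, patients, first, second)
            fits[(first, second)] = fit_direction(table, include_age=include_age,
                                                  test=test)
    n_models = sum(f.ok for f in fits.values())
    thr1 = alpha1 / n_models if n_models else float("nan")

    step1 = [pair for pair, f in fits.items()
             if f.ok and f.beta1 > 0 and f.pvalue < thr1]
    thr2 = alpha2 / len(step1) if step1 else float("nan")

    kept: dict[tuple[str, str], dict] = {}
    step2_info: dict[tuple[str, str], tuple] = {}
    for first, second in step1:
        x, n = ordering_counts(events, first, second)
        if n == 0:
            step2_info[(first, second)] = (x, n, np.nan, False)
            continue
        p = binomial_ordering_test(x, n)
        passed = p < thr2 and x / n > 0.5
        step2_info[(first, second)] = (x, n, p, passed)
        if passed:
            kept[(first, second)] = {
                "median_years": median_interval(events, first, second,
                                                min_followup_years),
                "x": x, "n": n, "binom_p": p,
            }

    for (first, second), f in sorted(fits.items()):
        x, n, p, passed = step2_info.get((first, second), (np.nan,) * 3 + (False,))
        records.append({
            "first": first, "second": second,
            "beta1": f.beta1, "beta1_p": f.pvalue,
            "estimable": f.ok, "drop_reason": f.reason,
            "step1_pass": (first, second) in step1,
            "x": x, "n_dual": n, "binom_p": p,
            "kept": passed and (first, second) in kept,
        })
    pair_stats = pd.DataFrame(records)

    graph = nx.DiGraph()
    for (first, second), info in kept.items():
        graph.add_edge(first, second,
                       median_years=info["median_years"],
                       time_bin=(time_bin(info["median_years"])
                                 if np.isfinite(info["median_years"]) else 0),
                       x=info["x"], n_dual=info["n"], binom_p=info["binom_p"])

    prevalence = events.groupby("phenocode")["patient_id"].nunique()
    node_codes = sorted(graph.nodes)
    rates = mortality_rates(patients, node_codes, prevalence) if node_codes \
        else pd.Series(dtype=float)
    giant = max(nx.weakly_connected_components(graph),
                key=lambda s: (len(s), min(s))) if node_codes else set()
    node_rows = []
    for code in node_codes:
        sink = graph.out_degree(code) == 0
        graph.nodes[code].update(
            prevalence=int(prevalence.get(code, 0)),
            mortality=float(rates[code]),
            sink=bool(sink),
            level=phenocode_level(code),
            category=subnet.nodes[code].get("category", ""),
            in_giant=code in giant,
        )
        node_rows.append({
            "Phenocode": code,
            "Disease": subnet.nodes[code].get("description", code),
            "Prev": int(prevalence.get(code, 0)),
            "Dprev": float(rates[code]),
            "Category": subnet.nodes[code].get("category", ""),
            "Sink": int(sink),
            "Level": phenocode_level(code),
        })
    nodes = pd.DataFrame(node_rows, columns=["Phenocode", "Disease", "Prev",
                                             "Dprev", "Category", "Sink", "Level"])

    arc_rows = []
    for first, second, data in sorted(graph.edges(data=True)):
        arc_rows.append({"First": first, "Second": second,
                         "MedianTime": data["median_years"],
                         "Time": data["time_bin"]})
    arcs = pd.DataFrame(arc_rows, columns=["First", "Second", "MedianTime", "Time"])

    return DirectedResult(graph=graph, pair_stats=pair_stats, nodes=nodes,
                          arcs=arcs, n_models=n_models, n_step1=len(step1),
                          dropped_patients=dropped)
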