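"""Cohort co-occurrence statistics and the co-occurrence-validated
sub-network.

For every pair of diseases the 2x2 table over N cohort participants is
summarised by the Matthews correlation coefficient,

    MCC_ij = (C_ij N - P_i P_j) / sqrt(P_i P_j (N - P_i)(N - P_j)),

the Pearson correlation of the two binary disease indicators, with C_ij
the number of patients carrying both diseases and P_i, P_j the
per-disease patient counts.  Enrichment is tested with a one-sided
Fisher exact test (upper hypergeometric tail at fixed margins) and
Bonferroni-corrected over the number of genetic-network links tested.

Pairs can be counted in two modes: *unordered* (all 2-subsets of each
patient's disease set) and *ordered* (only consecutive pairs of the
patient's date-sorted first-diagnosis sequence; simultaneous diagnoses
carry no temporal information and produce no pair between the tied
codes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .io_phenome import phenocode_ancestors

logger = logging.getLogger(__name__)


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-test significance threshold controlling the family-wise error
    rate at ``alpha`` over ``n_tests`` tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def expand_hierarchy(
    events: pd.DataFrame, universe, metadata: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Apply the phenocode hierarchy rule to raw first-diagnosis events.

    A diagnosis of a level-1/2 code implies a diagnosis of each ancestor
    code at the same date.  For every (patient, code), the
    first-diagnosis date is the minimum over explicit and implied dates.
    Events whose code is unknown to ``metadata`` (when given) are dropped
    with a warning; the returned events are restricted to codes in
    ``universe`` (ancestors outside it are not materialised).
    """
    universe = set(universe)
    events = events.copy()
    if metadata is not None:
        known = set(metadata["phenocode"])
        bad = ~events["phenocode"].isin(known)
        if bad.any():
            logger.warning("expand_hierarchy: dropping %d events with codes "
                           "absent from the metadata: %s", int(bad.sum()),
                           sorted(events.loc[bad, "phenocode"].unique())[:10])
            events = events.loc[~bad]

    frames = [events]
    for code in events["phenocode"].unique():
        for anc in phenocode_ancestors(code):
            if anc in universe:
                implied = events.loc[events["phenocode"] == code].copy()
                implied["phenocode"] = anc
                frames.append(implied)
    expanded = pd.concat(frames, ignore_index=True)
    expanded = expanded[expanded["phenocode"].isin(universe)]
    expanded = (expanded.groupby(["patient_id", "phenocode"], as_index=False)["date"]
                .min())
    return expanded.sort_values(["patient_id", "date", "phenocode"],
                                kind="mergesort").reset_index(drop=True)


def mcc(c: int, p_i: int, p_j: int, n: int) -> float:
    """Matthews correlation coefficient of two binary disease indicators."""
    if p_i in (0, n) or p_j in (0, n):
        raise ValueError(f"MCC undefined for degenerate margins "
                         f"P_i={p_i}, P_j={p_j}, N={n}")
    if c > min(p_i, p_j):
        raise ValueError(f"C={c} exceeds min(P_i, P_j)=({p_i}, {p_j})")
    num = c * n - p_i * p_j
    den = np.sqrt(float(p_i) * p_j * (n - p_i) * (n - p_j))
    return float(num / den)


def fisher_one_sided(c: int, p_i: int, p_j: int, n: int) -> float:
    """Upper-tail (enrichment) Fisher exact p-value, P(X >= C) for the
    hypergeometric distribution at fixed margins."""
    cells = (c, p_i - c, p_j - c, n - p_i - p_j + c)
    if any(v < 0 for v in cells):
        raise ValueError(f"negative contingency cell from C={c}, P_i={p_i}, "
                         f"P_j={p_j}, N={n}")
    return float(hypergeom.sf(c - 1, n, p_i, p_j))


def pair_counts(
    events: pd.DataFrame, mode: str = "unordered", n_patients: int | None = None
) -> tuple[dict[tuple[str, str], int], pd.Series, int]:
    """Count disease-pair co-occurrence over patients.

    Returns ``(counts, prevalence, n)``.  In unordered mode the count
    keys are sorted code pairs and every 2-subset of a patient's disease
    set contributes; in ordered mode the keys are (first, second) in
    diagnosis order and only consecutive pairs of the patient's
    date-sorted sequence contribute, skipping tied dates.  ``prevalence``
    is the per-disease patient count in both modes.  ``n`` is the cohort
    participant count ``n_patients`` when given (the MCC/Fisher N is the
    whole cohort, including participants with no recorded disease);
    otherwise it falls back to the number of patients with at least one
    event.
    """
    if mode not in ("unordered", "ordered"):
        raise ValueError(f"unknown mode {mode!r}")
    prevalence = events.groupby("phenocode")["patient_id"].nunique()
    observed = int(events["patient_id"].nunique())
    n = observed if n_patients is None else int(n_patients)
    if n < observed:
        raise ValueError(f"n_patients = {n} is smaller than the {observed} "
                         "patients present in the events")
    counts: dict[tuple[str, str], int] = {}
    if mode == "unordered":
        for _, codes in events.groupby("patient_id")["phenocode"]:
            for pair in combinations(sorted(codes), 2):
                counts[pair] = counts.get(pair, 0) + 1
    else:
        ordered = events.sort_values(["patient_id", "date", "phenocode"],
                                     kind="mergesort")
        for _, group in ordered.groupby("patient_id"):
            codes = group["phenocode"].to_numpy()
            dates = group["date"].to_numpy()
            for k in range(len(codes) - 1):
                if dates[k] == dates[k + 1]:
                    continue  # tie: no temporal information
                pair = (codes[k], codes[k + 1])
                counts[pair] = counts.get(pair, 0) + 1
    return counts, prevalence, n


@dataclass
class CohortPairStats:
    """Pair co-occurrence counts plus the machinery to score any pair.

    Prevalences (the MCC margins) are per-disease patient counts in both
    modes; ordered mode only changes which co-occurrences are counted in
    C.  Pairs with degenerate margins (a disease seen in no patient or in
    every patient) cannot be scored; they are recorded in ``skipped``.
    """

    counts: dict[tuple[str, str], int]
    prevalence: pd.Series
    n: int
    mode: str = "unordered"
    skipped: list[tuple[str, str]] = field(default_factory=list)

    @classmethod
    def from_events(cls, events: pd.DataFrame, mode: str = "unordered",
                    n_patients: int | None = None) -> "CohortPairStats":
        counts, prevalence, n = pair_counts(events, mode=mode,
                                            n_patients=n_patients)
        return cls(counts=counts, prevalence=prevalence, n=n, mode=mode)

    def _count(self, a: str, b: str) -> int:
        key = tuple(sorted((a, b))) if self.mode == "unordered" else (a, b)
        return self.counts.get(key, 0)

    def stat(self, a: str, b: str) -> dict | None:
        """MCC and Fisher p for one pair; None when a margin is degenerate
        (pair skipped and logged)."""
        p_i = int(self.prevalence.get(a, 0))
        p_j = int(self.prevalence.get(b, 0))
        if p_i in (0, self.n) or p_j in (0, self.n):
            self.skipped.append((a, b))
            logger.debug("pair (%s, %s) skipped: degenerate margins", a, b)
            return None
        c = self._count(a, b)
        if self.n - p_i - p_j + c < 0:
            # ordered-mode C (consecutive pairs only) can fall below the
            # hypergeometric lower bound P_i + P_j - N in tiny cohorts;
            # such a table is not scorable at fixed margins
            self.skipped.append((a, b))
            logger.debug("pair (%s, %s) skipped: infeasible 2x2 table "
                         "(C=%d, P_i=%d, P_j=%d, N=%d)", a, b, c, p_i, p_j,
                         self.n)
            return None
        return {
            "C": c, "P_i": p_i, "P_j": p_j, "N": self.n,
            "mcc": mcc(c, p_i, p_j, self.n),
            "fisher_p": fisher_one_sided(c, p_i, p_j, self.n),
        }

    def table(self, pairs=None) -> pd.DataFrame:
        """Per-pair statistics table; defaults to all counted pairs."""
        if pairs is None:
            pairs = sorted(self.counts)
        rows = []
        for a, b in pairs:
            s = self.stat(a, b)
            if s is None:
                continue
            rows.append({"code_a": a, "code_b": b, **s})
        return pd.DataFrame(
            rows, columns=["code_a", "code_b", "C", "P_i", "P_j", "N",
                           "mcc", "fisher_p"])


def link_significance(
    phenet: nx.Graph,
    stats: CohortPairStats,
    alpha: float = 0.05,
) -> tuple[dict[tuple[str, str], dict], float, int]:
    """Score every network link against the cohort at the Bonferroni level.

    Returns ``(results, threshold, n_tests)``.  In unordered mode each
    link is one test (m = number of scorable links).  In ordered mode
    each link yields two directed tests and the Bonferroni denominator is
    2m; a link counts as significant when EITHER direction passes.  Links
    with degenerate margins are treated as not significant and excluded
    from the denominator (the tested and total link counts are logged).
    """
    results: dict[tuple[str, str], dict] = {}
    for a, b in phenet.edges:
        key = tuple(sorted((a, b)))
        if stats.mode == "unordered":
            s = stats.stat(*key)
            if s is not None:
                results[key] = {"tests": [s]}
        else:
            directed = [s for s in (stats.stat(key[0], key[1]),
                                    stats.stat(key[1], key[0])) if s is not None]
            if directed:
                results[key] = {"tests": directed}
    n_tests = sum(len(r["tests"]) for r in results.values())
    logger.info("link_significance: %d tests over %d of %d links (mode=%s)",
                n_tests, len(results), phenet.number_of_edges(), stats.mode)
    threshold = bonferroni_threshold(alpha, max(1, n_tests))
    for r in results.values():
        r["significant"] = any(t["fisher_p"] < threshold for t in r["tests"])
        best = min(r["tests"], key=lambda t: t["fisher_p"])
        r.update(best)
    return results, threshold, n_tests


def extract_sub_phenet(
    phenet: nx.Graph,
    stats: CohortPairStats,
    alpha: float = 0.05,
) -> nx.Graph:
    """Keep exactly the network links with Bonferroni-significant
    co-occurrence; singletons are removed and the link weight attribute
    becomes the MCC (the genetic weight is kept as ``beta_weight``)."""
    results, _, _ = link_significance(phenet, stats, alpha=alpha)
    sub = nx.Graph()
    for (a, b), r in results.items():
        if not r["significant"]:
            continue
        data = dict(phenet.edges[a, b])
        data["beta_weight"] = data.pop("weight")
        data.update(weight=r["mcc"], mcc=r["mcc"], C=r["C"],
                    fisher_p=r["fisher_p"])
        sub.add_edge(a, b, **data)
    for node in sub.nodes:
        sub.nodes[node].update(phenet.nodes[node])
    return sub


def sub_phenet_edgelist(sub: nx.Graph) -> pd.DataFrame:
    """S4-schema edge list of a co-occurrence-validated sub-network."""
    rows = []
    for a, b, data in sorted(sub.edges(data=True)):
        rows.append({
            "From": sub.nodes[a].get("description", a),
            "To": sub.nodes[b].get("description", b),
            "N": data["n_shared"],
            "betaMerged": data["beta_weight"],
            "FromCode": a,
            "ToCode": b,
            "SNPs": ";".join(data["shared_units"]),
            "C": data["C"],
            "MCC": data["mcc"],
            "fisherp": data["fisher_p"],
        })
    return pd.DataFrame(
        rows, columns=["From", "To", "N", "betaMerged", "FromCode", "ToCode",
                       "SNPs", "C", "MCC", "fisherp"])
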