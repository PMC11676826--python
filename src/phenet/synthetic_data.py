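"""Synthetic PheWAS summary statistics, LD structure and cohort generator.

Every downstream stage of the pipeline consumes either PheWAS top-hit
summary statistics, a pairwise LD table, or dated first-diagnosis records
for a cohort.  Real sources for these (UK Biobank SAIGE PheWAS files,
LDlink extracts, linked registry data) are access-restricted, so this
module generates all three with *planted* structure and returns truth
records sufficient to score recovery:

* shared SNPs or LD-blocks between chosen disease pairs (drives the
  genetic network),
* pairwise co-occurrence at a chosen relative risk (drives the
  comorbidity overlay),
* directed orderings with log-normal inter-event gaps (drives the
  trajectory stage),
* optional per-disease onset-age distributions, age-dependent prevalence
  and sex effects (gives the covariate-adjusted regression something to
  adjust for),
* per-disease death attribution.

All generators are pure functions of the configuration (which carries
the seed); two runs with the same configuration are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io_phenome import PHENOCODE_RE, PhenocodeFormatError

#: The 17 disease categories of the phenocode system.
CATEGORIES = (
    "circulatory system",
    "congenital anomalies",
    "dermatologic",
    "digestive",
    "endocrine/metabolic",
    "genitourinary",
    "hematopoietic",
    "infectious diseases",
    "injuries & poisonings",
    "mental disorders",
    "musculoskeletal",
    "neoplasms",
    "neurological",
    "respiratory",
    "sense organs",
    "symptoms",
    "pregnancy complications",
)

_DAYS_PER_YEAR = 365.25

# Sub-stream identifiers so the three generators draw independent streams
# from one configuration seed.
_STREAM_STATS = 1
_STREAM_LD = 2
_STREAM_COHORT = 3


class ConfigError(ValueError):
    """The simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class SharedPairSpec:
    """Plant ``n_units`` shared genetic units between two diseases.

    When ``via_block`` is set the unit is an LD-block in which the two
    diseases are associated with *different* member SNPs; otherwise both
    diseases are associated with the same bare SNP.
    """

    code_a: str
    code_b: str
    n_units: int = 1
    beta_low: float = 0.1
    beta_high: float = 0.5
    via_block: bool = False


@dataclass(frozen=True)
class ComorbiditySpec:
    """Raise P(B | A) to ``min(1, rr * P(B))`` for one disease pair."""

    code_a: str
    code_b: str
    rr: float = 3.0


@dataclass(frozen=True)
class OrderingSpec:
    """Among dual-diagnosed patients, ``first`` precedes ``second`` with
    probability ``p_first``; the inter-event gap is log-normal with the
    given median (years) and log-scale spread."""

    first: str
    second: str
    p_first: float = 0.9
    median_gap_years: float = 2.0
    sigma: float = 0.5


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults emulate the shape of the real inputs at desk scale: a
    registry-linked cohort observed from August 1987 to June 2017 with
    birth cohorts spanning 1920-1985, per-disease lifetime prevalences
    around 10%, PheWAS rows passing p < 1e-6 and MAF >= 0.1%, and
    LD-blocks of a few SNPs within 500 kb at r^2 >= 0.8.
    """

    n_diseases: int = 12
    n_categories: int = 17
    hierarchy_depth: int = 0
    disease_codes: list[str] | None = None
    n_snps: int = 300
    snps_per_disease: int = 2
    planted_shared_pairs: list[SharedPairSpec] = field(default_factory=list)
    block_size: int = 3
    block_span: int = 200_000
    block_r2: tuple[float, float] = (0.8, 1.0)
    n_patients: int = 5000
    baseline_prevalence: float | dict[str, float] = 0.1
    planted_comorbidity: list[ComorbiditySpec] = field(default_factory=list)
    planted_orderings: list[OrderingSpec] = field(default_factory=list)
    window_start: str = "1987-08-01"
    window_end: str = "2017-06-30"
    birth_year_range: tuple[int, int] = (1920, 1985)
    onset_age: dict[str, tuple[float, float]] = field(default_factory=dict)
    presence_age_slope: dict[str, float] = field(default_factory=dict)
    sex_effect: dict[str, float] = field(default_factory=dict)
    death_rates: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- derived disease universe -----------------------------------------

    def codes(self) -> list[str]:
        """Disease phenocodes, generated unless supplied explicitly.

        Auto-generated codes start at "101"; with ``hierarchy_depth`` >= 1
        every third code also receives a ".1" child, and with depth 2 a
        ".11" grandchild, consuming the disease budget.
        """
        if self.disease_codes is not None:
            return list(self.disease_codes)
        codes: list[str] = []
        root = 101
        while len(codes) < self.n_diseases:
            codes.append(str(root))
            if self.hierarchy_depth >= 1 and root % 3 == 0 and len(codes) < self.n_diseases:
                codes.append(f"{root}.1")
                if self.hierarchy_depth >= 2 and len(codes) < self.n_diseases:
                    codes.append(f"{root}.11")
            root += 1
        return codes

    def prevalence(self, code: str) -> float:
        if isinstance(self.baseline_prevalence, dict):
            return self.baseline_prevalence[code]
        return float(self.baseline_prevalence)

    def validate(self) -> None:
        codes = set(self.codes())
        for code in codes:
            if not PHENOCODE_RE.match(code):
                raise PhenocodeFormatError(f"malformed phenocode: {code!r}")
        for spec in self.planted_shared_pairs:
            if spec.code_a not in codes or spec.code_b not in codes:
                raise ConfigError(f"shared pair {spec.code_a}-{spec.code_b} "
                                  "references unknown disease codes")
            if spec.n_units < 1:
                raise ConfigError("a shared pair must plant at least one unit")
        snp_budget = self.n_diseases * self.snps_per_disease + sum(
            s.n_units * (self.block_size if s.via_block else 1)
            for s in self.planted_shared_pairs
        )
        if snp_budget > self.n_snps:
            raise ConfigError(
                f"requested private + shared loci need {snp_budget} SNPs "
                f"but n_snps = {self.n_snps}"
            )
        lo, hi = self.block_r2
        if not (0.8 <= lo <= hi <= 1.0):
            raise ConfigError("block r2 range must lie within [0.8, 1.0]")
        for code in codes:
            if not 0.0 <= self.prevalence(code) <= 1.0:
                raise ConfigError(f"prevalence for {code} outside [0, 1]")
        targets = [s.code_b for s in self.planted_comorbidity]
        if len(targets) != len(set(targets)):
            raise ConfigError("a disease may be the target of at most one "
                              "planted comorbidity")
        for spec in self.planted_comorbidity:
            if spec.rr < 1.0:
                raise ConfigError("planted relative risks must be >= 1")
            if {spec.code_a, spec.code_b} - codes:
                raise ConfigError(f"comorbidity {spec.code_a}-{spec.code_b} "
                                  "references unknown disease codes")
            if spec.code_b not in self.presence_age_slope:
                if spec.rr * self.prevalence(spec.code_b) > 1.0:
                    raise ConfigError(
                        f"infeasible comorbidity: RR {spec.rr} pushes "
                        f"P({spec.code_b}|{spec.code_a}) above 1"
                    )
        for spec in self.planted_orderings:
            if not 0.0 <= spec.p_first <= 1.0:
                raise ConfigError("ordering probability outside [0, 1]")
            if spec.median_gap_years <= 0:
                raise ConfigError("inter-event gap median must be positive")

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        data = dict(data)
        data["planted_shared_pairs"] = [
            SharedPairSpec(**d) for d in data.get("planted_shared_pairs", [])]
        data["planted_comorbidity"] = [
            ComorbiditySpec(**d) for d in data.get("planted_comorbidity", [])]
        data["planted_orderings"] = [
            OrderingSpec(**d) for d in data.get("planted_orderings", [])]
        for key in ("block_r2", "birth_year_range"):
            if key in data:
                data[key] = tuple(data[key])
        if "onset_age" in data:
            data["onset_age"] = {k: tuple(v) for k, v in data["onset_age"].items()}
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SummaryTruth:
    """Planted genetic ground truth.

    ``shared_units`` maps each planted unordered pair (as a sorted tuple)
    to the list of planted unit descriptors: ``("snp", snp_id)`` or
    ``("block", (snp_id, ...))``.
    """

    shared_units: dict[tuple[str, str], list[tuple]]

    def expected_edges(self) -> set[tuple[str, str]]:
        return set(self.shared_units)

    def n_shared(self, code_a: str, code_b: str) -> int:
        key = tuple(sorted((code_a, code_b)))
        return len(self.shared_units.get(key, []))


@dataclass
class CohortTruth:
    """Planted cohort ground truth (prevalence targets, comorbidity
    relative risks and ordering probabilities)."""

    prevalence: dict[str, float]
    comorbidity: list[ComorbiditySpec]
    orderings: list[OrderingSpec]


def phenocode_metadata(config: SimulationConfig) -> pd.DataFrame:
    """Metadata table for the simulated diseases.

    Categories cycle through the phenocode category names; a child code
    inherits the category of its level-0 root so planted hierarchies look
    like real phenocode families.
    """
    codes = config.codes()
    roots = sorted({c.partition(".")[0] for c in codes})
    cats = CATEGORIES[:config.n_categories]
    root_cat = {r: cats[i % len(cats)] for i, r in enumerate(roots)}
    rows = [
        {"phenocode": c,
         "description": f"Synthetic disease {c}",
         "category": root_cat[c.partition(".")[0]]}
        for c in codes
    ]
    return pd.DataFrame(rows, columns=["phenocode", "description", "category"])


def _snp_scaffold(n: int) -> pd.DataFrame:
    """Deterministic SNP positions: 2-Mb strides across chromosomes 1-22
    so that unplanted SNPs can never fall within 500 kb of one another."""
    idx = np.arange(n)
    chrom = (idx % 22 + 1).astype(str)
    pos = (idx // 22) * 2_000_000 + 50_000
    return pd.DataFrame({
        "snp_id": [f"rs{100 + i}" for i in idx],
        "chrom": chrom,
        "pos": pos.astype(int),
        "block_id": [""] * n,
    })


def simulate_summary_stats(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SummaryTruth]:
    """Generate PheWAS top-hit rows with planted shared units.

    Returns ``(associations, snp_table, truth)``.  Every association row
    satisfies the input filters (p < 1e-6, MAF >= 0.1%); every planted
    pair shares exactly the requested units and non-planted pairs share
    none.  Block members are packed within the configured span (well
    inside 500 kb) on one chromosome.
    """
    rng = np.random.default_rng([config.seed, _STREAM_STATS])
    snps = _snp_scaffold(config.n_snps)
    free = list(snps.index)  # consumed front-to-back, scaffold is pre-spread

    def draw_beta(lo: float, hi: float) -> float:
        return float(rng.uniform(lo, hi) * rng.choice([-1.0, 1.0]))

    def draw_row(snp_idx: int, code: str, lo: float = 0.1, hi: float = 0.5) -> dict:
        return {
            "snp_id": snps.at[snp_idx, "snp_id"],
            "chrom": snps.at[snp_idx, "chrom"],
            "pos": int(snps.at[snp_idx, "pos"]),
            "phenocode": code,
            "beta": draw_beta(lo, hi),
            "pval": float(10.0 ** -rng.uniform(6.5, 20.0)),
            "maf": float(rng.uniform(0.01, 0.5)),
        }

    rows: list[dict] = []
    truth: dict[tuple[str, str], list[tuple]] = {}
    block_counter = 0

    for spec in config.planted_shared_pairs:
        key = tuple(sorted((spec.code_a, spec.code_b)))
        truth.setdefault(key, [])
        for _ in range(spec.n_units):
            if spec.via_block:
                # one block: members packed on one chromosome, each of the
                # two diseases associated with a different member SNP
                anchor = free.pop(0)
                block_counter += 1
                block_id = f"blk{block_counter}"
                chrom = snps.at[anchor, "chrom"]
                base = int(snps.at[anchor, "pos"])
                members = []
                for k in range(config.block_size):
                    if k == 0:
                        idx = anchor
                    else:
                        idx = free.pop(0)
                        snps.at[idx, "chrom"] = chrom
                        snps.at[idx, "pos"] = base + k * (
                            config.block_span // max(1, config.block_size - 1))
                    snps.at[idx, "block_id"] = block_id
                    members.append(idx)
                rows.append(draw_row(members[0], spec.code_a,
                                     spec.beta_low, spec.beta_high))
                rows.append(draw_row(members[-1], spec.code_b,
                                     spec.beta_low, spec.beta_high))
                truth[key].append(
                    ("block", tuple(snps.at[m, "snp_id"] for m in members)))
            else:
                idx = free.pop(0)
                rows.append(draw_row(idx, spec.code_a,
                                     spec.beta_low, spec.beta_high))
                rows.append(draw_row(idx, spec.code_b,
                                     spec.beta_low, spec.beta_high))
                truth[key].append(("snp", snps.at[idx, "snp_id"]))

    for code in config.codes():
        for _ in range(config.snps_per_disease):
            idx = free.pop(0)
            rows.append(draw_row(idx, code))

    associations = pd.DataFrame(
        rows, columns=["snp_id", "chrom", "pos", "phenocode", "beta", "pval", "maf"])
    return associations, snps, SummaryTruth(shared_units=truth)


def simulate_ld_r2(config: SimulationConfig, snp_table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise r-squared rows for the planted LD-blocks.

    All within-block pairs get r^2 drawn from the configured range (at
    least 0.8); SNP pairs outside a common block are omitted, i.e.
    treated as r^2 = 0.  The emitted table lists each pair once; lookups
    must treat it as symmetric.
    """
    rng = np.random.default_rng([config.seed, _STREAM_LD])
    lo, hi = config.block_r2
    rows = []
    for _, group in snp_table[snp_table["block_id"] != ""].groupby("block_id"):
        ids = list(group["snp_id"])
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                rows.append({"snp1": ids[i], "snp2": ids[j],
                             "r2": float(rng.uniform(lo, hi))})
    return pd.DataFrame(rows, columns=["snp1", "snp2", "r2"])


def _presence_probability(
    config: SimulationConfig, code: str, age_mid: np.ndarray, sex: np.ndarray,
) -> np.ndarray:
    """Per-patient presence probability for one disease.

    Baseline prevalence optionally modified on the log-odds scale by the
    patient's age at the window midpoint (per decade from age 50) and by
    sex; modifiers default to zero.
    """
    p = np.clip(config.prevalence(code), 1e-12, 1 - 1e-12)
    logit = np.log(p / (1 - p))
    logit = logit + config.presence_age_slope.get(code, 0.0) * (age_mid - 50.0) / 10.0
    logit = logit + config.sex_effect.get(code, 0.0) * sex
    return 1.0 / (1.0 + np.exp(-logit))


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, CohortTruth]:
    """Generate the patient table and dated first-diagnosis events.

    Presence is Bernoulli per disease (age/sex-modified when configured);
    planted comorbidity redraws the target disease conditional on the
    source with probability ``min(1, RR * p)``; planted orderings assign
    the two dates of dual-diagnosed patients so that the configured
    direction holds with probability ``p_first`` and the gap is
    log-normal (strictly positive, so tied dates cannot occur within a
    planted pair).  Deaths are attributed per-disease with the configured
    rates, dated after the patient's last event.
    """
    rng = np.random.default_rng([config.seed, _STREAM_COHORT])
    codes = config.codes()
    n = config.n_patients
    win_start = pd.Timestamp(config.window_start)
    win_end = pd.Timestamp(config.window_end)
    window_days = (win_end - win_start).days

    ids = np.array([f"P{i:06d}" for i in range(n)])
    sex = rng.integers(0, 2, size=n)
    y0, y1 = config.birth_year_range
    birth = pd.Timestamp(f"{y0}-01-01") + pd.to_timedelta(
        rng.integers(0, (y1 - y0) * 365, size=n), unit="D")
    window_mid = win_start + (win_end - win_start) / 2
    age_mid = (window_mid - birth).days / _DAYS_PER_YEAR

    # presence draws, then comorbidity overrides for target diseases
    present = {
        code: rng.random(n) < _presence_probability(config, code, age_mid, sex)
        for code in codes
    }
    for spec in config.planted_comorbidity:
        p_b = _presence_probability(config, spec.code_b, age_mid, sex)
        boosted = np.minimum(1.0, spec.rr * p_b)
        prob = np.where(present[spec.code_a], boosted, p_b)
        present[spec.code_b] = rng.random(n) < prob

    # diagnosis dates: uniform in the observation window unless an
    # onset-age distribution is configured for the disease
    date_offset = {}
    for code in codes:
        if code in config.onset_age:
            mean, sd = config.onset_age[code]
            age = rng.normal(mean, sd, size=n)
            offset = (birth - win_start).days / 1.0 + age * _DAYS_PER_YEAR
            date_offset[code] = np.clip(offset, 0, window_days).round()
        else:
            date_offset[code] = rng.integers(0, window_days + 1, size=n).astype(float)

    # ordering overrides for dual-diagnosed patients of planted pairs
    for spec in config.planted_orderings:
        dual = present[spec.first] & present[spec.second]
        k = int(dual.sum())
        if k == 0:
            continue
        first_wins = rng.random(k) < spec.p_first
        gap_years = spec.median_gap_years * np.exp(spec.sigma * rng.normal(size=k))
        gap_days = np.maximum(1, np.round(gap_years * _DAYS_PER_YEAR))
        gap_days = np.minimum(gap_days, window_days - 1)
        early = np.floor(rng.random(k) * (window_days - gap_days))
        late = early + gap_days
        idx = np.flatnonzero(dual)
        off_first = date_offset[spec.first].copy()
        off_second = date_offset[spec.second].copy()
        off_first[idx] = np.where(first_wins, early, late)
        off_second[idx] = np.where(first_wins, late, early)
        date_offset[spec.first] = off_first
        date_offset[spec.second] = off_second

    frames = []
    for code in codes:
        mask = present[code]
        frames.append(pd.DataFrame({
            "patient_id": ids[mask],
            "phenocode": code,
            "date": win_start + pd.to_timedelta(date_offset[code][mask], unit="D"),
        }))
    events = pd.concat(frames, ignore_index=True)
    events = events.sort_values(["patient_id", "date", "phenocode"],
                                kind="mergesort").reset_index(drop=True)

    # deaths, attributed per disease in deterministic (sorted) order
    death_date = np.full(n, np.datetime64("NaT"), dtype="datetime64[ns]")
    cod = np.array([""] * n, dtype=object)
    if config.death_rates:
        last_event = events.groupby("patient_id")["date"].max()
        last_off = np.full(n, 0.0)
        has_event = np.isin(ids, last_event.index)
        last_off[has_event] = (
            (last_event.loc[ids[has_event]] - win_start).dt.days.to_numpy())
        for code in sorted(config.death_rates):
            rate = config.death_rates[code]
            candidates = present[code] & (cod == "")
            dies = candidates & (rng.random(n) < rate)
            lag = rng.exponential(scale=365.0, size=n)
            for i in np.flatnonzero(dies):
                cod[i] = code
                death_date[i] = (win_start
                                 + pd.to_timedelta(last_off[i] + 1 + lag[i], unit="D"))

    patients = pd.DataFrame({
        "patient_id": ids,
        "sex": sex,
        "birth_date": birth,
        "death_date": death_date,
        "cod_phenocodes": cod,
    })

    truth = CohortTruth(
        prevalence={c: config.prevalence(c) for c in codes},
        comorbidity=list(config.planted_comorbidity),
        orderings=list(config.planted_orderings),
    )
    return patients, events, truth


def simulate_dataset(config: SimulationConfig) -> dict:
    """Convenience wrapper running all three generators.

    Returns a dict with keys ``associations, snp_table, ld, metadata,
    patients, events, summary_truth, cohort_truth``.
    """
    associations, snp_table, summary_truth = simulate_summary_stats(config)
    ld = simulate_ld_r2(config, snp_table)
    patients, events, cohort_truth = simulate_cohort(config)
    return {
        "associations": associations,
        "snp_table": snp_table,
        "ld": ld,
        "metadata": phenocode_metadata(config),
        "patients": patients,
        "events": events,
        "summary_truth": summary_truth,
        "cohort_truth": cohort_truth,
    }
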