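"""Synthetic FAERS-dialect corpora with a known ground truth.

The generator emulates the structure of the public FAERS quarterly
extracts — multi-table rows keyed by report ID, revision duplicates, drug
role codes, per-report PT lists, demographic fields with realistic
missingness, and therapy/event dates (some incomplete) inside the
2017-2023 study window — while keeping an exact machine-readable manifest
of what was planted, so every pipeline stage can be checked against truth.

Reactions are drawn from an independent multinomial over the bundled PT
vocabulary except for *injected pairs*: when the named drug is present in
a report (with the PS role, for the target drug), the conditional
probability of the injected PT is multiplied by the reporting-rate ratio
``rho`` and the PT distribution renormalized. For rare margins this makes
the pair's reporting odds ratio approximately ``rho``, which is the
estimand the signal-detection tests measure against. Onset times are
Weibull draws (scale in days) per primary SOC, floored to whole days.

All randomness flows from one integer seed through a single
``numpy.random.Generator`` (PCG64), so a given configuration regenerates
its corpus and manifest bit-identically.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .meddra_map import HierarchyTable, builtin_hierarchy, pt_to_soc

TARGET_SYNONYMS = ("BENDAMUSTINE", "TREANDA", "BENDEKA", "BELRAPZO", "VIVIMUSTA")
TARGET = "TARGET"  # sentinel accepted in injected_pairs for the target drug

_WINDOW_START = datetime.date(2017, 1, 1)
_WINDOW_END = datetime.date(2023, 9, 30)

_COUNTRIES = ("US", "JP", "DE", "FR", "GB", "IT", "ES", "CA")
_COUNTRY_W = (0.30, 0.25, 0.12, 0.10, 0.08, 0.06, 0.05, 0.04)
_REPORTERS = ("MD", "CN", "OT", "HP", "PH")
_REPORTER_W = (0.4544, 0.2477, 0.1385, 0.1132, 0.0462)
_OUTCOMES = ("DE", "LT", "HO", "DS", "OT")
_OUTCOME_W = (0.2041, 0.0337, 0.3038, 0.0062, 0.4522)


@dataclass(frozen=True)
class InjectedPair:
    drug: str      # drug name or the TARGET sentinel
    pt: str
    rho: float     # reporting-rate ratio on PT given drug, >= 1

    def __post_init__(self):
        if self.rho < 1.0:
            raise ValueError("rho must be >= 1")


@dataclass
class SynthConfig:
    """Generator configuration; the defaults emulate a FAERS-like
    background for a moderately reported oncology drug over 2017-2023."""

    seed: int
    n_reports: int = 50_000
    n_background_drugs: int = 39
    target_synonyms: tuple[str, ...] = TARGET_SYNONYMS
    target_share: float = 0.02          # P(report involves the target)
    target_ps_prob: float = 0.8         # P(role PS | target present)
    drugs_per_report_lambda: float = 1.2   # extra drugs ~ Poisson
    pts_per_report_lambda: float = 1.2     # extra PTs ~ Poisson
    injected_pairs: tuple[InjectedPair, ...] = ()
    # demographics
    age_missing: float = 0.18
    sex_missing: float = 0.10
    male_share: float = 0.5773
    country_known: float = 0.65
    reporter_known: float = 0.98
    severe_prob: float = 0.2635
    # dates
    missing_date_fraction: float = 0.15
    duplicate_fraction: float = 0.10
    #: per-SOC Weibull (scale_days, shape); ``default_tto`` covers the rest
    tto_spec: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    default_tto: tuple[float, float] = (30.0, 0.8)
    n_quarters: int = 1

    def __post_init__(self):
        for f in (self.target_share, self.target_ps_prob, self.age_missing,
                  self.sex_missing, self.male_share, self.country_known,
                  self.reporter_known, self.severe_prob,
                  self.missing_date_fraction, self.duplicate_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.n_reports < 1 or self.n_quarters < 1:
            raise ValueError("n_reports and n_quarters must be positive")
        self.injected_pairs = tuple(
            p if isinstance(p, InjectedPair) else InjectedPair(*p)
            for p in self.injected_pairs
        )


@dataclass
class GroundTruthManifest:
    """Exact truth of one generated corpus (regenerable from config+seed)."""

    seed: int
    n_reports: int
    n_report_versions: int
    n_duplicates: int
    n_ps_target: int
    table_row_counts: dict
    pt_a_counts: dict          # PT -> unique PS-target reports with the PT
    injected: list             # dicts: drug, pt, rho, expected_rr
    onset_days_by_caseid: dict # caseid -> true onset (days)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "GroundTruthManifest":
        return cls(**json.loads(Path(path).read_text()))


class InfeasibleConfigError(ValueError):
    pass


def _pt_weights(pts: Sequence[str]) -> np.ndarray:
    # long-tailed but fixed marginal PT frequencies (rank-based)
    w = 1.0 / (np.arange(len(pts)) + 5.0)
    return w / w.sum()


def _date_str(d: datetime.date) -> str:
    return f"{d.year:04d}{d.month:02d}{d.day:02d}"


def _simulate(config: SynthConfig, hierarchy: HierarchyTable):
    rng = np.random.default_rng(config.seed)
    pts = hierarchy.pts()
    pt_soc = {pt: pt_to_soc(pt, hierarchy) for pt in pts}
    base_w = _pt_weights(pts)
    pt_index = {pt: i for i, pt in enumerate(pts)}

    drugs = [f"DRUG_{i:03d}" for i in range(1, config.n_background_drugs + 1)]
    drug_w = _pt_weights(drugs)

    # feasibility: rho must not push any conditional PT probability past 1
    injected_by_drug: dict[str, list[InjectedPair]] = {}
    for pair in config.injected_pairs:
        if pair.pt not in pt_index:
            raise InfeasibleConfigError(f"injected PT {pair.pt!r} not in the PT vocabulary")
        if pair.rho * base_w[pt_index[pair.pt]] > 1.0:
            raise InfeasibleConfigError(
                f"rho={pair.rho} pushes P({pair.pt!r}) above 1"
            )
        key = TARGET if pair.drug == TARGET else pair.drug
        injected_by_drug.setdefault(key, []).append(pair)

    window_days = (_WINDOW_END - _WINDOW_START).days

    demo_rows: list[dict] = []
    drug_rows: list[dict] = []
    reac_rows: list[dict] = []
    ther_rows: list[dict] = []
    outc_rows: list[dict] = []
    quarter_of_row: dict[str, list[int]] = {k: [] for k in ("demo", "drug", "reac", "ther", "outc")}

    n_ps_target = 0
    pt_a_counts: dict[str, int] = {}
    onset_by_caseid: dict[str, int] = {}
    n_dups = 0

    for i in range(config.n_reports):
        caseid = str(10_000_000 + i)
        base_quarter = i % config.n_quarters

        # --- drugs
        has_target = rng.random() < config.target_share
        target_role = "PS" if (has_target and rng.random() < config.target_ps_prob) else \
                      (rng.choice(["SS", "C"]) if has_target else None)
        n_extra = int(rng.poisson(config.drugs_per_report_lambda))
        n_bg = max(1 - int(has_target), 0) + n_extra
        bg_idx = rng.choice(len(drugs), size=min(n_bg, len(drugs)), replace=False, p=drug_w) \
            if n_bg else np.array([], dtype=int)
        report_drugs: list[tuple[str, str]] = []
        if has_target:
            name = str(rng.choice(config.target_synonyms))
            report_drugs.append((name, target_role))
        for j, bi in enumerate(bg_idx):
            role = "PS" if (not report_drugs and j == 0) else str(rng.choice(["SS", "C", "I"], p=[0.5, 0.4, 0.1]))
            report_drugs.append((drugs[int(bi)], role))
        is_ps_target = has_target and target_role == "PS"

        # --- reactions (independent multinomial; injected pairs boosted)
        w = base_w
        boosts = []
        if is_ps_target:
            boosts.extend(injected_by_drug.get(TARGET, ()))
        present_names = sorted({d for d, _ in report_drugs})
        for dn in present_names:
            boosts.extend(injected_by_drug.get(dn, ()))
        if boosts:
            w = base_w.copy()
            for pair in boosts:
                w[pt_index[pair.pt]] *= pair.rho
            w = w / w.sum()
        n_pts_i = 1 + int(rng.poisson(config.pts_per_report_lambda))
        idx = rng.choice(len(pts), size=min(n_pts_i, len(pts)), replace=False, p=w)
        report_pts = [pts[int(k)] for k in idx]

        # --- onset + dates
        soc = pt_soc[report_pts[0]]
        alpha, beta = config.tto_spec.get(soc, config.default_tto)
        onset = int(np.floor(alpha * rng.weibull(beta)))
        onset_by_caseid[caseid] = onset
        start = _WINDOW_START + datetime.timedelta(days=int(rng.integers(0, window_days + 1)))
        event = start + datetime.timedelta(days=onset)
        rept = event + datetime.timedelta(days=int(rng.poisson(20.0)))
        start_txt, event_txt = _date_str(start), _date_str(event)
        if rng.random() < config.missing_date_fraction:
            if rng.random() < 0.5:
                start_txt = start_txt[:6] if rng.random() < 0.5 else ""
            else:
                event_txt = event_txt[:6] if rng.random() < 0.5 else ""

        # --- demographics
        if rng.random() < 0.04:
            age, age_cod = round(float(rng.uniform(1, 17)), 1), "YR"
        else:
            age, age_cod = round(float(np.clip(rng.normal(66.0, 15.0), 18.0, 100.0)), 1), "YR"
        if rng.random() < config.age_missing:
            age, age_cod = "", ""
        sex = ("M" if rng.random() < config.male_share else "F") \
            if rng.random() >= config.sex_missing else ""
        country = str(rng.choice(_COUNTRIES, p=_COUNTRY_W)) \
            if rng.random() < config.country_known else ""
        reporter = str(rng.choice(_REPORTERS, p=_REPORTER_W)) \
            if rng.random() < config.reporter_known else ""
        severe = rng.random() < config.severe_prob
        outcome = str(rng.choice(_OUTCOMES, p=_OUTCOME_W)) if severe else ""

        # --- accounting on the deduplicated (latest-version) case
        if is_ps_target:
            n_ps_target += 1
            for pt in set(report_pts):
                pt_a_counts[pt] = pt_a_counts.get(pt, 0) + 1

        is_dup = rng.random() < config.duplicate_fraction
        versions = (1, 2) if is_dup else (1,)
        if is_dup:
            n_dups += 1
        for version in versions:
            pid = f"{caseid}{version}"
            quarter = base_quarter if version == 1 else (base_quarter + 1) % config.n_quarters
            demo_rows.append(dict(
                primaryid=pid, caseid=caseid, caseversion=str(version),
                event_dt=event_txt, rept_dt=_date_str(rept), age=str(age),
                age_cod=age_cod, sex=sex, occp_cod=reporter, occr_country=country,
            ))
            quarter_of_row["demo"].append(quarter)
            for seq, (dname, role) in enumerate(report_drugs, start=1):
                drug_rows.append(dict(primaryid=pid, drug_seq=str(seq),
                                      role_cod=role, drugname=dname, prod_ai=dname))
                quarter_of_row["drug"].append(quarter)
                ther_rows.append(dict(primaryid=pid, dsg_drug_seq=str(seq),
                                      start_dt=start_txt))
                quarter_of_row["ther"].append(quarter)
            for pt in report_pts:
                reac_rows.append(dict(primaryid=pid, pt=pt))
                quarter_of_row["reac"].append(quarter)
            if outcome:
                outc_rows.append(dict(primaryid=pid, outc_cod=outcome))
                quarter_of_row["outc"].append(quarter)

    tables = dict(demo=pd.DataFrame(demo_rows), drug=pd.DataFrame(drug_rows),
                  reac=pd.DataFrame(reac_rows), ther=pd.DataFrame(ther_rows),
                  outc=pd.DataFrame(outc_rows))
    manifest = GroundTruthManifest(
        seed=config.seed,
        n_reports=config.n_reports,
        n_report_versions=config.n_reports + n_dups,
        n_duplicates=n_dups,
        n_ps_target=n_ps_target,
        table_row_counts={k: len(v) for k, v in tables.items()},
        pt_a_counts=pt_a_counts,
        injected=[dict(drug=p.drug, pt=p.pt, rho=p.rho, expected_rr=p.rho)
                  for p in config.injected_pairs],
        onset_days_by_caseid=onset_by_caseid,
    )
    return tables, quarter_of_row, manifest


def generate(
    config: SynthConfig,
    outdir: str | Path,
    hierarchy: HierarchyTable | None = None,
) -> tuple[list[dict], GroundTruthManifest]:
    """Write a synthetic corpus in the FAERS quarterly dialect.

    Returns (per-quarter path maps suitable for ``faers_io.read_quarter``,
    manifest). The manifest is also written as ``manifest.json``.
    """
    hierarchy = hierarchy or builtin_hierarchy()
    tables, quarter_of_row, manifest = _simulate(config, hierarchy)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    quarter_paths: list[dict] = []
    for q in range(config.n_quarters):
        qdir = outdir / f"q{q + 1:02d}"
        qdir.mkdir(exist_ok=True)
        paths = {}
        for table, df in tables.items():
            mask = np.asarray(quarter_of_row[table]) == q if len(df) else np.array([], dtype=bool)
            sub = df[mask] if len(df) else df
            path = qdir / f"{table.upper()}.txt"
            sub.to_csv(path, sep="$", index=False, lineterminator="\n")
            paths[table] = path
        quarter_paths.append(paths)
    manifest.to_json(outdir / "manifest.json")
    return quarter_paths, manifest


def regenerate_manifest(config: SynthConfig, hierarchy: HierarchyTable | None = None) -> GroundTruthManifest:
    """The manifest of ``generate(config, ...)`` without writing any files."""
    hierarchy = hierarchy or builtin_hierarchy()
    _, _, manifest = _simulate(config, hierarchy)
    return manifest
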