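"""Population-level simulation scenarios: how the wall-thickness model feeds
the electrophysiological endpoints.

Three ways of assigning the string length (= LVPWd) to a virtual population,
each run with and without an I_Kr-blocking drug:

* ``constant`` — every individual gets the pooled clinical average (8.3 mm);
* ``sjogren``  — the legacy age-sex linear equations plus residual noise;
* ``aslpm``    — random draws from the bounded beta-regression model fitted
  on the Polish data (age-sex predictors), the age-sex LVPWd population model.

Each individual's physiology is drawn once and reused across scenarios and
drug arms, so differences isolate the wall-thickness assignment and the drug.
Summaries follow the per-scenario, per-sex mean/SD layout (string length, QT,
QTcF, and the per-individual drug-minus-baseline dQTcF).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import fiber as fb
from . import published

__all__ = [
    "ScenarioSpec",
    "ExperimentResult",
    "TABLE2_LVPWD_GROUPS",
    "DEFAULT_DRUG",
    "constant_string_length",
    "assign_string_lengths",
    "run_experiment",
    "summarize",
]

SCENARIOS = ("constant", "sjogren", "aslpm")

# (n, group mean LVPWd mm) of the four clinical cells: dataset x sex
TABLE2_LVPWD_GROUPS = {
    ("uhz", "M"): (2104, 8.76),
    ("uhz", "F"): (2368, 7.78),
    ("polish", "M"): (189, 9.55),
    ("polish", "F"): (128, 8.63),
}

DEFAULT_DRUG = fb.DrugBlock(ic50_uM=9.64, hill_n=1.0, concentration_uM=15.0)


def constant_string_length(groups=None) -> float:
    """Sample-size-weighted mean of the clinical group LVPWd means, to 0.1 mm."""
    groups = TABLE2_LVPWD_GROUPS if groups is None else groups
    pairs = list(groups.values())
    n_tot = sum(n for n, _ in pairs)
    if n_tot == 0:
        raise ValueError("zero total sample size")
    return round(sum(n * m for n, m in pairs) / n_tot, 1)


@dataclass(frozen=True)
class ScenarioSpec:
    """One scenario over a virtual population (both drug arms are always run)."""

    scenario_id: str
    n_male: int = 30
    n_female: int = 30
    drug: fb.DrugBlock = DEFAULT_DRUG
    seed: int = 0
    age_range: tuple[float, float] = (20.0, 60.0)
    sjogren_residual_sd_mm: float = 1.0
    cell_model: str = "tp06"
    fiber_kwargs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scenario_id not in SCENARIOS:
            raise ValueError(f"scenario_id must be one of {SCENARIOS}")
        if self.n_male < 0 or self.n_female < 0:
            raise ValueError("population counts must be non-negative")


def _population(spec: ScenarioSpec) -> tuple[pd.DataFrame, list[fb.PhysioParams]]:
    """Ages, sexes and physiology; depends on the seed only, not the scenario."""
    ss = np.random.SeedSequence(spec.seed)
    s_age, s_phys = ss.spawn(2)
    rng = np.random.default_rng(s_age)
    n = spec.n_male + spec.n_female
    sex = np.array(["M"] * spec.n_male + ["F"] * spec.n_female)
    age = rng.uniform(*spec.age_range, size=n)
    physio = fb.sample_physio(n, seed=s_phys) if n else []
    pop = pd.DataFrame({
        "individual_id": [f"vi{i:03d}" for i in range(n)],
        "sex": sex, "age_years": age,
        **{f: [getattr(p, f) for p in physio] for f in fb.PhysioParams.__dataclass_fields__},
    })
    return pop, physio


def assign_string_lengths(spec: ScenarioSpec, population: pd.DataFrame) -> np.ndarray:
    """Per-individual string lengths (mm) under the scenario's assignment rule."""
    n = len(population)
    ss = np.random.SeedSequence(spec.seed)
    _, _, s_len = ss.spawn(3)
    rng = np.random.default_rng(s_len)
    if spec.scenario_id == "constant":
        return np.full(n, constant_string_length())
    age = population["age_years"].to_numpy(dtype=float)
    male = (population["sex"] == "M").to_numpy()
    if spec.scenario_id == "sjogren":
        mean = np.where(
            male,
            [published.legacy_mean("sjogren_male", {"age": a}) for a in age],
            [published.legacy_mean("sjogren_female", {"age": a}) for a in age])
        return mean + rng.normal(0.0, spec.sjogren_residual_sd_mm, size=n)
    coefs = published.get_coefficient_set("polish", "age_sex")
    return published.sample_lvpwd(
        coefs, {"age": age, "sex": male.astype(float)}, n=n, seed=rng)


@dataclass
class ExperimentResult:
    population: pd.DataFrame          # one row per individual, physiology incl.
    results: pd.DataFrame             # one row per individual x drug arm
    summary: pd.DataFrame             # per-group mean/SD table
    failures: list[tuple] = field(default_factory=list)


def run_experiment(spec: ScenarioSpec) -> ExperimentResult:
    """Run both drug arms of a scenario over the virtual population.

    Per-individual failures (e.g. undetectable T wave) are recorded and the
    remaining individuals summarized.
    """
    population, physio = _population(spec)
    lengths = assign_string_lengths(spec, population)
    rows = []
    failures: list[tuple] = []
    for i in range(len(population)):
        try:
            cfg = fb.build_fiber(float(lengths[i]), **spec.fiber_kwargs)
            for drug_on, drug in ((0, None), (1, spec.drug)):
                res = fb.simulate_fiber(cfg, physio[i], drug,
                                        cell_model=spec.cell_model)
                qt = fb.measure_qt(fb.pseudo_ecg(res))
                rows.append({
                    "individual_id": population["individual_id"].iloc[i],
                    "sex": population["sex"].iloc[i],
                    "scenario": spec.scenario_id,
                    "string_length_mm": float(lengths[i]),
                    "drug": drug_on,
                    "QT_ms": qt,
                    "RR_ms": res.rr_ms,
                    "QTcF_ms": fb.fridericia(qt, res.rr_ms),
                })
        except (fb.StabilityError, fb.MeasurementError, ValueError) as err:
            failures.append((population["individual_id"].iloc[i], str(err)))
    results = pd.DataFrame(rows)
    summary = summarize(results) if len(results) else pd.DataFrame()
    return ExperimentResult(population=population, results=results,
                            summary=summary, failures=failures)


def _group_stats(wide: pd.DataFrame) -> dict:
    out = {}
    for col, label in [("string_length_mm", "string_length_mm"),
                       ("QT_base_ms", "qt_baseline_ms"),
                       ("QT_drug_ms", "qt_drug_ms"),
                       ("QTcF_base_ms", "qtcf_baseline_ms"),
                       ("QTcF_drug_ms", "qtcf_drug_ms"),
                       ("dQTcF_ms", "delta_qtcf_ms")]:
        v = wide[col].to_numpy(dtype=float)
        out[f"{label}_mean"] = float(np.mean(v))
        out[f"{label}_sd"] = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    return out


def summarize(results: pd.DataFrame) -> pd.DataFrame:
    """Per-scenario, per-group (all/female/male) means and SDs.

    dQTcF is computed per individual (drug minus baseline) before summarizing;
    SDs use the n-1 denominator.
    """
    if len(results) == 0:
        raise ValueError("no successful individuals to summarize")
    base = results[results["drug"] == 0].set_index(["scenario", "individual_id"])
    drug = results[results["drug"] == 1].set_index(["scenario", "individual_id"])
    wide = pd.DataFrame({
        "sex": base["sex"],
        "string_length_mm": base["string_length_mm"],
        "QT_base_ms": base["QT_ms"],
        "QT_drug_ms": drug["QT_ms"],
        "QTcF_base_ms": base["QTcF_ms"],
        "QTcF_drug_ms": drug["QTcF_ms"],
    }).dropna()
    wide["dQTcF_ms"] = wide["QTcF_drug_ms"] - wide["QTcF_base_ms"]
    rows = []
    for scenario, sub in wide.groupby(level="scenario"):
        for group, sel in [("all", sub), ("female", sub[sub["sex"] == "F"]),
                           ("male", sub[sub["sex"] == "M"])]:
            if len(sel) == 0:
                continue
            rows.append({"scenario": scenario, "group": group, "n": len(sel),
                         **_group_stats(sel)})
    return pd.DataFrame(rows)
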