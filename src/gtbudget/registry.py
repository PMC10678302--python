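"""Disease/trial registry: data model, CSV readers and writers, and a
synthetic registry generator.

The registry mirrors the structure of a late-stage gene-therapy pipeline
snapshot: 57 diseases across three categories (dominated by oncology) under
study in 109 phase-2/3 or phase-3 trials, grouped into development programs
(one sponsor testing one therapeutic against one disease).  No public
machine-readable version of such a snapshot exists, so the generator builds
registries with the same structure — category mix, 1–4 programs per disease,
a fraction of trials with missing end dates, nested disease pairs, and
category-plausible epidemiology — for simulation and testing.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORIES",
    "THERAPEUTIC_AREAS",
    "AGE_GROUPS",
    "DiseaseRecord",
    "TrialRecord",
    "Registry",
    "RegistryError",
    "read_registry",
    "write_registry",
    "generate_registry",
    "adjust_overlaps",
]

CATEGORIES = ("cancer", "rare", "general")
THERAPEUTIC_AREAS = (
    "Autoimmune/Inflammation",
    "Cardiovascular",
    "CNS",
    "Metabolic/Endocrinology",
    "Oncology",
    "Ophthalmology",
)
AGE_GROUPS = ("minor", "adult", "elderly")

DISEASE_COLUMNS = [
    "disease_id", "name", "category", "therapeutic_area",
    "incidence_i", "prevalence_j", "survival_p", "survival_k",
    "age_minor", "age_adult", "age_elderly",
    "delta_qaly", "prior_approval", "parent_disease_id", "eligible_fraction",
]
TRIAL_COLUMNS = ["trial_id", "disease_id", "program_id", "phase", "start_date", "end_date"]


class RegistryError(ValueError):
    """Raised on schema or invariant violations in registry data."""


@dataclass
class DiseaseRecord:
    """Epidemiology and valuation inputs for one disease.

    At least one of ``incidence_i`` (persons/year) and ``prevalence_j``
    (persons) must be present; the missing one is recovered at simulation
    time through the steady-state conversion, which requires ``survival_p``
    (fraction alive after ``survival_k`` years).  ``age_mix`` gives the
    minor/adult/elderly shares of the patient population and must sum to 1.
    ``parent_disease_id`` links a sub-indication to its parent so that
    overlapping patient populations are not double-counted.
    """

    disease_id: str
    name: str
    category: str
    therapeutic_area: str
    incidence_i: float | None = None
    prevalence_j: float | None = None
    survival_p: float | None = None
    survival_k: float | None = None
    age_mix: dict[str, float] = field(
        default_factory=lambda: {"minor": 0.2, "adult": 0.5, "elderly": 0.3}
    )
    delta_qaly: float = 1.0
    prior_approval: bool = False
    parent_disease_id: str | None = None
    eligible_fraction: float = 1.0

    def validate(self) -> None:
        if self.category not in CATEGORIES:
            raise RegistryError(f"{self.disease_id}: unknown category {self.category!r}")
        if self.therapeutic_area not in THERAPEUTIC_AREAS:
            raise RegistryError(
                f"{self.disease_id}: unknown therapeutic area {self.therapeutic_area!r}"
            )
        if self.incidence_i is None and self.prevalence_j is None:
            raise RegistryError(
                f"{self.disease_id}: need at least one of incidence_i, prevalence_j"
            )
        for label, v in (("incidence_i", self.incidence_i), ("prevalence_j", self.prevalence_j)):
            if v is not None and v < 0:
                raise RegistryError(f"{self.disease_id}: {label} must be >= 0")
        needs_conversion = self.incidence_i is None or self.prevalence_j is None
        if self.survival_p is not None and not (0.0 <= self.survival_p < 1.0):
            raise RegistryError(f"{self.disease_id}: survival_p must lie in [0, 1)")
        if needs_conversion:
            if self.survival_p is None or self.survival_k is None or self.survival_k <= 0:
                raise RegistryError(
                    f"{self.disease_id}: steady-state conversion needs survival_p in [0,1) "
                    "and survival_k > 0"
                )
        if set(self.age_mix) != set(AGE_GROUPS):
            raise RegistryError(f"{self.disease_id}: age_mix must cover {AGE_GROUPS}")
        shares = np.array([self.age_mix[g] for g in AGE_GROUPS], dtype=float)
        if np.any(shares < 0) or abs(shares.sum() - 1.0) > 1e-9:
            raise RegistryError(f"{self.disease_id}: age_mix must be nonnegative and sum to 1")
        if self.delta_qaly <= 0:
            raise RegistryError(f"{self.disease_id}: delta_qaly must be > 0")
        if not (0.0 < self.eligible_fraction <= 1.0):
            raise RegistryError(f"{self.disease_id}: eligible_fraction must lie in (0, 1]")


@dataclass
class TrialRecord:
    """One clinical trial: phase 2/3 or phase 3, tied to a development program."""

    trial_id: str
    disease_id: str
    program_id: str
    phase: str = "3"
    start_date: _dt.date = _dt.date(2018, 1, 1)
    end_date: _dt.date | None = None

    def validate(self) -> None:
        if self.phase not in ("2/3", "3"):
            raise RegistryError(f"{self.trial_id}: phase must be '2/3' or '3'")
        if self.end_date is not None and self.end_date < self.start_date:
            raise RegistryError(f"{self.trial_id}: end_date precedes start_date")


@dataclass
class Registry:
    diseases: list[DiseaseRecord]
    trials: list[TrialRecord]
    overlap_adjusted: bool = False

    def validate(self) -> None:
        ids = [d.disease_id for d in self.diseases]
        if len(set(ids)) != len(ids):
            raise RegistryError("duplicate disease_id")
        known = set(ids)
        for d in self.diseases:
            d.validate()
            if d.parent_disease_id is not None:
                if d.parent_disease_id not in known:
                    raise RegistryError(
                        f"{d.disease_id}: parent {d.parent_disease_id!r} not in registry"
                    )
                parent = self.disease(d.parent_disease_id)
                for attr in ("incidence_i", "prevalence_j"):
                    child_v, parent_v = getattr(d, attr), getattr(parent, attr)
                    if child_v is not None and parent_v is not None and child_v > parent_v:
                        raise RegistryError(
                            f"{d.disease_id}: child {attr} ({child_v}) exceeds "
                            f"parent's ({parent_v})"
                        )
        trial_ids = [t.trial_id for t in self.trials]
        if len(set(trial_ids)) != len(trial_ids):
            raise RegistryError("duplicate trial_id")
        with_trials = set()
        for t in self.trials:
            t.validate()
            if t.disease_id not in known:
                raise RegistryError(f"{t.trial_id}: orphan trial (disease {t.disease_id!r})")
            with_trials.add(t.disease_id)
        missing = known - with_trials
        if missing:
            raise RegistryError(f"diseases without any trial: {sorted(missing)}")

    def disease(self, disease_id: str) -> DiseaseRecord:
        for d in self.diseases:
            if d.disease_id == disease_id:
                return d
        raise KeyError(disease_id)

    def trials_for(self, disease_id: str) -> list[TrialRecord]:
        return [t for t in self.trials if t.disease_id == disease_id]

    def programs(self) -> pd.DataFrame:
        """One row per development program: program_id, disease_id, area, category."""
        rows = {}
        for t in self.trials:
            if t.program_id not in rows:
                d = self.disease(t.disease_id)
                rows[t.program_id] = (
                    t.program_id, t.disease_id, d.therapeutic_area, d.category
                )
        return pd.DataFrame(
            rows.values(),
            columns=["program_id", "disease_id", "therapeutic_area", "category"],
        )

    def diseases_frame(self) -> pd.DataFrame:
        rows = []
        for d in self.diseases:
            rows.append({
                "disease_id": d.disease_id, "name": d.name, "category": d.category,
                "therapeutic_area": d.therapeutic_area,
                "incidence_i": d.incidence_i, "prevalence_j": d.prevalence_j,
                "survival_p": d.survival_p, "survival_k": d.survival_k,
                "age_minor": d.age_mix["minor"], "age_adult": d.age_mix["adult"],
                "age_elderly": d.age_mix["elderly"],
                "delta_qaly": d.delta_qaly, "prior_approval": d.prior_approval,
                "parent_disease_id": d.parent_disease_id,
                "eligible_fraction": d.eligible_fraction,
            })
        return pd.DataFrame(rows, columns=DISEASE_COLUMNS)

    def trials_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.trials:
            rows.append({
                "trial_id": t.trial_id, "disease_id": t.disease_id,
                "program_id": t.program_id, "phase": t.phase,
                "start_date": t.start_date.isoformat(),
                "end_date": t.end_date.isoformat() if t.end_date is not None else "",
            })
        return pd.DataFrame(rows, columns=TRIAL_COLUMNS)

    def copy(self) -> "Registry":
        return Registry(
            diseases=[dataclasses.replace(d, age_mix=dict(d.age_mix)) for d in self.diseases],
            trials=[dataclasses.replace(t) for t in self.trials],
            overlap_adjusted=self.overlap_adjusted,
        )


def _opt_float(v) -> float | None:
    if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
        return None
    return float(v)


def read_registry(disease_table_path, trial_table_path) -> Registry:
    """Load and validate a registry from two CSV tables.

    ``diseases.csv`` and ``trials.csv`` follow the documented column schema;
    empty cells denote missing optional values; dates are ISO-8601.
    """
    try:
        # round_trip parsing so write -> read -> write is byte-identical
        ddf = pd.read_csv(
            disease_table_path,
            dtype={"disease_id": str, "parent_disease_id": str},
            float_precision="round_trip",
        )
        tdf = pd.read_csv(
            trial_table_path,
            dtype={"trial_id": str, "disease_id": str, "program_id": str, "phase": str},
            float_precision="round_trip",
        )
    except Exception as exc:  # noqa: BLE001 - surface as a schema error
        raise RegistryError(f"could not parse registry CSVs: {exc}") from exc
    for col in DISEASE_COLUMNS:
        if col not in ddf.columns:
            raise RegistryError(f"diseases table missing column {col!r}")
    for col in TRIAL_COLUMNS:
        if col not in tdf.columns:
            raise RegistryError(f"trials table missing column {col!r}")

    diseases = []
    for row in ddf.itertuples(index=False):
        parent = row.parent_disease_id
        if parent is not None and (parent == "" or (isinstance(parent, float) and np.isnan(parent))):
            parent = None
        diseases.append(DiseaseRecord(
            disease_id=str(row.disease_id), name=str(row.name), category=str(row.category),
            therapeutic_area=str(row.therapeutic_area),
            incidence_i=_opt_float(row.incidence_i), prevalence_j=_opt_float(row.prevalence_j),
            survival_p=_opt_float(row.survival_p), survival_k=_opt_float(row.survival_k),
            age_mix={"minor": float(row.age_minor), "adult": float(row.age_adult),
                     "elderly": float(row.age_elderly)},
            delta_qaly=float(row.delta_qaly), prior_approval=bool(row.prior_approval),
            parent_disease_id=parent, eligible_fraction=float(row.eligible_fraction),
        ))
    trials = []
    for row in tdf.itertuples(index=False):
        end = row.end_date
        if end is None or end == "" or (isinstance(end, float) and np.isnan(end)):
            end_date = None
        else:
            end_date = _dt.date.fromisoformat(str(end))
        trials.append(TrialRecord(
            trial_id=str(row.trial_id), disease_id=str(row.disease_id),
            program_id=str(row.program_id), phase=str(row.phase),
            start_date=_dt.date.fromisoformat(str(row.start_date)), end_date=end_date,
        ))
    reg = Registry(diseases=diseases, trials=trials)
    reg.validate()
    return reg


def write_registry(registry: Registry, disease_table_path, trial_table_path) -> None:
    """Write a registry to the two-table CSV schema (inverse of read_registry)."""
    registry.diseases_frame().to_csv(disease_table_path, index=False)
    registry.trials_frame().to_csv(trial_table_path, index=False)


def registry_to_csv_bytes(registry: Registry) -> tuple[bytes, bytes]:
    """Serialize both tables to bytes (used for determinism checks/hashing)."""
    bufs = []
    for frame in (registry.diseases_frame(), registry.trials_frame()):
        buf = io.StringIO()
        frame.to_csv(buf, index=False)
        bufs.append(buf.getvalue().encode())
    return bufs[0], bufs[1]


# Therapeutic-area pools by category for the generator.  Oncology trials map
# to the Oncology area; rare and general diseases spread over the remaining
# areas with weights loosely matching a late-stage gene-therapy pipeline.
_AREA_POOLS = {
    "cancer": (["Oncology"], [1.0]),
    "rare": (
        ["CNS", "Metabolic/Endocrinology", "Ophthalmology", "Cardiovascular"],
        [0.35, 0.30, 0.25, 0.10],
    ),
    "general": (
        ["Cardiovascular", "Autoimmune/Inflammation", "CNS", "Metabolic/Endocrinology"],
        [0.35, 0.30, 0.20, 0.15],
    ),
}

# log10 prevalence ranges by category: rare diseases number hundreds to tens
# of thousands of U.S. patients, general/chronic diseases hundreds of
# thousands to millions, cancers in between.
_PREVALENCE_LOG10 = {"rare": (2.0, 4.0), "general": (5.0, 7.0), "cancer": (3.0, 6.0)}

# Incremental QALY ranges: curative rare-disease therapies deliver large
# gains; oncology and chronic-disease gains are more modest.
_DELTA_QALY = {"rare": (5.0, 25.0), "cancer": (0.5, 5.0), "general": (0.5, 5.0)}

DEFAULT_CATEGORY_WEIGHTS = {"cancer": 0.50, "rare": 0.30, "general": 0.20}


def generate_registry(
    n_diseases: int = 57,
    n_trials: int = 109,
    category_weights: dict[str, float] | None = None,
    seed: int | np.random.Generator = 0,
    missing_end_date_fraction: float = 0.20,
) -> Registry:
    """Generate a synthetic registry with pipeline-like structure.

    Reproducible given ``seed``.  Trials are partitioned into 1–4 programs
    per disease; about ``missing_end_date_fraction`` of trials lack end
    dates; at least one nested parent/child disease pair and one
    prior-approval disease are included (when n_diseases permits).
    """
    if n_diseases < 1:
        raise ValueError("n_diseases must be >= 1")
    if n_trials < n_diseases:
        raise ValueError("n_trials must be >= n_diseases (every disease needs a trial)")
    weights = dict(category_weights or DEFAULT_CATEGORY_WEIGHTS)
    if set(weights) - set(CATEGORIES):
        raise ValueError(f"unknown categories in weights: {set(weights) - set(CATEGORIES)}")
    w = np.array([weights.get(c, 0.0) for c in CATEGORIES], dtype=float)
    if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("category_weights must be nonnegative and sum to 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    cats = [CATEGORIES[i] for i in rng.choice(len(CATEGORIES), size=n_diseases, p=w)]
    diseases: list[DiseaseRecord] = []
    for i, cat in enumerate(cats):
        did = f"D{i:03d}"
        areas, aw = _AREA_POOLS[cat]
        area = areas[rng.choice(len(areas), p=np.array(aw) / np.sum(aw))]
        lo, hi = _PREVALENCE_LOG10[cat]
        prevalence = float(10.0 ** rng.uniform(lo, hi))
        survival_p = float(rng.uniform(0.2, 0.9))
        survival_k = float(rng.uniform(2.0, 10.0))
        incidence = prevalence * (1.0 - survival_p) / survival_k
        # a third of records carry only one of the two epidemiology fields,
        # exercising the steady-state conversion downstream
        u = rng.uniform()
        inc: float | None = incidence
        prev: float | None = prevalence
        if u < 1 / 6:
            prev = None
        elif u < 1 / 3:
            inc = None
        qlo, qhi = _DELTA_QALY[cat]
        if cat == "rare":
            raw = rng.dirichlet([4.0, 3.0, 1.0])  # rare diseases skew young
        elif cat == "cancer":
            raw = rng.dirichlet([1.0, 4.0, 4.0])  # cancers skew older
        else:
            raw = rng.dirichlet([1.5, 4.0, 2.5])
        age_mix = {g: float(v) for g, v in zip(AGE_GROUPS, raw)}
        # renormalise exactly to 1 against float round-off
        total = sum(age_mix.values())
        age_mix = {g: v / total for g, v in age_mix.items()}
        diseases.append(DiseaseRecord(
            disease_id=did, name=f"{cat.capitalize()} disease {i}", category=cat,
            therapeutic_area=area, incidence_i=inc, prevalence_j=prev,
            survival_p=survival_p, survival_k=survival_k, age_mix=age_mix,
            delta_qaly=float(rng.uniform(qlo, qhi)), prior_approval=False,
            parent_disease_id=None, eligible_fraction=1.0,
        ))

    # at least one prior-approval disease
    n_prior = max(1, int(round(0.05 * n_diseases)))
    for i in rng.choice(n_diseases, size=min(n_prior, n_diseases), replace=False):
        diseases[i].prior_approval = True

    # at least one nested parent/child pair (child counts below the parent's)
    if n_diseases >= 2:
        pi, ci = rng.choice(n_diseases, size=2, replace=False)
        parent, child = diseases[pi], diseases[ci]
        frac = float(rng.uniform(0.1, 0.5))
        child.category = parent.category
        child.therapeutic_area = parent.therapeutic_area
        child.survival_p, child.survival_k = parent.survival_p, parent.survival_k
        child.incidence_i = None if parent.incidence_i is None else parent.incidence_i * frac
        child.prevalence_j = None if parent.prevalence_j is None else parent.prevalence_j * frac
        child.parent_disease_id = parent.disease_id
        child.name = parent.name + " subtype I"

    # partition trials over diseases: one guaranteed each, rest multinomial
    extra = rng.multinomial(n_trials - n_diseases, np.full(n_diseases, 1.0 / n_diseases))
    trials: list[TrialRecord] = []
    tid = 0
    for i, d in enumerate(diseases):
        k = 1 + int(extra[i])
        n_programs = int(min(rng.integers(1, 5), k))
        program_of_trial = rng.integers(0, n_programs, size=k)
        program_of_trial[:n_programs] = np.arange(n_programs)  # each program nonempty
        for j in range(k):
            start = _dt.date(2015, 1, 1) + _dt.timedelta(days=int(rng.integers(0, 365 * 5)))
            duration_days = int(rng.integers(365, 365 * 5))
            end: _dt.date | None = start + _dt.timedelta(days=duration_days)
            if rng.uniform() < missing_end_date_fraction:
                end = None
            trials.append(TrialRecord(
                trial_id=f"T{tid:04d}", disease_id=d.disease_id,
                program_id=f"{d.disease_id}-P{program_of_trial[j]}",
                phase="3" if rng.uniform() < 0.7 else "2/3",
                start_date=start, end_date=end,
            ))
            tid += 1

    reg = Registry(diseases=diseases, trials=trials)
    reg.validate()
    return reg


def adjust_overlaps(registry: Registry) -> Registry:
    """Subtract child patient counts from their parents to avoid
    double-counting nested patient populations.

    Idempotent: a registry already adjusted is returned unchanged.
    """
    if registry.overlap_adjusted:
        return registry
    out = registry.copy()
    for child in out.diseases:
        if child.parent_disease_id is None:
            continue
        parent = out.disease(child.parent_disease_id)
        for attr in ("incidence_i", "prevalence_j"):
            cv, pv = getattr(child, attr), getattr(parent, attr)
            if cv is None or pv is None:
                continue
            if cv > pv:
                raise RegistryError(
                    f"{child.disease_id}: child {attr} exceeds parent {parent.disease_id}"
                )
            setattr(parent, attr, pv - cv)
    out.overlap_adjusted = True
    return out
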