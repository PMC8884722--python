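"""Cohort containers, synthetic-cohort simulation, and on-disk I/O.

A *cohort* bundles an integer count matrix (samples x RNA features), one
metadata record per serum sample, and one annotation record per feature
(its small-RNA class).  Real prediagnostic serum cohorts of this shape are
access-restricted, so the :func:`generate_cohort` simulator produces
seeded cohorts with the same statistical structure: negative-binomial
counts with per-sample library sizes, confounders (sex, age, blood-donor
group), repeated samples per case individual, and case/control signals
planted in chosen histology and time-to-diagnosis strata.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

RNA_CLASSES = (
    "miRNA",
    "isomiR",
    "piRNA",
    "miscRNA",
    "snoRNA",
    "tRF",
    "mRNA",
    "lncRNA",
)

HISTOLOGIES = ("NSCLC", "SCLC", "other", "none")
STAGES = ("early", "locally_advanced", "advanced", "unknown", "none")
SEXES = ("male", "female")
SMOKING = ("current", "former", "never", "unknown")

#: Study-scale feature composition by RNA class (the serum small-RNA-seq
#: feature panel after low-count filtering).
FULL_FEATURES_PER_CLASS = {
    "miRNA": 202,
    "isomiR": 1137,
    "miscRNA": 89,
    "piRNA": 380,
    "snoRNA": 119,
    "tRF": 530,
    "mRNA": 790,
    "lncRNA": 59,
}

#: Desk-scale default: the same composition scaled down 5x.
DEFAULT_FEATURES_PER_CLASS = {
    cls: max(2, round(n / 5)) for cls, n in FULL_FEATURES_PER_CLASS.items()
}


class CohortError(ValueError):
    """Raised for invalid cohort construction, configuration, or files."""


@dataclass(frozen=True)
class RnaAnnotation:
    """One RNA feature and its class."""

    feature_id: str
    rna_class: str

    def __post_init__(self) -> None:
        if self.rna_class not in RNA_CLASSES:
            raise CohortError(
                f"unknown rna_class {self.rna_class!r} for feature "
                f"{self.feature_id!r}; expected one of {RNA_CLASSES}"
            )


@dataclass(frozen=True)
class SampleRecord:
    """Metadata for one serum sample.

    Controls carry ``histology='none'``, ``stage='none'`` and have no
    diagnosis age or time; for cases ``time_to_diagnosis`` is the interval
    in years between blood donation and the later cancer diagnosis.
    """

    sample_id: str
    individual_id: str
    group: str  # case | control
    histology: str
    stage: str
    sex: str
    age_at_donation: float
    age_at_diagnosis: float | None
    time_to_diagnosis: float | None
    smoking: str
    bdg: str

    def __post_init__(self) -> None:
        if self.group not in ("case", "control"):
            raise CohortError(f"sample {self.sample_id}: bad group {self.group!r}")
        if self.histology not in HISTOLOGIES:
            raise CohortError(
                f"sample {self.sample_id}: bad histology {self.histology!r}"
            )
        if self.stage not in STAGES:
            raise CohortError(f"sample {self.sample_id}: bad stage {self.stage!r}")
        if self.sex not in SEXES:
            raise CohortError(f"sample {self.sample_id}: bad sex {self.sex!r}")
        if self.smoking not in SMOKING:
            raise CohortError(f"sample {self.sample_id}: bad smoking {self.smoking!r}")
        if self.group == "control":
            if self.histology != "none" or self.stage != "none":
                raise CohortError(
                    f"control sample {self.sample_id} must have histology/stage 'none'"
                )
            if self.age_at_diagnosis is not None or self.time_to_diagnosis is not None:
                raise CohortError(
                    f"control sample {self.sample_id} must not carry diagnosis fields"
                )
        else:
            if self.time_to_diagnosis is None or self.age_at_diagnosis is None:
                raise CohortError(
                    f"case sample {self.sample_id} needs age_at_diagnosis and "
                    "time_to_diagnosis"
                )
            if self.time_to_diagnosis < 0:
                raise CohortError(
                    f"case sample {self.sample_id}: negative time_to_diagnosis"
                )
            gap = self.age_at_diagnosis - self.age_at_donation
            if abs(gap - self.time_to_diagnosis) > 1e-6:
                raise CohortError(
                    f"case sample {self.sample_id}: time_to_diagnosis "
                    f"{self.time_to_diagnosis} inconsistent with donation/diagnosis ages"
                )


@dataclass
class Cohort:
    """Counts + sample metadata + feature annotation, with matched axes."""

    counts: np.ndarray  # (n_samples, n_features), non-negative integers
    samples: list[SampleRecord]
    annotation: list[RnaAnnotation]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise CohortError("counts must be a 2-D matrix")
        if self.counts.shape != (len(self.samples), len(self.annotation)):
            raise CohortError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.samples)} samples x {len(self.annotation)} features"
            )
        if self.counts.size and (
            not np.issubdtype(self.counts.dtype, np.integer) or (self.counts < 0).any()
        ):
            raise CohortError("counts must be non-negative integers")
        sids = self.sample_ids
        if len(set(sids)) != len(sids):
            dup = _first_duplicate(sids)
            raise CohortError(f"duplicated sample_id {dup!r}")
        fids = self.feature_ids
        if len(set(fids)) != len(fids):
            dup = _first_duplicate(fids)
            raise CohortError(f"duplicated feature_id {dup!r}")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def feature_ids(self) -> list[str]:
        return [a.feature_id for a in self.annotation]

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_features(self) -> int:
        return len(self.annotation)

    def subset_samples(self, sample_ids: list[str]) -> "Cohort":
        """Row-subset (and reorder) by sample id."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise CohortError(f"unknown sample ids: {missing[:5]}")
        rows = [index[s] for s in sample_ids]
        return Cohort(
            counts=self.counts[rows, :].copy(),
            samples=[self.samples[i] for i in rows],
            annotation=list(self.annotation),
        )

    def subset_features(self, feature_ids: list[str]) -> "Cohort":
        """Column-subset (and reorder) by feature id."""
        index = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in feature_ids if f not in index]
        if missing:
            raise CohortError(f"unknown feature ids: {missing[:5]}")
        cols = [index[f] for f in feature_ids]
        return Cohort(
            counts=self.counts[:, cols].copy(),
            samples=list(self.samples),
            annotation=[self.annotation[i] for i in cols],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        return (
            np.array_equal(self.counts, other.counts)
            and self.samples == other.samples
            and self.annotation == other.annotation
        )


# ---------------------------------------------------------------------------
# Simulation configuration
# ---------------------------------------------------------------------------


@dataclass
class SignalSpec:
    """A planted case/control expression difference.

    The negative-binomial mean of every feature in ``feature_ids`` is
    multiplied by ``2**log2_fold_change`` for case samples whose histology
    matches (``'all'`` matches every histology, including 'other') and
    whose time to diagnosis falls in ``window`` (half-open ``[start, end)``
    in years; ``None`` means the full horizon).  Controls never carry
    signal.
    """

    feature_ids: tuple[str, ...]
    log2_fold_change: float
    histology: str = "all"  # all | NSCLC | SCLC
    window: tuple[float, float] | None = None

    def applies_to(self, record: SampleRecord) -> bool:
        if record.group != "case":
            return False
        if self.histology != "all" and record.histology != self.histology:
            # 'other' histology receives only the all-histology signals
            return False
        if self.window is not None:
            lo, hi = self.window
            t = record.time_to_diagnosis
            if not (lo <= t < hi):
                return False
        return True


@dataclass
class ConfounderEffects:
    """Multiplicative confounder effects on NB means.

    ``bdg_log_scale_sd`` draws one global library-scale log-factor per
    blood-donor group (a technical batch).  ``sex_log2_sd`` and
    ``age_log2_slope_sd`` draw small per-feature random effects: a log2
    shift for male vs female, and a log2 slope per decade of donation age.
    """

    bdg_log_scale_sd: float = 0.3
    sex_log2_sd: float = 0.15
    age_log2_slope_sd: float = 0.10


@dataclass
class SimConfig:
    """Parameters of the synthetic prediagnostic serum cohort.

    Defaults emulate the study design: roughly 70% male, donation in
    middle age, time to diagnosis spread over a 10-year horizon, four
    blood-donor groups, a mostly-smoker population, and a histology mix
    dominated by NSCLC.  ``features_per_class`` defaults to the post-filter
    serum RNA panel composition scaled down 5x for desk-scale work
    (``full_scale=True`` selects the full composition).
    """

    n_case_individuals: int = 80
    n_control_individuals: int = 100
    extra_samples_per_case_prob: float = 0.35
    features_per_class: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_FEATURES_PER_CLASS)
    )
    nb_mean_log_range: tuple[float, float] = (1.0, 3.0)  # log10 of NB mean
    nb_dispersion: float = 0.2  # variance = m + phi * m^2
    libsize_log_sd: float = 0.3
    indiv_effect_log_sd: float = 0.2
    confounder_effects: ConfounderEffects = field(default_factory=ConfounderEffects)
    signal: list[SignalSpec] = field(default_factory=list)
    smoking_mix: tuple[float, float, float] = (0.45, 0.45, 0.10)
    histology_mix: tuple[float, float, float] = (0.68, 0.23, 0.09)
    stage_mix: tuple[float, float, float, float] = (0.19, 0.26, 0.51, 0.04)
    bdg_labels: tuple[str, ...] = ("BDg1", "BDg2", "BDg3", "BDg4")
    bdg_mix_case: tuple[float, ...] | None = None
    bdg_mix_control: tuple[float, ...] | None = None
    p_male_case: float = 0.70
    p_male_control: float = 0.70
    case_age_mean: float = 54.0
    case_age_sd: float = 8.0
    control_age_mean: float = 50.0
    control_age_sd: float = 10.0
    horizon: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_case_individuals <= 0 or self.n_control_individuals <= 0:
            raise CohortError("individual counts must be positive")
        if not 0.0 <= self.extra_samples_per_case_prob <= 1.0:
            raise CohortError("extra_samples_per_case_prob must be in [0, 1]")
        for cls, n in self.features_per_class.items():
            if cls not in RNA_CLASSES:
                raise CohortError(f"unknown RNA class {cls!r} in features_per_class")
            if n <= 0:
                raise CohortError(f"features_per_class[{cls!r}] must be positive")
        for name, mix in (
            ("smoking_mix", self.smoking_mix),
            ("histology_mix", self.histology_mix),
            ("stage_mix", self.stage_mix),
        ):
            if abs(sum(mix) - 1.0) > 1e-9:
                raise CohortError(f"{name} must sum to 1 (got {sum(mix)})")
            if any(p < 0 for p in mix):
                raise CohortError(f"{name} entries must be non-negative")
        for name, mix in (
            ("bdg_mix_case", self.bdg_mix_case),
            ("bdg_mix_control", self.bdg_mix_control),
        ):
            if mix is not None:
                if len(mix) != len(self.bdg_labels):
                    raise CohortError(f"{name} length must match bdg_labels")
                if abs(sum(mix) - 1.0) > 1e-9:
                    raise CohortError(f"{name} must sum to 1")
        if self.nb_dispersion < 0:
            raise CohortError("nb_dispersion must be >= 0")
        if self.horizon <= 0:
            raise CohortError("horizon must be positive")


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def _make_annotation(features_per_class: dict[str, int]) -> list[RnaAnnotation]:
    ann: list[RnaAnnotation] = []
    for cls in RNA_CLASSES:
        n = features_per_class.get(cls, 0)
        for i in range(n):
            ann.append(RnaAnnotation(f"{cls}_{i:04d}", cls))
    return ann


def generate_cohort(config: SimConfig) -> Cohort:
    """Simulate a seeded synthetic cohort.

    Counts are negative-binomial with per-feature baseline means drawn
    log-uniform over ``nb_mean_log_range`` (base 10) and dispersion
    ``nb_dispersion`` (variance ``m + phi*m**2``).  Per-sample library
    sizes, per-individual random effects, and the configured confounder
    effects act multiplicatively on the mean; planted signals multiply
    the means of their features by ``2**log2_fold_change`` in matching
    case samples only.  Identical configs (including the seed) produce
    identical cohorts.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    annotation = _make_annotation(config.features_per_class)
    feature_ids = [a.feature_id for a in annotation]
    feature_index = {f: i for i, f in enumerate(feature_ids)}
    for spec in config.signal:
        unknown = [f for f in spec.feature_ids if f not in feature_index]
        if unknown:
            raise CohortError(f"signal refers to unknown feature_ids: {unknown[:5]}")

    n_feat = len(annotation)
    lo, hi = config.nb_mean_log_range
    base_mean = 10.0 ** rng.uniform(lo, hi, size=n_feat)

    eff = config.confounder_effects
    bdg_log_scale = {
        b: rng.normal(0.0, eff.bdg_log_scale_sd) for b in config.bdg_labels
    }
    sex_log2 = rng.normal(0.0, eff.sex_log2_sd, size=n_feat)
    age_log2_slope = rng.normal(0.0, eff.age_log2_slope_sd, size=n_feat)

    samples: list[SampleRecord] = []
    indiv_effects: list[float] = []  # per sample, log-scale individual effect

    def _draw_common(group: str, rng: np.random.Generator) -> tuple[str, float, str, str]:
        p_male = config.p_male_case if group == "case" else config.p_male_control
        sex = "male" if rng.random() < p_male else "female"
        if group == "case":
            age = rng.normal(config.case_age_mean, config.case_age_sd)
        else:
            age = rng.normal(config.control_age_mean, config.control_age_sd)
        age = float(np.clip(age, 25.0, 75.0))
        mix = (
            config.bdg_mix_case if group == "case" else config.bdg_mix_control
        )
        if mix is None:
            bdg = config.bdg_labels[rng.integers(len(config.bdg_labels))]
        else:
            bdg = config.bdg_labels[rng.choice(len(mix), p=np.asarray(mix))]
        smoking = ("current", "former", "never")[
            rng.choice(3, p=np.asarray(config.smoking_mix))
        ]
        return sex, age, smoking, bdg

    for i in range(config.n_case_individuals):
        sex, age, smoking, bdg = _draw_common("case", rng)
        histology = ("NSCLC", "SCLC", "other")[
            rng.choice(3, p=np.asarray(config.histology_mix))
        ]
        stage = ("early", "locally_advanced", "advanced", "unknown")[
            rng.choice(4, p=np.asarray(config.stage_mix))
        ]
        indiv_eff = rng.normal(0.0, config.indiv_effect_log_sd)
        n_samp = 1 + int(rng.random() < config.extra_samples_per_case_prob)
        # diagnosis is a property of the individual; repeated donations
        # happen at different prediagnostic times
        ttds = np.sort(rng.uniform(0.0, config.horizon, size=n_samp))[::-1]
        age_dx = age + float(ttds[0])
        for k, ttd in enumerate(ttds):
            ttd = float(ttd)
            samples.append(
                SampleRecord(
                    sample_id=f"case_{i:04d}_s{k}",
                    individual_id=f"caseind_{i:04d}",
                    group="case",
                    histology=histology,
                    stage=stage,
                    sex=sex,
                    age_at_donation=round(age_dx - ttd, 6),
                    age_at_diagnosis=round(age_dx, 6),
                    time_to_diagnosis=round(age_dx - round(age_dx - ttd, 6), 6),
                    smoking=smoking,
                    bdg=bdg,
                )
            )
            indiv_effects.append(indiv_eff)

    for i in range(config.n_control_individuals):
        sex, age, smoking, bdg = _draw_common("control", rng)
        indiv_eff = rng.normal(0.0, config.indiv_effect_log_sd)
        samples.append(
            SampleRecord(
                sample_id=f"ctrl_{i:04d}_s0",
                individual_id=f"ctrlind_{i:04d}",
                group="control",
                histology="none",
                stage="none",
                sex=sex,
                age_at_donation=round(age, 6),
                age_at_diagnosis=None,
                time_to_diagnosis=None,
                smoking=smoking,
                bdg=bdg,
            )
        )
        indiv_effects.append(indiv_eff)

    n_samp = len(samples)
    libsize_log = rng.normal(0.0, config.libsize_log_sd, size=n_samp)

    counts = np.empty((n_samp, n_feat), dtype=np.int64)
    phi = config.nb_dispersion
    for si, rec in enumerate(samples):
        mean = base_mean * np.exp(libsize_log[si] + indiv_effects[si])
        mean = mean * np.exp(bdg_log_scale[rec.bdg])
        if rec.sex == "male":
            mean = mean * np.exp2(sex_log2)
        mean = mean * np.exp2(age_log2_slope * (rec.age_at_donation - 50.0) / 10.0)
        for spec in config.signal:
            if spec.applies_to(rec):
                idx = [feature_index[f] for f in spec.feature_ids]
                mean = mean.copy()
                mean[idx] *= 2.0 ** spec.log2_fold_change
        if phi > 0:
            # NB via gamma-Poisson mixture: shape 1/phi, scale phi*mean
            lam = rng.gamma(shape=1.0 / phi, scale=phi * mean)
            counts[si, :] = rng.poisson(lam)
        else:
            counts[si, :] = rng.poisson(mean)

    return Cohort(counts=counts, samples=samples, annotation=annotation)


# ---------------------------------------------------------------------------
# On-disk layout
# ---------------------------------------------------------------------------

SAMPLE_COLUMNS = [
    "sample_id",
    "individual_id",
    "group",
    "histology",
    "stage",
    "sex",
    "age_at_donation",
    "age_at_diagnosis",
    "time_to_diagnosis",
    "smoking",
    "bdg",
]


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write counts.tsv, samples.tsv, annotation.tsv under ``out_dir``.

    Features are written in lexicographic order; column order is stable,
    so identical cohorts produce identical bytes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    order = sorted(range(cohort.n_features), key=lambda i: cohort.feature_ids[i])
    fids = [cohort.feature_ids[i] for i in order]

    counts_df = pd.DataFrame(
        cohort.counts[:, order], index=cohort.sample_ids, columns=fids
    )
    counts_df.index.name = "sample_id"
    counts_path = out / "counts.tsv"
    counts_df.to_csv(counts_path, sep="\t")

    rows = []
    for s in cohort.samples:
        d = dataclasses.asdict(s)
        for key in ("age_at_diagnosis", "time_to_diagnosis"):
            if d[key] is None:
                d[key] = ""
            else:
                d[key] = repr(float(d[key]))
        d["age_at_donation"] = repr(float(d["age_at_donation"]))
        rows.append(d)
    samples_df = pd.DataFrame(rows, columns=SAMPLE_COLUMNS)
    samples_path = out / "samples.tsv"
    samples_df.to_csv(samples_path, sep="\t", index=False)

    ann_df = pd.DataFrame(
        [(f, cohort.annotation[i].rna_class) for f, i in zip(fids, order)],
        columns=["feature_id", "rna_class"],
    )
    annotation_path = out / "annotation.tsv"
    ann_df.to_csv(annotation_path, sep="\t", index=False)

    return {
        "counts": counts_path,
        "samples": samples_path,
        "annotation": annotation_path,
    }


def read_cohort(
    counts_path: str | Path,
    metadata_path: str | Path,
    annotation_path: str | Path,
) -> Cohort:
    """Load a cohort from the three-TSV layout, validating all invariants."""
    counts_df = pd.read_csv(counts_path, sep="\t", dtype=str, keep_default_na=False)
    if counts_df.columns[0] != "sample_id":
        raise CohortError(
            f"{counts_path}: first column must be 'sample_id', "
            f"got {counts_df.columns[0]!r}"
        )
    sample_ids = counts_df["sample_id"].tolist()
    feature_ids = list(counts_df.columns[1:])

    raw = counts_df.iloc[:, 1:]
    numeric = raw.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = ~np.isfinite(numeric) | (numeric < 0) | (numeric != np.floor(numeric))
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise CohortError(
            f"{counts_path}: non-integer or negative count {raw.iat[i, j]!r} at "
            f"sample {sample_ids[i]!r}, feature {feature_ids[j]!r} "
            f"(row {i + 2}, column {j + 2})"
        )
    counts = numeric.astype(np.int64)

    meta = pd.read_csv(metadata_path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = [c for c in SAMPLE_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise CohortError(f"{metadata_path}: missing columns {missing_cols}")
    meta_index = {row["sample_id"]: row for _, row in meta.iterrows()}
    absent = [s for s in sample_ids if s not in meta_index]
    if absent:
        raise CohortError(
            f"{metadata_path}: no metadata for sample_id {absent[0]!r}"
            + (f" (+{len(absent) - 1} more)" if len(absent) > 1 else "")
        )
    extra = [s for s in meta_index if s not in set(sample_ids)]
    if extra:
        raise CohortError(
            f"{metadata_path}: metadata for unknown sample_id {extra[0]!r}"
        )

    def _opt_float(v: str) -> float | None:
        return None if v == "" else float(v)

    samples = []
    for sid in sample_ids:
        row = meta_index[sid]
        samples.append(
            SampleRecord(
                sample_id=row["sample_id"],
                individual_id=row["individual_id"],
                group=row["group"],
                histology=row["histology"],
                stage=row["stage"],
                sex=row["sex"],
                age_at_donation=float(row["age_at_donation"]),
                age_at_diagnosis=_opt_float(row["age_at_diagnosis"]),
                time_to_diagnosis=_opt_float(row["time_to_diagnosis"]),
                smoking=row["smoking"],
                bdg=row["bdg"],
            )
        )

    ann_df = pd.read_csv(annotation_path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("feature_id", "rna_class"):
        if col not in ann_df.columns:
            raise CohortError(f"{annotation_path}: missing column {col!r}")
    ann_index = dict(zip(ann_df["feature_id"], ann_df["rna_class"]))
    unannotated = [f for f in feature_ids if f not in ann_index]
    if unannotated:
        raise CohortError(
            f"{annotation_path}: no annotation for feature {unannotated[0]!r}"
        )
    annotation = [RnaAnnotation(f, ann_index[f]) for f in feature_ids]

    return Cohort(counts=counts, samples=samples, annotation=annotation)


def _first_duplicate(items: list[str]) -> str:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return ""
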