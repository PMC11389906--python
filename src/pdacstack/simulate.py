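"""Synthetic serum-proteomics cohort generator.

Emulates the structure of a low-prevalence symptomatic cohort used to
develop a PDAC biomarker signature: 15 benign/confounding diagnosis
classes plus one healthy screening-derived class (all controls) and
PDAC cases with stage labels; clinical covariates whose marginals track
the published cohort characteristics; 12 binary presenting-symptom
flags (symptomatic source only); an optional QCancer-style percent-risk
score; two measurement batches with per-assay offsets and shared bridge
samples; and a ~97-marker panel (92 multiplex NPX-scale analytes plus 5
ELISA markers simulated on a log scale).

Marker values are additive on the NPX log2 scale:

    value = baseline(marker) + shift(marker, group) + batch_offset + noise

so planted effects in ``effect_map`` have exact mean-difference
semantics and downstream parameter-recovery tests can check them
against their standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CONTROL_CLASSES",
    "PDAC",
    "STAGES",
    "SYMPTOMS",
    "ELISA_MARKERS",
    "default_marker_panel",
    "SimulationConfig",
    "CohortTable",
    "BridgePairs",
    "generate_cohort",
    "generate_bridge_pairs",
]

PDAC = "PDAC"

CONTROL_CLASSES = [
    "Sphincter of Oddi dysfunction",
    "Pancreatic Cyst",
    "Other Cancer",
    "Other Biliary Duct Disease",
    "No Relevant Diagnosis",
    "Liver Disease",
    "Irritable Bowel Syndrome",
    "IgG4 Disease",
    "Gastritis/Reflux Disease",
    "Gallstone Disease",
    "Familial Pancreatic Cancer",
    "Chronic Pancreatitis",
    "Acute Pancreatitis",
    "Isolated LFT Derangement",
    "Non-specific Abdominal Pain",
    "Healthy",
]

STAGES = ["I", "II", "III", "IV", "unknown"]

SYMPTOMS = [
    "Jaundice",
    "Weight Loss",
    "Abdominal Pain",
    "Back Pain",
    "Change in Bowel Habit",
    "Asymptomatic LFT Derangement",
    "Vomiting",
    "Rectal Bleeding",
    "Reflux",
    "Bloating",
    "Heartburn",
    "Anaemia/Dysphagia",
]

ELISA_MARKERS = ["CA19-9", "IL6ST", "VWF", "PKM2", "THBS2"]

ETHNICITIES = ["Caucasian", "Unknown", "Asian", "Other", "Afro/Caribbean"]

# Multiplex oncology-panel assay names that appear in the signature
# literature; padded with neutral placeholders to the panel size of 92.
_NAMED_PANEL = [
    "ICOSLG", "GPNMB", "ESM1", "DLL1", "ERBB2", "FCRLB", "CEACAM5", "EGF",
    "CTSV", "FASLG", "CPE", "CA9", "CD207", "CRP", "CDKN1A", "EPHA2",
    "ITGAV", "MUC16", "CXCL13", "ERBB3", "FOLR1", "FADD", "ERBB4", "CD27",
    "AREG", "ADAMTS15", "ABL1", "ANXA1", "CXCL17", "CD70", "CEACAM1",
    "CD48", "CD160", "CYR61", "CRNN", "ADAM8", "FOLR3", "GZMB", "SYND1",
    "PPY", "TGFA", "VEGFA",
]


def default_marker_panel() -> list[str]:
    """92 multiplex assay names plus the 5 ELISA markers."""
    panel = list(_NAMED_PANEL)
    i = len(panel) + 1
    while len(panel) < 92:
        panel.append(f"ONC2_{i:02d}")
        i += 1
    return panel + list(ELISA_MARKERS)


def _default_control_counts() -> dict[str, int]:
    # 421 symptomatic-source controls across 15 benign classes plus 72
    # screening-source healthy controls.
    return {
        "Sphincter of Oddi dysfunction": 10,
        "Pancreatic Cyst": 40,
        "Other Cancer": 20,
        "Other Biliary Duct Disease": 30,
        "No Relevant Diagnosis": 35,
        "Liver Disease": 30,
        "Irritable Bowel Syndrome": 25,
        "IgG4 Disease": 6,
        "Gastritis/Reflux Disease": 50,
        "Gallstone Disease": 45,
        "Familial Pancreatic Cancer": 12,
        "Chronic Pancreatitis": 38,
        "Acute Pancreatitis": 30,
        "Isolated LFT Derangement": 20,
        "Non-specific Abdominal Pain": 30,
        "Healthy": 72,
    }


def _default_effect_map() -> dict[tuple[str, str], float]:
    # Case shifts concentrated on the markers reported as high-importance,
    # plus benign confounding shifts (pancreatitis elevates CA19-9/CRP).
    eff = {
        ("CA19-9", PDAC): 1.8,
        ("VWF", PDAC): 0.9,
        ("CPE", PDAC): 0.8,
        ("CTSV", PDAC): 0.7,
        ("CEACAM1", PDAC): 0.6,
        ("CD160", PDAC): 0.5,
        ("IL6ST", PDAC): 0.5,
        ("THBS2", PDAC): 0.5,
        ("PKM2", PDAC): 0.4,
        ("MUC16", PDAC): 0.5,
        ("CEACAM5", PDAC): 0.5,
        ("CA19-9", "Chronic Pancreatitis"): 0.6,
        ("CA19-9", "Acute Pancreatitis"): 0.5,
        ("CRP", "Acute Pancreatitis"): 1.2,
        ("CRP", "IgG4 Disease"): 0.8,
        ("VWF", "Liver Disease"): 0.4,
    }
    return eff


def _default_symptom_model() -> dict[str, tuple[float, float]]:
    # (case prevalence, control prevalence); directions follow the
    # reported associations: jaundice/weight loss enriched in cases,
    # reflux/bloating in benign controls.
    return {
        "Jaundice": (0.50, 0.07),
        "Weight Loss": (0.55, 0.22),
        "Abdominal Pain": (0.50, 0.60),
        "Back Pain": (0.25, 0.20),
        "Change in Bowel Habit": (0.20, 0.15),
        "Asymptomatic LFT Derangement": (0.15, 0.10),
        "Vomiting": (0.15, 0.09),
        "Rectal Bleeding": (0.04, 0.06),
        "Reflux": (0.10, 0.25),
        "Bloating": (0.12, 0.22),
        "Heartburn": (0.08, 0.15),
        "Anaemia/Dysphagia": (0.10, 0.08),
    }


@dataclass
class CovariateModel:
    """Per-arm clinical covariate distributions (cohort marginals)."""

    age_case: tuple = (69.72, 9.5, 43.0, 91.0)  # mean, sd, min, max
    age_control: tuple = (57.44, 15.0, 19.0, 93.0)
    age_healthy: tuple = (62.95, 6.5, 50.44, 76.86)
    male_prob_case: float = 31 / 46
    male_prob_control: float = 180 / 421
    male_prob_healthy: float = 0.0  # screening arm recruited women only
    diabetes_prob_case: float = 10 / 46
    diabetes_prob_control: float = 75 / 421
    diabetes_prob_healthy: float = 3 / 72
    bmi_case: tuple = (24.84, 4.0, 12.0, 42.0)
    bmi_control: tuple = (25.30, 3.8, 15.0, 40.0)
    bmi_healthy: tuple = (26.53, 4.5, 17.0, 43.0)
    ethnicity_probs_case: tuple = (21, 21, 3, 2, 0)
    ethnicity_probs_control: tuple = (291, 60, 30, 18, 22)
    ethnicity_probs_healthy: tuple = (0, 72, 0, 0, 0)


@dataclass
class QCancerModel:
    """Logistic-linked percent-risk score correlated with case status."""

    intercept: float = -4.0
    age_per_year: float = 0.05  # centred at 60
    male: float = 0.3
    case: float = 1.4
    jaundice: float = 1.5
    weight_loss: float = 1.0
    noise_sd: float = 0.5  # on the logit scale
    fraction_scored: float = 0.1


@dataclass
class BatchModel:
    n_batches: int = 2
    offset_sd: float = 0.3
    n_bridge: int = 16


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults reproduce the published
    cohort's marginal structure (class counts, stage mix, covariate
    means, symptom directions), which are generation targets, not
    fitted values."""

    n_per_control_class: dict = field(default_factory=_default_control_counts)
    n_cases: int = 46
    stage_counts: dict = field(
        default_factory=lambda: {"I": 4, "II": 15, "III": 10, "IV": 16, "unknown": 1}
    )
    marker_panel: list = field(default_factory=default_marker_panel)
    elisa_markers: list = field(default_factory=lambda: list(ELISA_MARKERS))
    effect_map: dict = field(default_factory=_default_effect_map)
    covariate_model: CovariateModel = field(default_factory=CovariateModel)
    symptom_model: dict = field(default_factory=_default_symptom_model)
    qcancer_model: QCancerModel = field(default_factory=QCancerModel)
    batch_model: BatchModel = field(default_factory=BatchModel)
    noise_sd: float = 1.0
    baseline_mean: float = 5.0
    baseline_sd: float = 1.0
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self):
        groups = set(CONTROL_CLASSES) | {PDAC}
        for cls, n in self.n_per_control_class.items():
            if cls not in CONTROL_CLASSES:
                raise ValueError(f"unknown diagnosis class {cls!r}")
            if n < 0:
                raise ValueError(f"negative count for class {cls!r}")
        if self.n_cases < 0:
            raise ValueError("n_cases must be >= 0")
        if sum(self.stage_counts.values()) != self.n_cases:
            raise ValueError("stage counts must sum to n_cases")
        if any(s not in STAGES for s in self.stage_counts):
            raise ValueError("unknown stage label")
        for (marker, group) in self.effect_map:
            if marker not in self.marker_panel:
                raise ValueError(f"effect_map references unknown marker {marker!r}")
            if group not in groups:
                raise ValueError(f"effect_map references unknown group {group!r}")
        for sym, (pc, pn) in self.symptom_model.items():
            if not (0 <= pc <= 1 and 0 <= pn <= 1):
                raise ValueError(f"symptom probabilities for {sym!r} outside [0,1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not 0 <= self.missing_rate <= 1:
            raise ValueError("missing_rate must be in [0,1]")
        return self


METADATA_COLUMNS = [
    "sample_id",
    "source_cohort",
    "diagnosis_class",
    "stage",
    "label",
    "age",
    "gender",
    "bmi",
    "diabetes",
    "ethnicity",
]


class CohortTable:
    """Sample-level cohort table: clinical metadata, symptoms, QCancer
    score, batch, and the marker matrix (all markers on a log scale).

    Thin wrapper over a :class:`pandas.DataFrame` that validates the
    cohort invariants on construction and knows which marker columns
    are ELISA concentrations (log-transformed in memory, exponentiated
    on disk).
    """

    def __init__(self, data: pd.DataFrame, marker_names: list, elisa_markers=None,
                 validate: bool = True):
        self.data = data.reset_index(drop=True)
        self.marker_names = list(marker_names)
        self.elisa_markers = list(elisa_markers or [m for m in ELISA_MARKERS if m in marker_names])
        if validate:
            self._validate()

    def _validate(self):
        d = self.data
        required = METADATA_COLUMNS + ["qcancer", "batch"] + self.marker_names
        missing = [c for c in required if c not in d.columns]
        if missing:
            raise ValueError(f"cohort table is missing required columns: {missing}")
        known = set(CONTROL_CLASSES) | {PDAC}
        bad = set(d["diagnosis_class"]) - known
        if bad:
            raise ValueError(f"unknown diagnosis classes: {sorted(bad)}")
        is_case = d["diagnosis_class"] == PDAC
        if not (d.loc[is_case, "label"] == "case").all() or not (
            d.loc[~is_case, "label"] == "control"
        ).all():
            raise ValueError("label must be 'case' iff diagnosis_class is PDAC")
        if d.loc[is_case, "stage"].isna().any() or d.loc[~is_case, "stage"].notna().any():
            raise ValueError("stage must be present exactly for cases")
        M = d[self.marker_names].to_numpy(dtype=float)
        if self._expected_complete(d) and not np.isfinite(M).all():
            raise ValueError("marker values must be finite")
        ages = d["age"].to_numpy(dtype=float)
        if (ages < 18).any() or (ages > 100).any():
            raise ValueError("age must lie in [18, 100]")
        screening = d["source_cohort"] == "screening"
        for s in SYMPTOMS:
            if s in d.columns and d.loc[screening, s].notna().any():
                raise ValueError("screening-source samples must not carry symptoms")
        if d.loc[screening, "qcancer"].notna().any():
            raise ValueError("screening-source samples must not carry QCancer scores")

    @staticmethod
    def _expected_complete(d):
        return True

    def __len__(self):
        return len(self.data)

    @property
    def y(self) -> np.ndarray:
        """Binary outcome: PDAC coded 1 throughout."""
        return (self.data["label"] == "case").to_numpy(dtype=int)

    @property
    def symptom_names(self):
        return [s for s in SYMPTOMS if s in self.data.columns]

    def markers(self) -> pd.DataFrame:
        return self.data[self.marker_names]

    def subset(self, mask) -> "CohortTable":
        return CohortTable(
            self.data.loc[mask].copy(), self.marker_names, self.elisa_markers, validate=False
        )

    def subset_ids(self, sample_ids) -> "CohortTable":
        keep = self.data["sample_id"].isin(set(sample_ids))
        return self.subset(keep.to_numpy())

    def feature_frame(self, features) -> pd.DataFrame:
        """Numeric design columns for modelling.

        Markers pass through; ``gender`` is coded male=1, ``diabetes``
        yes=1, ``age``/``bmi`` numeric, symptoms 0/1.
        """
        cols = {}
        d = self.data
        for f in features:
            if f in self.marker_names or f in ("age", "bmi", "qcancer"):
                cols[f] = d[f].to_numpy(dtype=float)
            elif f == "gender":
                cols[f] = (d[f] == "male").to_numpy(dtype=float)
            elif f == "diabetes":
                cols[f] = (d[f] == "yes").to_numpy(dtype=float)
            elif f in SYMPTOMS:
                cols[f] = d[f].to_numpy(dtype=float)
            else:
                raise KeyError(f"unknown feature {f!r}")
        return pd.DataFrame(cols, index=d.index)

    def copy(self) -> "CohortTable":
        return CohortTable(self.data.copy(), self.marker_names, self.elisa_markers,
                           validate=False)


@dataclass
class BridgePairs:
    """Reference samples measured in two batches (same latent values)."""

    reference: pd.DataFrame  # bridge samples x markers, reference batch
    new: pd.DataFrame  # same samples re-measured in the other batch
    reference_batch: str = "batch1"
    new_batch: str = "batch2"

    def __len__(self):
        return len(self.reference)


def _truncnorm(rng, mean, sd, lo, hi, n):
    vals = rng.normal(mean, sd, size=n)
    for _ in range(20):
        bad = (vals < lo) | (vals > hi)
        if not bad.any():
            break
        vals[bad] = rng.normal(mean, sd, size=bad.sum())
    return np.clip(vals, lo, hi)


def generate_cohort(config: SimulationConfig, seed: int | None = None) -> CohortTable:
    """Draw a cohort with exactly the configured class/stage counts.

    Deterministic given ``(config, seed)``.  Latent marker values and
    batch offsets are stashed on the returned table (``.sim_latent_``,
    ``.sim_batch_offsets_``) so that bridge samples can later be
    re-measured under both batch effects.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    cov = config.covariate_model
    markers = list(config.marker_panel)
    baselines = rng.normal(config.baseline_mean, config.baseline_sd, size=len(markers))
    batch_names = [f"batch{i + 1}" for i in range(config.batch_model.n_batches)]
    offsets = {batch_names[0]: np.zeros(len(markers))}
    for b in batch_names[1:]:
        offsets[b] = rng.normal(0.0, config.batch_model.offset_sd, size=len(markers))

    rows = []
    latents = []
    eprobs = {
        "case": np.asarray(cov.ethnicity_probs_case, dtype=float),
        "control": np.asarray(cov.ethnicity_probs_control, dtype=float),
        "healthy": np.asarray(cov.ethnicity_probs_healthy, dtype=float),
    }

    def draw_arm(n, group, stage_labels=None):
        if n == 0:
            return
        healthy = group == "Healthy"
        case = group == PDAC
        arm = "case" if case else ("healthy" if healthy else "control")
        age_par = {"case": cov.age_case, "healthy": cov.age_healthy, "control": cov.age_control}[arm]
        bmi_par = {"case": cov.bmi_case, "healthy": cov.bmi_healthy, "control": cov.bmi_control}[arm]
        male_p = {"case": cov.male_prob_case, "healthy": cov.male_prob_healthy,
                  "control": cov.male_prob_control}[arm]
        diab_p = {"case": cov.diabetes_prob_case, "healthy": cov.diabetes_prob_healthy,
                  "control": cov.diabetes_prob_control}[arm]
        ages = _truncnorm(rng, age_par[0], age_par[1], age_par[2], age_par[3], n)
        bmis = _truncnorm(rng, bmi_par[0], bmi_par[1], bmi_par[2], bmi_par[3], n)
        male = rng.uniform(size=n) < male_p
        diab = rng.uniform(size=n) < diab_p
        ep = eprobs[arm]
        eth = rng.choice(ETHNICITIES, size=n, p=ep / ep.sum())
        source = "screening" if healthy else "symptomatic"
        batch = batch_names[-1] if healthy else batch_names[0]
        shift = np.array(
            [config.effect_map.get((m, group), 0.0) for m in markers]
        )
        for i in range(n):
            latent = baselines + shift
            meas = latent + offsets[batch] + rng.normal(0.0, config.noise_sd, len(markers))
            row = {
                "sample_id": f"S{len(rows):04d}",
                "source_cohort": source,
                "diagnosis_class": group,
                "stage": (stage_labels[i] if case else None),
                "label": "case" if case else "control",
                "age": round(float(ages[i]), 2),
                "gender": "male" if male[i] else "female",
                "bmi": round(float(bmis[i]), 2),
                "diabetes": "yes" if diab[i] else "no",
                "ethnicity": eth[i],
                "batch": batch,
            }
            if source == "symptomatic":
                for s, (pc, pn) in config.symptom_model.items():
                    row[s] = float(rng.uniform() < (pc if case else pn))
            else:
                for s in config.symptom_model:
                    row[s] = np.nan
            row["qcancer"] = np.nan
            for m, v in zip(markers, meas):
                row[m] = v
            rows.append(row)
            latents.append(latent)

    for cls in CONTROL_CLASSES:
        draw_arm(config.n_per_control_class.get(cls, 0), cls)
    stage_labels = [s for s in STAGES for _ in range(config.stage_counts.get(s, 0))]
    draw_arm(config.n_cases, PDAC, stage_labels)

    data = pd.DataFrame(rows)
    # QCancer percent risk on a random subset of symptomatic samples
    qm = config.qcancer_model
    symptomatic = (data["source_cohort"] == "symptomatic").to_numpy()
    eligible = np.flatnonzero(symptomatic)
    n_scored = int(round(qm.fraction_scored * len(eligible)))
    scored = rng.choice(eligible, size=n_scored, replace=False) if n_scored else []
    for i in scored:
        lin = (
            qm.intercept
            + qm.age_per_year * (data.at[i, "age"] - 60.0)
            + qm.male * (data.at[i, "gender"] == "male")
            + qm.case * (data.at[i, "label"] == "case")
            + qm.jaundice * ("Jaundice" in data.columns and data.at[i, "Jaundice"] == 1.0)
            + qm.weight_loss * (
                "Weight Loss" in data.columns and data.at[i, "Weight Loss"] == 1.0
            )
            + rng.normal(0.0, qm.noise_sd)
        )
        data.at[i, "qcancer"] = 100.0 / (1.0 + np.exp(-lin))

    if config.missing_rate > 0:
        mask = rng.uniform(size=(len(data), len(markers))) < config.missing_rate
        M = data[markers].to_numpy()
        M[mask] = np.nan
        data[markers] = M

    order = METADATA_COLUMNS + list(config.symptom_model) + ["qcancer", "batch"] + markers
    table = CohortTable(data[order], markers, config.elisa_markers,
                        validate=config.missing_rate == 0)
    table.sim_latent_ = pd.DataFrame(latents, columns=markers,
                                     index=data["sample_id"].to_numpy())
    table.sim_batch_offsets_ = {b: pd.Series(o, index=markers) for b, o in offsets.items()}
    table.sim_noise_sd_ = config.noise_sd
    return table


def generate_bridge_pairs(
    cohort: CohortTable,
    n_bridge: int = 16,
    seed: int = 0,
    reference_batch: str = "batch1",
    new_batch: str = "batch2",
) -> BridgePairs:
    """Re-measure ``n_bridge`` reference-batch samples under both batch
    effects: identical latent values, independent noise.

    Requires the cohort to have been produced by :func:`generate_cohort`
    (it needs the latent values).  ``n_bridge = 0`` returns an empty
    pair set, which downstream bridging refuses to use.
    """
    if not hasattr(cohort, "sim_latent_"):
        raise ValueError("bridge pairs need a simulated cohort with latent values")
    rng = np.random.default_rng(seed)
    in_ref = cohort.data.loc[cohort.data["batch"] == reference_batch, "sample_id"]
    if n_bridge > len(in_ref):
        raise ValueError(
            f"n_bridge={n_bridge} exceeds the {len(in_ref)} samples in {reference_batch!r}"
        )
    chosen = rng.choice(in_ref.to_numpy(), size=n_bridge, replace=False) if n_bridge else []
    latent = cohort.sim_latent_.loc[list(chosen)]
    off_ref = cohort.sim_batch_offsets_[reference_batch]
    off_new = cohort.sim_batch_offsets_[new_batch]
    sd = cohort.sim_noise_sd_
    noise_ref = rng.normal(0.0, sd, size=latent.shape)
    noise_new = rng.normal(0.0, sd, size=latent.shape)
    return BridgePairs(
        reference=latent + off_ref.to_numpy() + noise_ref,
        new=latent + off_new.to_numpy() + noise_new,
        reference_batch=reference_batch,
        new_batch=new_batch,
    )
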