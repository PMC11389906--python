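"""Cohort I/O, stratified discovery/validation splitting, and
reference-sample bridging normalization.

The split stratifies on age bin x diabetes x case/control label x
diagnosis class (x stage for cases) and allocates two-thirds of each
stratum to discovery, with the rounding direction of fractional strata
randomized by seed so neither arm is systematically inflated.

Bridging normalization aligns a new measurement batch to a reference
batch using shared bridge samples: for each assay, the median of the
paired (new - reference) differences is subtracted from the new batch,
after which the per-assay median bridge difference is exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import (
    CONTROL_CLASSES,
    ELISA_MARKERS,
    METADATA_COLUMNS,
    PDAC,
    SYMPTOMS,
    BridgePairs,
    CohortTable,
)

__all__ = [
    "AGE_BIN_EDGES",
    "age_bin",
    "read_cohort",
    "write_cohort",
    "SplitAssignment",
    "assign_split",
    "bridge_normalize",
]

# (18,28], (28,38], ..., (68,78], [79, inf)
AGE_BIN_EDGES = [28, 38, 48, 58, 68, 78]
_AGE_BIN_LABELS = ["18-28", "29-38", "39-48", "49-58", "59-68", "69-78", "79+"]


def age_bin(age: float) -> str:
    if age < 18:
        raise ValueError("ages below 18 are outside the admissible range")
    idx = int(np.sum(age > np.asarray(AGE_BIN_EDGES)))
    return _AGE_BIN_LABELS[idx]


_ELISA_COMMENT = "# elisa_log_columns="


def write_cohort(cohort: CohortTable, path, exponentiate_elisa: bool = True) -> None:
    """UTF-8 TSV: metadata, symptoms, qcancer, batch, then markers.

    ELISA markers are stored in memory on the log scale; on disk they
    are written as concentrations (exponentiated), declared in a header
    comment so :func:`read_cohort` can invert the transform.
    """
    out = cohort.data.copy()
    elisa = [m for m in cohort.elisa_markers if m in out.columns]
    if exponentiate_elisa:
        for m in elisa:
            out[m] = np.exp(out[m].to_numpy(dtype=float))
    with open(path, "w", encoding="utf-8") as fh:
        if exponentiate_elisa and elisa:
            fh.write(_ELISA_COMMENT + ";".join(elisa) + "\n")
        out.to_csv(fh, sep="\t", index=False)


def read_cohort(path, marker_names=None) -> CohortTable:
    """Read a cohort TSV/CSV, re-applying the log transform to any
    ELISA columns declared in the file's header comment.

    Raises a schema error naming any missing required column and a
    parse error with the row index for non-numeric marker values.
    """
    elisa_logged = []
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith(_ELISA_COMMENT):
            elisa_logged = first.strip()[len(_ELISA_COMMENT):].split(";")
            header_line = fh.readline()
        else:
            header_line = first
        sep = "\t" if "\t" in header_line else ","
        columns = header_line.rstrip("\n").split(sep)
        body = pd.read_csv(fh, sep=sep, names=columns, dtype=str)
    required = METADATA_COLUMNS + ["qcancer", "batch"]
    missing = [c for c in required if c not in body.columns]
    if missing:
        raise ValueError(f"cohort file is missing required columns: {missing}")
    known_meta = set(required) | set(SYMPTOMS)
    if marker_names is None:
        marker_names = [c for c in body.columns if c not in known_meta]
    for col in marker_names + ["age", "bmi", "qcancer"] + [
        s for s in SYMPTOMS if s in body.columns
    ]:
        try:
            body[col] = pd.to_numeric(body[col])
        except (ValueError, TypeError):
            bad = pd.to_numeric(body[col], errors="coerce")
            row = int(np.flatnonzero(bad.isna() & body[col].notna())[0])
            raise ValueError(
                f"non-numeric value in column {col!r} at row {row}"
            ) from None
    body["stage"] = body["stage"].where(body["stage"].notna(), None)
    for m in elisa_logged:
        if m in body.columns:
            body[m] = np.log(body[m].to_numpy(dtype=float))
    return CohortTable(body, marker_names, elisa_markers=elisa_logged or None)


@dataclass
class SplitAssignment:
    """Per-sample discovery/validation arm with the stratum it came from."""

    table: pd.DataFrame  # sample_id, stratum_id, arm
    seed: int

    @property
    def arms(self) -> pd.Series:
        return self.table.set_index("sample_id")["arm"]

    def ids(self, arm: str):
        return self.table.loc[self.table["arm"] == arm, "sample_id"].tolist()

    def discovery(self, cohort: CohortTable) -> CohortTable:
        return cohort.subset_ids(self.ids("discovery"))

    def validation(self, cohort: CohortTable) -> CohortTable:
        return cohort.subset_ids(self.ids("validation"))

    def to_tsv(self, path):
        self.table.to_csv(path, sep="\t", index=False)


def _stratum_id(row) -> str:
    parts = [
        age_bin(float(row["age"])),
        str(row["diabetes"]),
        str(row["label"]),
        str(row["diagnosis_class"]),
    ]
    if row["label"] == "case":
        parts.append(str(row["stage"]))
    return "|".join(parts)


def assign_split(
    cohort: CohortTable,
    seed: int = 0,
    discovery_fraction: float = 2 / 3,
    external_assignment: dict | None = None,
) -> SplitAssignment:
    """Stratified 2/3 discovery / 1/3 validation allocation.

    Within each stratum ``floor`` or ``ceil`` of the fractional target
    is chosen by a seed-determined coin flip, so the discovery count
    deviates from ``round(2/3 * n)`` by at most one.  Samples listed in
    ``external_assignment`` (sample_id -> arm) keep that fixed arm —
    used when screening-source controls carry a split inherited from an
    earlier study.
    """
    if len(cohort) == 0:
        raise ValueError("cannot split an empty cohort")
    rng = np.random.default_rng(seed)
    external_assignment = external_assignment or {}
    records = []
    d = cohort.data
    strata = d.apply(_stratum_id, axis=1)
    for stratum in sorted(strata.unique()):
        members = d.loc[strata == stratum, "sample_id"].tolist()
        fixed = [s for s in members if s in external_assignment]
        free = [s for s in members if s not in external_assignment]
        for s in fixed:
            records.append((s, stratum, external_assignment[s]))
        if not free:
            continue
        target = discovery_fraction * len(free)
        n_disc = int(np.floor(target))
        frac = target - n_disc
        if frac > 0 and rng.uniform() < 0.5:
            n_disc += 1
        n_disc = min(n_disc, len(free))
        chosen = set(rng.choice(free, size=n_disc, replace=False)) if n_disc else set()
        for s in free:
            records.append((s, stratum, "discovery" if s in chosen else "validation"))
    table = pd.DataFrame(records, columns=["sample_id", "stratum_id", "arm"])
    assert len(table) == len(cohort) and table["sample_id"].is_unique
    return SplitAssignment(table=table, seed=seed)


def bridge_normalize(
    batch_ref: CohortTable,
    batch_new: CohortTable,
    bridge_pairs: BridgePairs,
) -> CohortTable:
    """Median-of-paired-differences bridging correction.

    For each assay, the median over bridge samples of
    ``new - reference`` is subtracted from every sample in the new
    batch.  The estimated per-assay offsets are attached to the
    returned table as ``.bridging_offsets_``.
    """
    if len(bridge_pairs) < 2:
        raise ValueError(
            "bridging needs at least 2 bridge pairs; re-measure more shared "
            "reference samples in both batches"
        )
    if list(batch_ref.marker_names) != list(batch_new.marker_names):
        raise ValueError("marker panels of the two batches do not match")
    markers = batch_new.marker_names
    diffs = bridge_pairs.new[markers].to_numpy() - bridge_pairs.reference[markers].to_numpy()
    offsets = pd.Series(np.median(diffs, axis=0), index=markers)
    corrected = batch_new.copy()
    corrected.data[markers] = corrected.data[markers].to_numpy() - offsets.to_numpy()
    corrected.bridging_offsets_ = offsets
    # carry corrected bridge measurements so a second pass is a no-op
    corrected.bridged_pairs_ = BridgePairs(
        reference=bridge_pairs.reference.copy(),
        new=bridge_pairs.new[markers] - offsets,
        reference_batch=bridge_pairs.reference_batch,
        new_batch=bridge_pairs.new_batch,
    )
    return corrected
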