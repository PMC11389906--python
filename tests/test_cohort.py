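"""Cohort I/O round-trips, stratified split allocation, and bridging
normalization against per-assay median oracles."""

import numpy as np
import pandas as pd
import pytest

from pdacstack.cohort import (
    SplitAssignment,
    age_bin,
    assign_split,
    bridge_normalize,
    read_cohort,
    write_cohort,
)
from pdacstack.simulate import BridgePairs, generate_bridge_pairs, generate_cohort

from conftest import small_config


def test_write_read_round_trip(tiny_cohort, tmp_path):
    path = tmp_path / "cohort.tsv"
    write_cohort(tiny_cohort, path)
    back = read_cohort(path)
    assert len(back) == len(tiny_cohort)
    assert back.marker_names == tiny_cohort.marker_names
    np.testing.assert_allclose(
        back.markers().to_numpy(), tiny_cohort.markers().to_numpy(), rtol=0, atol=1e-9
    )
    pd.testing.assert_series_equal(back.data["diagnosis_class"],
                                   tiny_cohort.data["diagnosis_class"])


def test_elisa_markers_written_as_concentrations(tiny_cohort, tmp_path):
    path = tmp_path / "cohort.tsv"
    write_cohort(tiny_cohort, path)
    raw = pd.read_csv(path, sep="\t", comment=None, skiprows=1)
    # on disk CA19-9 is exp() of the in-memory log value
    np.testing.assert_allclose(
        np.log(raw["CA19-9"].to_numpy()),
        tiny_cohort.data["CA19-9"].to_numpy(),
        atol=1e-9,
    )


def test_unknown_diagnosis_class_rejected(tiny_cohort, tmp_path):
    path = tmp_path / "bad.tsv"
    broken = tiny_cohort.copy()
    broken.data.loc[0, "diagnosis_class"] = "Dragon Pox"
    write_cohort(broken, path)
    with pytest.raises(ValueError, match="Dragon Pox"):
        read_cohort(path)


def test_missing_column_named_in_error(tiny_cohort, tmp_path):
    path = tmp_path / "bad.tsv"
    broken = tiny_cohort.copy()
    broken.data = broken.data.drop(columns=["batch"])
    broken.data.to_csv(path, sep="\t", index=False)
    with pytest.raises(ValueError, match="batch"):
        read_cohort(path)


def test_non_numeric_marker_reports_row(tiny_cohort, tmp_path):
    path = tmp_path / "bad.tsv"
    df = tiny_cohort.data.copy()
    df["M1"] = df["M1"].astype(object)
    df.loc[3, "M1"] = "oops"
    df.to_csv(path, sep="\t", index=False)
    with pytest.raises(ValueError, match="M1.*row 3"):
        read_cohort(path)


def test_full_size_file_round_trip(default_cohort, tmp_path):
    path = tmp_path / "full.tsv"
    write_cohort(default_cohort, path)
    back = read_cohort(path)
    assert len(back) == 539


def test_age_bins_partition_range():
    assert age_bin(19) == "18-28"
    assert age_bin(28) == "18-28"
    assert age_bin(28.5) == "29-38"
    assert age_bin(78) == "69-78"
    assert age_bin(79) == "79+"
    with pytest.raises(ValueError):
        age_bin(17)


def test_split_small_stratum_forced_rounding():
    """A stratum of 3 gives exactly 2 discovery / 1 validation."""
    cfg = small_config(["Healthy"], 3, 0, ["M1"])
    cfg.n_cases = 0
    cfg.stage_counts = {}
    coh = generate_cohort(cfg, seed=1)
    coh.data["age"] = 60.0
    coh.data["diabetes"] = "no"
    for seed in range(10):
        split = assign_split(coh, seed=seed)
        assert len(split.ids("discovery")) == 2
        assert len(split.ids("validation")) == 1


def test_split_hundred_in_one_stratum():
    rng = np.random.default_rng(0)
    cfg = small_config(["Healthy"], 100, 0, ["M1"])
    cfg.n_cases = 0
    cfg.stage_counts = {}
    coh = generate_cohort(cfg, seed=2)
    # collapse stratification variation: same age bin and diabetes for all
    coh.data["age"] = 60.0
    coh.data["diabetes"] = "no"
    counts = set()
    for seed in range(12):
        split = assign_split(coh, seed=seed)
        counts.add(len(split.ids("discovery")))
    assert counts <= {66, 67}
    assert len(counts) == 2  # rounding direction is randomized


def test_split_every_stratum_within_one(default_cohort):
    split = assign_split(default_cohort, seed=5)
    t = split.table
    assert t["sample_id"].is_unique and len(t) == len(default_cohort)
    for _, grp in t.groupby("stratum_id"):
        n_disc = (grp["arm"] == "discovery").sum()
        assert abs(n_disc - round(2 / 3 * len(grp))) <= 1


def test_split_deterministic_and_external_assignment(default_cohort):
    a = assign_split(default_cohort, seed=3).table
    b = assign_split(default_cohort, seed=3).table
    pd.testing.assert_frame_equal(a, b)
    # screening-source controls can keep an externally fixed arm
    screening_ids = default_cohort.data.loc[
        default_cohort.data["source_cohort"] == "screening", "sample_id"
    ].tolist()
    fixed = {s: "discovery" for s in screening_ids}
    split = assign_split(default_cohort, seed=3, external_assignment=fixed)
    arms = split.arms
    assert all(arms[s] == "discovery" for s in screening_ids)


def test_split_empty_cohort_rejected(tiny_cohort):
    empty = tiny_cohort.subset(np.zeros(len(tiny_cohort), dtype=bool))
    with pytest.raises(ValueError, match="empty"):
        assign_split(empty)


def _split_batches(cohort):
    mask = (cohort.data["batch"] == "batch2").to_numpy()
    return cohort.subset(~mask), cohort.subset(mask)


def test_bridging_corrects_constant_offset():
    """+0.8 on one assay: offset estimate near 0.8 and the
    post-correction median bridge difference is exactly 0."""
    cfg = small_config(["Healthy", "Gallstone Disease"], 30, 10, ["M1", "M2"],
                       noise_sd=0.2)
    cfg.batch_model.offset_sd = 1e-12
    coh = generate_cohort(cfg, seed=4)
    # plant an exact offset on M1 in batch2 manually
    coh.sim_batch_offsets_["batch2"]["M1"] = 0.8
    b2 = (coh.data["batch"] == "batch2").to_numpy()
    coh.data.loc[b2, "M1"] += 0.8
    pairs = generate_bridge_pairs(coh, n_bridge=16, seed=4)
    ref, new = _split_batches(coh)
    corrected = bridge_normalize(ref, new, pairs)
    assert corrected.bridging_offsets_["M1"] == pytest.approx(0.8, abs=0.2)
    post = corrected.bridged_pairs_
    med = np.median(post.new.to_numpy() - post.reference[["M1", "M2"]].to_numpy(), axis=0)
    np.testing.assert_allclose(med, 0.0, atol=1e-12)


def test_bridging_identity_when_no_offset_no_noise():
    ref = pd.DataFrame({"M1": [1.0, 2.0, 3.0]}, index=["a", "b", "c"])
    pairs = BridgePairs(reference=ref, new=ref.copy())
    cfg = small_config(["Healthy", "Gallstone Disease"], 4, 3, ["M1"])
    coh = generate_cohort(cfg, seed=1)
    r, n = _split_batches(coh)
    corrected = bridge_normalize(r, n, pairs)
    np.testing.assert_allclose(
        corrected.data["M1"].to_numpy(), n.data["M1"].to_numpy(), atol=1e-12
    )


def test_bridging_per_assay_median_oracle_and_equivariance():
    rng = np.random.default_rng(7)
    markers = ["M1", "M2", "M3"]
    ref = pd.DataFrame(rng.normal(size=(8, 3)), columns=markers)
    true_off = np.array([0.5, -1.2, 0.0])
    new = ref + true_off + rng.normal(0, 0.05, size=(8, 3))
    pairs = BridgePairs(reference=ref, new=new)
    cfg = small_config(["Healthy", "Gallstone Disease"], 6, 3, markers)
    coh = generate_cohort(cfg, seed=2)
    r, n = _split_batches(coh)
    corrected = bridge_normalize(r, n, pairs)
    oracle = np.median((new - ref).to_numpy(), axis=0)
    np.testing.assert_allclose(corrected.bridging_offsets_.to_numpy(), oracle, atol=1e-12)
    # shift-equivariance: +c on an assay in the new batch cancels out
    shifted = n.copy()
    shifted.data["M2"] = shifted.data["M2"] + 3.0
    pairs_shifted = BridgePairs(reference=ref, new=new + np.array([0, 3.0, 0]))
    corr2 = bridge_normalize(r, shifted, pairs_shifted)
    np.testing.assert_allclose(
        corr2.data["M2"].to_numpy(), corrected.data["M2"].to_numpy(), atol=1e-9
    )


def test_bridging_refuses_insufficient_pairs(tiny_cohort):
    ref = pd.DataFrame({"M1": [1.0]})
    pairs = BridgePairs(reference=ref, new=ref.copy())
    r, n = _split_batches(tiny_cohort)
    with pytest.raises(ValueError, match="at least 2"):
        bridge_normalize(r, n, pairs)


def test_bridging_idempotent():
    cfg = small_config(["Healthy", "Gallstone Disease"], 20, 8, ["M1", "M2"])
    cfg.batch_model.offset_sd = 0.6
    coh = generate_cohort(cfg, seed=6)
    pairs = generate_bridge_pairs(coh, n_bridge=10, seed=6)
    r, n = _split_batches(coh)
    once = bridge_normalize(r, n, pairs)
    twice = bridge_normalize(r, once, once.bridged_pairs_)
    np.testing.assert_allclose(
        twice.markers().to_numpy(), once.markers().to_numpy(), atol=1e-12
    )
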