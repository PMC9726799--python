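"""Three-phase cascade: sample labeling, per-phase selection rules, and
the nesting/containment structure."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from conftest import SMALL, make_log2_matrix, scaled
from mirpanel.cascade import (CRC_ABSENT, CRC_PRESENT, EXCLUDED, label_samples,
                              run_cascade, run_discovery, run_screening,
                              run_validation_decline,
                              run_validation_reelevation)
from mirpanel.cohort import simulate_cohort
from mirpanel.errors import ConfigurationError, DataError
from mirpanel.matrix import PREOP, sheet_index


# ---------------------------------------------------------------------------
# labeling
# ---------------------------------------------------------------------------

class TestLabeling:
    def test_rules(self, small_cohort):
        _, sheet, truth = small_cohort
        labels = label_samples(sheet)
        s = sheet_index(sheet)
        # preop always tumor-bearing
        assert (labels[s["timepoint"] == PREOP] == CRC_PRESENT).all()
        # healthy controls excluded from the recurrence labeling
        assert (labels[s["group"] == "NC"] == EXCLUDED).all()
        # postop of non-recurrence subjects: tumor-free
        postop_nr = (s["months_postop"].notna()
                     & ~s["recurrence"].astype(bool))
        assert (labels[postop_nr] == CRC_ABSENT).all()
        # recurrence subjects: pre-recurrence postop excluded, at/after present
        for subj, t_rec in truth["recurrence_times_months"].items():
            rows = s[(s["subject_id"] == subj) & s["months_postop"].notna()]
            before = rows.index[rows["months_postop"] < t_rec - 1e-9]
            at_or_after = rows.index[rows["months_postop"] >= t_rec - 1e-9]
            assert (labels[before] == EXCLUDED).all()
            assert (labels[at_or_after] == CRC_PRESENT).all()

    def test_missing_recurrence_time_raises(self, small_cohort):
        _, sheet, _ = small_cohort
        broken = sheet.copy()
        rec_mask = broken["recurrence"] & broken["months_postop"].notna()
        broken.loc[rec_mask, "recurrence_months"] = np.nan
        with pytest.raises(DataError):
            label_samples(broken)


# ---------------------------------------------------------------------------
# hand-built sheet for surgical phase tests
# ---------------------------------------------------------------------------

def tiny_sheet_and_matrix():
    """12 CRC subjects (2 recurrence) + 8 controls; 4 probes with known
    behavior: burden-tracking, NC-upregulated, constant, late-rising."""
    rng = np.random.default_rng(42)
    rows = []
    rec_times = {"CRC-01": 10.0, "CRC-02": 14.0}
    for i in range(1, 13):
        subj = f"CRC-{i:02d}"
        t_rec = rec_times.get(subj)
        rows.append((subj, PREOP, np.nan, t_rec))
        for tp, m in [("1M", 1.0), ("3M", 3.0), ("6M", 6.0), ("1Y", 12.0),
                      ("2Y", 24.0)]:
            if t_rec is not None and m > t_rec:
                continue
            rows.append((subj, tp, m, t_rec))
        if t_rec is not None:
            rows.append((subj, "REC", t_rec, t_rec))
    for i in range(1, 9):
        rows.append((f"NC-{i:02d}", "NC", np.nan, None))

    sheet = pd.DataFrame(rows, columns=["subject_id", "timepoint",
                                        "months_postop", "recurrence_months"])
    sheet["sample_id"] = sheet["subject_id"] + "-" + sheet["timepoint"]
    sheet["group"] = np.where(sheet["subject_id"].str.startswith("CRC"),
                              "CRC", "NC")
    sheet["cohort"] = np.where(sheet["group"] == "CRC", "chronological",
                               "control")
    sheet["recurrence"] = sheet["recurrence_months"].notna()
    sheet["batch"] = "B1"
    sheet["cea"] = 2.0
    sheet["ca19_9"] = 10.0

    def burden(row):
        if row["group"] == "NC":
            return 0.0
        if row["timepoint"] == PREOP:
            return 1.0
        t_rec = row["recurrence_months"]
        if np.isnan(t_rec):
            return 0.0
        return 1.0 if row["months_postop"] >= t_rec - 1e-9 else \
            (0.8 if t_rec - row["months_postop"] <= 3.0 else 0.0)

    b = sheet.apply(burden, axis=1).to_numpy()
    n = len(sheet)
    noise = rng.normal(0, 0.15, size=(4, n))
    tracking = 7.0 + 3.0 * b + noise[0]
    nc_up = 7.0 + 3.0 * (sheet["group"] == "NC").to_numpy() + noise[1]
    constant = np.full(n, 7.0)
    # elevated preop AND re-rising at 2Y in non-recurrence subjects
    late = 7.0 + 3.0 * ((sheet["timepoint"] == PREOP)
                        | (sheet["timepoint"] == "2Y")).to_numpy() + noise[3]
    values = np.vstack([tracking, nc_up, constant, late])
    matrix = make_log2_matrix(values)
    matrix.values.columns = sheet["sample_id"].to_numpy()
    matrix = matrix.with_values(
        pd.DataFrame(values, index=matrix.values.index,
                     columns=sheet["sample_id"].to_numpy()))
    return matrix, sheet


@pytest.fixture(scope="module")
def tiny():
    return tiny_sheet_and_matrix()


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------

class TestScreening:
    def test_selects_upregulated_only(self, tiny):
        matrix, sheet = tiny
        result = run_screening(matrix, sheet)
        assert "g0" in result.survivors        # burden-tracking
        assert "g3" in result.survivors        # elevated preop
        assert "g1" not in result.survivors    # upregulated in controls
        assert "g2" not in result.survivors    # constant

    def test_direction_filter_blocks_nc_marker_even_two_sided(self, tiny):
        matrix, sheet = tiny
        result = run_screening(matrix, sheet, alternative="two-sided")
        row = result.table.loc["g1"]
        assert row["p_value"] < 0.05           # significant...
        assert not row["survives"]             # ...but wrong direction

    def test_pvalues_match_scalar_oracle(self, tiny):
        matrix, sheet = tiny
        result = run_screening(matrix, sheet)
        s = sheet_index(sheet)
        crc_preop = s.index[(s["group"] == "CRC") & (s["timepoint"] == PREOP)]
        nc = s.index[s["group"] == "NC"]
        for probe in ["g0", "g1", "g3"]:
            ref = sps.mannwhitneyu(matrix.values.loc[probe, crc_preop],
                                   matrix.values.loc[probe, nc],
                                   alternative="greater",
                                   method="asymptotic").pvalue
            assert result.table.loc[probe, "p_value"] == pytest.approx(ref)

    def test_missing_group_raises(self, tiny):
        matrix, sheet = tiny
        with pytest.raises(ConfigurationError):
            run_screening(matrix, sheet[sheet["group"] == "CRC"])


# ---------------------------------------------------------------------------
# discovery
# ---------------------------------------------------------------------------

class TestDiscovery:
    def test_burden_tracking_survives(self, tiny):
        matrix, sheet = tiny
        result = run_discovery(matrix, sheet, ["g0", "g2", "g3"])
        assert "g0" in result.survivors
        assert "g2" not in result.survivors    # identical pre/post

    def test_untested_markers_absent(self, tiny):
        matrix, sheet = tiny
        result = run_discovery(matrix, sheet, ["g0"])
        assert "g3" not in result.table.index  # never tested
        assert set(result.survivors) <= {"g0"}

    def test_paired_mode(self, tiny):
        matrix, sheet = tiny
        unpaired = run_discovery(matrix, sheet, ["g0", "g3"], paired=False)
        paired = run_discovery(matrix, sheet, ["g0", "g3"], paired=True)
        assert paired.params["test"] == "wilcoxon-signed-rank"
        assert set(paired.survivors) == set(unpaired.survivors) == {"g0", "g3"}

    def test_no_pairs_raises(self, tiny):
        matrix, sheet = tiny
        no_1m = sheet[sheet["timepoint"] != "1M"]
        with pytest.raises(ConfigurationError):
            run_discovery(matrix, no_1m, ["g0"])


# ---------------------------------------------------------------------------
# validation: decline
# ---------------------------------------------------------------------------

class TestValidationDecline:
    def test_tracking_survives_late_riser_fails(self, tiny):
        matrix, sheet = tiny
        result = run_validation_decline(matrix, sheet, ["g0", "g3"])
        assert "g0" in result.survivors
        # g3 re-rises at 2Y in non-recurrence subjects: the 2Y test fails
        assert "g3" not in result.survivors
        assert result.table.loc["g3", "p_2Y"] > 0.05
        assert result.table.loc["g3", "p_1M"] < 0.05

    def test_all_timepoints_tested(self, tiny):
        matrix, sheet = tiny
        result = run_validation_decline(matrix, sheet, ["g0"])
        assert result.params["timepoints"] == ["1M", "3M", "6M", "1Y", "2Y"]

    def test_null_probes_essentially_always_fail(self):
        # a null probe must pass five one-sided tests simultaneously; the
        # shared preop samples correlate the tests, but the pass rate stays
        # far below alpha
        passes, total = 0, 0
        for seed in range(30):
            cfg = scaled(SMALL, effect_size=0.0, n_true_markers=0,
                         n_hemolysis_markers=0, seed=500 + seed,
                         batch_shift_sd=0.0, batch_scale_sd=0.0)
            matrix, sheet, _ = simulate_cohort(cfg)
            log2 = matrix.with_values(np.log2(matrix.values + 1.0), scale="log2")
            markers = list(matrix.regular_probe_ids)
            result = run_validation_decline(log2, sheet, markers)
            passes += len(result.survivors)
            total += len(markers)
        assert passes / total < 0.01


# ---------------------------------------------------------------------------
# validation: re-elevation
# ---------------------------------------------------------------------------

class TestValidationReelevation:
    def test_tracking_marker_flagged(self, tiny):
        matrix, sheet = tiny
        result = run_validation_reelevation(matrix, sheet, ["g0", "g2"])
        assert "g0" in result.survivors
        assert result.table.loc["g0", "fraction_flagged"] == 1.0
        # constant marker: nothing ever crosses
        assert "g2" not in result.survivors
        assert result.table.loc["g2", "n_flagged"] == 0

    def test_never_below_cutoff_not_flagged(self, tiny):
        # marker whose postop values in recurrence subjects sit above the
        # cut-off from the start: no decline, so the below-then-above
        # pattern never occurs and the subject is not flagged
        _, sheet = tiny
        vals = np.full(len(sheet), 12.0)           # tumor-free level
        preop = (sheet["timepoint"] == PREOP).to_numpy()
        rec_post = (sheet["recurrence"] & sheet["months_postop"].notna()).to_numpy()
        vals[preop] = 14.0
        vals[rec_post] = 13.5                       # above the 13 cut-off always
        vals[(sheet["timepoint"] == "REC").to_numpy()] = 14.0
        m = make_log2_matrix(vals.reshape(1, -1))
        m = m.with_values(pd.DataFrame(vals.reshape(1, -1), index=m.values.index,
                                       columns=sheet["sample_id"].to_numpy()))
        result = run_validation_reelevation(m, sheet, ["g0"])
        assert result.table.loc["g0", "n_flagged"] == 0
        assert "g0" not in result.survivors

    def test_no_recurrence_subjects_raises(self, tiny):
        matrix, sheet = tiny
        no_rec = sheet[~sheet["recurrence"]]
        with pytest.raises(ConfigurationError):
            run_validation_reelevation(matrix, no_rec, ["g0"])


# ---------------------------------------------------------------------------
# full cascade
# ---------------------------------------------------------------------------

class TestCascade:
    def test_containment_invariant(self, small_normalized):
        normalized, sheet, truth, _ = small_normalized
        phases = run_cascade(normalized, sheet)
        sets = [set(ph.survivors) for ph in phases]
        assert sets[3] <= sets[2] <= sets[1] <= sets[0]

    def test_planted_markers_recovered(self, small_normalized):
        normalized, sheet, truth, _ = small_normalized
        phases = run_cascade(normalized, sheet)
        planted = set(truth["planted_markers"])
        recovered = set(phases[-1].survivors) & planted
        assert len(recovered) >= 0.8 * len(planted)

    def test_alpha_zero_yields_empty_phases(self, small_normalized):
        normalized, sheet, _, _ = small_normalized
        with pytest.warns(UserWarning):
            phases = run_cascade(normalized, sheet, alpha=0.0)
        assert all(len(ph.survivors) == 0 for ph in phases)
        assert len(phases) == 4

    def test_permuted_group_labels_kill_the_effect(self):
        # permuting CRC/NC assignments breaks the planted association;
        # screening pass fraction falls back to the null rate
        fracs = []
        for seed in range(20):
            cfg = scaled(SMALL, seed=600 + seed, batch_shift_sd=0.0,
                         batch_scale_sd=0.0)
            matrix, sheet, _ = simulate_cohort(cfg)
            rng = np.random.default_rng(seed)
            sub = sheet[(sheet["timepoint"] == PREOP)
                        | (sheet["group"] == "NC")].copy()
            permuted_groups = rng.permutation(sub["group"].to_numpy())
            sub["group"] = permuted_groups
            sub["timepoint"] = np.where(sub["group"] == "NC", "NC", PREOP)
            log2 = matrix.with_values(np.log2(matrix.values + 1.0),
                                      scale="log2")
            result = run_screening(log2, sub)
            fracs.append(len(result.survivors)
                         / len(matrix.regular_probe_ids))
        mean = np.mean(fracs)
        # 99% binomial band around alpha for the pooled probe count
        total = 20 * (SMALL.n_probes - SMALL.n_negative_controls)
        sd = np.sqrt(0.05 * 0.95 / total)
        assert abs(mean - 0.05) < 2.58 * sd + 0.01
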