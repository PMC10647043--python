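"""Pose metrics, Pareto selection and isomeric-shift prediction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pswdesign import dockscore, fixtures, prep
from pswdesign.dockscore import DockedPose


def pose(idx=0, score=-50.0, contacts=10, clashes=0, uncontacted=0,
         variant="fam|trans|t0"):
    return DockedPose(variant_id=variant, pose_index=idx,
                      coords=np.zeros((1, 3)), total_score=score,
                      n_contacts=contacts, n_clashes=clashes,
                      n_uncontacted=uncontacted)


def brute_force_best(poses):
    """Independent oracle: full pairwise dominance enumeration."""
    def dominated(p, q):
        ge = (q.n_contacts >= p.n_contacts and q.n_clashes <= p.n_clashes
              and q.n_uncontacted <= p.n_uncontacted
              and q.total_score <= p.total_score)
        neq = (q.n_contacts, q.n_clashes, q.n_uncontacted, q.total_score) \
            != (p.n_contacts, p.n_clashes, p.n_uncontacted, p.total_score)
        return ge and neq
    front = [p for p in poses
             if not any(dominated(p, q) for q in poses)]
    return min(front, key=lambda p: (p.total_score, p.pose_index))


class TestPoseMetrics:
    def test_single_contact(self):
        n = dockscore.compute_pose_metrics(
            np.array([[0.0, 0.0, 0.0]]), np.array([[3.5, 0.0, 0.0]]))
        assert n == (1, 0, 0)

    def test_fully_disengaged_ligand(self):
        lig = np.array([[0.0, 0.0, 0.0], [1.5, 0.0, 0.0]])
        rec = np.array([[100.0, 0.0, 0.0]])
        assert dockscore.compute_pose_metrics(lig, rec) == (0, 0, 2)

    def test_clash_also_counts_as_contact(self):
        n = dockscore.compute_pose_metrics(
            np.array([[0.0, 0.0, 0.0]]), np.array([[2.0, 0.0, 0.0]]))
        assert n == (1, 1, 0)

    def test_against_bruteforce_pair_enumeration(self):
        rng = np.random.default_rng(7)
        lig = rng.uniform(-5, 5, size=(8, 3))
        rec = rng.uniform(-5, 5, size=(30, 3))
        nc = ncl = 0
        unc = 0
        for a in lig:
            touched = False
            for b in rec:
                d = float(np.linalg.norm(a - b))
                if d <= 4.0:
                    nc += 1
                    touched = True
                if d < 2.5:
                    ncl += 1
            unc += 0 if touched else 1
        assert dockscore.compute_pose_metrics(lig, rec) == (nc, ncl, unc)


class TestParetoSelection:
    def test_dominating_pose_wins(self):
        good = pose(0, -90, 30, 0, 0)
        rest = [pose(i, -50 + i, 10, 2, 3) for i in range(1, 5)]
        assert dockscore.pareto_best_pose([good] + rest) is good

    def test_nondominated_tie_breaks_on_score(self):
        a = pose(0, -85.0, contacts=10)
        b = pose(1, -80.0, contacts=20)  # nondominated vs a
        assert dockscore.pareto_best_pose([a, b]) is a

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            dockscore.pareto_best_pose([])

    def test_matches_bruteforce_oracle_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n = int(rng.integers(1, 13))
            poses = [pose(i, float(np.round(rng.uniform(-100, -40), 1)),
                          int(rng.integers(0, 30)), int(rng.integers(0, 5)),
                          int(rng.integers(0, 6))) for i in range(n)]
            chosen = dockscore.pareto_best_pose(poses)
            expect = brute_force_best(poses)
            assert (chosen.pose_index, chosen.total_score) == \
                   (expect.pose_index, expect.total_score)

    def test_selection_is_never_dominated(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            poses = [pose(i, float(rng.uniform(-100, -40)),
                          int(rng.integers(0, 30)), int(rng.integers(0, 5)),
                          int(rng.integers(0, 6))) for i in range(10)]
            best = dockscore.pareto_best_pose(poses)
            assert not any(dockscore._dominates(q, best) for q in poses)


class TestScoreToPki:
    def test_identity_when_score_equals_parent(self):
        assert dockscore.score_to_pki(-80.0, -80.0, 8.0) == 8.0

    def test_hand_arithmetic(self):
        assert dockscore.score_to_pki(-100.0, -80.0, 8.0) == \
            pytest.approx(10.0)

    def test_zero_score_gives_zero(self):
        assert dockscore.score_to_pki(0.0, -80.0, 8.0) == 0.0

    def test_zero_parent_score_rejected(self):
        with pytest.raises(ValueError):
            dockscore.score_to_pki(-50.0, 0.0, 8.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(paff=st.floats(1.0, 12.0), score=st.floats(-120.0, -1.0),
           parent=st.floats(-120.0, -1.0), k=st.floats(0.1, 10.0))
    def test_linear_in_paffinity_and_scale_invariant(self, paff, score,
                                                     parent, k):
        base = dockscore.score_to_pki(score, parent, paff)
        assert dockscore.score_to_pki(score, parent, 2 * paff) == \
            pytest.approx(2 * base, rel=1e-12)
        assert dockscore.score_to_pki(k * score, k * parent, paff) == \
            pytest.approx(base, rel=1e-9)


class TestFamilyShift:
    def family(self, score_trans, score_cis, parent_score=-80.0,
               labels=("t0",)):
        poses = [pose(0, parent_score, variant="fam|parent|t0")]
        for lab in labels:
            poses.append(pose(0, score_trans, variant=f"fam|trans|{lab}"))
            poses.append(pose(0, score_cis, variant=f"fam|cis|{lab}"))
        return poses

    def test_equal_scores_mean_no_shift(self):
        pred = dockscore.predict_family_shift(self.family(-80.0, -80.0), 8.0)
        assert pred.delta_pki == 0.0
        assert pred.fold_change == 1.0
        assert pred.active_isomer == "none"

    def test_arithmetic_oracle_cis_on(self):
        pred = dockscore.predict_family_shift(self.family(-80.0, -100.0),
                                              8.0)
        assert pred.delta_pki == pytest.approx(2.0)
        assert pred.fold_change == pytest.approx(100.0)
        assert pred.active_isomer == "cis"
        assert pred.fold_change_display == pytest.approx(-100.0)

    def test_median_over_three_pairs(self):
        poses = [pose(0, -80.0, variant="fam|parent|t0")]
        for lab, dpki in [("t0", 1.0), ("t1", 2.0), ("t2", 9.0)]:
            cis_score = -80.0 * (1 + dpki / 8.0)
            poses.append(pose(0, -80.0, variant=f"fam|trans|{lab}"))
            poses.append(pose(0, cis_score, variant=f"fam|cis|{lab}"))
        pred = dockscore.predict_family_shift(poses, 8.0)
        assert pred.delta_pki == pytest.approx(2.0)
        assert pred.n_pairs == 3

    def test_unpaired_variant_dropped_missing_pair_fatal(self):
        poses = [pose(0, -80.0, variant="fam|parent|t0"),
                 pose(0, -85.0, variant="fam|trans|t0")]
        with pytest.raises(ValueError):
            dockscore.predict_family_shift(poses, 8.0)

    def test_sign_consistency(self):
        for dpki in (-2.5, -0.3, 0.4, 3.0):
            cis_score = -80.0 * (1 + dpki / 8.0)
            pred = dockscore.predict_family_shift(
                self.family(-80.0, cis_score), 8.0)
            assert (pred.active_isomer == "cis") == (pred.delta_pki > 0)
            assert (pred.fold_change_display < 0) == \
                   (pred.active_isomer == "cis")

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(a=st.floats(-3.0, 3.0), b=st.floats(-3.0, 3.0))
    def test_fold_change_multiplicativity(self, a, b):
        if (a >= 0) == (b >= 0):  # magnitudes add only for same-sign shifts
            assert dockscore.fold_change(a + b) == pytest.approx(
                dockscore.fold_change(a) * dockscore.fold_change(b),
                rel=1e-9)


class TestShiftFilter:
    def prediction(self, fc):
        dpki = np.log10(fc)
        return dockscore.ShiftPrediction(
            family_id="f", parent_paffinity=8.0, parent_score=-80.0,
            score_trans=-80.0, score_cis=-80.0, delta_score=0.0,
            delta_pki=dpki, fold_change=fc, fold_change_display=fc,
            active_isomer="trans", n_pairs=1)

    def test_boundary_inclusive_default(self):
        preds = [self.prediction(fc) for fc in (1.0, 49.9, 50.0, 500.0)]
        kept = dockscore.apply_shift_filter(preds)
        assert [p.fold_change for p in kept] == [50.0, 500.0]

    def test_disabled_filter_passes_everything(self):
        preds = [self.prediction(fc) for fc in (1.0, 2.0)]
        assert len(dockscore.apply_shift_filter(preds, None)) == 2

    def test_dpki_1_7_passes_50_fold_default(self):
        fc = dockscore.fold_change(1.7)
        assert fc == pytest.approx(50.119, abs=0.001)
        assert dockscore.apply_shift_filter([self.prediction(fc)])


@pytest.fixture(scope="module")
def setup(toy_pocket):
    st_ = prep.load_structure(toy_pocket)
    rec = prep.prepare_receptor(st_, "A", keep_het_ids=("LIG",))
    site = prep.define_binding_site(rec, "LIG", 2.0)
    ligs = prep.prepare_ligand_variants(
        "fam", "trans", "c1ccc(/N=N/c2ccccc2)cc1")
    return rec, site, ligs


class TestDockOrchestration:
    def test_empty_ligand_list(self, setup):
        rec, site, _ = setup
        engine = fixtures.make_mock_engine()
        assert dockscore.dock(engine, rec, site, []) == []

    def test_ten_poses_per_variant(self, setup):
        rec, site, ligs = setup
        engine = fixtures.make_mock_engine()
        poses = dockscore.dock(engine, rec, site, ligs, n_poses=10)
        assert len(poses) == 10 * len(ligs)

    def test_worker_count_does_not_change_output(self, setup):
        rec, site, ligs = setup
        engine = fixtures.make_mock_engine()
        serial = dockscore.dock(engine, rec, site, ligs * 3, workers=1)
        parallel = dockscore.dock(engine, rec, site, ligs * 3, workers=4)
        assert [(p.variant_id, p.pose_index, p.total_score)
                for p in serial] == \
               [(p.variant_id, p.pose_index, p.total_score)
                for p in parallel]

    def test_engine_failure_skips_ligand_and_continues(self, setup):
        rec, site, ligs = setup

        class FlakyEngine:
            name = "flaky"

            def dock_one(self, receptor, s, ligand, n_poses):
                raise RuntimeError("boom")

        assert dockscore.dock(FlakyEngine(), rec, site, ligs) == []

    def test_absent_plants_binary_suggests_mock(self):
        with pytest.raises(dockscore.EngineNotAvailable, match="mock"):
            dockscore.PlantsEngine(binary="plants-definitely-absent")
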