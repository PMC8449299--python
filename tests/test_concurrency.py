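import numpy as np
import pandas as pd
import pytest

from ehrcollab import concurrency
from ehrcollab.concurrency import (
    MatrixSet,
    assemble_sessions,
    build_matrices,
    find_overlap_pairs,
    label_intervals,
)
from oracles import brute_pairs, brute_sessions, random_intervals


def make_intervals(rows):
    """rows: (hcw, patient, start_s, stop_s [, n_events])."""
    base = pd.Timestamp("2020-06-01")
    df = pd.DataFrame(
        [r[:4] for r in rows], columns=["hcw_id", "patient_id", "s", "e"]
    )
    df["start"] = base + pd.to_timedelta(df.pop("s"), unit="s")
    df["stop"] = base + pd.to_timedelta(df.pop("e"), unit="s")
    df["duration_s"] = (df["stop"] - df["start"]).dt.total_seconds()
    df["n_events"] = [r[4] if len(r) > 4 else 2 for r in rows]
    df["actions"] = [tuple(f"ACT{i}" for i in range(n)) for n in df["n_events"]]
    return df


class TestOverlapPairs:
    def test_touching_endpoints_do_not_overlap(self):
        iv = make_intervals([("A", "P", 0, 10), ("B", "P", 10, 20)])
        assert len(find_overlap_pairs(iv)) == 0

    def test_positive_overlap_measured(self):
        iv = make_intervals([("A", "P", 0, 10), ("B", "P", 5, 20)])
        pairs = find_overlap_pairs(iv)
        assert len(pairs) == 1
        assert pairs.loc[0, "overlap_s"] == 5

    def test_different_patients_never_pair(self):
        iv = make_intervals([("A", "P1", 0, 10), ("B", "P2", 0, 10)])
        assert len(find_overlap_pairs(iv)) == 0

    def test_same_hcw_never_pairs(self):
        iv = make_intervals([("A", "P", 0, 10), ("A", "P", 5, 20)])
        assert len(find_overlap_pairs(iv)) == 0

    def test_sweep_matches_brute_force(self, rng):
        for _ in range(20):
            iv = random_intervals(rng, int(rng.integers(5, 150)))
            got = {
                tuple(sorted((a, b)))
                for a, b in zip(
                    find_overlap_pairs(iv)["interval_a"],
                    find_overlap_pairs(iv)["interval_b"],
                )
            }
            assert got == brute_pairs(iv)


class TestSessions:
    def test_chained_overlaps_form_one_session(self):
        """A-B and B-C overlap but A-C do not: the component rule still
        yields a single three-interval session."""
        iv = make_intervals(
            [("A", "P", 0, 10), ("B", "P", 8, 15), ("C", "P", 14, 20)]
        )
        sessions, membership = assemble_sessions(iv, find_overlap_pairs(iv))
        assert len(sessions) == 1
        assert sessions.loc[0, "n_intervals"] == 3
        assert membership.nunique() == 1

    def test_clique_rule_splits_chain(self):
        iv = make_intervals(
            [("A", "P", 0, 10), ("B", "P", 8, 15), ("C", "P", 14, 20)]
        )
        sessions, _ = assemble_sessions(iv, find_overlap_pairs(iv), rule="clique")
        assert list(sessions["n_intervals"]) == [2]

    def test_disjoint_pairs_make_two_sessions(self):
        iv = make_intervals(
            [
                ("A", "P", 0, 5),
                ("B", "P", 4, 8),
                ("A", "P", 100, 110),
                ("B", "P", 105, 120),
            ]
        )
        sessions, _ = assemble_sessions(iv, find_overlap_pairs(iv))
        assert len(sessions) == 2

    def test_no_pairs_no_sessions_all_individual(self):
        iv = make_intervals([("A", "P", 0, 10), ("B", "P", 20, 30)])
        sessions, membership = assemble_sessions(iv, find_overlap_pairs(iv))
        labeled, counts = label_intervals(iv, membership)
        assert len(sessions) == 0
        assert counts == {"concurrent": 0, "individual": 2}

    def test_label_partition(self):
        iv = make_intervals(
            [
                ("A", "P", 0, 10),
                ("B", "P", 5, 12),
                ("A", "P", 100, 110),
                ("B", "P", 200, 210),
            ]
        )
        sessions, membership = assemble_sessions(iv, find_overlap_pairs(iv))
        labeled, counts = label_intervals(iv, membership)
        assert counts == {"concurrent": 2, "individual": 2}
        assert labeled["concurrent"].sum() == 2

    def test_session_ids_deterministic(self):
        iv = make_intervals([("A", "P", 0, 10), ("B", "P", 5, 12)])
        s1, _ = assemble_sessions(iv, find_overlap_pairs(iv))
        s2, _ = assemble_sessions(iv.copy(), find_overlap_pairs(iv))
        assert list(s1["session_id"]) == list(s2["session_id"])

    def test_components_match_networkx_oracle(self, rng):
        for _ in range(15):
            iv = random_intervals(rng, int(rng.integers(10, 200)))
            pairs = find_overlap_pairs(iv)
            sessions, membership = assemble_sessions(iv, pairs)
            got = {
                frozenset(membership[membership == sid].index)
                for sid in sessions["session_id"]
            }
            assert got == brute_sessions(iv, brute_pairs(iv))
            # partition: session sizes sum to the concurrent-interval count
            assert sessions["n_intervals"].sum() == len(membership)

    def test_isolated_interval_leaves_sessions_unchanged(self):
        iv = make_intervals([("A", "P", 0, 10), ("B", "P", 5, 12)])
        with_extra = make_intervals(
            [("A", "P", 0, 10), ("B", "P", 5, 12), ("C", "P", 500, 600)]
        )
        s1, _ = assemble_sessions(iv, find_overlap_pairs(iv))
        s2, _ = assemble_sessions(with_extra, find_overlap_pairs(with_extra))
        assert list(s1["session_id"]) == list(s2["session_id"])


class TestMatrices:
    @staticmethod
    def _labeled(rows):
        iv = make_intervals(rows)
        sessions, membership = assemble_sessions(iv, find_overlap_pairs(iv))
        labeled, _ = label_intervals(iv, membership)
        return labeled, sessions

    def test_action_row_sums_equal_event_counts(self):
        labeled, sessions = self._labeled(
            [("A", "P", 0, 10, 3), ("B", "P", 5, 12, 4)]
        )
        mats = build_matrices(labeled, sessions)
        assert list(np.asarray(mats.interval_action.sum(axis=1)).ravel()) == [3, 4]

    def test_type_invariants(self, pipe_default):
        mats = pipe_default.matrices
        row_sums = np.asarray(mats.interval_session.sum(axis=1)).ravel()
        assert (row_sums == 1).all()
        col_sums = np.asarray(mats.hcw_session.sum(axis=0)).ravel()
        assert (col_sums >= 2).all()
        conc = pipe_default.labeled[pipe_default.labeled["concurrent"]]
        np.testing.assert_array_equal(
            np.asarray(mats.interval_action.sum(axis=1)).ravel(),
            conc["n_events"].to_numpy(),
        )

    def test_cosession_diagonal_counts_sessions_per_hcw(self, pipe_default):
        m = pipe_default.matrices.hcw_session
        diag = (m @ m.T).diagonal()
        np.testing.assert_array_equal(
            diag, np.asarray(m.sum(axis=1)).ravel()
        )

    def test_empty_sessions_give_empty_but_valid_matrices(self):
        labeled, sessions = self._labeled([("A", "P", 0, 10), ("B", "P", 50, 60)])
        mats = build_matrices(labeled, sessions)
        assert mats.interval_action.shape[0] == 0
        assert mats.hcw_session.shape == (0, 0)

    def test_triplet_round_trip(self, tmp_path, pipe_default):
        mats = pipe_default.matrices
        mats.to_dir(tmp_path / "m")
        back = MatrixSet.from_dir(tmp_path / "m")
        for name in MatrixSet._NAMES:
            a, b = getattr(mats, name), getattr(back, name)
            assert (a != b).nnz == 0
        assert [str(i) for i in mats.interval_ids] == [str(i) for i in back.interval_ids]
        assert mats.session_ids == back.session_ids
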