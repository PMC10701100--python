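import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from degronkit import features, io
from degronkit.features import (
    BackgroundPeptide,
    aggregate_features,
    position_preferences,
    sample_background,
    unify_fragments,
)
from degronkit.motifs import MotifMatch


def make_protein(seq, pid="P1"):
    return io.ProteinRecord(pid, seq)


def make_tracks(pid, n, **overrides):
    """Uniform tracks with optional per-feature overrides."""
    tracks = io.TrackSet()
    defaults = {
        "disorder": 0.5, "accessibility": 0.5, "conservation": 0.5,
        "rigidity": 0.5, "stabilization": 0.5, "domain_flag": 0.0,
        "coil": 1.0, "helix": 0.0, "sheet": 0.0,
    }
    for feat, val in defaults.items():
        values = overrides.get(feat)
        tracks.set(pid, feat, np.full(n, val) if values is None else np.asarray(values, float))
    return tracks


def candidate(pid, start, end, motif="M"):
    return MotifMatch(pid, motif, start, end, "A" * (end - start + 1))


class TestAggregate:
    def test_span_mean(self):
        protein = make_protein("A" * 10)
        disorder = np.zeros(10)
        disorder[4], disorder[5] = 0.2, 0.4  # positions 5 and 6
        tracks = make_tracks("P1", 10, disorder=disorder)
        fv = aggregate_features(
            MotifMatch("P1", "M", 5, 6, "AA"), protein, tracks, []
        )
        assert fv.values["disorder"] == pytest.approx(0.3)

    def test_uniform_conservation_gives_zero_delta(self):
        protein = make_protein("A" * 30)
        tracks = make_tracks("P1", 30)
        fv = aggregate_features(candidate("P1", 10, 15), protein, tracks, [])
        assert fv.values["conservation_flank_delta"] == pytest.approx(0.0)

    def test_conserved_span_positive_delta(self):
        protein = make_protein("A" * 30)
        cons = np.full(30, 0.2)
        cons[9:15] = 0.9  # span [10, 15]
        tracks = make_tracks("P1", 30, conservation=cons)
        fv = aggregate_features(candidate("P1", 10, 15), protein, tracks, [])
        assert fv.values["conservation_flank_delta"] == pytest.approx(0.7)

    def test_ptm_window_clips_at_terminus(self):
        # degron [5,8] with flank 11 on a 25-residue protein: window [1,19],
        # so the phosphosite at 3 counts and the one at 20 does not
        protein = make_protein("A" * 2 + "S" + "A" * 16 + "S" + "A" * 5)
        tracks = make_tracks("P1", 25)
        ptm = [
            io.PTMSite("P1", 3, "phosphorylation"),
            io.PTMSite("P1", 20, "phosphorylation"),
        ]
        fv = aggregate_features(candidate("P1", 5, 8), protein, tracks, ptm, flank=11)
        assert fv.values["n_phospho"] == 1

    def test_flank_lysines_counted_with_min_distance(self):
        # lysines at 7 (distance 3 from start 10) and 18 (distance 3 from end 15)
        seq = list("A" * 30)
        seq[6] = "K"
        seq[17] = "K"
        protein = make_protein("".join(seq))
        tracks = make_tracks("P1", 30)
        fv = aggregate_features(candidate("P1", 10, 15), protein, tracks, [], flank=5)
        assert fv.values["flank_lysine_count"] == 2
        assert fv.values["flank_lysine_min_dist"] == 3

    def test_no_flank_lysine_is_zero_with_zero_count(self):
        protein = make_protein("A" * 30)
        tracks = make_tracks("P1", 30)
        fv = aggregate_features(candidate("P1", 10, 15), protein, tracks, [])
        assert fv.values["flank_lysine_count"] == 0
        assert fv.values["flank_lysine_min_dist"] == 0

    def test_missing_track_imputed_and_flagged(self):
        protein = make_protein("A" * 30)
        tracks = make_tracks("P1", 30)
        bare = io.TrackSet()
        for feat in ("accessibility", "conservation", "coil", "helix", "sheet",
                     "rigidity", "stabilization", "domain_flag"):
            bare.set("P1", feat, np.full(30, 0.5) if feat != "domain_flag" else np.zeros(30))
        fv = aggregate_features(
            candidate("P1", 10, 15), protein, bare, [],
            track_means={"disorder": 0.42},
        )
        assert fv.values["disorder"] == pytest.approx(0.42)
        assert fv.imputed == frozenset({"disorder"})
        with pytest.raises(KeyError):
            aggregate_features(candidate("P1", 10, 15), protein, bare, [])

    def test_span_outside_protein_is_error(self):
        protein = make_protein("A" * 10)
        tracks = make_tracks("P1", 10)
        with pytest.raises(ValueError):
            aggregate_features(candidate("P1", 8, 12), protein, tracks, [])

    def test_translation_equivariance(self):
        """Shifting sequence context, tracks, PTM sites, and span together
        leaves the feature vector unchanged."""
        rng = np.random.default_rng(3)
        core = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 40))
        shift = 7
        seq_a = core + "G" * shift
        seq_b = "G" * shift + core
        pa, pb = make_protein(seq_a, "A"), make_protein(seq_b, "B")
        disorder = rng.uniform(0, 1, 40)
        ta = make_tracks("A", 47, disorder=np.concatenate([disorder, np.zeros(shift)]))
        tb = make_tracks("B", 47, disorder=np.concatenate([np.zeros(shift), disorder]))
        span_a, span_b = (16, 22), (16 + shift, 22 + shift)
        ptm_a = [io.PTMSite("A", 14, "phosphorylation")] if seq_a[13] in "STY" else []
        ptm_b = [io.PTMSite("B", 14 + shift, "phosphorylation")] if seq_a[13] in "STY" else []
        fa = aggregate_features(candidate("A", *span_a), pa, ta, ptm_a, flank=5)
        fb = aggregate_features(candidate("B", *span_b), pb, tb, ptm_b, flank=5)
        for key, val in fa.values.items():
            assert fb.values[key] == pytest.approx(val), key


class TestBackground:
    def test_pigeonhole_gives_zero_with_warning(self):
        proteome = {"P1": make_protein("MRAALQQVK")}
        pos = [candidate("P1", 2, 8)]  # length 7 on a 9-residue protein
        with pytest.warns(UserWarning, match="no non-overlapping"):
            out = sample_background(proteome, pos, k_per_positive=1, seed=1)
        assert out == []

    def test_deterministic_and_never_overlapping(self):
        proteome = {"P1": make_protein("A" * 20)}
        pos = [candidate("P1", 2, 4)]
        a = sample_background(proteome, pos, k_per_positive=5, seed=9)
        b = sample_background(proteome, pos, k_per_positive=5, seed=9)
        assert a == b
        for pep in a:
            assert pep.end < 2 or pep.start > 4
            assert pep.end - pep.start + 1 == 3
            assert 1 <= pep.start and pep.end <= 20

    def test_length_distribution_matches_positives(self, small_fixture):
        manifest = small_fixture["manifest"]
        by_id = small_fixture["by_id"]
        bg = sample_background(by_id, manifest.implants, k_per_positive=2, seed=4)
        pos_lengths = sorted(
            (i.end - i.start + 1) for i in manifest.implants for _ in range(2)
        )
        bg_lengths = sorted(p.end - p.start + 1 for p in bg)
        assert bg_lengths == pos_lengths

    def test_background_never_overlaps_any_implant(self, small_fixture):
        manifest = small_fixture["manifest"]
        by_id = small_fixture["by_id"]
        bg = sample_background(by_id, manifest.implants, k_per_positive=5, seed=4)
        spans = {}
        for i in manifest.implants:
            spans.setdefault(i.protein_id, []).append((i.start, i.end))
        for pep in bg:
            for lo, hi in spans.get(pep.protein_id, []):
                assert pep.end < lo or pep.start > hi


class TestFragments:
    def test_centering_pads_left(self):
        proteome = {"P1": make_protein("ACDEFGHIKLMNPQRSTVWYACDEFGHIKL")}
        frags = unify_fragments([candidate("P1", 5, 8)], proteome, length=20)
        # midpoint floor((5+8)/2) = 6; window [-3, 16] -> positions -3..0 are
        # four left 'X' pads, then residues 1..16
        assert frags[0] == "XXXX" + proteome["P1"].sequence[:16]
        assert len(frags[0]) == 20

    def test_degron_spanning_full_length_is_identity(self):
        proteome = {"P1": make_protein("ACDEFGHIKLMNPQRSTVWY" + "A" * 10)}
        frags = unify_fragments([candidate("P1", 1, 20)], proteome, length=20)
        # midpoint 10; window [1, 20] = the degron itself
        assert frags[0] == proteome["P1"].sequence[:20]

    def test_identical_inputs_identical_fragments(self):
        proteome = {"P1": make_protein("A" * 60)}
        cands = [candidate("P1", 20, 27)] * 4
        frags = unify_fragments(cands, proteome)
        assert len(set(frags)) == 1

    def test_length_shorter_than_degron_rejected(self):
        proteome = {"P1": make_protein("A" * 60)}
        with pytest.raises(ValueError):
            unify_fragments([candidate("P1", 10, 40)], proteome, length=20)


class TestPositionPreferences:
    def test_identical_fragments_single_peak(self):
        pfm = position_preferences(["ACDG"] * 10)
        for pos, aa in enumerate("ACDG", start=1):
            assert pfm.frequencies.loc[pos, aa] == 1.0
        assert pfm.frequencies.to_numpy().sum() == pytest.approx(4.0)

    def test_split_column(self):
        pfm = position_preferences(["AAA", "AGA"])
        assert pfm.frequencies.loc[2, "A"] == 0.5
        assert pfm.frequencies.loc[2, "G"] == 0.5

    def test_all_x_column_flagged_not_nan(self):
        pfm = position_preferences(["XAG", "XAG"])
        assert not pfm.defined[0]
        assert pfm.defined[1] and pfm.defined[2]
        assert not np.isnan(pfm.frequencies.to_numpy()).any()

    @settings(max_examples=25, deadline=None)
    @given(
        st.lists(
            st.text(alphabet="ACDEFGHIKLMNPQRSTVWYX", min_size=8, max_size=8),
            min_size=1,
            max_size=20,
        )
    )
    def test_defined_columns_sum_to_one(self, frags):
        pfm = position_preferences(frags)
        sums = pfm.frequencies.to_numpy().sum(axis=1)
        for s, ok in zip(sums, pfm.defined):
            assert s == pytest.approx(1.0, abs=1e-9) if ok else s == 0.0
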