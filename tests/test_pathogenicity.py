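"""Consensus damage voting and ACMG/AMP evidence combining."""

import itertools

import pytest

from myxoseek import (
    Classification,
    EvidenceCodeSet,
    PredictorScores,
    PredictorThresholds,
    acmg_classify,
    consensus_damaging,
    damaging_votes,
)
from myxoseek.pathogenicity import ALL_EVIDENCE_CODES


class TestDamagingVotes:
    def test_all_damaging(self):
        s = PredictorScores(
            sift=0.01, polyphen2="D", phylop=2.0, gerp=5.1, mutationtaster="D", lrt="D"
        )
        assert damaging_votes(s) == 6

    def test_boundaries_are_strict(self):
        assert damaging_votes(PredictorScores(sift=0.1)) == 0
        assert damaging_votes(PredictorScores(sift=0.0999)) == 1
        assert damaging_votes(PredictorScores(phylop=0.95)) == 0
        assert damaging_votes(PredictorScores(gerp=4.0)) == 0

    def test_all_missing_abstain(self):
        assert damaging_votes(PredictorScores()) == 0

    def test_polyphen_p_counts(self):
        assert damaging_votes(PredictorScores(polyphen2="P")) == 1
        assert damaging_votes(PredictorScores(polyphen2="B")) == 0

    def test_monotone_in_evidence(self):
        base = PredictorScores(sift=0.5, polyphen2="B", phylop=0.0, gerp=0.0,
                               mutationtaster="N", lrt="N")
        v0 = damaging_votes(base)
        for extreme in (
            PredictorScores(sift=0.001, polyphen2="B", phylop=0.0, gerp=0.0,
                            mutationtaster="N", lrt="N"),
            PredictorScores(sift=0.5, polyphen2="D", phylop=0.0, gerp=0.0,
                            mutationtaster="N", lrt="N"),
            PredictorScores(sift=0.5, polyphen2="B", phylop=5.0, gerp=0.0,
                            mutationtaster="N", lrt="N"),
            PredictorScores(sift=0.5, polyphen2="B", phylop=0.0, gerp=6.0,
                            mutationtaster="N", lrt="N"),
        ):
            assert damaging_votes(extreme) >= v0


# coarse per-predictor states for the exhaustive consensus check
_STATES = {
    "damaging": PredictorScores(
        sift=0.01, polyphen2="D", phylop=2.0, gerp=5.0, mutationtaster="A", lrt="D"
    ),
    "benign": PredictorScores(
        sift=0.9, polyphen2="B", phylop=-1.0, gerp=0.0, mutationtaster="N", lrt="N"
    ),
    "missing": PredictorScores(),
}
_FIELDS = ["sift", "polyphen2", "phylop", "gerp", "mutationtaster", "lrt"]


class TestConsensus:
    def test_at_least_four(self):
        th = PredictorThresholds()
        four = PredictorScores(sift=0.01, polyphen2="D", phylop=2.0, gerp=5.0)
        three = PredictorScores(sift=0.01, polyphen2="D", phylop=2.0)
        assert consensus_damaging(four, th)
        assert not consensus_damaging(three, th)

    def test_exhaustive_coarse_states_match_count_oracle(self):
        """All 3^6 damaging/benign/missing predictor combinations agree with
        an independent predicate count; min_votes=4 behaves as 'at least'."""
        th = PredictorThresholds()
        for combo in itertools.product(_STATES, repeat=6):
            values = {
                f: getattr(_STATES[state], f) for f, state in zip(_FIELDS, combo)
            }
            scores = PredictorScores(**values)
            expected_votes = sum(1 for s in combo if s == "damaging")
            assert damaging_votes(scores, th) == expected_votes
            assert consensus_damaging(scores, th) is (expected_votes >= 4)

    def test_min_votes_validation(self):
        with pytest.raises(ValueError):
            PredictorThresholds(min_votes=0)
        with pytest.raises(ValueError):
            PredictorThresholds(min_votes=7)


# ---------------------------------------------------------------------------
# independent re-statement of the 2015 combining criteria, used as oracle
# ---------------------------------------------------------------------------

def _oracle_classify(codes):
    pvs = sum(c.startswith("PVS") for c in codes)
    ps = sum(c.startswith("PS") for c in codes)
    pm = sum(c.startswith("PM") for c in codes)
    pp = sum(c.startswith("PP") for c in codes)
    ba = sum(c.startswith("BA") for c in codes)
    bs = sum(c.startswith("BS") for c in codes)
    bp = sum(c.startswith("BP") for c in codes)

    pathogenic = (
        (pvs >= 1 and (ps >= 1 or pm >= 2 or (pm == 1 and pp == 1) or pp >= 2))
        or ps >= 2
        or (ps == 1 and (pm >= 3 or (pm == 2 and pp >= 2) or (pm == 1 and pp >= 4)))
    )
    likely_path = (
        (pvs == 1 and pm == 1)
        or (ps == 1 and 1 <= pm <= 2)
        or (ps == 1 and pp >= 2)
        or pm >= 3
        or (pm == 2 and pp >= 2)
        or (pm == 1 and pp >= 4)
    )
    benign = ba >= 1 or bs >= 2
    likely_benign = (bs == 1 and bp == 1) or bp >= 2

    if pathogenic or likely_path:
        if ba + bs + bp > 0:
            return "uncertain_significance"
        return "pathogenic" if pathogenic else "likely_pathogenic"
    if benign:
        return "benign"
    if likely_benign:
        return "likely_benign"
    return "uncertain_significance"


class TestAcmgClassify:
    @pytest.mark.parametrize(
        "codes,expected",
        [
            ({"PM1", "PM2"}, Classification.UNCERTAIN_SIGNIFICANCE),
            ({"PM1", "PM2", "PP3"}, Classification.UNCERTAIN_SIGNIFICANCE),
            ({"PM2", "BP4", "BP7"}, Classification.LIKELY_BENIGN),
            ({"BS1", "BP4"}, Classification.LIKELY_BENIGN),
            (set(), Classification.UNCERTAIN_SIGNIFICANCE),
            ({"PVS1", "PS1"}, Classification.PATHOGENIC),
            ({"PVS1", "PM2"}, Classification.LIKELY_PATHOGENIC),
            ({"PM1", "PM2", "PM4"}, Classification.LIKELY_PATHOGENIC),
            ({"BA1"}, Classification.BENIGN),
            ({"BS1", "BS2"}, Classification.BENIGN),
        ],
    )
    def test_known_code_sets(self, codes, expected):
        assert acmg_classify(codes) == expected

    def test_unknown_code_rejected(self):
        with pytest.raises(ValueError, match="PM9"):
            acmg_classify({"PM9"})

    def test_exhaustive_small_sets_match_oracle(self):
        """Every evidence set of size <= 3 agrees with the independently
        hand-coded rule table."""
        codes = sorted(ALL_EVIDENCE_CODES)
        for size in (0, 1, 2, 3):
            for combo in itertools.combinations(codes, size):
                got = acmg_classify(set(combo))
                assert got.value == _oracle_classify(combo), combo

    def test_one_sided_evidence_never_crosses(self):
        benign_only = [c for c in ALL_EVIDENCE_CODES if c[0] == "B"]
        path_only = [c for c in ALL_EVIDENCE_CODES if c[0] == "P"]
        for size in (1, 2, 3):
            for combo in itertools.combinations(sorted(benign_only), size):
                assert acmg_classify(set(combo)) in (
                    Classification.BENIGN,
                    Classification.LIKELY_BENIGN,
                    Classification.UNCERTAIN_SIGNIFICANCE,
                )
            for combo in itertools.combinations(sorted(path_only), size):
                assert acmg_classify(set(combo)) in (
                    Classification.PATHOGENIC,
                    Classification.LIKELY_PATHOGENIC,
                    Classification.UNCERTAIN_SIGNIFICANCE,
                )

    def test_supporting_codes_move_in_their_direction(self):
        """Adding PP never moves toward benign; adding BP never toward
        pathogenic (checked on all size-<=2 bases)."""
        order = {
            Classification.BENIGN: -2,
            Classification.LIKELY_BENIGN: -1,
            Classification.UNCERTAIN_SIGNIFICANCE: 0,
            Classification.LIKELY_PATHOGENIC: 1,
            Classification.PATHOGENIC: 2,
        }
        codes = sorted(ALL_EVIDENCE_CODES)
        for size in (0, 1, 2):
            for combo in itertools.combinations(codes, size):
                base = order[acmg_classify(set(combo))]
                if "PP5" not in combo:
                    with_pp = order[acmg_classify(set(combo) | {"PP5"})]
                    assert with_pp >= base or with_pp == 0
                if "BP5" not in combo:
                    with_bp = order[acmg_classify(set(combo) | {"BP5"})]
                    assert with_bp <= base or with_bp == 0

    def test_strict_profile_resolves_conflicts_to_uncertain(self):
        assert (
            acmg_classify({"PM2", "BP4", "BP7"}, profile="strict_acmg")
            == Classification.LIKELY_BENIGN
        )
        assert (
            acmg_classify({"PVS1", "PM1", "BS1", "BP4"}, profile="strict_acmg")
            == Classification.UNCERTAIN_SIGNIFICANCE
        )
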