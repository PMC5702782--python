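import math

import numpy as np
import pytest

from regionks.pswm import (
    DEFAULT_POSITION_FLOOR,
    PSWM,
    PromoterModel,
    build_pswm,
    load_promoter_model,
    pswm_from_consensus,
    read_meme_minimal,
    read_pswm_tsv,
    scan_region,
    scan_sequence,
    score_promoter,
    score_window,
    write_meme_minimal,
    write_pswm_tsv,
)
from regionks.regions import GenomicRegion

from conftest import random_dna

BASES = "ACGT"


# ---------------------------------------------------------------------------
# matrix construction


def test_consensus_normalization_forces_column_max_zero():
    m = build_pswm(["AA", "AT"], pseudocount=0.0)
    # column 1: A observed twice -> weight 0; all others floored
    assert m.weights[0, 0] == 0.0
    for b in (1, 2, 3):
        assert m.weights[0, b] == DEFAULT_POSITION_FLOOR
    # column 2: A and T tie at the max -> both 0, C/G floored
    assert m.weights[1, 0] == 0.0
    assert m.weights[1, 3] == 0.0
    assert m.weights[1, 1] == DEFAULT_POSITION_FLOOR
    assert m.weights[1, 2] == DEFAULT_POSITION_FLOOR


@pytest.mark.parametrize("pc", [0.0, 0.5, 1.0, 3.0])
def test_identity_alignment_consensus_scores_zero(pc):
    m = build_pswm(["ACGT", "ACGT"], pseudocount=pc)
    assert score_window(m, "ACGT") == pytest.approx(0.0, abs=1e-12)


def test_pseudocount_weight_formula_hand_value():
    # alignment AA/AT/AT/AT, pseudocount 1, uniform background:
    # unnormalized w(T,2) = log2((3 + 0.25)/(4 + 1)/0.25) = log2(2.6) and
    # w(A,2) = log2((1 + 0.25)/5/0.25) = log2(1.0); after consensus
    # normalization the difference is preserved.
    m = build_pswm(["AA", "AT", "AT", "AT"], pseudocount=1.0)
    t, a = m.weights[1, 3], m.weights[1, 0]
    assert t - a == pytest.approx(math.log2(2.6), abs=1e-12)
    assert t == 0.0  # T is the column-2 consensus


def test_column_max_invariant_and_validation():
    with pytest.raises(ValueError):
        PSWM(
            weights=np.array([[0.1, -1.0, -1.0, -1.0]]),
            background_freqs=np.full(4, 0.25),
        )
    with pytest.raises(ValueError):
        PSWM(
            weights=np.array([[0.0, -1.0, -1.0, -1.0]]),
            background_freqs=np.array([0.5, 0.5, 0.5, 0.5]),
        )


# ---------------------------------------------------------------------------
# window scoring


def test_consensus_window_scores_zero(toy_pswm):
    assert score_window(toy_pswm, toy_pswm.consensus) == pytest.approx(0.0)


def test_single_mismatch_additivity(toy_pswm):
    cons = toy_pswm.consensus
    for i in range(toy_pswm.width):
        for b, base in enumerate(BASES):
            if base == cons[i]:
                continue
            w = cons[:i] + base + cons[i + 1 :]
            assert score_window(toy_pswm, w) == pytest.approx(
                toy_pswm.weights[i, b], abs=1e-12
            )


def test_score_window_matches_per_position_sum(rng, toy_pswm):
    for _ in range(100):
        w = random_dna(rng, toy_pswm.width)
        expected = sum(
            toy_pswm.weights[i, BASES.index(ch)] for i, ch in enumerate(w)
        )
        assert score_window(toy_pswm, w) == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------------------
# composite promoter model


def _promoter():
    return PromoterModel(
        pswm_minus10=pswm_from_consensus("TATAAT", 0.9),
        pswm_minus35=pswm_from_consensus("TTGACA", 0.9),
        spacer_weights={15: -1.5, 16: -0.5, 17: 0.0, 18: -0.5, 19: -1.5},
        name="sigma70",
    )


def test_promoter_consensus_with_best_spacer_scores_zero():
    pm = _promoter()
    seq = "TTGACA" + "A" * 17 + "TATAAT" + "AA"
    assert score_promoter(pm, seq) == pytest.approx(0.0, abs=1e-12)


def test_promoter_spacer_independence_when_elements_identical():
    # single uninformative (all-N) elements: every spacer gives the same
    # element scores, so the best composite score is the max spacer weight
    # (normalized to 0)
    pm = PromoterModel(
        pswm_minus10=pswm_from_consensus("NNN", 0.9),
        pswm_minus35=pswm_from_consensus("NNN", 0.9),
        spacer_weights={2: -1.0, 3: 0.0, 4: -2.0},
    )
    assert score_promoter(pm, "ACGTACGTACGT") == pytest.approx(0.0)


def test_promoter_matches_bruteforce_spacer_enumeration(rng):
    pm = _promoter()
    for _ in range(25):
        seq = random_dna(rng, 60)
        best = -np.inf
        for sp, wsp in pm.spacer_weights.items():
            s35 = score_window(pm.pswm_minus35, seq[:6])
            s10 = score_window(pm.pswm_minus10, seq[6 + sp : 12 + sp])
            best = max(best, s35 + wsp + s10)
        assert score_promoter(pm, seq) == pytest.approx(best, abs=1e-12)


def test_promoter_spacer_weights_normalized_and_contiguous():
    pm = _promoter()
    assert max(pm.spacer_weights.values()) == 0.0
    with pytest.raises(ValueError):
        PromoterModel(
            pswm_minus10=pswm_from_consensus("TATAAT", 0.9),
            spacer_weights={15: 0.0, 17: -1.0},  # gap at 16
        )


# ---------------------------------------------------------------------------
# scanning


def _region(seq, rid="r"):
    return GenomicRegion(
        region_id=rid, seq=seq, chrom="chr", start=0, end=len(seq),
        region_class="other",
    )


def test_scan_window_count_both_strands(toy_pswm):
    s = scan_region(toy_pswm, _region("ACGTACGTAC"))  # L=10, w=4
    assert s.n == 2 * (10 - 4 + 1)


def test_scan_strand_symmetry(rng, toy_pswm):
    from regionks.pswm import reverse_complement

    for _ in range(10):
        seq = random_dna(rng, 50)
        a = np.sort(scan_sequence(toy_pswm, seq, strands="both"))
        b = np.sort(
            scan_sequence(toy_pswm, reverse_complement(seq), strands="both")
        )
        np.testing.assert_allclose(a, b, atol=1e-12)


def test_both_strand_pool_is_union_of_forward_scans(rng, toy_pswm):
    from regionks.pswm import reverse_complement

    for _ in range(20):
        seq = random_dna(rng, 40)
        pooled = np.sort(scan_sequence(toy_pswm, seq, strands="both"))
        manual = np.sort(
            np.concatenate(
                [
                    scan_sequence(toy_pswm, seq, strands="forward"),
                    scan_sequence(
                        toy_pswm,
                        reverse_complement(seq),
                        strands="forward",
                    ),
                ]
            )
        )
        np.testing.assert_allclose(pooled, manual, atol=1e-12)


def test_scan_region_too_short_errors(toy_pswm):
    with pytest.raises(ValueError, match="tiny"):
        scan_region(toy_pswm, _region("ACG", rid="tiny"))


def test_scanner_id_distinguishes_configurations(toy_pswm, consensus_pswm):
    assert toy_pswm.scanner_id("both") != toy_pswm.scanner_id("forward")
    assert toy_pswm.scanner_id("both") != consensus_pswm.scanner_id("both")


# ---------------------------------------------------------------------------
# I/O


def test_pswm_tsv_roundtrip(tmp_path, toy_pswm):
    path = tmp_path / "m.tsv"
    write_pswm_tsv(toy_pswm, path)
    back = read_pswm_tsv(path)
    np.testing.assert_allclose(back.weights, toy_pswm.weights, atol=1e-9)


def test_meme_minimal_roundtrip(tmp_path, consensus_pswm):
    path = tmp_path / "m.meme"
    write_meme_minimal([consensus_pswm], path)
    (back,) = read_meme_minimal(path)
    np.testing.assert_allclose(
        back.probabilities(), consensus_pswm.probabilities(), atol=1e-5
    )


def test_promoter_yaml_roundtrip(tmp_path):
    import yaml

    pm = _promoter()
    write_pswm_tsv(pm.pswm_minus35, tmp_path / "m35.tsv")
    write_pswm_tsv(pm.pswm_minus10, tmp_path / "m10.tsv")
    cfg = {
        "minus35": "m35.tsv",
        "minus10": "m10.tsv",
        "spacer_weights": {k: v for k, v in pm.spacer_weights.items()},
    }
    (tmp_path / "p.yaml").write_text(yaml.safe_dump(cfg))
    back = load_promoter_model(tmp_path / "p.yaml")
    assert back.spacer_weights == pm.spacer_weights
    for seq in ("TTGACA" + "A" * 17 + "TATAATAA",):
        assert score_promoter(back, seq) == pytest.approx(
            score_promoter(pm, seq), abs=1e-9
        )
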