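import numpy as np
import pandas as pd
import pytest

from kbcascade.motifs import (Alignment, align_pair, conserved_site_fraction,
                              load_kb_pwms, motif_prevalence, revcomp, scan,
                              window_conservation)


@pytest.fixture(scope="module")
def pwm(kb_pwms):
    return kb_pwms["KB1"]


def _random_seq(n, seed=0):
    rng = np.random.default_rng(seed)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


class TestScan:
    def test_consensus_at_offset_scores_relative_one(self, pwm):
        seq = _random_seq(200, 1)
        seq = seq[:37] + pwm.consensus + seq[37 + pwm.width:]
        hits = scan(seq, pwm, rel_threshold=0.99)
        fwd = hits[hits["strand"] == "+"]
        assert 37 in set(fwd["offset"])
        assert fwd.set_index("offset").loc[37, "rel_score"] == pytest.approx(1.0)

    def test_reverse_complement_reported_on_minus_strand(self, pwm):
        seq = _random_seq(200, 2)
        planted = revcomp(pwm.consensus)
        seq = seq[:80] + planted + seq[80 + pwm.width:]
        hits = scan(seq, pwm, rel_threshold=0.99)
        minus = hits[hits["strand"] == "-"]
        assert 80 in set(minus["offset"])

    def test_windows_containing_n_are_skipped(self, pwm):
        seq = pwm.consensus[:4] + "N" + pwm.consensus[5:]
        assert len(scan(seq, pwm, rel_threshold=0.0)) == 0

    def test_short_sequence_warns_and_returns_empty(self, pwm):
        with pytest.warns(UserWarning, match="shorter"):
            hits = scan("ACGT", pwm)
        assert len(hits) == 0

    def test_random_sequence_has_no_perfect_hits(self, pwm):
        hits = scan(_random_seq(1000, 3), pwm, rel_threshold=1.0)
        assert len(hits) == 0

    def test_scan_of_revcomp_mirrors_sites(self, pwm):
        seq = _random_seq(300, 4)
        fwd = scan(seq, pwm, rel_threshold=0.7)
        rev = scan(revcomp(seq), pwm, rel_threshold=0.7)
        n, w = len(seq), pwm.width
        mirrored = {(n - off - w, {"+": "-", "-": "+"}[s])
                    for off, s in zip(fwd["offset"], fwd["strand"])}
        assert mirrored == set(zip(rev["offset"], rev["strand"]))


class TestPrevalence:
    def test_strict_boundary_excludes_exact_threshold(self, kb_pwms):
        pwm = kb_pwms["KB1"]
        rng = np.random.default_rng(5)
        # 15 of 78 promoters with a planted site; threshold fraction = 15/78
        proms = {}
        for i in range(78):
            s = _random_seq(500, 100 + i)
            if i < 15:
                s = s[:100] + pwm.consensus + s[100 + pwm.width:]
            proms[f"g{i}"] = s
        res = motif_prevalence(proms, {"KB1": pwm}, rel_threshold=0.97,
                               prevalence_threshold=15 / 78)
        assert res.loc["KB1", "n_promoters_with_site"] == 15
        assert not res.loc["KB1", "selected"]
        res2 = motif_prevalence(proms, {"KB1": pwm}, rel_threshold=0.97,
                                prevalence_threshold=14 / 78)
        assert res2.loc["KB1", "selected"]

    def test_everywhere_and_nowhere(self, kb_pwms):
        pwm = kb_pwms["KB1"]
        proms = {f"g{i}": _random_seq(100, 200 + i)[:50] + pwm.consensus
                 for i in range(5)}
        res = motif_prevalence(proms, {"KB1": pwm}, rel_threshold=0.97)
        assert res.loc["KB1", "fraction"] == 1.0 and res.loc["KB1", "selected"]
        empty = {f"g{i}": "ACACAC" * 20 for i in range(5)}
        res0 = motif_prevalence(empty, {"KB1": pwm}, rel_threshold=0.99)
        assert res0.loc["KB1", "n_promoters_with_site"] == 0

    def test_empty_promoter_set_raises(self, kb_pwms):
        with pytest.raises(ValueError, match="empty"):
            motif_prevalence({}, kb_pwms)


def _enumerate_score(a, b, match=1, mismatch=-1, gap=-2):
    """Exhaustive recursion over all global alignments (tiny inputs only)."""
    if not a and not b:
        return 0
    best = -np.inf
    if a and b:
        s = match if a[0] == b[0] else mismatch
        best = max(best, s + _enumerate_score(a[1:], b[1:], match, mismatch, gap))
    if a:
        best = max(best, gap + _enumerate_score(a[1:], b, match, mismatch, gap))
    if b:
        best = max(best, gap + _enumerate_score(a, b[1:], match, mismatch, gap))
    return best


class TestAlign:
    def test_identical_sequences(self):
        seq = _random_seq(100, 6)
        aln = align_pair(seq, seq)
        assert aln.identity == 1.0
        assert "-" not in aln.aligned_a + aln.aligned_b
        assert aln.score == 100

    def test_single_substitution_identity(self):
        seq = _random_seq(100, 7)
        other = seq[:50] + ("A" if seq[50] != "A" else "C") + seq[51:]
        aln = align_pair(seq, other)
        assert aln.identity == pytest.approx(0.99)

    @pytest.mark.parametrize("seed", range(6))
    def test_score_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a = _random_seq(int(rng.integers(3, 8)), seed * 2 + 50)
        b = _random_seq(int(rng.integers(3, 8)), seed * 2 + 51)
        assert align_pair(a, b).score == _enumerate_score(a, b)

    def test_non_acgtn_raises(self):
        with pytest.raises(ValueError, match="non-ACGTN"):
            align_pair("ACGU", "ACGT")


class TestWindowConservation:
    def test_identical_gives_one(self):
        seq = _random_seq(1000, 8)
        aln = align_pair(seq, seq)
        assert window_conservation(aln, 500) == 1.0

    def test_boundary_truncation_denominator(self):
        # site at position 10: window truncated to [0, 35], 36 positions
        seq = _random_seq(1000, 9)
        mismatched = "".join("A" if c != "A" else "C" for c in seq[:18]) + seq[18:]
        aln = Alignment(seq, mismatched, 0.0)
        # positions 0..17 mismatch, 18..35 match -> identity 18/36
        assert window_conservation(aln, 10) == pytest.approx(18 / 36)

    def test_scrambled_ortholog_near_quarter_identity(self):
        seq = _random_seq(2000, 10)
        scrambled = _random_seq(2000, 11)
        aln = Alignment(seq, scrambled, 0.0)  # positional comparison
        idents = [window_conservation(aln, c) for c in range(200, 1800, 100)]
        assert abs(np.mean(idents) - 0.25) < 0.05

    def test_even_window_rejected(self):
        aln = align_pair("ACGTACGT", "ACGTACGT")
        with pytest.raises(ValueError, match="odd"):
            window_conservation(aln, 4, window=50)


class TestConservedFraction:
    def test_identical_ortholog_fully_conserved(self, kb_pwms):
        pwm = kb_pwms["KB1"]
        seq = _random_seq(1000, 12)
        seq = seq[:300] + pwm.consensus + seq[300 + pwm.width:]
        sites = scan(seq, pwm, rel_threshold=0.99)
        res = conserved_site_fraction("g", sites, {"sp": align_pair(seq, seq)},
                                      kb_pwms)
        assert res.percent_conserved == 100.0

    def test_destroyed_site_not_conserved(self, kb_pwms):
        pwm = kb_pwms["KB1"]
        seq = _random_seq(1000, 13)
        seq = seq[:300] + pwm.consensus + seq[300 + pwm.width:]
        # ortholog: flanks intact, site scrambled
        ortho = seq[:300] + _random_seq(pwm.width, 14) + seq[300 + pwm.width:]
        sites = scan(seq, pwm, rel_threshold=0.99)
        sites = sites[(sites["offset"] == 300) & (sites["strand"] == "+")]
        res = conserved_site_fraction("g", sites, {"sp": align_pair(seq, ortho)},
                                      kb_pwms)
        assert res.percent_conserved == 0.0

    def test_one_of_four_conserved_is_25_percent(self, kb_pwms):
        seq = _random_seq(1000, 15)
        # ortholog identical only around the first site's window
        ortho = _random_seq(1000, 16)
        ortho = ortho[:60] + seq[60:150] + ortho[150:]
        aln = Alignment(seq, ortho, 0.0)
        sites = pd.DataFrame({"offset": [100, 300, 500, 700],
                              "strand": "+", "motif_id": "KB1"})
        res = conserved_site_fraction("g", sites, {"sp": aln}, kb_pwms,
                                      require_ortholog_hit=False)
        assert res.percent_conserved == pytest.approx(25.0)

    def test_zero_sites_flagged_missing(self, kb_pwms):
        empty = pd.DataFrame(columns=["offset", "strand", "motif_id"])
        res = conserved_site_fraction("g", empty, {}, kb_pwms)
        assert res.n_total_sites == 0 and np.isnan(res.percent_conserved)


def test_conservation_monotone_in_divergence(kb_pwms):
    """Mean percent conserved never increases along a divergence grid."""
    from kbcascade.simulate import (SimulationConfig, generate_gene_models,
                                    make_truth, simulate_promoters)
    from kbcascade.motifs import scan_all
    cfg = SimulationConfig(n_genes=12, seed=19)
    gm = generate_gene_models(cfg)
    truth = make_truth(gm, cfg)
    means = []
    for d in (0.0, 0.2, 0.4):
        pcts = []
        for seed in range(2):
            c = cfg.replace(seed=100 + seed,
                            divergence_per_species={"sp": d})
            proms = simulate_promoters(gm, truth, kb_pwms, c)
            for gid, hseq in proms["human"].items():
                sites = scan_all(hseq, kb_pwms, 0.85)
                if len(sites) == 0:
                    continue
                aln = align_pair(hseq, proms["sp"][gid])
                res = conserved_site_fraction(gid, sites, {"sp": aln}, kb_pwms)
                pcts.append(res.percent_conserved)
        means.append(np.mean(pcts))
    assert means[0] >= means[1] >= means[2]
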